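"""Geometric detection of non-covalent interactions and thermostability profiles.

Interactions are detected from heavy atoms only, under explicit distance and
angle criteria per class:

* hydrogen bond: N/O/S donor to N/O acceptor, d <= 3.9 A, donor-centred angle
  theta > 90 deg, where theta is measured between the donor->antecedent and
  donor->acceptor directions (no hydrogens required);
* weak hydrogen bond: C-H...A with a carbon donor, 3.6 <= d <= 3.9 A and
  90 < theta < 130 deg;
* ionic: oppositely charged side-chain N/O pair within 4.0 A, counted once
  per residue pair;
* hydrophobic: apolar carbon pair within 4.0 A, counted per atom pair;
* aromatic: two rings (His/Phe/Tyr/Trp) with any ring-atom pair within
  4.0 A, counted once per ring pair.

Profiles summarise a structure the way thermophile/mesophile comparisons are
usually tabulated: absolute counts, relative values (percent of residues for
residue categories, per-residue density for interactions), and a scaled
occurrence column where the larger of two structures' relative values maps
to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import chemistry
from .structure import Residue, Structure

BACKBONE_NAMES = {"N", "CA", "C", "O"}

#: Table layout: category name -> kind ("residue" categories report percent,
#: "interaction" categories report per-residue density).
PROFILE_CATEGORIES: dict[str, str] = {
    "helix_residues": "residue",
    "sheet_residues": "residue",
    "proline_residues": "residue",
    "polar_residues": "residue",
    "charged_residues": "residue",
    "hydrophobic_residues": "residue",
    "hydrogen_bonds": "interaction",
    "weak_hydrogen_bonds": "interaction",
    "ionic_interactions": "interaction",
    "hydrophobic_contacts": "interaction",
    "aromatic_contacts": "interaction",
}


@dataclass
class InteractionCriteria:
    """Distance/angle thresholds per interaction class (angstroms, degrees)."""

    hbond_dmax: float = 3.9
    hbond_theta_min: float = 90.0
    weak_dmin: float = 3.6
    weak_dmax: float = 3.9
    weak_theta_lo: float = 90.0
    weak_theta_hi: float = 130.0
    ionic_dmax: float = 4.0
    hydrophobic_dmax: float = 4.0
    aromatic_dmax: float = 4.0
    charged_his: bool = False

    def __post_init__(self) -> None:
        for name in ("hbond_dmax", "weak_dmin", "weak_dmax", "ionic_dmax",
                     "hydrophobic_dmax", "aromatic_dmax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weak_dmin > self.weak_dmax:
            raise ValueError("weak_dmin must not exceed weak_dmax")
        for name in ("hbond_theta_min", "weak_theta_lo", "weak_theta_hi"):
            if not 0 <= getattr(self, name) <= 180:
                raise ValueError(f"{name} must lie in [0, 180] degrees")


@dataclass(frozen=True)
class Interaction:
    """One detected interaction between two residues."""

    kind: str  # hbond | weak_hbond | ionic | hydrophobic | aromatic
    res_a: tuple[str, int, str]
    res_b: tuple[str, int, str]
    atom_a: str
    atom_b: str
    distance: float
    angle: float | None = None


def _angle_deg(center: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    u, v = p1 - center, p2 - center
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _adjacent_backbone(r1: Residue, a1: str, r2: Residue, a2: str) -> bool:
    """Backbone-backbone pair of sequence neighbours (covalent geometry)."""
    return (r1.chain == r2.chain and abs(r1.seq - r2.seq) == 1
            and a1 in BACKBONE_NAMES and a2 in BACKBONE_NAMES)


class _AtomTable:
    """Flat per-role atom arrays for KD-tree searches."""

    def __init__(self, entries: list[tuple[Residue, str, np.ndarray]]):
        self.entries = entries
        self.xyz = np.array([e[2] for e in entries]) if entries else np.empty((0, 3))
        self.tree = cKDTree(self.xyz) if entries else None


def _collect(structure: Structure, selector) -> list[tuple[Residue, str, np.ndarray]]:
    out = []
    for r in structure.polymer_residues:
        for a in r.atoms:
            extra = selector(r, a)
            if extra is not None:
                out.append((r, a.name, a.coords) if extra is True else (r, a.name, a.coords, extra))
    return out


def detect_interactions(
    structure: Structure,
    criteria: InteractionCriteria | None = None,
    strict: bool = False,
) -> list[Interaction]:
    """Detect every intra-protein non-covalent interaction in a structure.

    A pair is reported at most once per class; intra-residue pairs and
    covalently bonded backbone pairs of adjacent residues are excluded.
    In strict mode a polymer residue type absent from the chemistry tables
    raises; otherwise it is silently treated as contributing no typed atoms.
    """
    criteria = criteria or InteractionCriteria()
    residues = structure.polymer_residues
    if strict:
        for r in residues:
            if r.name not in chemistry.AA3_TO_1:
                raise KeyError(f"no chemistry entry for residue type {r.name!r}")

    out: list[Interaction] = []
    out.extend(_detect_hbonds(residues, criteria, weak=False))
    out.extend(_detect_hbonds(residues, criteria, weak=True))
    out.extend(_detect_ionic(residues, criteria))
    aromatic, atom_rings, contact_pairs = _detect_aromatic(residues, criteria)
    out.extend(aromatic)
    out.extend(_detect_hydrophobic(residues, criteria, atom_rings, contact_pairs))
    return out


def _detect_hbonds(residues: list[Residue], c: InteractionCriteria, weak: bool) -> list[Interaction]:
    donors = []  # (residue, donor atom, antecedent atom)
    for r in residues:
        dmap = chemistry.WEAK_DONORS if weak else chemistry.donors_for(r.name)
        for dn, an in dmap.items():
            d, a = r.atom(dn), r.atom(an)
            if d is not None and a is not None:
                donors.append((r, d, a))
    acceptors = [(r, a) for r in residues
                 for nm in chemistry.acceptors_for(r.name)
                 if (a := r.atom(nm)) is not None]
    if not donors or not acceptors:
        return []

    dxyz = np.array([d.coords for _, d, _ in donors])
    axyz = np.array([a.coords for _, a in acceptors])
    dmax = c.weak_dmax if weak else c.hbond_dmax
    dmin = c.weak_dmin if weak else 0.0
    pairs = cKDTree(dxyz).query_ball_tree(cKDTree(axyz), dmax)

    found: list[Interaction] = []
    seen: set[tuple] = set()
    for i, js in enumerate(pairs):
        rd, datom, ante = donors[i]
        for j in js:
            ra, aatom = acceptors[j]
            if rd.key == ra.key:
                continue
            if _adjacent_backbone(rd, datom.name, ra, aatom.name):
                continue
            dist = float(np.linalg.norm(datom.coords - aatom.coords))
            if dist < dmin or dist > dmax:
                continue
            theta = _angle_deg(datom.coords, ante.coords, aatom.coords)
            if weak:
                if not (c.weak_theta_lo < theta < c.weak_theta_hi):
                    continue
            elif theta <= c.hbond_theta_min:
                continue
            key = (rd.key, datom.name, ra.key, aatom.name)
            if key in seen:
                continue
            seen.add(key)
            found.append(Interaction("weak_hbond" if weak else "hbond",
                                     rd.key, ra.key, datom.name, aatom.name, dist, theta))
    return found


def _detect_ionic(residues: list[Residue], c: InteractionCriteria) -> list[Interaction]:
    pos_atoms = dict(chemistry.POSITIVE_ATOMS)
    if c.charged_his:
        pos_atoms = {**pos_atoms, **chemistry.POSITIVE_ATOMS_HIS}
    neg = [(r, a) for r in residues for nm in chemistry.NEGATIVE_ATOMS.get(r.name, ())
           if (a := r.atom(nm)) is not None]
    pos = [(r, a) for r in residues for nm in pos_atoms.get(r.name, ())
           if (a := r.atom(nm)) is not None]
    if not neg or not pos:
        return []
    pairs = cKDTree(np.array([a.coords for _, a in neg])).query_ball_tree(
        cKDTree(np.array([a.coords for _, a in pos])), c.ionic_dmax)
    best: dict[tuple, Interaction] = {}
    for i, js in enumerate(pairs):
        rn, an = neg[i]
        for j in js:
            rp, ap = pos[j]
            dist = float(np.linalg.norm(an.coords - ap.coords))
            if dist > c.ionic_dmax:
                continue
            key = (rn.key, rp.key)
            if key not in best or dist < best[key].distance:
                best[key] = Interaction("ionic", rn.key, rp.key, an.name, ap.name, dist)
    return list(best.values())


def _detect_aromatic(residues: list[Residue], c: InteractionCriteria):
    rings = []  # (residue, [atoms]); ring id = index into this list
    atom_rings: dict[tuple, set[int]] = {}
    for r in residues:
        for names in chemistry.AROMATIC_RINGS.get(r.name, ()):
            atoms = [a for nm in names if (a := r.atom(nm)) is not None]
            if len(atoms) >= 3:
                rid = len(rings)
                rings.append((r, atoms))
                for a in atoms:
                    atom_rings.setdefault((r.key, a.name), set()).add(rid)
    found = []
    contact_pairs: set[frozenset[int]] = set()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            r1, atoms1 = rings[i]
            r2, atoms2 = rings[j]
            if r1.key == r2.key:
                continue
            d = np.linalg.norm(
                np.array([a.coords for a in atoms1])[:, None, :]
                - np.array([a.coords for a in atoms2])[None, :, :], axis=-1)
            if d.min() <= c.aromatic_dmax:
                ii, jj = np.unravel_index(int(d.argmin()), d.shape)
                contact_pairs.add(frozenset((i, j)))
                found.append(Interaction("aromatic", r1.key, r2.key,
                                         atoms1[ii].name, atoms2[jj].name, float(d.min())))
    return found, atom_rings, contact_pairs


def _detect_hydrophobic(residues: list[Residue], c: InteractionCriteria,
                        atom_rings: dict[tuple, set[int]],
                        contact_pairs: set[frozenset[int]]) -> list[Interaction]:
    apolar = [(r, a) for r in residues
              for nm in chemistry.APOLAR_CARBONS.get(r.name, ())
              if (a := r.atom(nm)) is not None]
    if len(apolar) < 2:
        return []
    xyz = np.array([a.coords for _, a in apolar])
    tree = cKDTree(xyz)
    found = []
    for i, j in sorted(tree.query_pairs(c.hydrophobic_dmax)):
        r1, a1 = apolar[i]
        r2, a2 = apolar[j]
        if r1.key == r2.key:
            continue
        # pairs within a ring pair already typed aromatic are not re-counted
        rings1 = atom_rings.get((r1.key, a1.name), ())
        rings2 = atom_rings.get((r2.key, a2.name), ())
        if any(frozenset((x, y)) in contact_pairs for x in rings1 for y in rings2):
            continue
        dist = float(np.linalg.norm(a1.coords - a2.coords))
        found.append(Interaction("hydrophobic", r1.key, r2.key, a1.name, a2.name, dist))
    return found


# ---------------------------------------------------------------------------
# Profiles and comparison tables
# ---------------------------------------------------------------------------

@dataclass
class StructureProfile:
    """Absolute counts and relative values per category for one structure."""

    name: str
    denominator: int
    counts: dict[str, int]
    denominator_kind: str = "resolved"
    relative: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        missing = set(PROFILE_CATEGORIES) - set(self.counts)
        if missing:
            raise ValueError(f"profile missing categories: {sorted(missing)}")
        self.relative = {}
        for cat, kind in PROFILE_CATEGORIES.items():
            v = self.counts[cat] / self.denominator
            self.relative[cat] = 100.0 * v if kind == "residue" else v

    @classmethod
    def from_counts(cls, name: str, counts: dict[str, int], denominator: int,
                    denominator_kind: str = "resolved") -> "StructureProfile":
        return cls(name, denominator, dict(counts), denominator_kind)


def structure_profile(
    s: Structure,
    criteria: InteractionCriteria | None = None,
    denominator: str = "resolved",
    full_length: int | None = None,
    residue_classes: dict[str, frozenset[str]] | None = None,
) -> StructureProfile:
    """Build a thermostability-style profile of one structure.

    ``denominator`` is ``"resolved"`` (modelled polymer residues; always used
    for interaction densities) or ``"full_length"`` (requires ``full_length``;
    applied to residue-category percentages only in the sense that the stated
    denominator is recorded; interaction densities keep n_resolved).
    """
    from .structure import classify_residues

    classes = residue_classes or chemistry.DEFAULT_RESIDUE_CLASSES
    comp = classify_residues(s, scheme=classes, strict=False)
    ss = list(s.ss_labels.values())
    inter = detect_interactions(s, criteria)
    by_kind = {k: 0 for k in ("hbond", "weak_hbond", "ionic", "hydrophobic", "aromatic")}
    for it in inter:
        by_kind[it.kind] += 1
    counts = {
        "helix_residues": ss.count("H"),
        "sheet_residues": ss.count("E"),
        "proline_residues": comp["proline"],
        "polar_residues": comp["polar"],
        "charged_residues": comp["charged"],
        "hydrophobic_residues": comp["hydrophobic"],
        "hydrogen_bonds": by_kind["hbond"],
        "weak_hydrogen_bonds": by_kind["weak_hbond"],
        "ionic_interactions": by_kind["ionic"],
        "hydrophobic_contacts": by_kind["hydrophobic"],
        "aromatic_contacts": by_kind["aromatic"],
    }
    if denominator == "resolved":
        denom = s.n_resolved
    elif denominator == "full_length":
        if full_length is None:
            raise ValueError("denominator='full_length' requires full_length")
        denom = full_length
        warnings.warn("residue-category percentages use the full-length denominator; "
                      "interaction densities conventionally use resolved residues",
                      stacklevel=2)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return StructureProfile(s.name or "structure", denom, counts, denominator)


@dataclass
class ComparisonTable:
    """Two profiles side by side with per-category scaled occurrences."""

    profile_a: StructureProfile
    profile_b: StructureProfile

    def __post_init__(self) -> None:
        if set(self.profile_a.counts) != set(self.profile_b.counts):
            raise ValueError("profiles cover different categories")

    def scaled(self, category: str) -> tuple[float, float]:
        ra = self.profile_a.relative[category]
        rb = self.profile_b.relative[category]
        m = max(ra, rb)
        if m == 0 or ra == rb:
            return (100.0, 100.0)
        # the larger value maps to exactly 100; the smaller keeps the ratio
        if ra < rb:
            return (100.0 * ra / rb, 100.0)
        return (100.0, 100.0 * rb / ra)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cat, kind in PROFILE_CATEGORIES.items():
            sa, sb = self.scaled(cat)
            ndec = 2 if kind == "residue" else 3
            rows.append({
                "category": cat,
                "abs_a": self.profile_a.counts[cat],
                "rel_a": round(self.profile_a.relative[cat], ndec),
                "abs_b": self.profile_b.counts[cat],
                "rel_b": round(self.profile_b.relative[cat], ndec),
                "scaled_a": round(sa, 1),
                "scaled_b": round(sb, 1),
            })
        return pd.DataFrame(rows)


def compare_profiles(p1: StructureProfile, p2: StructureProfile) -> ComparisonTable:
    """Pair two profiles; per category the larger relative value scales to 100."""
    return ComparisonTable(p1, p2)
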