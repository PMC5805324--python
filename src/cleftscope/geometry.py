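"""Static-structure geometry of the two-domain peptidase fold.

Inter-domain motion of M49-family peptidases is conventionally tracked by two
C-alpha distances across the cleft, d1 (E142-K404 in the thermophilic enzyme's
numbering) and d2 (E330-K404), together with the backbone radius of gyration.
Conformers with similar (d1, d2) are grouped into named classes (e.g. the
crystal form versus compact/extended simulation forms).  This module also
covers rigid superposition (Kabsch), polar contacts of a bound peptide, and
the zinc coordination sphere with carboxylate denticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Residue, Structure, StructureError

#: Default d1/d2 anchor residues (author numbering of the thermophilic enzyme).
DEFAULT_PAIRS: tuple[tuple[int, int], tuple[int, int]] = ((142, 404), (330, 404))

#: Default upper/lower domain residue ranges (author numbering).
DEFAULT_DOMAINS: dict[str, tuple[tuple[int, int], ...]] = {
    "upper": ((264, 298), (350, 541)),
    "lower": ((32, 263), (299, 349), (542, 555)),
}


@dataclass
class DomainDefinition:
    """Named, disjoint residue-range sets defining structural domains."""

    ranges: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAINS))

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, spans in self.ranges.items():
            members = set()
            for lo, hi in spans:
                members.update(range(lo, hi + 1))
            if members & seen:
                raise ValueError(f"domain {name!r} overlaps another domain")
            seen |= members

    def members(self, name: str) -> set[int]:
        return {i for lo, hi in self.ranges[name] for i in range(lo, hi + 1)}


@dataclass
class GeometrySnapshot:
    """One frame's compactness coordinates: d1, d2 (A) and backbone Rg (A)."""

    d1: float
    d2: float
    rg: float


@dataclass
class ConformerClassScheme:
    """Labelled (d1, d2) reference points with an assignment tolerance in A."""

    references: dict[str, tuple[float, float]]
    tolerance: float = 1.0

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("scheme needs at least one reference")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class ZincSite:
    """Zinc first coordination sphere: ligands, CN, and carboxylate denticity."""

    zinc_coords: np.ndarray
    ligands: list[dict]  # element, res (key), res_name, atom, distance
    cutoff: float
    denticity: dict[tuple[str, int, str], str] = field(default_factory=dict)

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)

    @property
    def n_water_ligands(self) -> int:
        return sum(1 for lg in self.ligands if lg["is_water"])


# ---------------------------------------------------------------------------
# Distances / gyration
# ---------------------------------------------------------------------------

def domain_distances(
    s: Structure,
    pairs: tuple[tuple[int, int], ...] = DEFAULT_PAIRS,
    chain: str | None = None,
) -> tuple[float, ...]:
    """C-alpha distances for each (res_i, res_j) pair, in angstroms."""
    out = []
    for ri, rj in pairs:
        a, b = s.ca(ri, chain), s.ca(rj, chain)
        out.append(float(np.linalg.norm(a.coords - b.coords)))
    return tuple(out)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance from the centroid (unit masses by default)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("need a non-empty (n, 3) coordinate set")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def backbone_coords(s: Structure, frame: np.ndarray | None = None) -> np.ndarray:
    """Coordinates of backbone (N, CA, C, O) atoms of polymer residues."""
    idx = []
    i = 0
    for r in s.residues:
        for a in r.atoms:
            if r.kind == "polymer" and a.name in ("N", "CA", "C", "O"):
                idx.append(i)
            i += 1
    allc = s.coords() if frame is None else np.asarray(frame)
    return allc[idx]


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose_rmsd(
    a: np.ndarray, b: np.ndarray,
    correspondence: list[tuple[int, int]] | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of b onto a (Kabsch).

    Returns ``(rmsd, rotation, translation)`` such that
    ``b @ rotation.T + translation`` best fits ``a`` over the paired points.
    The rotation is proper (det = +1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if correspondence is not None:
        ia, ib = zip(*correspondence)
        a, b = a[list(ia)], b[list(ib)]
    if a.shape != b.shape or a.shape[0] < 3:
        raise ValueError("need >= 3 paired points of equal count")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0) < 2 or np.linalg.matrix_rank(b0) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(a0, b0)
    R = rot.as_matrix()
    t = ca - cb @ R.T
    rmsd = float(rssd / np.sqrt(len(a)))
    return rmsd, R, t


def read_correspondence(path) -> list[tuple[int, int]]:
    """Two-column TSV of paired residue numbers -> list of (res_a, res_b)."""
    pairs = []
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        x, y = line.split()[:2]
        pairs.append((int(x), int(y)))
    return pairs


def domain_ca_rmsd(sa: Structure, sb: Structure,
                   residue_pairs: list[tuple[int, int]]) -> float:
    """C-alpha RMSD between two structures over a residue-number pairing."""
    xa = np.array([sa.ca(i).coords for i, _ in residue_pairs])
    xb = np.array([sb.ca(j).coords for _, j in residue_pairs])
    rmsd, _, _ = superpose_rmsd(xa, xb)
    return rmsd


# ---------------------------------------------------------------------------
# Conformer classification
# ---------------------------------------------------------------------------

def classify_conformer(snap: GeometrySnapshot | tuple[float, float],
                       scheme: ConformerClassScheme) -> str:
    """Nearest (d1, d2) reference within tolerance, else "unassigned".

    Ties (equal distance to several references) resolve to the reference
    listed first in the scheme.
    """
    d1, d2 = (snap.d1, snap.d2) if isinstance(snap, GeometrySnapshot) else snap
    best_label, best_dist = "unassigned", np.inf
    for label, (r1, r2) in scheme.references.items():
        dist = float(np.hypot(d1 - r1, d2 - r2))
        if dist <= scheme.tolerance and dist < best_dist:
            best_label, best_dist = label, dist
    return best_label


# ---------------------------------------------------------------------------
# Ligand polar contacts
# ---------------------------------------------------------------------------

def ligand_polar_contacts(s: Structure, ligand: Residue | str | None = None,
                          dmax: float = 3.2) -> list[dict]:
    """Polar (N/O-N/O) ligand-protein contacts within dmax, sorted by distance.

    ``ligand`` may be a residue, a residue name (e.g. a bound dipeptide's
    het code), or None to use the structure's single ligand entity.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    lig_residues: list[Residue]
    if ligand is None:
        lig_residues = s.ligands
    elif isinstance(ligand, Residue):
        lig_residues = [ligand]
    else:
        lig_residues = [r for r in s.ligands if r.name == ligand]
    if not lig_residues:
        raise StructureError(f"ligand selector {ligand!r} matches nothing")

    contacts = []
    for lig in lig_residues:
        for la in lig.atoms:
            if la.element not in ("N", "O"):
                continue
            for pr in s.polymer_residues:
                for pa in pr.atoms:
                    if pa.element not in ("N", "O"):
                        continue
                    d = float(np.linalg.norm(la.coords - pa.coords))
                    if d <= dmax:
                        contacts.append({
                            "partner_res": pr.key, "partner_res_name": pr.name,
                            "partner_label": pr.label,
                            "ligand_atom": la.name, "partner_atom": pa.name,
                            "distance": d,
                        })
    return sorted(contacts, key=lambda c: c["distance"])


# ---------------------------------------------------------------------------
# Zinc coordination sphere
# ---------------------------------------------------------------------------

CARBOXYLATE_OXYGENS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}


def zinc_site(s: Structure, cutoff: float = 2.6,
              frame: np.ndarray | None = None) -> ZincSite:
    """Describe the zinc first coordination sphere at a distance cutoff.

    Ligand atoms are protein N/O/S and water O within ``cutoff`` of the zinc.
    Each nearby Glu/Asp carboxylate is labelled mono- or bidentate according
    to whether one or both carboxylate oxygens fall inside the cutoff.
    """
    zinc_atoms = [a for r in s.metals for a in r.atoms if a.element.upper() == "ZN"]
    if not zinc_atoms:
        raise StructureError("no zinc atom in structure")
    zn = zinc_atoms[0]

    coords = s.coords() if frame is None else np.asarray(frame)
    index_of = {}
    i = 0
    for r in s.residues:
        for a in r.atoms:
            index_of[(r.key, a.name)] = i
            i += 1
    zpos = coords[index_of[(next(r for r in s.metals if zn in r.atoms).key, zn.name)]]

    ligands = []
    denticity: dict[tuple[str, int, str], str] = {}
    for r in s.residues:
        if r.kind == "metal":
            continue
        for a in r.atoms:
            if a.element not in ("N", "O", "S"):
                continue
            d = float(np.linalg.norm(coords[index_of[(r.key, a.name)]] - zpos))
            if d <= cutoff:
                ligands.append({
                    "element": a.element, "res": r.key, "res_name": r.name,
                    "label": r.label, "atom": a.name, "distance": d,
                    "is_water": r.kind == "water",
                })
        if r.name in CARBOXYLATE_OXYGENS:
            n_in = 0
            for nm in CARBOXYLATE_OXYGENS[r.name]:
                a = r.atom(nm)
                if a is not None:
                    d = float(np.linalg.norm(coords[index_of[(r.key, nm)]] - zpos))
                    if d <= cutoff:
                        n_in += 1
            denticity[r.key] = {0: "none", 1: "mono", 2: "bi"}[n_in]
    return ZincSite(zinc_coords=zpos, ligands=sorted(ligands, key=lambda x: x["distance"]),
                    cutoff=cutoff, denticity=denticity)
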