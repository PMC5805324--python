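"""Per-frame analytics over MD-style trajectories.

A :class:`Trajectory` is a topology (:class:`~cleftscope.structure.Structure`)
plus an ``(n_frames, n_atoms, 3)`` coordinate array; the native interchange
format is multi-model PDB so that synthetic trajectories are self-contained
text.  Analyses cover the quantities used to characterise inter-domain
breathing of a two-domain metallopeptidase: d1/d2/Rg traces, ligand-protein
hydrogen-bond populations, zinc coordination dynamics with carboxylate
denticity, water residence at the zinc site, cleft-water counting with the
water-expulsion free-energy estimate, accelerated-MD boost parameters, and
interval summaries of externally computed per-frame energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemistry
from .geometry import DEFAULT_PAIRS, GeometrySnapshot, backbone_coords, radius_of_gyration, zinc_site
from .structure import Structure, StructureError, read_structure


@dataclass
class Trajectory:
    """Topology plus frame coordinates; ``frame_interval`` is metadata only."""

    topology: Structure
    frames: np.ndarray
    frame_interval: float = 1.0  # arbitrary time units per frame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (n_frames, n_atoms, 3) with >= 1 frame")
        if self.frames.shape[1] != self.topology.n_atoms():
            raise ValueError("frame atom count differs from topology")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @classmethod
    def from_structure(cls, s: Structure, frame_interval: float = 1.0) -> "Trajectory":
        return cls(s, s.model_coords, frame_interval)

    @classmethod
    def from_pdb(cls, path: str | Path, frame_interval: float = 1.0,
                 keep_hydrogens: bool = True) -> "Trajectory":
        # hydrogens are kept by default: the explicit-H angle criterion of
        # hbond_populations needs them when the trajectory provides them
        return cls.from_structure(
            read_structure(path, fmt="pdb", keep_hydrogens=keep_hydrogens), frame_interval)

    def atom_index(self) -> dict[tuple[tuple[str, int, str], str], int]:
        idx = {}
        i = 0
        for r in self.topology.residues:
            for a in r.atoms:
                idx[(r.key, a.name)] = i
                i += 1
        return idx


# ---------------------------------------------------------------------------
# Geometry trace
# ---------------------------------------------------------------------------

def geometry_trace(traj: Trajectory, pairs=DEFAULT_PAIRS, chain: str | None = None) -> pd.DataFrame:
    """Per-frame d1, d2 (C-alpha pair distances) and backbone Rg, as a table."""
    s = traj.topology
    idx = traj.atom_index()
    pair_idx = []
    for ri, rj in pairs:
        a = s.ca(ri, chain)
        b = s.ca(rj, chain)
        pair_idx.append((idx[((a.chain, a.res_seq, a.icode), "CA")],
                         idx[((b.chain, b.res_seq, b.icode), "CA")]))
    bb_idx = []
    i = 0
    for r in s.residues:
        for a in r.atoms:
            if r.kind == "polymer" and a.name in ("N", "CA", "C", "O"):
                bb_idx.append(i)
            i += 1

    cols: dict[str, np.ndarray] = {}
    for k, (ia, ib) in enumerate(pair_idx, start=1):
        cols[f"d{k}"] = np.linalg.norm(traj.frames[:, ia] - traj.frames[:, ib], axis=1)
    cols["rg"] = np.array([radius_of_gyration(traj.frames[f][bb_idx])
                           for f in range(traj.n_frames)])
    df = pd.DataFrame(cols)
    df.index.name = "frame"
    return df


def snapshots(trace: pd.DataFrame) -> list[GeometrySnapshot]:
    return [GeometrySnapshot(row.get("d1", np.nan), row.get("d2", np.nan), row["rg"])
            for _, row in trace.iterrows()]


# ---------------------------------------------------------------------------
# Hydrogen-bond populations
# ---------------------------------------------------------------------------

@dataclass
class HBondPopulation:
    """Per-bond and per-residue hydrogen-bond populations over a trajectory.

    ``bonds`` rows carry donor/acceptor identities and the population
    percentage N(frames with bond)/N(frames) * 100.  ``residue_sums`` sums
    populations per (protein residue, role), so a residue engaging several
    simultaneous bonds can exceed 100%.
    """

    bonds: pd.DataFrame
    n_frames: int
    dist_cutoff: float = 3.0
    angle_cutoff: float = 135.0
    threshold: float = 5.0
    heavy_atom_fallback: bool = False

    def residue_sums(self, apply_threshold: bool = True) -> pd.DataFrame:
        if self.bonds.empty:
            return pd.DataFrame(columns=["residue", "role", "population"])
        g = (self.bonds.groupby(["protein_residue", "protein_role"])["population"]
             .sum().reset_index())
        g.columns = ["residue", "role", "population"]
        if apply_threshold:
            g = g[g["population"] >= self.threshold].reset_index(drop=True)
        return g


def _donor_hydrogens(residue, donor_name: str):
    """Hydrogens bonded to a donor, by topology distance (< 1.25 A)."""
    d = residue.atom(donor_name)
    out = []
    for a in residue.atoms:
        if a.element == "H" and float(np.linalg.norm(a.coords - d.coords)) < 1.25:
            out.append(a)
    return out


def hbond_populations(
    traj: Trajectory,
    dist_cutoff: float = 3.0,
    angle_cutoff: float = 135.0,
    threshold: float = 5.0,
    frames: slice | None = None,
) -> HBondPopulation:
    """Ligand-protein hydrogen-bond populations over (a range of) frames.

    Candidate bonds pair ligand donors with protein acceptors and vice versa.
    With explicit hydrogens the criterion is heavy-atom distance <=
    ``dist_cutoff`` and D-H...A angle >= ``angle_cutoff``; without hydrogens a
    heavy-atom fallback applies the antecedent-centred angle > 90 deg and the
    result is flagged.  ``frames`` restricts the analysis to a frame range.
    """
    s = traj.topology
    if not s.ligands:
        raise StructureError("trajectory topology has no ligand entity")
    idx = traj.atom_index()
    sel = frames if frames is not None else slice(None)
    F = traj.frames[sel]
    nF = F.shape[0]
    if nF == 0:
        raise ValueError("empty frame selection")

    has_h = any(a.element == "H" for a in s.atoms())

    # candidate (donor residue, donor atom, H list, antecedent, acceptor residue,
    #            acceptor atom, protein residue, protein role)
    candidates = []
    prot = s.polymer_residues
    lig = s.ligands
    for ld in lig:
        ldonors = {**chemistry.BACKBONE_DONOR, **chemistry.SIDECHAIN_DONORS.get(ld.name, {})}
        for dn, an in ldonors.items():
            if ld.atom(dn) is None:
                continue
            for pr in prot:
                for acc in chemistry.acceptors_for(pr.name):
                    if pr.atom(acc) is not None:
                        candidates.append((ld, dn, an, pr, acc, pr, "acceptor"))
    for pr in prot:
        for dn, an in chemistry.donors_for(pr.name).items():
            if pr.atom(dn) is None:
                continue
            for la in lig:
                for acc in chemistry.acceptors_for(la.name):
                    if la.atom(acc) is not None:
                        candidates.append((pr, dn, an, la, acc, pr, "donor"))

    rows = []
    for dres, dn, an, ares, acc, pres, role in candidates:
        di = idx[(dres.key, dn)]
        ai = idx[(ares.key, acc)]
        dvec = F[:, ai] - F[:, di]
        dist = np.linalg.norm(dvec, axis=1)
        present = dist <= dist_cutoff
        if has_h:
            hyds = _donor_hydrogens(dres, dn)
            if hyds:
                ok = np.zeros(nF, dtype=bool)
                for h in hyds:
                    hi = idx[(dres.key, h.name)]
                    u = F[:, di] - F[:, hi]
                    v = F[:, ai] - F[:, hi]
                    cosang = np.einsum("ij,ij->i", u, v) / (
                        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    ok |= ang >= angle_cutoff
                present &= ok
            else:
                present &= _antecedent_ok(F, idx, dres, dn, an, ai)
        else:
            present &= _antecedent_ok(F, idx, dres, dn, an, ai)
        n = int(present.sum())
        if n:
            rows.append({
                "donor_residue": dres.label, "donor_atom": dn,
                "acceptor_residue": ares.label, "acceptor_atom": acc,
                "protein_residue": pres.label, "protein_role": role,
                "n_frames_present": n, "population": 100.0 * n / nF,
            })
    bonds = pd.DataFrame(rows, columns=[
        "donor_residue", "donor_atom", "acceptor_residue", "acceptor_atom",
        "protein_residue", "protein_role", "n_frames_present", "population"])
    return HBondPopulation(bonds, nF, dist_cutoff, angle_cutoff, threshold,
                           heavy_atom_fallback=not has_h)


def _antecedent_ok(F, idx, dres, dn, an, ai) -> np.ndarray:
    if dres.atom(an) is None:
        return np.ones(F.shape[0], dtype=bool)
    di, ni = idx[(dres.key, dn)], idx[(dres.key, an)]
    u = F[:, ni] - F[:, di]
    v = F[:, ai] - F[:, di]
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 90.0


# ---------------------------------------------------------------------------
# Zinc dynamics
# ---------------------------------------------------------------------------

@dataclass
class ZincDynamics:
    """Per-frame zinc coordination number and carboxylate denticity labels."""

    coordination_numbers: np.ndarray
    denticity: pd.DataFrame  # one column per carboxylate residue label
    cutoff: float

    def denticity_fractions(self, residue_label: str) -> dict[str, float]:
        col = self.denticity[residue_label]
        return (col.value_counts() / len(col)).to_dict()

    def switch_frame(self, residue_label: str, frm: str = "bi", to: str = "mono") -> int | None:
        """First frame at which a residue's denticity changes from ``frm`` to ``to``."""
        col = self.denticity[residue_label].to_numpy()
        for f in range(1, len(col)):
            if col[f - 1] == frm and col[f] == to:
                return f
        return None


def zinc_dynamics(traj: Trajectory, cutoff: float = 2.6) -> ZincDynamics:
    """Zinc coordination sphere evaluated in every frame."""
    s = traj.topology
    cns = np.zeros(traj.n_frames, dtype=int)
    dent_rows = []
    for f in range(traj.n_frames):
        site = zinc_site(s, cutoff=cutoff, frame=traj.frames[f])
        cns[f] = site.coordination_number
        row = {}
        for key, label in site.denticity.items():
            res = s.find_residue(key[1], key[0], key[2])
            row[res.label] = label
        dent_rows.append(row)
    return ZincDynamics(cns, pd.DataFrame(dent_rows), cutoff)


# ---------------------------------------------------------------------------
# Water residence
# ---------------------------------------------------------------------------

@dataclass
class ResidenceTable:
    """Frames each water spends in the zinc coordination sphere."""

    counts: dict[str, int]  # water label -> frames present
    n_frames: int
    min_frames: int = 200

    def report(self) -> dict[str, int]:
        return {w: n for w, n in self.counts.items() if n >= self.min_frames}


def water_residence(traj: Trajectory, cutoff: float = 2.6, min_frames: int = 200) -> ResidenceTable:
    """Count frames each water oxygen spends within ``cutoff`` of the zinc."""
    s = traj.topology
    zn_atoms = [(r, a) for r in s.metals for a in r.atoms if a.element.upper() == "ZN"]
    if not zn_atoms:
        raise StructureError("no zinc atom in topology")
    idx = traj.atom_index()
    zi = idx[(zn_atoms[0][0].key, zn_atoms[0][1].name)]
    counts = {}
    for w in s.waters:
        oa = next((a for a in w.atoms if a.element == "O"), None)
        if oa is None:
            continue
        wi = idx[(w.key, oa.name)]
        d = np.linalg.norm(traj.frames[:, wi] - traj.frames[:, zi], axis=1)
        counts[f"{w.name}{w.seq}"] = int((d <= cutoff).sum())
    return ResidenceTable(counts, traj.n_frames, min_frames)


# ---------------------------------------------------------------------------
# Cleft waters and the expulsion estimate
# ---------------------------------------------------------------------------

@dataclass
class CleftRegion:
    """Union of spheres around cleft-lining residues (C-alpha centres)."""

    residues: tuple[int, ...]
    radius: float = 8.0
    chain: str | None = None


def cleft_waters(traj: Trajectory, region: CleftRegion) -> np.ndarray:
    """Per-frame count of waters whose O lies inside the cleft region."""
    s = traj.topology
    idx = traj.atom_index()
    centers = []
    for rnum in region.residues:
        a = s.ca(rnum, region.chain)
        centers.append(idx[((a.chain, a.res_seq, a.icode), "CA")])
    wat_idx = [idx[(w.key, a.name)] for w in s.waters
               for a in w.atoms if a.element == "O"]
    counts = np.zeros(traj.n_frames, dtype=int)
    if not wat_idx:
        return counts
    W = traj.frames[:, wat_idx]  # (F, nw, 3)
    C = traj.frames[:, centers]  # (F, nc, 3)
    d = np.linalg.norm(W[:, :, None, :] - C[:, None, :, :], axis=-1)
    inside = (d <= region.radius).any(axis=2)
    return inside.sum(axis=1)


def phase_means(counts: np.ndarray, labels) -> dict[str, float]:
    """Mean per-frame count per phase label (e.g. open/closed)."""
    counts = np.asarray(counts)
    labels = np.asarray(labels)
    return {lab: float(counts[labels == lab].mean()) for lab in np.unique(labels)}


def expulsion_energy(n_open: float, n_closed: float,
                     e_lo: float = 1.2, e_hi: float = 2.3) -> tuple[float, float]:
    """Free-energy range for expelling (n_open - n_closed) cleft waters.

    Uses per-water release energies ``e_lo``..``e_hi`` kcal/mol; a negative
    water difference yields a signed result with a warning.
    """
    dn = n_open - n_closed
    if dn < 0:
        warnings.warn("n_open < n_closed: expulsion estimate is negative", stacklevel=2)
    lo, hi = dn * e_lo, dn * e_hi
    return (lo, hi) if lo <= hi else (hi, lo)


# ---------------------------------------------------------------------------
# Accelerated-MD boost parameters
# ---------------------------------------------------------------------------

@dataclass
class AMDParams:
    """Dual-boost accelerated-MD thresholds and roughness parameters.

    The dihedral threshold adds ``e_r`` kcal/mol per residue to the average
    dihedral energy; the total-potential threshold adds ``e_a`` kcal/mol per
    atom to the average total potential energy.  Roughness parameters follow
    the conventional recipe alpha_t = e_r*n_res/5, alpha_T = e_a*n_atoms.
    """

    mean_total_E: float
    mean_dih_E: float
    n_res: int
    n_atoms: int
    e_r: float = 1.0
    e_a: float = 0.1
    dih_threshold: float = field(init=False)
    total_threshold: float = field(init=False)
    alpha_t: float = field(init=False)
    alpha_T: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_res < 1 or self.n_atoms < 1:
            raise ValueError("n_res and n_atoms must be >= 1")
        self.dih_threshold = self.mean_dih_E + self.e_r * self.n_res
        self.total_threshold = self.mean_total_E + self.e_a * self.n_atoms
        self.alpha_t = self.e_r * self.n_res / 5.0
        self.alpha_T = self.e_a * self.n_atoms


def amd_boost_params(mean_total_E: float, mean_dih_E: float, n_res: int, n_atoms: int,
                     e_r: float = 1.0, e_a: float = 0.1) -> AMDParams:
    """Compute dual-boost aMD parameters from cMD average energies."""
    return AMDParams(mean_total_E, mean_dih_E, n_res, n_atoms, e_r, e_a)


# ---------------------------------------------------------------------------
# Interval energy summaries
# ---------------------------------------------------------------------------

@dataclass
class EnergyIntervalSummary:
    """Consecutive-interval means and sample SDs of a per-frame energy series."""

    intervals: pd.DataFrame  # start, stop, n, mean, sd, partial
    interval_frames: int

    def formatted(self, ndec: int = 1) -> list[str]:
        return [format_mean_sd(r["mean"], r["sd"], ndec) for _, r in self.intervals.iterrows()]


def format_mean_sd(mean: float, sd: float, ndec: int = 1) -> str:
    return f"{mean:.{ndec}f} (±{sd:.{ndec}f})"


def interval_energy_summary(series, interval_frames: int) -> EnergyIntervalSummary:
    """Tile a per-frame energy series into consecutive intervals.

    Each interval reports mean and sample SD (ddof=1); a trailing interval
    shorter than ``interval_frames`` is kept and flagged partial.
    """
    if interval_frames < 2:
        raise ValueError("interval_frames must be >= 2")
    x = np.asarray(series, dtype=float)
    rows = []
    for start in range(0, len(x), interval_frames):
        chunk = x[start:start + interval_frames]
        rows.append({
            "start": start, "stop": start + len(chunk), "n": len(chunk),
            "mean": float(chunk.mean()),
            "sd": float(chunk.std(ddof=1)) if len(chunk) > 1 else 0.0,
            "partial": len(chunk) < interval_frames,
        })
    return EnergyIntervalSummary(pd.DataFrame(rows), interval_frames)
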