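"""Seeded generators for toy structures, breathing trajectories, and rate data.

Every pipeline stage in this package can be exercised without downloads:
the generators here emit chemically plausible but deliberately minimal
structures (reduced side chains on a sparse spatial grid of "interaction
islands") together with a ground-truth manifest listing every planted
feature, so that analysis operations can be checked for exact recovery and
zero false positives.

Geometry discipline: each island hosts exactly one planted feature; islands
are separated by ~30 A so that no atom pair across islands can satisfy any
default criterion; planted geometries satisfy their criterion with margin,
decoys violate it with margin.  Structures are non-physical (no force-field
realism) by design.

All randomness flows from a single ``numpy.random.default_rng(seed)`` per
artifact; identical specs and seeds give byte-identical PDB output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, Residue, Structure

#: Residue numbers with fixed meanings in generated structures (cleft anchors
#: and ligand-contact partners mirror the enzyme's author numbering).
RESERVED_NUMBERS = {142, 318, 330, 346, 404, 450}

_GRID = 30.0  # island spacing, A


class GeometryRequestError(ValueError):
    """Raised when a spec asks for geometry that cannot satisfy the criteria."""


@dataclass
class ToyStructureSpec:
    """Planted-feature counts and geometries for a static toy structure."""

    n_salt_bridges: int = 7
    n_salt_decoys: int = 4
    n_hbonds: int = 5
    n_hbond_decoys: int = 2
    n_weak_hbonds: int = 3
    n_hydrophobic: int = 4
    n_hydrophobic_decoys: int = 2
    n_aromatic: int = 2
    salt_bridge_distance: float = 3.2
    salt_decoy_distance: float = 4.5
    hbond_distance: float = 2.9
    hbond_decoy_distance: float = 4.3
    weak_hbond_distance: float = 3.75
    hydrophobic_distance: float = 3.8
    hydrophobic_decoy_distance: float = 4.5
    aromatic_distance: float = 3.8
    include_zinc: bool = True
    zinc_his_distance: float = 2.1
    zinc_glu_distances: tuple[float, float] = (2.0, 2.26)
    zinc_water_distance: float = 2.2
    include_ligand: bool = True
    n_cleft_waters: int = 12
    n_outside_waters: int = 8
    cleft_radius: float = 8.0
    d1: float = 22.6
    d2: float = 27.0
    seed: int = 0

    def validate(self) -> None:
        for nm in ("n_salt_bridges", "n_salt_decoys", "n_hbonds", "n_hbond_decoys",
                   "n_weak_hbonds", "n_hydrophobic", "n_hydrophobic_decoys",
                   "n_aromatic", "n_cleft_waters", "n_outside_waters"):
            if getattr(self, nm) < 0:
                raise GeometryRequestError(f"{nm} must be >= 0")
        if not self.salt_bridge_distance <= 3.8:
            raise GeometryRequestError("salt bridges must sit at <= 3.8 A (4.0 cutoff, 0.2 margin)")
        if self.salt_decoy_distance < 4.2:
            raise GeometryRequestError("salt decoys must sit at >= 4.2 A")
        if not self.hbond_distance <= 3.7:
            raise GeometryRequestError("planted H-bonds must sit at <= 3.7 A")
        if not 3.6 <= self.weak_hbond_distance <= 3.9:
            raise GeometryRequestError("weak H-bond distance must lie in [3.6, 3.9] A")
        if not self.hydrophobic_distance <= 3.8 or self.hydrophobic_decoy_distance < 4.2:
            raise GeometryRequestError("hydrophobic plant <= 3.8 A, decoys >= 4.2 A")
        if self.aromatic_distance > 3.8:
            raise GeometryRequestError("aromatic ring-atom distance must be <= 3.8 A")


class _Builder:
    """Accumulates residues with automatic numbering and atom serials."""

    def __init__(self):
        self.residues: list[Residue] = []
        self._next_seq = 1
        self._next_serial = 1
        self._used: set[tuple[str, int]] = set()

    def next_seq(self, chain: str = "A") -> int:
        while self._next_seq in RESERVED_NUMBERS or (chain, self._next_seq) in self._used:
            self._next_seq += 1
        n = self._next_seq
        self._next_seq += 1
        return n

    def add(self, name: str, atoms: list[tuple[str, str, np.ndarray]],
            seq: int | None = None, chain: str = "A", kind: str = "polymer") -> Residue:
        seq = self.next_seq(chain) if seq is None else seq
        if (chain, seq) in self._used:
            raise GeometryRequestError(f"residue number {chain}/{seq} already in use")
        self._used.add((chain, seq))
        res = Residue(name=name, chain=chain, seq=seq, kind=kind)
        for aname, el, xyz in atoms:
            res.atoms.append(Atom(
                serial=self._next_serial, name=aname, element=el,
                altloc="", res_name=name, chain=chain, res_seq=seq, icode="",
                coords=np.asarray(xyz, dtype=float), is_hetero=(kind != "polymer"),
            ))
            self._next_serial += 1
        self.residues.append(res)
        return res


def _bb(u: np.ndarray, start: float = 3.6) -> list[tuple[str, str, np.ndarray]]:
    """Minimal backbone trailing along unit direction u from a side-chain tip."""
    u = np.asarray(u, dtype=float)
    p = np.array([0.0, 1.0, 0.0]) if abs(u[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return [
        ("CA", "C", start * u + 0.25 * p),
        ("N", "N", (start + 1.3) * u + 1.0 * p),
        ("C", "C", (start + 0.7) * u - 1.1 * p + np.array([0, 0, 0.3])),
        ("O", "O", (start + 1.8) * u - 1.5 * p + np.array([0, 0, 0.3])),
    ]


def _shift(atoms, origin):
    origin = np.asarray(origin, dtype=float)
    return [(n, e, np.asarray(x) + origin) for n, e, x in atoms]


# --- island builders (tip atom of residue A at island origin, partner tip at
#     +x * distance; bodies trail away from the partner) ----------------------

_X, _NX = np.array([1.0, 0, 0]), np.array([-1.0, 0, 0])


def _island_ionic(b: _Builder, origin, d: float):
    glu = [("OE1", "O", np.zeros(3)), ("CD", "C", np.array([-1.25, 0.3, 0])),
           ("CG", "C", np.array([-2.4, 0.0, 0])), ("CB", "C", np.array([-3.5, 0.3, 0]))]
    glu += _bb(_NX, 4.6)
    # CZ placed so the angle CZ-NH1-OE1 is ~60 deg: the contact stays purely
    # ionic (the donor-centred H-bond angle criterion fails)
    arg = [("NH1", "N", np.array([d, 0, 0])), ("CZ", "C", np.array([d - 0.68, 1.17, 0])),
           ("CD", "C", np.array([d + 1.0, 2.0, 0])), ("CB", "C", np.array([d + 2.2, 2.4, 0]))]
    arg += _shift(_bb(_X, 3.6), [d, 0, 0])
    ra = b.add("GLU", _shift(glu, origin))
    rb = b.add("ARG", _shift(arg, origin))
    return ra, rb


def _island_hbond(b: _Builder, origin, d: float):
    ser = [("OG", "O", np.zeros(3)), ("CB", "C", np.array([-1.4, 0.3, 0]))] + _bb(_NX, 2.9)
    asn = [("OD1", "O", np.array([d, 0, 0])), ("CG", "C", np.array([d + 1.25, 0.3, 0])),
           ("CB", "C", np.array([d + 2.5, 0.0, 0]))] + _shift(_bb(_X, 3.7), [d, 0, 0])
    ra = b.add("SER", _shift(ser, origin))
    rb = b.add("ASN", _shift(asn, origin))
    return ra, rb


def _island_weak_hbond(b: _Builder, origin, d: float, theta_deg: float = 110.0):
    # donor is the GLY alpha-carbon; antecedent N sits along -x, the acceptor
    # at theta from the donor->antecedent direction
    t = np.radians(180.0 - theta_deg)
    acc = d * np.array([np.cos(t), np.sin(t), 0.0])
    gly = [("CA", "C", np.zeros(3)), ("N", "N", np.array([-1.46, 0, 0])),
           ("C", "C", np.array([-0.5, -1.3, 0.2])), ("O", "O", np.array([-1.6, -1.7, 0.2]))]
    asn = [("OD1", "O", acc), ("CG", "C", acc + np.array([1.25, 0.3, 0])),
           ("CB", "C", acc + np.array([2.5, 0.0, 0]))] + _shift(_bb(_X, 3.7), acc)
    ra = b.add("GLY", _shift(gly, origin))
    rb = b.add("ASN", _shift(asn, origin))
    return ra, rb


def _island_hydrophobic(b: _Builder, origin, d: float):
    ala_a = [("CB", "C", np.zeros(3))] + _bb(_NX, 1.52)
    ala_b = _shift([("CB", "C", np.zeros(3))] + _bb(_X, 1.52), [d, 0, 0])
    ra = b.add("ALA", _shift(ala_a, origin))
    rb = b.add("ALA", _shift(ala_b, origin))
    return ra, rb


_RING_NAMES = ["CZ", "CE1", "CD1", "CG", "CD2", "CE2"]


def _island_aromatic(b: _Builder, origin, d: float):
    def ring(center, phase):
        return [(nm, "C", center + 1.39 * np.array([np.cos(np.radians(phase + 60 * k)),
                                                    np.sin(np.radians(phase + 60 * k)), 0]))
                for k, nm in enumerate(_RING_NAMES)]
    ring_a = ring(np.array([-1.39, 0, 0]), 0.0)       # nearest vertex (CZ) at origin
    ring_b = ring(np.array([d + 1.39, 0, 0]), 180.0)  # mirrored, CZ at (d, 0, 0)
    phe_a = ring_a + [("CB", "C", np.array([-4.28, 0.3, 0]))] + _bb(_NX, 5.6)
    phe_b = ring_b + [("CB", "C", np.array([d + 4.28, 0.3, 0]))] + _shift(_bb(_X, 5.6), [d, 0, 0])
    ra = b.add("PHE", _shift(phe_a, origin))
    rb = b.add("PHE", _shift(phe_b, origin))
    return ra, rb


def _zinc_site_atoms(spec: "ToyStructureSpec", b: _Builder, origin,
                     water_seq_start: int, glu_bidentate: bool = True):
    origin = np.asarray(origin, dtype=float)
    dh = spec.zinc_his_distance
    dg1, dg2 = spec.zinc_glu_distances
    b.add("ZN", [("ZN", "Zn", origin)], seq=601, kind="metal")
    # histidines truncated after NE2/CD2/CG: the imidazole N coordinates the
    # metal but cannot be typed as an H-bond donor (no CE1 antecedent)
    his1 = [("NE2", "N", np.array([dh, 0, 0])), ("CD2", "C", np.array([dh + 1.2, 0.7, 0])),
            ("CG", "C", np.array([dh + 2.4, 0.4, 0]))] + _shift(_bb(_X, 3.8), [dh, 0, 0])
    his2 = [("NE2", "N", np.array([-dh, 0, 0])), ("CD2", "C", np.array([-dh - 1.2, 0.7, 0])),
            ("CG", "C", np.array([-dh - 2.4, 0.4, 0]))] + _shift(_bb(_NX, 3.8), [-dh, 0, 0])
    oe2_r = dg2 if glu_bidentate else 3.4
    glu = [("OE1", "O", np.array([0, dg1, 0])),
           ("OE2", "O", np.array([oe2_r * 0.465, oe2_r * 0.885, 0])),
           ("CD", "C", np.array([0.52, dg1 + 1.1, 0])),
           ("CG", "C", np.array([0.5, dg1 + 2.3, 0])),
           ("CB", "C", np.array([0.5, dg1 + 3.5, 0])),
           ("CA", "C", np.array([0.6, dg1 + 4.7, 0])),
           ("N", "N", np.array([1.4, dg1 + 5.5, 0])),
           ("C", "C", np.array([-0.5, dg1 + 5.4, 0.3])),
           ("O", "O", np.array([-0.6, dg1 + 6.5, 0.5]))]
    h1 = b.add("HIS", _shift(his1, origin))
    h2 = b.add("HIS", _shift(his2, origin))
    ge = b.add("GLU", _shift(glu, origin))
    wat = b.add("HOH", [("O", "O", origin + [0, -spec.zinc_water_distance, 0])],
                seq=water_seq_start, kind="water")
    far = b.add("HOH", [("O", "O", origin + [0, -3.4, 0])],
                seq=water_seq_start + 1, kind="water")
    return h1, h2, ge, wat, far


def _ligand_site(b: _Builder, origin):
    """Bound Ala-Lys dipeptide with four polar contacts (2.7/2.8/2.8/3.1 A)."""
    origin = np.asarray(origin, dtype=float)
    ala = [("N", "N", [-1.2, 1.0, 0]), ("CA", "C", [-0.5, -0.2, 0]),
           ("C", "C", [1.0, -0.2, 0]), ("O", "O", [1.6, 0.9, 0]), ("CB", "C", [-1.1, -1.4, 0])]
    lys = [("N", "N", [1.7, -1.3, 0]), ("CA", "C", [3.1, -1.3, 0]),
           ("C", "C", [3.8, -2.6, 0]), ("O", "O", [3.3, -3.6, 0]),
           ("CB", "C", [3.9, -0.1, 0]), ("NZ", "N", [5.3, -0.1, 0])]
    b.add("ALA", _shift([(n, e, np.array(x, dtype=float)) for n, e, x in ala], origin),
          seq=701, chain="B", kind="ligand")
    b.add("LYS", _shift([(n, e, np.array(x, dtype=float)) for n, e, x in lys], origin),
          seq=702, chain="B", kind="ligand")
    # protein partners: Arg450 twice (to Ala O), Lys346 (to Lys O), Leu318 (to Ala N)
    arg = [("NH1", "N", [1.6, 3.7, 0]), ("NH2", "N", [3.5926, 3.2749, 0]),
           ("CZ", "C", [2.6, 4.4, 0]), ("CD", "C", [2.6, 5.8, 0]),
           ("CB", "C", [2.7, 7.0, 0]), ("CA", "C", [2.8, 8.2, 0]),
           ("N", "N", [3.6, 9.0, 0]), ("C", "C", [1.7, 9.0, 0.3]), ("O", "O", [1.6, 10.1, 0.4])]
    lysp = [("NZ", "N", [3.3, -6.3, 0]), ("CE", "C", [3.3, -7.6, 0]),
            ("CB", "C", [3.3, -8.8, 0]), ("CA", "C", [3.4, -10.0, 0]),
            ("N", "N", [4.2, -10.8, 0]), ("C", "C", [2.3, -10.9, 0.3]), ("O", "O", [2.2, -12.0, 0.4])]
    leu = [("N", "N", [-4.0, 1.0, 0]), ("CA", "C", [-5.4, 1.2, 0]),
           ("C", "C", [-6.1, 2.4, 0.3]), ("O", "O", [-7.3, 2.5, 0.4])]
    decoy = [("OD1", "O", [1.6, 0.9, 3.6]), ("CG", "C", [1.6, 1.1, 4.9]),
             ("CB", "C", [1.6, 0.8, 6.2]), ("CA", "C", [1.7, 1.0, 7.5]),
             ("N", "N", [2.5, 1.8, 8.0]), ("C", "C", [0.7, 0.3, 8.3]), ("O", "O", [0.6, 0.6, 9.4])]
    conv = lambda at: _shift([(n, e, np.array(x, dtype=float)) for n, e, x in at], origin)
    b.add("ARG", conv(arg), seq=450)
    b.add("LYS", conv(lysp), seq=346)
    b.add("LEU", conv(leu), seq=318)
    b.add("ASN", conv(decoy))


def _cleft_site(spec: "ToyStructureSpec", b: _Builder, origin, rng, water_seq_start: int):
    origin = np.asarray(origin, dtype=float)
    anchors = []
    for dx in (-1.0, 1.0):
        gly = [("CA", "C", np.array([dx, 0, 0])), ("N", "N", np.array([dx, 1.4, 0])),
               ("C", "C", np.array([dx + 1.2, -0.8, 0])), ("O", "O", np.array([dx + 1.3, -2.0, 0]))]
        anchors.append(b.add("GLY", _shift(gly, origin)))
    seq = water_seq_start
    for _ in range(spec.n_cleft_waters):
        v = rng.normal(size=3)
        pos = origin + (v / np.linalg.norm(v)) * rng.uniform(2.5, 6.5)
        b.add("HOH", [("O", "O", pos)], seq=seq, kind="water")
        seq += 1
    for _ in range(spec.n_outside_waters):
        v = rng.normal(size=3)
        pos = origin + (v / np.linalg.norm(v)) * rng.uniform(10.5, 13.0)
        b.add("HOH", [("O", "O", pos)], seq=seq, kind="water")
        seq += 1
    return anchors


def make_toy_structure(spec: ToyStructureSpec | None = None) -> tuple[Structure, dict]:
    """Generate a toy structure plus a ground-truth manifest.

    The manifest lists planted interaction counts per class (with residue
    pairs and distances), decoy counts, the zinc-site composition, ligand
    polar-contact distances, cleft-water placement, and the d1/d2 anchors.
    """
    spec = spec or ToyStructureSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    manifest: dict = {"seed": spec.seed, "interactions": {}, "decoys": {},
                      "pairs": {k: [] for k in ("ionic", "hbond", "weak_hbond",
                                                "hydrophobic", "aromatic")}}

    def row(y):
        # island origins along one row, one plant or decoy per cell
        k = 0
        while True:
            yield np.array([_GRID * k, y, 0.0])
            k += 1

    cells = row(0.0)
    for _ in range(spec.n_salt_bridges):
        ra, rb = _island_ionic(b, next(cells), spec.salt_bridge_distance)
        manifest["pairs"]["ionic"].append([ra.seq, rb.seq, spec.salt_bridge_distance])
    for _ in range(spec.n_salt_decoys):
        _island_ionic(b, next(cells), spec.salt_decoy_distance)

    cells = row(_GRID)
    for _ in range(spec.n_hbonds):
        ra, rb = _island_hbond(b, next(cells), spec.hbond_distance)
        manifest["pairs"]["hbond"].append([ra.seq, rb.seq, spec.hbond_distance])
    for _ in range(spec.n_hbond_decoys):
        _island_hbond(b, next(cells), spec.hbond_decoy_distance)

    cells = row(2 * _GRID)
    for _ in range(spec.n_weak_hbonds):
        ra, rb = _island_weak_hbond(b, next(cells), spec.weak_hbond_distance)
        manifest["pairs"]["weak_hbond"].append([ra.seq, rb.seq, spec.weak_hbond_distance])

    cells = row(3 * _GRID)
    for _ in range(spec.n_hydrophobic):
        ra, rb = _island_hydrophobic(b, next(cells), spec.hydrophobic_distance)
        manifest["pairs"]["hydrophobic"].append([ra.seq, rb.seq, spec.hydrophobic_distance])
    for _ in range(spec.n_hydrophobic_decoys):
        _island_hydrophobic(b, next(cells), spec.hydrophobic_decoy_distance)

    cells = row(4 * _GRID)
    for _ in range(spec.n_aromatic):
        ra, rb = _island_aromatic(b, next(cells), spec.aromatic_distance)
        manifest["pairs"]["aromatic"].append([ra.seq, rb.seq, spec.aromatic_distance])

    manifest["interactions"] = {
        "ionic": spec.n_salt_bridges, "hbond": spec.n_hbonds,
        "weak_hbond": spec.n_weak_hbonds, "hydrophobic": spec.n_hydrophobic,
        "aromatic": spec.n_aromatic,
    }
    manifest["decoys"] = {"ionic": spec.n_salt_decoys, "hbond": spec.n_hbond_decoys,
                          "hydrophobic": spec.n_hydrophobic_decoys}

    if spec.include_zinc:
        _, _, ge, _, _ = _zinc_site_atoms(spec, b, [0.0, 5 * _GRID, 0.0], water_seq_start=801)
        manifest["zinc"] = {"coordination_number": 5, "n_water_ligands": 1,
                            "glu_denticity": {str(ge.seq): "bi"}}
    if spec.include_ligand:
        _ligand_site(b, [_GRID * 2, 6 * _GRID, 0.0])
        manifest["ligand_contacts"] = [2.7, 2.8, 2.8, 3.1]

    anchors = _cleft_site(spec, b, np.array([0.0, 8 * _GRID, 0.0]), rng, water_seq_start=901)
    manifest["cleft"] = {"anchor_residues": [a.seq for a in anchors],
                         "n_inside": spec.n_cleft_waters,
                         "n_outside": spec.n_outside_waters,
                         "radius": spec.cleft_radius}

    base = np.array([0.0, 10 * _GRID, 0.0])
    e142 = base
    k404 = base + np.array([spec.d1, 0, 0])
    e330 = k404 + np.array([0.0, spec.d2, 0])
    for name, seq, pos in (("GLU", 142, e142), ("LYS", 404, k404), ("GLU", 330, e330)):
        b.add(name, [("CA", "C", pos), ("N", "N", pos + [0, 1.4, 0.2]),
                     ("C", "C", pos + [1.2, -0.7, 0.2]), ("O", "O", pos + [1.3, -1.9, 0.2])],
              seq=seq)
    manifest["anchors"] = {"d1": spec.d1, "d2": spec.d2, "pairs": [[142, 404], [330, 404]]}

    s = Structure(b.residues, name="toy")
    manifest["n_polymer_residues"] = s.n_resolved
    manifest["n_atoms"] = s.n_atoms()
    return s, manifest


# ---------------------------------------------------------------------------
# Breathing trajectory
# ---------------------------------------------------------------------------

@dataclass
class BondSpec:
    """One planted ligand-protein hydrogen bond with a target occupancy."""

    res_name: str  # protein residue type (GLU/ASP acceptors, SER/ASN donors)
    res_seq: int
    role: str  # protein role: "acceptor" or "donor"
    occupancy_pct: float


@dataclass
class TrajectorySpec:
    """Schedules for a synthetic open/close breathing trajectory."""

    n_frames: int = 100
    phases: tuple[tuple[str, int], ...] = (("open", 50), ("closed", 50))
    d1_targets: dict = field(default_factory=lambda: {"open": 22.6, "closed": 15.4})
    d1_series: np.ndarray | None = None  # overrides phases for d1 only
    d2: float = 27.0
    bonds: tuple[BondSpec, ...] = (
        BondSpec("GLU", 240, "acceptor", 100.0),
        BondSpec("GLU", 240, "acceptor", 100.0),
        BondSpec("ASP", 310, "acceptor", 40.0),
        BondSpec("ASN", 321, "donor", 23.0),
    )
    cleft_waters: dict = field(default_factory=lambda: {"open": 90, "closed": 40})
    n_outside_waters: int = 10
    cleft_radius: float = 8.0
    zinc_water_frames: tuple[int, ...] = (50, 25, 10)
    denticity_switch_frame: int = 35
    zinc_cutoff_hint: float = 2.6
    seed: int = 0

    def validate(self) -> None:
        if self.d1_series is None and sum(n for _, n in self.phases) != self.n_frames:
            raise GeometryRequestError("phase lengths must sum to n_frames")
        for bs in self.bonds:
            if not 0 <= bs.occupancy_pct <= 100:
                raise GeometryRequestError("occupancy must lie in [0, 100]%")
            if bs.role not in ("acceptor", "donor"):
                raise GeometryRequestError(f"unknown bond role {bs.role!r}")
        if any(f > self.n_frames for f in self.zinc_water_frames):
            raise GeometryRequestError("water residence exceeds n_frames")
        if not 0 < self.denticity_switch_frame <= self.n_frames:
            raise GeometryRequestError("denticity switch frame out of range")

    def phase_labels(self) -> np.ndarray:
        labels = []
        for lab, n in self.phases:
            labels.extend([lab] * n)
        if len(labels) < self.n_frames:
            labels.extend([labels[-1]] * (self.n_frames - len(labels)))
        return np.array(labels[:self.n_frames])


def make_breathing_trajectory(spec: TrajectorySpec | None = None):
    """Generate a multi-model synthetic trajectory plus its manifest.

    Frames realise the d1 schedule exactly; each planted hydrogen bond is
    present in exactly ``round(occ/100 * n_frames)`` frames (chosen by the
    seeded RNG); zinc waters enter/leave the coordination sphere for their
    scheduled frame counts; the bidentate glutamate becomes monodentate at
    the scheduled switch frame; cleft-water counts follow the phase schedule.

    Returns ``(Trajectory, manifest)``.  The trajectory's topology carries
    frame 0; write it with :func:`cleftscope.structure.write_pdb`.
    """
    from .trajectory import Trajectory

    spec = spec or TrajectorySpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nF = spec.n_frames
    labels = spec.phase_labels()
    if spec.d1_series is not None:
        d1_series = np.asarray(spec.d1_series, dtype=float)
        if len(d1_series) != nF:
            raise GeometryRequestError("d1_series length must equal n_frames")
    else:
        d1_series = np.array([spec.d1_targets[lab] for lab in labels])

    b = _Builder()
    moves: list[tuple[Residue, np.ndarray]] = []  # (residue, per-frame offset array)

    # --- d1/d2 anchors (K404 slides along x) -------------------------------
    base = np.array([0.0, 0.0, 0.0])
    for name, seq, pos in (("GLU", 142, base),
                           ("LYS", 404, base + [d1_series[0], 0, 0]),
                           ("GLU", 330, base + [d1_series[0], spec.d2, 0])):
        r = b.add(name, [("CA", "C", np.array(pos, dtype=float)),
                         ("N", "N", np.array(pos) + [0, 1.4, 0.2]),
                         ("C", "C", np.array(pos) + [1.2, -0.7, 0.2]),
                         ("O", "O", np.array(pos) + [1.3, -1.9, 0.2])], seq=seq)
        if seq == 404:
            off = np.zeros((nF, 3))
            off[:, 0] = d1_series - d1_series[0]
            moves.append((r, off))

    # --- zinc site with exchanging waters and a denticity switch ------------
    zorigin = np.array([0.0, 2 * _GRID, 0.0])
    tspec = ToyStructureSpec()
    h1, h2, ge, w_coord, w_far = _zinc_site_atoms(tspec, b, zorigin, water_seq_start=801)
    # glutamate OE2: in-sphere until the switch frame, then displaced outward
    oe2_off = np.zeros((nF, 3))
    out_vec = np.array([0.465, 0.885, 0]) * (3.4 - tspec.zinc_glu_distances[1])
    oe2_off[spec.denticity_switch_frame:] = out_vec
    ge_mask = np.array([a.name == "OE2" for a in ge.atoms])
    moves.append((ge, (oe2_off, ge_mask)))  # per-atom move

    # exchanging waters: distinct slots below the zinc
    slots = [np.array([0, -2.2, 0]), np.array([-1.55, -1.55, 0]), np.array([1.55, -1.55, 0])]
    park = np.array([0, -6.5, 0])
    water_frames = {}
    for k, n_present in enumerate(spec.zinc_water_frames):
        slot = slots[k % len(slots)]
        w = b.add("HOH", [("O", "O", zorigin + slot)], seq=810 + k, kind="water")
        present = np.zeros(nF, dtype=bool)
        present[rng.permutation(nF)[:n_present]] = True
        off = np.where(present[:, None], 0.0, np.tile(park - slot, (nF, 1)))
        moves.append((w, off))
        water_frames[f"HOH{810 + k}"] = int(n_present)

    # --- planted ligand-protein hydrogen bonds ------------------------------
    # Bonds sharing one protein residue (e.g. both carboxylate oxygens of a
    # glutamate engaged simultaneously, driving the residue sum above 100%)
    # are realised as a double-acceptor island with two ligand donors.
    groups: dict[tuple[str, int, str], list[BondSpec]] = {}
    for bs in spec.bonds:
        groups.setdefault((bs.res_name, bs.res_seq, bs.role), []).append(bs)
    bond_truth = []
    lig_seq = 751
    acc_names = {"GLU": ("OE1", "OE2", "CD"), "ASP": ("OD1", "OD2", "CG")}
    for gi, ((rname, rseq, role), members) in enumerate(groups.items()):
        origin = np.array([_GRID * (1 + gi), 4 * _GRID, 0.0])
        presences = []
        for bs in members:
            k_present = int(round(bs.occupancy_pct / 100.0 * nF))
            present = np.zeros(nF, dtype=bool)
            present[rng.permutation(nF)[:k_present]] = True
            presences.append((k_present, present))
        if role == "acceptor":
            if rname not in acc_names:
                raise GeometryRequestError("acceptor bonds use GLU or ASP protein residues")
            if len(members) > 2:
                raise GeometryRequestError("at most two bonds per carboxylate acceptor")
            o1, o2, cx = acc_names[rname]
            prot = [(o1, "O", np.zeros(3)), (cx, "C", np.array([-0.7, 1.1, 0])),
                    ("CB", "C", np.array([-1.9, 1.1, 0]))] + _shift(_bb(_NX, 3.2), [0, 1.1, 0])
            if len(members) == 2:
                prot.insert(1, (o2, "O", np.array([0.0, 2.2, 0])))
            pres = b.add(rname, _shift(prot, origin), seq=rseq)
            for k, (bs, (k_present, present)) in enumerate(zip(members, presences)):
                dy = 2.2 * k
                lig = [("N", "N", np.array([2.8, dy, 0])), ("H", "H", np.array([1.83, dy, 0])),
                       ("CA", "C", np.array([4.2, dy + 0.3, 0]))]
                lres = b.add("LIG", _shift(lig, origin), seq=lig_seq, chain="B", kind="ligand")
                lig_seq += 1
                off = np.where(present[:, None], 0.0, np.tile(np.array([4.0, 0, 0]), (nF, 1)))
                moves.append((lres, off))
                bond_truth.append({"protein_residue": pres.label, "role": role,
                                   "occupancy_pct": 100.0 * k_present / nF,
                                   "n_frames_present": k_present})
        else:
            if len(members) > 1:
                raise GeometryRequestError("one donor bond per protein residue")
            if rname != "ASN":
                raise GeometryRequestError("donor bonds use ASN protein residues")
            k_present, present = presences[0]
            prot = [("ND2", "N", np.zeros(3)), ("HD2", "H", np.array([0.97, 0, 0])),
                    ("CG", "C", np.array([-1.3, 0.4, 0])),
                    ("OD1", "O", np.array([-1.5, 1.6, 0])),
                    ("CB", "C", np.array([-2.5, -0.3, 0]))] + _bb(_NX, 3.8)
            pres = b.add(rname, _shift(prot, origin), seq=rseq)
            lig = [("O", "O", np.array([2.8, 0, 0])), ("C", "C", np.array([4.0, 0.4, 0]))]
            lres = b.add("LIG", _shift(lig, origin), seq=lig_seq, chain="B", kind="ligand")
            lig_seq += 1
            off = np.where(present[:, None], 0.0, np.tile(np.array([4.0, 0, 0]), (nF, 1)))
            moves.append((lres, off))
            bond_truth.append({"protein_residue": pres.label, "role": role,
                               "occupancy_pct": 100.0 * k_present / nF,
                               "n_frames_present": k_present})

    # --- cleft waters --------------------------------------------------------
    corigin = np.array([0.0, 6 * _GRID, 0.0])
    anchors = []
    for dx in (-1.0, 1.0):
        gly = [("CA", "C", np.array([dx, 0, 0])), ("N", "N", np.array([dx, 1.4, 0])),
               ("C", "C", np.array([dx + 1.2, -0.8, 0])), ("O", "O", np.array([dx + 1.3, -2.0, 0]))]
        anchors.append(b.add("GLY", _shift(gly, corigin)))
    n_max = max(spec.cleft_waters.values())
    inside_counts = np.array([spec.cleft_waters[lab] for lab in labels])
    wseq = 901
    for k in range(n_max):
        v = rng.normal(size=3)
        pos = corigin + (v / np.linalg.norm(v)) * rng.uniform(2.5, 6.0)
        w = b.add("HOH", [("O", "O", pos)], seq=wseq, kind="water")
        wseq += 1
        inside = k < inside_counts  # water k present in frames needing > k waters
        off = np.where(inside[:, None], 0.0, np.tile(np.array([0, 0, 14.0]), (nF, 1)))
        moves.append((w, off))
    for _ in range(spec.n_outside_waters):
        v = rng.normal(size=3)
        pos = corigin + (v / np.linalg.norm(v)) * rng.uniform(10.5, 13.0)
        b.add("HOH", [("O", "O", pos)], seq=wseq, kind="water")
        wseq += 1

    # --- assemble frames -----------------------------------------------------
    topo = Structure(b.residues, name="breathing")
    flat_index = {}
    i = 0
    for r in topo.residues:
        for a in r.atoms:
            flat_index[(id(r), a.name)] = i
            i += 1
    frames = np.tile(topo.coords()[None, :, :], (nF, 1, 1))
    for res, off in moves:
        if isinstance(off, tuple):
            off_arr, mask = off
            for k, a in enumerate(res.atoms):
                if mask[k]:
                    frames[:, flat_index[(id(res), a.name)]] += off_arr
        else:
            for a in res.atoms:
                frames[:, flat_index[(id(res), a.name)]] += off
    topo.model_coords = frames

    manifest = {
        "seed": spec.seed,
        "n_frames": nF,
        "phase_labels": labels.tolist(),
        "d1_series": d1_series.tolist(),
        "bonds": bond_truth,
        "zinc": {"water_frames": water_frames,
                 "denticity_switch_frame": spec.denticity_switch_frame,
                 "glu_label": ge.label},
        "cleft": {"anchor_residues": [a.seq for a in anchors],
                  "radius": spec.cleft_radius,
                  "counts_by_phase": dict(spec.cleft_waters)},
    }
    return Trajectory(topo, frames), manifest


# ---------------------------------------------------------------------------
# Kinetic datasets
# ---------------------------------------------------------------------------

@dataclass
class KineticSpec:
    """Ground truth and noise model for synthetic initial-rate datasets.

    Defaults emulate the preferred dipeptide substrate at its measured
    parameters (KM 35.2 microM, kcat 3.07 s^-1) on a 9-point concentration
    grid spanning 5-300 microM.
    """

    km: float = 35.2  # microM
    kcat: float = 3.07  # s^-1
    enzyme_conc: float = 0.01  # microM
    concentrations: tuple[float, ...] = (5, 10, 20, 40, 75, 120, 180, 240, 300)
    noise_sd: float = 0.05  # relative
    n_replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.concentrations) <= 0:
            raise ValueError("concentrations must be positive")


def make_kinetic_dataset(spec: KineticSpec | None = None):
    """Generate replicate rate datasets v = kcat*E*S/(KM+S) * (1 + eps).

    eps ~ Normal(0, noise_sd), seeded.  Returns ``(datasets, truth)`` where
    truth records the generating parameters.
    """
    from .kinetics import RateDataset

    spec = spec or KineticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = np.array(spec.concentrations, dtype=float)
    v0 = spec.kcat * spec.enzyme_conc * s / (spec.km + s)
    datasets = []
    for rep in range(spec.n_replicates):
        eps = rng.normal(0.0, spec.noise_sd, size=len(s)) if spec.noise_sd > 0 else 0.0
        datasets.append(RateDataset(s.copy(), v0 * (1.0 + eps), spec.enzyme_conc, replicate=rep))
    truth = {"km": spec.km, "kcat": spec.kcat, "enzyme_conc": spec.enzyme_conc,
             "noise_sd": spec.noise_sd, "seed": spec.seed}
    return datasets, truth
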