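"""Atomic-structure model, I/O, residue classification, and crystal-form scalars.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Residue` objects, each holding :class:`Atom` records with
coordinates from the first model; additional models (e.g. trajectory frames
stored as a multi-model PDB) are kept as an ``(n_models, n_atoms, 3)``
coordinate array that shares the topology.  Parsing is delegated to gemmi,
which handles both PDB and mmCIF dialects; writing produces plain
(multi-model) PDB.

Conventions: author residue numbering with insertion codes; hydrogens are
dropped on read unless requested; for alternate locations the
highest-occupancy conformer is kept (ties resolved toward altloc 'A').
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chemistry
from .chemistry import (
    AA3_TO_1,
    DEFAULT_RESIDUE_CLASSES,
    METAL_ELEMENTS,
    STANDARD_AA1,
    WATER_NAMES,
)


class StructureError(ValueError):
    """Raised for unreadable, empty, or inconsistent structural input."""


@dataclass
class Atom:
    """One heavy (or hydrogen) atom with author-numbering metadata."""

    serial: int
    name: str
    element: str
    altloc: str
    res_name: str
    chain: str
    res_seq: int
    icode: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial} {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.serial} {self.name}: element symbol is empty")


@dataclass
class Residue:
    """A residue (polymer, ligand, metal, or water) and its atoms."""

    name: str
    chain: str
    seq: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    kind: str = "polymer"  # polymer | ligand | metal | water

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq, self.icode)

    @property
    def label(self) -> str:
        one = AA3_TO_1.get(self.name, "X")
        return f"{one}{self.seq}{self.icode}".strip()

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class SequenceRecord:
    """A validated one-letter amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - STANDARD_AA1
        if bad:
            raise ValueError(f"non-standard residue codes in sequence {self.id!r}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


class Structure:
    """Parsed atomic model: residues partitioned by kind, plus extra models.

    ``ss_labels`` maps a residue key ``(chain, seq, icode)`` to one of
    ``{"H", "E", "other"}``; every polymer residue has a label (default
    ``"other"``).
    """

    def __init__(self, residues: list[Residue], name: str = "", model_coords: np.ndarray | None = None):
        if not residues or not any(r.atoms for r in residues):
            raise StructureError("structure contains no atoms")
        self.name = name
        self.residues = residues
        serials = [a.serial for r in residues for a in r.atoms]
        if len(serials) != len(set(serials)):
            raise StructureError("duplicate atom serials within a model")
        self.ss_labels: dict[tuple[str, int, str], str] = {
            r.key: "other" for r in residues if r.kind == "polymer"
        }
        n_atoms = len(serials)
        if model_coords is None:
            model_coords = self.coords()[None, :, :]
        model_coords = np.asarray(model_coords, dtype=float)
        if model_coords.ndim != 3 or model_coords.shape[1:] != (n_atoms, 3):
            raise StructureError("model_coords must have shape (n_models, n_atoms, 3)")
        self.model_coords = model_coords

    # -- residue subsets ----------------------------------------------------
    @property
    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "polymer"]

    @property
    def ligands(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "ligand"]

    @property
    def metals(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "metal"]

    @property
    def waters(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "water"]

    @property
    def n_resolved(self) -> int:
        """Number of polymer residues with at least one atom."""
        return sum(1 for r in self.polymer_residues if r.atoms)

    @property
    def n_models(self) -> int:
        return self.model_coords.shape[0]

    def atoms(self):
        for r in self.residues:
            yield from r.atoms

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        i = 0
        for a in self.atoms():
            a.coords = coords[i]
            i += 1
        self.model_coords = self.model_coords.copy()
        self.model_coords[0] = coords

    def find_residue(self, seq: int, chain: str | None = None, icode: str = "") -> Residue:
        for r in self.residues:
            if r.seq == seq and r.icode == icode and (chain is None or r.chain == chain):
                return r
        raise KeyError(f"no residue {seq}{icode} in chain {chain or '*'}")

    def ca(self, seq: int, chain: str | None = None) -> Atom:
        res = self.find_residue(seq, chain)
        a = res.atom("CA")
        if a is None:
            raise StructureError(f"residue {res.label}: no C-alpha atom")
        return a

    def sequence(self) -> SequenceRecord:
        """One-letter sequence over resolved polymer residues (unknowns -> X rejected)."""
        seq = "".join(AA3_TO_1.get(r.name, "X") for r in self.polymer_residues)
        return SequenceRecord(self.name or "structure", seq)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _classify_kind(res_name: str, element_names: set[str], het: bool) -> str:
    if res_name in WATER_NAMES:
        return "water"
    if het and len(element_names) == 1 and next(iter(element_names)).upper() in METAL_ELEMENTS:
        return "metal"
    if res_name in AA3_TO_1 and not het:
        return "polymer"
    if res_name in AA3_TO_1 and het:
        # peptide-like HETATM entity (e.g. a bound dipeptide)
        return "ligand"
    return "ligand"


def read_structure(path: str | Path, fmt: str = "auto", keep_hydrogens: bool = False) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Multi-model files yield models in file order as ``model_coords``;
    secondary-structure labels are filled from HELIX/SHEET (or mmCIF
    struct_conf/struct_sheet_range) records when present.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path.name}: {exc}") from exc

    if len(st) == 0 or sum(1 for _ in st[0].all()) == 0:
        raise StructureError(f"{path.name}: structure contains no atoms")

    residues: list[Residue] = []
    first = st[0]
    for chain in first:
        for gres in chain:
            het = gres.het_flag == "H"
            atoms: list[Atom] = []
            by_name: dict[str, list] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            for name, group in by_name.items():
                # altloc policy: highest occupancy, tie toward 'A'/blank
                ga = sorted(group, key=lambda a: (-a.occ, a.altloc or "A"))[0]
                el = ga.element.name
                if not keep_hydrogens and el in ("H", "D"):
                    continue
                atoms.append(Atom(
                    serial=ga.serial, name=name, element=el,
                    altloc="" if ga.altloc == "\x00" else ga.altloc,
                    res_name=gres.name, chain=chain.name,
                    res_seq=gres.seqid.num, icode=gres.seqid.icode.strip(),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ, b_factor=ga.b_iso, is_hetero=het,
                ))
            if not atoms:
                continue
            kind = _classify_kind(gres.name, {a.element for a in atoms}, het)
            residues.append(Residue(
                name=gres.name, chain=chain.name, seq=gres.seqid.num,
                icode=gres.seqid.icode.strip(), atoms=atoms, kind=kind,
            ))

    # extra models: match atoms positionally (same atom count enforced)
    coords0 = np.array([a.coords for r in residues for a in r.atoms])
    models = [coords0]
    if len(st) > 1:
        kept = {(r.chain, r.seq, r.icode, a.name) for r in residues for a in r.atoms}
        for model in list(st)[1:]:
            xyz = []
            for chain in model:
                for gres in chain:
                    for ga in gres:
                        if (chain.name, gres.seqid.num, gres.seqid.icode.strip(), ga.name) in kept:
                            xyz.append([ga.pos.x, ga.pos.y, ga.pos.z])
            if len(xyz) != len(coords0):
                raise StructureError(
                    f"{path.name}: model atom count {len(xyz)} != first model {len(coords0)}")
            models.append(np.array(xyz))

    out = Structure(residues, name=path.stem, model_coords=np.stack(models))

    for helix in st.helices:
        _label_range(out, helix.start.res_id.seqid.num, helix.end.res_id.seqid.num,
                     helix.start.chain_name, "H")
    for sheet in st.sheets:
        for strand in sheet.strands:
            _label_range(out, strand.start.res_id.seqid.num, strand.end.res_id.seqid.num,
                         strand.start.chain_name, "E")
    return out


def _label_range(s: Structure, start: int, end: int, chain: str, label: str) -> None:
    for r in s.polymer_residues:
        if r.chain == chain and start <= r.seq <= end:
            s.ss_labels[r.key] = label


# ---------------------------------------------------------------------------
# Writing (multi-model PDB)
# ---------------------------------------------------------------------------

def write_pdb(s: Structure, path: str | Path) -> None:
    """Write all models of a structure as a (multi-model) PDB file."""
    path = Path(path)
    lines: list[str] = []
    multi = s.n_models > 1
    for im in range(s.n_models):
        if multi:
            lines.append(f"MODEL     {im + 1:4d}")
        i = 0
        for r in s.residues:
            record = "HETATM" if (r.kind != "polymer" or any(a.is_hetero for a in r.atoms)) else "ATOM  "
            for a in r.atoms:
                x, y, z = s.model_coords[im, i]
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"{record}{a.serial:5d} {name:<4s}{a.altloc or ' ':1s}{r.name:>3s} "
                    f"{r.chain:1s}{r.seq:4d}{r.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                    f"          {a.element:>2s}"
                )
                i += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> SequenceRecord:
    """Read the first record of a FASTA file."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return SequenceRecord(rec.id, str(rec.seq).upper())


# ---------------------------------------------------------------------------
# Residue classification
# ---------------------------------------------------------------------------

def classify_residues(
    seq_or_structure: SequenceRecord | Structure | str,
    scheme: dict[str, frozenset[str]] | None = None,
    strict: bool = True,
) -> dict[str, int]:
    """Count residues per class (proline / charged / polar / hydrophobic).

    Returns absolute counts plus the denominator under key ``"total"``.
    Classes need not partition the sequence.  Unknown residue codes raise in
    strict mode and are tallied as ``"other"`` with a warning otherwise.
    """
    scheme = scheme or DEFAULT_RESIDUE_CLASSES
    if isinstance(seq_or_structure, Structure):
        letters = [AA3_TO_1.get(r.name, "?") for r in seq_or_structure.polymer_residues]
    elif isinstance(seq_or_structure, SequenceRecord):
        letters = list(seq_or_structure.sequence)
    else:
        letters = list(str(seq_or_structure).upper())

    counts = {name: 0 for name in scheme}
    counts["other"] = 0
    for c in letters:
        if c not in STANDARD_AA1:
            if strict:
                raise ValueError(f"unknown residue code {c!r} (strict mode)")
            warnings.warn(f"unknown residue code {c!r} counted as 'other'", stacklevel=2)
            counts["other"] += 1
            continue
        for name, members in scheme.items():
            if c in members:
                counts[name] += 1
    counts["total"] = len(letters)
    return counts


# ---------------------------------------------------------------------------
# Crystal-form scalars
# ---------------------------------------------------------------------------

@dataclass
class CrystalForm:
    """Unit cell, content, and the derived Matthews/solvent scalars."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group: str = ""
    z: int = 1
    mass: float = 0.0

    def cell_volume(self) -> float:
        """General triclinic cell volume in cubic angstroms."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return self.a * self.b * self.c * math.sqrt(
            1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)

    @property
    def v_m(self) -> float:
        return self.cell_volume() / (self.z * self.mass)

    @property
    def solvent_fraction(self) -> float:
        return solvent_fraction_from_vm(self.v_m)


def solvent_fraction_from_vm(v_m: float) -> float:
    """Solvent fraction 1 - 1.23/VM, clamped to [0, 1].

    1.23 Da/A^3 is the reciprocal of the typical protein partial specific
    volume expressed in crystallographic units.
    """
    frac = 1.0 - 1.23 / v_m
    if frac < 0:
        warnings.warn(f"VM = {v_m:.3g} below 1.23: solvent fraction clamped to 0", stacklevel=2)
        return 0.0
    return min(frac, 1.0)


def matthews_and_solvent(cell: CrystalForm | None = None, z: int | None = None,
                         mass: float | None = None, v_m: float | None = None) -> tuple[float, float]:
    """Matthews coefficient (A^3/Da) and solvent content (%).

    Either pass a :class:`CrystalForm` (with ``z`` and ``mass`` set or given
    here), or a precomputed ``v_m``.
    """
    if v_m is None:
        if cell is None:
            raise ValueError("need either a CrystalForm or v_m")
        if z is not None:
            cell.z = z
        if mass is not None:
            cell.mass = mass
        if cell.z < 1 or cell.mass <= 0:
            raise ValueError("z must be >= 1 and mass > 0")
        v_m = cell.v_m
    return v_m, solvent_fraction_from_vm(v_m) * 100.0


# ---------------------------------------------------------------------------
# Extinction coefficient
# ---------------------------------------------------------------------------

#: Molar absorptivities at 280 nm (M^-1 cm^-1) for Trp, Tyr, and cystine.
EPS_TRP, EPS_TYR, EPS_CYSTINE = 5500.0, 1490.0, 125.0


def extinction_coefficient(seq: SequenceRecord | str, cystine_mode: str = "reduced") -> float:
    """Theoretical molar extinction coefficient at 280 nm.

    ``oxidized`` mode counts each cystine pair (nCys // 2) at 125 M^-1 cm^-1;
    ``reduced`` omits the cystine term.
    """
    if isinstance(seq, str):
        seq = SequenceRecord("seq", seq.upper())
    s = seq.sequence
    eps = EPS_TRP * s.count("W") + EPS_TYR * s.count("Y")
    if cystine_mode == "oxidized":
        eps += EPS_CYSTINE * (s.count("C") // 2)
    elif cystine_mode != "reduced":
        raise ValueError(f"cystine_mode must be 'reduced' or 'oxidized', got {cystine_mode!r}")
    return eps
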