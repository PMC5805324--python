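"""Interaction detection against an exhaustive pair-scan oracle, and profile
arithmetic for the thermophile/mesophile comparison table."""

import math

import numpy as np
import pytest

from cleftscope import chemistry
from cleftscope.interactions import (
    InteractionCriteria,
    StructureProfile,
    compare_profiles,
    detect_interactions,
    structure_profile,
)
from cleftscope.structure import Atom, Residue, Structure
from cleftscope.synthetic import ToyStructureSpec, make_toy_structure

# ---------------------------------------------------------------------------
# Brute-force oracle: plain nested loops over all atom pairs, no spatial
# indexing, written directly from the geometric definitions.
# ---------------------------------------------------------------------------


def _angle(center, p1, p2):
    u = p1 - center
    v = p2 - center
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _adjacent_bb(r1, a1, r2, a2):
    bb = {"N", "CA", "C", "O"}
    return r1.chain == r2.chain and abs(r1.seq - r2.seq) == 1 and a1 in bb and a2 in bb


def oracle_counts(s: Structure, c: InteractionCriteria) -> dict[str, int]:
    res = s.polymer_residues
    counts = {"hbond": 0, "weak_hbond": 0, "ionic": 0, "hydrophobic": 0, "aromatic": 0}

    for kind, donor_map in (("hbond", None), ("weak_hbond", chemistry.WEAK_DONORS)):
        for rd in res:
            dmap = chemistry.donors_for(rd.name) if donor_map is None else donor_map
            for dn, an in dmap.items():
                d, ante = rd.atom(dn), rd.atom(an)
                if d is None or ante is None:
                    continue
                for ra in res:
                    if ra.key == rd.key:
                        continue
                    for accn in chemistry.acceptors_for(ra.name):
                        a = ra.atom(accn)
                        if a is None or _adjacent_bb(rd, dn, ra, accn):
                            continue
                        dist = float(np.linalg.norm(d.coords - a.coords))
                        theta = _angle(d.coords, ante.coords, a.coords)
                        if kind == "hbond":
                            if dist <= c.hbond_dmax and theta > c.hbond_theta_min:
                                counts["hbond"] += 1
                        else:
                            if c.weak_dmin <= dist <= c.weak_dmax \
                                    and c.weak_theta_lo < theta < c.weak_theta_hi:
                                counts["weak_hbond"] += 1

    pos = dict(chemistry.POSITIVE_ATOMS)
    if c.charged_his:
        pos.update(chemistry.POSITIVE_ATOMS_HIS)
    ionic_pairs = set()
    for rn in res:
        for on in chemistry.NEGATIVE_ATOMS.get(rn.name, ()):
            an = rn.atom(on)
            if an is None:
                continue
            for rp in res:
                for pn in pos.get(rp.name, ()):
                    ap = rp.atom(pn)
                    if ap is None:
                        continue
                    if np.linalg.norm(an.coords - ap.coords) <= c.ionic_dmax:
                        ionic_pairs.add((rn.key, rp.key))
    counts["ionic"] = len(ionic_pairs)

    rings = []
    for r in res:
        for names in chemistry.AROMATIC_RINGS.get(r.name, ()):
            atoms = [r.atom(nm) for nm in names if r.atom(nm) is not None]
            if len(atoms) >= 3:
                rings.append((r, atoms))
    contact = set()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if rings[i][0].key == rings[j][0].key:
                continue
            dmin = min(np.linalg.norm(a.coords - b.coords)
                       for a in rings[i][1] for b in rings[j][1])
            if dmin <= c.aromatic_dmax:
                contact.add((i, j))
    counts["aromatic"] = len(contact)

    in_ring = {}
    for k, (r, atoms) in enumerate(rings):
        for a in atoms:
            in_ring.setdefault((r.key, a.name), set()).add(k)
    for i, r1 in enumerate(res):
        for n1 in chemistry.APOLAR_CARBONS.get(r1.name, ()):
            a1 = r1.atom(n1)
            if a1 is None:
                continue
            for r2 in res[i + 1:]:
                for n2 in chemistry.APOLAR_CARBONS.get(r2.name, ()):
                    a2 = r2.atom(n2)
                    if a2 is None:
                        continue
                    if np.linalg.norm(a1.coords - a2.coords) > c.hydrophobic_dmax:
                        continue
                    rings1 = in_ring.get((r1.key, n1), set())
                    rings2 = in_ring.get((r2.key, n2), set())
                    if any((min(x, y), max(x, y)) in contact
                           for x in rings1 for y in rings2):
                        continue
                    counts["hydrophobic"] += 1
    return counts


def _kind_counts(interactions):
    out = {"hbond": 0, "weak_hbond": 0, "ionic": 0, "hydrophobic": 0, "aromatic": 0}
    for it in interactions:
        out[it.kind] += 1
    return out


def _mini_structure(residues):
    return Structure(residues, name="mini")


def _res(name, seq, atoms, chain="A"):
    r = Residue(name=name, chain=chain, seq=seq)
    for i, (an, el, xyz) in enumerate(atoms):
        r.atoms.append(Atom(serial=seq * 100 + i, name=an, element=el, altloc="",
                            res_name=name, chain=chain, res_seq=seq, icode="",
                            coords=np.array(xyz, dtype=float)))
    return r


# ---------------------------------------------------------------------------


class TestDetection:
    def test_matches_manifest_and_oracle_on_toy_structure(self, toy):
        s, manifest = toy
        crit = InteractionCriteria()
        counts = _kind_counts(detect_interactions(s, crit))
        assert counts == manifest["interactions"]
        assert counts == oracle_counts(s, crit)

    def test_oracle_equivalence_on_perturbed_structures(self):
        # varied planted counts and distances, including near-cutoff cases
        spec = ToyStructureSpec(n_salt_bridges=3, n_hbonds=2, n_weak_hbonds=2,
                                n_hydrophobic=3, n_aromatic=1,
                                salt_bridge_distance=3.7, hydrophobic_distance=3.5,
                                seed=5)
        s, manifest = make_toy_structure(spec)
        crit = InteractionCriteria()
        counts = _kind_counts(detect_interactions(s, crit))
        assert counts == oracle_counts(s, crit) == manifest["interactions"]

    def test_weak_hbond_band_and_angle(self):
        # carbon donor at 3.7 A with a 120 deg donor-centred angle
        t = math.radians(60.0)
        acc = 3.7 * np.array([math.cos(t), math.sin(t), 0.0])
        gly = _res("GLY", 1, [("CA", "C", [0, 0, 0]), ("N", "N", [-1.46, 0, 0]),
                              ("C", "C", [-0.5, -1.3, 0]), ("O", "O", [-1.6, -1.7, 0])])
        asn = _res("ASN", 10, [("OD1", "O", acc), ("CG", "C", acc + [1.25, 0.3, 0])])
        out = detect_interactions(_mini_structure([gly, asn]))
        assert [i.kind for i in out] == ["weak_hbond"]
        assert out[0].angle == pytest.approx(120.0, abs=0.5)

    def test_far_pair_yields_nothing(self):
        a = _res("SER", 1, [("OG", "O", [0, 0, 0]), ("CB", "C", [-1.4, 0, 0])])
        b = _res("ASN", 5, [("OD1", "O", [5.0, 0, 0]), ("CG", "C", [6.3, 0, 0])])
        assert detect_interactions(_mini_structure([a, b])) == []

    def test_intra_residue_pairs_excluded(self):
        ser = _res("SER", 1, [("OG", "O", [0, 0, 0]), ("CB", "C", [-1.4, 0, 0]),
                              ("N", "N", [2.9, 0, 0]), ("CA", "C", [4.0, 0.4, 0]),
                              ("C", "C", [5.0, -0.5, 0]), ("O", "O", [2.2, 1.9, 0])])
        assert detect_interactions(_mini_structure([ser])) == []

    def test_monotone_in_distance_cutoffs(self, toy):
        s, _ = toy
        base = _kind_counts(detect_interactions(s, InteractionCriteria()))
        wide = _kind_counts(detect_interactions(s, InteractionCriteria(
            hbond_dmax=4.6, weak_dmax=4.6, ionic_dmax=4.8,
            hydrophobic_dmax=4.8, aromatic_dmax=4.8)))
        for kind in base:
            assert wide[kind] >= base[kind]
        # decoys fall inside the widened cut-offs
        assert wide["ionic"] > base["ionic"]
        assert wide["hydrophobic"] > base["hydrophobic"]

    def test_rigid_motion_invariance(self, toy, rng):
        from scipy.spatial.transform import Rotation

        s, _ = toy
        base = _kind_counts(detect_interactions(s))
        R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        t = rng.uniform(-50, 50, 3)
        moved, _ = make_toy_structure(ToyStructureSpec(seed=0))
        moved.set_coords(moved.coords() @ R.T + t)
        assert _kind_counts(detect_interactions(moved)) == base

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            InteractionCriteria(hbond_dmax=-1)
        with pytest.raises(ValueError):
            InteractionCriteria(weak_dmin=4.0, weak_dmax=3.6)


# ---------------------------------------------------------------------------
# Table arithmetic: densities, percentages, and scaled occurrences
# ---------------------------------------------------------------------------

MESO_COUNTS = {  # 647 resolved residues
    "helix_residues": 374, "sheet_residues": 86, "proline_residues": 23,
    "polar_residues": 122, "charged_residues": 130, "hydrophobic_residues": 288,
    "hydrogen_bonds": 741, "weak_hydrogen_bonds": 502, "ionic_interactions": 94,
    "hydrophobic_contacts": 1814, "aromatic_contacts": 127,
}
THERMO_COUNTS = {  # 524 resolved residues
    "helix_residues": 332, "sheet_residues": 82, "proline_residues": 26,
    "polar_residues": 87, "charged_residues": 130, "hydrophobic_residues": 247,
    "hydrogen_bonds": 606, "weak_hydrogen_bonds": 431, "ionic_interactions": 92,
    "hydrophobic_contacts": 1614, "aromatic_contacts": 113,
}


class TestProfiles:
    def test_hbond_density(self):
        p = StructureProfile.from_counts("meso", MESO_COUNTS, 647)
        assert round(p.relative["hydrogen_bonds"], 3) == 1.145

    def test_structure_profile_of_toy(self, toy):
        s, manifest = toy
        prof = structure_profile(s)
        assert prof.denominator == s.n_resolved
        assert prof.counts["ionic_interactions"] == manifest["interactions"]["ionic"]
        assert prof.relative["ionic_interactions"] == pytest.approx(
            manifest["interactions"]["ionic"] / s.n_resolved)

    def test_helix_sheet_percentages_from_planted_labels(self, toy):
        s, _ = toy
        keys = [r.key for r in s.polymer_residues]
        for k in keys[:6]:
            s.ss_labels[k] = "H"
        for k in keys[6:10]:
            s.ss_labels[k] = "E"
        prof = structure_profile(s)
        assert prof.counts["helix_residues"] == 6
        assert prof.counts["sheet_residues"] == 4
        assert prof.relative["helix_residues"] == pytest.approx(600 / s.n_resolved)
        for k in keys[:10]:
            s.ss_labels[k] = "other"  # restore shared fixture

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            StructureProfile.from_counts("x", MESO_COUNTS, 0)

    def test_missing_category_rejected(self):
        bad = dict(MESO_COUNTS)
        bad.pop("helix_residues")
        with pytest.raises(ValueError):
            StructureProfile.from_counts("x", bad, 647)


class TestComparison:
    @pytest.fixture()
    def table(self):
        return compare_profiles(
            StructureProfile.from_counts("meso", MESO_COUNTS, 647),
            StructureProfile.from_counts("thermo", THERMO_COUNTS, 524))

    def test_helix_row(self, table):
        # the printed table truncates 57.8052 to 57.80
        assert table.profile_a.relative["helix_residues"] == pytest.approx(57.80, abs=0.01)
        assert table.profile_b.relative["helix_residues"] == pytest.approx(63.36, abs=0.01)
        sa, sb = table.scaled("helix_residues")
        assert round(sa, 1) == 91.2 and sb == 100.0

    def test_sheet_and_weak_hbond_scaling(self, table):
        assert round(table.scaled("sheet_residues")[0], 1) == 84.9
        assert round(table.scaled("weak_hydrogen_bonds")[0], 1) == 94.3

    def test_identical_profiles_scale_to_100(self):
        p = StructureProfile.from_counts("a", MESO_COUNTS, 647)
        t = compare_profiles(p, StructureProfile.from_counts("b", MESO_COUNTS, 647))
        for cat in MESO_COUNTS:
            assert t.scaled(cat) == (100.0, 100.0)

    def test_swap_invariance(self, table):
        swapped = compare_profiles(table.profile_b, table.profile_a)
        for cat in MESO_COUNTS:
            assert swapped.scaled(cat) == table.scaled(cat)[::-1]

    def test_dataframe_layout(self, table):
        df = table.to_dataframe()
        assert list(df.columns) == ["category", "abs_a", "rel_a", "abs_b", "rel_b",
                                    "scaled_a", "scaled_b"]
        assert len(df) == 11
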