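"""Trajectory analytics recover planted ground truth: geometry traces,
H-bond populations, zinc dynamics, water residence, cleft waters, aMD
parameters, and interval energy summaries."""

import numpy as np
import pandas as pd
import pytest

from cleftscope.structure import StructureError
from cleftscope.synthetic import BondSpec, TrajectorySpec, make_breathing_trajectory
from cleftscope.trajectory import (
    CleftRegion,
    Trajectory,
    amd_boost_params,
    cleft_waters,
    expulsion_energy,
    format_mean_sd,
    geometry_trace,
    hbond_populations,
    interval_energy_summary,
    phase_means,
    water_residence,
    zinc_dynamics,
)


def _reordered(traj: Trajectory, rng) -> Trajectory:
    perm = rng.permutation(traj.n_frames)
    return Trajectory(traj.topology, traj.frames[perm])


class TestGeometryTrace:
    def test_single_frame_equals_static_geometry(self, toy):
        from cleftscope.geometry import backbone_coords, domain_distances, radius_of_gyration

        s, _ = toy
        t = Trajectory.from_structure(s)
        trace = geometry_trace(t)
        d1, d2 = domain_distances(s)
        assert trace.loc[0, "d1"] == pytest.approx(d1)
        assert trace.loc[0, "d2"] == pytest.approx(d2)
        assert trace.loc[0, "rg"] == pytest.approx(radius_of_gyration(backbone_coords(s)))

    def test_sinusoidal_d1_schedule_realized(self):
        frames = 100
        d1 = 16.5 + 5.5 * np.sin(np.linspace(0, 4 * np.pi, frames))  # 11..22 A
        spec = TrajectorySpec(n_frames=frames, d1_series=d1, seed=7)
        traj, _ = make_breathing_trajectory(spec)
        trace = geometry_trace(traj)
        assert abs(trace["d1"].min() - d1.min()) < 0.1
        assert abs(trace["d1"].max() - d1.max()) < 0.1
        np.testing.assert_allclose(trace["d1"], d1, atol=1e-9)

    def test_two_phase_schedule_realized(self, breathing):
        traj, manifest = breathing
        trace = geometry_trace(traj)
        np.testing.assert_allclose(trace["d1"], manifest["d1_series"], atol=1e-9)

    def test_constant_trajectory_zero_variance(self, toy):
        s, _ = toy
        frames = np.tile(s.coords()[None], (5, 1, 1))
        trace = geometry_trace(Trajectory(s, frames))
        assert trace.std().max() == 0.0


class TestHBondPopulations:
    def test_planted_occupancies_recovered_exactly(self, breathing):
        traj, manifest = breathing
        hb = hbond_populations(traj)
        got = hb.bonds.sort_values(["protein_residue", "population"])
        want = sorted((b["protein_residue"], b["occupancy_pct"]) for b in manifest["bonds"])
        assert sorted(zip(got["protein_residue"], got["population"])) == want

    def test_multiple_bonds_sum_above_100(self, breathing):
        traj, _ = breathing
        sums = hbond_populations(traj).residue_sums()
        e240 = sums.loc[sums["residue"] == "E240", "population"].item()
        assert e240 == pytest.approx(200.0)

    def test_report_threshold_omits_rare_bonds(self):
        spec = TrajectorySpec(bonds=(BondSpec("GLU", 240, "acceptor", 3.0),
                                     BondSpec("ASP", 310, "acceptor", 40.0)), seed=2)
        traj, _ = make_breathing_trajectory(spec)
        hb = hbond_populations(traj)
        report = hb.residue_sums()
        assert set(report["residue"]) == {"D310"}
        full = hb.residue_sums(apply_threshold=False)
        assert set(full["residue"]) == {"D310", "E240"}

    def test_bond_frame_count_conserved_at_threshold_zero(self, breathing):
        traj, manifest = breathing
        hb = hbond_populations(traj, threshold=0.0)
        total_from_populations = hb.bonds["population"].sum() * hb.n_frames / 100.0
        assert total_from_populations == pytest.approx(
            sum(b["n_frames_present"] for b in manifest["bonds"]))

    def test_frame_reordering_invariance(self, breathing, rng):
        traj, _ = breathing
        base = hbond_populations(traj).residue_sums()
        shuffled = hbond_populations(_reordered(traj, rng)).residue_sums()
        pd.testing.assert_frame_equal(
            base.sort_values(["residue", "role"]).reset_index(drop=True),
            shuffled.sort_values(["residue", "role"]).reset_index(drop=True))

    def test_no_ligand_raises(self, toy):
        s, _ = toy
        spec = TrajectorySpec(bonds=())
        traj, _ = make_breathing_trajectory(spec)
        with pytest.raises(StructureError):
            hbond_populations(traj)


class TestZincDynamics:
    def test_denticity_switch_at_scheduled_frame(self, breathing):
        traj, manifest = breathing
        zd = zinc_dynamics(traj, cutoff=2.6)
        glu = manifest["zinc"]["glu_label"]
        assert zd.switch_frame(glu) == manifest["zinc"]["denticity_switch_frame"]
        frac = zd.denticity_fractions(glu)
        n = manifest["zinc"]["denticity_switch_frame"]
        assert frac["bi"] == pytest.approx(n / traj.n_frames)
        assert frac["mono"] == pytest.approx(1 - n / traj.n_frames)

    def test_static_frames_give_constant_cn(self, toy):
        s, _ = toy
        frames = np.tile(s.coords()[None], (4, 1, 1))
        zd = zinc_dynamics(Trajectory(s, frames), cutoff=2.6)
        assert set(zd.coordination_numbers) == {5}

    def test_degenerate_zero_cutoff(self, toy):
        s, _ = toy
        zd = zinc_dynamics(Trajectory.from_structure(s), cutoff=1e-9)
        assert set(zd.coordination_numbers) == {0}


class TestWaterResidence:
    def test_planted_residencies_and_omission_threshold(self):
        spec = TrajectorySpec(n_frames=1000,
                              phases=(("open", 500), ("closed", 500)),
                              zinc_water_frames=(500, 250, 100),
                              denticity_switch_frame=350,
                              cleft_waters={"open": 6, "closed": 3},
                              seed=4)
        traj, manifest = make_breathing_trajectory(spec)
        table = water_residence(traj, cutoff=2.6, min_frames=200)
        for w, n in manifest["zinc"]["water_frames"].items():
            assert table.counts[w] == n
        exchanging_reported = set(table.report()) & set(manifest["zinc"]["water_frames"])
        assert exchanging_reported == {w for w, n in manifest["zinc"]["water_frames"].items()
                                       if n >= 200}
        assert len(exchanging_reported) == 2

    def test_always_present_water_counts_all_frames(self, breathing):
        traj, _ = breathing
        table = water_residence(traj, cutoff=2.6, min_frames=0)
        assert table.counts["HOH801"] == traj.n_frames

    def test_reordering_invariance(self, breathing, rng):
        traj, _ = breathing
        a = water_residence(traj, min_frames=0).counts
        b = water_residence(_reordered(traj, rng), min_frames=0).counts
        assert a == b


class TestCleftWaters:
    def test_phase_counts_and_expulsion_estimate(self, breathing):
        traj, manifest = breathing
        region = CleftRegion(tuple(manifest["cleft"]["anchor_residues"]),
                             radius=manifest["cleft"]["radius"])
        counts = cleft_waters(traj, region)
        means = phase_means(counts, manifest["phase_labels"])
        assert means["open"] == pytest.approx(manifest["cleft"]["counts_by_phase"]["open"])
        assert means["closed"] == pytest.approx(manifest["cleft"]["counts_by_phase"]["closed"])
        lo, hi = expulsion_energy(means["open"], means["closed"])
        assert (lo, hi) == pytest.approx((60.0, 115.0))

    def test_static_frame_point_in_region_count(self, toy):
        s, manifest = toy
        region = CleftRegion(tuple(manifest["cleft"]["anchor_residues"]),
                             radius=manifest["cleft"]["radius"])
        counts = cleft_waters(Trajectory.from_structure(s), region)
        assert counts[0] == manifest["cleft"]["n_inside"]

    def test_equal_phases_give_zero_energy(self):
        assert expulsion_energy(40, 40) == (0.0, 0.0)

    def test_negative_delta_warns(self):
        with pytest.warns(UserWarning):
            lo, hi = expulsion_energy(40, 90)
        assert lo < 0 and lo <= hi


class TestAMDBoost:
    def test_zero_boost_leaves_means(self):
        p = amd_boost_params(-50000, 1000, 524, 40000, e_r=0.0, e_a=0.0)
        assert p.dih_threshold == 1000 and p.total_threshold == -50000

    def test_linear_formulas(self):
        p = amd_boost_params(-50000, 1000, 524, 40000)
        assert p.dih_threshold == pytest.approx(1524.0)
        assert p.total_threshold == pytest.approx(-46000.0)
        assert p.alpha_t == pytest.approx(524 / 5)
        assert p.alpha_T == pytest.approx(4000.0)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            amd_boost_params(0, 0, 0, 10)


class TestIntervalSummary:
    def test_constant_series(self):
        out = interval_energy_summary([-80.0] * 40, 10)
        assert (out.intervals["mean"] == -80.0).all()
        assert (out.intervals["sd"] == 0.0).all()
        assert not out.intervals["partial"].any()

    def test_two_block_series(self):
        out = interval_energy_summary([-80.0] * 50 + [-90.0] * 50, 50)
        assert list(out.intervals["mean"]) == [-80.0, -90.0]

    def test_trailing_partial_interval_flagged(self):
        out = interval_energy_summary(np.arange(25.0), 10)
        assert list(out.intervals["n"]) == [10, 10, 5]
        assert list(out.intervals["partial"]) == [False, False, True]

    def test_short_series_single_partial(self):
        out = interval_energy_summary([1.0, 2.0, 3.0], 10)
        assert len(out.intervals) == 1 and out.intervals.loc[0, "partial"]

    def test_weighted_interval_means_reaggregate(self, rng):
        x = rng.normal(-85, 8, size=137)
        out = interval_energy_summary(x, 25)
        recombined = np.average(out.intervals["mean"], weights=out.intervals["n"])
        assert recombined == pytest.approx(x.mean(), abs=1e-9)

    def test_formatting_style(self):
        assert format_mean_sd(-86.04, 9.81) == "-86.0 (±9.8)"

    def test_interval_too_small_rejected(self):
        with pytest.raises(ValueError):
            interval_energy_summary([1.0, 2.0], 1)
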