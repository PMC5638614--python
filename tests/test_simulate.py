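"""Fork-trap schedules, copy-number and degradation profiles, sampling,
and the lineage-forest simulator."""

import numpy as np
import pytest

from terloss.genome import ChromosomeMap, TerSite
from terloss.lineage import (
    BranchingParams,
    classify_divisions,
    initial_event_fraction,
)
from terloss.scenarios import SCENARIO_NAMES, get_scenario
from terloss.simulate import (
    DegradationModel,
    ForkTrapError,
    ReplicationParams,
    copy_number_profile,
    degradation_survival,
    fork_arrival_times,
    mixture_mfa_profile,
    sample_reads,
    simulate_lineage_forest,
)

PARAMS = ReplicationParams(tau=50.0, fork_speed=1000.0)  # 1 kb/min


def toy_map(ter_sites=()):
    return ChromosomeMap(length_bp=100_000, oriC=0, ter_sites=ter_sites)


class TestForkArrivalTimes:
    def test_symmetric_no_ter(self):
        s = fork_arrival_times(toy_map(), PARAMS, 1000)
        assert s.m[50] == 50.0  # antipode replicated last
        assert s.c_eff == 50.0
        assert s.merge_position == 50_000

    def test_single_clockwise_trap(self):
        # clockwise fork arrests at 30 kb; the rest is replicated
        # counter-clockwise, so 40 kb is reached at minute 60 and the merge
        # happens at the arrest site (continuous C period 70, attained on
        # the grid one window short)
        s = fork_arrival_times(
            toy_map([TerSite("T", 30_000, "clockwise")]), PARAMS, 1000
        )
        assert s.m[40] == 60.0
        assert 70.0 - 1.0 <= s.c_eff <= 70.0
        assert abs(s.merge_position - 30_000) <= 1000

    def test_zero_efficiency_equals_no_ter(self):
        free = fork_arrival_times(toy_map(), PARAMS, 1000)
        gated = fork_arrival_times(
            toy_map([TerSite("T", 30_000, "clockwise", efficiency=0.0)]),
            PARAMS,
            1000,
        )
        np.testing.assert_array_equal(free.m, gated.m)

    def test_partial_efficiency_mixture(self):
        site = TerSite("T", 30_000, "clockwise", efficiency=0.6)
        mixed = fork_arrival_times(toy_map([site]), PARAMS, 1000)
        assert len(mixed.branches) == 2
        weights = sorted(b.weight for b in mixed.branches)
        assert weights == pytest.approx([0.4, 0.6])
        arrest = fork_arrival_times(
            toy_map([TerSite("T", 30_000, "clockwise")]), PARAMS, 1000
        )
        free = fork_arrival_times(toy_map(), PARAMS, 1000)
        n_mixed = copy_number_profile(mixed, PARAMS)
        expect = 0.6 * np.exp2(-arrest.m / PARAMS.tau) + 0.4 * np.exp2(
            -free.m / PARAMS.tau
        )
        np.testing.assert_allclose(n_mixed, expect / expect.sum(), rtol=1e-12)

    def test_two_partial_sites_same_direction_rejected(self):
        sites = [
            TerSite("T1", 30_000, "clockwise", efficiency=0.5),
            TerSite("T2", 40_000, "clockwise", efficiency=0.5),
        ]
        with pytest.raises(ValueError):
            fork_arrival_times(toy_map(sites), PARAMS, 1000)

    def test_opposing_traps_with_gap_rejected(self):
        sites = [
            TerSite("Tcw", 30_000, "clockwise"),
            TerSite("Tccw", 60_000, "counterclockwise"),
        ]
        with pytest.raises(ForkTrapError):
            fork_arrival_times(toy_map(sites), PARAMS, 1000)

    def test_terb_star_like_map_merges_at_ectopic_site(self):
        sc = get_scenario("terB_star")
        s = fork_arrival_times(sc.chrom, sc.replication, 1000)
        assert abs(s.merge_position - sc.chrom.ter("TerB*").position) <= 1000

    def test_invt2_like_map_merges_in_flipped_region(self):
        sc = get_scenario("invT2")
        s = fork_arrival_times(sc.chrom, sc.replication, 1000)
        assert 1_229_000 <= s.merge_position < 1_379_000
        assert s.merge_position != sc.chrom.loci["dif"]


class TestCopyNumberProfile:
    def test_exponential_copy_number_law(self):
        s = fork_arrival_times(toy_map(), PARAMS, 1000)
        n = copy_number_profile(s, PARAMS)
        # origin window (m=0) carries weight 1 pre-normalization, and a
        # window one doubling-time later carries 0.5 of it
        i50 = 50  # m = 50 min = tau
        assert n[i50] / n[0] == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize("name", SCENARIO_NAMES)
    def test_max_min_ratio_equals_ceff_doublings(self, name):
        sc = get_scenario(name)
        s = fork_arrival_times(sc.chrom, sc.replication, 1000)
        n = copy_number_profile(s, sc.replication)
        expected = 2.0 ** (s.c_eff / sc.replication.tau)
        assert n.max() / n.min() == pytest.approx(expected, rel=1e-12)
        assert n.sum() == pytest.approx(1.0, abs=1e-12)


class TestDegradationSurvival:
    def test_break_point_always_lost(self):
        chrom = toy_map()
        r = degradation_survival(chrom, DegradationModel(0.3, 40_000, 10_000), 1000)
        assert r[40] == 0.0

    def test_one_mean_extent_away(self):
        chrom = toy_map()
        r = degradation_survival(chrom, DegradationModel(0.3, 40_000, 10_000), 1000)
        assert r[50] == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_symmetry_about_break(self):
        chrom = toy_map()
        r = degradation_survival(chrom, DegradationModel(0.3, 40_000, 7_000), 1000)
        for d in (1, 5, 17, 30):
            assert r[40 - d] == pytest.approx(r[40 + d], rel=1e-12)


class TestMixtureProfile:
    def setup_method(self):
        chrom = toy_map()
        sched = fork_arrival_times(chrom, PARAMS, 1000)
        self.n = copy_number_profile(sched, PARAMS)
        self.r = degradation_survival(
            chrom, DegradationModel(0.3, 50_000, 10_000), 1000
        )

    def test_f_zero_is_identity(self):
        np.testing.assert_allclose(
            mixture_mfa_profile(self.n, self.r, 0.0), self.n, rtol=1e-12
        )

    def test_f_one_is_proportional_to_survival(self):
        mix = mixture_mfa_profile(self.n, self.r, 1.0)
        np.testing.assert_allclose(mix, self.r / self.r.sum(), rtol=1e-12)

    def test_ratio_minimum_at_break_window(self):
        mix = mixture_mfa_profile(self.n, self.r, 0.3)
        ratio = mix / self.n
        assert int(np.argmin(ratio)) == 50

    def test_components_must_share_grid(self):
        with pytest.raises(ValueError):
            mixture_mfa_profile(self.n, self.r[:-1], 0.3)

    def test_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError):
            mixture_mfa_profile(self.n, [self.r, self.r], [0.6, 0.6])


class TestSampleReads:
    def test_conservation_and_determinism(self):
        p = np.full(100, 0.01)
        c1 = sample_reads(p, 10**6, seed=4)
        c2 = sample_reads(p, 10**6, seed=4)
        assert c1.sum() == 10**6
        np.testing.assert_array_equal(c1, c2)
        assert not np.array_equal(c1, sample_reads(p, 10**6, seed=5))

    def test_law_of_large_numbers(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.full(1000, 50.0))
        counts = sample_reads(p, 10**7, seed=1)
        assert np.abs(counts / 10**7 - p).max() < 5e-4

    def test_rejects_unnormalized_profile(self):
        with pytest.raises(ValueError):
            sample_reads(np.full(10, 0.2), 100, seed=0)


class TestLineageForest:
    def test_no_events_without_q(self):
        t = simulate_lineage_forest(BranchingParams(0.0, 0.0), 20, 5, seed=1)
        assert t.divisions["daughter1_focus"].all()
        assert t.divisions["daughter2_focus"].all()

    def test_deterministic_chain(self):
        t = simulate_lineage_forest(BranchingParams(1.0, 1.0), 1, 3, seed=0)
        # one dividing line producing exactly one focus-less cell per frame
        assert len(t.divisions) == 3
        per_frame = t.divisions.groupby("frame").size()
        assert (per_frame == 1).all()
        losses = (~t.divisions["daughter1_focus"]).astype(int) + (
            ~t.divisions["daughter2_focus"]
        ).astype(int)
        assert (losses == 1).all()

    def test_initial_event_fraction_unbiased(self):
        q = 0.177
        t = simulate_lineage_forest(BranchingParams(q, 0.745), 10_000, 2, seed=8)
        stats = initial_event_fraction(t, assume_roots_normal=True)
        se = np.sqrt(q * (1 - q) / stats.n_counted)
        assert abs(stats.fraction - q) < 3 * se

    def test_double_loss_with_p_dimer(self):
        t = simulate_lineage_forest(
            BranchingParams(0.0, 0.0, p_dimer=1.0), 10, 3, seed=2
        )
        # every root division loses both daughters; nothing divides again
        assert len(t.divisions) == 10
        assert (~t.divisions["daughter1_focus"]).all()
        assert (~t.divisions["daughter2_focus"]).all()

    def test_interruption_produces_normal_generation(self):
        t = simulate_lineage_forest(
            BranchingParams(1.0, 1.0, p_interrupt=1.0), 1, 2, seed=3
        )
        # generation 1: the initial event; generation 2: the affected
        # retainer's division is interrupted, so both daughters keep foci
        assert len(t.divisions) == 2
        second = t.divisions[t.divisions["frame"] == 2].iloc[0]
        assert second["daughter1_focus"] and second["daughter2_focus"]
        labels = classify_divisions(t, assume_roots_normal=True)
        assert (labels["label"] == "INITIAL").sum() == 1

    def test_frames_strictly_increase(self):
        t = simulate_lineage_forest(BranchingParams(0.2, 0.7), 50, 6, seed=9)
        assert t.validate() == []
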