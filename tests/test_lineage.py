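"""Division classification, event statistics, branching steady state and
parameter estimation."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_labels, random_lineage_table
from terloss.fixtures import fig2e_table
from terloss.lineage import (
    BranchingParams,
    LineageTable,
    LineageValidationError,
    SupercriticalLossError,
    UndefinedStatisticError,
    classify_divisions,
    estimate_parameters,
    initial_event_fraction,
    steady_state_fractions,
    transmission_stats,
)
from terloss.simulate import simulate_lineage_forest


def simple_table(rows):
    return LineageTable(
        divisions=pd.DataFrame(
            rows,
            columns=[
                "division_id", "frame", "mother", "daughter1", "daughter2",
                "daughter1_focus", "daughter2_focus",
            ],
        )
    )


class TestClassifyDivisions:
    def test_single_normal_division(self):
        t = simple_table([("d0", 1, "r", "a", "b", True, True)])
        labels = classify_divisions(t)
        assert labels.loc["d0", "label"] == "NORMAL"

    def test_counting_schematic_labels(self):
        labels = classify_divisions(fig2e_table())
        assert labels.loc["2", "label"] == "INITIAL"
        assert labels.loc["7", "label"] == "INITIAL"
        assert labels.loc["X1", "label"] == "INHERITED"
        assert labels.loc["X2", "label"] == "INHERITED"
        normals = labels[labels["label"] == "NORMAL"].index
        assert sorted(normals) == ["1", "3", "4", "5", "6", "8", "9"]

    def test_root_starting_with_loss_excluded_with_subtree(self):
        t = simple_table(
            [
                ("d0", 1, "r", "a", "b", False, True),
                ("d1", 2, "b", "c", "e", False, True),
            ]
        )
        labels = classify_divisions(t)
        assert set(labels["label"]) == {"EXCLUDED"}
        labels = classify_divisions(t, assume_roots_normal=True)
        assert labels.loc["d0", "label"] == "INITIAL"
        assert labels.loc["d1", "label"] == "INHERITED"

    def test_retaining_branch_normal_divisions_flagged(self):
        rows = [
            ("d0", 1, "r", "a", "b", True, True),
            ("d1", 2, "a", "c", "e", False, True),  # initial event
            ("d2", 3, "e", "f", "g", True, True),   # normal on retaining branch
            ("d3", 4, "f", "h", "i", False, True),  # resumed loss
        ]
        t = simple_table(rows)
        labels = classify_divisions(t)
        assert labels.loc["d2", "label"] == "EXCLUDED"
        assert labels.loc["d3", "label"] == "INHERITED"
        labels = classify_divisions(t, count_retaining_normals=True)
        assert labels.loc["d2", "label"] == "NORMAL"

    def test_matches_brute_force_oracle_on_random_forests(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(1000):
            t = random_lineage_table(rng)
            if t is None:
                continue
            for flags in (
                {},
                {"assume_roots_normal": True},
                {"count_retaining_normals": True},
            ):
                got = classify_divisions(t, **flags)["label"].to_dict()
                assert got == brute_force_labels(t, **flags)
            checked += 1
        assert checked > 700

    def test_label_partition_reconciles(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            t = random_lineage_table(rng)
            if t is None:
                continue
            labels = classify_divisions(t)
            assert len(labels) == len(t.divisions)
            assert set(labels["label"]) <= {
                "NORMAL", "INITIAL", "INHERITED", "DOUBLE_LOSS", "EXCLUDED"
            }

    def test_duplicate_division_id_rejected(self):
        t = simple_table(
            [
                ("d0", 1, "r", "a", "b", True, True),
                ("d0", 2, "a", "c", "e", True, True),
            ]
        )
        with pytest.raises(LineageValidationError):
            classify_divisions(t)

    def test_non_increasing_frames_rejected(self):
        t = simple_table(
            [
                ("d0", 3, "r", "a", "b", True, True),
                ("d1", 2, "a", "c", "e", True, True),
            ]
        )
        with pytest.raises(LineageValidationError):
            classify_divisions(t)

    def test_dividing_focusless_cell_warns(self):
        t = simple_table(
            [
                ("d0", 1, "r", "a", "b", False, True),
                ("d1", 2, "a", "c", "e", True, True),
            ]
        )
        assert any("focus-less" in w for w in t.validate())


class TestInitialEventFraction:
    def test_counting_schematic_arithmetic(self):
        stats = initial_event_fraction(fig2e_table())
        assert stats.n_initial == 2
        assert stats.n_counted == 9
        assert stats.fraction == pytest.approx(2 / 9)

    def test_no_losses(self):
        rows = [("d%d" % i, 1 + i, "c%d" % i, "c%d" % (2 * i + 1), "c%d" % (2 * i + 2), True, True)
                for i in range(5)]
        # chain: each mother is a fresh root cell except linked below
        t = simple_table(
            [
                ("d0", 1, "r", "a", "b", True, True),
                ("d1", 2, "a", "c", "e", True, True),
                ("d2", 2, "b", "f", "g", True, True),
            ]
        )
        stats = initial_event_fraction(t)
        assert stats.fraction == 0.0
        assert stats.n_counted == 3

    def test_undefined_without_countable_divisions(self):
        t = simple_table([("d0", 1, "r", "a", "b", False, False)])
        with pytest.raises(UndefinedStatisticError):
            initial_event_fraction(t)

    def test_simulation_recovers_q(self):
        q = 0.177
        t = simulate_lineage_forest(BranchingParams(q, 0.745), 10_000, 3, seed=5)
        stats = initial_event_fraction(t, assume_roots_normal=True)
        se = np.sqrt(q * (1 - q) / stats.n_counted)
        assert abs(stats.fraction - q) < 3 * se


class TestTransmissionStats:
    def test_counting_schematic_transmission(self):
        trans = transmission_stats(fig2e_table())
        assert trans.n_observable == 1  # event 7 has no visible progeny
        assert trans.n_full == 1
        assert trans.pct_transmitted == 100.0

    def test_event_followed_by_censoring_unobservable(self):
        t = simple_table([("d0", 1, "r", "a", "b", True, True),
                          ("d1", 2, "a", "c", "e", False, True)])
        trans = transmission_stats(t)
        assert trans.n_observable == 0
        with pytest.raises(UndefinedStatisticError):
            trans.pct_transmitted

    def test_interrupted_transmission_detected(self):
        rows = [
            ("d0", 1, "r", "a", "b", True, True),
            ("d1", 2, "a", "c", "e", False, True),  # initial event
            ("d2", 3, "e", "f", "g", True, True),   # interruption
            ("d3", 4, "f", "h", "i", False, True),  # resumes
        ]
        trans = transmission_stats(simple_table(rows))
        assert trans.n_observable == 1
        assert trans.n_interrupted == 1
        assert trans.n_full == 0

    def test_single_occurrence_detected(self):
        rows = [
            ("d0", 1, "r", "a", "b", True, True),
            ("d1", 2, "a", "c", "e", False, True),  # initial event
            ("d2", 3, "e", "f", "g", True, True),   # only normal progeny
        ]
        trans = transmission_stats(simple_table(rows))
        assert trans.n_single == 1

    def test_full_heredity_fraction_matches_h_at_low_q(self):
        # at low q the confound (a fresh loss event mimicking transmission)
        # is negligible and the descriptive percentage estimates h
        h = 0.745
        t = simulate_lineage_forest(BranchingParams(0.02, h), 4000, 7, seed=6)
        trans = transmission_stats(t, assume_roots_normal=True)
        p = trans.n_full / trans.n_observable
        se = np.sqrt(h * (1 - h) / trans.n_observable)
        assert abs(p - h) < 3 * se + 0.02


class TestSteadyState:
    def test_no_events(self):
        ss = steady_state_fractions(BranchingParams(0.0, 0.5))
        assert (ss.normal, ss.affected, ss.focus_less) == (1.0, 0.0, 0.0)

    def test_no_transmission_focusless_equals_q(self):
        for q in (0.05, 0.177, 0.3):
            ss = steady_state_fractions(BranchingParams(q, 0.0))
            assert ss.focus_less == pytest.approx(q, rel=1e-12)

    def test_supercritical_rejected(self):
        with pytest.raises(SupercriticalLossError):
            steady_state_fractions(BranchingParams(0.6, 0.9))

    @pytest.mark.parametrize(
        "q,h", [(0.177, 0.745), (0.253, 0.8065), (0.1, 0.5), (0.3, 0.2)]
    )
    def test_matches_compartment_recursion(self, q, h):
        N, A, F = 1.0, 0.0, 0.0
        lam = 2 - q * (1 + h)
        for _ in range(200):
            N, A, F = lam * N, A + q * h * N, F + q * N + A
        total = N + A + F
        ss = steady_state_fractions(BranchingParams(q, h))
        assert ss.focus_less == pytest.approx(F / total, abs=1e-10)
        assert ss.normal == pytest.approx(N / total, abs=1e-10)

    def test_monotone_in_q_and_h(self):
        grid = np.linspace(0.01, 0.4, 8)
        for h in (0.0, 0.3, 0.7):
            fr = [steady_state_fractions(BranchingParams(q, h)).focus_less for q in grid]
            assert all(a < b for a, b in zip(fr, fr[1:]))
        for q in (0.05, 0.177):
            fr = [steadyness for steadyness in (
                steady_state_fractions(BranchingParams(q, h)).focus_less
                for h in np.linspace(0.0, 0.9, 8)
            )]
            assert all(a < b for a, b in zip(fr, fr[1:]))

    def test_agrees_with_stochastic_simulation(self):
        q, h = 0.177, 0.745
        gens = 11
        lam = 2 - q * (1 + h)
        N, A, F = 1.0, 0.0, 0.0
        for _ in range(gens):
            N, A, F = lam * N, A + q * h * N, F + q * N + A
        expect = F / (N + A + F)
        t = simulate_lineage_forest(BranchingParams(q, h), 300, gens, seed=4)
        alive = t.cells[t.cells["fate"] != "divided"]
        grp = alive.groupby("root")["fate"].agg(
            a=lambda s: (s == "arrested").sum(), n="size"
        )
        phat = grp["a"].sum() / grp["n"].sum()
        se = np.sqrt(((grp["a"] - phat * grp["n"]) ** 2).sum()) / grp["n"].sum()
        assert abs(phat - expect) < 3 * se


class TestEstimateParameters:
    def test_deterministic_chain(self):
        t = simulate_lineage_forest(BranchingParams(1.0, 1.0), 1, 3, seed=0)
        est = estimate_parameters(t, n_boot=50, seed=0, assume_roots_normal=True)
        assert est.q == 1.0
        assert est.h == 1.0

    def test_empty_forest_rejected(self):
        t = simulate_lineage_forest(BranchingParams(0.2, 0.5), 5, 0, seed=0)
        with pytest.raises(UndefinedStatisticError):
            estimate_parameters(t)

    def test_no_observable_events_flagged(self):
        t = simple_table(
            [
                ("d0", 1, "r", "a", "b", True, True),
                ("d1", 2, "a", "c", "e", False, True),
            ]
        )
        est = estimate_parameters(t, n_boot=50, seed=0)
        assert not est.h_defined
        assert np.isnan(est.h)

    def test_invariant_to_relabeling_and_row_order(self):
        t = simulate_lineage_forest(BranchingParams(0.25, 0.6), 100, 5, seed=11)
        div = t.divisions.copy()
        mapping = {c: f"cell_{c}" for c in
                   set(div["mother"]) | set(div["daughter1"]) | set(div["daughter2"])}
        div["mother"] = div["mother"].map(mapping)
        div["daughter1"] = div["daughter1"].map(mapping)
        div["daughter2"] = div["daughter2"].map(mapping)
        div = div.sample(frac=1.0, random_state=3).reset_index(drop=True)
        t2 = LineageTable(divisions=div)
        e1 = estimate_parameters(t, n_boot=10, seed=0, assume_roots_normal=True)
        e2 = estimate_parameters(t2, n_boot=10, seed=0, assume_roots_normal=True)
        assert e1.q == e2.q
        assert e1.h == e2.h
        assert e1.n_counted == e2.n_counted
        assert e1.n_observable == e2.n_observable

    def test_recovery_within_cis(self):
        true_q, true_h = 0.177, 0.745
        t = simulate_lineage_forest(BranchingParams(true_q, true_h), 500, 8, seed=42)
        est = estimate_parameters(t, n_boot=500, seed=1, assume_roots_normal=True)
        assert est.q_ci[0] <= true_q <= est.q_ci[1]
        assert est.h_ci[0] <= true_h <= est.h_ci[1]
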