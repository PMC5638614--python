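import numpy as np
import pandas as pd
import pytest

from terloss.lineage import LineageTable
from terloss.mfa import normalize, profile_from_counts, ratio_profile
from terloss.pipeline import simulate_scenario_counts
from terloss.scenarios import get_scenario


@pytest.fixture(scope="session")
def recb_scenario():
    return get_scenario("recB")


@pytest.fixture(scope="session")
def wild_type_scenario():
    return get_scenario("wild_type")


def scenario_ratio(scenario, depth, seed, window_bp=1000):
    """Mutant/reference ratio profile for a simulated scenario."""
    sample, reference, schedule = simulate_scenario_counts(
        scenario, window_bp, depth, seed
    )
    ratio = ratio_profile(
        normalize(profile_from_counts(sample, window_bp)),
        normalize(profile_from_counts(reference, window_bp)),
    )
    return ratio, schedule


def random_lineage_table(rng, max_depth=5, p_divide=0.75, p_loss=0.25, p_double=0.05):
    """A random valid lineage tree (focus-less daughters never divide)."""
    rows = []
    counter = [0]

    def new_id():
        counter[0] += 1
        return f"c{counter[0]}"

    def grow(cell, frame, depth):
        if depth >= max_depth or rng.random() > p_divide:
            return
        u = rng.random()
        if u < p_double:
            f1 = f2 = False
        elif u < p_double + p_loss:
            f1, f2 = (False, True) if rng.random() < 0.5 else (True, False)
        else:
            f1 = f2 = True
        d1, d2 = new_id(), new_id()
        rows.append((f"d{len(rows)}", frame, cell, d1, d2, f1, f2))
        if f1:
            grow(d1, frame + 1, depth + 1)
        if f2:
            grow(d2, frame + 1, depth + 1)

    grow("root", 1, 0)
    divisions = pd.DataFrame(
        rows,
        columns=[
            "division_id", "frame", "mother", "daughter1", "daughter2",
            "daughter1_focus", "daughter2_focus",
        ],
    )
    if divisions.empty:
        return None
    return LineageTable(divisions=divisions)


def brute_force_labels(table, count_retaining_normals=False, assume_roots_normal=False):
    """Independent ancestor-walk oracle for division classification."""
    div = {r["division_id"]: r for r in table.records()}
    creating = {}  # daughter cell -> division that created it
    for r in table.records():
        creating[r["daughter1"]] = r
        creating[r["daughter2"]] = r

    def chain(division):
        """Divisions strictly above this one, bottom-up, ending at the root's."""
        out = []
        cell = division["mother"]
        while cell in creating:
            parent = creating[cell]
            out.append(parent)
            cell = parent["mother"]
        return out

    def n_less(r):
        return (not r["daughter1_focus"]) + (not r["daughter2_focus"])

    labels = {}
    for did, r in div.items():
        ancestors = chain(r)
        top = ancestors[-1] if ancestors else r
        if n_less(top) > 0 and not assume_roots_normal:
            labels[did] = "EXCLUDED"
            continue
        anc_loss = any(n_less(a) == 1 for a in ancestors)
        k = n_less(r)
        if k == 2:
            labels[did] = "DOUBLE_LOSS"
        elif k == 1:
            labels[did] = "INHERITED" if anc_loss else "INITIAL"
        elif anc_loss and not count_retaining_normals:
            labels[did] = "EXCLUDED"
        else:
            labels[did] = "NORMAL"
    return labels
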