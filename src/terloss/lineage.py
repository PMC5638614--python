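"""Time-lapse lineage analysis of heritable focus loss.

A lineage table records cell divisions observed by time-lapse microscopy of
a fluorescently tagged terminus-proximal locus (ParB/parS focus).  Each
division has a mother, two daughters, and per-daughter focus status; cells
form a binary forest.  Divisions are classified following the field's
counting scheme:

* NORMAL      - both daughters keep a focus;
* INITIAL     - the first division of a lineage producing one focus-less
                daughter (the "initial event");
* INHERITED   - a single-loss division descending, through focus-retaining
                daughters, from an earlier single-loss division;
* DOUBLE_LOSS - both daughters lose the focus (dimer guillotining);
* EXCLUDED    - divisions outside the counting denominator: subtrees of
                roots whose first observed division is already a loss, and
                (by default) normal divisions on the retaining branch after
                an initial event.

The initial-event fraction is #INITIAL / (#NORMAL + #INITIAL), and
transmission statistics follow the focus-retaining daughter of each initial
event: an event is *observable* if at least one further division is seen,
*fully transmitted* if every observed subsequent division again produces a
focus-less daughter, *interrupted* if the loss pattern resumes after normal
division(s), and *single* otherwise.

The three-compartment branching model (normal / affected / focus-less)
behind these statistics has per-division initial-event probability q and
transmission probability h; its steady state is solved in closed form by
:func:`steady_state_fractions`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
import pandas as pd

NORMAL = "NORMAL"
INITIAL = "INITIAL"
INHERITED = "INHERITED"
DOUBLE_LOSS = "DOUBLE_LOSS"
EXCLUDED = "EXCLUDED"
LABELS = (NORMAL, INITIAL, INHERITED, DOUBLE_LOSS, EXCLUDED)

DIVISION_COLUMNS = [
    "division_id", "frame", "mother", "daughter1", "daughter2",
    "daughter1_focus", "daughter2_focus",
]
CELL_COLUMNS = ["cell_id", "fate"]
FATES = ("divided", "arrested", "censored")


class LineageValidationError(ValueError):
    """Structural defect in a lineage table (cycles, duplicate ids, ...)."""


class UndefinedStatisticError(ValueError):
    """A statistic has an empty denominator."""


class SupercriticalLossError(ValueError):
    """q(1+h) >= 1: the dividing population shrinks; no steady state."""


@dataclass
class BranchingParams:
    """Parameters of the heritable focus-loss branching process.

    q: per-division probability that a normal cell's division is an initial
       event (one focus-less daughter); h: probability that the retaining
       daughter of an initial event transmits the defect (becomes
       "affected", producing one focus-less daughter at every division);
    p_interrupt: per-division probability that an affected cell divides
       normally for one generation before resuming; p_dimer: probability
       that both daughters lose the focus (dimer breakage).
    """

    q: float
    h: float
    p_interrupt: float = 0.0
    p_dimer: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("q", "h", "p_interrupt", "p_dimer"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be a probability, got {v}")
        if self.q + self.p_dimer > 1.0:
            raise ValueError("q + p_dimer must not exceed 1")


@dataclass
class LineageTable:
    """Division records plus per-cell fates forming a binary forest."""

    divisions: pd.DataFrame
    cells: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in DIVISION_COLUMNS if c not in self.divisions.columns]
        if missing:
            raise LineageValidationError(f"missing division columns: {missing}")
        if self.cells is None:
            self.cells = self._derive_cells()

    def _derive_cells(self) -> pd.DataFrame:
        div = self.divisions
        mothers = set(div["mother"])
        rows = []
        for r in self.records():
            for d, focus in (
                (r["daughter1"], r["daughter1_focus"]),
                (r["daughter2"], r["daughter2_focus"]),
            ):
                if d in mothers:
                    fate = "divided"
                elif focus:
                    fate = "censored"
                else:
                    fate = "arrested"
                rows.append((d, fate))
        for root in self.roots():
            rows.append((root, "divided"))
        return pd.DataFrame(rows, columns=CELL_COLUMNS)

    def records(self) -> list[dict]:
        """Division rows as plain dicts (cached; much faster than iterrows)."""
        rec = getattr(self, "_records", None)
        if rec is None:
            rec = self.divisions.to_dict("records")
            object.__setattr__(self, "_records", rec)
        return rec

    def roots(self) -> list[Hashable]:
        div = self.divisions
        daughters = set(div["daughter1"]) | set(div["daughter2"])
        return sorted(
            {m for m in div["mother"] if m not in daughters}, key=lambda x: str(x)
        )

    def division_by_mother(self) -> dict[Hashable, dict]:
        out: dict[Hashable, dict] = {}
        for r in self.records():
            if r["mother"] in out:
                raise LineageValidationError(f"cell {r['mother']!r} divides twice")
            out[r["mother"]] = r
        return out

    def validate(self) -> list[str]:
        """Structural checks; returns soft warnings, raises on hard errors."""
        div = self.divisions
        warnings: list[str] = []
        if div["division_id"].duplicated().any():
            raise LineageValidationError("duplicate division ids")
        daughters = list(div["daughter1"]) + list(div["daughter2"])
        if len(daughters) != len(set(daughters)):
            raise LineageValidationError("a cell appears as daughter twice")
        by_mother = self.division_by_mother()
        focusless: set[Hashable] = set()
        for r in self.records():
            if not r["daughter1_focus"]:
                focusless.add(r["daughter1"])
            if not r["daughter2_focus"]:
                focusless.add(r["daughter2"])
        # frames strictly increase along every lineage; walk from roots
        for root in self.roots():
            stack = [(root, -np.inf)]
            seen: set[Hashable] = set()
            while stack:
                cell, frame = stack.pop()
                if cell in seen:
                    raise LineageValidationError("cycle detected in lineage")
                seen.add(cell)
                r = by_mother.get(cell)
                if r is None:
                    continue
                if not r["frame"] > frame:
                    raise LineageValidationError(
                        f"frames do not increase at division {r['division_id']!r}"
                    )
                stack.append((r["daughter1"], r["frame"]))
                stack.append((r["daughter2"], r["frame"]))
        for cell in focusless:
            if cell in by_mother:
                warnings.append(
                    f"focus-less cell {cell!r} divides later; "
                    "focus-less cells are expected to arrest"
                )
        return warnings


def classify_divisions(
    table: LineageTable,
    count_retaining_normals: bool = False,
    assume_roots_normal: bool = False,
) -> pd.DataFrame:
    """Label every division; returns a frame indexed by division_id.

    Columns: ``label`` (one of :data:`LABELS`) and ``root`` (the root cell
    of the tree the division belongs to).  ``assume_roots_normal`` disables
    the rule excluding roots whose first observed division is a loss (use it
    for simulated forests whose roots are normal by construction).
    ``count_retaining_normals=True`` keeps normal divisions on the
    post-initial-event retaining branch in the NORMAL denominator instead of
    excluding them.
    """
    table.validate()
    by_mother = table.division_by_mother()
    labels: dict[Hashable, str] = {}
    roots_of: dict[Hashable, Hashable] = {}
    for root in table.roots():
        # (cell, has single-loss ancestor division, subtree excluded)
        stack: list[tuple[Hashable, bool, bool]] = [(root, False, False)]
        while stack:
            cell, anc_loss, excluded = stack.pop()
            r = by_mother.get(cell)
            if r is None:
                continue
            f1 = bool(r["daughter1_focus"])
            f2 = bool(r["daughter2_focus"])
            n_less = (not f1) + (not f2)
            if cell == root and n_less > 0 and not assume_roots_normal:
                excluded = True  # observation started mid-phenomenon
            if excluded:
                label = EXCLUDED
            elif n_less == 2:
                label = DOUBLE_LOSS
            elif n_less == 1:
                label = INHERITED if anc_loss else INITIAL
            elif anc_loss and not count_retaining_normals:
                label = EXCLUDED
            else:
                label = NORMAL
            labels[r["division_id"]] = label
            roots_of[r["division_id"]] = root
            for d, focus in ((r["daughter1"], f1), (r["daughter2"], f2)):
                child_excluded = excluded or not focus  # dividing focus-less: excluded
                child_anc = anc_loss or (n_less == 1 and focus)
                stack.append((d, child_anc, child_excluded))
    out = pd.DataFrame(
        {
            "label": pd.Series(labels),
            "root": pd.Series(roots_of),
        }
    )
    out.index.name = "division_id"
    return out


@dataclass
class InitialEventStats:
    n_initial: int
    n_normal: int
    n_inherited: int
    n_double_loss: int
    n_excluded: int

    @property
    def n_counted(self) -> int:
        return self.n_initial + self.n_normal

    @property
    def fraction(self) -> float:
        if self.n_counted == 0:
            raise UndefinedStatisticError("no countable divisions")
        return self.n_initial / self.n_counted


def initial_event_fraction(
    table: LineageTable, labels: pd.DataFrame | None = None, **classify_kwargs
) -> InitialEventStats:
    """Initial-event statistic: #INITIAL / (#NORMAL + #INITIAL)."""
    if labels is None:
        labels = classify_divisions(table, **classify_kwargs)
    counts = labels["label"].value_counts()
    stats = InitialEventStats(
        n_initial=int(counts.get(INITIAL, 0)),
        n_normal=int(counts.get(NORMAL, 0)),
        n_inherited=int(counts.get(INHERITED, 0)),
        n_double_loss=int(counts.get(DOUBLE_LOSS, 0)),
        n_excluded=int(counts.get(EXCLUDED, 0)),
    )
    if stats.n_counted == 0:
        raise UndefinedStatisticError("no countable divisions")
    return stats


@dataclass
class TransmissionStats:
    n_observable: int
    n_full: int
    n_interrupted: int
    n_single: int
    n_first_loss: int  # observable events whose first further division is a loss
    events: pd.DataFrame  # division_id, root, observable, outcome, first_loss

    @property
    def pct_transmitted(self) -> float:
        if self.n_observable == 0:
            raise UndefinedStatisticError("no initial event with observable progeny")
        return 100.0 * self.n_full / self.n_observable


def _retaining_daughter(row: Mapping) -> Hashable:
    return row["daughter1"] if row["daughter1_focus"] else row["daughter2"]


def _walk_transmission(
    start: Hashable, by_mother: Mapping[Hashable, Mapping]
) -> list[str]:
    """Loss/normal pattern of the retaining branch after an initial event."""
    statuses: list[str] = []
    cell = start
    while True:
        r = by_mother.get(cell)
        if r is None:
            return statuses
        f1, f2 = bool(r["daughter1_focus"]), bool(r["daughter2_focus"])
        n_less = (not f1) + (not f2)
        if n_less == 2:
            statuses.append("loss")
            return statuses  # both daughters arrest
        if n_less == 1:
            statuses.append("loss")
            cell = _retaining_daughter(r)
            continue
        statuses.append("normal")
        # after an interruption, continue with the daughter whose own next
        # division resumes the loss pattern, if any
        nxt = None
        for d in (r["daughter1"], r["daughter2"]):
            dr = by_mother.get(d)
            if dr is not None and (
                not dr["daughter1_focus"] or not dr["daughter2_focus"]
            ):
                nxt = d
                break
        if nxt is None:
            return statuses
        cell = nxt


def transmission_stats(
    table: LineageTable, labels: pd.DataFrame | None = None, **classify_kwargs
) -> TransmissionStats:
    """Transmission outcome of each initial event (full-heredity counting).

    Interrupted events (loss resuming after a normal generation) are
    reported separately and never enter ``pct_transmitted``.
    """
    if labels is None:
        labels = classify_divisions(table, **classify_kwargs)
    by_mother = table.division_by_mother()
    div_by_id = {r["division_id"]: r for r in table.records()}
    rows = []
    for division_id, rec in labels[labels["label"] == INITIAL].iterrows():
        r = div_by_id[division_id]
        statuses = _walk_transmission(_retaining_daughter(r), by_mother)
        observable = len(statuses) > 0
        if not observable:
            outcome = "unobservable"
        elif all(s == "loss" for s in statuses):
            outcome = "full"
        elif any(s == "loss" for s in statuses):
            outcome = "interrupted"
        else:
            outcome = "single"
        first_loss = observable and statuses[0] == "loss"
        rows.append((division_id, rec["root"], observable, outcome, first_loss))
    events = pd.DataFrame(
        rows, columns=["division_id", "root", "observable", "outcome", "first_loss"]
    )
    n_obs = int(events["observable"].sum())
    return TransmissionStats(
        n_observable=n_obs,
        n_full=int((events["outcome"] == "full").sum()),
        n_interrupted=int((events["outcome"] == "interrupted").sum()),
        n_single=int((events["outcome"] == "single").sum()),
        n_first_loss=int(events["first_loss"].sum()),
        events=events,
    )


@dataclass(frozen=True)
class SteadyState:
    """Asymptotic population composition of the branching model."""

    normal: float
    affected: float
    focus_less: float

    @property
    def focus_less_pct(self) -> float:
        return 100.0 * self.focus_less


def steady_state_fractions(params: BranchingParams) -> SteadyState:
    """Closed-form steady-state composition (normal, affected, focus-less).

    Per generation a normal cell divides into two normal cells, except with
    probability q the division is an initial event: one daughter is
    focus-less (and arrests) and the retaining daughter becomes affected
    with probability h.  Affected cells produce one affected and one
    focus-less daughter at every division; focus-less cells persist without
    dividing.  The dividing population grows by lambda = 2 - q(1+h) per
    generation; relative to normal cells the stable ratios are
    affected = qh/(lambda-1) and focus-less = (q + affected)/(lambda-1),
    which simplifies to a focus-less share of exactly q(1+h).
    """
    q, h = params.q, params.h
    if q == 0:
        return SteadyState(1.0, 0.0, 0.0)
    lam = 2.0 - q * (1.0 + h)
    if lam <= 1.0:
        raise SupercriticalLossError(
            f"q(1+h) = {q * (1 + h):.4g} >= 1: dividing population shrinks"
        )
    affected = q * h / (lam - 1.0)
    focus_less = (q + affected) / (lam - 1.0)
    total = 1.0 + affected + focus_less
    return SteadyState(1.0 / total, affected / total, focus_less / total)


@dataclass
class ParameterEstimate:
    """Moment estimates of the branching parameters.

    q is the initial-event fraction.  h uses the first-transition
    correction h = (p1 - q)/(1 - q), where p1 is the fraction of
    observable initial events whose first subsequent division is again a
    loss: the raw full-heredity percentage overestimates h because a
    non-transmitted retainer whose only observed division is a fresh loss
    event is indistinguishable from transmission.  ``h_full_fraction``
    keeps the uncorrected descriptive value.
    """

    q: float
    h: float
    q_ci: tuple[float, float]
    h_ci: tuple[float, float]
    n_counted: int
    n_observable: int
    h_full_fraction: float = float("nan")
    h_defined: bool = True


def _per_root_counts(
    labels: pd.DataFrame, trans: TransmissionStats
) -> pd.DataFrame:
    lab = labels.reset_index()
    counted = (
        lab[lab["label"].isin([NORMAL, INITIAL])].groupby("root").size()
    )
    initial = lab[lab["label"] == INITIAL].groupby("root").size()
    ev = trans.events
    observable = ev[ev["observable"]].groupby("root").size()
    first_loss = ev[ev["first_loss"]].groupby("root").size()
    roots = sorted(set(lab["root"]), key=lambda x: str(x))
    out = pd.DataFrame(index=pd.Index(roots, name="root"))
    for nm, s in (
        ("counted", counted), ("initial", initial),
        ("observable", observable), ("first_loss", first_loss),
    ):
        out[nm] = s.reindex(out.index).fillna(0).astype(int)
    return out


def estimate_parameters(
    table: LineageTable,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    ci_method: str = "normal",
    **classify_kwargs,
) -> ParameterEstimate:
    """Moment estimators (q-hat, h-hat) with root-resampling bootstrap CIs.

    ``ci_method`` is "normal" (estimate +/- z * bootstrap SD; slightly
    conservative for h in calibration runs) or "percentile".
    """
    labels = classify_divisions(table, **classify_kwargs)
    stats = initial_event_fraction(table, labels=labels)
    trans = transmission_stats(table, labels=labels)
    q_hat = stats.fraction
    h_defined = trans.n_observable > 0

    def h_from(p1: float, q: float) -> float:
        if q >= 1.0:
            return 1.0
        return float(np.clip((p1 - q) / (1.0 - q), 0.0, 1.0))

    if h_defined:
        p1 = trans.n_first_loss / trans.n_observable
        h_hat = h_from(p1, q_hat)
        h_full = trans.n_full / trans.n_observable
    else:
        h_hat = float("nan")
        h_full = float("nan")

    per_root = _per_root_counts(labels, trans).to_numpy()
    rng = np.random.default_rng(seed)
    n_roots = per_root.shape[0]
    idx = rng.integers(0, n_roots, size=(n_boot, n_roots))
    sums = per_root[idx].sum(axis=1)  # counted, initial, observable, first_loss
    with np.errstate(invalid="ignore", divide="ignore"):
        q_star = sums[:, 1] / sums[:, 0]
        p1_star = sums[:, 3] / sums[:, 2]
        h_star = np.clip((p1_star - q_star) / (1.0 - q_star), 0.0, 1.0)
    alpha = 100.0 * (1.0 - ci_level) / 2.0
    q_star = q_star[np.isfinite(q_star)]
    h_star = h_star[np.isfinite(h_star)]

    def interval(stars: np.ndarray, point: float) -> tuple[float, float]:
        if len(stars) == 0:
            return (float("nan"), float("nan"))
        if ci_method == "percentile":
            lo, hi = np.percentile(stars, [alpha, 100 - alpha])
        elif ci_method == "normal":
            from scipy import stats as _st

            z = _st.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
            sd = float(stars.std())
            lo, hi = point - z * sd, point + z * sd
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        return (float(lo), float(hi))

    q_ci = interval(q_star, q_hat)
    h_ci = interval(h_star, h_hat) if h_defined else (float("nan"), float("nan"))
    return ParameterEstimate(
        q=q_hat, h=h_hat, q_ci=q_ci, h_ci=h_ci,
        n_counted=stats.n_counted, n_observable=trans.n_observable,
        h_full_fraction=h_full, h_defined=h_defined,
    )
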