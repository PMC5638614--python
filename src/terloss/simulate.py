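"""Synthetic MFA and lineage data with the structure the analyses assume.

Marker-frequency data: in an exponentially growing population a locus first
replicated at time m(x) after initiation is present at relative copy number
2^(-m(x)/tau) (tau = doubling time), giving the familiar origin-to-terminus
read-count gradient.  Two forks leave oriC in opposite directions at a
constant speed; an oriented Ter site arrests the fork arriving from its
blocked direction, and the arrested fork waits until the opposing fork
reaches it, which sets the fork merge point and the effective C period.

Terminus degradation: a fraction f of cells carry a fully replicated,
non-replicating chromosome broken at position b and resected from the break
on both sides by independent exponential extents of mean L; the expected
retained fraction of window x among broken chromosomes is
r(x) = 1 - exp(-d(x,b)/L).  The population profile is the mixture
(1-f) n(x) + f c r(x) with c the copy number of a completed chromosome
(max of n), and finite sequencing depth is a multinomial draw from it.

Lineage forests follow the branching model of :mod:`terloss.lineage`:
normal cells suffer an initial event with probability q per division, the
retaining daughter transmits with probability h, focus-less cells arrest.

All stochastic operations take explicit seeds; there is no global state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CLOCKWISE, COUNTERCLOCKWISE, ChromosomeMap
from .lineage import BranchingParams, DIVISION_COLUMNS, LineageTable


class ForkTrapError(ValueError):
    """Both forks permanently trapped with an unreplicated gap between them."""


@dataclass(frozen=True)
class ReplicationParams:
    """Doubling time tau (min) and fork speed (bp/min); the effective
    replication period C_eff is derived from the map, never set."""

    tau: float = 60.0
    fork_speed: float = 50_000.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.fork_speed <= 0:
            raise ValueError("tau and fork_speed must be positive")


@dataclass(frozen=True)
class DegradationModel:
    """Broken-cell fraction f, break position b (bp), mean per-side
    exonucleolytic degradation extent L (bp)."""

    f: float
    b: int
    L: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must be in [0, 1]")
        if self.L <= 0:
            raise ValueError("L must be positive")


@dataclass(frozen=True)
class ForkBranch:
    """One deterministic arrest outcome with its mixture weight."""

    weight: float
    m: np.ndarray  # minutes, per window
    c_eff: float
    merge_position: int


@dataclass(frozen=True)
class ForkSchedule:
    window_bp: int
    coords: np.ndarray  # per-window evaluation coordinates (window starts), bp
    branches: tuple[ForkBranch, ...]

    def _single(self) -> ForkBranch:
        if len(self.branches) != 1:
            raise ValueError(
                "schedule is a mixture over arrest outcomes; inspect .branches"
            )
        return self.branches[0]

    @property
    def m(self) -> np.ndarray:
        return self._single().m

    @property
    def c_eff(self) -> float:
        return self._single().c_eff

    @property
    def merge_position(self) -> int:
        return self._single().merge_position


def window_grid(length_bp: int, window_bp: int) -> np.ndarray:
    """Window start coordinates; densities are evaluated at window starts
    so that a map whose oriC lies on the grid attains m = 0 exactly (the
    final window may be short; no width weighting is applied)."""
    return np.arange(0, length_bp, window_bp, dtype=np.int64)


def _branch_times(
    chrom: ChromosomeMap,
    params: ReplicationParams,
    blocking: list,
    offsets: np.ndarray,
) -> tuple[np.ndarray, float, int]:
    length = chrom.length_bp
    v = params.fork_speed
    cw_offsets = [chrom.offset(t.position) for t in blocking if t.blocks == CLOCKWISE]
    ccw_offsets = [chrom.offset(t.position) for t in blocking if t.blocks == COUNTERCLOCKWISE]
    b_cw = min(cw_offsets) if cw_offsets else np.inf  # first arrest of the cw fork
    a_ccw = max(ccw_offsets) if ccw_offsets else 0.0  # first arrest of the ccw fork
    t_cw = np.where(offsets <= b_cw, offsets / v, np.inf)
    t_ccw = np.where(offsets >= a_ccw, (length - offsets) / v, np.inf)
    m = np.minimum(t_cw, t_ccw)
    if not np.all(np.isfinite(m)):
        raise ForkTrapError(
            "opposing blocking Ter sites leave an unreplicated gap; "
            "both forks are trapped with no meeting point"
        )
    i = int(np.argmax(m))
    return m, float(m[i] - m.min()), i


def fork_arrival_times(
    chrom: ChromosomeMap, params: ReplicationParams, window_bp: int = 1000
) -> ForkSchedule:
    """Per-window first-replication time m(x) under the Ter fork trap.

    Sites with efficiency 1 always arrest, efficiency 0 never; at most one
    site per direction may be partial, in which case the schedule is a
    mixture over the enumerable arrest outcomes with weights given by the
    efficiencies.
    """
    coords = window_grid(chrom.length_bp, window_bp)
    offsets = (coords - chrom.oriC) % chrom.length_bp
    always = [t for t in chrom.ter_sites if t.efficiency == 1.0]
    partial = [t for t in chrom.ter_sites if 0.0 < t.efficiency < 1.0]
    for direction in (CLOCKWISE, COUNTERCLOCKWISE):
        if sum(t.blocks == direction for t in partial) > 1:
            raise ValueError(
                f"at most one {direction}-blocking Ter may have partial efficiency"
            )
    branches = []
    for active in itertools.product([True, False], repeat=len(partial)):
        weight = 1.0
        blocking = list(always)
        for site, on in zip(partial, active):
            weight *= site.efficiency if on else 1.0 - site.efficiency
            if on:
                blocking.append(site)
        if weight == 0.0:
            continue
        m, c_eff, i_merge = _branch_times(chrom, params, blocking, offsets)
        branches.append(
            ForkBranch(
                weight=weight, m=m, c_eff=c_eff,
                merge_position=int(coords[i_merge]),
            )
        )
    return ForkSchedule(window_bp=window_bp, coords=coords, branches=tuple(branches))


def copy_number_profile(
    schedule: ForkSchedule, params: ReplicationParams
) -> np.ndarray:
    """Normalized per-window relative copy number n(x) = 2^(-m(x)/tau).

    For a mixture schedule the branch profiles are averaged with their
    weights before normalization.  Within a single branch the pre-
    normalization max/min ratio equals 2^(C_eff/tau) exactly.
    """
    dens = np.zeros_like(schedule.coords, dtype=float)
    for br in schedule.branches:
        dens += br.weight * np.exp2(-br.m / params.tau)
    return dens / dens.sum()


def degradation_survival(
    chrom: ChromosomeMap, model: DegradationModel, window_bp: int = 1000
) -> np.ndarray:
    """Expected retained fraction r(x) among broken chromosomes.

    Per-side degradation extents are independent Exponential(mean L) from
    the break at b, so r(x) = 1 - exp(-d(x, b)/L) with d the circular
    distance; r(b) = 0 and r is symmetric about b.
    """
    chrom._check_position(model.b)
    coords = window_grid(chrom.length_bp, window_bp)
    d = np.abs(coords - model.b)
    d = np.minimum(d, chrom.length_bp - d)
    return 1.0 - np.exp(-d / model.L)


def mixture_mfa_profile(copy_number, r, f) -> np.ndarray:
    """Expected read-frequency profile of the intact/broken cell mixture.

    rho(x) = (1 - sum f_i) n(x) + c sum_i f_i r_i(x), normalized to 1, with
    c = max(n) the copy number of a completed non-replicating chromosome.
    ``r``/``f`` may be a single survival profile and fraction or parallel
    sequences of them (e.g. a dif-centred break plus a weaker Ter break).
    """
    n = np.asarray(copy_number, dtype=float)
    if np.isscalar(f) or isinstance(f, float | int):
        fs = [float(f)]
        rs = [np.asarray(r, dtype=float)]
    else:
        fs = [float(x) for x in f]
        rs = [np.asarray(x, dtype=float) for x in r]
    if len(fs) != len(rs):
        raise ValueError("r and f must have the same number of components")
    total_f = sum(fs)
    if not 0.0 <= total_f <= 1.0:
        raise ValueError("broken-cell fractions must sum into [0, 1]")
    for ri in rs:
        if ri.shape != n.shape:
            raise ValueError("survival profile grid does not match copy-number grid")
    c = n.max()
    rho = (1.0 - total_f) * n
    for fi, ri in zip(fs, rs):
        rho = rho + fi * c * ri
    return rho / rho.sum()


def sample_reads(profile: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Multinomial per-window read counts at a given total depth."""
    p = np.asarray(profile, dtype=float)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
        raise ValueError("profile must be a normalized frequency vector")
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, p / p.sum())


# --- lineage forest simulation -------------------------------------------

_NORMAL, _AFFECTED, _FOCUSLESS = 0, 1, 2


def simulate_lineage_forest(
    params: BranchingParams, n_roots: int, n_generations: int, seed: int
) -> LineageTable:
    """Generation-synchronous forest under the heritable-loss model.

    Roots are normal cells.  A normal cell's division is, with probability
    p_dimer, a double loss (both daughters arrest); with probability q an
    initial event (one focus-less daughter, retainer affected with
    probability h); otherwise two normal daughters.  An affected cell
    produces one affected and one focus-less daughter per division, except
    with probability p_interrupt it divides into one affected and one
    normal daughter with both foci kept (a one-generation interruption).
    Focus-less cells never divide.  Cells alive at the horizon are censored.
    """
    rng = np.random.default_rng(seed)
    next_id = itertools.count(n_roots)
    cur_ids = np.arange(n_roots, dtype=np.int64)
    cur_states = np.full(n_roots, _NORMAL, dtype=np.int8)
    cur_roots = np.arange(n_roots, dtype=np.int64)
    frames: list[np.ndarray] = []
    mothers: list[np.ndarray] = []
    d1s: list[np.ndarray] = []
    d2s: list[np.ndarray] = []
    f1s: list[np.ndarray] = []
    f2s: list[np.ndarray] = []
    arrested: list[np.ndarray] = []
    arrested_roots: list[np.ndarray] = []

    for gen in range(n_generations):
        n = len(cur_ids)
        if n == 0:
            break
        d1 = np.fromiter(next_id, dtype=np.int64, count=n)
        d2 = np.fromiter(next_id, dtype=np.int64, count=n)
        s1 = np.empty(n, dtype=np.int8)
        s2 = np.empty(n, dtype=np.int8)
        u = rng.random(n)
        v = rng.random(n)
        swap = rng.random(n) < 0.5  # which daughter is focus-less

        normal = cur_states == _NORMAL
        dimer = normal & (u < params.p_dimer)
        initial = normal & ~dimer & (u < params.p_dimer + params.q)
        plain = normal & ~dimer & ~initial
        affected = cur_states == _AFFECTED
        interrupt = affected & (v < params.p_interrupt)
        transmit = affected & ~interrupt

        s1[plain] = _NORMAL
        s2[plain] = _NORMAL
        s1[dimer] = _FOCUSLESS
        s2[dimer] = _FOCUSLESS
        retainer_state = np.where(rng.random(n) < params.h, _AFFECTED, _NORMAL)
        s1[initial] = np.where(swap[initial], _FOCUSLESS, retainer_state[initial])
        s2[initial] = np.where(swap[initial], retainer_state[initial], _FOCUSLESS)
        s1[transmit] = np.where(swap[transmit], _FOCUSLESS, _AFFECTED)
        s2[transmit] = np.where(swap[transmit], _AFFECTED, _FOCUSLESS)
        s1[interrupt] = _AFFECTED
        s2[interrupt] = _NORMAL

        frames.append(np.full(n, gen + 1, dtype=np.int64))
        mothers.append(cur_ids)
        d1s.append(d1)
        d2s.append(d2)
        f1s.append(s1 != _FOCUSLESS)
        f2s.append(s2 != _FOCUSLESS)

        ids = np.concatenate([d1, d2])
        states = np.concatenate([s1, s2])
        roots2 = np.concatenate([cur_roots, cur_roots])
        arrested.append(ids[states == _FOCUSLESS])
        arrested_roots.append(roots2[states == _FOCUSLESS])
        keep = states != _FOCUSLESS
        cur_ids = ids[keep]
        cur_states = states[keep]
        cur_roots = roots2[keep]

    if frames:
        divisions = pd.DataFrame(
            {
                "division_id": np.arange(sum(len(f) for f in frames)),
                "frame": np.concatenate(frames),
                "mother": np.concatenate(mothers),
                "daughter1": np.concatenate(d1s),
                "daughter2": np.concatenate(d2s),
                "daughter1_focus": np.concatenate(f1s),
                "daughter2_focus": np.concatenate(f2s),
            }
        )
    else:
        divisions = pd.DataFrame(columns=DIVISION_COLUMNS)
    arrested_ids = np.concatenate(arrested) if arrested else np.array([], dtype=np.int64)
    arrested_rt = (
        np.concatenate(arrested_roots) if arrested_roots else np.array([], dtype=np.int64)
    )
    live = cur_ids >= n_roots  # roots listed separately below
    cur_ids, cur_roots = cur_ids[live], cur_roots[live]
    mothers_all = set(divisions["mother"]) if len(divisions) else set()
    root_fates = ["divided" if r in mothers_all else "censored" for r in range(n_roots)]
    cells = pd.DataFrame(
        {
            "cell_id": np.concatenate(
                [np.arange(n_roots), arrested_ids, cur_ids]
            ),
            "fate": (
                root_fates
                + ["arrested"] * len(arrested_ids)
                + ["censored"] * len(cur_ids)
            ),
            "root": np.concatenate(
                [np.arange(n_roots), arrested_rt, cur_roots]
            ),
        }
    )
    return LineageTable(divisions=divisions, cells=cells)
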