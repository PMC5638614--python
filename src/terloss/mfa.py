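"""Marker-frequency-analysis pipeline.

Windowed read counts are normalized to frequencies (reads per window over
total reads), pairs of frequency profiles on the same grid form ratio
profiles (mutant over isogenic reference), and a terminus DNA-loss dip in a
ratio profile is detected and quantified by fitting the degradation mixture
model of :mod:`terloss.simulate`: broken-cell fraction f, break position b
and mean per-side degradation extent L.

Profiles carry a per-window validity mask.  Masked windows are excluded
from totals and averages but never dropped, so grids stay aligned across
strains; ratios are only defined between profiles on identical grids.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import ndimage, optimize, signal

from .genome import ChromosomeMap
from .simulate import (
    DegradationModel,
    ForkSchedule,
    ReplicationParams,
    copy_number_profile,
    fork_arrival_times,
)

COUNTS = "counts"
FREQUENCY = "frequency"
RATIO = "ratio"


class GridMismatchError(ValueError):
    """Profiles are not on the same window grid."""


class FitError(RuntimeError):
    """Degradation-model fit failed to converge; carries initial values."""


@dataclass(frozen=True)
class MfaProfile:
    """Per-window values over the circular genome.

    kind is "counts", "frequency" (sums to 1 over unmasked windows) or
    "ratio" (sample frequency over reference frequency).
    """

    window_bp: int
    values: np.ndarray
    kind: str = COUNTS
    mask: np.ndarray | None = None  # True = valid
    chrom: str = "chr"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.kind not in (COUNTS, FREQUENCY, RATIO):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        mask = self.mask
        if mask is None:
            mask = np.ones(len(self.values), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")
        object.__setattr__(self, "mask", mask)

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows, dtype=np.int64) * self.window_bp

    def same_grid(self, other: "MfaProfile") -> bool:
        return (
            self.window_bp == other.window_bp and self.n_windows == other.n_windows
        )


def profile_from_counts(
    counts, window_bp: int, mask=None, chrom: str = "chr"
) -> MfaProfile:
    return MfaProfile(
        window_bp=window_bp, values=counts, kind=COUNTS, mask=mask, chrom=chrom
    )


def normalize(profile: MfaProfile) -> MfaProfile:
    """Counts -> frequencies; masked windows are excluded from the total."""
    if profile.kind != COUNTS:
        raise ValueError("normalize expects a counts profile")
    total = profile.values[profile.mask].sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero counts profile")
    values = np.where(profile.mask, profile.values / total, 0.0)
    return _dc_replace(profile, values=values, kind=FREQUENCY)


def ratio_profile(sample: MfaProfile, reference: MfaProfile) -> MfaProfile:
    """Per-window sample/reference; zero-reference windows are masked."""
    if sample.kind != FREQUENCY or reference.kind != FREQUENCY:
        raise ValueError("ratio_profile expects two frequency profiles")
    if not sample.same_grid(reference):
        raise GridMismatchError("sample and reference are on different grids")
    mask = sample.mask & reference.mask & (reference.values > 0)
    values = np.zeros_like(sample.values)
    values[mask] = sample.values[mask] / reference.values[mask]
    return MfaProfile(
        window_bp=sample.window_bp, values=values, kind=RATIO, mask=mask,
        chrom=sample.chrom,
    )


def smooth(profile: MfaProfile, half_width_windows: int) -> MfaProfile:
    """Circular moving average of width 2h+1 ignoring masked windows."""
    if half_width_windows < 0:
        raise ValueError("half_width must be >= 0")
    if half_width_windows == 0:
        return profile
    size = 2 * half_width_windows + 1
    m = profile.mask.astype(float)
    num = ndimage.uniform_filter1d(profile.values * m, size=size, mode="wrap")
    den = ndimage.uniform_filter1d(m, size=size, mode="wrap")
    values = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return _dc_replace(profile, values=values)


@dataclass(frozen=True)
class LossPeak:
    """A DNA-loss dip in a ratio profile."""

    center: int  # bp, window midpoint convention: window start used
    depth: float  # baseline minus minimum
    width: int  # bp at half depth
    baseline: float


def _circular_region_below(values, mask, center_idx, threshold) -> np.ndarray:
    """Indices of the contiguous (circular) run around center below threshold."""
    n = len(values)
    below = (values < threshold) & mask
    idx = [center_idx]
    i = (center_idx + 1) % n
    while below[i] and len(idx) < n:
        idx.append(i)
        i = (i + 1) % n
    i = (center_idx - 1) % n
    while below[i] and len(idx) < n:
        idx.append(i)
        i = (i - 1) % n
    return np.array(sorted(set(idx)))


def detect_loss_peaks(
    ratio: MfaProfile,
    baseline_exclusion_bp: int = 700_000,
    mad_factor: float = 3.0,
    smooth_half_width: int = 5,
    max_peaks: int = 5,
) -> list[LossPeak]:
    """Ordered (deepest first) DNA-loss dips in a ratio profile.

    The candidate center is the global argmin of the smoothed ratio (ties:
    smallest coordinate); the baseline is the median over windows more than
    ``baseline_exclusion_bp`` from the deepest center (outside a Ter-
    macrodomain-sized neighbourhood) and a dip is kept only if its depth
    exceeds ``mad_factor`` times the MAD of those baseline windows.
    Secondary dips are found after masking each accepted dip's half-depth
    region.
    """
    if ratio.kind != RATIO:
        raise ValueError("detect_loss_peaks expects a ratio profile")
    sm = smooth(ratio, smooth_half_width)
    values = sm.values
    mask = sm.mask.copy()
    if not mask.any():
        return []
    n = ratio.n_windows
    w = ratio.window_bp
    length = n * w
    primary_idx = int(np.flatnonzero(mask)[np.argmin(values[mask])])
    starts = ratio.starts()
    dist = np.abs(starts - starts[primary_idx])
    dist = np.minimum(dist, length - dist)
    base_sel = (dist > baseline_exclusion_bp) & sm.mask
    if not base_sel.any():
        base_sel = sm.mask
    # baseline level and noise scale from the raw (unsmoothed) ratio, so
    # smoothing cannot talk a flat noisy profile into a spurious dip; the
    # per-window MAD is taken on first differences (detrended) so the
    # genuine copy-number tilt of mixture ratios does not inflate it
    base_vals = ratio.values[base_sel]
    baseline = float(np.median(base_vals))
    mad = float(np.median(np.abs(np.diff(base_vals)))) / np.sqrt(2.0)

    peaks: list[LossPeak] = []
    depth = baseline - float(values[primary_idx])
    if depth < mad_factor * mad or depth <= 0:
        return peaks
    half = baseline - depth / 2.0
    region = _circular_region_below(values, sm.mask, primary_idx, half)
    peaks.append(
        LossPeak(
            center=int(starts[primary_idx]), depth=depth,
            width=int(len(region) * w), baseline=baseline,
        )
    )
    claimed = np.zeros(n, dtype=bool)
    claimed[region] = True
    margin = max(len(region) // 4, 5)
    for i in region.tolist():
        claimed[(np.arange(i - margin, i + margin + 1)) % n] = True

    # secondary dips (ectopic/inverted Ter breaks) ride on the primary
    # dip's flanks and on the copy-number tilt of the mixture, so they are
    # found as local minima by prominence rather than against the global
    # baseline; the same noise threshold applies to the prominence
    rolled = np.roll(values, -primary_idx)  # cut the circle at the primary
    minima, props = signal.find_peaks(
        -rolled, prominence=mad_factor * mad, width=1, rel_height=0.5
    )
    order = np.argsort(rolled[minima])
    for j in order:
        if len(peaks) >= max_peaks:
            break
        cand = int((minima[j] + primary_idx) % n)
        if claimed[cand] or not sm.mask[cand]:
            continue
        prominence = float(props["prominences"][j])
        width_w = max(int(round(props["widths"][j])), 1)
        peaks.append(
            LossPeak(
                center=int(starts[cand]), depth=prominence,
                width=int(width_w * w),
                baseline=float(rolled[minima[j]] + prominence),
            )
        )
        radius = min(max(width_w, 5), 150_000 // w)  # broad basins claim at most 150 kb
        claimed[np.arange(cand - radius, cand + radius + 1) % n] = True
    return peaks


def detect_loss_peak(ratio: MfaProfile, **kwargs) -> LossPeak | None:
    """The deepest DNA-loss dip, or None when no dip clears the threshold."""
    peaks = detect_loss_peaks(ratio, **kwargs)
    return peaks[0] if peaks else None


@dataclass
class DegradationFit:
    model: DegradationModel
    residual_norm: float
    n_windows: int
    peak: LossPeak


def _model_ratio(
    n_freq: np.ndarray, mids: np.ndarray, length: int,
    f: float, b: float, L: float,
) -> np.ndarray:
    d = np.abs(mids - (b % length))
    d = np.minimum(d, length - d)
    r = 1.0 - np.exp(-d / L)
    c = n_freq.max()
    rho = (1.0 - f) * n_freq + f * c * r
    rho = rho / rho.sum()
    return rho / n_freq


def fit_degradation_model(
    ratio: MfaProfile,
    chrom: ChromosomeMap,
    params: ReplicationParams | None = None,
    schedule: ForkSchedule | None = None,
    peak: LossPeak | None = None,
    **detect_kwargs,
) -> DegradationFit:
    """Least-squares fit of (f, b, L) to an observed mutant/reference ratio.

    The model curve is the mixture profile over its intact (f = 0)
    counterpart, with the copy-number gradient computed analytically from
    the chromosome map and replication parameters.  The break position is
    initialized at the detected dip center, f at its depth and L at half
    its width.  Raises :class:`FitError` (carrying the initial values) when
    no dip is detected or the optimizer fails.
    """
    if params is None:
        params = ReplicationParams()
    if peak is None:
        peak = detect_loss_peak(ratio, **detect_kwargs)
    if peak is None:
        raise FitError("no DNA-loss dip detected; nothing to fit")
    if schedule is None:
        schedule = fork_arrival_times(chrom, params, window_bp=ratio.window_bp)
    n_freq = copy_number_profile(schedule, params)
    if len(n_freq) != ratio.n_windows:
        raise GridMismatchError("map grid does not match the ratio grid")
    mids = schedule.coords.astype(float)
    length = chrom.length_bp
    sel = ratio.mask
    obs = ratio.values[sel]

    f0 = float(np.clip(peak.depth / max(peak.baseline, 1e-9), 0.02, 0.95))
    L0 = float(max(peak.width / 2.0, ratio.window_bp))
    b0 = float(peak.center)

    def residuals(x: np.ndarray) -> np.ndarray:
        f, db, logL = x
        model = _model_ratio(n_freq, mids, length, f, b0 + db, np.exp(logL))
        return model[sel] - obs

    x0 = np.array([f0, 0.0, np.log(L0)])
    res = optimize.least_squares(
        residuals,
        x0,
        bounds=(
            [1e-6, -length / 2.0 + 1, np.log(ratio.window_bp / 2.0)],
            [1.0 - 1e-6, length / 2.0 - 1, np.log(length / 4.0)],
        ),
        x_scale=[0.1, 1e4, 0.5],
    )
    if not res.success:
        raise FitError(
            f"degradation fit did not converge from f0={f0:.3g}, b0={b0:.0f}, "
            f"L0={L0:.0f}: {res.message}"
        )
    f_hat, db_hat, logL_hat = res.x
    model = DegradationModel(
        f=float(f_hat), b=int(round((b0 + db_hat) % length)), L=float(np.exp(logL_hat))
    )
    return DegradationFit(
        model=model,
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        n_windows=int(sel.sum()),
        peak=peak,
    )
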