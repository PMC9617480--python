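"""Intensity time-course extraction, normalization, and model fitting.

The measurement convention throughout is the one used for rupture-site
quantification: Gaussian-filter each frame at sigma = 2.0 px (reflective
borders, 2-D per frame), then take the max (or mean) over the ROI; traces
are normalized either to the first acquired frame ("initial") or to the
per-cell peak ("peak"). FRAP traces use the two-step normalization: subtract
background from the bleached and reference signals, divide bleached by
reference, then scale by the pre-bleach average of that ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import optimize
from skimage import measure as skmeasure

from .errors import (
    ConfigurationError,
    DegenerateTraceError,
    InsufficientDataError,
)

__all__ = [
    "KineticsConfig",
    "KineticTrace",
    "FRAPTrace",
    "RecoveryFit",
    "AccumulationFit",
    "EnrichmentCall",
    "roi_trace",
    "normalize_initial",
    "normalize_peak",
    "cn_ratio_trace",
    "frap_normalize",
    "fit_recovery",
    "fit_accumulation",
    "onset_time",
    "snapshot_max",
    "enrichment_call",
    "line_profile",
]


@dataclass
class KineticsConfig:
    """Measurement settings: filter width, ROI statistic, normalization mode,
    and background handling for ratio measurements."""

    gaussian_sigma: float = 2.0
    statistic: str = "max"  # "max" | "mean"
    normalization: str = "none"  # "none" | "initial" | "peak"
    background_mode: str = "none"  # "none" | "constant" | "roi" | "percentile"
    background_value: float = 0.0
    background_mask: Optional[np.ndarray] = None
    background_percentile: float = 1.0  # darkest percentile used in "percentile" mode

    def validate(self) -> None:
        if self.gaussian_sigma < 0:
            raise ConfigurationError("gaussian_sigma must be >= 0")
        if self.statistic not in ("max", "mean"):
            raise ConfigurationError(f"unknown statistic {self.statistic!r}")
        if self.background_mode not in ("none", "constant", "roi", "percentile"):
            raise ConfigurationError(
                f"unknown background_mode {self.background_mode!r}"
            )
        if self.background_mode == "roi" and self.background_mask is None:
            raise ConfigurationError("background_mode='roi' needs background_mask")


@dataclass
class KineticTrace:
    """Per-cell time series of one intensity statistic.

    ``normalization`` records the state of ``values`` (``none``, ``initial``
    or ``peak``); ``raw`` always keeps the unnormalized values so a trace can
    be re-normalized or written to the tidy CSV without loss.
    """

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    normalization: str = "none"
    channel: str = ""
    roi: str = ""
    condition: str = ""
    raw: Optional[np.ndarray] = None
    peak_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ConfigurationError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ConfigurationError("times must be strictly increasing")
        if self.raw is None:
            self.raw = self.values.copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "condition": self.condition,
                "channel": self.channel,
                "roi": self.roi,
                "frame": np.arange(len(self.times)),
                "time_s": self.times,
                "raw": self.raw,
                "normalized": self.values,
                "normalization": self.normalization,
            }
        )


def _filtered(frame: np.ndarray, sigma: float) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if sigma > 0:
        return ndi.gaussian_filter(frame, sigma, mode="reflect")
    return frame


def _stat(frame: np.ndarray, mask: np.ndarray, statistic: str) -> float:
    vals = frame[mask]
    return float(vals.max() if statistic == "max" else vals.mean())


def _frames(stack) -> np.ndarray:
    """Accept a T x Y x X array (a single channel of a stack)."""
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise ConfigurationError(f"expected a T x Y x X channel stack, got {arr.shape}")
    return arr


def roi_trace(stack, roi_mask: np.ndarray, config: Optional[KineticsConfig] = None,
              times: Optional[np.ndarray] = None, cell_id: str = "cell0",
              **trace_kwargs) -> KineticTrace:
    """Per frame: Gaussian-filter, then take the configured statistic over the ROI."""
    config = config or KineticsConfig()
    config.validate()
    arr = _frames(stack)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ConfigurationError("ROI mask is empty")
    values = np.array(
        [_stat(_filtered(f, config.gaussian_sigma), roi_mask, config.statistic) for f in arr]
    )
    if times is None:
        times = np.arange(len(arr), dtype=float)
    trace = KineticTrace(cell_id=cell_id, times=times, values=values, **trace_kwargs)
    if config.normalization == "initial":
        trace = normalize_initial(trace)
    elif config.normalization == "peak":
        trace = normalize_peak(trace)
    return trace


def normalize_initial(trace: KineticTrace) -> KineticTrace:
    """Divide by the first sample; the first normalized value is exactly 1.

    Idempotent: re-normalizing an already-normalized trace is the identity.
    """
    if trace.values[0] <= 0:
        raise DegenerateTraceError(
            f"initial value {trace.values[0]!r} is not positive; cannot normalize"
        )
    return replace(
        trace,
        values=trace.values / trace.values[0],
        normalization="initial",
        raw=trace.raw,
    )


def normalize_peak(trace: KineticTrace) -> KineticTrace:
    """Divide by the per-cell peak; ties resolve to the earliest peak frame."""
    peak_idx = int(np.argmax(trace.values))  # argmax takes the first maximum
    peak = trace.values[peak_idx]
    if peak <= 0:
        raise DegenerateTraceError(f"peak value {peak!r} is not positive")
    return replace(
        trace,
        values=trace.values / peak,
        normalization="peak",
        raw=trace.raw,
        peak_index=peak_idx,
    )


def _background(frame: np.ndarray, config: KineticsConfig) -> float:
    if config.background_mode == "none":
        return 0.0
    if config.background_mode == "constant":
        return float(config.background_value)
    if config.background_mode == "roi":
        return float(frame[np.asarray(config.background_mask, dtype=bool)].mean())
    return float(np.mean(np.sort(frame.ravel())[: max(1, int(frame.size * config.background_percentile / 100.0))]))


def cn_ratio_trace(stack, nucleus_mask: np.ndarray, cytoplasm_mask: np.ndarray,
                   config: Optional[KineticsConfig] = None,
                   times: Optional[np.ndarray] = None,
                   cell_id: str = "cell0", **trace_kwargs) -> KineticTrace:
    """Cytoplasmic-to-nuclear mean-intensity ratio, frame by frame.

    ``(mean over cytoplasm - background) / (mean over nucleus - background)``;
    background handling follows ``config.background_mode`` (default none).
    """
    config = config or KineticsConfig(statistic="mean")
    config.validate()
    arr = _frames(stack)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cytoplasm_mask = np.asarray(cytoplasm_mask, dtype=bool)
    if not nucleus_mask.any() or not cytoplasm_mask.any():
        raise ConfigurationError("both masks must be nonempty")
    if (nucleus_mask & cytoplasm_mask).any():
        raise ConfigurationError("nucleus and cytoplasm masks must be disjoint")
    values = []
    for frame in arr:
        filt = _filtered(frame, config.gaussian_sigma)
        bg = _background(filt, config)
        denom = filt[nucleus_mask].mean() - bg
        if denom <= 0:
            raise DegenerateTraceError(
                f"nuclear mean {denom + bg:.4g} not above background {bg:.4g}"
            )
        values.append((filt[cytoplasm_mask].mean() - bg) / denom)
    if times is None:
        times = np.arange(len(arr), dtype=float)
    return KineticTrace(cell_id=cell_id, times=times, values=np.array(values),
                        **trace_kwargs)


@dataclass
class FRAPTrace:
    """Raw FRAP traces (bleached spot, nuclear reference, background) plus the
    double-normalized trace once computed. ``n_pre`` pre-bleach frames precede
    the bleach (default five)."""

    times: np.ndarray
    bleached: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    n_pre: int = 5
    normalized: Optional[np.ndarray] = None
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        lengths = {len(self.times), len(self.bleached), len(self.reference),
                   len(self.background)}
        if len(lengths) != 1:
            raise ConfigurationError("all FRAP traces must have the same length")
        if not 1 <= self.n_pre < len(self.times):
            raise ConfigurationError(
                f"n_pre={self.n_pre} must leave at least one post-bleach frame"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "frame": np.arange(len(self.times)),
                "time_s": self.times,
                "bleached": self.bleached,
                "reference": self.reference,
                "background": self.background,
                "normalized": (np.full_like(self.times, np.nan)
                               if self.normalized is None else self.normalized),
            }
        )


def frap_normalize(frap: FRAPTrace) -> FRAPTrace:
    """Two-step (double) normalization of a FRAP trace.

    ``q(t) = (B(t) - G(t)) / (R(t) - G(t))`` corrects acquisition bleaching
    and laser fluctuations via the reference region; dividing by the
    pre-bleach mean of ``q`` sets the pre-bleach level to exactly 1.
    """
    ref = frap.reference - frap.background
    if np.any(ref <= 0):
        raise DegenerateTraceError(
            "reference minus background must be positive at every frame"
        )
    q = (frap.bleached - frap.background) / ref
    pre = q[: frap.n_pre].mean()
    if pre <= 0:
        raise DegenerateTraceError("pre-bleach mean is not positive")
    return replace(frap, normalized=q / pre)


@dataclass
class RecoveryFit:
    """Single-exponential FRAP recovery fit on the double-normalized scale.

    ``F(t) = F_inf - (F_inf - F0) exp(-k_rec t)`` with t measured from the
    bleach; mobile fraction ``M = (F_inf - F0) / (1 - F0)``.
    """

    f_inf: float
    f0: float
    k_rec: float
    mobile_fraction: float
    half_time: float
    residual_norm: float
    converged: bool
    k_identifiable: bool = True


def _multistart_least_squares(model, t, y, starts, bounds):
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: model(t, *p) - y, x0=x0, bounds=bounds, method="trf"
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_recovery(normalized: np.ndarray, times_post: np.ndarray) -> RecoveryFit:
    """Fit the recovery model to post-bleach samples of a normalized trace.

    ``times_post`` is measured from the bleach (first post-bleach sample at
    t >= 0). Bounded least squares (0 <= F0 <= F_inf <= 1.5, k >= 0) with
    three deterministic starts; non-convergence is flagged, never papered
    over with fabricated parameters.
    """
    y = np.asarray(normalized, dtype=float)
    t = np.asarray(times_post, dtype=float)
    if len(y) < 5:
        raise InsufficientDataError("need >= 5 post-bleach samples")

    def model(tt, f0, df, k):
        return f0 + df * (1.0 - np.exp(-k * tt))

    span = max(t[-1] - t[0], 1e-9)
    f0_guess = float(np.clip(y[0], 0.0, 1.5))
    df_guess = float(np.clip(y[-1] - y[0], 0.0, 1.5))
    starts = [
        (f0_guess, max(df_guess, 1e-3), 1.0 / span),
        (f0_guess, max(df_guess, 1e-3), 10.0 / span),
        (0.5, 0.5, 0.1 / span),
    ]
    res = _multistart_least_squares(model, t, y, starts,
                                    bounds=([0.0, 0.0, 0.0], [1.5, 1.5, np.inf]))
    if res is None:
        return RecoveryFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False, False)
    f0, df, k = res.x
    f_inf = f0 + df
    # With no recovery the rate has no information in the data.
    identifiable = df > 1e-6
    mobile = df / (1.0 - f0) if f0 < 1.0 - 1e-12 else np.nan
    half = np.log(2.0) / k if (k > 0 and identifiable) else np.nan
    return RecoveryFit(
        f_inf=float(f_inf),
        f0=float(f0),
        k_rec=float(k) if identifiable else 0.0,
        mobile_fraction=float(mobile),
        half_time=float(half) if half == half else np.nan,
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=bool(res.success),
        k_identifiable=bool(identifiable),
    )


@dataclass
class AccumulationFit:
    """Saturating-accumulation fit ``1 + A (1 - e^{-k (t - t0)})`` on an
    initial-normalized site trace."""

    amplitude: float
    k_acc: float
    residual_norm: float
    converged: bool
    k_identifiable: bool = True


def fit_accumulation(trace: KineticTrace, t0: float) -> AccumulationFit:
    """Fit the post-rupture portion (t >= t0) of an initial-normalized trace."""
    if trace.normalization != "initial":
        raise ConfigurationError("fit_accumulation expects an initial-normalized trace")
    sel = trace.times >= t0
    t = trace.times[sel] - t0
    y = trace.values[sel]
    if len(t) < 4:
        raise InsufficientDataError(
            f"only {len(t)} samples at t >= t0; need at least 4"
        )

    def model(tt, a, k):
        return 1.0 + a * (1.0 - np.exp(-k * tt))

    span = max(t[-1] - t[0], 1e-9)
    a_guess = max(float(y.max() - 1.0), 1e-3)
    starts = [(a_guess, 1.0 / span), (a_guess, 10.0 / span), (0.5, 0.1 / span)]
    res = _multistart_least_squares(model, t, y, starts,
                                    bounds=([0.0, 0.0], [np.inf, np.inf]))
    if res is None:
        return AccumulationFit(np.nan, np.nan, np.inf, False, False)
    a, k = res.x
    # Prefer the nested flat model (A = 0) when it explains the data equally
    # well; with A = 0 the rate carries no information.
    cost_flat = 0.5 * float(((y - 1.0) ** 2).sum())
    if cost_flat <= res.cost * (1.0 + 1e-9) + 1e-12:
        return AccumulationFit(0.0, 0.0, float(np.sqrt(2.0 * cost_flat)),
                               True, False)
    identifiable = a > 1e-6
    return AccumulationFit(
        amplitude=float(a),
        k_acc=float(k) if identifiable else 0.0,
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=bool(res.success),
        k_identifiable=bool(identifiable),
    )


def onset_time(trace: KineticTrace, threshold_fold: float = 1.2,
               sustain_frames: int = 2) -> Optional[float]:
    """First time the initial-normalized trace reaches ``threshold_fold`` and
    stays there for at least ``sustain_frames`` consecutive frames; None if it
    never does. The threshold is a repo convention, not a measured constant.
    """
    if trace.normalization != "initial":
        raise ConfigurationError("onset_time expects an initial-normalized trace")
    above = trace.values >= threshold_fold
    n = len(above)
    for i in range(n - sustain_frames + 1):
        if above[i : i + sustain_frames].all():
            return float(trace.times[i])
    return None


def snapshot_max(frame: np.ndarray, roi_mask: np.ndarray,
                 config: Optional[KineticsConfig] = None) -> float:
    """Single-frame max-intensity score over an ROI (filtered like roi_trace)."""
    config = config or KineticsConfig()
    cfg = replace(config, statistic="max", normalization="none")
    trace = roi_trace(np.asarray(frame, dtype=float)[None], roi_mask, cfg)
    return float(trace.values[0])


@dataclass
class EnrichmentCall:
    positive: bool
    fold: float


def enrichment_call(site_value: float, reference_value: float,
                    fold_threshold: float = 1.5) -> EnrichmentCall:
    """Binary enrichment score: site statistic over the same cell's NE-ring
    statistic; positive iff the fold change is >= the threshold (ties count
    as positive). The default 1.5-fold threshold is a repo convention."""
    if reference_value <= 0:
        raise DegenerateTraceError(
            f"reference value {reference_value!r} is not positive"
        )
    fold = float(site_value) / float(reference_value)
    return EnrichmentCall(positive=bool(fold >= fold_threshold), fold=fold)


def line_profile(frame: np.ndarray, p0: tuple[float, float], p1: tuple[float, float],
                 width_px: int = 1) -> pd.DataFrame:
    """Intensity profile along a segment, averaged across ``width_px``
    perpendicular to it; sampled at unit-pixel spacing.

    Returns a table with columns ``distance_px`` and ``value``.
    """
    frame = np.asarray(frame, dtype=float)
    ny, nx = frame.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= ny - 1 and 0 <= p[1] <= nx - 1):
            raise ConfigurationError(f"endpoint {p} outside image of shape {frame.shape}")
    if np.hypot(p1[0] - p0[0], p1[1] - p0[1]) == 0:
        raise ConfigurationError("zero-length profile segment")
    values = skmeasure.profile_line(
        frame, p0, p1, linewidth=int(width_px), mode="reflect", reduce_func=np.mean
    )
    return pd.DataFrame(
        {"distance_px": np.arange(len(values), dtype=float), "value": values}
    )
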