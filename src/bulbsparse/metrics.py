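"""Analysis of network responses: sparseness, coherence, response
correlation, half-time of sparseness, and odor-input similarity.

Population sparseness follows the Treves-Rolls / Vinje-Gallant
construction over per-cell mean rates,

    S = (1 - (sum r_i / N)^2 / (sum r_i^2 / N)) / (1 - 1/N),

which is 0 for a uniform population and 1 when a single cell carries
all activity.  Pairwise coherence is the normalized zero-lag
cross-correlation of binarized spike trains at bin width tau (20 ms
default), K_ij = sum X*Y / sqrt(sum X * sum Y); the network coherence
is its mean over all distinct cell pairs.  Between-response similarity
C_xy is the per-cell Pearson correlation of binned responses to two
odors, averaged over cells.  The sparseness time course is summarized
by fitting a four-parameter Hill sigmoid in time and reporting the
time S_1/2 at which the fit crosses the midpoint of its asymptotes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dynamics import SpikeRaster
from .network_builder import Network
from .synthetic_odors import OdorPanel

__all__ = [
    "SparsenessTrace",
    "FitResult",
    "sparseness",
    "per_sniff_sparseness",
    "coherence_pair",
    "network_coherence",
    "response_correlation",
    "response_correlation_from_counts",
    "fit_S_half",
    "odor_similarity",
    "weight_summary",
]

#: spike-train coherence bin width used throughout the analysis (ms)
DEFAULT_TAU_MS = 20.0


def sparseness(rates) -> float:
    """Population sparseness of a rate vector, in [0, 1].

    Returns NaN (the undefined-sparseness sentinel) when all rates are
    zero, so sweeps propagate missing data instead of aborting.
    """
    r = np.asarray(rates, float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("need a 1-D rate vector with N >= 2 cells")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    if not r.any():
        return float("nan")
    n = r.size
    r = r / r.max()  # scale-invariant; also guards squared underflow
    mean_sq = np.mean(r) ** 2
    sq_mean = np.mean(r**2)
    return float((1.0 - mean_sq / sq_mean) / (1.0 - 1.0 / n))


@dataclass
class SparsenessTrace:
    """Per-sniff sparseness time series, times relative to odor onset."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")

    def dropna(self) -> "SparsenessTrace":
        m = np.isfinite(self.values)
        return SparsenessTrace(self.times[m], self.values[m])


def per_sniff_sparseness(
    raster: SpikeRaster,
    sniff_times,
    window: float | None = None,
    cumulative: bool = False,
) -> SparsenessTrace:
    """Sparseness evaluated at each sniff point.

    Windowed variant (default): rates from [sniff, sniff + window),
    window defaulting to the sniff spacing.  Cumulative variant: rates
    from the first sniff up to each sniff's window end, mirroring
    "one period of odor input" read from stimulus onset.
    """
    sniff_times = np.asarray(sniff_times, float)
    if sniff_times.size == 0:
        return SparsenessTrace(np.array([]), np.array([]))
    if np.any(sniff_times < raster.t_start - 1e-9) or np.any(
        sniff_times > raster.t_stop + 1e-9
    ):
        raise ValueError("sniff times outside raster epoch")
    if window is None:
        window = float(np.median(np.diff(sniff_times))) if sniff_times.size > 1 else (
            raster.t_stop - sniff_times[-1]
        )
    if window <= 0:
        raise ValueError("window must be positive")
    vals = []
    for t in sniff_times:
        t0 = sniff_times[0] if cumulative else t
        vals.append(sparseness(raster.rates(t0, t + window)))
    return SparsenessTrace(sniff_times, np.array(vals))


def _binarize(train, tau_s, t0, t1):
    edges = np.arange(t0, t1 + tau_s * 0.5, tau_s)
    counts, _ = np.histogram(np.asarray(train, float), bins=edges)
    return (counts > 0).astype(float)


def coherence_pair(train_x, train_y, tau_ms: float = DEFAULT_TAU_MS, epoch=None) -> float:
    """Zero-lag coherence of two spike trains at bin width tau.

    K = sum X*Y / sqrt(sum X * sum Y) over binarized bins; defined as 0
    when either train has no occupied bin.
    """
    if epoch is None:
        both = np.concatenate([np.asarray(train_x, float), np.asarray(train_y, float)])
        if both.size == 0:
            return 0.0
        epoch = (float(both.min()), float(both.max()) + tau_ms * 1e-3)
    t0, t1 = epoch
    tau_s = tau_ms * 1e-3
    if tau_s <= 0 or t1 - t0 < tau_s:
        raise ValueError("epoch must cover at least one bin")
    x = _binarize(train_x, tau_s, t0, t1)
    y = _binarize(train_y, tau_s, t0, t1)
    nx, ny = x.sum(), y.sum()
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.dot(x, y) / np.sqrt(nx * ny))


def network_coherence(
    raster: SpikeRaster, tau_ms: float = DEFAULT_TAU_MS, epoch=None
) -> float:
    """Mean pairwise coherence over all distinct cell pairs."""
    if raster.n_cells < 2:
        raise ValueError("need >= 2 cells")
    if epoch is None:
        epoch = (raster.t_start, raster.t_stop)
    t0, t1 = epoch
    tau_s = tau_ms * 1e-3
    B = np.vstack([_binarize(s, tau_s, t0, t1) for s in raster.spikes])
    occ = B.sum(axis=1)
    num = B @ B.T
    denom = np.sqrt(np.outer(occ, occ))
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(denom > 0, num / denom, 0.0)
    n = raster.n_cells
    return float((K.sum() - np.trace(K)) / (n * (n - 1)))


def response_correlation_from_counts(counts_x: np.ndarray, counts_y: np.ndarray) -> tuple:
    """C_xy from per-cell binned responses (cells x bins); returns
    (C_xy, n_cells_used).  Cells with zero variance in either response
    are skipped; NaN when no cell qualifies."""
    X = np.asarray(counts_x, float)
    Y = np.asarray(counts_y, float)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("count matrices must share shape (cells x bins)")
    sx = X.std(axis=1)
    sy = Y.std(axis=1)
    valid = (sx > 0) & (sy > 0)
    if not valid.any():
        return float("nan"), 0
    Xv = X[valid] - X[valid].mean(axis=1, keepdims=True)
    Yv = Y[valid] - Y[valid].mean(axis=1, keepdims=True)
    r = (Xv * Yv).mean(axis=1) / (sx[valid] * sy[valid])
    return float(r.mean()), int(valid.sum())


def response_correlation(
    raster_x: SpikeRaster, raster_y: SpikeRaster, bin_edges_x, bin_edges_y=None
) -> tuple:
    """C_xy between two rasters' responses, per-sniff binning by default.

    ``bin_edges_x``/``bin_edges_y`` give the analysis bins in each
    raster's own time frame (equal counts of bins required).
    """
    if raster_x.n_cells != raster_y.n_cells:
        raise ValueError("rasters must cover identical cell sets")
    if bin_edges_y is None:
        bin_edges_y = bin_edges_x
    cx = raster_x.counts_matrix(np.asarray(bin_edges_x, float))
    cy = raster_y.counts_matrix(np.asarray(bin_edges_y, float))
    return response_correlation_from_counts(cx, cy)


@dataclass
class FitResult:
    """Four-parameter sigmoid fit of a sparseness time course."""

    A1: float
    A2: float
    x0: float
    hill_exponent: float
    S_half: float
    r_squared: float
    converged: bool
    message: str = ""


def _hill(x, a1, a2, x0, h):
    return a2 + (a1 - a2) / (1.0 + (x / x0) ** h)


def fit_S_half(
    trace: SparsenessTrace,
    fix_exponent: float | None = None,
    min_range: float = 1e-3,
) -> FitResult:
    """Least-squares Hill-sigmoid fit; S_half is the time at which the
    fitted curve crosses the midpoint of its asymptotes (= x0).

    Deterministic: initialization is A1 = first value, A2 = last value,
    x0 = linear-interpolated half-range crossing, exponent 2 (or the
    fixed exponent).  Degenerate (near-constant) traces and failed fits
    return a flagged result with S_half falling back to the first
    half-range crossing of the raw trace.
    """
    tr = trace.dropna()
    t, y = tr.times, tr.values
    if t.size < 5:
        raise ValueError("need >= 5 finite trace points")
    t = t - t[0] + max(np.median(np.diff(t)), 1e-6)  # strictly positive times
    lo, hi = float(y.min()), float(y.max())
    half = 0.5 * (lo + hi)
    cross = np.flatnonzero((y[:-1] - half) * (y[1:] - half) <= 0)
    if cross.size:
        i = cross[0]
        denom = y[i + 1] - y[i]
        frac = 0.0 if denom == 0 else (half - y[i]) / denom
        x0_init = t[i] + frac * (t[i + 1] - t[i])
    else:
        x0_init = float(np.median(t))
    fallback = float(x0_init)

    if hi - lo < min_range:
        return FitResult(
            A1=float(y[0]), A2=float(y[-1]), x0=np.nan, hill_exponent=np.nan,
            S_half=fallback, r_squared=0.0, converged=False,
            message="degenerate trace",
        )

    span = float(t[-1])
    try:
        if fix_exponent is None:
            p0 = [y[0], y[-1], x0_init, 2.0]
            bounds = ([-1.0, -1.0, t[0] * 0.1, 0.1], [2.0, 2.0, span * 4, 50.0])
            popt, _ = curve_fit(_hill, t, y, p0=p0, bounds=bounds, maxfev=20000)
            a1, a2, x0, h = popt
        else:
            p0 = [y[0], y[-1], x0_init]
            bounds = ([-1.0, -1.0, t[0] * 0.1], [2.0, 2.0, span * 4])
            popt, _ = curve_fit(
                lambda x, a1, a2, x0: _hill(x, a1, a2, x0, fix_exponent),
                t, y, p0=p0, bounds=bounds, maxfev=20000,
            )
            a1, a2, x0 = popt
            h = fix_exponent
    except RuntimeError as err:
        return FitResult(
            A1=np.nan, A2=np.nan, x0=np.nan, hill_exponent=np.nan,
            S_half=fallback, r_squared=0.0, converged=False, message=str(err),
        )
    resid = y - _hill(t, a1, a2, x0, h)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    s_half = float(x0)
    in_window = t[0] * 0.5 <= x0 <= span * 1.5
    return FitResult(
        A1=float(a1), A2=float(a2), x0=float(x0), hill_exponent=float(h),
        S_half=s_half if in_window else fallback,
        r_squared=r2, converged=bool(in_window),
        message="" if in_window else "midpoint outside fitted window",
    )


def odor_similarity(panel: OdorPanel, odor_x, odor_y, network: Network | None = None) -> float:
    """Pearson correlation of two odors' input-strength vectors.

    With a network, strengths are expanded to one value per mitral cell
    (each MC inherits its home glomerulus's strength), matching the
    per-cell construction; without one, the glomerular vectors are used
    directly.  NaN sentinel for zero-variance vectors.
    """
    x = panel.odor_strengths(odor_x).astype(float)
    y = panel.odor_strengths(odor_y).astype(float)
    if network is not None:
        x = network.strengths_per_mitral(x)
        y = network.strengths_per_mitral(y)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def weight_summary(network: Network, panel: OdorPanel, odor_id) -> pd.DataFrame:
    """Mean component weights by input class for the named odor.

    Classes partition mitral cells by that odor's strength: strong
    (3-4), weak (0-2), and all; means are over the synapse components of
    each class's cells.
    """
    per_mc = network.strengths_per_mitral(panel.odor_strengths(odor_id))
    syn_strength = per_mc[network.syn_mc]
    rows = []
    for name, mask in (
        ("strong", syn_strength >= 3),
        ("weak", syn_strength <= 2),
        ("all", np.ones_like(syn_strength, bool)),
    ):
        n_cells = int(np.count_nonzero(per_mc >= 3)) if name == "strong" else (
            int(np.count_nonzero(per_mc <= 2)) if name == "weak" else per_mc.size
        )
        rows.append(
            {
                "group": name,
                "n_cells": n_cells,
                "n_components": int(mask.sum()),
                "G_ex": float(network.w_exc[mask].mean()) if mask.any() else np.nan,
                "G_in": float(network.w_inh[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")
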