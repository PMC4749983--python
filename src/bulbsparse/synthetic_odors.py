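"""Synthetic odor panels and sniff-locked stimulation.

Odors are represented, as in glomerular-imaging maps, by an integer
activation strength in {0..4} for each glomerulus.  A panel of such
vectors is the sole source of stimulation for the network: strengths
are converted to aggregate input conductances (up to a configurable
ceiling, 10 nS by default) and delivered as alpha-shaped transients
locked to a 4-10 Hz sniff cycle.

The reference glomerular maps this generator emulates are not publicly
deposited, so panels are drawn synthetically: each odor activates a
sparse subset of the responsive glomeruli at levels 1-4, and pairs of
odors can be forced into a target band of pairwise Pearson similarity
by mutating one odor away from a shared template.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OdorPanel",
    "StimulusSpec",
    "SimilarityProfile",
    "SimilarityTarget",
    "generate_panel",
    "strength_to_conductance",
    "make_sniff_train",
    "sniff_kernel",
    "read_panel_csv",
    "write_panel_csv",
]

MAX_STRENGTH = 4
#: aggregate synaptic input at strength 4 and unit concentration (nS)
DEFAULT_CONDUCTANCE_CEILING_NS = 10.0
#: conductance grows as (strength/4)**exponent, keeping levels 0-2 subthreshold
DEFAULT_CONDUCTANCE_EXPONENT = 3.0


@dataclass(frozen=True)
class OdorPanel:
    """A set of odors as integer glomerular activation strengths.

    Attributes
    ----------
    strengths : ndarray of shape (n_odors, n_glomeruli)
        Integer activation strengths in {0..4}.
    labels : tuple of str
        One name per odor.
    """

    strengths: np.ndarray
    labels: tuple

    def __post_init__(self):
        s = np.asarray(self.strengths)
        if s.ndim != 2:
            raise ValueError("strengths must be a 2-D odors x glomeruli matrix")
        if not np.issubdtype(s.dtype, np.integer):
            if not np.all(s == np.round(s)):
                raise ValueError("strengths must be integers")
            s = s.astype(np.int64)
        if s.min(initial=0) < 0 or s.max(initial=0) > MAX_STRENGTH:
            raise ValueError(f"strengths must lie in [0, {MAX_STRENGTH}]")
        if len(self.labels) != s.shape[0]:
            raise ValueError("one label per odor required")
        if s.shape[0] and not np.all((s >= 3).any(axis=1)):
            raise ValueError("every odor must activate >=1 glomerulus at level >=3")
        object.__setattr__(self, "strengths", s)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_odors(self) -> int:
        return self.strengths.shape[0]

    @property
    def n_glomeruli(self) -> int:
        return self.strengths.shape[1]

    @property
    def responsive_glomeruli(self) -> np.ndarray:
        """Indices of glomeruli that are nonzero for at least one odor."""
        return np.flatnonzero(self.strengths.any(axis=0))

    def odor_index(self, odor_id) -> int:
        if isinstance(odor_id, str):
            try:
                return self.labels.index(odor_id)
            except ValueError:
                raise KeyError(f"unknown odor {odor_id!r}") from None
        i = int(odor_id)
        if not 0 <= i < self.n_odors:
            raise KeyError(f"odor index {i} out of range")
        return i

    def odor_strengths(self, odor_id) -> np.ndarray:
        return self.strengths[self.odor_index(odor_id)]

    def total_strength(self, odor_id) -> int:
        """Summed glomerular strength; the panel-wide intensity ordering key."""
        return int(self.odor_strengths(odor_id).sum())

    def to_table(self) -> dict:
        """Plain-structure form suitable for embedding in YAML/JSON configs."""
        return {
            "labels": list(self.labels),
            "strengths": self.strengths.tolist(),
        }

    @classmethod
    def from_table(cls, table: dict) -> "OdorPanel":
        return cls(
            strengths=np.asarray(table["strengths"], dtype=np.int64),
            labels=tuple(table["labels"]),
        )


@dataclass(frozen=True)
class StimulusSpec:
    """One odor presentation: which odor, how strong, and when."""

    odor_id: object
    onset: float = 0.0
    duration: float = 5.0
    concentration_coefficient: float = 1.0
    sniff_frequency: float = 5.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 4.0 <= self.sniff_frequency <= 10.0:
            raise ValueError("sniff_frequency must lie in [4, 10] Hz")
        if self.concentration_coefficient <= 0:
            raise ValueError("concentration_coefficient must be positive")


@dataclass(frozen=True)
class SimilarityTarget:
    """Request that a pair of odors land in a band of Pearson similarity."""

    odor_a: int
    odor_b: int
    r_lo: float
    r_hi: float


@dataclass(frozen=True)
class SimilarityProfile:
    """Statistical shape of a generated panel.

    ``active_fraction`` is the fraction of responsive glomeruli each odor
    activates; ``strength_probs`` are the probabilities of levels 1..4 for
    an active glomerulus.  ``targets`` lists odor pairs whose strength
    vectors must reach a requested Pearson-correlation band.
    """

    active_fraction: float = 0.25
    strength_probs: tuple = (0.35, 0.30, 0.20, 0.15)
    targets: tuple = ()

    def __post_init__(self):
        if not 0.0 < self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in (0, 1]")
        p = np.asarray(self.strength_probs, dtype=float)
        if p.shape != (4,) or p.min() < 0 or not np.isclose(p.sum(), 1.0):
            raise ValueError("strength_probs must be 4 probabilities summing to 1")
        object.__setattr__(self, "targets", tuple(self.targets))


DEFAULT_PROFILE = SimilarityProfile()


def _draw_odor(rng, responsive, n_active, strength_probs):
    """One sparse odor vector over the responsive glomeruli."""
    active = rng.choice(responsive, size=n_active, replace=False)
    levels = rng.choice([1, 2, 3, 4], size=n_active, p=strength_probs)
    return active, levels


def _ensure_suprathreshold(vec, rng):
    """Promote the strongest active glomerulus to level 3 if none is >=3."""
    if (vec >= 3).any():
        return
    nz = np.flatnonzero(vec)
    if nz.size == 0:
        raise ValueError("odor with no active glomeruli")
    vec[rng.choice(nz)] = 3


def _pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _mutate_to_band(base, target, rng, responsive, strength_probs, max_iter=10000):
    """Mutate a copy of ``base`` one glomerulus at a time until its Pearson
    correlation with ``base`` falls into [r_lo, r_hi]."""
    vec = base.copy()
    r = _pearson(vec, base)
    if np.isnan(r):
        raise ValueError("cannot target similarity against a constant odor")
    if target.r_lo <= r <= target.r_hi:
        return vec
    for _ in range(max_iter):
        g = rng.choice(responsive)
        old = vec[g]
        if rng.random() < 0.5 or vec[g] == 0:
            vec[g] = rng.choice([1, 2, 3, 4], p=strength_probs)
        else:
            vec[g] = 0
        r_new = _pearson(vec, base)
        # accept moves that walk r toward the band; revert overshoots
        if target.r_lo <= r_new <= target.r_hi and (vec >= 3).any():
            return vec
        if r_new > target.r_hi or (r_new > target.r_lo and not np.isnan(r_new)):
            r = r_new
        else:
            vec[g] = old
    raise RuntimeError(
        f"could not reach similarity band [{target.r_lo}, {target.r_hi}] "
        f"for odor pair ({target.odor_a}, {target.odor_b})"
    )


def generate_panel(
    n_glomeruli: int = 100,
    n_odors: int = 72,
    n_responsive: int = 74,
    similarity_profile: SimilarityProfile | None = None,
    seed: int | None = None,
    labels: list | None = None,
) -> OdorPanel:
    """Generate an odor panel with sparse integer glomerular strengths.

    Exactly ``n_responsive`` glomerulus columns end up nonzero for at
    least one odor; the remaining columns are all-zero (they stand for
    glomeruli tuned to odors outside the panel).  Deterministic for a
    fixed seed.
    """
    if n_responsive > n_glomeruli:
        raise ValueError("n_responsive cannot exceed n_glomeruli")
    if n_odors < 1 or n_glomeruli < 1 or n_responsive < 1:
        raise ValueError("counts must be >= 1")
    profile = similarity_profile or DEFAULT_PROFILE
    rng = np.random.default_rng(seed)

    responsive = np.sort(rng.choice(n_glomeruli, size=n_responsive, replace=False))
    n_active = max(1, int(round(profile.active_fraction * n_responsive)))
    probs = np.asarray(profile.strength_probs, dtype=float)

    strengths = np.zeros((n_odors, n_glomeruli), dtype=np.int64)
    templated = {t.odor_b for t in profile.targets}
    for i in range(n_odors):
        if i in templated:
            continue
        active, levels = _draw_odor(rng, responsive, n_active, probs)
        strengths[i, active] = levels
        _ensure_suprathreshold(strengths[i], rng)
    # guarantee every responsive glomerulus is used by >=1 odor before
    # similarity targeting (so pairing is not disturbed afterwards)
    free = [i for i in range(n_odors) if i not in templated] or list(range(n_odors))
    unused = [g for g in responsive if not strengths[:, g].any()]
    for g in unused:
        strengths[free[rng.integers(len(free))], g] = rng.choice(
            [1, 2, 3, 4], p=probs
        )
    for t in profile.targets:
        if not (0 <= t.odor_a < n_odors and 0 <= t.odor_b < n_odors):
            raise ValueError("similarity target references odor outside panel")
        strengths[t.odor_b] = _mutate_to_band(
            strengths[t.odor_a], t, rng, responsive, probs
        )

    if labels is None:
        labels = [f"odor{i:02d}" for i in range(n_odors)]
    return OdorPanel(strengths=strengths, labels=tuple(labels))


def strength_to_conductance(
    strength,
    concentration_coefficient: float = 1.0,
    ceiling_ns: float = DEFAULT_CONDUCTANCE_CEILING_NS,
    exponent: float = DEFAULT_CONDUCTANCE_EXPONENT,
):
    """Map integer activation strength to aggregate input conductance (nS).

    g(s) = coefficient * ceiling * (s / 4)**exponent.  The supralinear
    default keeps levels 1-2 below the single-cell firing threshold while
    levels 3-4 are suprathreshold (see the dynamics calibration), and
    strength 4 at unit concentration reaches the 10 nS ceiling.
    """
    s = np.asarray(strength)
    if not np.all(np.isin(s, np.arange(MAX_STRENGTH + 1))):
        raise ValueError(f"strength must be an integer in 0..{MAX_STRENGTH}")
    if concentration_coefficient <= 0:
        raise ValueError("concentration_coefficient must be positive")
    g = concentration_coefficient * ceiling_ns * (s / MAX_STRENGTH) ** exponent
    return float(g) if np.isscalar(strength) else g


def make_sniff_train(
    stimulus: StimulusSpec, seed: int | None = None, jitter_ms: float = 0.0
) -> np.ndarray:
    """Sniff-locked input-burst onset times (s) for one presentation.

    Bursts sit on a periodic grid at the sniff frequency, starting at the
    stimulus onset, optionally jittered by +/- ``jitter_ms``; all times
    stay inside [onset, onset + duration).
    """
    period = 1.0 / stimulus.sniff_frequency
    n = int(np.ceil(stimulus.duration / period - 1e-9))
    times = stimulus.onset + np.arange(n) * period
    times = times[times < stimulus.onset + stimulus.duration - 1e-12]
    if jitter_ms > 0.0:
        rng = np.random.default_rng(seed)
        jit = rng.uniform(-jitter_ms, jitter_ms, size=times.shape) * 1e-3
        times = np.clip(times + jit, stimulus.onset, None)
    return times


def sniff_kernel(dt_ms: float, tau_rise_ms: float = 40.0, cutoff_taus: float = 8.0):
    """Alpha-shaped conductance transient, unit peak, sampled at dt.

    k(t) = (t/tau) * exp(1 - t/tau); each sniff burst contributes this
    waveform scaled by the odor's aggregate conductance.
    """
    n = int(np.ceil(cutoff_taus * tau_rise_ms / dt_ms))
    t = np.arange(1, n + 1) * dt_ms / tau_rise_ms
    return (t * np.exp(1.0 - t)).astype(np.float64)


def write_panel_csv(panel: OdorPanel, path) -> None:
    """Panel as an odors x glomeruli integer CSV with glomerulus-id header."""
    df = pd.DataFrame(
        panel.strengths,
        index=pd.Index(panel.labels, name="odor"),
        columns=[f"g{j}" for j in range(panel.n_glomeruli)],
    )
    df.to_csv(path)


def read_panel_csv(path) -> OdorPanel:
    df = pd.read_csv(path, index_col=0)
    return OdorPanel(strengths=df.to_numpy(dtype=np.int64), labels=tuple(df.index))
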