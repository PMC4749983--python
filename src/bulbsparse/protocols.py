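"""Odor-experience training protocols.

A protocol is an initial rest, a sequence of experienced odors (each
presented for 5 s with a 5 s trailing rest by default), and a final
"new" odor presentation.  The naive control presents only the new odor,
with its onset aligned to the matched experience condition so that the
two runs are comparable sniff-for-sniff.  Plasticity persists across
phases — the network is never reset between odors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .dynamics import EpochResult, SimConfig, SpikeRaster, WeightTrajectory, run_epoch
from .network_builder import Network
from .synthetic_odors import OdorPanel, StimulusSpec

__all__ = [
    "ExperienceProtocol",
    "ProtocolResult",
    "order_odors",
    "run_protocol",
    "sweep_experience_count",
]


@dataclass(frozen=True)
class ExperienceProtocol:
    """Which odors to experience, in what order, before the new odor."""

    experienced_odor_ids: tuple = ()
    new_odor_id: object = 0
    presentation_duration: float = 5.0
    rest_duration: float = 5.0
    ordering: str = "lh"          # lh | hl | as-given
    sniff_frequency: float = 5.0
    concentration_coefficient: float = 1.0
    #: naive-control alignment: pad the initial rest as if this many
    #: experienced odors had been presented (None = no padding)
    align_to_count: int | None = None

    def __post_init__(self):
        if self.presentation_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("durations must be positive")
        if self.ordering not in ("lh", "hl", "as-given"):
            raise ValueError("ordering must be lh, hl or as-given")
        object.__setattr__(
            self, "experienced_odor_ids", tuple(self.experienced_odor_ids)
        )


def order_odors(panel: OdorPanel, odor_ids, ordering: str) -> list:
    """Order odors by total input strength: lh ascending, hl descending,
    as-given pass-through; ties broken by odor index."""
    ids = list(odor_ids)
    if ordering == "as-given":
        return ids
    if ordering not in ("lh", "hl"):
        raise ValueError("ordering must be lh, hl or as-given")
    keyed = [(panel.total_strength(o), panel.odor_index(o), o) for o in ids]
    keyed.sort(key=lambda k: (-k[0], k[1]) if ordering == "hl" else (k[0], k[1]))
    return [k[2] for k in keyed]


@dataclass
class ProtocolResult:
    """Observables of one protocol run, focused on the new-odor period."""

    protocol: ExperienceProtocol
    mitral: SpikeRaster
    granule: SpikeRaster
    weights: WeightTrajectory
    network: Network
    new_odor_onset: float
    sniff_times: np.ndarray
    mitral_sparseness: metrics.SparsenessTrace
    granule_sparseness: metrics.SparsenessTrace
    #: sparseness over growing windows from odor onset ("one period of
    #: odor input" read from the start of the presentation); smoother
    #: input for the half-time fit
    mitral_sparseness_cumulative: metrics.SparsenessTrace
    phase_onsets: list  # (odor_id, onset) per presentation, new odor last

    @property
    def new_odor_window(self) -> tuple:
        return (self.new_odor_onset,
                self.new_odor_onset + self.protocol.presentation_duration)

    def new_odor_counts(self, population: str = "mitral") -> np.ndarray:
        """Per-cell per-sniff spike counts during the new-odor period."""
        raster = self.mitral if population == "mitral" else self.granule
        spacing = 1.0 / self.protocol.sniff_frequency
        edges = np.concatenate([self.sniff_times, [self.sniff_times[-1] + spacing]])
        return raster.counts_matrix(edges)


def protocol_timeline(protocol: ExperienceProtocol, panel: OdorPanel):
    """(stimuli, new_odor_onset, total_duration) for a protocol."""
    p = protocol
    ordered = order_odors(panel, p.experienced_odor_ids, p.ordering)
    k = len(ordered)
    pad_count = p.align_to_count if p.align_to_count is not None else k
    if pad_count < k:
        raise ValueError("align_to_count smaller than experienced-odor count")
    slot = p.presentation_duration + p.rest_duration
    # naive alignment: initial rest stretched by the missing slots
    t = p.rest_duration + (pad_count - k) * slot
    stimuli = []
    for odor in ordered:
        stimuli.append(
            StimulusSpec(
                odor_id=odor,
                onset=t,
                duration=p.presentation_duration,
                concentration_coefficient=p.concentration_coefficient,
                sniff_frequency=p.sniff_frequency,
            )
        )
        t += slot
    new_onset = t
    stimuli.append(
        StimulusSpec(
            odor_id=p.new_odor_id,
            onset=new_onset,
            duration=p.presentation_duration,
            concentration_coefficient=p.concentration_coefficient,
            sniff_frequency=p.sniff_frequency,
        )
    )
    total = new_onset + p.presentation_duration
    return stimuli, new_onset, total


def run_protocol(
    network: Network,
    panel: OdorPanel,
    protocol: ExperienceProtocol,
    sim_config: SimConfig,
    seed: int | None = None,
) -> ProtocolResult:
    """Execute a protocol on a network (mutating its plasticity state).

    Runs the whole timeline as a single simulation epoch, then extracts
    per-sniff mitral and granule sparseness for the new-odor period.
    The number of sniff points equals floor(duration * sniff_frequency).
    """
    panel.odor_index(protocol.new_odor_id)  # fail fast on unknown odors
    for o in protocol.experienced_odor_ids:
        panel.odor_index(o)
    stimuli, new_onset, total = protocol_timeline(protocol, panel)
    epoch: EpochResult = run_epoch(
        network,
        stimuli,
        panel,
        sim_config,
        duration=total,
        seed=seed,
        weight_class_odor=protocol.new_odor_id,
    )
    n_sniffs = int(np.floor(protocol.presentation_duration * protocol.sniff_frequency))
    sniffs = new_onset + np.arange(n_sniffs) / protocol.sniff_frequency
    return ProtocolResult(
        protocol=protocol,
        mitral=epoch.mitral,
        granule=epoch.granule,
        weights=epoch.weights,
        network=network,
        new_odor_onset=new_onset,
        sniff_times=sniffs,
        mitral_sparseness=metrics.per_sniff_sparseness(epoch.mitral, sniffs),
        granule_sparseness=metrics.per_sniff_sparseness(epoch.granule, sniffs),
        mitral_sparseness_cumulative=metrics.per_sniff_sparseness(
            epoch.mitral, sniffs, cumulative=True
        ),
        phase_onsets=[(s.odor_id, s.onset) for s in stimuli],
    )


def _first_last(trace: metrics.SparsenessTrace):
    vals = trace.values
    first = vals[0] if vals.size else np.nan
    last = vals[-1] if vals.size else np.nan
    return float(first), float(last)


def sweep_experience_count(
    network_factory,
    panel: OdorPanel,
    counts,
    new_odor_ids,
    sim_config: SimConfig,
    seeds,
    experienced_pool=None,
    ordering: str = "lh",
    tau_ms: float = metrics.DEFAULT_TAU_MS,
    protocol_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Run the prior-odor-count sweep and tabulate the headline observables.

    For every (count, new odor, seed) cell a fresh network is built with
    ``network_factory(seed)`` and trained on the first ``count`` odors of
    the experienced pool (panel order, excluding the new odors, presented
    in the requested intensity order); onsets are aligned across counts
    via the naive-control padding rule, and the same simulation seed is
    reused across counts so only protocol content differs.  Rows report
    first- and last-sniff mitral and granule sparseness, network
    coherence over the new-odor period, the between-response correlation
    against the other new odors' naive (count 0) responses, the sparseness
    half-time, and mean component weights by input class.
    """
    counts = sorted(set(int(c) for c in counts))
    if experienced_pool is None:
        new_idx = {panel.odor_index(o) for o in new_odor_ids}
        experienced_pool = [i for i in range(panel.n_odors) if i not in new_idx]
    if max(counts) > len(experienced_pool):
        raise ValueError("not enough odors in the experienced pool")
    kwargs = protocol_kwargs or {}
    align = max(counts)

    rows = []
    naive_counts_cache: dict = {}
    for seed in seeds:
        seed = int(seed)
        for new_odor in new_odor_ids:
            results = {}
            for count in counts:
                net = network_factory(seed)
                proto = ExperienceProtocol(
                    experienced_odor_ids=tuple(experienced_pool[:count]),
                    new_odor_id=new_odor,
                    ordering=ordering,
                    align_to_count=align,
                    **kwargs,
                )
                results[count] = run_protocol(net, panel, proto, sim_config, seed=seed)
            if 0 in counts:
                naive_counts_cache[(seed, panel.odor_index(new_odor))] = (
                    results[0].new_odor_counts("mitral")
                )
            for count, res in results.items():
                mf, ml = _first_last(res.mitral_sparseness)
                gf, gl = _first_last(res.granule_sparseness)
                fit = metrics.fit_S_half(res.mitral_sparseness_cumulative)
                coh = metrics.network_coherence(
                    res.mitral.window(*res.new_odor_window), tau_ms=tau_ms
                )
                ws = metrics.weight_summary(res.network, panel, new_odor)
                rows.append(
                    {
                        "count": count,
                        "new_odor": panel.labels[panel.odor_index(new_odor)],
                        "new_odor_index": panel.odor_index(new_odor),
                        "seed": seed,
                        "mitral_sparseness_first": mf,
                        "mitral_sparseness_last": ml,
                        "granule_sparseness_first": gf,
                        "granule_sparseness_last": gl,
                        "s_half": fit.S_half,
                        "s_half_converged": fit.converged,
                        "network_coherence": coh,
                        "G_ex_strong": ws.loc["strong", "G_ex"],
                        "G_ex_weak": ws.loc["weak", "G_ex"],
                        "G_ex_all": ws.loc["all", "G_ex"],
                        "G_in_strong": ws.loc["strong", "G_in"],
                        "G_in_weak": ws.loc["weak", "G_in"],
                        "G_in_all": ws.loc["all", "G_in"],
                        "_counts_matrix": res.new_odor_counts("mitral"),
                    }
                )

    # between-response correlation: each condition's new-odor response vs
    # the other new odors' naive responses (same seed)
    df = pd.DataFrame(rows)
    resp = []
    for _, row in df.iterrows():
        others = [
            naive_counts_cache.get((row["seed"], panel.odor_index(o)))
            for o in new_odor_ids
            if panel.odor_index(o) != row["new_odor_index"]
        ]
        others = [o for o in others if o is not None]
        if not others:
            resp.append(np.nan)
            continue
        vals = [
            metrics.response_correlation_from_counts(row["_counts_matrix"], o)[0]
            for o in others
        ]
        vals = [v for v in vals if np.isfinite(v)]
        resp.append(float(np.mean(vals)) if vals else np.nan)
    df["response_correlation"] = resp
    return df.drop(columns=["_counts_matrix"])
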