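"""Construction of the 1-D-tract mitral-granule network.

Glomeruli are laid out uniformly along a one-dimensional tract.  Each
glomerulus drives a fixed number of mitral cells (MCs) whose somata sit
at the glomerulus position; every MC extends two lateral dendrites in
opposite directions along the tract, split into equal segments and
truncated at the tract ends.  Granule cells (GCs) are placed uniformly
along the tract and form reciprocal dendrodendritic synapses with the
mitral dendrite segments that overlap their position.  Every synapse
carries two independently plastic components: an excitatory MC->GC
component and an inhibitory GC->MC component, both starting fully
depressed (p = 0, w = 0).

The default configuration reproduces the reference census —
100 glomeruli, 500 mitral cells and 10,000 granule cells
(glom:MC:GC = 1:5:100) with 1.5 mm lateral dendrites — and a reduced
desk-scale preset (20 glomeruli, 100 MC, 2,000 GC) keeps the same
ratios for fast experimentation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NetworkConfig",
    "Network",
    "SynapseComponent",
    "DendrodendriticSynapse",
    "build_network",
    "count_summary",
    "synapse_distance_profile",
    "write_network_bundle",
    "read_network_bundle",
    "FULL_PRESET",
    "REDUCED_PRESET",
]

P_MAX = 50.0


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes and geometry of the mitral-granule network."""

    n_glomeruli: int = 100
    mitral_per_glomerulus: int = 5
    granule_per_mitral: int = 20           # glom : MC : GC = 1 : 5 : 100
    lateral_dendrite_length: float = 1.5   # mm, each of the two dendrites
    segments_per_dendrite: int = 10
    granule_dendrite_segments: int = 20
    granule_dendrite_length_um: float = 250.0
    tract_length: float = 5.0              # mm
    contacts_per_granule: float = 6.0      # mean reciprocal synapses per GC
    g_max_exc: float = 4.0                 # nS ceiling, MC->GC component
    g_max_inh: float = 1.0                 # nS ceiling, GC->MC component

    def __post_init__(self):
        for name in (
            "n_glomeruli",
            "mitral_per_glomerulus",
            "granule_per_mitral",
            "segments_per_dendrite",
            "granule_dendrite_segments",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lateral_dendrite_length <= 0 or self.tract_length <= 0:
            raise ValueError("lengths must be positive")
        if self.tract_length < self.lateral_dendrite_length:
            raise ValueError(
                "tract shorter than a lateral dendrite; widen tract_length"
            )
        if self.contacts_per_granule <= 0:
            raise ValueError("contacts_per_granule must be positive")

    @property
    def n_mitral(self) -> int:
        return self.n_glomeruli * self.mitral_per_glomerulus

    @property
    def n_granule(self) -> int:
        return self.n_mitral * self.granule_per_mitral


FULL_PRESET = NetworkConfig()
REDUCED_PRESET = NetworkConfig(n_glomeruli=20)


@dataclass
class SynapseComponent:
    """One plastic component (excitatory MC->GC or inhibitory GC->MC).

    The weight is slaved to the state through the sigmoid:
    w = g_max * S(p), p clipped to [0, 50].
    """

    p: float = 0.0
    w: float = 0.0
    g_max: float = 1.0
    last_presyn_time: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.p <= P_MAX:
            raise ValueError(f"p must lie in [0, {P_MAX}]")
        if self.g_max < 0 or not 0.0 <= self.w <= self.g_max + 1e-12:
            raise ValueError("w must lie in [0, g_max]")


@dataclass(frozen=True)
class DendrodendriticSynapse:
    """Read-only view of one reciprocal contact (snapshot of array state)."""

    mitral_id: int
    dendrite: int
    segment: int
    granule_id: int
    distance_mm: float
    exc: SynapseComponent
    inh: SynapseComponent


class Network:
    """Columnar network state: cells, dendrite segments and synapses.

    Segment arrays are indexed by a global segment id covering
    n_mitral x 2 dendrites x segments_per_dendrite entries; synapse
    arrays are indexed by synapse id.  Plasticity state lives here
    (p/w per component) and is mutated in place by the simulator.
    """

    def __init__(self, config: NetworkConfig, seed: int | None):
        self.config = config
        self.seed = seed
        self.glom_pos: np.ndarray = None
        self.mc_glom: np.ndarray = None
        self.mc_pos: np.ndarray = None
        self.gc_pos: np.ndarray = None
        # per global segment id
        self.seg_mc: np.ndarray = None
        self.seg_dendrite: np.ndarray = None
        self.seg_index: np.ndarray = None
        self.seg_x0: np.ndarray = None
        self.seg_x1: np.ndarray = None
        self.seg_dist: np.ndarray = None      # mm, midpoint distance from soma
        # per synapse id
        self.syn_seg: np.ndarray = None
        self.syn_mc: np.ndarray = None
        self.syn_gc: np.ndarray = None
        self.syn_dist: np.ndarray = None
        self.p_exc: np.ndarray = None
        self.p_inh: np.ndarray = None
        self.w_exc: np.ndarray = None
        self.w_inh: np.ndarray = None
        self.last_exc: np.ndarray = None
        self.last_inh: np.ndarray = None

    # -- census ---------------------------------------------------------
    @property
    def n_glomeruli(self) -> int:
        return self.config.n_glomeruli

    @property
    def n_mitral(self) -> int:
        return self.config.n_mitral

    @property
    def n_granule(self) -> int:
        return self.config.n_granule

    @property
    def n_segments(self) -> int:
        return self.seg_mc.size

    @property
    def n_synapses(self) -> int:
        return self.syn_seg.size

    def mitral_of_glomerulus(self, glom: int) -> np.ndarray:
        return np.flatnonzero(self.mc_glom == glom)

    def strengths_per_mitral(self, odor_strengths: np.ndarray) -> np.ndarray:
        """Expand a per-glomerulus strength vector to one value per MC."""
        return np.asarray(odor_strengths)[self.mc_glom]

    def synapse(self, i: int) -> DendrodendriticSynapse:
        """Snapshot of synapse ``i`` as a pair of components."""
        seg = self.syn_seg[i]
        last_e = self.last_exc[i]
        last_i = self.last_inh[i]
        return DendrodendriticSynapse(
            mitral_id=int(self.syn_mc[i]),
            dendrite=int(self.seg_dendrite[seg]),
            segment=int(self.seg_index[seg]),
            granule_id=int(self.syn_gc[i]),
            distance_mm=float(self.syn_dist[i]),
            exc=SynapseComponent(
                p=float(self.p_exc[i]),
                w=float(self.w_exc[i]),
                g_max=self.config.g_max_exc,
                last_presyn_time=None if np.isnan(last_e) else float(last_e),
            ),
            inh=SynapseComponent(
                p=float(self.p_inh[i]),
                w=float(self.w_inh[i]),
                g_max=self.config.g_max_inh,
                last_presyn_time=None if np.isnan(last_i) else float(last_i),
            ),
        )

    def reset_plasticity(self) -> None:
        self.p_exc[:] = 0.0
        self.p_inh[:] = 0.0
        self.w_exc[:] = 0.0
        self.w_inh[:] = 0.0
        self.last_exc[:] = np.nan
        self.last_inh[:] = np.nan


def build_network(config: NetworkConfig = FULL_PRESET, seed: int | None = None) -> Network:
    """Build the network; deterministic for a fixed (config, seed).

    All synapse components start fully depressed (p = 0, w = 0).  Granule
    cells that capture no contact after density thinning are attached to
    the nearest dendrite segment so the 1:5:100 census stays exact and no
    GC is isolated.
    """
    rng = np.random.default_rng(seed)
    net = Network(config, seed)
    c = config

    # glomeruli uniformly spaced; MC somata at their glomerulus position
    net.glom_pos = (np.arange(c.n_glomeruli) + 0.5) * (c.tract_length / c.n_glomeruli)
    net.mc_glom = np.repeat(np.arange(c.n_glomeruli), c.mitral_per_glomerulus)
    net.mc_pos = net.glom_pos[net.mc_glom]

    # two lateral dendrites per MC in opposite tract directions
    S = c.segments_per_dendrite
    seg_len = c.lateral_dendrite_length / S
    n_mc = c.n_mitral
    net.seg_mc = np.repeat(np.arange(n_mc), 2 * S)
    net.seg_dendrite = np.tile(np.repeat([0, 1], S), n_mc)
    net.seg_index = np.tile(np.concatenate([np.arange(S), np.arange(S)]), n_mc)
    prox = net.seg_index * seg_len
    dist = prox + seg_len
    soma = net.mc_pos[net.seg_mc]
    sign = np.where(net.seg_dendrite == 0, 1.0, -1.0)
    a = soma + sign * prox
    b = soma + sign * dist
    net.seg_x0 = np.clip(np.minimum(a, b), 0.0, c.tract_length)
    net.seg_x1 = np.clip(np.maximum(a, b), 0.0, c.tract_length)
    net.seg_dist = prox + 0.5 * seg_len

    # granule cells uniform along the tract
    n_gc = c.n_granule
    net.gc_pos = np.sort(rng.uniform(0.0, c.tract_length, size=n_gc))

    # candidate contacts: every segment whose extent covers the GC position
    live = net.seg_x1 > net.seg_x0  # segments truncated to zero length drop out
    order = np.argsort(net.seg_x0, kind="stable")
    x0s = net.seg_x0[order]
    syn_seg_parts, syn_gc_parts = [], []
    x1_sorted = net.seg_x1[order]
    live_sorted = live[order]
    hi = np.searchsorted(x0s, net.gc_pos, side="right")
    for g in range(n_gc):
        cand = order[:hi[g]][(x1_sorted[:hi[g]] >= net.gc_pos[g]) & live_sorted[:hi[g]]]
        if cand.size == 0:
            mid = 0.5 * (net.seg_x0 + net.seg_x1)
            cand = np.array([int(np.argmin(np.abs(mid - net.gc_pos[g])))])
            keep = cand
        else:
            p_keep = min(1.0, c.contacts_per_granule / cand.size)
            keep = cand[rng.random(cand.size) < p_keep]
            if keep.size == 0:  # never leave a GC isolated
                keep = cand[[rng.integers(cand.size)]]
        syn_seg_parts.append(keep)
        syn_gc_parts.append(np.full(keep.size, g, dtype=np.int64))

    net.syn_seg = np.concatenate(syn_seg_parts)
    net.syn_gc = np.concatenate(syn_gc_parts)
    net.syn_mc = net.seg_mc[net.syn_seg]
    net.syn_dist = net.seg_dist[net.syn_seg]
    n_syn = net.syn_seg.size
    net.p_exc = np.zeros(n_syn)
    net.p_inh = np.zeros(n_syn)
    net.w_exc = np.zeros(n_syn)
    net.w_inh = np.zeros(n_syn)
    net.last_exc = np.full(n_syn, np.nan)
    net.last_inh = np.full(n_syn, np.nan)
    return net


def count_summary(network: Network) -> dict:
    """Entity counts and per-glomerulus mitral fan-out."""
    c = network.config
    fan = np.bincount(network.mc_glom, minlength=c.n_glomeruli)
    return {
        "n_glomeruli": c.n_glomeruli,
        "n_mitral": network.n_mitral,
        "n_granule": network.n_granule,
        "n_synapses": network.n_synapses,
        "ratio": (
            1,
            network.n_mitral // c.n_glomeruli,
            network.n_granule // c.n_glomeruli,
        ),
        "mitral_fanout_per_glomerulus": fan,
        "mean_contacts_per_granule": network.n_synapses / network.n_granule,
    }


def synapse_distance_profile(network: Network, mitral_id: int) -> pd.DataFrame:
    """Synapse count and mean component weights per segment of one MC,
    indexed by segment distance from the soma."""
    if not 0 <= mitral_id < network.n_mitral:
        raise KeyError(f"unknown mitral cell {mitral_id}")
    mask = network.syn_mc == mitral_id
    S = network.config.segments_per_dendrite
    seg_idx = network.seg_index[network.syn_seg[mask]]
    seg_len = network.config.lateral_dendrite_length / S
    rows = []
    for s in range(S):
        sel = seg_idx == s
        n = int(sel.sum())
        rows.append(
            {
                "segment": s,
                "distance_mm": (s + 0.5) * seg_len,
                "n_synapses": n,
                "mean_w_exc": float(network.w_exc[mask][sel].mean()) if n else 0.0,
                "mean_w_inh": float(network.w_inh[mask][sel].mean()) if n else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("segment")


# -- serialization ------------------------------------------------------

_CELL_COLS = ["kind", "cell_id", "glomerulus", "position_mm"]
_SYN_COLS = [
    "mitral_id", "dendrite", "segment", "granule_id", "distance_mm",
    "p_exc", "p_inh", "w_exc", "w_inh",
]


def write_network_bundle(network: Network, prefix) -> list:
    """Serialize to ``<prefix>.config.json / .cells.csv / .synapses.csv``.

    Byte-stable: same network state writes identical files.
    """
    prefix = str(prefix)
    paths = []
    cfg = asdict(network.config)
    cfg["seed"] = network.seed
    p = prefix + ".config.json"
    with open(p, "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
    paths.append(p)

    cells = pd.concat(
        [
            pd.DataFrame(
                {
                    "kind": "mitral",
                    "cell_id": np.arange(network.n_mitral),
                    "glomerulus": network.mc_glom,
                    "position_mm": network.mc_pos,
                }
            ),
            pd.DataFrame(
                {
                    "kind": "granule",
                    "cell_id": np.arange(network.n_granule),
                    "glomerulus": -1,
                    "position_mm": network.gc_pos,
                }
            ),
        ],
        ignore_index=True,
    )
    p = prefix + ".cells.csv"
    cells.to_csv(p, index=False, float_format="%.9g")
    paths.append(p)

    syn = pd.DataFrame(
        {
            "mitral_id": network.syn_mc,
            "dendrite": network.seg_dendrite[network.syn_seg],
            "segment": network.seg_index[network.syn_seg],
            "granule_id": network.syn_gc,
            "distance_mm": network.syn_dist,
            "p_exc": network.p_exc,
            "p_inh": network.p_inh,
            "w_exc": network.w_exc,
            "w_inh": network.w_inh,
        }
    )
    p = prefix + ".synapses.csv"
    syn.to_csv(p, index=False, float_format="%.9g")
    paths.append(p)
    return paths


def read_network_bundle(prefix) -> Network:
    """Rebuild a network from a serialized bundle (geometry is rebuilt
    deterministically from the stored config and seed; plasticity state
    is restored from the synapse table)."""
    prefix = str(prefix)
    with open(prefix + ".config.json") as fh:
        cfg = json.load(fh)
    seed = cfg.pop("seed", None)
    net = build_network(NetworkConfig(**cfg), seed=seed)
    syn = pd.read_csv(prefix + ".synapses.csv")
    if len(syn) != net.n_synapses:
        raise ValueError("synapse table does not match rebuilt geometry")
    net.p_exc[:] = syn["p_exc"].to_numpy()
    net.p_inh[:] = syn["p_inh"].to_numpy()
    net.w_exc[:] = syn["w_exc"].to_numpy()
    net.w_inh[:] = syn["w_inh"].to_numpy()
    return net
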