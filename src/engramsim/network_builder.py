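"""Random E-I network construction, engram embedding, and impairment
transforms.

The circuit is a directed Erdos-Renyi graph over nE excitatory and nI
inhibitory neurons: every ordered pair (j, i), j != i, is connected
independently with probability C.  Weights follow the pre/post type
(g_EE, g_IE, g_EI, g_II), except that E->E synapses between two members of
the same engram carry the elevated weight g_M_EE.  Engrams are contiguous,
disjoint blocks of excitatory neurons (engram k = neurons
[k*engram_size, (k+1)*engram_size)), matching the convention that the
learning engram is neurons 0-199.

Impairment transforms model three degradation modes: neuronal loss (R_N,
remove a random fraction of neurons, stratified to preserve the E:I ratio),
connection loss (R_C, remove a random fraction of edges), and synaptic
weakening (R_w, scale every weight).  E/I balance manipulation rewrites all
E->I weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import DegradationSpec, NetworkConfig

__all__ = [
    "SynapticGraph",
    "build_network",
    "apply_degradation",
    "set_ei_manipulation",
]

# receptor-class codes on edges, derived from the presynaptic type
RECEPTOR_EXC = 0  # E presynaptic: AMPA + NMDA
RECEPTOR_INH = 1  # I presynaptic: GABA


@dataclass
class SynapticGraph:
    """Directed weighted connectivity with engram labels.

    Edge arrays are parallel and sorted by (pre, post); iteration order is
    therefore deterministic for a fixed seed.  ``engram_id`` is -1 for
    neurons outside any engram (all I neurons and unassigned E neurons).
    """

    pre: np.ndarray  # int32 presynaptic ids
    post: np.ndarray  # int32 postsynaptic ids
    weight: np.ndarray  # float64
    is_exc: np.ndarray  # bool per neuron, True for E
    engram_id: np.ndarray  # int32 per neuron, -1 outside engrams
    config: NetworkConfig

    @property
    def n_neurons(self) -> int:
        return self.is_exc.size

    @property
    def n_edges(self) -> int:
        return self.pre.size

    @property
    def nE(self) -> int:
        return int(self.is_exc.sum())

    @property
    def nI(self) -> int:
        return int((~self.is_exc).sum())

    @property
    def receptor(self) -> np.ndarray:
        """Receptor class per edge (excitatory vs inhibitory presynapse)."""
        return np.where(self.is_exc[self.pre], RECEPTOR_EXC, RECEPTOR_INH).astype(
            np.int8
        )

    @property
    def plastic(self) -> np.ndarray:
        """True exactly for E->E edges."""
        return self.is_exc[self.pre] & self.is_exc[self.post]

    def engram_members(self, k: int) -> np.ndarray:
        """Neuron ids belonging to engram k."""
        return np.flatnonzero(self.engram_id == k)

    @property
    def n_engrams(self) -> int:
        m = self.engram_id.max(initial=-1)
        return int(m) + 1

    def to_frame(self) -> pd.DataFrame:
        """Edge table matching the CSV export schema."""
        return pd.DataFrame(
            {
                "pre": self.pre,
                "post": self.post,
                "weight": self.weight,
                "receptor": np.where(
                    self.receptor == RECEPTOR_EXC, "exc", "inh"
                ),
                "plastic": self.plastic,
                "engram_pre": self.engram_id[self.pre],
                "engram_post": self.engram_id[self.post],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def copy(self) -> "SynapticGraph":
        return SynapticGraph(
            pre=self.pre.copy(),
            post=self.post.copy(),
            weight=self.weight.copy(),
            is_exc=self.is_exc.copy(),
            engram_id=self.engram_id.copy(),
            config=self.config,
        )


def build_network(config: NetworkConfig) -> SynapticGraph:
    """Construct the random circuit defined by ``config``.

    Every ordered pair of distinct neurons is an edge independently with
    probability C; self-connections are excluded, and at most one edge exists
    per ordered pair.  Weights follow the type-pair rule, overridden to
    g_M_EE for intra-engram E->E pairs.  Reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    nE = config.nE

    is_exc = np.zeros(n, dtype=bool)
    is_exc[:nE] = True

    engram_id = np.full(n, -1, dtype=np.int32)
    for k in range(config.n_engrams):
        engram_id[k * config.engram_size : (k + 1) * config.engram_size] = k

    if config.C == 0.0 or n < 2:
        pre = np.empty(0, dtype=np.int32)
        post = np.empty(0, dtype=np.int32)
        weight = np.empty(0, dtype=np.float64)
        return SynapticGraph(pre, post, weight, is_exc, engram_id, config)

    # Bernoulli mask over the full n x n ordered-pair matrix, diagonal off.
    mask = rng.random((n, n)) < config.C
    np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    pre = pre.astype(np.int32)
    post = post.astype(np.int32)

    weight = _assign_weights(pre, post, is_exc, engram_id, config)
    return SynapticGraph(pre, post, weight, is_exc, engram_id, config)


def _assign_weights(
    pre: np.ndarray,
    post: np.ndarray,
    is_exc: np.ndarray,
    engram_id: np.ndarray,
    config: NetworkConfig,
) -> np.ndarray:
    pe, po = is_exc[pre], is_exc[post]
    weight = np.empty(pre.size, dtype=np.float64)
    weight[pe & po] = config.g_EE
    weight[~pe & po] = config.g_IE
    weight[pe & ~po] = config.g_EI
    weight[~pe & ~po] = config.g_II
    same_engram = (
        pe & po & (engram_id[pre] >= 0) & (engram_id[pre] == engram_id[post])
    )
    weight[same_engram] = config.g_M_EE
    return weight


def apply_degradation(
    graph: SynapticGraph, spec: DegradationSpec, seed: int = 0
) -> SynapticGraph:
    """Apply neuronal loss, connection loss, and weight scaling.

    R_N removes a uniform random fraction (1 - R_N) of neurons together with
    all incident edges, drawn separately within the E and I populations so the
    E:I ratio is preserved (and hence engram neurons are removed
    proportionally).  Removed neurons stay in the id space but become
    isolated, so ids remain stable.  R_C removes a uniform random fraction
    (1 - R_C) of the surviving edges.  R_w multiplies every remaining weight
    by R_w.  The three transforms are independent.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    g = graph.copy()

    if spec.R_N < 1.0:
        keep = np.ones(g.n_neurons, dtype=bool)
        for pop_mask in (g.is_exc, ~g.is_exc):
            ids = np.flatnonzero(pop_mask)
            n_keep = int(round(spec.R_N * ids.size))
            removed = rng.choice(ids, size=ids.size - n_keep, replace=False)
            keep[removed] = False
        edge_keep = keep[g.pre] & keep[g.post]
        g = _subset_edges(g, edge_keep)
        g.engram_id = np.where(keep, g.engram_id, -1).astype(np.int32)

    if spec.R_C < 1.0:
        edge_keep = rng.random(g.n_edges) < spec.R_C
        g = _subset_edges(g, edge_keep)

    if spec.R_w != 1.0:
        g.weight = g.weight * spec.R_w

    return g


def _subset_edges(g: SynapticGraph, keep: np.ndarray) -> SynapticGraph:
    return SynapticGraph(
        pre=g.pre[keep],
        post=g.post[keep],
        weight=g.weight[keep],
        is_exc=g.is_exc,
        engram_id=g.engram_id,
        config=g.config,
    )


def set_ei_manipulation(graph: SynapticGraph, g_EI_new: float) -> SynapticGraph:
    """Set all E->I weights to ``g_EI_new`` (E-I balance manipulation)."""
    if g_EI_new < 0:
        raise ValueError("g_EI_new must be non-negative")
    g = graph.copy()
    ei = g.is_exc[g.pre] & ~g.is_exc[g.post]
    g.weight[ei] = g_EI_new
    g.config = replace(g.config, g_EI=g_EI_new)
    return g
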