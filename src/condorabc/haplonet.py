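"""Temporal parsimony haplotype networks.

A minimum-spanning network is built on (optionally position-weighted) Hamming
distances between haplotypes, keeping every co-minimal edge, and each link is
annotated with a statistical-parsimony probability: the probability that a
connection of j observed steps involves no hidden (homoplasious) change.

The link probability uses a finite-sites model: substitutions hit one of L
equally mutable sites uniformly at random and change the base to one of the
three alternatives, so the observed difference count d performs a random walk
(d -> d+1 with probability (L-d)/L, d -> d-1 with probability d/(3L)).  The
number of substitutions separating two haplotypes is given a Poisson prior
with mean set to the Jukes-Cantor-corrected expected substitution count, and
the reported probability is the posterior mass on "exactly j substitutions",
i.e. a fully parsimonious link.

Temporal layering reports per-period presence of each haplotype and the
fraction of haplotype diversity lost between the earliest and latest period.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._seqarray import encode
from .samples import HaplotypeTable


def link_probability(steps: int, seq_length: int, max_extra: int = 24) -> float:
    """Probability that a ``steps``-step link is non-homoplasious.

    Strictly decreasing in ``steps`` at fixed length and increasing in
    ``seq_length`` at fixed steps.  ``max_extra`` truncates the Poisson sum
    over hidden substitution counts.
    """
    j, L = int(steps), int(seq_length)
    if j < 1:
        raise ValueError("steps must be >= 1")
    if j >= L:
        raise ValueError(f"steps ({j}) must be < sequence length ({L})")
    p = j / L
    if p >= 0.75:
        raise ValueError("divergence too high for the Jukes-Cantor correction")
    lam = -0.75 * L * math.log(1.0 - 4.0 * p / 3.0)  # expected substitutions

    smax = j + max_extra
    # random walk over difference counts, one substitution per step
    probs = np.zeros(smax + 1)
    probs[0] = 1.0
    like = {}  # s -> P(d = j | s substitutions)
    for s in range(1, smax + 1):
        nxt = np.zeros_like(probs)
        d = np.arange(smax + 1)
        up = (L - d) / L
        down = d / (3.0 * L)
        stay = 1.0 - up - down
        nxt[1:] += probs[:-1] * up[:-1]
        nxt[:-1] += probs[1:] * down[1:]
        nxt += probs * stay
        probs = nxt
        like[s] = probs[j]

    log_pois = {s: s * math.log(lam) - lam - math.lgamma(s + 1)
                for s in range(j, smax + 1)}
    weights = {s: math.exp(log_pois[s]) * like[s] for s in range(j, smax + 1)}
    total = sum(weights.values())
    return weights[j] / total


def partition_weights(partitions, cr_weight: float = 0.5,
                      cr_name: str = "control_region") -> np.ndarray:
    """Per-column weights downweighting the fast-evolving Control region.

    Mutation-rate heterogeneity between the noncoding Control region and the
    12S coding fragment is expressed as one scalar (< 1) applied to the
    Control-region columns; all other columns get weight 1.
    """
    total = sum(p[2] for p in partitions)
    w = np.ones(total)
    for name, start, length in partitions:
        if name == cr_name:
            w[start:start + length] = cr_weight
    return w


@dataclass
class HaplotypeNetwork:
    """Minimum-spanning haplotype network with temporal annotations."""

    graph: nx.Graph
    table: HaplotypeTable
    seq_length: int

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return [(a, b, d["steps"], d["link_probability"])
                for a, b, d in self.graph.edges(data=True)]

    def edge_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"hap_a": a, "hap_b": b, "steps": s, "link_probability": p}
             for a, b, s, p in sorted(self.edges)]
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_network(table: HaplotypeTable,
                  position_weights: np.ndarray | None = None) -> HaplotypeNetwork:
    """Minimum-spanning network over the haplotypes of ``table``.

    Edges are chosen greedily by (weighted) distance class; within one class
    every edge joining two still-separate components is kept, so co-minimal
    alternative connections survive (a network, not a tree).  Edge ``steps``
    is the unweighted number of differing sites and ``link_probability`` the
    statistical-parsimony support of the link.  Deterministic for any input
    order because classes are processed in full.
    """
    haps = table.haplotypes
    if not haps:
        raise ValueError("empty haplotype table")
    ids = [h for h, _ in haps]
    mat = encode([s for _, s in haps])
    n, L = mat.shape
    weights = (np.ones(L) if position_weights is None
               else np.asarray(position_weights, dtype=float))
    if weights.shape != (L,):
        raise ValueError("position_weights length must equal alignment length")

    g = nx.Graph()
    for hid in ids:
        per_stratum = {f"{per}:{reg}": c
                       for (h, per, reg), c in table.counts.items() if h == hid}
        g.add_node(hid, total=sum(per_stratum.values()), **per_stratum)
    if n == 1:
        return HaplotypeNetwork(graph=g, table=table, seq_length=L)

    pairs = []
    for i, j in itertools.combinations(range(n), 2):
        mism = mat[i] != mat[j]
        steps = int(mism.sum())
        pairs.append((float(weights[mism].sum()), steps, i, j))
    pairs.sort(key=lambda t: (t[0], t[2], t[3]))

    comp = {i: i for i in range(n)}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for _, cls in itertools.groupby(pairs, key=lambda t: t[0]):
        cls = list(cls)
        roots_before = {i: find(i) for i in range(n)}
        added = []
        for _, steps, i, j in cls:
            if roots_before[i] != roots_before[j]:
                added.append((i, j, steps))
        for i, j, steps in added:
            ri, rj = find(i), find(j)
            if ri != rj:
                comp[ri] = rj
            g.add_edge(ids[i], ids[j], steps=steps,
                       link_probability=link_probability(steps, L))
        if len({find(i) for i in range(n)}) == 1:
            break
    return HaplotypeNetwork(graph=g, table=table, seq_length=L)


@dataclass
class LayeredNetwork:
    """Per-period view of a haplotype network."""

    periods: list[str]
    presence: dict[str, dict[str, int]]  # period -> hap -> count
    loss_percent: float
    lost_haplotypes: list[str] = field(default_factory=list)
    gained_haplotypes: list[str] = field(default_factory=list)


def layer_by_period(network: HaplotypeNetwork,
                    table: HaplotypeTable | None = None) -> LayeredNetwork:
    """Split the network into chronological layers and summarize haplotype
    turnover.  The loss statistic is the percentage of all distinct
    haplotypes that were present in the earliest period but absent from the
    latest one."""
    table = table if table is not None else network.table
    periods = table.periods()
    if not periods:
        raise ValueError("table has no strata")
    presence = {per: {h: c for h, c in table.haplotype_counts(period=per).items()
                      if c > 0}
                for per in periods}
    first, last = periods[0], periods[-1]
    lost = sorted(set(presence[first]) - set(presence[last]))
    gained = sorted(set(presence[last]) - set(presence[first]))
    loss = 100.0 * len(lost) / table.n_H if table.n_H else 0.0
    return LayeredNetwork(periods=periods, presence=presence,
                          loss_percent=loss, lost_haplotypes=lost,
                          gained_haplotypes=gained)
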