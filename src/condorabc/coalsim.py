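"""Serial-sample matrilineal coalescent simulation with HKY mutations.

The simulator draws genealogies for samples collected at different times
(museum vs. modern pulses) under a single panmictic population whose female
effective size Nef is piecewise constant backward in time.  Four demographic
scenarios are supported:

1. constant size Nef1;
2. recent bottleneck: Nef1 since t1, larger Nef2 before;
3. ancient bottleneck: Nef1 since t2, smaller Nef3 before;
4. expansion between two bottlenecks: Nef1 since t1, Nef2 back to te,
   ancient-bottleneck size Nef4 back to t2, and ancestral Nef2 beyond.

mtDNA is matrilineally haploid, so the pairwise coalescence rate is
k(k-1)/(2 Nef(t)) per generation with no diploid factor.  Times are years at
the interface and generations internally (default generation time 7 years).
Sequences evolve under HKY with per-partition rate multipliers on one shared
genealogy (the mitochondrion is fully linked).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seqarray import decode
from .samples import CONTEMPORARY, HISTORICAL, SampleRecord, SampleSet

DEFAULT_GENERATION_TIME = 7.0


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioParams:
    """Demographic parameters of one simulation.

    Sizes are female effective sizes (individuals); times are years before
    present.  Only the fields used by ``scenario_id`` need to be set.
    """

    scenario_id: int
    nef1: float
    nef2: float = math.nan
    nef3: float = math.nan
    nef4: float = math.nan
    t1: float = math.nan
    te: float = math.nan
    t2: float = math.nan
    generation_time: float = DEFAULT_GENERATION_TIME

    def validate(self) -> None:
        if self.scenario_id not in (1, 2, 3, 4):
            raise ValueError(f"unknown scenario {self.scenario_id}")
        if self.nef1 < 2:
            raise ValueError("nef1 must be >= 2")
        if self.scenario_id == 2:
            if not self.nef2 > self.nef1:
                raise ValueError("scenario 2 requires nef2 > nef1")
            if not self.t1 > 0:
                raise ValueError("scenario 2 requires t1 > 0")
        if self.scenario_id == 3:
            if not self.nef3 < self.nef1:
                raise ValueError("scenario 3 requires nef3 < nef1")
            if self.nef3 < 2:
                raise ValueError("nef3 must be >= 2")
            if not self.t2 > 0:
                raise ValueError("scenario 3 requires t2 > 0")
        if self.scenario_id == 4:
            if not self.nef2 > self.nef1:
                raise ValueError("scenario 4 requires nef2 > nef1")
            if not self.nef4 < self.nef2:
                raise ValueError("scenario 4 requires nef4 < nef2")
            if self.nef4 < 2:
                raise ValueError("nef4 must be >= 2")
            if not (0 < self.t1 < self.te < self.t2):
                raise ValueError("scenario 4 requires 0 < t1 < te < t2")


@dataclass(frozen=True)
class MutationModel:
    """HKY substitution model over linked partitions.

    ``mu`` is the substitution rate per site per generation averaged across
    the alignment; each partition scales it by its rate multiplier (mean-1
    across columns by convention).
    """

    mu: float = 1e-6
    kappa: float = 10.0
    base_freqs: tuple[float, float, float, float] = (0.30, 0.30, 0.15, 0.25)
    partitions: tuple[tuple[int, float], ...] = ((145, 1.5), (165, 0.5606060606060606))

    def __post_init__(self):
        if self.mu < 0 or self.kappa <= 0:
            raise ValueError("mu must be >= 0 and kappa > 0")
        f = np.asarray(self.base_freqs, dtype=float)
        if (f <= 0).any() or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("base_freqs must be positive and sum to 1")

    @property
    def length(self) -> int:
        return sum(l for l, _ in self.partitions)

    def mean_rate_multiplier(self) -> float:
        tot = self.length
        return sum(l * r for l, r in self.partitions) / tot


def condor_mutation_model(mu: float = 1e-6, kappa: float = 10.0,
                          cr_multiplier: float = 1.5) -> MutationModel:
    """Default two-partition model: 145 bp Control region evolving faster
    than the 165 bp 12S fragment, multipliers normalized to mean 1."""
    l_cr, l_12s = 145, 165
    r_12s = (l_cr + l_12s - l_cr * cr_multiplier) / l_12s
    if r_12s <= 0:
        raise ValueError("cr_multiplier too large for mean-1 normalization")
    return MutationModel(mu=mu, kappa=kappa,
                         partitions=((l_cr, cr_multiplier), (l_12s, r_12s)))


@dataclass(frozen=True)
class Pulse:
    count: int
    years_before_present: float
    label: str = ""


@dataclass(frozen=True)
class SamplingDesign:
    """Sampling pulses: how many sequences enter at which tip age."""

    pulses: tuple[Pulse, ...]

    def __post_init__(self):
        if sum(p.count for p in self.pulses) < 2:
            raise ValueError("total sample size must be >= 2")
        if any(p.count < 1 or p.years_before_present < 0 for p in self.pulses):
            raise ValueError("pulse counts must be >= 1 and times >= 0")

    @property
    def total(self) -> int:
        return sum(p.count for p in self.pulses)


def condor_design(n_historical: int = 35, n_contemporary: int = 38,
                  historical_year: int = 1915, contemporary_year: int = 1985
                  ) -> SamplingDesign:
    """Two-pulse design at the stratum-median collection years."""
    delta = contemporary_year - historical_year
    return SamplingDesign((
        Pulse(n_contemporary, 0.0, CONTEMPORARY),
        Pulse(n_historical, float(delta), HISTORICAL),
    ))


def design_from_sample_set(sample_set,
                           generation_time: float = DEFAULT_GENERATION_TIME
                           ) -> SamplingDesign:
    """Sampling pulses from real collection years: each sample's tip age is
    (max year - year) / generation_time, rounded to the nearest generation;
    samples sharing a rounded age merge into one pulse."""
    years = [r.year for r in sample_set.records]
    if len(years) < 2:
        raise ValueError("need at least two samples")
    ref = max(years)
    ages: dict[float, list] = {}
    for r in sample_set.records:
        age = round((ref - r.year) / generation_time) * generation_time
        ages.setdefault(age, []).append(r)
    pulses = tuple(
        Pulse(len(recs), float(age),
              label=recs[0].period if len({x.period for x in recs}) == 1 else "")
        for age, recs in sorted(ages.items())
    )
    return SamplingDesign(pulses)


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Demography:
    """Piecewise-constant Nef(t), backward time in generations.

    ``boundaries`` are epoch start times (first is 0); epoch i spans
    [boundaries[i], boundaries[i+1]) with size ``sizes[i]``; the last epoch
    extends to infinity.
    """

    boundaries: tuple[float, ...]
    sizes: tuple[float, ...]
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self):
        if len(self.boundaries) != len(self.sizes):
            raise ValueError("boundaries and sizes must have equal length")
        if self.boundaries[0] != 0.0:
            raise ValueError("first epoch must start at 0")
        if any(b >= c for b, c in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("epoch boundaries must be strictly increasing")
        if any(s < 2 for s in self.sizes):
            raise ValueError("all sizes must be >= 2")

    def ne_at(self, t_generations: float) -> float:
        idx = int(np.searchsorted(self.boundaries, t_generations, side="right")) - 1
        return self.sizes[idx]


def demography_from_scenario(params: ScenarioParams,
                             scenario4_oldest_nef2: bool = True) -> Demography:
    """Epoch structure of a scenario, with event times converted from years
    to generations.

    Scenario 4 defaults to an ancestral Nef2 before the ancient bottleneck
    (sizes Nef1, Nef2, Nef4, Nef2 going back in time); setting
    ``scenario4_oldest_nef2=False`` swaps the two oldest epochs so the
    ancestral size is Nef4.
    """
    params.validate()
    g = params.generation_time
    if params.scenario_id == 1:
        return Demography((0.0,), (params.nef1,), g)
    if params.scenario_id == 2:
        return Demography((0.0, params.t1 / g), (params.nef1, params.nef2), g)
    if params.scenario_id == 3:
        return Demography((0.0, params.t2 / g), (params.nef1, params.nef3), g)
    sizes = ((params.nef1, params.nef2, params.nef4, params.nef2)
             if scenario4_oldest_nef2
             else (params.nef1, params.nef2, params.nef2, params.nef4))
    return Demography((0.0, params.t1 / g, params.te / g, params.t2 / g),
                      sizes, g)


# ---------------------------------------------------------------------------
# genealogy
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """Binary genealogy over 2n-1 nodes; tips are nodes [0, n)."""

    n_tips: int
    parent: np.ndarray        # int, -1 at the root
    node_times: np.ndarray    # generations before present
    tip_pulse: np.ndarray     # pulse index of each tip

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_times[-1])

    @property
    def total_branch_length(self) -> float:
        child = np.arange(self.n_nodes - 1)
        return float((self.node_times[self.parent[child]]
                      - self.node_times[child]).sum())


def sample_genealogy(design: SamplingDesign, demography: Demography,
                     seed=None) -> Genealogy:
    """Draw one heterochronous coalescent genealogy.

    Lineages enter at their pulse ages; between events the waiting time to
    the next coalescence is exponential with rate k(k-1)/(2 Nef) inside each
    epoch, re-drawn at epoch boundaries (valid by memorylessness).
    """
    rng = np.random.default_rng(seed)
    g = demography.generation_time
    pulses = sorted(
        ((p.years_before_present / g, pi) for pi, p in enumerate(design.pulses)),
        key=lambda x: x[0],
    )
    n = design.total
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    times = np.zeros(2 * n - 1)
    tip_pulse = np.empty(n, dtype=np.int64)

    tip = 0
    pending = []  # (time, [tip ids]) not yet entered
    for t_p, pi in pulses:
        ids = list(range(tip, tip + design.pulses[pi].count))
        for i in ids:
            times[i] = t_p
            tip_pulse[i] = pi
        pending.append((t_p, ids))
        tip += len(ids)

    boundaries = list(demography.boundaries)
    t, active = 0.0, []
    next_node = n
    while pending or len(active) > 1:
        next_pulse = pending[0][0] if pending else math.inf
        k = len(active)
        if k < 2:
            # jump to the next pulse
            t = next_pulse
            _, ids = pending.pop(0)
            active.extend(ids)
            continue
        epoch = int(np.searchsorted(boundaries, t, side="right")) - 1
        epoch_end = boundaries[epoch + 1] if epoch + 1 < len(boundaries) else math.inf
        rate = k * (k - 1) / (2.0 * demography.sizes[epoch])
        wait = rng.exponential(1.0 / rate)
        horizon = min(epoch_end, next_pulse)
        if t + wait < horizon:
            t += wait
            i = active.pop(rng.integers(len(active)))
            j = active.pop(rng.integers(len(active)))
            parent[i] = parent[j] = next_node
            times[next_node] = t
            active.append(next_node)
            next_node += 1
        elif next_pulse <= epoch_end:
            t = next_pulse
            _, ids = pending.pop(0)
            active.extend(ids)
        else:
            t = epoch_end
    return Genealogy(n_tips=n, parent=parent, node_times=times,
                     tip_pulse=tip_pulse)


# ---------------------------------------------------------------------------
# HKY mutation
# ---------------------------------------------------------------------------

def hky_transition_matrix(distance: float, kappa: float, freqs) -> np.ndarray:
    """Closed-form HKY transition probability matrix.

    ``distance`` is the expected number of substitutions per site along the
    branch (rate already normalized so the mean substitution rate is 1)."""
    pa, pc, pg, pt = freqs
    pi = np.array([pa, pc, pg, pt])
    pr, py = pa + pg, pc + pt
    beta = 1.0 / (2.0 * pr * py + 2.0 * kappa * (pa * pg + pt * pc))
    bigpi = np.array([pr, py, pr, py])  # class frequency of each base
    e2 = math.exp(-beta * distance)
    a_j = 1.0 + bigpi * (kappa - 1.0)
    e3 = np.exp(-beta * distance * a_j)

    P = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            same_class = (i % 2) == (j % 2)
            if not same_class:
                P[i, j] = pi[j] * (1.0 - e2)
            elif i == j:
                P[i, j] = (pi[j] + pi[j] * (1.0 / bigpi[j] - 1.0) * e2
                           + (bigpi[j] - pi[j]) / bigpi[j] * e3[j])
            else:
                P[i, j] = (pi[j] + pi[j] * (1.0 / bigpi[j] - 1.0) * e2
                           - pi[j] / bigpi[j] * e3[j])
    return P


def _hky_matrices(distances: np.ndarray, kappa: float, freqs) -> np.ndarray:
    """Vectorized closed-form HKY transition matrices, shape (m, 4, 4)."""
    pi = np.asarray(freqs, dtype=float)
    pr, py = pi[0] + pi[2], pi[1] + pi[3]
    beta = 1.0 / (2.0 * pr * py + 2.0 * kappa * (pi[0] * pi[2] + pi[1] * pi[3]))
    bigpi = np.array([pr, py, pr, py])
    d = np.asarray(distances, dtype=float)[:, None]
    e2 = np.exp(-beta * d)                      # (m, 1)
    e3 = np.exp(-beta * d * (1.0 + bigpi * (kappa - 1.0)))  # (m, 4)

    P = np.empty((len(d), 4, 4))
    # transversions: target column j, independent of source class
    P[:] = (pi * (1.0 - e2))[:, None, :]
    for j in range(4):
        same = pi[j] + pi[j] * (1.0 / bigpi[j] - 1.0) * e2[:, 0]
        for i in (j, (j + 2) % 4):  # same purine/pyrimidine class
            if i == j:
                P[:, i, j] = same + (bigpi[j] - pi[j]) / bigpi[j] * e3[:, j]
            else:
                P[:, i, j] = same - pi[j] / bigpi[j] * e3[:, j]
    return P


def apply_mutations(genealogy: Genealogy, model: MutationModel,
                    seed=None) -> np.ndarray:
    """Simulate sequences on a genealogy; returns the tip alignment as a
    uint8 matrix (rows in tip order).

    The root state of every site is drawn from the stationary base
    frequencies; each branch applies the closed-form HKY transition matrix
    at distance mu * rate_multiplier * branch_length, per partition."""
    rng = np.random.default_rng(seed)
    n_nodes = genealogy.n_nodes
    L = model.length
    states = np.empty((n_nodes, L), dtype=np.uint8)
    freqs = np.asarray(model.base_freqs)
    root = n_nodes - 1
    states[root] = rng.choice(4, size=L, p=freqs)

    order = [int(i) for i in np.argsort(-genealogy.node_times, kind="stable")
             if i != root]
    blen = (genealogy.node_times[genealogy.parent[order]]
            - genealogy.node_times[order])
    starts = np.cumsum([0] + [l for l, _ in model.partitions])
    # cumulative transition probabilities per (branch, source base), partition
    cums = [np.cumsum(_hky_matrices(model.mu * r * blen, model.kappa, freqs),
                      axis=2)
            for _, r in model.partitions]
    u = rng.random((len(order), L))
    for bi, node in enumerate(order):
        par = genealogy.parent[node]
        row = states[par]
        for (plen, _), s0, cum in zip(model.partitions, starts, cums):
            sl = slice(s0, s0 + plen)
            c = cum[bi][row[sl]]            # (plen, 4)
            states[node, sl] = (u[bi, sl, None] > c).sum(axis=1)
    return states[: genealogy.n_tips]


# ---------------------------------------------------------------------------
# end-to-end simulation
# ---------------------------------------------------------------------------

def simulate_matrix(params: ScenarioParams, model: MutationModel,
                    design: SamplingDesign, seed=None,
                    scenario4_oldest_nef2: bool = True
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Fast path for ABC: one simulated alignment as (uint8 matrix,
    per-row pulse index)."""
    rng = np.random.default_rng(seed)
    demog = demography_from_scenario(params, scenario4_oldest_nef2)
    gen = sample_genealogy(design, demog, rng)
    mat = apply_mutations(gen, model, rng)
    return mat, gen.tip_pulse


def simulate_dataset(params: ScenarioParams, model: MutationModel,
                     design: SamplingDesign, seed=None,
                     reference_year: int = 1985) -> SampleSet:
    """One simulated SampleSet: sequences plus period/year metadata derived
    from the sampling pulses.  Reproducible given the seed."""
    mat, tip_pulse = simulate_matrix(params, model, design, seed)
    seqs = decode(mat)
    g = params.generation_time
    records = []
    for i, (seq, pi) in enumerate(zip(seqs, tip_pulse)):
        pulse = design.pulses[pi]
        year = int(round(reference_year - pulse.years_before_present))
        label = pulse.label or (HISTORICAL if pulse.years_before_present > 0
                                else CONTEMPORARY)
        records.append(SampleRecord(
            sample_id=f"sim{i:04d}", year=min(max(year, 1800), 2100),
            latitude=0.0, longitude=0.0, region="simulated",
            sequence=seq, period=label,
        ))
    partitions = []
    pos = 0
    for idx, (plen, _) in enumerate(model.partitions):
        name = ("control_region", "s12")[idx] if idx < 2 else f"part{idx}"
        partitions.append((name, pos, plen))
        pos += plen
    return SampleSet(records, tuple(partitions))
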