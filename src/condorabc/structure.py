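"""Population differentiation and spatial structure.

Implements the Arlequin-style toolbox for haplotype data:

* pairwise phi_ST from an AMOVA variance partition on the matrix of raw
  pairwise nucleotide differences, with permutation p-values;
* Raymond & Rousset exact tests of differentiation (Markov chain over
  contingency tables with fixed margins);
* hierarchical (two-level) AMOVA with the three Excoffier permutation
  schemes;
* maximum-composite-likelihood (TN93 with pooled base frequencies) genetic
  distances;
* Mantel tests of isolation by distance on log-transformed great-circle
  distances.

Permutation p-values use the (b+1)/(B+1) estimator; exact enumeration is
available for small designs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .diversity import pairwise_difference_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "phi_st",
    "pairwise_phist",
    "exact_test",
    "hierarchical_amova",
    "mcl_distance",
    "mantel_test",
    "geographic_distance_matrix",
    "PairwiseDifferentiation",
    "AmovaResult",
    "MantelResult",
    "ExactTestResult",
    "DistanceResult",
]


# ---------------------------------------------------------------------------
# phi_ST (one-level AMOVA on a distance matrix)
# ---------------------------------------------------------------------------

def _one_level_components(d: np.ndarray, labels: np.ndarray):
    """Variance components (sigma2_a, sigma2_w) of a one-level AMOVA.

    ``d`` holds squared inter-individual distances (for haplotype data the
    raw count of pairwise differences plays that role)."""
    n_total = len(labels)
    groups = np.unique(labels)
    k = len(groups)
    iu = np.triu_indices(n_total, k=1)
    ssd_total = d[iu].sum() / n_total
    ssd_wp = 0.0
    sizes = np.empty(k)
    for gi, g in enumerate(groups):
        idx = np.flatnonzero(labels == g)
        sizes[gi] = len(idx)
        sub = d[np.ix_(idx, idx)]
        ssd_wp += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ssd_ap = ssd_total - ssd_wp
    df_ap, df_wp = k - 1, n_total - k
    sigma_w = ssd_wp / df_wp if df_wp > 0 else 0.0
    n_c = (n_total - (sizes**2).sum() / n_total) / df_ap
    sigma_a = (ssd_ap / df_ap - sigma_w) / n_c
    return sigma_a, sigma_w


def phi_st(d: np.ndarray, labels) -> float:
    """phi_ST among the label groups; 0 when there is no molecular variance.

    Negative estimates are reported as computed (not truncated)."""
    labels = np.asarray(labels)
    sigma_a, sigma_w = _one_level_components(np.asarray(d, dtype=float), labels)
    total = sigma_a + sigma_w
    if total == 0.0:
        return 0.0
    return sigma_a / total


def _phist_pvalue(d, labels, n_perm, rng, exact):
    obs = phi_st(d, labels)
    labels = np.asarray(labels)
    if exact:
        # enumerate distinct assignments of individuals to group sizes
        n = len(labels)
        groups, counts = np.unique(labels, return_counts=True)
        if len(groups) != 2:
            raise ValueError("exact enumeration implemented for 2 groups")
        hits = total = 0
        for combo in itertools.combinations(range(n), int(counts[0])):
            perm = np.full(n, groups[1], dtype=labels.dtype)
            perm[list(combo)] = groups[0]
            total += 1
            if phi_st(d, perm) >= obs - 1e-12:
                hits += 1
        return obs, hits / total
    b = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if phi_st(d, perm) >= obs - 1e-12:
            b += 1
    return obs, (b + 1) / (n_perm + 1)


@dataclass
class PairwiseDifferentiation:
    """Pairwise phi_ST and p-value matrices over a set of group labels."""

    groups: list[str]
    phi_st: np.ndarray
    perm_p: np.ndarray
    exact_p: np.ndarray | None = None
    exact_se: np.ndarray | None = None


def pairwise_phist(sample_set, grouping, n_perm: int = 10000, seed=None,
                   exact: bool = False) -> PairwiseDifferentiation:
    """Pairwise phi_ST between groups with permutation (or exact) p-values.

    ``grouping`` is either an attribute name of the sample records
    (``"period"``/``"region"``) or an explicit per-record label sequence.
    Groups with fewer than 2 samples yield NaN cells.
    """
    rng = np.random.default_rng(seed)
    labels, d = _labels_and_distance(sample_set, grouping)
    groups = list(dict.fromkeys(labels))
    k = len(groups)
    phi = np.zeros((k, k))
    pval = np.full((k, k), np.nan)
    np.fill_diagonal(pval, 1.0)
    for i, j in itertools.combinations(range(k), 2):
        idx = np.flatnonzero(np.isin(labels, [groups[i], groups[j]]))
        sizes = [np.sum(labels[idx] == g) for g in (groups[i], groups[j])]
        if min(sizes) < 2:
            phi[i, j] = phi[j, i] = np.nan
            logger.warning("group pair (%s, %s) has a group with <2 samples",
                           groups[i], groups[j])
            continue
        sub = d[np.ix_(idx, idx)]
        obs, p = _phist_pvalue(sub, labels[idx], n_perm, rng, exact)
        phi[i, j] = phi[j, i] = obs
        pval[i, j] = pval[j, i] = p
    return PairwiseDifferentiation(groups=groups, phi_st=phi, perm_p=pval)


def pairwise_exact_tests(sample_set, grouping, steps: int = 1_000_000,
                         dememorization: int = 500_000,
                         seed=None) -> PairwiseDifferentiation:
    """Pairwise Raymond & Rousset exact tests between groups, on the
    haplotype-by-group contingency tables; fills the ``exact_p`` /
    ``exact_se`` matrices (phi_st left at zero)."""
    from .samples import collapse_haplotypes

    rng = np.random.default_rng(seed)
    clean = sample_set.drop_ambiguous()
    if isinstance(grouping, str):
        labels = np.array([getattr(r, grouping) for r in clean])
    else:
        labels = np.asarray(list(grouping))
    table = collapse_haplotypes(clean)
    groups = list(dict.fromkeys(labels))
    hap_ids = [h for h, _ in table.haplotypes]

    def counts_for(label):
        idx = np.flatnonzero(labels == label)
        ids = {clean.records[i].sample_id for i in idx}
        out = dict.fromkeys(hap_ids, 0)
        seq_to_h = {s: h for h, s in table.haplotypes}
        for i in idx:
            out[seq_to_h[clean.records[i].sequence]] += 1
        return out

    per_group = {g: counts_for(g) for g in groups}
    k = len(groups)
    pmat = np.full((k, k), np.nan)
    semat = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        cont = [[per_group[groups[i]][h], per_group[groups[j]][h]]
                for h in hap_ids]
        res = exact_test(cont, steps=steps, dememorization=dememorization,
                         seed=rng.integers(2**31))
        pmat[i, j] = pmat[j, i] = res.p
        semat[i, j] = semat[j, i] = res.se
    return PairwiseDifferentiation(groups=groups, phi_st=np.zeros((k, k)),
                                   perm_p=np.full((k, k), np.nan),
                                   exact_p=pmat, exact_se=semat)


def _labels_and_distance(sample_set, grouping):
    from .samples import SampleSet

    if isinstance(sample_set, SampleSet):
        clean = sample_set.drop_ambiguous()
        if isinstance(grouping, str):
            labels = np.array([getattr(r, grouping) for r in clean])
        else:
            labels = np.asarray(list(grouping))
        d = pairwise_difference_matrix(clean)
    else:  # distance matrix given directly
        d = np.asarray(sample_set, dtype=float)
        labels = np.asarray(list(grouping))
    return labels, d


# ---------------------------------------------------------------------------
# exact test of differentiation (Raymond & Rousset Markov chain)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExactTestResult:
    p: float
    se: float
    steps: int
    dememorization: int


def _log_table_prob(table: np.ndarray) -> float:
    """log multivariate hypergeometric probability of a table given margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def exact_test(table, steps: int = 1_000_000, dememorization: int = 500_000,
               seed=None, n_batches: int = 50) -> ExactTestResult:
    """Exact test of population differentiation on a haplotype-by-group table.

    A Metropolis Markov chain walks over contingency tables with the observed
    margins; the p-value is the chain-estimated probability of tables no more
    probable than the observed one under the hypergeometric null.  The
    standard error comes from batch means over the post-dememorization chain.
    """
    table = np.array(table, dtype=np.int64)
    if table.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    row_ok = table.sum(axis=1) > 0
    col_ok = table.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning("dropping %d empty row(s) and %d empty column(s)",
                       (~row_ok).sum(), (~col_ok).sum())
        table = table[row_ok][:, col_ok]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least two haplotypes and two groups")
    if (table < 0).any():
        raise ValueError("table entries must be nonnegative")

    rng = np.random.default_rng(seed)
    current = table.astype(float).copy()
    log_obs = _log_table_prob(table)
    # running log-prob differs from log_obs only through the x_ij! term
    log_cur = 0.0  # log P(current) - log P(observed)
    r, c = table.shape
    total = steps + dememorization
    hits = np.zeros(n_batches, dtype=np.int64)
    counts = np.zeros(n_batches, dtype=np.int64)
    chunk = 65536
    done = 0
    while done < total:
        m = min(chunk, total - done)
        r1 = rng.integers(0, r, size=m)
        r2 = (r1 + 1 + rng.integers(0, r - 1, size=m)) % r
        c1 = rng.integers(0, c, size=m)
        c2 = (c1 + 1 + rng.integers(0, c - 1, size=m)) % c
        dirs = rng.integers(0, 2, size=m) * 2 - 1
        us = rng.random(size=m)
        for t in range(m):
            i1, i2, j1, j2, dd = r1[t], r2[t], c1[t], c2[t], dirs[t]
            a, b2 = current[i1, j1], current[i2, j2]
            cc, e = current[i1, j2], current[i2, j1]
            if dd == 1:
                if cc < 1 or e < 1:
                    ratio = 0.0
                else:
                    ratio = (cc * e) / ((a + 1.0) * (b2 + 1.0))
            else:
                if a < 1 or b2 < 1:
                    ratio = 0.0
                else:
                    ratio = (a * b2) / ((cc + 1.0) * (e + 1.0))
            if ratio >= 1.0 or us[t] < ratio:
                current[i1, j1] += dd
                current[i2, j2] += dd
                current[i1, j2] -= dd
                current[i2, j1] -= dd
                log_cur += math.log(ratio)
            step = done + t
            if step >= dememorization:
                k = (step - dememorization) * n_batches // steps
                counts[k] += 1
                if log_cur <= 1e-9:
                    hits[k] += 1
        done += m
    batch_p = hits / np.maximum(counts, 1)
    p = hits.sum() / counts.sum()
    se = float(batch_p.std(ddof=1) / math.sqrt(n_batches))
    return ExactTestResult(p=float(p), se=se, steps=steps,
                           dememorization=dememorization)


# ---------------------------------------------------------------------------
# hierarchical AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    df: tuple[int, int, int]
    ssd: tuple[float, float, float]
    variance_components: tuple[float, float, float]
    percent_variation: tuple[float, float, float]
    fct: float
    fsc: float
    fst: float
    p_fct: float = math.nan
    p_fsc: float = math.nan
    p_fst: float = math.nan

    @property
    def total_ssd(self) -> float:
        return sum(self.ssd)

    def to_rows(self):
        names = ("Among groups", "Among populations within groups",
                 "Within populations")
        return list(zip(names, self.df, self.ssd, self.variance_components,
                        self.percent_variation))


def _amova_components(d, pops, groups):
    """Two-level AMOVA variance components from squared distances."""
    n = len(pops)
    pop_ids = list(dict.fromkeys(pops))
    grp_of_pop = {}
    for p, g in zip(pops, groups):
        grp_of_pop[p] = g
    grp_ids = list(dict.fromkeys(grp_of_pop[p] for p in pop_ids))
    P, G = len(pop_ids), len(grp_ids)

    iu = np.triu_indices(n, k=1)
    ssd_total = d[iu].sum() / n

    pop_idx = {p: np.flatnonzero(np.asarray(pops, dtype=object) == p)
               for p in pop_ids}
    pops_arr = np.asarray(pops, dtype=object)
    groups_arr = np.asarray(groups, dtype=object)

    ssd_wp = 0.0
    for p in pop_ids:
        idx = pop_idx[p]
        sub = d[np.ix_(idx, idx)]
        ssd_wp += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)

    ssd_wg = 0.0  # within groups (pops pooled per group)
    grp_sizes = {}
    for g in grp_ids:
        idx = np.flatnonzero(groups_arr == g)
        grp_sizes[g] = len(idx)
        sub = d[np.ix_(idx, idx)]
        ssd_wg += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)

    ssd_ap_wg = ssd_wg - ssd_wp          # among pops within groups
    ssd_ag = ssd_total - ssd_wg          # among groups

    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    sizes = np.array([len(pop_idx[p]) for p in pop_ids], dtype=float)
    grp_of = np.array([grp_of_pop[p] for p in pop_ids], dtype=object)
    Ng = np.array([grp_sizes[g] for g in grp_ids], dtype=float)

    sum_npg = 0.0  # sum over groups of (sum n_p^2 / N_g)
    for gi, g in enumerate(grp_ids):
        ss = sizes[grp_of == g]
        sum_npg += (ss**2).sum() / Ng[gi]
    n_coef = (n - sum_npg) / df_ap if df_ap > 0 else math.nan
    n_prime = (sum_npg - (sizes**2).sum() / n) / df_ag if df_ag > 0 else math.nan
    n_dprime = (n - (Ng**2).sum() / n) / df_ag if df_ag > 0 else math.nan

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    msd_ap = ssd_ap_wg / df_ap if df_ap > 0 else 0.0
    sigma_b = (msd_ap - sigma_c) / n_coef if df_ap > 0 else 0.0
    msd_ag = ssd_ag / df_ag if df_ag > 0 else 0.0
    sigma_a = (msd_ag - sigma_c - n_prime * sigma_b) / n_dprime if df_ag > 0 else 0.0
    return ((df_ag, df_ap, df_wp), (ssd_ag, ssd_ap_wg, ssd_wp),
            (sigma_a, sigma_b, sigma_c))


def _f_stats(sig):
    a, b, c = sig
    tot = a + b + c
    if tot == 0:
        return (0.0, 0.0, 0.0)
    fct = a / tot
    fsc = b / (b + c) if (b + c) != 0 else 0.0
    fst = (a + b) / tot
    return (fct, fsc, fst)


def hierarchical_amova(sample_set, groups=None, pops=None, n_perm: int = 10000,
                       seed=None) -> AmovaResult:
    """Two-level AMOVA: among groups / among populations within groups /
    within populations, with the three standard permutation schemes
    (whole populations across groups for F_CT, individuals across populations
    within groups for F_SC, individuals across everything for F_ST).

    ``groups``/``pops`` default to (period) and (period, region); populations
    with a single sample are excluded with a warning.
    """
    from .samples import SampleSet

    if isinstance(sample_set, SampleSet):
        clean = sample_set.drop_ambiguous()
        if groups is None:
            groups = [r.period for r in clean]
        if pops is None:
            pops = [f"{r.period}:{r.region}" for r in clean]
        d = pairwise_difference_matrix(clean)
    else:
        d = np.asarray(sample_set, dtype=float)
    groups = list(groups)
    pops = list(pops)

    # drop singleton populations
    sizes = {p: pops.count(p) for p in set(pops)}
    keep = [i for i, p in enumerate(pops) if sizes[p] >= 2]
    if len(keep) < len(pops):
        dropped = sorted({p for p in set(pops) if sizes[p] < 2})
        logger.warning("excluding singleton population(s): %s", dropped)
        d = d[np.ix_(keep, keep)]
        groups = [groups[i] for i in keep]
        pops = [pops[i] for i in keep]

    df, ssd, sig = _amova_components(d, pops, groups)
    fct, fsc, fst = _f_stats(sig)
    tot = sum(sig)
    pct = tuple(100.0 * s / tot if tot != 0 else 0.0 for s in sig)

    rng = np.random.default_rng(seed)
    n = len(pops)
    pops_arr = np.asarray(pops, dtype=object)
    groups_arr = np.asarray(groups, dtype=object)
    pop_ids = list(dict.fromkeys(pops))
    grp_of_pop = {p: g for p, g in zip(pops, groups)}

    b_fst = b_fsc = b_fct = 0
    for _ in range(n_perm):
        # F_ST: permute individuals globally
        perm = rng.permutation(n)
        _, _, s = _amova_components(d[np.ix_(perm, perm)], pops, groups)
        if _f_stats(s)[2] >= fst - 1e-12:
            b_fst += 1
        # F_SC: permute individuals among pops within each group
        perm2 = np.arange(n)
        for g in set(groups):
            idx = np.flatnonzero(groups_arr == g)
            perm2[idx] = rng.permutation(idx)
        _, _, s = _amova_components(d[np.ix_(perm2, perm2)], pops, groups)
        if _f_stats(s)[1] >= fsc - 1e-12:
            b_fsc += 1
        # F_CT: permute whole populations among groups
        shuffled = rng.permutation([grp_of_pop[p] for p in pop_ids])
        new_grp_of_pop = dict(zip(pop_ids, shuffled))
        new_groups = [new_grp_of_pop[p] for p in pops]
        _, _, s = _amova_components(d, pops, new_groups)
        if _f_stats(s)[0] >= fct - 1e-12:
            b_fct += 1

    def pv(b):
        return (b + 1) / (n_perm + 1) if n_perm > 0 else math.nan

    return AmovaResult(df=df, ssd=ssd, variance_components=sig,
                       percent_variation=pct, fct=fct, fsc=fsc, fst=fst,
                       p_fct=pv(b_fct), p_fsc=pv(b_fsc), p_fst=pv(b_fst))


# ---------------------------------------------------------------------------
# maximum-composite-likelihood (TN93 pooled-frequency) distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceResult:
    matrix: np.ndarray
    fallback: np.ndarray  # True where the p-distance fallback was used
    labels: list[str] = field(default_factory=list)


def mcl_distance(data) -> DistanceResult:
    """Evolutionary distances accounting for base-frequency inequality and
    transition/transversion asymmetry.

    Implemented as the Tamura–Nei (TN93) distance with base frequencies pooled
    across all sequences (the composite convention).  Pairs where a TN93
    logarithm is undefined (substitutional saturation) fall back to the
    p-distance and are flagged.
    """
    from ._seqarray import AMBIG
    from .diversity import _as_matrix

    mat = _as_matrix(data)
    n, L = mat.shape
    valid = mat != AMBIG
    counts = np.array([(mat[valid] == b).sum() for b in range(4)], dtype=float)
    freqs = counts / counts.sum()
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    # guard empty purine/pyrimidine classes (degenerate base composition)
    k1 = 2.0 * pa * pg / pr if pr > 0 else 0.0
    k2 = 2.0 * pt * pc / py if py > 0 else 0.0
    k3 = 2.0 * (pr * py
                - (pa * pg * py / pr if pr > 0 else 0.0)
                - (pt * pc * pr / py if py > 0 else 0.0))

    D = np.zeros((n, n))
    fb = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        ok = valid[i] & valid[j]
        a, b = mat[i][ok], mat[j][ok]
        m = ok.sum()
        diff = a != b
        ts_ag = (diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))).sum()
        ts_ct = (diff & (((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))).sum()
        q = diff.sum() - ts_ag - ts_ct
        P1, P2, Q = ts_ag / m, ts_ct / m, q / m
        w1 = 1.0 - P1 / k1 - Q / (2.0 * pr) if k1 > 0 else (1.0 if P1 == 0 else 0.0)
        w2 = 1.0 - P2 / k2 - Q / (2.0 * py) if k2 > 0 else (1.0 if P2 == 0 else 0.0)
        w3 = 1.0 - Q / (2.0 * pr * py) if pr * py > 0 else (1.0 if Q == 0 else 0.0)
        if min(w1, w2, w3) <= 0.0:
            d = diff.sum() / m
            fb[i, j] = fb[j, i] = True
            logger.warning("TN93 saturation for pair (%d, %d); p-distance used",
                           i, j)
        else:
            d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
        D[i, j] = D[j, i] = d
    return DistanceResult(matrix=D, fallback=fb)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n: int


def geographic_distance_matrix(latitudes, longitudes, log10: bool = True,
                               floor_km: float = 1.0) -> np.ndarray:
    """Great-circle (haversine) distances in km, optionally log10-transformed.

    Pairs closer than ``floor_km`` are floored before the log so identical
    sampling locations stay finite.
    """
    lat = np.radians(np.asarray(latitudes, dtype=float))
    lon = np.radians(np.asarray(longitudes, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (np.sin(dlat / 2.0) ** 2
         + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2.0) ** 2)
    km = 2.0 * 6371.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if log10:
        km = np.log10(np.maximum(km, floor_km))
        np.fill_diagonal(km, 0.0)
    return km


def mantel_test(genetic_dist, geo_dist, n_perm: int = 10000, seed=None,
                exact: bool = False) -> MantelResult:
    """Mantel correlation between two distance matrices with a permutation
    (or exhaustive, for small n) test.  The p-value is the one-sided
    probability of a correlation at least as large under simultaneous
    row/column permutation of one matrix."""
    x = np.asarray(genetic_dist, dtype=float)
    y = np.asarray(geo_dist, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("matrices must be square and same shape")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need n >= 4")
    iu = np.triu_indices(n, k=1)
    xv = x[iu]
    if xv.std() == 0 or y[iu].std() == 0:
        return MantelResult(r=math.nan, p=math.nan, n=n)

    def corr(perm):
        yv = y[np.ix_(perm, perm)][iu]
        return float(np.corrcoef(xv, yv)[0, 1])

    obs = corr(np.arange(n))
    if exact:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if corr(np.asarray(perm)) >= obs - 1e-12:
                hits += 1
        return MantelResult(r=obs, p=hits / total, n=n)
    rng = np.random.default_rng(seed)
    b = sum(corr(rng.permutation(n)) >= obs - 1e-12 for _ in range(n_perm))
    return MantelResult(r=obs, p=(b + 1) / (n_perm + 1), n=n)
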