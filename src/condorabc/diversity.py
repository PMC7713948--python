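"""Per-stratum molecular diversity statistics for aligned haplotype data.

Estimators follow the DnaSP conventions: unbiased haplotype diversity
H = n(1 - sum p_i^2)/(n - 1) with Nei's (1987) sampling variance, the mean
number of pairwise nucleotide differences K with Tajima's (1983)
no-recombination total variance, nucleotide diversity pi = K / L, the count
of segregating sites S, and Tajima's D.  n = 1 strata and other undefined
cases are returned as NaN rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seqarray import AMBIG, encode
from .samples import CONTEMPORARY, HISTORICAL, SampleSet, collapse_haplotypes


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SampleSet):
        return data.drop_ambiguous().matrix()
    if isinstance(data, np.ndarray):
        return np.asarray(data, dtype=np.uint8)
    return encode(list(data))


def haplotype_diversity(counts) -> tuple[float, float]:
    """Unbiased haplotype (gene) diversity and its standard deviation.

    ``counts`` are per-haplotype sample counts.  H equals the probability that
    two sequences drawn without replacement are different haplotypes.  Returns
    (nan, nan) for a single sequence.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0 or (counts < 1).any():
        raise ValueError("counts must be nonempty positive integers")
    n = counts.sum()
    if n < 2:
        return (math.nan, math.nan)
    p = counts / n
    sum2 = float((p**2).sum())
    sum3 = float((p**3).sum())
    h = n * (1.0 - sum2) / (n - 1.0)
    # Nei (1987) eq. 8.12 sampling variance of heterozygosity
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    return (h, math.sqrt(max(var, 0.0)))


def pairwise_difference_matrix(data) -> np.ndarray:
    """Hamming distance matrix (counts of differing sites) between sequences."""
    mat = _as_matrix(data)
    # compare via broadcasting; alignments here are short so n^2 L is cheap
    diff = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    return diff.astype(float)


def mean_pairwise_differences(data) -> tuple[float, float]:
    """Mean number of nucleotide differences K over all unordered pairs, with
    Tajima's (1983) total (no recombination) variance."""
    mat = _as_matrix(data)
    n = mat.shape[0]
    if n < 2:
        return (math.nan, math.nan)
    d = pairwise_difference_matrix(mat)
    iu = np.triu_indices(n, k=1)
    k = float(d[iu].mean())
    var = _tajima_k_variance(n, k)
    return (k, var)


def _tajima_k_variance(n: int, k: float) -> float:
    # total (stochastic + sampling) variance without recombination
    return ((n + 1.0) / (3.0 * (n - 1.0)) * k
            + 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0)) * k**2)


def nucleotide_diversity(data, length: int | None = None) -> tuple[float, float]:
    """Nucleotide diversity pi = K / L per site, with sd = sd(K)/L."""
    mat = _as_matrix(data)
    L = length if length is not None else mat.shape[1]
    k, var = mean_pairwise_differences(mat)
    if math.isnan(k):
        return (math.nan, math.nan)
    return (k / L, math.sqrt(var) / L if not math.isnan(var) else math.nan)


def segregating_sites(data) -> int:
    """Number of polymorphic alignment columns (ambiguity codes ignored)."""
    mat = _as_matrix(data)
    if mat.shape[0] == 0:
        return 0
    poly = 0
    for col in mat.T:
        obs = np.unique(col[col != AMBIG])
        if obs.size > 1:
            poly += 1
    return poly


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d(data) -> float:
    """Tajima's D; NaN when there is no segregating site or n < 4."""
    mat = _as_matrix(data)
    n = mat.shape[0]
    if n < 4:
        return math.nan
    s = segregating_sites(mat)
    if s == 0:
        return math.nan
    k, _ = mean_pairwise_differences(mat)
    c = _tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1.0)
    return (k - s / c["a1"]) / math.sqrt(var)


@dataclass(frozen=True)
class DiversityStats:
    """One row of a diversity summary table."""

    label: str
    n: int
    n_H: int
    pi: float
    pi_sd: float
    H: float
    H_sd: float
    K: float
    K_var: float
    S: int
    D: float


def stratum_stats(sample_set: SampleSet, label: str) -> DiversityStats:
    clean = sample_set.drop_ambiguous()
    mat = clean.matrix()
    table = collapse_haplotypes(clean)
    hap_counts = list(table.haplotype_counts().values())
    n = len(clean)
    if n >= 2:
        h, h_sd = haplotype_diversity(hap_counts)
        k, k_var = mean_pairwise_differences(mat)
        pi, pi_sd = nucleotide_diversity(mat)
    else:
        h = h_sd = k = k_var = pi = pi_sd = math.nan
    return DiversityStats(
        label=label, n=n, n_H=table.n_H, pi=pi, pi_sd=pi_sd, H=h, H_sd=h_sd,
        K=k, K_var=k_var, S=segregating_sites(mat), D=tajimas_d(mat),
    )


def diversity_table(sample_set: SampleSet, by: str = "period") -> pd.DataFrame:
    """Diversity summary stratified by ``period``, ``region`` or overall.

    Always appends an Overall row.  Reported rounding follows the field's
    reporting convention: 4 decimals for pi, 3 for H and K.
    """
    rows: list[DiversityStats] = []
    if by == "period":
        for period in (HISTORICAL, CONTEMPORARY):
            sub = sample_set.by_period(period)
            if len(sub):
                rows.append(stratum_stats(sub, period.capitalize()))
    elif by == "region":
        seen = []
        for r in sample_set.records:
            if r.region not in seen:
                seen.append(r.region)
        for region in seen:
            sub = sample_set.subset(lambda r: r.region == region)
            rows.append(stratum_stats(sub, region))
    elif by != "overall":
        raise ValueError(f"unknown stratification {by!r}")
    rows.append(stratum_stats(sample_set, "Overall"))
    frame = pd.DataFrame(
        {
            "stratum": [r.label for r in rows],
            "n": [r.n for r in rows],
            "n_H": [r.n_H for r in rows],
            "pi": [round(r.pi, 4) for r in rows],
            "pi_sd": [round(r.pi_sd, 4) for r in rows],
            "H": [round(r.H, 3) for r in rows],
            "H_sd": [round(r.H_sd, 3) for r in rows],
            "K": [round(r.K, 3) for r in rows],
            "K_var": [round(r.K_var, 3) for r in rows],
            "S": [r.S for r in rows],
            "D": [round(r.D, 3) if not math.isnan(r.D) else math.nan for r in rows],
        }
    )
    return frame
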