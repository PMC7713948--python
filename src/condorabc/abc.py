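"""Approximate Bayesian computation over the demographic scenarios.

The engine follows the classic rejection + regression recipe: draw parameters
from (conditioned) uniform priors, simulate heterochronous datasets with
:mod:`condorabc.coalsim`, reduce each to a fixed vector of summary statistics,
keep the simulations closest to the observed vector (1% by default), choose
among scenarios with a polychotomous logistic regression of the scenario
label on summary-statistic deviations, and estimate parameters with
Beaumont-style local-linear adjustment under an Epanechnikov kernel.
Confidence in the selection is quantified with type I/II error rates over
pseudo-observed datasets (pods), and fit with posterior-predictive checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .coalsim import (DEFAULT_GENERATION_TIME, MutationModel, SamplingDesign,
                      ScenarioParams, condor_design, condor_mutation_model,
                      simulate_matrix)
from .diversity import _tajima_constants
from .samples import CONTEMPORARY, HISTORICAL, SampleSet

logger = logging.getLogger(__name__)

PARAM_NAMES = ("nef1", "nef2", "nef3", "nef4", "t1", "te", "t2")

#: which parameters each scenario actually uses
SCENARIO_PARAMS = {
    1: ("nef1",),
    2: ("nef1", "nef2", "t1"),
    3: ("nef1", "nef3", "t2"),
    4: ("nef1", "nef2", "nef4", "t1", "te", "t2"),
}


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Uniform prior bounds (years for times, individuals for sizes) plus the
    conditioning inherited from the scenario definitions: Nef2 > Nef1,
    Nef3 < Nef1, Nef4 < Nef2 and t1 < te < t2."""

    nef1: tuple[float, float] = (50.0, 1000.0)
    nef2: tuple[float, float] = (500.0, 50000.0)
    nef3: tuple[float, float] = (2.0, 1000.0)
    nef4: tuple[float, float] = (2.0, 50000.0)
    t1: tuple[float, float] = (7.0, 350.0)
    te: tuple[float, float] = (7.0, 50000.0)
    t2: tuple[float, float] = (1000.0, 500000.0)
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self):
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"prior {name}: lower bound must be < upper")

    def bounds(self, name: str) -> tuple[float, float]:
        return getattr(self, name)


#: regional presets for the recent female effective size
NORTH_PRIOR = PriorConfig(nef1=(50.0, 1000.0))
CENTRAL_SOUTH_PRIOR = PriorConfig(nef1=(500.0, 5000.0))
CALIFORNIA_PRIOR = PriorConfig(nef1=(10.0, 500.0))


def _conditioning_ok(scenario_id: int, draws: dict[str, np.ndarray]) -> np.ndarray:
    ok = np.ones(len(draws["nef1"]), dtype=bool)
    if scenario_id == 2:
        ok &= draws["nef2"] > draws["nef1"]
    elif scenario_id == 3:
        ok &= draws["nef3"] < draws["nef1"]
    elif scenario_id == 4:
        ok &= draws["nef2"] > draws["nef1"]
        ok &= draws["nef4"] < draws["nef2"]
        ok &= (draws["t1"] < draws["te"]) & (draws["te"] < draws["t2"])
    return ok


def draw_priors(scenario_id: int, prior: PriorConfig, n: int,
                rng) -> pd.DataFrame:
    """Draw ``n`` conditioned prior parameter vectors (rejection resampling).

    Raises when the conditioning acceptance rate falls below 1e-4."""
    rng = np.random.default_rng(rng)
    used = SCENARIO_PARAMS[scenario_id]
    out = {name: np.empty(n) for name in used}
    filled = 0
    attempts = 0
    while filled < n:
        m = max(n - filled, 256)
        draws = {}
        for name in used:
            lo, hi = prior.bounds(name)
            draws[name] = rng.uniform(lo, hi, size=m)
        ok = _conditioning_ok(scenario_id, draws)
        attempts += m
        take = min(int(ok.sum()), n - filled)
        for name in used:
            out[name][filled:filled + take] = draws[name][ok][:take]
        filled += take
        if attempts > 1e4 and filled / attempts < 1e-4:
            raise ValueError(
                f"scenario {scenario_id} conditioning acceptance rate < 1e-4; "
                "prior bounds are incompatible with the conditioning")
    frame = pd.DataFrame({name: out.get(name, np.full(n, np.nan))
                          for name in PARAM_NAMES})
    frame.insert(0, "scenario", scenario_id)
    return frame


def draw_prior(scenario_id: int, prior: PriorConfig, rng) -> ScenarioParams:
    """One conditioned prior draw as a ScenarioParams."""
    row = draw_priors(scenario_id, prior, 1, rng).iloc[0]
    return params_from_row(row, prior.generation_time)


def params_from_row(row, generation_time: float = DEFAULT_GENERATION_TIME
                    ) -> ScenarioParams:
    return ScenarioParams(
        scenario_id=int(row["scenario"]), nef1=row["nef1"], nef2=row["nef2"],
        nef3=row["nef3"], nef4=row["nef4"], t1=row["t1"], te=row["te"],
        t2=row["t2"], generation_time=generation_time,
    )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

STAT_NAMES = tuple(
    [f"{s}_{g}" for g in ("hist", "cont")
     for s in ("n_hap", "seg_sites", "mean_pw", "var_pw", "hap_div",
               "tajima_d", "tajima_d_defined")]
    + ["fst_hudson", "mean_pw_between", "private_s_hist", "private_s_cont"]
)


def _within_stats(hmat, counts, dmat):
    n = counts.sum()
    present = counts > 0
    n_hap = int(present.sum())
    p = counts / n
    hap_div = n * (1.0 - (p**2).sum()) / (n - 1.0) if n > 1 else 0.0
    w = np.outer(counts, counts).astype(float)
    np.fill_diagonal(w, counts * (counts - 1.0))
    npairs = n * (n - 1.0) / 2.0
    sum_d = (w * dmat).sum() / 2.0
    sum_d2 = (w * dmat**2).sum() / 2.0
    k = sum_d / npairs if npairs > 0 else 0.0
    var = max(sum_d2 / npairs - k**2, 0.0) if npairs > 0 else 0.0
    sub = hmat[present]
    seg = ~np.all(sub == sub[0], axis=0)
    s = int(seg.sum())
    if n >= 4 and s >= 1:
        c = _tajima_constants(int(n))
        denom = math.sqrt(c["e1"] * s + c["e2"] * s * (s - 1.0))
        d = (k - s / c["a1"]) / denom if denom > 0 else 0.0
        d_def = 1.0
    else:
        d, d_def = 0.0, 0.0
    return (n_hap, s, k, var, hap_div, d, d_def), seg


def summarize_matrix(matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Summary-statistic vector from an alignment and binary temporal labels
    (0 = historical pulse, 1 = contemporary pulse)."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    labels = np.asarray(labels)
    groups = [matrix[labels == g] for g in (0, 1)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each temporal sample needs >= 2 sequences")
    hmat, inverse = np.unique(matrix, axis=0, return_inverse=True)
    u = hmat.shape[0]
    dmat = (hmat[:, None, :] != hmat[None, :, :]).sum(axis=2).astype(float)
    counts = np.zeros((2, u))
    for g in (0, 1):
        idx, c = np.unique(inverse[labels == g], return_counts=True)
        counts[g, idx] = c
    per_group = []
    segs = []
    for g in (0, 1):
        stats, seg = _within_stats(hmat, counts[g], dmat)
        per_group.append(stats)
        segs.append(seg)
    n0, n1 = counts[0].sum(), counts[1].sum()
    k_between = counts[0] @ dmat @ counts[1] / (n0 * n1)
    kw = 0.5 * (per_group[0][2] + per_group[1][2])
    fst = 1.0 - kw / k_between if k_between > 0 else 0.0
    priv0 = int((segs[0] & ~segs[1]).sum())
    priv1 = int((segs[1] & ~segs[0]).sum())
    return np.array(list(per_group[0]) + list(per_group[1])
                    + [fst, k_between, priv0, priv1])


def summarize(sample_set: SampleSet) -> np.ndarray:
    """Summary statistics of an observed dataset split into its historical
    and contemporary strata (same ordering as simulated tables)."""
    clean = sample_set.drop_ambiguous()
    labels = np.array([0 if r.period == HISTORICAL else 1 for r in clean])
    for g, name in ((0, HISTORICAL), (1, CONTEMPORARY)):
        if (labels == g).sum() < 2:
            raise ValueError(f"missing or too small {name} stratum")
    return summarize_matrix(clean.matrix(), labels)


# ---------------------------------------------------------------------------
# reference tables and rejection
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    scenario_id: int
    params: pd.DataFrame
    stats: np.ndarray
    stat_names: tuple[str, ...] = STAT_NAMES


def reference_table(scenario_id: int, prior: PriorConfig, n_sims: int,
                    model: MutationModel | None = None,
                    design: SamplingDesign | None = None,
                    seed=None) -> ReferenceTable:
    """Simulate ``n_sims`` datasets under the scenario's prior and summarize
    each; the backbone of every ABC computation."""
    model = model or condor_mutation_model()
    design = design or condor_design()
    rng = np.random.default_rng(seed)
    params = draw_priors(scenario_id, prior, n_sims, rng)
    g = prior.generation_time
    labels_hist = np.array([p.years_before_present > 0 for p in design.pulses])
    stats = np.empty((n_sims, len(STAT_NAMES)))
    for i in range(n_sims):
        sp = params_from_row(params.iloc[i], g)
        mat, tip_pulse = simulate_matrix(sp, model, design,
                                         seed=rng.integers(2**31))
        labels = (~labels_hist[tip_pulse]).astype(int)
        stats[i] = summarize_matrix(mat, labels)
    return ReferenceTable(scenario_id=scenario_id, params=params, stats=stats)


def _robust_scale(stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(scale, keep_mask): median absolute deviation per statistic, falling
    back to the standard deviation, dropping constants."""
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    sd = stats.std(axis=0)
    scale = np.where(mad > 0, mad, sd)
    keep = scale > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance statistic(s) from distance",
                       int((~keep).sum()))
    return scale, keep


def rejection(stats: np.ndarray, observed: np.ndarray,
              tolerance: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the ceil(tolerance * N) simulations closest to the observed
    vector in MAD-standardized Euclidean distance, plus all N distances."""
    stats = np.asarray(stats, dtype=float)
    n = stats.shape[0]
    if n < 100:
        raise ValueError("need at least 100 simulations")
    scale, keep = _robust_scale(stats)
    z = (stats[:, keep] - observed[keep]) / scale[keep]
    dist = np.sqrt((z**2).sum(axis=1))
    n_keep = int(math.ceil(tolerance * n))
    order = np.argsort(dist, kind="stable")
    return order[:n_keep], dist


# ---------------------------------------------------------------------------
# scenario choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    scenarios: tuple[int, ...]
    probabilities: dict[int, float]
    ci: dict[int, tuple[float, float]]
    method: str
    tolerance: float
    n_accepted: int

    @property
    def best(self) -> int:
        return max(self.probabilities, key=self.probabilities.get)

    @property
    def decisive(self) -> bool:
        """True when the best scenario's CI does not overlap any other's."""
        lo = self.ci[self.best][0]
        return all(lo > hi for k, (_, hi) in self.ci.items() if k != self.best)


def model_choice(tables: dict[int, ReferenceTable] | list[ReferenceTable],
                 observed: np.ndarray, tolerance: float = 0.01,
                 method: str = "logistic", n_boot: int = 500,
                 seed=None) -> ModelChoiceResult:
    """Posterior probability of each scenario.

    All simulations are pooled, the closest fraction kept, and (for the
    logistic method) a polychotomous logistic regression of the scenario
    label on standardized statistic deviations is evaluated at deviation
    zero.  The direct method reports acceptance fractions.  Confidence
    intervals come from a nonparametric bootstrap over accepted simulations.
    """
    if isinstance(tables, dict):
        tables = list(tables.values())
    if len(tables) < 2:
        raise ValueError("need at least two scenarios")
    scen = tuple(t.scenario_id for t in tables)
    stats = np.vstack([t.stats for t in tables])
    label = np.concatenate([np.full(len(t.stats), t.scenario_id)
                            for t in tables])
    idx, _ = rejection(stats, observed, tolerance)
    acc_stats, acc_label = stats[idx], label[idx]
    scale, keep = _robust_scale(stats)
    dev = (acc_stats[:, keep] - observed[keep]) / scale[keep]
    rng = np.random.default_rng(seed)

    def estimate(x, y):
        if method == "direct":
            return {k: float((y == k).mean()) for k in scen}
        present = np.unique(y)
        if len(present) < 2:
            return {k: float(k in present) for k in scen}
        try:
            clf = LogisticRegression(max_iter=2000, C=10.0)
            clf.fit(x, y)
            pr = clf.predict_proba(np.zeros((1, x.shape[1])))[0]
            out = {int(c): float(p) for c, p in zip(clf.classes_, pr)}
            return {k: out.get(k, 0.0) for k in scen}
        except Exception:  # pragma: no cover - degenerate fits
            logger.warning("logistic fit failed; falling back to direct")
            return {k: float((y == k).mean()) for k in scen}

    probs = estimate(dev, acc_label)
    ci = {k: (math.nan, math.nan) for k in scen}
    if n_boot > 0:
        boot = {k: [] for k in scen}
        n_acc = len(idx)
        for _ in range(n_boot):
            take = rng.integers(0, n_acc, size=n_acc)
            for k, v in estimate(dev[take], acc_label[take]).items():
                boot[k].append(v)
        ci = {k: (float(np.quantile(boot[k], 0.025)),
                  float(np.quantile(boot[k], 0.975))) for k in scen}
    return ModelChoiceResult(scenarios=scen, probabilities=probs, ci=ci,
                             method=method, tolerance=tolerance,
                             n_accepted=len(idx))


# ---------------------------------------------------------------------------
# posterior estimation (local-linear adjustment)
# ---------------------------------------------------------------------------

def _logit(x, lo, hi, eps=1e-9):
    p = np.clip((x - lo) / (hi - lo), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def _expit(z, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-z))


@dataclass
class PosteriorSample:
    """Regression-adjusted posterior draws with Epanechnikov weights."""

    samples: pd.DataFrame
    weights: np.ndarray
    parameters: tuple[str, ...]

    def quantile(self, name: str, q) -> np.ndarray:
        x = self.samples[name].to_numpy()
        order = np.argsort(x)
        cw = np.cumsum(self.weights[order])
        cw /= cw[-1]
        return np.interp(np.atleast_1d(q), cw, x[order])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.parameters:
            q = self.quantile(name, [0.025, 0.25, 0.5, 0.75, 0.975])
            rows.append({"parameter": name, "q2.5": q[0], "q25": q[1],
                         "median": q[2], "q75": q[3], "q97.5": q[4]})
        return pd.DataFrame(rows)


def adjust_posterior(table: ReferenceTable, observed: np.ndarray,
                     prior: PriorConfig, tolerance: float = 0.01,
                     ridge: float = 1e-8) -> PosteriorSample:
    """Beaumont-style local-linear posterior adjustment.

    Accepted parameter draws are logit-transformed to their prior bounds,
    regressed on standardized statistic deviations with Epanechnikov weights
    on acceptance distance, shifted to deviation zero, and back-transformed.
    A small ridge keeps the weighted normal equations solvable when
    statistics are collinear.
    """
    idx, dist = rejection(table.stats, observed, tolerance)
    scale, keep = _robust_scale(table.stats)
    if len(idx) < 5 * (int(keep.sum()) + 1):
        logger.warning(
            "only %d accepted draws for a regression on %d statistics; "
            "the local-linear adjustment may overfit - raise the tolerance "
            "or the table size", len(idx), int(keep.sum()))
    dev = (table.stats[idx][:, keep] - observed[keep]) / scale[keep]
    h = dist[idx].max()
    if h == 0:
        w = np.ones(len(idx))
    else:
        w = np.maximum(1.0 - (dist[idx] / h)**2, 0.0)
        w[w == 0] = (1.0 / len(idx))**2  # keep the boundary point in play
    names = SCENARIO_PARAMS[table.scenario_id]
    X = np.hstack([np.ones((len(idx), 1)), dev])
    wsqrt = np.sqrt(w)
    adj = {}
    for name in names:
        lo, hi = prior.bounds(name)
        z = _logit(table.params[name].to_numpy()[idx], lo, hi)
        A = X * wsqrt[:, None]
        b = z * wsqrt
        gram = A.T @ A + ridge * np.eye(A.shape[1])
        beta = np.linalg.solve(gram, A.T @ b)
        z_adj = z - dev @ beta[1:]
        adj[name] = _expit(z_adj, lo, hi)
    return PosteriorSample(samples=pd.DataFrame(adj), weights=w,
                           parameters=tuple(names))


# ---------------------------------------------------------------------------
# prior-predictive PCA check
# ---------------------------------------------------------------------------

@dataclass
class PcaReport:
    coordinates: np.ndarray
    outlier_score: float
    explained_variance_ratio: np.ndarray


def prior_predictive_pca(stats: np.ndarray, observed: np.ndarray,
                         n_components: int = 2) -> PcaReport:
    """Project the observed statistics into the PCA space of the simulated
    ones; the outlier score is the fraction of simulations farther from the
    centroid than the observed point (1 = dead centre, 0 = far outside)."""
    from sklearn.decomposition import PCA

    stats = np.asarray(stats, dtype=float)
    if stats.shape[0] < 50 or stats.shape[1] < 2:
        raise ValueError("need >= 50 simulations and >= 2 statistics")
    sd = stats.std(axis=0)
    keep = sd > 0
    z = (stats[:, keep] - stats[:, keep].mean(axis=0)) / sd[keep]
    zo = (observed[keep] - stats[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=min(n_components, z.shape[1]))
    proj = pca.fit_transform(z)
    obs_proj = pca.transform(zo[None, :])[0]
    d_sims = np.linalg.norm(proj, axis=1)
    d_obs = float(np.linalg.norm(obs_proj))
    return PcaReport(coordinates=obs_proj,
                     outlier_score=float((d_sims >= d_obs).mean()),
                     explained_variance_ratio=pca.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# confidence: type I / II errors over pods
# ---------------------------------------------------------------------------

@dataclass
class ConfusionResult:
    scenarios: tuple[int, ...]
    counts: pd.DataFrame       # rows: true scenario, cols: selected scenario
    type_i: dict[int, float]
    type_ii: dict[int, float]


def confusion_errors(prior: PriorConfig, scenarios=(1, 2, 3, 4),
                     n_pods: int = 100, sims_per_scenario: int = 10000,
                     model: MutationModel | None = None,
                     design: SamplingDesign | None = None,
                     tolerance: float = 0.01, method: str = "logistic",
                     seed=None,
                     tables: dict[int, ReferenceTable] | None = None
                     ) -> ConfusionResult:
    """Scenario-selection error rates estimated on pseudo-observed datasets.

    type I(k) = fraction of scenario-k pods not selecting k;
    type II(k) = fraction of other-scenario pods selecting k.
    Reference tables may be passed in to amortize simulation cost.
    """
    model = model or condor_mutation_model()
    design = design or condor_design()
    rng = np.random.default_rng(seed)
    if tables is None:
        tables = {s: reference_table(s, prior, sims_per_scenario, model,
                                     design, seed=rng.integers(2**31))
                  for s in scenarios}
    counts = pd.DataFrame(0, index=list(scenarios), columns=list(scenarios))
    labels_hist = np.array([p.years_before_present > 0 for p in design.pulses])
    for true_s in scenarios:
        pods = draw_priors(true_s, prior, n_pods, rng)
        for i in range(n_pods):
            sp = params_from_row(pods.iloc[i], prior.generation_time)
            mat, tip_pulse = simulate_matrix(sp, model, design,
                                             seed=rng.integers(2**31))
            obs = summarize_matrix(mat, (~labels_hist[tip_pulse]).astype(int))
            res = model_choice(tables, obs, tolerance, method=method,
                               n_boot=0)
            counts.loc[true_s, res.best] += 1
    type_i = {s: 1.0 - counts.loc[s, s] / n_pods for s in scenarios}
    type_ii = {}
    for s in scenarios:
        others = [t for t in scenarios if t != s]
        wrong = sum(counts.loc[t, s] for t in others)
        type_ii[s] = wrong / (n_pods * len(others))
    return ConfusionResult(scenarios=tuple(scenarios), counts=counts,
                           type_i=type_i, type_ii=type_ii)


# ---------------------------------------------------------------------------
# posterior-predictive model checking
# ---------------------------------------------------------------------------

def posterior_model_check(posterior: PosteriorSample, scenario_id: int,
                          observed: np.ndarray,
                          model: MutationModel | None = None,
                          design: SamplingDesign | None = None,
                          generation_time: float = DEFAULT_GENERATION_TIME,
                          n_rep: int = 200, seed=None) -> pd.DataFrame:
    """Posterior-predictive p-values per summary statistic.

    Parameters are resampled from the adjusted posterior (weighted), new
    datasets simulated, and a two-sided tail probability reported for every
    statistic: p = 2 min(P(rep <= obs), P(rep >= obs)), capped at 1."""
    model = model or condor_mutation_model()
    design = design or condor_design()
    rng = np.random.default_rng(seed)
    w = posterior.weights / posterior.weights.sum()
    labels_hist = np.array([p.years_before_present > 0 for p in design.pulses])
    reps = np.empty((n_rep, len(STAT_NAMES)))
    for i in range(n_rep):
        row = posterior.samples.iloc[rng.choice(len(w), p=w)]
        full = {name: row.get(name, math.nan) for name in PARAM_NAMES}
        full["scenario"] = scenario_id
        sp = params_from_row(pd.Series(full), generation_time)
        mat, tip_pulse = simulate_matrix(sp, model, design,
                                         seed=rng.integers(2**31))
        reps[i] = summarize_matrix(mat, (~labels_hist[tip_pulse]).astype(int))
    rows = []
    for j, name in enumerate(STAT_NAMES):
        lo = ((reps[:, j] <= observed[j]).sum() + 1) / (n_rep + 1)
        hi = ((reps[:, j] >= observed[j]).sum() + 1) / (n_rep + 1)
        rows.append({"statistic": name, "observed": observed[j],
                     "predictive_mean": reps[:, j].mean(),
                     "p_two_sided": min(1.0, 2.0 * min(lo, hi))})
    return pd.DataFrame(rows)
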