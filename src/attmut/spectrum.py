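"""Mutation-spectrum statistics.

The central model: given per-round counts (k transitions out of n new SNPs),
each data point is binomial with a shared transition probability p_ti, and
the likelihood of p_ti is the product over data points

    L(p_ti) = prod_i C(n_i, k_i) p_ti^k_i (1 - p_ti)^(n_i - k_i)

whose maximiser has the closed form p̂ = Σk / Σn (only the pooled counts
matter). The transition probability maps to the familiar ts/tv ratio by
R = p/(1-p). The module also provides the index-of-dispersion test for
over-dispersion of per-round mutation counts relative to a Poisson law
(parametric bootstrap), a per-lineage χ² test of transition bias against a
literature null, and the OLS regression of ts/tv ratio on per-round
mutation load.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .errors import FitError, ParameterError


@dataclass(frozen=True)
class RoundCounts:
    """Transition count k out of n total SNPs for one lineage × round."""

    lineage_id: str
    round: int
    k: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ParameterError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")


@dataclass(frozen=True)
class TransitionModel:
    """A transition probability p_ti in [0, 1]."""

    p_ti: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_ti <= 1.0:
            raise ParameterError("p_ti must be in [0, 1]")


@dataclass(frozen=True)
class LikelihoodCurve:
    """Likelihood over a p_ti grid, normalised so the maximum equals 1."""

    p_grid: np.ndarray
    likelihood: np.ndarray


@dataclass(frozen=True)
class DispersionResult:
    mean: float
    variance: float
    index: float
    p_value: float
    n_boot: int


@dataclass(frozen=True)
class ChisqResult:
    chi2: float
    df: int
    p_value: float
    n_lineages: int


@dataclass(frozen=True)
class OlsResult:
    slope: float
    intercept: float
    f_stat: float
    df: int
    p_value: float
    r2: float


def _extract_kn(data) -> tuple[np.ndarray, np.ndarray]:
    """Accept RoundCounts lists, (k, n) tuples or a k/n DataFrame."""
    if isinstance(data, pd.DataFrame):
        return data["k"].to_numpy(float), data["n"].to_numpy(float)
    ks, ns = [], []
    for item in data:
        if hasattr(item, "k"):
            ks.append(item.k)
            ns.append(item.n)
        else:
            k, n = item
            ks.append(k)
            ns.append(n)
    k_arr, n_arr = np.asarray(ks, float), np.asarray(ns, float)
    if np.any(k_arr < 0) or np.any(k_arr > n_arr):
        raise ParameterError("counts must satisfy 0 <= k <= n")
    return k_arr, n_arr


def binom_log_likelihood(model: TransitionModel | float, data) -> float:
    """Summed binomial log-likelihood of the data under one p_ti.

    Uses the conventions 0·log 0 = 0; an impossible datum (e.g. k < n at
    p = 1) yields -inf.
    """
    p = model.p_ti if isinstance(model, TransitionModel) else float(model)
    if not 0.0 <= p <= 1.0:
        raise ParameterError("p_ti must be in [0, 1]")
    k, n = _extract_kn(data)
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_k = np.where(k > 0, k * np.log(p), 0.0)
        term_nk = np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
    return float(np.sum(const + term_k + term_nk))


def mle_transition_freq(
    data, grid_size: int = 2001
) -> tuple[float, LikelihoodCurve]:
    """Maximum-likelihood transition probability with its likelihood curve.

    The MLE is the pooled fraction Σk/Σn; the curve is the likelihood on an
    even grid over [0, 1] (with p̂ inserted), normalised by its maximum so
    the curve value at p̂ equals 1.
    """
    k, n = _extract_kn(data)
    total_n = n.sum()
    if total_n <= 0:
        raise FitError("cannot estimate transition frequency from n = 0")
    p_hat = float(k.sum() / total_n)

    grid = np.union1d(np.linspace(0.0, 1.0, grid_size), [p_hat])
    loglik = np.array([binom_log_likelihood(p, list(zip(k, n))) for p in grid])
    finite = np.isfinite(loglik)
    peak = loglik[finite].max()
    norm = np.zeros_like(loglik)
    norm[finite] = np.exp(loglik[finite] - peak)
    return p_hat, LikelihoodCurve(p_grid=grid, likelihood=norm)


def ratio_from_freq(p: float) -> float:
    """ts/tv ratio R = p/(1-p); p = 1 maps to +inf."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError("p must be in [0, 1]")
    if p == 1.0:
        return math.inf
    return p / (1.0 - p)


def freq_from_ratio(ratio: float) -> float:
    """Transition probability p = R/(1+R); R = +inf maps to 1."""
    if ratio < 0:
        raise ParameterError("ts/tv ratio must be non-negative")
    if math.isinf(ratio):
        return 1.0
    return ratio / (1.0 + ratio)


def dispersion_test(
    counts: Sequence[int], n_boot: int = 10_000, seed=None
) -> DispersionResult:
    """Index-of-dispersion test against a Poisson null.

    The index is sample variance (n-1 denominator) over sample mean; the
    p-value is the parametric-bootstrap upper-tail probability of an index
    at least as large under Poisson(mean) samples of the same size.
    """
    x = np.asarray(counts, float)
    if x.size < 2:
        raise ParameterError("need at least 2 rounds of counts")
    if n_boot < 1000:
        raise ParameterError("n_boot must be at least 1000")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if mean == 0.0:
        return DispersionResult(mean=0.0, variance=var, index=0.0, p_value=1.0, n_boot=n_boot)
    index = var / mean

    rng = np.random.default_rng(seed)
    sims = rng.poisson(mean, size=(n_boot, x.size))
    sim_means = sims.mean(axis=1)
    sim_vars = sims.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim_idx = np.where(sim_means > 0, sim_vars / sim_means, 0.0)
    p = (1 + int(np.sum(sim_idx >= index))) / (n_boot + 1)
    return DispersionResult(mean=mean, variance=var, index=index, p_value=p, n_boot=n_boot)


def transition_bias_chisq(counts, null_p: float = 0.70) -> ChisqResult:
    """Per-lineage χ² goodness of fit of transition counts against null_p.

    ``counts`` is one (k, n) per lineage, or RoundCounts rows (summed per
    lineage). Each lineage contributes a 2-cell goodness-of-fit term; the
    statistic is the sum and df = n_lineages - 1 (df = 1 for a single
    lineage). Lineages with n = 0 are excluded with a warning. The null
    defaults to p = 0.70 (ts/tv ≈ 2.33, a typical wild-type spectrum).
    """
    if not 0.0 < null_p < 1.0:
        raise ParameterError("null_p must be in (0, 1)")
    per_lineage: dict[str, list[float]] = {}
    if isinstance(counts, pd.DataFrame) or (
        counts and hasattr(next(iter(counts)), "lineage_id")
    ):
        if isinstance(counts, pd.DataFrame):
            it = (
                (r.lineage_id, r.k, r.n) for r in counts.itertuples(index=False)
            )
        else:
            it = ((c.lineage_id, c.k, c.n) for c in counts)
        for lid, k, n in it:
            acc = per_lineage.setdefault(str(lid), [0.0, 0.0])
            acc[0] += k
            acc[1] += n
        pairs = list(per_lineage.values())
    else:
        pairs = [[float(k), float(n)] for k, n in counts]

    usable = []
    for k, n in pairs:
        if n == 0:
            warnings.warn("excluding lineage with n = 0 from chi-square test")
        else:
            usable.append((k, n))
    if not usable:
        raise FitError("no lineage with observations")

    q = 1.0 - null_p
    chi2 = 0.0
    for k, n in usable:
        e_ti, e_tv = n * null_p, n * q
        chi2 += (k - e_ti) ** 2 / e_ti + ((n - k) - e_tv) ** 2 / e_tv
    df = len(usable) - 1 if len(usable) > 1 else 1
    p = float(stats.chi2.sf(chi2, df))
    return ChisqResult(chi2=float(chi2), df=df, p_value=p, n_lineages=len(usable))


def ols_ratio_vs_load(points: Iterable[tuple[float, float]]) -> OlsResult:
    """OLS of per-round ts/tv ratio against per-round mutation load.

    ``points`` are (mutation count, ratio) pairs pooled across lineages.
    The F statistic tests slope = 0; df is the residual degrees of freedom
    (n_points - 2).
    """
    pts = np.asarray(list(points), float)
    if pts.shape[0] < 3:
        raise ParameterError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(x, x[0]):
        raise FitError("mutation load is constant; slope is undefined")
    if np.allclose(y, y[0]):
        # flat response: slope 0 by construction, no variance to explain
        return OlsResult(
            slope=0.0, intercept=float(y[0]), f_stat=0.0,
            df=len(x) - 2, p_value=1.0, r2=0.0,
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return OlsResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        f_stat=float(res.fvalue),
        df=int(res.df_resid),
        p_value=float(res.f_pvalue),
        r2=float(res.rsquared),
    )
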