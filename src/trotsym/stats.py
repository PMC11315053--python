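"""Pooling check and linear mixed-model analysis of re-shoeing differences.

Two stages mirror the study's statistical workflow:

1. *Pooling check* — left- and right-limb intervention differences are
   compared per variable against published test-retest repeatability
   thresholds (6 mm for head variables, 3 mm for withers and pelvis).
   Normality of the left-minus-right differences decides whether the mean
   or the median is used as the center. If all twelve variables pass, the
   side of intervention may be pooled and treated as a random factor.

2. *Mixed models* — for each of the twelve difference variables, a linear
   mixed model with additive fixed effects for surface (hard/soft) and
   direction (inside/outside/straight) and random intercepts for horse and
   limb-within-horse, fitted by REML. Fixed factors are tested with F tests
   using Satterthwaite denominator degrees of freedom; estimated marginal
   means average model predictions over the levels of the other factor with
   equal weights. Pairwise direction contrasts are Bonferroni-corrected.

The REML criterion is implemented directly over the three variance
components (the closed-form profiled likelihood), which makes the
variance-parameter information matrix needed by the Satterthwaite
approximation available; the fit is cross-checked against independent
mixed-model software in the test suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as spstats

from .normalize import variable_columns
from .types import DIFF_COLUMNS, threshold_for

logger = logging.getLogger(__name__)

ALPHA = 0.05
CONF_LEVEL = 0.95
SURFACE_LEVELS = ("hard", "soft")
DIRECTION_LEVELS = ("inside", "outside", "straight")


# ---------------------------------------------------------------------------
# Lilliefors normality test (Monte-Carlo null distribution)


def _ks_statistic_normal(x: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance to a normal with estimated parameters."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = spstats.norm.cdf(z)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    return max(d_plus, d_minus)


def lilliefors_normal(
    x: np.ndarray, n_sim: int = 10000, seed: int = 0
) -> Tuple[float, float]:
    """Lilliefors test for normality with mean and SD estimated from data.

    The null distribution of the KS statistic is simulated (``n_sim``
    standard-normal samples of the same size, seeded), avoiding table
    interpolation. Returns ``(statistic, p_value)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations for a normality test")
    if x.std(ddof=1) == 0:
        return 0.0, 1.0
    d_obs = _ks_statistic_normal(x)

    rng = np.random.default_rng(seed)
    n = x.size
    sims = rng.standard_normal((n_sim, n))
    sims = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(
        axis=1, ddof=1, keepdims=True
    )
    sims.sort(axis=1)
    cdf = spstats.norm.cdf(sims)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_sim = np.maximum(
        (grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1)
    )
    p = (1.0 + np.sum(d_sim >= d_obs)) / (n_sim + 1.0)
    return float(d_obs), float(p)


# ---------------------------------------------------------------------------
# pooling check


@dataclass
class PoolingResult:
    """Outcome of the side-pooling check."""

    table: pd.DataFrame
    pooling_permitted: bool

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        state = "permitted" if self.pooling_permitted else "NOT permitted"
        return f"<PoolingResult: pooling {state}, {len(self.table)} variables>"


def apply_pooling_thresholds(centers: Mapping[str, float]) -> PoolingResult:
    """Threshold rule on pre-computed left/right difference centers.

    ``centers`` maps difference-variable names to the mean or median
    left-minus-right intervention difference (mm). A variable passes when
    the absolute center does not exceed its repeatability threshold.
    """
    rows = []
    for var, center in centers.items():
        thr = threshold_for(var)
        rows.append(
            {
                "variable": var,
                "center": float(center),
                "threshold": thr,
                "passed": abs(center) <= thr,
            }
        )
    table = pd.DataFrame(rows)
    return PoolingResult(table, bool(table["passed"].all()))


def pooling_check(
    diffs: pd.DataFrame,
    alpha: float = ALPHA,
    n_sim: int = 10000,
    seed: int = 0,
) -> PoolingResult:
    """Check whether left/right intervention data may be pooled.

    Pairs the side-normalized left- and right-intervention records of each
    horse within each (surface, direction) cell, tests the per-variable
    left-minus-right differences for normality (Lilliefors), summarises
    them by the mean (normal) or median (non-normal), and compares the
    absolute center against the variable's test-retest repeatability
    threshold. Pooling is permitted iff all variables pass.
    """
    cols = variable_columns(diffs)
    if not cols:
        raise ValueError("no difference-variable columns present")
    left = diffs[diffs["reshod_limb"] == "left"]
    right = diffs[diffs["reshod_limb"] == "right"]
    keys = ["horse_id", "surface", "direction"]
    merged = left.merge(right, on=keys, suffixes=("_L", "_R"))
    if len(merged) < 3:
        raise ValueError(
            "fewer than 3 paired left/right intervention records; "
            "cannot run the pooling check"
        )
    rows = []
    for i, var in enumerate(cols):
        d = (merged[f"{var}_L"] - merged[f"{var}_R"]).to_numpy()
        stat, p_norm = lilliefors_normal(d, n_sim=n_sim, seed=seed + i)
        normal = p_norm >= alpha
        center = float(np.mean(d)) if normal else float(np.median(d))
        thr = threshold_for(var)
        rows.append(
            {
                "variable": var,
                "n_pairs": d.size,
                "normality_p": p_norm,
                "center_type": "mean" if normal else "median",
                "center": center,
                "threshold": thr,
                "passed": abs(center) <= thr,
            }
        )
    table = pd.DataFrame(rows)
    permitted = bool(table["passed"].all())
    if not permitted:
        failing = table.loc[~table["passed"], "variable"].tolist()
        logger.warning("pooling not permitted; failing variables: %s", failing)
    return PoolingResult(table, permitted)


# ---------------------------------------------------------------------------
# linear mixed model with Satterthwaite degrees of freedom


def _group_indicator(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels)
    z = np.zeros((labels.size, codes.max() + 1))
    z[np.arange(labels.size), codes] = 1.0
    return z


def _design_matrix(
    data: pd.DataFrame, include_side: bool = False
) -> Tuple[np.ndarray, List[str]]:
    """Reference-coded fixed-effects design (surface ref hard, direction ref inside)."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    cols.append((data["surface"] == "soft").to_numpy(float))
    names.append("surface[soft]")
    for lev in ("outside", "straight"):
        cols.append((data["direction"] == lev).to_numpy(float))
        names.append(f"direction[{lev}]")
    if include_side:
        cols.append((data["reshod_limb"] == "right").to_numpy(float))
        names.append("side[right]")
    return np.column_stack(cols), names


class _REMLModel:
    """REML machinery for y = X beta + sum_k u_k + eps with variance
    components ``theta`` (one per random grouping factor, plus residual)."""

    def __init__(self, y: np.ndarray, x: np.ndarray, gmats: List[np.ndarray]):
        self.y = y
        self.x = x
        self.gmats = gmats  # Z Z' per random factor
        self.n, self.p = x.shape
        self.k = len(gmats)

    def _v(self, theta: np.ndarray) -> np.ndarray:
        v = theta[-1] * np.eye(self.n)
        for g, t in zip(self.gmats, theta[:-1]):
            v = v + t * g
        return v

    def reml_loglike(self, theta: np.ndarray) -> float:
        try:
            v = self._v(theta)
            c, low = np.linalg.cholesky(v), True
        except np.linalg.LinAlgError:
            return -np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        vi_x = np.linalg.solve(v, self.x)
        vi_y = np.linalg.solve(v, self.y)
        xtvx = self.x.T @ vi_x
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(xtvx, self.x.T @ vi_y)
        r = self.y - self.x @ beta
        quad = r @ np.linalg.solve(v, r)
        return -0.5 * (logdet_v + logdet_x + quad)

    def beta_cov(self, theta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        v = self._v(theta)
        vi_x = np.linalg.solve(v, self.x)
        xtvx = self.x.T @ vi_x
        cov = np.linalg.inv(xtvx)
        beta = cov @ (vi_x.T @ self.y)
        return beta, cov

    def fit(self) -> np.ndarray:
        var_y = max(self.y.var(ddof=1), 1e-10)
        x0 = np.log(np.full(self.k + 1, var_y / (self.k + 1)))
        lb, ub = np.log(1e-8 * var_y), np.log(1e3 * var_y)
        best = None
        for start in (x0, x0 + np.log(4), x0 - np.log(4)):
            res = optimize.minimize(
                lambda lv: -self.reml_loglike(np.exp(lv)),
                start,
                method="L-BFGS-B",
                bounds=[(lb, ub)] * (self.k + 1),
            )
            if best is None or res.fun < best.fun:
                best = res
        return np.exp(best.x)

    def theta_cov(self, theta: np.ndarray) -> np.ndarray:
        """Inverse observed REML information over the variance scale."""
        m = theta.size
        h = np.empty((m, m))
        steps = np.maximum(1e-3 * theta, 1e-6 * max(theta.max(), 1e-8))

        def f(t):
            return self.reml_loglike(np.maximum(t, 0.0))

        f0 = f(theta)
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m)
                ej = np.zeros(m)
                ei[i], ej[j] = steps[i], steps[j]
                if i == j:
                    val = (f(theta + ei) - 2 * f0 + f(theta - ei)) / steps[i] ** 2
                else:
                    val = (
                        f(theta + ei + ej)
                        - f(theta + ei - ej)
                        - f(theta - ei + ej)
                        + f(theta - ei - ej)
                    ) / (4 * steps[i] * steps[j])
                h[i, j] = h[j, i] = val
        info = -h
        try:
            return np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(info)

    def satterthwaite_df(
        self, ell: np.ndarray, theta: np.ndarray, theta_cov: np.ndarray
    ) -> float:
        """Denominator df for the single contrast ``ell`` via the delta method."""

        def fvar(t):
            v = self._v(np.maximum(t, 1e-12))
            xtvx = self.x.T @ np.linalg.solve(v, self.x)
            return float(ell @ np.linalg.solve(xtvx, ell))

        f0 = fvar(theta)
        m = theta.size
        grad = np.empty(m)
        steps = np.maximum(1e-3 * theta, 1e-6 * max(theta.max(), 1e-8))
        for i in range(m):
            e = np.zeros(m)
            e[i] = steps[i]
            grad[i] = (fvar(theta + e) - fvar(theta - e)) / (2 * steps[i])
        denom = float(grad @ theta_cov @ grad)
        resid_df = float(self.n - self.p)
        if denom <= 0 or not np.isfinite(denom):
            return resid_df
        nu = 2.0 * f0**2 / denom
        if not np.isfinite(nu) or nu <= 0:
            return resid_df
        return float(np.clip(nu, 1.0, 1e6))


@dataclass
class ModelResult:
    """Mixed-model results for one difference variable."""

    outcome: str
    n: int
    p_direction: float
    p_surface: float
    emm: Dict[str, Tuple[float, float, float]]  # level -> (est, lo, hi)
    pairwise_direction: pd.DataFrame
    varcomp: Dict[str, float]
    fixed_effects: pd.DataFrame
    conf_level: float = CONF_LEVEL
    warnings: List[str] = field(default_factory=list)


def _emm_rows(names: List[str]) -> Dict[str, np.ndarray]:
    """Prediction rows averaging over the other factor with equal weights."""
    p = len(names)

    def row(surface_w: float, dir_w: Dict[str, float]) -> np.ndarray:
        r = np.zeros(p)
        r[names.index("intercept")] = 1.0
        r[names.index("surface[soft]")] = surface_w
        for lev in ("outside", "straight"):
            r[names.index(f"direction[{lev}]")] = dir_w.get(lev, 0.0)
        if "side[right]" in names:
            r[names.index("side[right]")] = 0.5
        return r

    third = {"outside": 1 / 3, "straight": 1 / 3}
    return {
        "inside": row(0.5, {}),
        "outside": row(0.5, {"outside": 1.0}),
        "straight": row(0.5, {"straight": 1.0}),
        "hard": row(0.0, third),
        "soft": row(1.0, third),
    }


def _multi_df_ftest(
    lmat: np.ndarray,
    beta: np.ndarray,
    cov: np.ndarray,
    model: _REMLModel,
    theta: np.ndarray,
    theta_cov: np.ndarray,
) -> Tuple[float, float, float]:
    """F statistic and Satterthwaite denominator df for a multi-row contrast."""
    q = lmat.shape[0]
    middle = lmat @ cov @ lmat.T
    est = lmat @ beta
    fstat = float(est @ np.linalg.solve(middle, est)) / q
    # per-eigenvector 1-df Satterthwaite dfs, combined as in mixed-model
    # software practice
    evals, evecs = np.linalg.eigh(middle)
    nus = []
    for lam, vec in zip(evals, evecs.T):
        if lam <= 0:
            continue
        ell = lmat.T @ vec
        nus.append(model.satterthwaite_df(ell, theta, theta_cov))
    if not nus:
        return fstat, q, float(model.n - model.p)
    nus = np.asarray(nus)
    usable = nus[nus > 2.0]
    if usable.size == 0:
        ddf = float(model.n - model.p)
    else:
        e_sum = float(np.sum(usable / (usable - 2.0)))
        ddf = 2.0 * e_sum / (e_sum - q) if e_sum > q else float(model.n - model.p)
    return fstat, q, ddf


def fit_mixed_model(
    data: pd.DataFrame,
    outcome: str,
    include_side: bool = False,
    conf_level: float = CONF_LEVEL,
) -> ModelResult:
    """Fit the surface + direction mixed model for one difference variable.

    Random intercepts for horse and for limb nested within horse; REML
    estimation; Satterthwaite denominator degrees of freedom; estimated
    marginal means per factor level with equal weights over the other
    factor; Bonferroni-corrected pairwise direction contrasts.

    A singular limb-within-horse component (estimate on the zero boundary)
    triggers a refit without that term, with a logged warning.
    """
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} not present")
    if data["horse_id"].nunique() < 2:
        raise ValueError("need at least two horses to fit the mixed model")
    warnings: List[str] = []
    y = data[outcome].to_numpy(float)
    x, names = _design_matrix(data, include_side=include_side)

    z_horse = _group_indicator(data["horse_id"])
    limb_labels = data["horse_id"].astype(str) + ":" + data["reshod_limb"].astype(str)
    z_limb = _group_indicator(limb_labels)
    gmats = [z_horse @ z_horse.T, z_limb @ z_limb.T]
    comp_names = ["horse", "limb_within_horse", "residual"]

    model = _REMLModel(y, x, gmats)
    theta = model.fit()
    var_y = max(y.var(ddof=1), 1e-10)
    if theta[1] <= 1e-6 * var_y:
        warnings.append(
            "limb-within-horse variance estimated at the zero boundary; "
            "refitting without the nested term"
        )
        logger.warning(warnings[-1])
        model = _REMLModel(y, x, [gmats[0]])
        theta_red = model.fit()
        theta = np.array([theta_red[0], 0.0, theta_red[1]])
        theta_fit = theta_red
    else:
        theta_fit = theta
    theta_cov = model.theta_cov(theta_fit)
    beta, cov = model.beta_cov(theta_fit)

    # fixed-effect table
    tvals, fe_rows = [], []
    for j, nm in enumerate(names):
        se = float(np.sqrt(cov[j, j]))
        ell = np.zeros(len(names))
        ell[j] = 1.0
        ddf = model.satterthwaite_df(ell, theta_fit, theta_cov)
        t = beta[j] / se if se > 0 else np.nan
        fe_rows.append(
            {
                "term": nm,
                "estimate": float(beta[j]),
                "se": se,
                "ddf": ddf,
                "t": float(t),
                "p": float(2 * spstats.t.sf(abs(t), ddf)),
            }
        )
        tvals.append(t)
    fixed_effects = pd.DataFrame(fe_rows)

    # omnibus F tests
    def _contrast_rows(terms: List[str]) -> np.ndarray:
        rows = []
        for t in terms:
            r = np.zeros(len(names))
            r[names.index(t)] = 1.0
            rows.append(r)
        return np.asarray(rows)

    f_dir, q_dir, ddf_dir = _multi_df_ftest(
        _contrast_rows(["direction[outside]", "direction[straight]"]),
        beta,
        cov,
        model,
        theta_fit,
        theta_cov,
    )
    p_direction = float(spstats.f.sf(f_dir, q_dir, ddf_dir))
    f_sur, q_sur, ddf_sur = _multi_df_ftest(
        _contrast_rows(["surface[soft]"]), beta, cov, model, theta_fit, theta_cov
    )
    p_surface = float(spstats.f.sf(f_sur, q_sur, ddf_sur))

    # estimated marginal means with CIs
    emm = {}
    for level, row in _emm_rows(names).items():
        est = float(row @ beta)
        se = float(np.sqrt(row @ cov @ row))
        ddf = model.satterthwaite_df(row, theta_fit, theta_cov)
        tq = spstats.t.ppf(0.5 + conf_level / 2.0, ddf)
        emm[level] = (est, est - tq * se, est + tq * se)

    # pairwise direction comparisons, Bonferroni over the three pairs
    emm_rows = _emm_rows(names)
    pw = []
    pairs = list(itertools.combinations(DIRECTION_LEVELS, 2))
    for a, b in pairs:
        ell = emm_rows[a] - emm_rows[b]
        est = float(ell @ beta)
        se = float(np.sqrt(ell @ cov @ ell))
        ddf = model.satterthwaite_df(ell, theta_fit, theta_cov)
        t = est / se if se > 0 else np.nan
        p_raw = float(2 * spstats.t.sf(abs(t), ddf))
        pw.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": est,
                "se": se,
                "ddf": ddf,
                "t": float(t),
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, len(pairs) * p_raw),
            }
        )
    pairwise = pd.DataFrame(pw)

    return ModelResult(
        outcome=outcome,
        n=len(data),
        p_direction=p_direction,
        p_surface=p_surface,
        emm=emm,
        pairwise_direction=pairwise,
        varcomp=dict(zip(comp_names, theta.tolist())),
        fixed_effects=fixed_effects,
        conf_level=conf_level,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# full analysis


@dataclass
class AnalysisReport:
    """Pooling result plus one mixed model per difference variable."""

    pooling: Optional[PoolingResult]
    results: Dict[str, ModelResult]
    report: pd.DataFrame

    def format_text(self) -> str:
        """Plain-text rendition of the report table."""
        lines = []
        if self.pooling is not None:
            state = "permitted" if self.pooling.pooling_permitted else "NOT permitted"
            lines.append(f"Side pooling: {state}")
        lines.append(
            self.report.to_string(index=False, float_format=lambda v: f"{v:.3f}")
        )
        return "\n".join(lines)


def _report_frame(results: Dict[str, ModelResult]) -> pd.DataFrame:
    rows = []
    for var, res in results.items():
        row = {
            "parameter": var,
            "p_direction": res.p_direction,
            "p_surface": res.p_surface,
        }
        for level in ("inside", "outside", "straight", "hard", "soft"):
            est, lo, hi = res.emm[level]
            row[f"emm_{level}"] = est
            row[f"emm_{level}_lo"] = lo
            row[f"emm_{level}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(
    data: pd.DataFrame,
    do_pooling_check: bool = True,
    conf_level: float = CONF_LEVEL,
    pooling_seed: int = 0,
) -> AnalysisReport:
    """Pooling check followed by mixed models for all difference variables.

    If the pooling check fails, the analysis proceeds with the side of
    intervention as an additional fixed covariate and logs the deviation.
    """
    pooling = None
    include_side = False
    if do_pooling_check:
        pooling = pooling_check(data, seed=pooling_seed)
        if not pooling.pooling_permitted:
            include_side = True
            logger.warning(
                "pooling check failed: side of intervention included as a "
                "fixed covariate"
            )
    results = {}
    for var in variable_columns(data):
        results[var] = fit_mixed_model(
            data, var, include_side=include_side, conf_level=conf_level
        )
    return AnalysisReport(pooling, results, _report_frame(results))
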