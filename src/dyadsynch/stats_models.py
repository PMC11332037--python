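"""Inference stages: mixed ANCOVA, hierarchical moderation regression, slopes.

The mixed ANCOVA handles the split-plot design of transmission-chain data —
one between-subjects factor (Generation), within-subject factors Cue (Tx/NT)
and Trial, and a subject-constant covariate (dyad gender match). It is
computed stratum-wise from orthonormal within-subject contrasts: each within
effect is projected to per-subject contrast scores, regressed on the between
design, and tested with the classic sphericity-uncorrected univariate F
(integer degrees of freedom). Effect sizes are partial eta squared with
noncentral-F confidence intervals; covariate-adjusted marginal means weight
the between groups equally at the covariate mean.

Hierarchical regressions are nested OLS stages on an identical
complete-case sample (synchrony → + generation → + interaction), reporting
unstandardised B, SE, standardised β, t, p and 95% CI per predictor plus
stage-level adjusted R² and F. Simple slopes evaluate the conditional effect
of a focal predictor at chosen moderator levels with delta-method intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "EffectTest",
    "AdjustedMean",
    "AncovaOutput",
    "RegressionStageResult",
    "SimpleSlopes",
    "fit_mixed_ancova",
    "fit_hierarchical_regression",
    "simple_slopes",
    "partial_eta_squared_ci",
]


@dataclass
class EffectTest:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p2: float
    eta_p2_ci: tuple


@dataclass
class AdjustedMean:
    level: str
    mean: float
    se: float
    ci: tuple


@dataclass
class AncovaOutput:
    effects: dict  # name -> EffectTest
    adjusted_means: dict  # cue level -> AdjustedMean
    adjusted_difference: AdjustedMean | None  # Tx − NT
    n_subjects: int
    dropped_subjects: list


@dataclass
class RegressionStageResult:
    stage: int
    predictors: list
    table: pd.DataFrame  # index = term; columns B, SE, beta, t, p, ci_low, ci_high
    r2: float
    r2_adj: float
    F: float
    f_p: float
    df_model: int
    df_resid: int
    nobs: int
    cov_params: pd.DataFrame = field(repr=False, default=None)


@dataclass
class SimpleSlopes:
    focal: str
    moderator: str
    levels: list
    slopes: list  # (level, B, se, (lo, hi))


# ---------------------------------------------------------------------------
# partial eta squared


def _eta_from_lambda(lam: float, df1: int, df2: int) -> float:
    return lam / (lam + df1 + df2 + 1)


def partial_eta_squared_ci(
    F: float, df1: int, df2: int, conf: float = 0.95
) -> tuple[float, float]:
    """Two-sided CI for partial η² by inverting the noncentral-F CDF."""
    if not np.isfinite(F) or F < 0:
        return (float("nan"), float("nan"))
    alpha = (1.0 - conf) / 2.0

    def cdf(lam: float) -> float:
        return float(stats.ncf.cdf(F, df1, df2, lam))

    def solve(target: float) -> float:
        if cdf(0.0) <= target:
            return 0.0
        hi = 10.0
        while cdf(hi) > target and hi < 1e8:
            hi *= 2.0
        return float(optimize.brentq(lambda l: cdf(l) - target, 0.0, hi))

    lam_lo = solve(1.0 - alpha)
    lam_hi = solve(alpha)
    return (_eta_from_lambda(lam_lo, df1, df2), _eta_from_lambda(lam_hi, df1, df2))


# ---------------------------------------------------------------------------
# mixed ANCOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k × (k−1) orthonormal contrast matrix (columns ⟂ the unit vector)."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, :-1]]))
    c = q[:, 1:]
    return c


def _between_design(
    n: int, groups: pd.Series | None, covariate: pd.Series | None
) -> tuple[np.ndarray, list]:
    cols = [np.ones(n)]
    names = ["intercept"]
    if groups is not None:
        levels = sorted(groups.unique())
        if len(levels) != 2:
            raise ValueError("between factor must have exactly 2 levels")
        # effect coding: first level +1, second −1
        cols.append(np.where(groups.to_numpy() == levels[0], 1.0, -1.0))
        names.append("between")
    if covariate is not None:
        c = covariate.to_numpy(dtype=float)
        cols.append(c - c.mean())
        names.append("covariate")
    return np.column_stack(cols), names


def _stratum_f(
    Z: np.ndarray, X: np.ndarray, term: int, scale: float = 1.0
) -> tuple[float, float, float, int, int]:
    """Univariate F for one design column within one within-subject stratum.

    ``Z`` holds per-subject orthonormal contrast scores (N × q); the
    hypothesis and error SS are pooled over the q columns. A stratum whose
    total SS vanishes relative to ``scale`` (e.g., Tx cells identical to NT
    cells) has no effect and no error: its F is 0 by convention.
    """
    n, q = Z.shape
    p = X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Z  # p × q
    resid = Z - X @ B
    ss_err = float((resid**2).sum())
    ss_hyp = float((B[term] ** 2).sum() / xtx_inv[term, term])
    df_num, df_den = q, q * (n - p)
    if ss_hyp + ss_err <= 1e-14 * max(scale, 1.0):
        return 0.0, 0.0, ss_err, df_num, df_den
    F = (ss_hyp / df_num) / (ss_err / df_den)
    return F, ss_hyp, ss_err, df_num, df_den


def fit_mixed_ancova(
    data: pd.DataFrame,
    outcome: str = "value",
    *,
    subject: str = "subject",
    between: str | None = "generation",
    within: Sequence[str] = ("cue", "trial"),
    covariate: str | None = "gender_match",
) -> AncovaOutput:
    """Type-III mixed ANCOVA with Cue/Trial within and Generation between.

    ``data`` is tidy (one row per subject × within-cell). Subjects with any
    missing cell are dropped listwise (the trial-pair averaging upstream is
    what keeps that rare). The first within factor is treated as the Cue
    factor for adjusted marginal means; with two levels its adjusted
    difference (first − second sorted level ordering follows ["Tx", "NT"]
    when present) is reported with an OLS confidence interval.
    """
    cells = [c for c in within]
    wide = data.pivot_table(index=subject, columns=cells, values=outcome, aggfunc="mean")
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if complete.shape[0] < 3:
        raise ValueError("fewer than 3 complete subjects")
    subj_meta = data.drop_duplicates(subject).set_index(subject)
    meta = subj_meta.loc[complete.index]
    groups = meta[between] if between else None
    cov = meta[covariate].astype(float) if covariate else None
    X, names = _between_design(len(complete), groups, cov)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular between-subjects design")

    # cell ordering and per-factor levels (Tx before NT reads naturally)
    def level_order(factor):
        levels = list(pd.unique(data[factor]))
        if set(levels) == {"Tx", "NT"}:
            return ["Tx", "NT"]
        return sorted(levels)

    level_lists = [level_order(f) for f in cells]
    if len(cells) == 1:
        ordered_cols = [(lv,) for lv in level_lists[0]]
        complete = complete[[lv for lv in level_lists[0]]]
        Y = complete.to_numpy(dtype=float)
    else:
        ordered_cols = [
            tuple(levels) for levels in _cartesian(level_lists)
        ]
        complete = complete[ordered_cols]
        Y = complete.to_numpy(dtype=float)
    n = Y.shape[0]
    ks = [len(lv) for lv in level_lists]

    contrasts = {f: _orthonormal_contrasts(k) for f, k in zip(cells, ks)}
    unit = {f: np.ones((k, 1)) / np.sqrt(k) for f, k in zip(cells, ks)}

    effects: dict[str, EffectTest] = {}

    ss_scale = float((Y**2).sum())

    def record(name, F, ss_hyp, ss_err, df1, df2):
        p = float(stats.f.sf(F, df1, df2))
        eta = ss_hyp / (ss_hyp + ss_err) if ss_hyp + ss_err > 0 else 0.0
        effects[name] = EffectTest(
            name, float(F), df1, df2, p, float(eta),
            partial_eta_squared_ci(F, df1, df2),
        )

    # between stratum: subject means
    Z0 = Y @ _kron([unit[f] for f in cells])
    for term, tname in enumerate(names):
        if tname == "intercept":
            continue
        label = between if tname == "between" else covariate
        F, sh, se_, d1, d2 = _stratum_f(Z0, X, term, ss_scale)
        record(label, F, sh, se_, d1, d2)

    # within strata: every non-empty subset of within factors
    for mask in range(1, 2 ** len(cells)):
        in_effect = [f for b, f in enumerate(cells) if mask >> b & 1]
        M = _kron([contrasts[f] if f in in_effect else unit[f] for f in cells])
        Z = Y @ M
        wname = " x ".join(in_effect)
        F, sh, se_, d1, d2 = _stratum_f(Z, X, 0, ss_scale)  # intercept = main effect
        record(wname, F, sh, se_, d1, d2)
        if between:
            term = names.index("between")
            F, sh, se_, d1, d2 = _stratum_f(Z, X, term, ss_scale)
            record(f"{wname} x {between}", F, sh, se_, d1, d2)

    # adjusted marginal means for the first within factor (Cue)
    cue = cells[0]
    cue_levels = level_lists[0]
    adjusted: dict[str, AdjustedMean] = {}
    cue_means = {}
    for lv in cue_levels:
        if len(cells) == 1:
            m = complete[lv].to_numpy(dtype=float)
        else:
            sel = [col for col in ordered_cols if col[0] == lv]
            m = complete[sel].to_numpy(dtype=float).mean(axis=1)
        cue_means[lv] = m
        adjusted[lv] = _ols_intercept_summary(m, X, str(lv))
    diff = None
    if len(cue_levels) == 2:
        d = cue_means[cue_levels[0]] - cue_means[cue_levels[1]]
        diff = _ols_intercept_summary(d, X, f"{cue_levels[0]} - {cue_levels[1]}")

    return AncovaOutput(
        effects=effects,
        adjusted_means=adjusted,
        adjusted_difference=diff,
        n_subjects=n,
        dropped_subjects=dropped,
    )


def _cartesian(level_lists):
    import itertools

    return list(itertools.product(*level_lists))


def _kron(mats: list) -> np.ndarray:
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def _ols_intercept_summary(y: np.ndarray, X: np.ndarray, label: str) -> AdjustedMean:
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    b = xtx_inv @ X.T @ y
    resid = y - X @ b
    s2 = float(resid @ resid) / (n - p)
    se = float(np.sqrt(s2 * xtx_inv[0, 0]))
    tcrit = float(stats.t.ppf(0.975, n - p))
    est = float(b[0])
    return AdjustedMean(label, est, se, (est - tcrit * se, est + tcrit * se))


# ---------------------------------------------------------------------------
# hierarchical regression


def fit_hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    stage_predictors: Sequence[Sequence[str]],
    *,
    max_condition_number: float = 1e8,
) -> list[RegressionStageResult]:
    """Nested OLS stages on an identical complete-case sample.

    ``stage_predictors`` lists the predictors *added* at each stage; stage k
    fits the union of stages 1..k. Complete cases are determined on the
    final-stage predictor set so every stage sees the same subjects.
    Standardised β are computed as B·sd(x)/sd(y) on the analysis sample.
    """
    cumulative: list[list[str]] = []
    acc: list[str] = []
    for preds in stage_predictors:
        acc = acc + [p for p in preds if p not in acc]
        cumulative.append(list(acc))
    all_cols = [outcome] + cumulative[-1]
    sample = data[all_cols].dropna()
    y = sample[outcome].to_numpy(dtype=float)
    sd_y = y.std(ddof=1)
    results = []
    for k, preds in enumerate(cumulative, start=1):
        Xdf = sample[preds].astype(float)
        Xs = (Xdf - Xdf.mean()) / Xdf.std(ddof=1)
        cond = np.linalg.cond(Xs.to_numpy())
        if cond > max_condition_number:
            raise ValueError(
                f"stage {k}: collinear predictors (condition number {cond:.3g})"
            )
        X = sm.add_constant(Xdf)
        fit = sm.OLS(y, X).fit()
        ci = fit.conf_int(alpha=0.05)
        table = pd.DataFrame(
            {
                "B": fit.params,
                "SE": fit.bse,
                "beta": [
                    np.nan
                    if term == "const"
                    else fit.params[term] * Xdf[term].std(ddof=1) / sd_y
                    for term in X.columns
                ],
                "t": fit.tvalues,
                "p": fit.pvalues,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
        results.append(
            RegressionStageResult(
                stage=k,
                predictors=list(preds),
                table=table,
                r2=float(fit.rsquared),
                r2_adj=float(fit.rsquared_adj),
                F=float(fit.fvalue),
                f_p=float(fit.f_pvalue),
                df_model=int(fit.df_model),
                df_resid=int(fit.df_resid),
                nobs=int(fit.nobs),
                cov_params=fit.cov_params(),
            )
        )
    return results


def simple_slopes(
    stage: RegressionStageResult,
    focal: str,
    moderator: str,
    levels: Sequence[float] | dict | None = None,
    *,
    interaction: str | None = None,
    moderator_values: np.ndarray | None = None,
) -> SimpleSlopes:
    """Conditional slope of ``focal`` at chosen ``moderator`` levels.

    ``levels`` may be a dict {label: code} (e.g., effect codes {"G2": 1,
    "G3": -1}), a sequence of numeric levels, or None — in which case
    ``moderator_values`` supplies the sample and levels default to the mean
    and ±1 SD. The slope at level m is B_focal + m·B_interaction with a
    delta-method interval on the stage's residual t distribution.
    """
    if interaction is None:
        candidates = [f"{focal}:{moderator}", f"{moderator}:{focal}"]
        hits = [c for c in candidates if c in stage.table.index]
        if not hits:
            raise ValueError(
                f"no interaction term between {focal!r} and {moderator!r} in model"
            )
        interaction = hits[0]
    for term in (focal, moderator):
        if term not in stage.table.index:
            raise ValueError(f"term {term!r} absent from model")
    if levels is None:
        if moderator_values is None:
            raise ValueError("provide levels or moderator_values")
        mv = np.asarray(moderator_values, dtype=float)
        mv = mv[~np.isnan(mv)]
        levels = {
            "mean - 1SD": mv.mean() - mv.std(ddof=1),
            "mean": mv.mean(),
            "mean + 1SD": mv.mean() + mv.std(ddof=1),
        }
    if not isinstance(levels, dict):
        levels = {str(v): float(v) for v in levels}

    b_f = stage.table.loc[focal, "B"]
    b_i = stage.table.loc[interaction, "B"]
    V = stage.cov_params
    v_ff = V.loc[focal, focal]
    v_ii = V.loc[interaction, interaction]
    v_fi = V.loc[focal, interaction]
    tcrit = float(stats.t.ppf(0.975, stage.df_resid))
    slopes = []
    for label, m in levels.items():
        est = float(b_f + m * b_i)
        se = float(np.sqrt(v_ff + m * m * v_ii + 2 * m * v_fi))
        slopes.append((label, est, se, (est - tcrit * se, est + tcrit * se)))
    return SimpleSlopes(focal, moderator, list(levels.keys()), slopes)
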