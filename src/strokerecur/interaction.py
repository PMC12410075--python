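"""Additive and multiplicative interaction analysis for binary outcomes.

Additive interaction between two binary exposures is measured on the
odds-ratio scale with the three classical indices

* RERI (relative excess risk due to interaction) = OR11 − OR10 − OR01 + 1
* AP (attributable proportion)                   = RERI / OR11
* S (synergy index)                              = (OR11 − 1) / ((OR10 − 1) + (OR01 − 1))

where ORij is the odds ratio for exposure cell (A=i, B=j) against the doubly
unexposed cell, estimated from a logistic model with three cell-indicator
dummies (optionally adjusted). Confidence intervals come from the delta
method on the dummy-coefficient covariance (S on the log scale when S > 0)
or from patient-level bootstrap resampling.

The decision rule: an index "triggers" synergy when it exceeds its null
(0 for RERI/AP, 1 for S) with a 95% CI excluding that null, and antagonism
in the mirror case; any single triggering index suffices for a verdict, and
conflicting directions yield "none" with a diagnostic.

Multiplicative interaction uses ordinary product-term logistic models, up to
the full three-way factorial whose triple product term is the headline test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from ._rand import child_rng

__all__ = [
    "JointExposureFit",
    "AdditiveIndices",
    "InteractionCall",
    "ThreeWayFit",
    "cross_classify",
    "fit_joint_logistic",
    "additive_indices",
    "delta_ci",
    "bootstrap_ci",
    "classify_additive",
    "multilevel_contrasts",
    "fit_main_effects",
    "fit_three_way",
    "collinearity_screen",
    "two_way_report",
]

OUTCOME = "recurrence_binary"


# ---------------------------------------------------------------------------
# joint exposure fit


@dataclass
class JointExposureFit:
    """Joint ORs for two binary exposures versus the doubly-unexposed cell."""

    or10: float
    or01: float
    or11: float
    params: np.ndarray  # log-ORs for the (1,0), (0,1), (1,1) dummies
    cov: np.ndarray  # 3x3 covariance of those coefficients
    adjust: tuple[str, ...] = ()
    n: int = 0

    def or_ci(self, level: float = 0.95) -> pd.DataFrame:
        """Wald CIs for the three cell ORs."""
        z = norm.ppf(0.5 + level / 2.0)
        se = np.sqrt(np.diag(self.cov))
        lo = np.exp(self.params - z * se)
        hi = np.exp(self.params + z * se)
        return pd.DataFrame(
            {"or": [self.or10, self.or01, self.or11], "ci_lower": lo, "ci_upper": hi},
            index=["(1,0)", "(0,1)", "(1,1)"],
        )


def cross_classify(
    code_a: Sequence[int], code_b: Sequence[int], outcome: Sequence[int]
) -> np.ndarray:
    """2x2x2 count table indexed [a, b, y]."""
    a = np.asarray(code_a, dtype=int)
    b = np.asarray(code_b, dtype=int)
    y = np.asarray(outcome, dtype=int)
    if not (len(a) == len(b) == len(y)):
        raise ValueError(f"length mismatch: {len(a)}, {len(b)}, {len(y)}")
    table = np.zeros((2, 2, 2), dtype=int)
    for i in range(2):
        for j in range(2):
            for k in range(2):
                table[i, j, k] = int(((a == i) & (b == j) & (y == k)).sum())
    return table


def _check_cells(a: np.ndarray, b: np.ndarray, names: tuple[str, str]) -> None:
    for i in range(2):
        for j in range(2):
            if not ((a == i) & (b == j)).any():
                raise ValueError(
                    f"empty exposure cell ({names[0]}={i}, {names[1]}={j}); "
                    "joint ORs are not estimable (separation)"
                )


def fit_joint_logistic(
    cohort: pd.DataFrame,
    exposure_a: str,
    exposure_b: str,
    outcome: str = OUTCOME,
    adjust: Iterable[str] = (),
) -> JointExposureFit:
    """Logistic fit with cell-indicator dummies for the joint exposure.

    The model is logit P(y=1) = b0 + b10*I(a=1,b=0) + b01*I(a=0,b=1)
    + b11*I(a=1,b=1) [+ adjustment covariates]; exp of the dummy coefficients
    are the joint ORs against the (0,0) reference.
    """
    adjust = tuple(adjust)
    a = cohort[exposure_a].to_numpy(dtype=int)
    b = cohort[exposure_b].to_numpy(dtype=int)
    y = cohort[outcome].to_numpy(dtype=int)
    for arr, name in ((a, exposure_a), (b, exposure_b)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"exposure {name!r} must be binary 0/1")
    _check_cells(a, b, (exposure_a, exposure_b))

    X = pd.DataFrame(
        {
            "i10": ((a == 1) & (b == 0)).astype(float),
            "i01": ((a == 0) & (b == 1)).astype(float),
            "i11": ((a == 1) & (b == 1)).astype(float),
        },
        index=cohort.index,
    )
    for c in adjust:
        X[c] = cohort[c].astype(float)
    X = sm.add_constant(X, has_constant="add")
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    idx = [list(X.columns).index(c) for c in ("i10", "i01", "i11")]
    params = np.asarray(res.params)[idx]
    cov = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    return JointExposureFit(
        or10=float(np.exp(params[0])),
        or01=float(np.exp(params[1])),
        or11=float(np.exp(params[2])),
        params=params,
        cov=cov,
        adjust=adjust,
        n=len(cohort),
    )


# ---------------------------------------------------------------------------
# additive indices


@dataclass
class AdditiveIndices:
    reri: float
    ap: float
    s: float  # NaN when undefined (denominator 0)
    ci_reri: tuple[float, float] | None = None
    ci_ap: tuple[float, float] | None = None
    ci_s: tuple[float, float] | None = None
    method: str | None = None
    notes: list[str] = field(default_factory=list)


def _point_indices(or10: float, or01: float, or11: float) -> tuple[float, float, float]:
    reri = or11 - or10 - or01 + 1.0
    ap = reri / or11 if or11 != 0 else float("nan")
    denom = (or10 - 1.0) + (or01 - 1.0)
    s = (or11 - 1.0) / denom if denom != 0.0 else float("nan")
    return reri, ap, s


def additive_indices(
    fit: JointExposureFit | tuple[float, float, float],
    level: float = 0.95,
    with_ci: bool = True,
) -> AdditiveIndices:
    """RERI, AP and S for a joint-exposure fit (delta-method CIs by default).

    A bare (or10, or01, or11) triple yields point estimates only.
    """
    if isinstance(fit, JointExposureFit):
        or10, or01, or11 = fit.or10, fit.or01, fit.or11
    else:
        or10, or01, or11 = fit
        fit = None
    reri, ap, s = _point_indices(or10, or01, or11)
    out = AdditiveIndices(reri=reri, ap=ap, s=s)
    if np.isnan(s):
        out.notes.append("S undefined: (OR10 - 1) + (OR01 - 1) = 0")
    if or11 == 0:
        out.notes.append("AP undefined: OR11 = 0")
    if fit is not None and with_ci:
        out.ci_reri = delta_ci(fit, "RERI", level)
        out.ci_ap = delta_ci(fit, "AP", level)
        out.ci_s = delta_ci(fit, "S", level) if not np.isnan(s) else None
        out.method = "delta"
        if not np.isnan(s) and s <= 0:
            out.notes.append(
                "S <= 0 is outside the synergy index's usual domain; "
                "direct (untransformed) delta interval used"
            )
    return out


def _index_gradient(index: str, or10: float, or01: float, or11: float) -> tuple[np.ndarray, float, bool]:
    """(gradient wrt the three dummy log-ORs, point value, on_log_scale)."""
    if index == "RERI":
        value = or11 - or10 - or01 + 1.0
        return np.array([-or10, -or01, or11]), value, False
    if index == "AP":
        value = (or11 - or10 - or01 + 1.0) / or11
        g = np.array([-or10 / or11, -or01 / or11, (or10 + or01 - 1.0) / or11])
        return g, value, False
    if index == "S":
        denom = (or10 - 1.0) + (or01 - 1.0)
        if denom == 0.0:
            raise ValueError("S undefined: denominator (OR10-1)+(OR01-1) is 0")
        value = (or11 - 1.0) / denom
        if value > 0:
            # delta on ln S
            g = np.array(
                [-or10 / denom, -or01 / denom, or11 / (or11 - 1.0)]
            )
            return g, value, True
        g = np.array(
            [
                -(or11 - 1.0) * or10 / denom**2,
                -(or11 - 1.0) * or01 / denom**2,
                or11 / denom,
            ]
        )
        return g, value, False
    raise ValueError(f"unknown index {index!r}; expected RERI, AP or S")


def delta_ci(
    fit: JointExposureFit, index: str, level: float = 0.95
) -> tuple[float, float]:
    """Delta-method CI for RERI, AP or S from the dummy-coefficient covariance."""
    cov = np.asarray(fit.cov, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariance contains non-finite entries")
    g, value, on_log = _index_gradient(index, fit.or10, fit.or01, fit.or11)
    var = float(g @ cov @ g)
    if var < 0:
        raise ValueError("covariance is not positive semidefinite for this gradient")
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    if on_log:
        # var was computed for ln(index); exponentiate the log-scale interval
        return (float(value * np.exp(-half)), float(value * np.exp(half)))
    return (float(value - half), float(value + half))


def bootstrap_ci(
    cohort: pd.DataFrame,
    exposure_a: str,
    exposure_b: str,
    index: str,
    outcome: str = OUTCOME,
    adjust: Iterable[str] = (),
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for an additive index (patient resampling)."""
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    rng = child_rng(seed, "bootstrap")
    n = len(cohort)
    values = []
    failures = 0
    max_failures = int(0.1 * n_boot)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = cohort.iloc[idx]
        try:
            fit = fit_joint_logistic(sample, exposure_a, exposure_b, outcome, adjust)
            _, value, _ = _index_gradient(index, fit.or10, fit.or01, fit.or11)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            if failures > max_failures:
                raise ValueError(
                    f"bootstrap aborted: {failures}/{n_boot} resamples degenerate "
                    "(empty exposure cell or inestimable fit)"
                ) from None
            continue
        values.append(value)
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# decision rule


@dataclass
class InteractionCall:
    verdict: str  # "synergy" | "antagonism" | "none"
    triggers: tuple[str, ...] = ()
    note: str = ""


def _excludes(ci: tuple[float, float] | None, null: float) -> bool:
    return ci is not None and (ci[0] > null or ci[1] < null)


def classify_additive(ind: AdditiveIndices) -> InteractionCall:
    """Synergy/antagonism verdict from RERI, AP and S with their CIs.

    RERI or AP triggers when its sign is strict and its CI excludes 0; S
    triggers when it departs from 1 with a CI excluding 1. One triggering
    index suffices; indices pointing both ways yield "none" with a note.
    An undefined S never triggers.
    """
    synergy: list[str] = []
    antagonism: list[str] = []
    for name, value, ci, null in (
        ("RERI", ind.reri, ind.ci_reri, 0.0),
        ("AP", ind.ap, ind.ci_ap, 0.0),
        ("S", ind.s, ind.ci_s, 1.0),
    ):
        if np.isnan(value) or not _excludes(ci, null):
            continue
        (synergy if value > null else antagonism).append(name)
    if synergy and antagonism:
        return InteractionCall(
            "none",
            (),
            f"conflicting directions: synergy by {synergy}, antagonism by {antagonism}",
        )
    if synergy:
        return InteractionCall("synergy", tuple(synergy))
    if antagonism:
        return InteractionCall("antagonism", tuple(antagonism))
    return InteractionCall("none", ())


# ---------------------------------------------------------------------------
# multi-level contrasts


def multilevel_contrasts(
    cohort: pd.DataFrame,
    code_a: str,
    exposure: str,
    outcome: str = OUTCOME,
    adjust: Iterable[str] = (),
    level: float = 0.95,
) -> list[tuple[str, AdditiveIndices]]:
    """One binary additive analysis per level pair of a multi-level exposure.

    Each pair (j vs i, j > i) restricts the cohort to those levels, recodes
    level j as exposed, and runs the binary path; contrasts whose levels are
    empty are skipped with a warning.
    """
    levels = sorted(pd.unique(cohort[exposure]))
    if len(levels) < 2:
        raise ValueError(f"exposure {exposure!r} has fewer than 2 observed levels")
    results: list[tuple[str, AdditiveIndices]] = []
    for lo_i in range(len(levels)):
        for hi_j in range(lo_i + 1, len(levels)):
            li, lj = levels[lo_i], levels[hi_j]
            sub = cohort[cohort[exposure].isin([li, lj])].copy()
            label = f"{lj}v{li}"
            if (sub[exposure] == li).sum() == 0 or (sub[exposure] == lj).sum() == 0:
                warnings.warn(f"contrast {label}: empty level, skipped")
                continue
            sub["_contrast"] = (sub[exposure] == lj).astype(int)
            try:
                fit = fit_joint_logistic(sub, code_a, "_contrast", outcome, adjust)
            except ValueError as err:
                warnings.warn(f"contrast {label} skipped: {err}")
                continue
            results.append((label, additive_indices(fit, level=level)))
    return results


# ---------------------------------------------------------------------------
# product-term logistic models


def _coef_table(res, names: Sequence[str], level: float = 0.95) -> pd.DataFrame:
    z = norm.ppf(0.5 + level / 2.0)
    est = np.asarray(res.params)
    se = np.asarray(res.bse)
    stat = est / se
    p = 2.0 * norm.sf(np.abs(stat))
    return pd.DataFrame(
        {
            "estimate": est,
            "std_error": se,
            "statistic": stat,
            "p_value": p,
            "or": np.exp(est),
            "ci_lower": np.exp(est - z * se),
            "ci_upper": np.exp(est + z * se),
        },
        index=list(names),
    )


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear terms)")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as err:  # statsmodels raises several separation flavours
            raise ValueError(f"logistic fit failed (separation or singularity): {err}") from err
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge (quasi-separation likely)")
    return res


def fit_main_effects(
    cohort: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = OUTCOME,
    level: float = 0.95,
) -> pd.DataFrame:
    """Joint multivariable logistic model; one report row per predictor."""
    y = cohort[outcome].to_numpy(dtype=int)
    X = cohort.loc[:, list(predictors)].astype(float)
    X = sm.add_constant(X, has_constant="add")
    res = _fit_logit(y, X)
    table = _coef_table(res, X.columns, level)
    return table.drop(index="const")


@dataclass
class ThreeWayFit:
    """Full-factorial three-way logistic fit; the triple term is the headline."""

    table: pd.DataFrame
    factors: tuple[str, str, str]

    @property
    def triple_term(self) -> str:
        return "*".join(self.factors)

    @property
    def triple_row(self) -> pd.Series:
        return self.table.loc[self.triple_term]

    @property
    def triple_significant(self) -> bool:
        return bool(self.triple_row["p_value"] < 0.05)


def fit_three_way(
    cohort: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    factor_c: str,
    outcome: str = OUTCOME,
    level: float = 0.95,
) -> ThreeWayFit:
    """Logistic model with all mains, pairwise products and the triple product.

    Binary factor combinations are checked for empty joint cells (named in
    the error); rank deficiency (e.g. duplicated factors) raises rather than
    returning silently unstable output.
    """
    names = (factor_a, factor_b, factor_c)
    cols = {n: cohort[n].to_numpy(dtype=float) for n in names}
    y = cohort[outcome].to_numpy(dtype=int)

    if all(np.isin(v, (0.0, 1.0)).all() for v in cols.values()):
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    mask = (
                        (cols[factor_a] == i) & (cols[factor_b] == j) & (cols[factor_c] == k)
                    )
                    if not mask.any():
                        raise ValueError(
                            f"empty joint cell ({factor_a}={i}, {factor_b}={j}, "
                            f"{factor_c}={k}); full factorial not estimable"
                        )

    X = pd.DataFrame(index=cohort.index)
    for n in names:
        X[n] = cols[n]
    X[f"{factor_a}*{factor_b}"] = cols[factor_a] * cols[factor_b]
    X[f"{factor_a}*{factor_c}"] = cols[factor_a] * cols[factor_c]
    X[f"{factor_b}*{factor_c}"] = cols[factor_b] * cols[factor_c]
    X["*".join(names)] = cols[factor_a] * cols[factor_b] * cols[factor_c]
    X = sm.add_constant(X, has_constant="add")
    res = _fit_logit(y, X)
    table = _coef_table(res, X.columns, level).drop(index="const")
    return ThreeWayFit(table=table, factors=names)


# ---------------------------------------------------------------------------
# collinearity screen (pre-check plumbing)


def collinearity_screen(
    cohort: pd.DataFrame, variables: Sequence[str]
) -> tuple[pd.Series, pd.DataFrame]:
    """Variance inflation factors and the pairwise correlation matrix."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    X = cohort.loc[:, list(variables)].astype(float)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    Xc = sm.add_constant(X, has_constant="add")
    vifs = {}
    for i, c in enumerate(variables):
        if c in constant:
            warnings.warn(f"variable {c!r} is constant; VIF undefined")
            vifs[c] = float("nan")
            continue
        with np.errstate(divide="ignore"):
            vifs[c] = float(variance_inflation_factor(Xc.to_numpy(dtype=float), i + 1))
    return pd.Series(vifs, name="vif"), X.corr()


# ---------------------------------------------------------------------------
# reporting


def two_way_report(
    cohort: pd.DataFrame,
    code_a: str,
    exposure_b: str,
    outcome: str = OUTCOME,
    adjust: Iterable[str] = (),
) -> dict:
    """Counts, joint ORs, additive indices and verdict for one exposure pair."""
    fit = fit_joint_logistic(cohort, code_a, exposure_b, outcome, adjust)
    counts = cross_classify(cohort[code_a], cohort[exposure_b], cohort[outcome])
    ind = additive_indices(fit)
    call = classify_additive(ind)
    return {
        "counts": counts,
        "fit": fit,
        "or_table": fit.or_ci(),
        "indices": ind,
        "call": call,
    }
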