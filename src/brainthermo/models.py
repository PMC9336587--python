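"""Mixed-effects temperature models and the logistic mortality model.

Two model families are covered:

* Gaussian linear mixed models for oral and brain temperature with fixed
  effects for chronotype-normalized time of day, sex (reference: luteal
  female), environmental temperature or brain region (reference: Sup1),
  age, BMI or reported in-scanner sleep, and random intercept and
  random time-slope per subject (REML, Wald 95% CIs).
* A binomial-logit model of death in intensive care on age, sex, mean brain
  temperature, brain temperature range and presence of a daily temperature
  rhythm, with death coded 1.  With a single observation per patient the
  per-patient random intercept of the full specification is unidentifiable
  and degenerates to the plain fixed-effects logit fitted here; under
  complete separation a Jeffreys-prior (Firth) penalized fit is used and
  flagged.

Estimates on the log-odds scale are transformed to odds ratios by
exponentiation; transformed CIs become numerically asymmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "ORAL_TEMP_SPEC",
    "BRAIN_TEMP_SPEC",
    "OUTCOME_SPEC",
    "OutcomeModelResult",
    "assemble_model_table",
    "fit_temperature_model",
    "fit_outcome_model",
    "odds_transform",
    "power_simulation",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model specification.

    fixed_effects maps term name -> kind, where kind is "continuous" or the
    reference level of a categorical term.
    """

    response: str
    fixed_effects: dict[str, str]
    random_intercept: bool = True
    random_slope_on: str | None = None
    family: str = "gaussian"  # gaussian | binomial

    def formula(self) -> str:
        terms = []
        for name, kind in self.fixed_effects.items():
            if kind == "continuous":
                terms.append(name)
            else:
                terms.append(f"C({name}, Treatment(reference='{kind}'))")
        return f"{self.response} ~ " + " + ".join(terms)


ORAL_TEMP_SPEC = ModelSpec(
    response="oral_temp_c",
    fixed_effects={
        "time_norm": "continuous",
        "sex": "luteal_female",
        "ed_temp_c": "continuous",
        "age": "continuous",
        "bmi": "continuous",
    },
    random_slope_on="time_norm",
)

BRAIN_TEMP_SPEC = ModelSpec(
    response="brain_temp_c",
    fixed_effects={
        "time_norm": "continuous",
        "sex": "luteal_female",
        "region": "Sup1",
        "age": "continuous",
        "sleep": "no",
    },
    random_slope_on="time_norm",
)

OUTCOME_SPEC = ModelSpec(
    response="died",
    fixed_effects={
        "age": "continuous",
        "sex": "male",
        "brain_mean_c": "continuous",
        "brain_range_c": "continuous",
        "daily_rhythm": "continuous",
    },
    family="binomial",
)


@dataclass
class OutcomeModelResult:
    table: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p, or_, or_low, or_high
    n_used: int
    converged: bool
    penalized: bool = False
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        match = self.table[self.table["term"].str.contains(name, regex=False)]
        if match.empty:
            raise KeyError(name)
        return match.iloc[0]


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

def assemble_model_table(
    sources: pd.DataFrame | list[pd.DataFrame],
    spec: ModelSpec,
    *,
    group_col: str = "subject_id",
) -> tuple[pd.DataFrame, int]:
    """Merge sources and apply complete-case filtering for the spec's terms.

    Rows missing the response or any fixed-effect term are dropped (no
    imputation).  Returns the filtered table and the retained row count.
    """
    if isinstance(sources, pd.DataFrame):
        table = sources.copy()
    else:
        table = sources[0].copy()
        for other in sources[1:]:
            shared = [c for c in other.columns if c in table.columns]
            table = table.merge(other, on=shared, how="left")
    needed = [spec.response, *spec.fixed_effects]
    missing_terms = [c for c in needed if c not in table.columns]
    if missing_terms:
        raise KeyError(f"model terms absent from sources: {missing_terms}")
    out = table.dropna(subset=needed)
    return out, len(out)


# ---------------------------------------------------------------------------
# Gaussian mixed model
# ---------------------------------------------------------------------------

def fit_temperature_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    group_col: str = "subject_id",
    deep_only: bool = False,
) -> OutcomeModelResult:
    """REML linear mixed model with random intercept (and optional random
    time-slope) per subject.

    ``deep_only`` restricts rows to the thalamic and hypothalamic regions
    before fitting.  Subjects must contribute >=2 observations for the
    random slope; otherwise the slope is dropped with a note.  A singular
    random-effects covariance triggers a refit with the intercept-only
    structure, flagged in the notes.
    """
    df = table
    if deep_only:
        df = df[df["region"].isin(["Thalamus", "Hypothalamus"])].copy()
        if spec.fixed_effects.get("region") not in (None, "continuous"):
            fe = dict(spec.fixed_effects)
            fe["region"] = "Thalamus"
            spec = ModelSpec(
                response=spec.response, fixed_effects=fe,
                random_intercept=spec.random_intercept,
                random_slope_on=spec.random_slope_on, family=spec.family,
            )
    df, n_used = assemble_model_table(df, spec, group_col=group_col)
    notes: list[str] = []

    re_formula = None
    if spec.random_slope_on is not None:
        # a subject-level slope needs >=2 distinct time values per subject
        min_distinct = df.groupby(group_col)[spec.random_slope_on].nunique().min()
        if min_distinct >= 2:
            re_formula = f"~{spec.random_slope_on}"
        else:
            notes.append("random slope dropped: <2 distinct time values for some subject")

    def _fit(re_form):
        model = smf.mixedlm(spec.formula(), df, groups=df[group_col], re_formula=re_form)
        last_err = None
        for method in ("lbfgs", "bfgs", "cg"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return model.fit(reml=True, method=method)
            except np.linalg.LinAlgError as err:  # optimizer wandered into a singularity
                last_err = err
        raise last_err

    res = _fit(re_formula)
    if re_formula is not None:
        cov_re = np.asarray(res.cov_re)
        if not np.all(np.linalg.eigvalsh(cov_re) > 1e-8):
            notes.append("singular random-effects covariance: refit intercept-only")
            res = _fit(None)

    # Wald intervals on t quantiles with between-subject df: subject-level
    # effects carry roughly (n_subjects - 1) df, and z-based intervals
    # undercover at cohort sizes in the tens
    n_groups = df[group_col].nunique()
    tcrit = float(stats.t.ppf(0.975, max(n_groups - 1, 2)))

    if not np.all(np.isfinite(np.asarray(res.bse_fe))):
        # the random-effect structure collapsed entirely; the model
        # degenerates to ordinary least squares on the fixed effects
        notes.append("degenerate random effects: ordinary least-squares fit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(spec.formula(), df).fit()
        rows = [
            {"term": term, "estimate": float(ols.params[term]),
             "se": float(ols.bse[term]),
             "ci_low": float(ols.params[term] - tcrit * ols.bse[term]),
             "ci_high": float(ols.params[term] + tcrit * ols.bse[term]),
             "p": float(ols.pvalues[term]), "or_": np.nan,
             "or_low": np.nan, "or_high": np.nan}
            for term in ols.params.index
        ]
        return OutcomeModelResult(
            table=pd.DataFrame(rows), n_used=n_used, converged=True, notes=notes
        )

    rows = []
    for term in res.fe_params.index:
        est = float(res.fe_params[term])
        se = float(res.bse_fe[term])
        lo, hi = est - tcrit * se, est + tcrit * se
        p = float(res.pvalues[term])
        rows.append({"term": term, "estimate": est, "se": se,
                     "ci_low": lo, "ci_high": hi, "p": p,
                     "or_": np.nan, "or_low": np.nan, "or_high": np.nan})
    return OutcomeModelResult(
        table=pd.DataFrame(rows), n_used=n_used,
        converged=bool(res.converged), notes=notes,
    )


# ---------------------------------------------------------------------------
# Binomial-logit outcome model
# ---------------------------------------------------------------------------

def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Jeffreys-prior penalized logistic regression (Firth correction).

    Finite estimates exist even under complete separation.  Returns
    (beta, covariance).
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1 - p)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        # hat diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None] ** 0.5, info_inv, X * w[:, None] ** 0.5)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = expit(eta)
    w = p * (1 - p)
    cov = np.linalg.pinv((X.T * w) @ X)
    return beta, cov


def fit_outcome_model(
    table: pd.DataFrame, spec: ModelSpec = OUTCOME_SPEC
) -> OutcomeModelResult:
    """Maximum-likelihood binomial-logit fit of mortality (death = 1).

    Produces per-term log-odds estimates with Wald 95% CIs and their
    odds-ratio transforms.  Complete separation (or non-convergence /
    exploding estimates) falls back to the Firth-penalized fit, flagged.
    """
    df, n_used = assemble_model_table(table, spec)
    y = df[spec.response].to_numpy(float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary with death coded 1")

    from patsy import dmatrices

    ymat, X = dmatrices(spec.formula(), df, return_type="dataframe")
    names = list(X.columns)
    Xa = X.to_numpy(float)
    ya = ymat.to_numpy(float).ravel()

    penalized = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(ya, Xa, family=sm.families.Binomial()).fit()
        beta = np.asarray(res.params, float)
        cov = np.asarray(res.cov_params(), float)
        ses = np.sqrt(np.diag(cov))
        skip_intercept = 1 if names and names[0] == "Intercept" else 0
        slopes = beta[skip_intercept:]
        slope_ses = ses[skip_intercept:]
        if (
            not np.all(np.isfinite(beta))
            or not np.all(np.isfinite(ses))
            or np.max(np.abs(slopes), initial=0.0) > 15
            or np.max(slope_ses, initial=0.0) > 15
        ):
            raise np.linalg.LinAlgError("separation suspected")
    except Exception:
        beta, cov = _firth_logit(Xa, ya)
        penalized = True

    se = np.sqrt(np.diag(cov))
    rows = []
    for i, term in enumerate(names):
        est, s = float(beta[i]), float(se[i])
        lo, hi = est - 1.96 * s, est + 1.96 * s
        p = 2 * stats.norm.sf(abs(est / s)) if s > 0 else np.nan
        or_, (or_lo, or_hi) = odds_transform(est, (lo, hi))
        rows.append({"term": term, "estimate": est, "se": s, "ci_low": lo,
                     "ci_high": hi, "p": float(p), "or_": or_, "or_low": or_lo,
                     "or_high": or_hi})
    notes = ["Firth-penalized fit (separation or unstable MLE)"] if penalized else []
    return OutcomeModelResult(
        table=pd.DataFrame(rows), n_used=n_used, converged=converged,
        penalized=penalized, notes=notes,
    )


def odds_transform(estimate: float, ci: tuple[float, float]) -> tuple[float, tuple[float, float]]:
    """Log-odds estimate and CI -> odds ratio and transformed CI."""
    return float(np.exp(estimate)), (float(np.exp(ci[0])), float(np.exp(ci[1])))


# ---------------------------------------------------------------------------
# Power simulation
# ---------------------------------------------------------------------------

def power_simulation(
    n_subjects: int = 36,
    true_diff: float = 0.5,
    sd_within: float = 0.35,
    sd_between: float = 0.3,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
    session_times: tuple[float, ...] = (0.21, 0.52, 0.81),
) -> dict:
    """Monte-Carlo power for detecting a diurnal mean-temperature difference.

    Each replicate draws ``n_subjects`` with a random intercept
    (SD ``sd_between``) measured at the given chronotype-normalized session
    times; ``true_diff`` is the mean difference between the first and last
    session.  The time effect is tested on within-subject centred data,
    which for this balanced design is exactly the random-intercept
    mixed-model test.  Returns the rejection fraction with a 95% binomial
    (Wilson) CI.
    """
    if n_reps < 100:
        warnings.warn("n_reps < 100 gives an unstable power estimate")
    rng = np.random.default_rng(seed)
    t = np.asarray(session_times, float)
    span = t[-1] - t[0]
    beta = true_diff / span if span > 0 else 0.0
    S = t.size
    n_total = n_subjects * S
    df_resid = n_total - n_subjects - 1
    tc = t - t.mean()
    denom = n_subjects * float(tc @ tc)
    rejections = 0
    for _ in range(n_reps):
        b = rng.normal(0.0, sd_between, n_subjects)[:, None]
        y = beta * t[None, :] + b + rng.normal(0.0, sd_within, (n_subjects, S))
        yc = y - y.mean(axis=1, keepdims=True)
        bhat = float((yc * tc[None, :]).sum()) / denom
        resid = yc - bhat * tc[None, :]
        sigma2 = float((resid**2).sum()) / df_resid
        se = np.sqrt(sigma2 / denom)
        pval = 2 * stats.t.sf(abs(bhat / se), df_resid)
        rejections += pval < alpha
    power = rejections / n_reps
    z = 1.96
    centre = (power + z**2 / (2 * n_reps)) / (1 + z**2 / n_reps)
    half = (
        z
        * np.sqrt(power * (1 - power) / n_reps + z**2 / (4 * n_reps**2))
        / (1 + z**2 / n_reps)
    )
    return {
        "power": power,
        "ci_low": max(centre - half, 0.0),
        "ci_high": min(centre + half, 1.0),
        "n_reps": n_reps,
        "alpha": alpha,
    }
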