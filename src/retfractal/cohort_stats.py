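"""Cohort association analysis of fractal dimension and cognitive ability.

Implements the statistical design of the study: exclusion rules, IQ-type
rescaling of the childhood test, PCA-derived cognitive domain scores, OLS
association models per (eye x dimension x outcome) cell under three nested
covariate sets, significance and trend counting, contralateral-eye
verification, and the power calculation for a correlation test.

Models: model 1 adjusts for age and sex; model 2 adds childhood IQ;
model 3 adds hypertension, cardiovascular disease, diabetes, stroke and a
current-smoker indicator.  Predictors and outcomes are z-scored on the
per-cell analysis subsample, so the coefficient on the predictor is the
standardized beta per 1 SD of fractal dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort_gen import DEFAULT_DOMAIN_SPEC, DIMENSIONS, DOMAINS, EYES

__all__ = [
    "AssociationResult",
    "MODEL_COVARIATES",
    "apply_exclusions",
    "iq_scale",
    "derive_domain_scores",
    "fit_association",
    "run_grid",
    "count_significant",
    "contralateral_check",
    "power_correlation",
]

MODEL_COVARIATES: dict[int, tuple[str, ...]] = {
    1: ("age", "sex"),
    2: ("age", "sex", "age11_iq"),
    3: (
        "age",
        "sex",
        "age11_iq",
        "hypertension",
        "cardiovascular_disease",
        "diabetes",
        "stroke",
        "current_smoker",
    ),
}


@dataclass(frozen=True)
class AssociationResult:
    model: int
    eye: str
    dimension: str
    outcome: str
    n: int
    beta: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05

    @property
    def trend(self) -> bool:
        return 0.05 <= self.p < 0.10


def apply_exclusions(
    roster: pd.DataFrame, mmse_cutoff: int = 24
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove possible-dementia and ungradable-image participants.

    Rules apply in order — MMSE below the cutoff first, then absence of a
    gradable image — and a participant failing both is counted once, under
    the first rule.  Returns the remaining table and per-rule counts.
    """
    for colname in ("mmse", "gradable"):
        if colname not in roster.columns:
            raise ValueError(f"roster lacks required column {colname!r}")
    low_mmse = roster["mmse"] < mmse_cutoff
    after_mmse = roster[~low_mmse]
    ungradable = after_mmse["gradable"] == 0
    remaining = after_mmse[~ungradable]
    counts = {
        "mmse_below_cutoff": int(low_mmse.sum()),
        "no_gradable_image": int(ungradable.sum()),
    }
    return remaining.reset_index(drop=True), counts


def iq_scale(raw: np.ndarray, age_days: np.ndarray) -> np.ndarray:
    """Age-correct a childhood test score and rescale to IQ units.

    The raw score is residualized on age (linear fit over non-missing
    cases) and the residuals are affinely mapped to mean 100, SD 15 (sample
    SD, n-1).  Missing entries stay missing.
    """
    raw = np.asarray(raw, dtype=float)
    age_days = np.asarray(age_days, dtype=float)
    ok = ~(np.isnan(raw) | np.isnan(age_days))
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing scores")
    slope, intercept = np.polyfit(age_days[ok], raw[ok], 1)
    resid = raw - (slope * age_days + intercept)
    sd = np.nanstd(resid[ok], ddof=1)
    if sd < 1e-12:
        raise ValueError("zero variance after age correction")
    out = np.full_like(raw, np.nan)
    out[ok] = 100.0 + 15.0 * (resid[ok] - resid[ok].mean()) / sd
    return out


def derive_domain_scores(
    subtests: pd.DataFrame,
    domain_spec: dict[str, list[str]] | None = None,
    invert: list[str] | None = None,
) -> pd.DataFrame:
    """First-principal-component domain scores from subtest batteries.

    For each domain, complete-case rows of its subtests are standardized
    and the first unrotated principal component is extracted, sign-oriented
    so that higher means better performance (positive average loading),
    then standardized to mean 0, SD 1.  Rows with any missing subtest get a
    missing domain score.

    ``invert`` names smaller-is-better columns (reaction/inspection times)
    that are negated before the PCA, so all loadings share a sign and the
    orientation is unambiguous; by default the reaction-time subtests of
    the built-in battery are inverted when present.
    """
    domain_spec = domain_spec or DEFAULT_DOMAIN_SPEC
    if invert is None:
        from .cohort_gen import SUBTEST_LOADINGS

        invert = [
            c for c in subtests.columns
            if c in SUBTEST_LOADINGS and SUBTEST_LOADINGS[c][1] < 0
        ]
    out = pd.DataFrame(index=subtests.index)
    for domain, tests in domain_spec.items():
        if len(tests) < 2:
            raise ValueError(f"domain {domain!r} needs at least 2 subtests")
        x = subtests[tests].astype(float)
        for col in tests:
            if col in invert:
                x[col] = -x[col]
        complete = x.dropna()
        z = (complete - complete.mean()) / complete.std(ddof=1)
        _, _, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        pc = vt[0]
        if pc.sum() < 0:  # orient so higher score = better performance
            pc = -pc
        scores = z.to_numpy() @ pc
        scores = (scores - scores.mean()) / scores.std(ddof=1)
        col = pd.Series(np.nan, index=subtests.index)
        col.loc[complete.index] = scores
        out[domain] = col
    return out


def _prepare(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.copy()
    if "current_smoker" not in df.columns and "smoking" in df.columns:
        df["current_smoker"] = (df["smoking"] == "current").astype(int)
    return df


def fit_association(
    cohort: pd.DataFrame,
    model: int,
    eye: str,
    dimension: str,
    outcome: str,
) -> AssociationResult:
    """One cell of the association grid, on complete cases.

    The fractal predictor ``{dimension}_{eye}`` and the outcome are
    z-scored on the analysis subsample (so beta is per 1 SD); covariates
    enter on their natural scale.  Two-sided p from the OLS t statistic.
    """
    if model not in MODEL_COVARIATES:
        raise ValueError(f"unknown model id {model}")
    df = _prepare(cohort)
    predictor = f"{dimension}_{eye}"
    covars = list(MODEL_COVARIATES[model])
    cols = [outcome, predictor] + covars
    data = df[cols].dropna()
    n = len(data)
    if n < len(covars) + 10:
        raise ValueError(
            f"only {n} complete cases for {predictor} -> {outcome} (model {model})"
        )
    y = stats.zscore(data[outcome].to_numpy(), ddof=1)
    x = stats.zscore(data[predictor].to_numpy(), ddof=1)
    design = sm.add_constant(
        np.column_stack([x, data[covars].to_numpy(dtype=float)]), has_constant="add"
    )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"singular design for {predictor} -> {outcome} (model {model}): "
            f"rank {rank} < {design.shape[1]} columns"
        )
    fit = sm.OLS(y, design).fit()
    return AssociationResult(
        model=model,
        eye=eye,
        dimension=dimension,
        outcome=outcome,
        n=n,
        beta=float(fit.params[1]),
        p=float(fit.pvalues[1]),
    )


def run_grid(
    cohort: pd.DataFrame,
    outcomes: tuple[str, ...] = DOMAINS,
    models: tuple[int, ...] = (1, 2, 3),
) -> list[AssociationResult]:
    """All (outcome x dimension x eye x model) association cells.

    With the default three domains, four dimensions, two eyes and three
    models this is the full 72-cell grid (24 tests per model), emitted
    outcome-major with the right eye before the left within each dimension.
    """
    results = []
    for outcome in outcomes:
        for dimension in DIMENSIONS:
            for eye in ("right", "left"):
                for model in models:
                    results.append(
                        fit_association(cohort, model, eye, dimension, outcome)
                    )
    return results


def count_significant(
    results: list[AssociationResult], alpha: float = 0.05, trend: float = 0.10
) -> pd.DataFrame:
    """Per-model counts of significant (p < alpha) and trend cells."""
    if not results:
        raise ValueError("no results to count")
    rows = []
    for model in sorted({r.model for r in results}):
        sub = [r for r in results if r.model == model]
        rows.append(
            {
                "model": model,
                "n_tests": len(sub),
                "significant": sum(r.p < alpha for r in sub),
                "trend": sum(alpha <= r.p < trend for r in sub),
            }
        )
    return pd.DataFrame(rows)


def contralateral_check(
    results: list[AssociationResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Concordance of each association across the two eyes.

    A (dimension, outcome, model) combination is verified only if both eyes
    are significant at ``alpha`` and the betas share a sign; combinations
    with an eye missing are flagged unevaluable rather than unverified.
    """
    key = lambda r: (r.dimension, r.outcome, r.model)
    by_cell: dict[tuple, dict[str, AssociationResult]] = {}
    for r in results:
        by_cell.setdefault(key(r), {})[r.eye] = r
    rows = []
    for (dim, outcome, model), eyes in sorted(by_cell.items()):
        if set(eyes) != {"left", "right"}:
            rows.append(
                {
                    "dimension": dim,
                    "outcome": outcome,
                    "model": model,
                    "evaluable": False,
                    "verified": False,
                }
            )
            continue
        l, r = eyes["left"], eyes["right"]
        verified = (
            l.p < alpha and r.p < alpha and np.sign(l.beta) == np.sign(r.beta)
        )
        rows.append(
            {
                "dimension": dim,
                "outcome": outcome,
                "model": model,
                "evaluable": True,
                "verified": bool(verified),
            }
        )
    return pd.DataFrame(rows)


def power_correlation(n: int, r: float, alpha: float = 0.05) -> float:
    """Two-sided power to detect a correlation ``r`` at sample size ``n``.

    Fisher z approximation: power = Phi(nc - z_{1-alpha/2}) +
    Phi(-nc - z_{1-alpha/2}) with nc = |arctanh(r)| * sqrt(n - 3); the
    second (far-tail) term makes the power exactly alpha at r = 0.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not abs(r) < 1.0:
        raise ValueError("|r| must be < 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    noncentral = abs(np.arctanh(r)) * np.sqrt(n - 3)
    return float(
        stats.norm.cdf(noncentral - z_crit) + stats.norm.cdf(-noncentral - z_crit)
    )
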