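"""Inferential layer over the composite scores.

Covers: linear age/sex models per composite, Spearman inter-composite
correlations, cross-timepoint stability (Spearman, Bonferroni over the 15
composite x pair tests), within-subject percentile stability, paired
contrasts of composite vs single-variable stability, and longitudinal
mixed models linking composites to ASQ behavioral scores.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

TIMEPOINTS = (3, 6, 12)
PAIRS = ((3, 6), (6, 12), (3, 12))

#: Bonferroni family sizes: 5 composites x 3 timepoint pairs; 10 composite
#: pairs for the inter-correlation matrix.
N_STABILITY_TESTS = 15
N_CORR_TESTS = 10


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and p (mean ranks for ties)."""
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Percentile rank of each value among all: rank/(n+1) x 100, mean
    rank for ties.  Invariant under monotone transforms."""
    v = np.asarray(values, dtype=float)
    r = sps.rankdata(v, method="average")
    return r / (v.size + 1) * 100.0


def flag_outliers(values: pd.Series, k: float = 1.5) -> pd.Series:
    """Tukey fences: outside [Q1 - k*IQR, Q3 + k*IQR]."""
    q1, q3 = values.quantile([0.25, 0.75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


# ---------------------------------------------------------------------------
# age / sex effects
# ---------------------------------------------------------------------------

def age_sex_models(scores: pd.DataFrame, composites: list[str] | None = None
                   ) -> pd.DataFrame:
    """Per-composite linear model ``score ~ exact_age + female``.

    ``scores`` is long over assessments with columns ``exact_age`` (months),
    ``female`` (0/1) and one column per composite.  Returns a tidy table of
    coefficients and their standard errors / p-values.
    """
    import statsmodels.formula.api as smf

    if composites is None:
        composites = [c for c in scores.columns
                      if c not in ("participant", "timepoint", "exact_age",
                                   "female")]
    rows = []
    for comp in composites:
        df = scores[["exact_age", "female", comp]].dropna().rename(
            columns={comp: "y"})
        fit = smf.ols("y ~ exact_age + female", data=df).fit()
        for term in ("exact_age", "female"):
            rows.append({"composite": comp, "term": term,
                         "b": fit.params[term], "se": fit.bse[term],
                         "t": fit.tvalues[term], "p": fit.pvalues[term]})
    return pd.DataFrame(rows)


def pool_model_tables(tables: list[pd.DataFrame],
                      keys: tuple = ("composite", "term")) -> pd.DataFrame:
    """Rubin-pool tidy coefficient tables across imputations."""
    from .composites import pool_over_imputations

    cat = pd.concat(tables)
    rows = []
    for key, grp in cat.groupby(list(keys), sort=False):
        pooled = pool_over_imputations(grp["b"].to_numpy(),
                                       grp["se"].to_numpy() ** 2)
        se = np.sqrt(pooled["variance"])
        t = pooled["estimate"] / se if se > 0 else np.nan
        df = pooled["df"]
        p = (2 * sps.t.sf(abs(t), df) if np.isfinite(df)
             else 2 * sps.norm.sf(abs(t)))
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update({"b": pooled["estimate"], "se": se, "t": t,
                    "df": df, "p": p})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations and stability
# ---------------------------------------------------------------------------

def composite_correlations(scores: pd.DataFrame, composites: list[str]
                           ) -> pd.DataFrame:
    """Pairwise Spearman correlations over all pooled assessments, with
    Bonferroni significance over the 10 pairs."""
    rows = []
    for a, b in itertools.combinations(composites, 2):
        df = scores[[a, b]].dropna()
        rho, p = spearman(df[a], df[b])
        rows.append({"a": a, "b": b, "rho": rho, "p": p,
                     "significant": p < 0.05 / N_CORR_TESTS})
    return pd.DataFrame(rows)


@dataclass
class StabilityResult:
    composite: str
    pair: tuple[int, int]
    rho: float
    p: float
    n: int
    significant: bool


def stability_table(scores: pd.DataFrame, composites: list[str],
                    alpha: float = 0.05) -> list[StabilityResult]:
    """Cross-timepoint Spearman stability per composite.

    ``scores`` is long with ``participant`` and ``timepoint`` columns;
    participants missing a timepoint are dropped pairwise.  Significance
    uses the Bonferroni threshold alpha / 15.
    """
    out = []
    thresh = alpha / N_STABILITY_TESTS
    for comp in composites:
        wide = scores.pivot_table(index="participant", columns="timepoint",
                                  values=comp)
        for t1, t2 in PAIRS:
            df = wide[[t1, t2]].dropna()
            if len(df) < 3:
                out.append(StabilityResult(comp, (t1, t2), np.nan, np.nan,
                                           len(df), False))
                continue
            rho, p = spearman(df[t1], df[t2])
            out.append(StabilityResult(comp, (t1, t2), rho, p, len(df),
                                       p < thresh))
    return out


def within_subject_stability(scores: pd.DataFrame, columns: list[str]
                             ) -> pd.DataFrame:
    """Percentile-rank range of each participant across timepoints.

    For each column and timepoint, participants are converted to
    percentile ranks (rank/(n+1) x 100); a participant's instability is
    the max-min range of those ranks across their observed timepoints
    (participants with fewer than two timepoints are excluded).  Returns a
    long table (participant, variable, range, n_timepoints).
    """
    rows = []
    for col in columns:
        sub = scores[["participant", "timepoint", col]].dropna()
        sub = sub.assign(pct=sub.groupby("timepoint")[col]
                         .transform(lambda v: percentile_ranks(v.to_numpy())))
        for pid, grp in sub.groupby("participant"):
            if grp["timepoint"].nunique() < 2:
                continue
            rows.append({"participant": pid, "variable": col,
                         "range": grp["pct"].max() - grp["pct"].min(),
                         "n_timepoints": grp["timepoint"].nunique()})
    return pd.DataFrame(rows)


def stability_contrast(ranges: pd.DataFrame, a: str, b: str) -> dict:
    """Paired t-test of within-subject ranges between two variables.

    ``ranges`` comes from :func:`within_subject_stability`.  Degenerate
    pairs (zero variance of differences) are flagged rather than tested.
    """
    wide = ranges.pivot_table(index="participant", columns="variable",
                              values="range")[[a, b]].dropna()
    d = wide[a] - wide[b]
    if len(d) < 2 or np.allclose(d.var(ddof=1), 0):
        if len(d) >= 2 and np.allclose(d, 0):
            return {"a": a, "b": b, "t": 0.0, "df": len(d) - 1, "p": 1.0,
                    "n": len(d), "degenerate": False}
        return {"a": a, "b": b, "t": np.nan, "df": len(d) - 1, "p": np.nan,
                "n": len(d), "degenerate": True}
    t, p = sps.ttest_rel(wide[a], wide[b])
    return {"a": a, "b": b, "t": float(t), "df": len(d) - 1, "p": float(p),
            "n": len(d), "degenerate": False}


# ---------------------------------------------------------------------------
# ASQ mixed models
# ---------------------------------------------------------------------------

def asq_models(data: pd.DataFrame, outcome: str, composites: list[str],
               reduced: bool = False, outlier_action: str = "keep") -> pd.DataFrame:
    """Longitudinal mixed model of one ASQ outcome on the composites.

    ``data`` is long over assessments with columns ``participant``,
    ``timepoint_index`` (0,1,2), ``exact_age``, ``female``, the composite
    scores and the outcome.  The model has a random intercept per
    participant and a random slope on the assessment index; a singular
    fit falls back to random-intercept-only with a warning.  With
    ``reduced`` only Sleep Day (plus covariates) enters.  Outcome values
    outside the Tukey fences (per timepoint) are dropped when
    ``outlier_action='drop'``.
    """
    import statsmodels.formula.api as smf

    preds = [c for c in composites if not reduced or c == "Sleep Day"]
    cols = ["participant", "timepoint_index", "exact_age", "female",
            outcome] + preds
    df = data[cols].dropna().copy()
    if outlier_action == "drop":
        mask = df.groupby("timepoint_index")[outcome].transform(
            lambda v: flag_outliers(v))
        df = df[~mask.astype(bool)]
    df = df.rename(columns={outcome: "y"})
    df.columns = [c.replace(" ", "_") for c in df.columns]
    terms = " + ".join(["exact_age", "female"]
                       + [p.replace(" ", "_") for p in preds])
    formula = f"y ~ {terms}"

    def _fit(re_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["participant"],
                                re_formula=re_formula)
            return model.fit(reml=True, method="lbfgs", maxiter=200)

    try:
        fit = _fit("~timepoint_index")
        singular = (not fit.converged or
                    np.any(np.diag(fit.cov_re) <= 1e-8))
    except Exception:
        fit, singular = None, True
    if singular:
        warnings.warn("random-slope fit singular; falling back to "
                      "random intercept only", stacklevel=2)
        try:
            fit = _fit("1")
        except Exception:
            warnings.warn("mixed model could not be fit; using OLS",
                          stacklevel=2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.ols(formula, df).fit()

    rows = []
    for term in ["Intercept", "exact_age", "female"] + \
                [p.replace(" ", "_") for p in preds]:
        rows.append({"outcome": outcome, "term": term.replace("_", " "),
                     "b": fit.params[term], "se": fit.bse[term],
                     "t": fit.tvalues[term], "p": fit.pvalues[term]})
    return pd.DataFrame(rows)
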