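"""Dataset-level statistics over collections of NMJ morphometric records.

Operates on a tidy table (one row per NMJ) with categorical factors
``muscle``, ``mouse`` (animal) and ``side`` (L/R) plus the morphometric
variable columns.  The analyses mirror a standard comparative-morphometry
workflow:

* PCA of the 11 core variables on the correlation matrix (variables are
  z-scored - they mix µm, µm² and counts);
* three-way fixed-effects ANOVA (muscle + mouse + side, type-III sums of
  squares, main effects by default);
* Pearson (optionally Spearman) correlation of every NMJ variable with
  axon diameter and with muscle fibre diameter;
* cumulative-mean sampling-adequacy curves;
* inter-observer concordance between two raters' matched tables;
* per-(muscle, mouse) left/right t-tests with Bonferroni correction;
* within-sample coefficient-of-variation summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import CORE_VARIABLES, DERIVED_VARIABLES

__all__ = [
    "PCAResult",
    "AnovaResult",
    "ConcordanceResult",
    "RunningMeanResult",
    "validate_table",
    "pca_core",
    "three_way_anova",
    "diameter_correlations",
    "running_mean_curve",
    "interobserver",
    "left_right_tests",
    "cv_summary",
    "CORE_VARIABLES",
]

FACTORS = ["muscle", "mouse", "side"]

#: Variables correlated against the two diameters: core + derived (18).
NMJ_VARIABLES = CORE_VARIABLES + DERIVED_VARIABLES

#: Sampling adequacy: warn below this many NMJs per sample.
MIN_SAMPLE_WARN = 30
RECOMMENDED_SAMPLE = 40


class StatsError(ValueError):
    pass


def validate_table(df: pd.DataFrame, variables: Sequence[str] = ()) -> pd.DataFrame:
    """Check factor columns and requested variables; return a copy with
    categorical factors.  ``mouse`` falls back to an ``animal`` column."""
    df = df.copy()
    if "mouse" not in df.columns and "animal" in df.columns:
        df = df.rename(columns={"animal": "mouse"})
    for f in FACTORS:
        if f not in df.columns:
            raise StatsError(f"table lacks factor column {f!r}")
        df[f] = df[f].astype("category")
    for v in variables:
        if v not in df.columns:
            raise StatsError(f"table lacks variable column {v!r}")
    key = df[FACTORS + (["nmj"] if "nmj" in df.columns else [])]
    if key.duplicated().any() and "nmj" in df.columns:
        raise StatsError("duplicated (muscle, mouse, side, nmj) keys")
    return df


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA of the core variables."""

    explained_variance: np.ndarray  # % per component, descending
    loadings: pd.DataFrame  # variables x components, unit-norm columns
    scores: pd.DataFrame  # records x components
    mean: pd.Series  # per-variable centering
    scale: pd.Series  # per-variable scaling (SD)
    variables: tuple


@dataclass(frozen=True)
class AnovaResult:
    """Type-III three-way ANOVA for one response variable."""

    response: str
    table: pd.DataFrame  # rows: factors (+ residual); cols: sum_sq, df, F, p
    model: str

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-variable Pearson concordance between two raters."""

    table: pd.DataFrame  # index: variable; cols: r, p, n


@dataclass(frozen=True)
class RunningMeanResult:
    """Cumulative-mean curve and its plateau diagnostic."""

    means: np.ndarray  # m_k = mean of first k values
    plateau_deviation: float  # max |m_k - m_n| / |m_n| over k >= 30


def pca_core(
    table: pd.DataFrame, variables: Sequence[str] = CORE_VARIABLES
) -> PCAResult:
    """PCA of the core morphometric variables after z-scoring.

    Variables are centred and scaled to unit SD (correlation-matrix PCA)
    because they mix incommensurate units.  Components are sorted by
    explained variance; loadings columns have unit norm, scores are the
    z-scored data projected onto them.
    """
    variables = list(variables)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise StatsError(f"PCA variables missing from table: {missing}")
    X = table[variables].to_numpy(dtype=float)
    if len(X) < 2:
        raise StatsError("PCA needs at least 2 records")
    if np.isnan(X).any():
        raise StatsError("PCA input contains missing values")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    const = [v for v, s in zip(variables, scale) if s == 0]
    if const:
        raise StatsError(f"constant variable(s) in PCA input: {const}")
    Z = (X - mean) / scale

    from sklearn.decomposition import PCA as _PCA

    n_comp = min(Z.shape)
    p = _PCA(n_components=n_comp, svd_solver="full")
    scores = p.fit_transform(Z)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        explained_variance=100.0 * p.explained_variance_ratio_,
        loadings=pd.DataFrame(p.components_.T, index=variables, columns=comp_names),
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        mean=pd.Series(mean, index=variables),
        scale=pd.Series(scale, index=variables),
        variables=tuple(variables),
    )


def three_way_anova(
    table: pd.DataFrame, response: str, interactions: bool = False
) -> AnovaResult:
    """Fixed-effects ANOVA of one response on muscle + mouse + side.

    Type-III sums of squares with sum-to-zero contrasts; all three factors
    are fixed.  ``interactions=True`` adds the two-way interaction terms.
    """
    df = validate_table(table, [response])
    for f in FACTORS:
        if df[f].nunique() < 2:
            raise StatsError(f"factor {f!r} has a single level")
    if df[response].nunique() <= 1:
        raise StatsError(f"response {response!r} is constant")

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    work = df[FACTORS + [response]].rename(columns={response: "_y"})
    terms = [f"C({f}, Sum)" for f in FACTORS]
    if interactions:
        terms += [
            "C(muscle, Sum):C(mouse, Sum)",
            "C(muscle, Sum):C(side, Sum)",
            "C(mouse, Sum):C(side, Sum)",
        ]
    formula = "_y ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=work).fit()
    aov = sm.stats.anova_lm(fit, typ=3)
    aov = aov.rename(columns={"PR(>F)": "p"})
    idx = {f"C({f}, Sum)": f for f in FACTORS}
    aov = aov.rename(index=idx)
    aov = aov.drop(index="Intercept", errors="ignore")
    return AnovaResult(response=response, table=aov, model=formula)


def diameter_correlations(
    table: pd.DataFrame,
    variables: Sequence[str] = NMJ_VARIABLES,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate each NMJ variable with axon and muscle fibre diameter.

    Returns one row per variable with r and p against each diameter,
    computed over individual NMJs.  ``method`` is ``"pearson"`` (default)
    or ``"spearman"``.
    """
    corr = {"pearson": sps.pearsonr, "spearman": sps.spearmanr}[method]
    for col in ("axon_diameter", "muscle_fibre_diameter"):
        if col not in table.columns:
            raise StatsError(f"table lacks {col!r}")
    rows = []
    for v in variables:
        if v not in table.columns:
            continue
        sub = table[[v, "axon_diameter", "muscle_fibre_diameter"]].dropna()
        x = sub[v].to_numpy(dtype=float)
        if len(x) < 3:
            raise StatsError(f"too few complete observations for {v!r}")
        if np.std(x) == 0:
            raise StatsError(f"zero-variance variable {v!r}")
        ra, pa = corr(x, sub["axon_diameter"])
        rf, pf = corr(x, sub["muscle_fibre_diameter"])
        rows.append(
            {
                "variable": v,
                "r_axon": float(ra),
                "p_axon": float(pa),
                "r_fibre": float(rf),
                "p_fibre": float(pf),
                "n": len(x),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def running_mean_curve(values: Sequence[float]) -> RunningMeanResult:
    """Cumulative mean of successive measurements (sampling adequacy).

    ``m_k`` is the mean of the first k values.  The plateau diagnostic is
    ``max_{k >= 30} |m_k - m_n| / |m_n|`` (over all k when n < 30): small
    values mean the running mean has settled by the 30-sample mark.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise StatsError("empty measurement series")
    means = np.cumsum(x) / np.arange(1, x.size + 1)
    k0 = min(MIN_SAMPLE_WARN, x.size)
    final = means[-1]
    tail = np.abs(means[k0 - 1 :] - final)
    plateau = float(tail.max() / abs(final)) if final != 0 else float(tail.max())
    return RunningMeanResult(means=means, plateau_deviation=plateau)


def interobserver(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    variables: Sequence[str] = NMJ_VARIABLES,
    keys: Sequence[str] = ("muscle", "mouse", "side", "nmj"),
) -> ConcordanceResult:
    """Pearson concordance between two raters measuring the same NMJs."""
    keys = [k for k in keys if k in table_a.columns]
    if not keys:
        raise StatsError("no key columns to match records on")
    a = table_a.set_index(keys).sort_index()
    b = table_b.set_index(keys).sort_index()
    if not a.index.equals(b.index):
        raise StatsError("the two tables do not contain the same NMJ keys")
    rows = []
    for v in variables:
        if v not in a.columns or v not in b.columns:
            continue
        xa = a[v].to_numpy(dtype=float)
        xb = b[v].to_numpy(dtype=float)
        ok = ~(np.isnan(xa) | np.isnan(xb))
        if ok.sum() < 3:
            continue
        r, p = sps.pearsonr(xa[ok], xb[ok])
        rows.append({"variable": v, "r": float(r), "p": float(p), "n": int(ok.sum())})
    return ConcordanceResult(table=pd.DataFrame(rows).set_index("variable"))


def left_right_tests(
    table: pd.DataFrame, variable: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Unpaired t-test of L vs R per (muscle, mouse), Bonferroni-corrected.

    One comparison per muscle/mouse pair; the family-wise threshold is
    ``alpha`` divided by the number of comparisons.  Returns a table with
    raw and Bonferroni-adjusted p-values and a significance flag.
    """
    df = validate_table(table, [variable])
    rows = []
    for (muscle, mouse), grp in df.groupby(["muscle", "mouse"], observed=True):
        left = grp.loc[grp["side"] == "L", variable].dropna()
        right = grp.loc[grp["side"] == "R", variable].dropna()
        if len(left) < 2 or len(right) < 2:
            raise StatsError(
                f"missing or degenerate side for muscle={muscle}, mouse={mouse}"
            )
        t, p = sps.ttest_ind(left, right)
        rows.append(
            {
                "muscle": muscle,
                "mouse": mouse,
                "n_left": len(left),
                "n_right": len(right),
                "mean_left": float(left.mean()),
                "mean_right": float(right.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def cv_summary(
    table: pd.DataFrame,
    variables: Sequence[str] = CORE_VARIABLES,
    interval: tuple[float, float] = (5.0, 95.0),
) -> dict:
    """Coefficient-of-variation summary across within-sample groups.

    A *sample* is one muscle from one side of one animal.  For every sample
    with >= 2 records and every variable, CV = SD/mean; the pooled CVs are
    summarised by their median and central 90% interval (5th-95th
    percentiles by default).  Samples with a single record are excluded
    with a warning; a zero-mean variable within a sample is an error.
    """
    df = validate_table(table, variables)
    cvs = []
    n_single = 0
    for _, grp in df.groupby(FACTORS, observed=True):
        if len(grp) < 2:
            n_single += 1
            continue
        for v in variables:
            vals = grp[v].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                continue
            mean = vals.mean()
            if mean == 0:
                raise StatsError(f"zero-mean variable {v!r} within a sample")
            cvs.append(vals.std(ddof=1) / abs(mean))
    if n_single:
        warnings.warn(f"excluded {n_single} single-record sample(s) from CV summary")
    if not cvs:
        raise StatsError("no samples with >= 2 records")
    cvs = np.asarray(cvs)
    lo, hi = np.percentile(cvs, interval)
    return {
        "median_cv": float(np.median(cvs)),
        "interval": (float(lo), float(hi)),
        "n_cvs": int(cvs.size),
    }


def sample_size_warnings(table: pd.DataFrame, threshold: int = MIN_SAMPLE_WARN):
    """Per-(muscle, mouse, side) group sizes below the adequacy threshold."""
    df = validate_table(table)
    sizes = df.groupby(FACTORS, observed=True).size()
    return sizes[sizes < threshold]
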