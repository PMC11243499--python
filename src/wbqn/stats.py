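"""Group statistics and ordinal regression for scored cohorts.

Reproduces the analytical toolkit of the study design: robust group
summaries (5% trimmed mean, IQR), Kruskal-Wallis comparisons of skewed
continuous variables, chi-square tests of proportions, water-balance
quartile tables, and proportional-odds (cumulative logit) ordinal
regression of balance quartiles on participant descriptors, with a
likelihood-ratio check of the parallel-lines assumption.

"Ordinary logistic regression" on an ordered four-level outcome with a
parallelism test is read as ordinal proportional-odds regression; the model
is exposed statsmodels-style (`ProportionalOddsModel(...).fit()` returning a
results object with a `summary()` table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.discrete.discrete_model import MNLogit
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "trimmed_mean_5",
    "iqr",
    "kruskal_wallis",
    "chi_square_independence",
    "group_summaries",
    "categorical_group_summary",
    "QuartileTable",
    "build_quartile_table",
    "ProportionalOddsModel",
    "ProportionalOddsResults",
    "ParallelLinesTest",
    "fit_proportional_odds",
    "test_parallel_lines",
    "per_predictor_fits",
]

QUARTILE_LEVELS = ("Q1", "Q2", "Q3", "Q4")


# ---------------------------------------------------------------------------
# descriptive statistics


def trimmed_mean_5(values) -> float:
    """5% trimmed mean: drop the floor(0.05 n) smallest and largest values,
    then average. Trims nothing below n = 20."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("trimmed mean of an empty sample")
    if not np.isfinite(x).all():
        raise ValueError("trimmed mean requires finite values")
    return float(sps.trim_mean(x, 0.05))


def trimmed_mean_se(values, proportion: float = 0.05) -> float:
    """Standard error of the trimmed mean: winsorized SD / ((1-2p) sqrt(n))."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("standard error needs at least two values")
    k = int(np.floor(proportion * n))
    w = np.clip(x, x[k], x[n - 1 - k])
    return float(w.std(ddof=1) / ((1 - 2 * proportion) * np.sqrt(n)))


def iqr(values) -> float:
    """Interquartile range (P75 - P25, linear interpolation)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("IQR of an empty sample")
    q25, q75 = np.percentile(x, [25, 75])
    return float(q75 - q25)


def kruskal_wallis(groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 2 groups, tie-corrected; the p-value
    uses the chi-square reference with k - 1 df. Degenerate pooled samples
    (all values identical) give H = 0, p = 1."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("Kruskal-Wallis: empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on an r x c count table
    (no continuity correction), (r-1)(c-1) df."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH false-discovery-rate adjusted p-values (optional; raw p-values are
    reported by default, matching the study design)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def group_summaries(
    scored: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-variable, per-group 5% trimmed mean (IQR) with a Kruskal-Wallis
    comparison across groups. Rows with a missing value for a variable are
    excluded from that variable's summary and counted in ``n_missing``."""
    groups = list(dict.fromkeys(scored[group_col]))
    rows = []
    for var in variables:
        per_group = {}
        samples = []
        n_missing = 0
        for g in groups:
            vals = scored.loc[scored[group_col] == g, var]
            n_missing += int(vals.isna().sum())
            vals = vals.dropna().to_numpy(dtype=float)
            per_group[g] = vals
            samples.append(vals)
        h, p = kruskal_wallis(samples)
        row = {"variable": var, "test": "kruskal-wallis",
               "statistic": h, "p_value": p, "n_missing": n_missing}
        for g in groups:
            row[f"{g}_trimmed_mean"] = trimmed_mean_5(per_group[g])
            row[f"{g}_iqr"] = iqr(per_group[g])
            row[f"{g}_n"] = per_group[g].size
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["p_adjusted"] = benjamini_hochberg(out["p_value"])
    return out


def categorical_group_summary(
    scored: pd.DataFrame, variable: str, group_col: str = "group"
) -> dict:
    """Cross-tabulation of a categorical variable by group with a chi-square
    test of equal proportions."""
    table = pd.crosstab(scored[variable], scored[group_col])
    stat, p = chi_square_independence(table.to_numpy())
    return {"variable": variable, "counts": table, "test": "chi-square",
            "statistic": stat, "p_value": p}


# ---------------------------------------------------------------------------
# quartile table


@dataclass
class QuartileTable:
    """Counts and summaries of scored variables by water-balance quartile,
    within each breastfeeding group."""

    cutoffs: tuple[float, float, float]
    counts: pd.DataFrame          # group x quartile participant counts
    summaries: pd.DataFrame       # per group/variable/quartile trimmed mean+IQR
    tests: pd.DataFrame           # per group/variable KW p across quartiles

    def to_dict(self) -> dict:
        return {
            "cutoffs": list(self.cutoffs),
            "counts": {g: row.to_dict() for g, row in self.counts.iterrows()},
            "summaries": self.summaries.to_dict(orient="records"),
            "tests": self.tests.to_dict(orient="records"),
        }


def build_quartile_table(
    scored: pd.DataFrame,
    variables: Sequence[str] = (
        "intake_total", "intake_liquids_excl_water", "intake_drinking_water",
        "intake_foods", "loss_total", "loss_urine", "loss_feces", "loss_sweat",
    ),
    cutoffs: Optional[Sequence[float]] = None,
    group_col: str = "group",
) -> QuartileTable:
    """Build the quartile distribution table from a scored cohort.

    Quartiles come from the ``quartile`` column if present (and ``cutoffs``
    is None they are recomputed from the pooled balance distribution).
    """
    if len(scored) == 0:
        raise ValueError("cannot build a quartile table from an empty cohort")
    from .scoring import quartile_labels  # lazy: avoid import cycle
    from .config import ScoringConfig

    if cutoffs is not None:
        c = tuple(float(v) for v in cutoffs)
        labels = quartile_labels(
            scored["balance_observed"].to_numpy(),
            ScoringConfig(quartile_cutoffs=c),
        )
    elif "quartile" in scored.columns:
        balance = scored["balance_observed"].to_numpy()
        c = tuple(np.quantile(balance, [0.25, 0.5, 0.75]))
        labels = scored["quartile"].to_numpy()
    else:
        balance = scored["balance_observed"].to_numpy()
        c = tuple(np.quantile(balance, [0.25, 0.5, 0.75]))
        labels = quartile_labels(balance, ScoringConfig(quartile_cutoffs=c))

    work = scored.assign(_q=labels)
    counts = (
        pd.crosstab(work[group_col], work["_q"])
        .reindex(columns=QUARTILE_LEVELS, fill_value=0)
    )
    srows, trows = [], []
    for g, sub in work.groupby(group_col, sort=False):
        for var in variables:
            per_q = []
            for q in QUARTILE_LEVELS:
                vals = sub.loc[sub["_q"] == q, var].dropna().to_numpy(dtype=float)
                per_q.append(vals)
                srows.append({
                    "group": g, "variable": var, "quartile": q,
                    "n": vals.size,
                    "trimmed_mean": trimmed_mean_5(vals) if vals.size else np.nan,
                    "iqr": iqr(vals) if vals.size else np.nan,
                })
            occupied = [v for v in per_q if v.size]
            if len(occupied) >= 2:
                h, p = kruskal_wallis(occupied)
            else:
                h, p = np.nan, np.nan
            trows.append({"group": g, "variable": var,
                          "statistic": h, "p_value": p})
    return QuartileTable(
        cutoffs=c, counts=counts,
        summaries=pd.DataFrame(srows), tests=pd.DataFrame(trows),
    )


# ---------------------------------------------------------------------------
# proportional-odds ordinal regression


@dataclass
class ParallelLinesTest:
    """Likelihood-ratio test of the proportional-odds (parallel lines)
    assumption against an unconstrained multinomial alternative."""

    statistic: float
    p_value: float
    df: int
    indeterminate: bool = False


class ProportionalOddsResults:
    """Fitted proportional-odds model: estimates, uncertainty, diagnostics."""

    def __init__(self, smres, exog_names: list[str], endog: np.ndarray,
                 exog: np.ndarray, alpha: float = 0.05):
        self._res = smres
        self.exog_names = exog_names
        self._endog = endog
        self._exog = exog
        self.alpha = alpha
        k = len(np.unique(endog))
        self.n_levels = k
        p = len(exog_names)
        params = np.asarray(smres.params)
        self.params = pd.Series(params[:p], index=exog_names)
        self.bse = pd.Series(np.asarray(smres.bse)[:p], index=exog_names)
        self.pvalues = pd.Series(np.asarray(smres.pvalues)[:p], index=exog_names)
        ci = np.asarray(smres.conf_int(alpha))[:p]
        self.conf_int = pd.DataFrame(ci, index=exog_names,
                                     columns=["lower", "upper"])
        # actual ordered cut-points (the per-quartile-boundary estimates)
        thr = smres.model.transform_threshold_params(np.asarray(smres.params))
        self.thresholds = np.asarray(thr[1:-1], dtype=float)
        self.llf = float(smres.llf)
        self.nobs = int(smres.nobs)
        self.converged = bool(getattr(smres, "mle_retvals", {}).get(
            "converged", True))
        if np.any(np.abs(self.params.to_numpy()) > 15):
            warnings.warn(
                "very large coefficient magnitude: possible (quasi-)separation",
                RuntimeWarning, stacklevel=3,
            )

    def test_parallel_lines(self) -> ParallelLinesTest:
        """LR comparison of the proportional-odds fit against an unconstrained
        multinomial logit on the same design; df = (k - 2) x p predictors."""
        k, p = self.n_levels, len(self.exog_names)
        df = (k - 2) * p
        x = np.column_stack([np.ones(len(self._endog)), self._exog])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mn = MNLogit(self._endog, x).fit(disp=False, maxiter=300)
            converged = bool(mn.mle_retvals.get("converged", True))
        except Exception:
            return ParallelLinesTest(np.nan, np.nan, df, indeterminate=True)
        if not converged or not np.isfinite(mn.llf):
            return ParallelLinesTest(np.nan, np.nan, df, indeterminate=True)
        stat = max(0.0, 2.0 * (float(mn.llf) - self.llf))
        return ParallelLinesTest(stat, float(sps.chi2.sf(stat, df)), df)

    def summary(self) -> str:
        lines = [
            "Proportional-odds (cumulative logit) regression",
            f"  n = {self.nobs}, outcome levels = {self.n_levels}, "
            f"log-likelihood = {self.llf:.3f}, converged = {self.converged}",
            "",
            f"  {'predictor':<28}{'coef':>10}{'se':>9}"
            f"{'[' + format(100 * (1 - self.alpha), '.0f') + '% CI]':>22}{'p':>9}",
        ]
        for name in self.exog_names:
            lo, hi = self.conf_int.loc[name]
            lines.append(
                f"  {name:<28}{self.params[name]:>10.4f}{self.bse[name]:>9.4f}"
                f"{f'({lo:.3f}, {hi:.3f})':>22}{self.pvalues[name]:>9.4f}"
            )
        lines.append("")
        for i, t in enumerate(self.thresholds, start=1):
            lines.append(f"  threshold Q{i}|Q{i + 1}: {t:.4f}")
        pl = self.test_parallel_lines()
        if pl.indeterminate:
            lines.append("  parallel-lines test: indeterminate "
                         "(unconstrained model did not converge)")
        else:
            lines.append(
                f"  parallel-lines LR = {pl.statistic:.3f} "
                f"(df={pl.df}), p = {pl.p_value:.4f}"
            )
        return "\n".join(lines)


class ProportionalOddsModel:
    """Cumulative-logit model with proportional odds for an ordered outcome.

    P(Y <= j | x) = logistic(theta_j - x'beta); a single coefficient vector
    beta is shared across all outcome thresholds (the parallel-lines
    assumption, testable via the results object).
    """

    def __init__(self, endog, exog, exog_names: Optional[list[str]] = None):
        endog = np.asarray(endog)
        levels = np.unique(endog)
        if levels.size < 3:
            raise ValueError("ordinal outcome needs at least 3 ordered levels")
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        if exog_names is None:
            exog_names = [f"x{i + 1}" for i in range(exog.shape[1])]
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            raise ValueError("design matrix is rank deficient")
        # map outcome onto 0..k-1 in sorted-level order
        self._codes = np.searchsorted(levels, endog)
        self._exog = exog
        self.exog_names = exog_names

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str = "quartile",
        predictors: Sequence[str] = (),
    ) -> "ProportionalOddsModel":
        sub = data[[outcome, *predictors]].dropna()
        endog = sub[outcome]
        if endog.dtype == object:
            order = [q for q in QUARTILE_LEVELS if q in set(endog)]
            endog = endog.map({q: i for i, q in enumerate(order)}).to_numpy()
        else:
            endog = endog.to_numpy()
        return cls(endog, sub[list(predictors)].to_numpy(dtype=float),
                   exog_names=list(predictors))

    def fit(self, method: str = "bfgs", maxiter: int = 300,
            alpha: float = 0.05) -> ProportionalOddsResults:
        model = OrderedModel(self._codes, self._exog, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method=method, maxiter=maxiter, disp=False)
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(method="lbfgs", maxiter=2 * maxiter, disp=False)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError(
                    "proportional-odds fit did not converge; "
                    f"retvals: {res.mle_retvals}"
                )
        return ProportionalOddsResults(
            res, self.exog_names, self._codes, self._exog, alpha=alpha
        )


def fit_proportional_odds(
    outcome, predictors, exog_names: Optional[list[str]] = None,
) -> ProportionalOddsResults:
    """Functional surface over :class:`ProportionalOddsModel`."""
    return ProportionalOddsModel(outcome, predictors, exog_names).fit()


def test_parallel_lines(fit: ProportionalOddsResults) -> ParallelLinesTest:
    """Functional surface over the results object's parallel-lines test."""
    return fit.test_parallel_lines()


DEFAULT_REGRESSION_PREDICTORS: tuple[str, ...] = (
    "bmi", "age", "education_years",
    "intake_drinking_water", "intake_foods", "intake_juice",
    "intake_soft_drink", "intake_tea", "intake_coffee", "intake_milk",
    "intake_milkshake_sherbet", "intake_isotonic_energy", "intake_alcoholic",
)


def per_predictor_fits(
    scored: pd.DataFrame,
    predictors: Sequence[str] = DEFAULT_REGRESSION_PREDICTORS,
    outcome: str = "quartile",
) -> pd.DataFrame:
    """One proportional-odds model per predictor of the balance quartile,
    reporting the coefficient (95% CI, p) alongside the per-boundary
    threshold estimates and the parallel-lines check."""
    rows = []
    for pred in predictors:
        if pred not in scored.columns:
            continue
        fit = ProportionalOddsModel.from_dataframe(
            scored, outcome=outcome, predictors=[pred]).fit()
        pl = fit.test_parallel_lines()
        row = {
            "predictor": pred,
            "estimate": fit.params[pred],
            "ci_lower": fit.conf_int.loc[pred, "lower"],
            "ci_upper": fit.conf_int.loc[pred, "upper"],
            "p_value": fit.pvalues[pred],
            "parallel_lines_stat": pl.statistic,
            "parallel_lines_p": pl.p_value,
        }
        for i, t in enumerate(fit.thresholds, start=1):
            row[f"threshold_q{i}"] = t
        rows.append(row)
    return pd.DataFrame(rows)


def group_dummies(scored: pd.DataFrame, reference: str = "none") -> pd.DataFrame:
    """Indicator columns for breastfeeding group against a reference level
    (e.g. exclusive-vs-none, mixed-vs-none)."""
    out = pd.DataFrame(index=scored.index)
    for g in dict.fromkeys(scored["group"]):
        if g != reference:
            out[f"{g}_vs_{reference}"] = (scored["group"] == g).astype(float)
    return out
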