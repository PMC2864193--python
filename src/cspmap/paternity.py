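"""Second-male paternity statistics for double-mating sperm-competition assays.

A doubly-mated female's progeny are scored by a recessive body-colour marker:
offspring sired by the first (marker) male are mutant, offspring sired by the
second (tester) male are wild type.  P2 is the wild-type fraction of the
progeny produced after the second mating; it is arcsine-square-root
transformed (TP2) before ANOVA, with post-remating fecundity as a covariate
and line and block as crossed factors.  Lines whose mean P2 is not
significantly higher than a heterospecific baseline male are flagged as
showing a breakdown in second-male paternity success.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRIAL_COLUMNS",
    "compute_p2",
    "angular_transform",
    "add_paternity_records",
    "filter_trials",
    "fit_ancova",
    "one_way_anova",
    "pearson_correlation",
    "baseline_comparison",
    "line_summaries",
    "flag_breakdown_lines",
    "AnovaTable",
    "CorrelationResult",
    "BaselineTest",
]

TRIAL_COLUMNS = ("female_id", "line_id", "block",
                 "vial1_ebony", "vial23_wildtype", "vial23_ebony")


class UndefinedP2Error(ValueError):
    """No progeny after the second mating: P2 is undefined."""


def compute_p2(vial23_wildtype: int, vial23_ebony: int) -> float:
    """Fraction of post-remating progeny sired by the second (wild-type) male."""
    total = vial23_wildtype + vial23_ebony
    if total <= 0:
        raise UndefinedP2Error("no progeny in vials 2+3; P2 undefined")
    if vial23_wildtype < 0 or vial23_ebony < 0:
        raise ValueError("progeny counts must be non-negative")
    return vial23_wildtype / total


def angular_transform(p) -> float:
    """Arcsine-square-root transform, arcsin(sqrt(p)), in radians.

    The standard variance-stabilising transform for proportions; maps
    [0, 1] monotonically onto [0, pi/2].
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("proportion outside [0, 1]")
    out = np.arcsin(np.sqrt(p_arr))
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


def add_paternity_records(trials: pd.DataFrame) -> pd.DataFrame:
    """Append ``p2``, ``tp2`` and ``fecundity`` columns to a trial table.

    Rows with zero progeny after the second mating get NaN P2; they are
    removed by :func:`filter_trials` before analysis.
    """
    df = trials.copy()
    total = df["vial23_wildtype"] + df["vial23_ebony"]
    df["fecundity"] = total
    with np.errstate(invalid="ignore", divide="ignore"):
        p2 = df["vial23_wildtype"] / total
    df["p2"] = p2.where(total > 0, np.nan)
    df["tp2"] = np.arcsin(np.sqrt(df["p2"]))
    return df


def filter_trials(trials: pd.DataFrame, policy: str = "full",
                  min_fecundity: int = 20, min_males_per_line: int = 10) -> pd.DataFrame:
    """Apply the analysis inclusion rules.

    ``full``
        Keep only females that mated successfully with both males
        (mutant progeny in vial 1, any progeny in vials 2+3).
    ``restricted``
        Additionally drop females with fewer than ``min_fecundity``
        post-remating progeny, then drop whole lines left with fewer than
        ``min_males_per_line`` successfully mated males.
    """
    if policy not in ("full", "restricted"):
        raise ValueError(f"unknown filter policy: {policy!r}")
    df = trials if "fecundity" in trials.columns else add_paternity_records(trials)
    kept = df[(df["vial1_ebony"] > 0) & (df["fecundity"] > 0)].copy()
    if policy == "restricted":
        kept = kept[kept["fecundity"] >= min_fecundity]
        counts = kept.groupby("line_id")["female_id"].transform("size")
        kept = kept[counts >= min_males_per_line]
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ANOVA machinery: sequential (Type I) sums of squares from nested designs
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Sequential-SS decomposition; one row per model term plus residual."""

    table: pd.DataFrame          # index: term; columns: ss, df, ms, F, p
    total_ss: float
    n_obs: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def f_stat(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _dummies(values: pd.Series) -> np.ndarray:
    """Treatment-coded indicator columns (first level dropped)."""
    levels = pd.unique(values)
    cols = [(values == lv).to_numpy(float) for lv in levels[1:]]
    if not cols:
        return np.empty((len(values), 0))
    return np.column_stack(cols)


def _term_blocks(df: pd.DataFrame, covariate: Optional[str],
                 factors: Sequence[str], interaction: bool) -> List[Tuple[str, np.ndarray]]:
    blocks: List[Tuple[str, np.ndarray]] = []
    if covariate is not None:
        blocks.append((covariate, df[covariate].to_numpy(float)[:, None]))
    fac_dummies = {f: _dummies(df[f].astype(str)) for f in factors}
    for f in factors:
        blocks.append((f, fac_dummies[f]))
    if interaction and len(factors) == 2:
        a, b = (fac_dummies[f] for f in factors)
        if a.shape[1] and b.shape[1]:
            inter = np.einsum("ni,nj->nij", a, b).reshape(len(df), -1)
        else:
            inter = np.empty((len(df), 0))
        blocks.append((f"{factors[0]}:{factors[1]}", inter))
    return blocks


def _rss_and_rank(X: np.ndarray, y: np.ndarray) -> Tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def fit_ancova(records: pd.DataFrame, response: str = "tp2",
               covariate: Optional[str] = "fecundity",
               factors: Sequence[str] = ("line_id", "block"),
               interaction: bool = True) -> AnovaTable:
    """Covariate-adjusted ANOVA of transformed paternity scores.

    Least-squares fit of ``response`` on the covariate (continuous) plus the
    factors and their interaction (treatment coded), with sequential Type-I
    sums of squares in the stated term order.  Degrees of freedom use the
    realized design-matrix rank, so missing line-by-block cells are handled
    naturally.  F for each term is its mean square over the residual mean
    square.
    """
    df = records.dropna(subset=[response] + ([covariate] if covariate else []))
    n = len(df)
    if n < 3 or df[factors[0]].nunique() < 2:
        raise ValueError("need >= 2 lines and >= 3 usable observations")
    y = df[response].to_numpy(float)
    total_ss = float(((y - y.mean()) ** 2).sum())

    blocks = _term_blocks(df, covariate, factors, interaction)
    X = np.ones((n, 1))
    rss_prev, rank_prev = _rss_and_rank(X, y)
    rows = []
    for name, cols in blocks:
        X = np.hstack([X, cols])
        rss, rank = _rss_and_rank(X, y)
        rows.append((name, rss_prev - rss, rank - rank_prev))
        rss_prev, rank_prev = rss, rank

    resid_df = n - rank_prev
    if resid_df <= 0:
        raise ValueError("saturated model: zero residual degrees of freedom")
    resid_ms = rss_prev / resid_df

    out = []
    degenerate = total_ss <= 1e-12 or resid_ms <= 0
    for name, ss, dfree in rows:
        ss = max(ss, 0.0)
        ms = ss / dfree if dfree > 0 else np.nan
        if dfree > 0 and not degenerate:
            F = ms / resid_ms
            p = float(stats.f.sf(F, dfree, resid_df))
        else:
            F, p = np.nan, np.nan
        out.append({"term": name, "ss": ss, "df": dfree, "ms": ms, "F": F, "p": p})
    out.append({"term": "residual", "ss": rss_prev, "df": resid_df,
                "ms": resid_ms, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(out).set_index("term")
    return AnovaTable(table=table, total_ss=total_ss, n_obs=n)


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaTable:
    """Standard one-way decomposition (used for copulation-duration checks)."""
    df = pd.DataFrame({"y": np.asarray(values, float), "g": list(groups)})
    if df["g"].nunique() < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    return fit_ancova(df, response="y", covariate=None, factors=("g",),
                      interaction=False)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=len(x), p_value=float(p))


# ---------------------------------------------------------------------------
# Baseline comparison: is a line significantly better than the heterospecific?
# ---------------------------------------------------------------------------

@dataclass
class BaselineTest:
    line_id: str
    n_line: int
    n_baseline: int
    t_stat: float
    p_value: float
    breakdown_flag: bool
    baseline_ci_upper: float


def _ci_upper(values: np.ndarray, level: float = 0.95) -> float:
    n = len(values)
    if n < 2:
        return float(values.mean())
    se = values.std(ddof=1) / math.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2, n - 1)
    return float(values.mean() + tcrit * se)


def baseline_comparison(line_values: Sequence[float], baseline_values: Sequence[float],
                        alpha: float = 0.05, line_id: str = "",
                        equal_var: bool = False) -> BaselineTest:
    """One-sided t-test of a line's transformed paternity scores vs a baseline.

    H1: line mean > baseline mean.  The breakdown flag is set when H1 is NOT
    rejected at ``alpha``, i.e. the line performs no better than the
    heterospecific baseline male.  Welch's unequal-variance form is the
    default.  Also reports the baseline mean's two-sided 95% CI upper bound
    (t distribution), the quantity drawn as the reference line in plots.
    """
    a = np.asarray(line_values, float)
    b = np.asarray(baseline_values, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var, alternative="greater")
    return BaselineTest(line_id=line_id, n_line=len(a), n_baseline=len(b),
                        t_stat=float(t_stat), p_value=float(p),
                        breakdown_flag=bool(p >= alpha),
                        baseline_ci_upper=_ci_upper(b))


def line_summaries(records: pd.DataFrame) -> pd.DataFrame:
    """Per-line mean/SE of P2 and mean TP2 (for plotting and reporting)."""
    g = records.groupby("line_id")
    out = pd.DataFrame({
        "n_females": g["p2"].size(),
        "mean_p2": g["p2"].mean(),
        "se_p2": g["p2"].sem(ddof=1),
        "mean_tp2": g["tp2"].mean(),
    })
    return out.reset_index()


def flag_breakdown_lines(records: pd.DataFrame, baseline_records: pd.DataFrame,
                         alpha: float = 0.05, equal_var: bool = False) -> pd.DataFrame:
    """Run the baseline comparison for every line; returns a per-line table."""
    base_tp2 = baseline_records["tp2"].dropna().to_numpy()
    rows = []
    for line_id, grp in records.groupby("line_id", sort=True):
        vals = grp["tp2"].dropna().to_numpy()
        if len(vals) < 2:
            continue
        res = baseline_comparison(vals, base_tp2, alpha=alpha,
                                  line_id=str(line_id), equal_var=equal_var)
        rows.append({"line_id": str(line_id), "n_females": res.n_line,
                     "mean_p2": float(grp["p2"].mean()),
                     "se_p2": float(grp["p2"].sem(ddof=1)),
                     "p_value": res.p_value,
                     "breakdown_flag": res.breakdown_flag})
    return pd.DataFrame(rows)
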