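"""Relative-expression screen: 2^-ddCt fold changes with a bootstrap
experiment-wise significance threshold.

Target-gene Ct values are normalised within each species to a reference gene
(ddCt method): dCt = Ct_target - Ct_reference, ddCt = dCt_species2 -
dCt_species1, fold = 2^-ddCt (species 2 relative to species 1).  Replicates
are paired across species by replicate index, converted to folds, and
averaged on the fold scale.  Because many genes are screened at once, the
significance threshold is experiment-wise: a population of bootstrap
averages (resampled with replacement from the pooled replicate-level folds)
supplies empirical two-sided tail bounds at each configured level, and a
gene is flagged when its average fold falls outside the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CT_COLUMNS",
    "delta_ct",
    "fold_change",
    "average_fold",
    "fold_table",
    "bootstrap_thresholds",
    "screen_genes",
    "ScreenThresholds",
]

CT_COLUMNS = ("gene", "species", "replicate", "ct_target", "ct_reference")


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Reference-normalised cycle threshold: Ct_target - Ct_reference."""
    if ct_target is None or ct_reference is None or \
            not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("missing or non-finite Ct value")
    return float(ct_target) - float(ct_reference)


def fold_change(dct_species2: float, dct_species1: float) -> float:
    """2^-(dCt2 - dCt1): expression of species 2 relative to species 1."""
    ddct = float(dct_species2) - float(dct_species1)
    if not np.isfinite(ddct):
        raise ValueError("non-finite delta-Ct")
    return float(2.0 ** (-ddct))


def average_fold(replicate_folds: Sequence[float]) -> float:
    """Arithmetic mean of the replicate fold values (averaged on the fold
    scale, not the ddCt scale)."""
    folds = np.asarray(list(replicate_folds), float)
    if folds.size == 0:
        raise ValueError("no replicate folds")
    return float(folds.mean())


def fold_table(ct: pd.DataFrame, species1: str, species2: str) -> pd.DataFrame:
    """Per-gene fold changes (species2 relative to species1) from a Ct table.

    Replicates are paired across species by replicate index; pairs missing
    in either species are dropped for that gene.  Returns columns
    ``gene``, ``fold`` (the replicate average) and ``replicate_folds``.
    """
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    df = ct.copy()
    df["dct"] = df["ct_target"].astype(float) - df["ct_reference"].astype(float)
    rows = []
    for gene, grp in df.groupby("gene", sort=True):
        d1 = grp[grp["species"] == species1].set_index("replicate")["dct"]
        d2 = grp[grp["species"] == species2].set_index("replicate")["dct"]
        common = d1.index.intersection(d2.index)
        if len(common) == 0:
            continue
        folds = [fold_change(d2[r], d1[r]) for r in sorted(common)]
        rows.append({"gene": str(gene), "fold": average_fold(folds),
                     "replicate_folds": folds})
    return pd.DataFrame(rows)


@dataclass
class ScreenThresholds:
    """Empirical two-sided tail bounds per level, from the bootstrap null."""

    bounds: Dict[float, Tuple[float, float]]   # level -> (lower, upper)
    n_boot: int
    sample_size: int
    seed: int

    def band(self, level: float) -> Tuple[float, float]:
        return self.bounds[level]

    @property
    def levels(self) -> List[float]:
        return sorted(self.bounds)


def bootstrap_thresholds(fold_values: Sequence[float], n_boot: int = 1000,
                         tails: Sequence[float] = (0.05, 0.10),
                         sample_size: Optional[int] = None,
                         seed: int = 0) -> ScreenThresholds:
    """Experiment-wise thresholds from bootstrap averages of pooled folds.

    ``n_boot`` resamples of size ``sample_size`` (default: the per-gene
    replicate count, 2) are drawn with replacement from the pooled
    replicate-level fold values and averaged; thresholds at a two-sided tail
    level ``q`` are the empirical ``q/2`` and ``1 - q/2`` quantiles of that
    population.  Fully determined by ``seed``.
    """
    values = np.asarray(list(fold_values), float)
    if values.size < 2:
        raise ValueError("need >= 2 fold values")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if sample_size is None:
        sample_size = 2
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, values.size, size=(n_boot, sample_size))
    means = values[draws].mean(axis=1)
    bounds = {}
    for q in tails:
        lo, hi = np.quantile(means, [q / 2, 1 - q / 2])
        bounds[float(q)] = (float(lo), float(hi))
    return ScreenThresholds(bounds=bounds, n_boot=n_boot,
                            sample_size=sample_size, seed=seed)


def screen_genes(folds: pd.DataFrame, thresholds: ScreenThresholds,
                 twofold_rule: bool = False) -> pd.DataFrame:
    """Flag genes whose average fold lies outside each level's null band.

    Wider tail levels have narrower bands, so genes flagged at 5% are always
    flagged at 10% as well.  With ``twofold_rule`` an additional column
    flags |log2 fold| >= 1, a simple fixed-magnitude alternative threshold.
    """
    out = folds.copy()
    for level in thresholds.levels:
        lo, hi = thresholds.band(level)
        out[f"flag_{level:g}"] = (out["fold"] < lo) | (out["fold"] > hi)
    if twofold_rule:
        out["flag_twofold"] = np.abs(np.log2(out["fold"].astype(float))) >= 1.0
    return out
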