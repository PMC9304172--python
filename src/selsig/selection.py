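"""Selection candidate calls, method intersection, estimator correlations
and the essential-gene randomisation test.

Conventional thresholds: dN/dS > 1, DOS > 0, NI < 0, D < 0, D* < 0, H < 0
and E < 0 (all strict).  The outlier mode instead flags the top 5% of each
statistic's distribution in its selection-indicating direction.

The randomisation test draws subsets of the focal-set size from all genes
with a defined value of the statistic, s times without replacement, and
compares subset medians with the focal median.  For a lower-tail test, r
counts draws whose median is less than or equal to the focal median (ties
are conservative) and p = (r + 1)/(s + 1); q = s - r is the number of draws
the focal subset beats outright.  The smallest reportable p is 1/(s + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STATISTICS = ["omega", "ni", "dos", "tajima_d", "fu_li_d_star", "fay_wu_h", "zeng_e"]

# statistic -> (threshold, side flagged as under selection)
SELECTION_THRESHOLDS: dict[str, tuple[float, str]] = {
    "omega": (1.0, "above"),
    "dos": (0.0, "above"),
    "ni": (0.0, "below"),
    "tajima_d": (0.0, "below"),
    "fu_li_d_star": (0.0, "below"),
    "fay_wu_h": (0.0, "below"),
    "zeng_e": (0.0, "below"),
}

# essential genes are expected at this tail of each distribution
ESSENTIAL_TEST_DIRECTIONS: dict[str, str] = {
    "omega": "lower",
    "dos": "lower",
    "fay_wu_h": "lower",
    "ni": "higher",
    "tajima_d": "higher",
    "fu_li_d_star": "higher",
    "zeng_e": "higher",
}


def classify_selection(
    profiles: pd.DataFrame,
    mode: str = "threshold",
    thresholds: dict[str, tuple[float, str]] | None = None,
    outlier_fraction: float = 0.05,
) -> pd.DataFrame:
    """Boolean candidate flags per gene and statistic.

    ``profiles`` is a gene-indexed frame with statistic columns (NaN where
    undefined).  Threshold mode applies the strict inequalities; outlier
    mode flags values at or beyond the empirical (1 - outlier_fraction)
    quantile in the selection-indicating direction (ties at the cutoff are
    included).  Flags are only set where the statistic is defined.
    """
    thresholds = thresholds or SELECTION_THRESHOLDS
    flags = pd.DataFrame(index=profiles.index)
    for stat, (cut, side) in thresholds.items():
        if stat not in profiles.columns:
            continue
        values = profiles[stat]
        defined = values.notna()
        if mode == "threshold":
            if side == "above":
                hit = values > cut
            else:
                hit = values < cut
        elif mode == "outlier5pct":
            vals = values.dropna()
            if side == "above":
                edge = np.quantile(vals, 1.0 - outlier_fraction)
                hit = values >= edge
            else:
                edge = np.quantile(vals, outlier_fraction)
                hit = values <= edge
        else:
            raise ValueError(f"unknown mode {mode!r}")
        flags[stat] = hit & defined
    return flags


def intersect_methods(flags: pd.DataFrame, profiles: pd.DataFrame) -> list[str]:
    """Genes flagged by every statistic; any undefined statistic excludes a gene."""
    all_defined = profiles[flags.columns].notna().all(axis=1)
    all_flagged = flags.all(axis=1)
    return sorted(flags.index[all_defined & all_flagged])


def estimator_correlations(
    profiles: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise complete-case Spearman rho and p-values between estimators."""
    cols = [c for c in STATISTICS if c in profiles.columns]
    rho = pd.DataFrame(np.nan, index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        rho.loc[a, a] = 1.0
        pval.loc[a, a] = 0.0
        for b in cols[i + 1 :]:
            pair = profiles[[a, b]].dropna()
            if len(pair) < min_pairs:
                continue
            r, p = stats.spearmanr(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


@dataclass
class RandomisationResult:
    statistic_name: str
    direction: str
    observed_median: float
    s: int
    q: int
    r: int
    p: float
    n_focal: int
    n_defined: int

    def __post_init__(self) -> None:
        if not (1.0 / (self.s + 1) <= self.p <= 1.0):
            raise ValueError("p outside [1/(s+1), 1]")


def randomisation_test(
    values: pd.Series,
    focal_genes: set[str],
    direction: str,
    s: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    statistic_name: str = "",
) -> RandomisationResult:
    """Is the focal gene set's median lower (or higher) than chance?

    Draws ``s`` subsets of the focal size without replacement from all
    genes with a defined value.  ``r`` counts draws whose median is <=
    (direction="lower") or >= (direction="higher") the focal median;
    p = (r + 1)/(s + 1).
    """
    if direction not in {"lower", "higher"}:
        raise ValueError("direction must be 'lower' or 'higher'")
    if s < 1:
        raise ValueError("s must be >= 1")
    defined = values.dropna()
    focal = defined[defined.index.isin(focal_genes)]
    if focal.empty:
        raise ValueError("focal set empty after intersecting with defined genes")
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = defined.to_numpy()
    k = len(focal)
    observed = float(np.median(focal.to_numpy()))
    draw_medians = np.empty(s)
    for i in range(s):
        draw = rng.choice(pool, size=k, replace=False)
        draw_medians[i] = np.median(draw)
    if direction == "lower":
        r = int(np.sum(draw_medians <= observed))
    else:
        r = int(np.sum(draw_medians >= observed))
    q = s - r
    p = (r + 1) / (s + 1)
    return RandomisationResult(
        statistic_name=statistic_name or str(values.name or ""),
        direction=direction,
        observed_median=observed,
        s=s,
        q=q,
        r=r,
        p=p,
        n_focal=k,
        n_defined=len(defined),
    )


def randomisation_suite(
    profiles: pd.DataFrame,
    focal_genes: set[str],
    s: int = 10000,
    seed: int | None = None,
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """The essential-gene randomisation test for every statistic column."""
    directions = directions or ESSENTIAL_TEST_DIRECTIONS
    rng = np.random.default_rng(seed)
    rows = []
    for stat in STATISTICS:
        if stat not in profiles.columns:
            continue
        try:
            res = randomisation_test(
                profiles[stat],
                focal_genes,
                direction=directions[stat],
                s=s,
                rng=rng,
                statistic_name=stat,
            )
        except ValueError:
            # no focal gene has a defined value of this statistic
            continue
        rows.append(
            {
                "statistic": stat,
                "direction": res.direction,
                "observed_median": res.observed_median,
                "n_focal": res.n_focal,
                "n_defined": res.n_defined,
                "s": res.s,
                "q": res.q,
                "r": res.r,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
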