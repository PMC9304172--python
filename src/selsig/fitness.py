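"""Per-gene relative knockout fitness and its association with selection
signatures.

Relative fitness w of one data point is the KO plant's fruit count divided
by its paired wild-type count within the same experimental replicate; a
gene's fitness is the mean over its data points.  Genes with three or fewer
usable observations are excluded (strictly more than three required), as
are data points with a zero wild-type count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_OBSERVATIONS = 4  # "more than three observations"
AREA_RATIO_MAX = 1.5


@dataclass
class GeneFitness:
    gene_id: str
    w: float
    n_obs: int
    z: Optional[float] = None
    area_ratio: Optional[float] = None
    area_ratio_ok: bool = True

    def __post_init__(self) -> None:
        if self.w < 0 or self.n_obs < 1:
            raise ValueError("invalid gene fitness record")


def relative_fitness(ko_fruits: int, wt_fruits: int) -> Optional[float]:
    """KO/WT fruit-count ratio; None (dropped) when the WT count is zero."""
    if ko_fruits < 0 or wt_fruits < 0:
        raise ValueError("fruit counts must be non-negative")
    if wt_fruits == 0:
        return None
    return ko_fruits / wt_fruits


def _ratio_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Add the per-row relative-fitness ratio, dropping zero-WT rows with a log."""
    n_zero_wt = int((table["wt_fruit_count"] == 0).sum())
    if n_zero_wt:
        logger.info("dropping %d data points with WT fruit count 0", n_zero_wt)
    df = table[table["wt_fruit_count"] > 0].copy()
    df["ratio"] = df["ko_fruit_count"] / df["wt_fruit_count"]
    return df


def aggregate_gene_fitness(
    table: pd.DataFrame, min_obs: int = MIN_OBSERVATIONS
) -> list[GeneFitness]:
    """Mean relative fitness per gene over all replicate data points.

    Genes with fewer than ``min_obs`` defined ratios are excluded.  The
    gene's area ratio is the maximum over its lines (the conservative flag
    for possible multiple insertions); missing stays missing.
    """
    df = _ratio_frame(table)
    out = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        n_obs = len(grp)
        if n_obs < min_obs:
            continue
        ar = grp["area_ratio"].dropna()
        out.append(
            GeneFitness(
                gene_id=str(gene_id),
                w=float(grp["ratio"].mean()),
                n_obs=n_obs,
                area_ratio=float(ar.max()) if len(ar) else None,
                area_ratio_ok=bool(ar.max() <= AREA_RATIO_MAX) if len(ar) else True,
            )
        )
    return out


def area_ratio_filter(
    genes: list[GeneFitness], max_ratio: float = AREA_RATIO_MAX
) -> list[GeneFitness]:
    """Drop genes whose area ratio exceeds ``max_ratio`` (strictly).

    Missing area ratios are retained (flagged via ``area_ratio_ok=True`` but
    ``area_ratio=None``), since absence of the assay is not evidence of
    extra insertions.
    """
    return [
        g for g in genes if g.area_ratio is None or g.area_ratio <= max_ratio
    ]


def zscore_by_chamber(table: pd.DataFrame, min_obs: int = MIN_OBSERVATIONS) -> list[GeneFitness]:
    """Chamber-standardised gene fitness (population-SD Z-scores).

    Ratios are standardised to mean 0, variance 1 within each growth
    chamber before gene-level averaging; a chamber with zero variance
    leaves its rows undefined (logged and dropped).
    """
    df = _ratio_frame(table)
    zs = np.full(len(df), np.nan)
    for chamber, grp in df.groupby("chamber_id"):
        sd = grp["ratio"].std(ddof=0)
        if sd == 0 or len(grp) < 2:
            logger.warning("chamber %s: zero variance or <2 observations; z undefined", chamber)
            continue
        zs[df.index.get_indexer(grp.index)] = (grp["ratio"] - grp["ratio"].mean()) / sd
    df = df.assign(z=zs).dropna(subset=["z"])
    out = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        if len(grp) < min_obs:
            continue
        ar = grp["area_ratio"].dropna()
        out.append(
            GeneFitness(
                gene_id=str(gene_id),
                w=float(grp["ratio"].mean()),
                n_obs=len(grp),
                z=float(grp["z"].mean()),
                area_ratio=float(ar.max()) if len(ar) else None,
            )
        )
    return out


def compare_fitness_by_class(
    genes: list[GeneFitness],
    flags: pd.Series,
    use_z: bool = False,
) -> Optional[dict]:
    """Kruskal-Wallis rank test of fitness between candidate and other genes.

    ``flags`` is a boolean gene-indexed series (the candidate call for one
    statistic).  Returns None (with a log entry) when either class is empty.
    """
    values = {g.gene_id: (g.z if use_z else g.w) for g in genes}
    cand = [values[g] for g in values if flags.get(g, False)]
    rest = [values[g] for g in values if not flags.get(g, False)]
    if not cand or not rest:
        logger.warning("one fitness class empty; Kruskal-Wallis skipped")
        return None
    if set(cand) == set(rest) and len(set(cand)) == 1:
        return {
            "n_candidate": len(cand), "n_other": len(rest),
            "median_candidate": float(np.median(cand)),
            "median_other": float(np.median(rest)),
            "H": 0.0, "p": 1.0,
        }
    h, p = stats.kruskal(cand, rest)
    return {
        "n_candidate": len(cand),
        "n_other": len(rest),
        "median_candidate": float(np.median(cand)),
        "median_other": float(np.median(rest)),
        "H": float(h),
        "p": float(p),
    }


def correlate_fitness_with_stats(
    genes: list[GeneFitness],
    profiles: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-statistic Spearman rho of fitness vs the statistic, with raw and
    Benjamini-Hochberg adjusted p-values."""
    w = pd.Series({g.gene_id: g.w for g in genes}, name="w")
    rows = []
    for stat in profiles.columns:
        pair = pd.concat([w, profiles[stat]], axis=1, join="inner").dropna()
        if len(pair) < min_pairs or pair["w"].nunique() == 1 or pair[stat].nunique() == 1:
            rows.append({"statistic": stat, "n": len(pair), "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(pair["w"], pair[stat])
        rows.append({"statistic": stat, "n": len(pair), "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    defined = out["p"].notna()
    out["p_bh"] = np.nan
    if defined.any():
        out.loc[defined, "p_bh"] = stats.false_discovery_control(
            out.loc[defined, "p"], method="bh"
        )
    return out
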