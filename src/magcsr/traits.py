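"""Genome trait profiles and community-aggregated traits (CATs).

Per-genome gene counts in COG functional categories are normalised to
within-genome fractions (controlling for genome size and completeness),
then aggregated to the community level as abundance-weighted means — the
community-aggregated trait (CAT) value of a sample. Level-mean CATs can be
Z-scored across disturbance levels for heatmap-style summaries, and genome
sizes compared across strategy cohorts with Welch's heteroscedastic
one-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .design import DisturbanceDesign

logger = logging.getLogger(__name__)

#: Quality thresholds for retaining a genome profile.
MIN_COMPLETENESS = 50.0
MAX_CONTAMINATION = 10.0


def quality_filter(genome_meta: pd.DataFrame,
                   min_completeness: float = MIN_COMPLETENESS,
                   max_contamination: float = MAX_CONTAMINATION) -> pd.Index:
    """Ids of genomes meeting the completeness/contamination thresholds."""
    keep = (genome_meta["completeness"] >= min_completeness) & (
        genome_meta["contamination"] <= max_contamination
    )
    dropped = genome_meta.index[~keep]
    if len(dropped):
        logger.warning("quality filter dropped %d genomes: %s",
                       len(dropped), ", ".join(dropped))
    return genome_meta.index[keep]


def aggregate_gene_annotations(genes: pd.DataFrame,
                               genome_col: str = "genome_id",
                               category_col: str = "cog_category",
                               categories: tuple[str, ...] | None = None,
                               multi_letter: str = "full") -> pd.DataFrame:
    """Aggregate a per-gene annotation table to genome x category counts.

    Genes annotated with multiple category letters (e.g. ``"KT"``)
    contribute one count to each letter under the default ``full`` policy,
    or ``1/len`` per letter under ``fractional``.
    """
    if multi_letter not in ("full", "fractional"):
        raise ValueError("multi_letter must be 'full' or 'fractional'")
    records = []
    for genome, cats in zip(genes[genome_col], genes[category_col]):
        cats = str(cats).strip()
        if not cats or cats == "-":
            continue
        w = 1.0 / len(cats) if multi_letter == "fractional" else 1.0
        for letter in cats:
            records.append((genome, letter, w))
    agg = (pd.DataFrame(records, columns=[genome_col, "category", "count"])
           .pivot_table(index=genome_col, columns="category", values="count",
                        aggfunc="sum", fill_value=0.0))
    if categories is not None:
        agg = agg.reindex(columns=list(categories), fill_value=0.0)
    if multi_letter == "full":
        agg = agg.astype(np.int64)
    agg.index.name = "genome_id"
    agg.columns.name = None
    return agg


def normalize_traits(trait_counts: pd.DataFrame) -> pd.DataFrame:
    """Within-genome trait fractions: counts / total annotated counts.

    Rows sum to 1. Genomes with zero annotated genes are rejected by id.
    """
    totals = trait_counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            "genomes with zero COG-annotated genes: "
            + ", ".join(map(str, zero.index))
        )
    return trait_counts.div(totals, axis=0)


def to_relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Close each sample row to sum 1."""
    totals = counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError("samples with zero total: " + ", ".join(map(str, zero.index)))
    return counts.div(totals, axis=0)


def compute_cats(rel_abundance: pd.DataFrame,
                 trait_fractions: pd.DataFrame) -> pd.DataFrame:
    """Community-aggregated traits: abundance-weighted mean trait fractions.

    ``CAT(s, t) = sum_g p(s, g) * f(g, t)`` — a convex combination of the
    contributing genomes' trait fractions per sample.
    """
    if set(rel_abundance.columns) != set(trait_fractions.index):
        missing = set(rel_abundance.columns) ^ set(trait_fractions.index)
        raise ValueError(f"genome sets differ between abundance and trait "
                         f"tables: {sorted(missing)}")
    if (rel_abundance.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    sums = rel_abundance.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = sums.index[~np.isclose(sums, 1.0, atol=1e-6)]
        raise ValueError(f"per-sample abundances must sum to 1: {list(bad)}")
    f = trait_fractions.loc[rel_abundance.columns]
    cats = rel_abundance.to_numpy() @ f.to_numpy()
    return pd.DataFrame(cats, index=rel_abundance.index, columns=f.columns)


def zscore_level_means(cat_matrix: pd.DataFrame,
                       design: DisturbanceDesign) -> tuple[pd.DataFrame, list[str]]:
    """Z-score of per-level mean CAT values, per trait, across levels.

    Returns the level x trait Z matrix and the list of traits flagged as
    constant across levels (mapped to all-zero rows).
    """
    meta = design.metadata().loc[cat_matrix.index]
    levels = sorted(meta["level"].unique())
    if len(levels) < 2:
        raise ValueError("Z-scoring level means requires >= 2 levels")
    level_means = cat_matrix.groupby(meta["level"]).mean()
    mu = level_means.mean(axis=0)
    sd = level_means.std(axis=0, ddof=1)
    constant = list(level_means.columns[sd <= 0])
    if constant:
        logger.warning("traits constant across levels (Z set to 0): %s",
                       ", ".join(constant))
    sd_safe = sd.replace(0.0, 1.0)
    z = (level_means - mu) / sd_safe
    z[constant] = 0.0
    z.index = [f"L{lvl}" for lvl in level_means.index]
    return z, constant


@dataclass(frozen=True)
class WelchAnovaResult:
    F: float
    df1: float
    df2: float
    p: float


def genome_size_welch_anova(sizes_by_group: dict[str, np.ndarray]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    Group means are compared without assuming equal variances; the
    denominator degrees of freedom follow the Satterthwaite-type
    approximation. Groups need >= 2 members and positive variance.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in sizes_by_group.items()}
    if len(groups) < 2:
        raise ValueError("Welch's ANOVA needs >= 2 groups")
    for name, x in groups.items():
        if len(x) < 2:
            raise ValueError(f"group {name!r} has < 2 observations")
        if np.var(x, ddof=1) <= 0:
            raise ValueError(f"group {name!r} has zero variance")

    k = len(groups)
    n = np.array([len(x) for x in groups.values()], dtype=float)
    m = np.array([x.mean() for x in groups.values()])
    v = np.array([x.var(ddof=1) for x in groups.values()])
    w = n / v
    W = w.sum()
    grand = (w * m).sum() / W
    num = ((w * (m - grand) ** 2).sum()) / (k - 1)
    lam = ((1 - w / W) ** 2 / (n - 1)).sum()  # heterogeneity term
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    F = num / den
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3.0 * lam)
    p = float(scipy.stats.f.sf(F, df1, df2)) if F > 0 else 1.0
    return WelchAnovaResult(F=float(F), df1=df1, df2=float(df2), p=p)
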