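"""CSR life-history strategy assignment from regime enrichment tests.

Features (genome relative abundances, or community-aggregated trait
values) are tested for enrichment in each disturbance regime with a
permutation test on the mean difference

    T(feature, regime) = mean(value | regime) - mean(value | other regimes)

against a null built by re-drawing the sample-to-regime labels. Features
significantly enriched (one-sided, Benjamini-Hochberg adjusted across the
full feature x regime family) in a regime receive the strategy letter that
regime selects for: undisturbed -> Competitor (C), intermediate -> Ruderal
(R), press -> Stress-tolerant (S). Multi-regime enrichment yields
multi-letter labels (canonical order C < R < S); no enrichment yields
"unassigned". Depletion p-values are reported but never drive labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .design import DisturbanceDesign, REGIMES

REGIME_LETTER = {"undisturbed": "C", "intermediate": "R", "press": "S"}
CANONICAL_LABELS = ("C", "R", "S", "CR", "CS", "RS", "CRS", "unassigned")


def canonical_label(strategy_set: set[str] | frozenset[str]) -> str:
    if not strategy_set:
        return "unassigned"
    return "".join(l for l in "CRS" if l in strategy_set)


def regime_enrichment_test(
    values: pd.DataFrame,
    regimes: pd.Series,
    n_sim: int = 9999,
    seed: int = 0,
    backend: str = "permutation",
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Permutation enrichment test of every feature in every regime.

    Parameters
    ----------
    values
        sample x feature table of the tested quantity.
    regimes
        regime label per sample (index-aligned with ``values``).
    n_sim
        number of null re-draws (>= 99).
    backend
        ``"permutation"``: unrestricted permutation of sample-to-regime
        labels (default). ``"multinomial"``: parametric bootstrap re-drawing
        each sample's counts multinomially from the pooled composition
        (requires the integer ``counts`` table).

    Returns
    -------
    Long-format DataFrame with one row per feature x regime:
    observed effect, one-sided enrichment p, one-sided depletion p, and
    BH-adjusted q over the whole feature x regime family. The p-value
    convention is ``(exceedances + 1) / (n_sim + 1)`` with ties counted
    as exceedances, so p is never 0.
    """
    if n_sim < 99:
        raise ValueError("n_sim must be >= 99")
    regimes = regimes.loc[values.index]
    unknown = set(regimes.unique()) - set(REGIMES)
    if unknown:
        raise ValueError(f"unknown regime labels: {sorted(unknown)}")
    present = [r for r in REGIMES if (regimes == r).any()]
    if len(present) < 2:
        missing = [r for r in REGIMES if r not in present]
        raise ValueError(f"regimes with zero samples: {missing}")
    V = values.to_numpy(dtype=float)
    if not np.isfinite(V).all():
        raise ValueError("non-finite feature values")
    n, p = V.shape
    rng = np.random.default_rng(seed)

    # contrast weights per regime: +1/n_in on regime samples, -1/n_out off
    weights = {}
    for r in present:
        mask = (regimes == r).to_numpy()
        w = np.where(mask, 1.0 / mask.sum(), -1.0 / (n - mask.sum()))
        weights[r] = w

    if backend == "permutation":
        perms = np.argsort(rng.random((n_sim, n)), axis=1)  # n_sim random orders

        def null_stats(w: np.ndarray) -> np.ndarray:
            return w[perms] @ V  # (n_sim, p)

    elif backend == "multinomial":
        if counts is None:
            raise ValueError("multinomial backend requires the counts table")
        C = counts.loc[values.index].to_numpy()
        if not np.issubdtype(C.dtype, np.integer):
            raise ValueError("multinomial backend requires integer counts")
        pooled = C.sum(axis=0).astype(float)
        pooled /= pooled.sum()
        depths = C.sum(axis=1)

        def null_stats(w: np.ndarray) -> np.ndarray:
            out = np.empty((n_sim, p))
            for b in range(n_sim):
                draw = np.vstack([rng.multinomial(d, pooled) for d in depths])
                rel = draw / draw.sum(axis=1, keepdims=True)
                out[b] = w @ rel
            return out

    else:
        raise ValueError(f"unknown backend {backend!r}")

    rows = []
    for r in present:
        w = weights[r]
        t_obs = w @ V
        t_null = null_stats(w)
        tol = 1e-12
        exceed_hi = (t_null >= t_obs - tol).sum(axis=0)
        exceed_lo = (t_null <= t_obs + tol).sum(axis=0)
        p_enrich = (exceed_hi + 1) / (n_sim + 1)
        p_deplete = (exceed_lo + 1) / (n_sim + 1)
        for j, feat in enumerate(values.columns):
            rows.append({
                "feature_id": feat, "regime": r, "effect": t_obs[j],
                "p_enrich": p_enrich[j], "p_deplete": p_deplete[j],
            })
    res = pd.DataFrame(rows)
    res["q_enrich"] = multipletests(res["p_enrich"], method="fdr_bh")[1]
    res["n_permutations"] = n_sim
    res["seed"] = seed
    return res


def assign_strategy(enrichment: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Map per-regime enrichment q-values onto CSR strategy labels."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    need = set(REGIME_LETTER)
    rows = []
    for feat, grp in enrichment.groupby("feature_id", sort=False):
        have = set(grp["regime"])
        if not need <= have:
            raise ValueError(
                f"feature {feat!r} missing regimes: {sorted(need - have)}"
            )
        strategy_set = {
            REGIME_LETTER[r]
            for r, q in zip(grp["regime"], grp["q_enrich"])
            if q <= alpha
        }
        rows.append({"feature_id": feat, "label": canonical_label(strategy_set)})
    assignments = pd.DataFrame(rows).set_index("feature_id")
    wide = enrichment.pivot(index="feature_id", columns="regime",
                            values=["effect", "p_enrich", "q_enrich"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    return assignments.join(wide)


def venn_counts(assignments: pd.DataFrame) -> dict[str, int]:
    """Counts per CSR label region (the 8 subsets of {C, R, S})."""
    counts = {label: 0 for label in CANONICAL_LABELS}
    for label in assignments["label"]:
        if label not in counts:
            raise ValueError(f"non-canonical label {label!r}")
        counts[label] += 1
    counts["total"] = len(assignments)
    counts["unique"] = counts["C"] + counts["R"] + counts["S"]
    return counts


@dataclass
class CSRResults:
    """Fitted CSR assignment results.

    Attributes
    ----------
    enrichment : long-format per feature x regime test table.
    assignments : per-feature strategy labels with supporting statistics.
    """

    enrichment: pd.DataFrame
    assignments: pd.DataFrame
    alpha: float
    n_sim: int
    seed: int

    def venn_counts(self) -> dict[str, int]:
        return venn_counts(self.assignments)

    def labels(self) -> pd.Series:
        return self.assignments["label"]

    def summary(self) -> str:
        v = self.venn_counts()
        lines = [
            "CSR strategy assignment",
            "=" * 47,
            f"features tested      {v['total']}",
            f"permutations         {self.n_sim}   (seed {self.seed})",
            f"BH FDR alpha         {self.alpha}",
            "-" * 47,
            "label    count",
        ]
        for label in CANONICAL_LABELS:
            lines.append(f"{label:<8} {v[label]}")
        lines.append("-" * 47)
        lines.append(f"uniquely assigned    {v['unique']}")
        return "\n".join(lines)


class CSRModel:
    """Strategy-assignment model for a sample x feature table.

    Parameters
    ----------
    values
        sample x feature quantities (relative abundances or CAT values).
    design
        the disturbance design, or a per-sample regime Series.
    """

    def __init__(self, values: pd.DataFrame,
                 design: DisturbanceDesign | pd.Series):
        self.values = values
        if isinstance(design, DisturbanceDesign):
            self.regimes = design.metadata().loc[values.index, "regime"]
        else:
            self.regimes = design.loc[values.index]

    @classmethod
    def from_counts(cls, counts: pd.DataFrame,
                    design: DisturbanceDesign | pd.Series) -> "CSRModel":
        rel = counts.div(counts.sum(axis=1), axis=0)
        model = cls(rel, design)
        model._counts = counts
        return model

    def fit(self, n_sim: int = 9999, alpha: float = 0.05, seed: int = 0,
            backend: str = "permutation") -> CSRResults:
        enrichment = regime_enrichment_test(
            self.values, self.regimes, n_sim=n_sim, seed=seed,
            backend=backend, counts=getattr(self, "_counts", None),
        )
        assignments = assign_strategy(enrichment, alpha=alpha)
        return CSRResults(enrichment=enrichment, assignments=assignments,
                          alpha=alpha, n_sim=n_sim, seed=seed)
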