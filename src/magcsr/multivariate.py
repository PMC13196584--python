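"""Distance-based multivariate community statistics.

Implements the resemblance-based toolkit used to test community
structuring along a disturbance gradient: Bray-Curtis dissimilarity on
square-root transformed relative abundances, principal coordinates
analysis (PCoA), one-way PERMANOVA and PERMDISP permutation tests,
canonical analysis of principal coordinates (CAP) with leave-one-out
allocation, distance-based linear modelling (DistLM) with AICc stepwise
predictor selection, distance-based redundancy analysis (dbRDA), Pearson
correlation vector overlays, and group-average (UPGMA) similarity
clustering.

All permutation tests use the ``(exceedances + 1) / (n_perm + 1)``
convention, are seeded, and default to 9999 permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

DEFAULT_N_PERM = 9999


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.ids):
            raise ValueError("ids do not match matrix dimension")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        object.__setattr__(self, "data", d)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids),
                            columns=list(self.ids))


@dataclass(frozen=True)
class PermutationTestResult:
    name: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class OrdinationResult:
    """Sample scores on ordered axes plus axis variance accounting."""

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    percent_fitted: np.ndarray | None = None
    percent_total: np.ndarray | None = None
    loo_allocation_success: float | None = None
    m: int | None = None
    vectors: pd.DataFrame | None = None
    negative_scores: np.ndarray = field(default=None, repr=False)


def sqrt_bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity of square-root transformed relative
    abundances.

    ``BC(i,j) = sum_k |y_ik - y_jk| / sum_k (y_ik + y_jk)`` with
    ``y = sqrt(relative abundance)``; the square-root transform damps the
    influence of dominant taxa.
    """
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        bad = table.index[totals <= 0]
        raise ValueError("samples with zero total: " + ", ".join(map(str, bad)))
    y = np.sqrt(x / totals[:, None])
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(y, metric="braycurtis"))
    return DistanceMatrix(tuple(map(str, table.index)), d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    c = np.eye(n) - np.full((n, n), 1.0 / n)
    return c @ a @ c


@dataclass
class PCoAResult:
    ids: tuple[str, ...]
    eigenvalues: np.ndarray          # all, descending (negatives retained)
    coordinates: np.ndarray          # axes with positive eigenvalues
    negative_coordinates: np.ndarray  # axes with negative eigenvalues

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PCoA{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.ids), columns=cols)

    @property
    def percent_variation(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return 100.0 * pos / pos.sum()


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> PCoAResult:
    """Principal coordinates: eigen-decomposition of the Gower-centered
    matrix ``G = -1/2 C D^2 C``. Negative eigenvalues (semi-metric input)
    are retained and their axes kept separately for corrected geometry.
    """
    g = _gower_center(dm.data)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = np.sqrt(np.maximum(np.abs(evals), 0.0))
    pos = evals > eps * max(1.0, np.abs(evals).max())
    neg = evals < -eps * max(1.0, np.abs(evals).max())
    coords = evecs[:, pos] * scale[pos]
    neg_coords = evecs[:, neg] * scale[neg]
    return PCoAResult(ids=dm.ids, eigenvalues=evals, coordinates=coords,
                      negative_coordinates=neg_coords)


def _group_indices(dm: DistanceMatrix, grouping: pd.Series) -> list[np.ndarray]:
    grouping = grouping.loc[list(dm.ids)]
    groups = [np.flatnonzero((grouping == g).to_numpy())
              for g in pd.unique(grouping)]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, idx in zip(pd.unique(grouping), groups):
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    return groups


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(dm: DistanceMatrix, grouping: pd.Series,
              n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> PermutationTestResult:
    """One-way fixed-factor PERMANOVA (pseudo-F on squared dissimilarities,
    p by unrestricted seeded permutation of group labels)."""
    grouping = grouping.loc[list(dm.ids)]
    _group_indices(dm, grouping)  # validates
    codes, _ = pd.factorize(grouping)
    n_groups = codes.max() + 1
    d2 = dm.data**2
    f_obs = _permanova_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm = _permanova_f(d2, rng.permutation(codes), n_groups)
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermutationTestResult("PERMANOVA pseudo-F", float(f_obs), p,
                                 n_perm, seed)


def _centroid_distances(pc: PCoAResult, codes: np.ndarray,
                        n_groups: int) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space, with
    the negative-eigenvalue correction: squared distance = contribution
    from real axes minus contribution from imaginary axes, floored at 0."""
    z2 = np.zeros(len(codes))
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        cp = pc.coordinates[idx].mean(axis=0)
        z2[idx] += ((pc.coordinates[idx] - cp) ** 2).sum(axis=1)
        if pc.negative_coordinates.shape[1]:
            cn = pc.negative_coordinates[idx].mean(axis=0)
            z2[idx] -= ((pc.negative_coordinates[idx] - cn) ** 2).sum(axis=1)
    return np.sqrt(np.maximum(z2, 0.0))


def _anova_f(z: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        zi = z[codes == g]
        ss_between += len(zi) * (zi.mean() - grand) ** 2
        ss_within += ((zi - zi.mean()) ** 2).sum()
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permdisp(dm: DistanceMatrix, grouping: pd.Series,
             n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions: one-way F on distances to
    group centroids (negative-eigenvalue-corrected), p by permuting the
    centroid distances across groups."""
    grouping = grouping.loc[list(dm.ids)]
    _group_indices(dm, grouping)
    codes, _ = pd.factorize(grouping)
    n_groups = codes.max() + 1
    pc = pcoa(dm)
    z = _centroid_distances(pc, codes, n_groups)
    f_obs = _anova_f(z, codes, n_groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm = _anova_f(z[rng.permutation(len(z))], codes, n_groups)
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermutationTestResult("PERMDISP F", float(f_obs), p, n_perm, seed)


def _loo_success(axes: np.ndarray, codes: np.ndarray) -> float:
    n = len(codes)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(codes[mask])) < 2:
            continue
        lda = LinearDiscriminantAnalysis()
        lda.fit(axes[mask], codes[mask])
        correct += int(lda.predict(axes[i:i + 1])[0] == codes[i])
    return correct / n


def cap(dm: DistanceMatrix, grouping: pd.Series,
        m: int | None = None) -> OrdinationResult:
    """Canonical analysis of principal coordinates.

    Discriminates a-priori groups by canonical discriminant analysis on
    the first ``m`` PCoA axes. When ``m`` is not given it is chosen to
    maximise leave-one-out allocation success (smallest ``m`` on ties).
    """
    grouping = grouping.loc[list(dm.ids)]
    _group_indices(dm, grouping)
    codes, _ = pd.factorize(grouping)
    pc = pcoa(dm)
    n_axes = pc.coordinates.shape[1]
    m_max = min(n_axes, dm.n - 2)
    if m is not None:
        if not 1 <= m <= dm.n - 1:
            raise ValueError(f"m must be in [1, {dm.n - 1}]")
        m = min(m, n_axes)
        best_m, best_rate = m, _loo_success(pc.coordinates[:, :m], codes)
    else:
        best_m, best_rate = 1, -1.0
        for mm in range(1, m_max + 1):
            rate = _loo_success(pc.coordinates[:, :mm], codes)
            if rate > best_rate + 1e-12:
                best_m, best_rate = mm, rate
    lda = LinearDiscriminantAnalysis()
    axes = pc.coordinates[:, :best_m]
    scores = lda.fit_transform(axes, codes)
    evr = getattr(lda, "explained_variance_ratio_", None)
    cols = [f"CAP{i+1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=list(dm.ids), columns=cols),
        eigenvalues=np.asarray(evr) if evr is not None else np.array([]),
        percent_fitted=(100.0 * np.asarray(evr)) if evr is not None else None,
        loo_allocation_success=best_rate,
        m=best_m,
    )


def _hat_matrix(x: np.ndarray) -> np.ndarray:
    # pseudoinverse-based: rank deficiency (duplicated predictors) tolerated
    return x @ np.linalg.pinv(x)


def _aicc(n: int, ss_res: float, v: int) -> float:
    if n - v - 1 <= 0:
        return np.inf
    return n * np.log(ss_res / n) + 2.0 * v * n / (n - v - 1)


@dataclass
class DistLMResults:
    """Fitted distance-based linear model.

    ``r2`` is the proportion of total resemblance-matrix variation
    explained (tr(HGH)/tr(G), McArdle-Anderson partitioning); ``aicc``
    the small-sample Akaike criterion of the selected model; ``trace``
    the per-step stepwise record.
    """

    model: "DistLM"
    selected: list[str]
    aicc: float
    r2: float
    trace: pd.DataFrame

    @property
    def ss_explained(self) -> float:
        return self.r2 * self.model.ss_total

    def dbrda(self) -> OrdinationResult:
        return dbrda(self.model.distance, self.model.predictors[self.selected])

    def summary(self) -> str:
        lines = [
            "Distance-based linear model (stepwise AICc)",
            "=" * 47,
            f"samples              {self.model.n}",
            f"candidates           {len(self.model.predictors.columns)}",
            f"selected             {len(self.selected)}: "
            + ", ".join(self.selected),
            f"AICc                 {self.aicc:.2f}",
            f"R2 (of total var.)   {self.r2:.4f}",
            "-" * 47,
            "step trace:",
        ]
        for _, row in self.trace.iterrows():
            lines.append(f"  {row['action']:<8} {row['predictor']:<12} "
                         f"AICc={row['aicc']:.2f}")
        return "\n".join(lines)


class DistLM:
    """Distance-based linear modelling of a resemblance matrix.

    Partitions the variation of a (possibly semi-metric) dissimilarity
    matrix by a set of numeric predictors: with hat matrix ``H`` of the
    predictor subset (plus intercept) and Gower-centered ``G``,
    ``SS_explained = tr(HGH)`` and ``SS_residual = tr((I-H)G(I-H))``.
    """

    def __init__(self, distance: DistanceMatrix, predictors: pd.DataFrame):
        missing = set(distance.ids) ^ set(map(str, predictors.index))
        if missing:
            raise ValueError(f"predictor/sample mismatch: {sorted(missing)}")
        self.distance = distance
        self.predictors = predictors.loc[list(distance.ids)].astype(float)
        self.g = _gower_center(distance.data)
        self.n = distance.n
        self.ss_total = float(np.trace(self.g))

    def _ss_explained(self, subset: list[str]) -> float:
        x = np.column_stack(
            [np.ones(self.n)] + [self.predictors[c].to_numpy() for c in subset])
        h = _hat_matrix(x)
        # H symmetric idempotent: tr(HGH) = tr(HG)
        return float(np.einsum("ij,ji->", h, self.g))

    def score(self, subset: list[str]) -> tuple[float, float, float]:
        """(AICc, R2, SS_res) for a predictor subset."""
        ss_exp = self._ss_explained(subset) if subset else 0.0
        ss_res = self.ss_total - ss_exp
        v = len(subset) + 1  # predictors + intercept
        return _aicc(self.n, max(ss_res, 1e-12), v), ss_exp / self.ss_total, ss_res

    def fit(self, criterion: str = "AICc") -> DistLMResults:
        """Bidirectional stepwise search: alternate the best single
        addition and the best single removal, accepting only moves that
        strictly decrease AICc."""
        if criterion != "AICc":
            raise ValueError("only the AICc criterion is supported")
        selected: list[str] = []
        current_aicc, current_r2, _ = self.score(selected)
        trace = [{"action": "start", "predictor": "(intercept)",
                  "aicc": current_aicc, "r2": current_r2}]
        improved = True
        while improved:
            improved = False
            # best addition
            candidates = [c for c in self.predictors.columns
                          if c not in selected]
            best = None
            for c in candidates:
                aicc, r2, _ = self.score(selected + [c])
                if best is None or aicc < best[0]:
                    best = (aicc, r2, c)
            if best is not None and best[0] < current_aicc - 1e-10:
                selected.append(best[2])
                current_aicc, current_r2 = best[0], best[1]
                trace.append({"action": "add", "predictor": best[2],
                              "aicc": current_aicc, "r2": current_r2})
                improved = True
            # best removal
            best = None
            for c in selected:
                rest = [s for s in selected if s != c]
                aicc, r2, _ = self.score(rest)
                if best is None or aicc < best[0]:
                    best = (aicc, r2, c)
            if best is not None and best[0] < current_aicc - 1e-10:
                selected.remove(best[2])
                current_aicc, current_r2 = best[0], best[1]
                trace.append({"action": "remove", "predictor": best[2],
                              "aicc": current_aicc, "r2": current_r2})
                improved = True
        return DistLMResults(model=self, selected=selected,
                             aicc=current_aicc, r2=current_r2,
                             trace=pd.DataFrame(trace))


def distlm_stepwise(distance: DistanceMatrix, predictors: pd.DataFrame,
                    criterion: str = "AICc") -> DistLMResults:
    """Functional wrapper around :class:`DistLM`."""
    return DistLM(distance, predictors).fit(criterion=criterion)


def dbrda(distance: DistanceMatrix, predictors: pd.DataFrame,
          eps: float = 1e-9) -> OrdinationResult:
    """Distance-based redundancy analysis: ordination of the fitted
    component ``HGH`` of a distance-based linear model."""
    if predictors.shape[1] == 0:
        raise ValueError("dbRDA requires a non-empty predictor set")
    model = DistLM(distance, predictors)
    x = np.column_stack([np.ones(model.n)] + [model.predictors[c].to_numpy()
                                              for c in predictors.columns])
    h = _hat_matrix(x)
    fitted = h @ model.g @ h
    fitted = (fitted + fitted.T) / 2
    evals, evecs = np.linalg.eigh(fitted)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eps * max(1.0, abs(evals).max())
    evals_k = evals[keep]
    scores = evecs[:, keep] * np.sqrt(evals_k)
    cols = [f"dbRDA{i+1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=list(distance.ids), columns=cols),
        eigenvalues=evals_k,
        percent_fitted=100.0 * evals_k / evals_k.sum(),
        percent_total=100.0 * evals_k / model.ss_total,
    )


def vector_overlay(scores: pd.DataFrame, variables: pd.DataFrame,
                   r_min: float = 0.20, axes: tuple[int, int] = (0, 1)
                   ) -> pd.DataFrame:
    """Pearson correlation vectors of variables with two ordination axes.

    A variable is retained iff the two-axis vector norm
    ``sqrt(r1^2 + r2^2)`` exceeds ``r_min``; constant variables are
    excluded (their correlation is undefined).
    """
    if not 0 <= r_min < 1:
        raise ValueError("r_min must be in [0, 1)")
    common = scores.index.intersection(variables.index)
    if len(common) != len(scores.index):
        raise ValueError("scores and variables must share sample ids")
    use_axes = [scores.columns[a] for a in axes if a < scores.shape[1]]
    rows = []
    for var in variables.columns:
        v = variables.loc[common, var].to_numpy(dtype=float)
        if np.std(v) == 0:
            continue
        rs = [float(np.corrcoef(v, scores.loc[common, ax])[0, 1])
              for ax in use_axes]
        norm = float(np.sqrt(np.sum(np.square(rs))))
        if norm > r_min:
            row = {"variable": var, "r_norm": norm}
            for ax, r in zip(use_axes, rs):
                row[f"r_{ax}"] = r
            rows.append(row)
    return pd.DataFrame(rows)


def upgma_similarity_clusters(dm: DistanceMatrix,
                              similarity_threshold: float = 85.0) -> pd.Series:
    """Group-average (UPGMA) clustering cut at a percent-similarity
    threshold (dissimilarity cut height ``1 - threshold/100``)."""
    if not 0 < similarity_threshold < 100:
        raise ValueError("similarity_threshold must be in (0, 100)")
    condensed = scipy.spatial.distance.squareform(dm.data, checks=False)
    link = scipy.cluster.hierarchy.linkage(condensed, method="average")
    cut = 1.0 - similarity_threshold / 100.0
    labels = scipy.cluster.hierarchy.fcluster(link, t=cut, criterion="distance")
    return pd.Series(labels, index=list(dm.ids), name="cluster")
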