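"""Sample-level multivariate analysis of the methylome.

PCA on the RPM table ordains the samples; epigenetic distances are the
Euclidean distances between samples in the full PCA score space (with all
components retained and no unit scaling this equals the distance on the
centered RPM matrix itself — rotations preserve distances).  Within-group
distance lists are compared with a Shapiro-Wilk normality gate followed by
a two-sided Wilcoxon rank-sum test, and two distance matrices over the
same samples (e.g. chloroplast vs nuclear methylome) are compared with a
permutation Mantel test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from methylrad.quantification import RPMMatrix

__all__ = [
    "PCAResult",
    "DistanceSet",
    "MantelResult",
    "pca",
    "detect_outliers",
    "epi_distances",
    "compare_distance_groups",
    "mantel",
]

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Principal components of the samples.

    ``scores`` is samples x components; ``loadings`` is components x
    variables; ``variance_explained`` is in percent and sums to 100 over
    the retained components.  Component signs are fixed by making each
    component's largest-magnitude loading positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    center: pd.Series
    scale: pd.Series | None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class DistanceSet:
    """Pairwise Euclidean distances in PCA score space, with a grouping."""

    matrix: pd.DataFrame
    grouping: pd.Series
    within_group: dict[str, np.ndarray] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


@dataclass(frozen=True)
class MantelResult:
    """Mantel statistic between two distance matrices."""

    r: float
    p: float
    n_perm: int
    seed: int
    alternative: str = "greater"


def pca(
    rpm: RPMMatrix | pd.DataFrame,
    scale_unit: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of samples on the (site x sample) RPM table.

    Site variables are centered and, by default, scaled to unit variance
    (matching the common PCA convention for heterogeneous variables);
    zero-variance sites are dropped first, with a log message.  The
    decomposition is a thin SVD of the standardized sample x site matrix;
    it is deterministic up to component sign, which is fixed by making the
    largest-magnitude loading of each component positive.
    """
    values = rpm.values if isinstance(rpm, RPMMatrix) else rpm
    X = values.T.astype(float)  # samples x sites
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    sd = X.std(axis=0, ddof=1)
    zero_var = sd[sd == 0].index
    if len(zero_var):
        logger.info("dropping %d zero-variance site(s) before PCA", len(zero_var))
        X = X.drop(columns=zero_var)
        sd = sd.drop(zero_var)
    if X.shape[1] == 0:
        raise ValueError("no variable sites left for PCA")
    center = X.mean(axis=0)
    Z = X - center
    scale = None
    if scale_unit:
        scale = sd
        Z = Z / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    k = len(S)
    if n_components is not None:
        k = min(k, n_components)
    # fix signs: largest-|loading| entry of each component positive
    for j in range(k):
        idx = np.argmax(np.abs(Vt[j]))
        if Vt[j, idx] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * S[:k]
    total_var = (S**2).sum()
    var_exp = 100.0 * (S[:k] ** 2) / total_var
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(Vt[:k], index=comp_names, columns=X.columns),
        variance_explained=var_exp,
        center=center,
        scale=scale,
    )


def detect_outliers(
    result: PCAResult, threshold_sd: float = 3.0
) -> pd.DataFrame:
    """Flag samples unusually far from the score-space centroid.

    A sample is flagged when its Euclidean distance from the centroid
    exceeds ``mean + threshold_sd * SD`` of all such distances; after
    removing flagged samples the criterion is re-evaluated once on the
    remainder (two passes in total).  Returns a table of flagged samples
    and their distances (empty when none).
    """
    scores = result.scores.to_numpy()
    if scores.shape[0] < 4:
        return pd.DataFrame(columns=["sample_id", "distance"]).set_index("sample_id")
    ids = np.array(result.sample_ids)
    flagged: dict[str, float] = {}
    active = np.ones(len(ids), dtype=bool)
    for _ in range(2):
        sub = scores[active]
        centroid = sub.mean(axis=0)
        dist_all = np.linalg.norm(scores - centroid, axis=1)
        dist_active = dist_all[active]
        cut = dist_active.mean() + threshold_sd * dist_active.std(ddof=1)
        new = active & (dist_all > cut)
        if not new.any():
            break
        for i in np.where(new)[0]:
            flagged[ids[i]] = float(dist_all[i])
        active &= ~new
    out = pd.DataFrame(
        {"sample_id": list(flagged), "distance": list(flagged.values())}
    ).set_index("sample_id")
    return out.sort_values("distance", ascending=False)


def epi_distances(
    result: PCAResult, grouping: pd.Series | Mapping[str, str]
) -> DistanceSet:
    """All-component Euclidean distances among samples, with the pairwise
    distances *within* each group level collected per level.

    A level with fewer than 2 samples contributes an empty list (warned).
    """
    grouping = pd.Series(grouping).reindex(result.sample_ids)
    if grouping.isna().any():
        missing = list(grouping.index[grouping.isna()])
        raise ValueError(f"samples without a group level: {missing}")
    dmat = squareform(pdist(result.scores.to_numpy(), metric="euclidean"))
    matrix = pd.DataFrame(dmat, index=result.sample_ids, columns=result.sample_ids)
    within: dict[str, np.ndarray] = {}
    for level in pd.unique(grouping):
        members = list(grouping.index[grouping == level])
        if len(members) < 2:
            logger.warning("group %r has < 2 samples; no within-group distances",
                           level)
            within[str(level)] = np.array([])
            continue
        pairs = [matrix.loc[a, b] for a, b in itertools.combinations(members, 2)]
        within[str(level)] = np.asarray(pairs, dtype=float)
    return DistanceSet(matrix=matrix, grouping=grouping, within_group=within)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value: exact enumeration of rank
    splits for group sizes up to 50, normal approximation with tie
    correction beyond."""
    method = "exact" if max(len(x), len(y)) <= 50 else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_distance_groups(dset: DistanceSet) -> pd.DataFrame:
    """Compare within-group epigenetic distances between the two levels of
    the grouping factor.

    Reports the Shapiro-Wilk normality p per group (the gate that
    motivates the non-parametric comparison), the two-sided Wilcoxon
    rank-sum p, and the group medians.  Each group needs at least three
    within-group distances.
    """
    levels = [lvl for lvl, d in dset.within_group.items() if len(d) > 0]
    if len(levels) != 2:
        raise ValueError(
            f"expected exactly two group levels with distances, got {levels}"
        )
    x, y = (dset.within_group[lvl] for lvl in levels)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs >= 3 within-group distances")
    shapiro = {
        lvl: float(scipy.stats.shapiro(dset.within_group[lvl]).pvalue)
        for lvl in levels
    }
    p = wilcoxon_rank_sum(x, y)
    return pd.DataFrame(
        [
            {
                "group1": levels[0],
                "group2": levels[1],
                "n1": len(x),
                "n2": len(y),
                "median1": float(np.median(x)),
                "median2": float(np.median(y)),
                "shapiro_p1": shapiro[levels[0]],
                "shapiro_p2": shapiro[levels[1]],
                "wilcoxon_p": p,
            }
        ]
    )


def _as_square(d, name: str) -> pd.DataFrame:
    d = pd.DataFrame(d)
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name}: distance matrix must be square")
    if not np.allclose(arr, arr.T):
        raise ValueError(f"{name}: distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0):
        raise ValueError(f"{name}: distance matrix must have zero diagonal")
    return d


def mantel(
    d1,
    d2,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    method: str = "auto",
) -> MantelResult:
    """Mantel test: Pearson correlation of two distance matrices with a
    permutation p-value.

    ``r`` is the Pearson correlation over the upper-triangle entries; the
    p-value permutes the rows/columns of ``d2`` jointly ``n_perm`` times
    with a seeded generator and reports ``(1 + #extreme) / (n_perm + 1)``
    (one-sided 'greater' by default; 'less' and 'two-sided' available).
    When the full permutation group is no larger than the requested number
    of draws (``method='auto'``, e.g. n <= 6 at the default 999) the test
    enumerates *all* n! permutations instead and reports the exact
    ``#extreme / n!`` (the identity permutation is always extreme, playing
    the '+1' role).  Constant distance matrices are rejected.
    """
    d1 = _as_square(d1, "d1")
    d2 = _as_square(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices differ in size")
    if not (d1.index.equals(d1.columns) and d2.index.equals(d2.columns)):
        raise ValueError("row and column labels must match within each matrix")
    if not d1.index.equals(d2.index):
        if set(d1.index) != set(d2.index):
            raise ValueError("distance matrices cover different sample sets")
        d2 = d2.loc[d1.index, d1.index]
    a1 = d1.to_numpy(dtype=float)
    a2 = d2.to_numpy(dtype=float)
    n = a1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1, v2 = a1[iu], a2[iu]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("constant distance matrix: Mantel r is undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])

    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    def _is_extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        if alternative == "less":
            return r_perm <= r_obs + 1e-12
        return abs(r_perm) >= abs(r_obs) - 1e-12

    z1 = (v1 - v1.mean()) / v1.std()

    def _r_of(perm) -> float:
        vp = a2[np.ix_(perm, perm)][iu]
        sd = vp.std()
        if sd == 0:
            return 0.0
        return float(np.mean(z1 * (vp - vp.mean()) / sd))

    import math

    exhaustive = method == "exact" or (
        method == "auto" and math.factorial(n) <= n_perm + 1
    )
    if method not in ("auto", "exact", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        count = sum(_is_extreme(_r_of(np.array(p))) for p in perms)
        p_val = count / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = sum(
            _is_extreme(_r_of(rng.permutation(n))) for _ in range(n_perm)
        )
        p_val = (1 + count) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(r=r_obs, p=p_val, n_perm=n_used, seed=seed,
                        alternative=alternative)
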