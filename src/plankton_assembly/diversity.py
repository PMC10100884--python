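"""Alpha and beta diversity: indices, Bray-Curtis, PCoA, PERMANOVA, two-group tests.

Alpha indices use the conventions common in community ecology: Shannon in
natural log, bias-corrected Chao1, Pielou evenness as Shannon / ln(richness),
and Faith's phylogenetic diversity including the path to the root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from plankton_assembly.io_tables import AsvTable, AsvTableError

ALPHA_INDICES = ("chao1", "shannon", "pielou", "faith_pd")


@dataclass(frozen=True)
class PcoaResult:
    """Principal coordinates of samples with per-axis eigenvalues.

    ``proportion_explained`` is each retained axis's share of the sum of
    positive eigenvalues; negative eigenvalues are reported in
    ``eigenvalues_all`` but excluded from the denominator.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    eigenvalues_all: np.ndarray


@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA (Adonis) pseudo-F and permutation p-value."""

    pseudo_f: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int


def alpha_diversity(
    counts: np.ndarray,
    index: str,
    tree: TreeNode | None = None,
    taxon_ids: list[str] | None = None,
) -> float:
    """Alpha diversity of a single sample's count vector.

    Parameters
    ----------
    counts :
        Nonnegative integer counts for one sample.
    index :
        One of ``chao1``, ``shannon``, ``pielou``, ``faith_pd``.
    tree, taxon_ids :
        Required for ``faith_pd``: the phylogeny and the taxon label of each
        entry of ``counts`` (labels must be tree tips).

    Notes
    -----
    chao1 is the bias-corrected estimator S_obs + F1(F1-1) / (2(F2+1)) with
    F1 and F2 the singleton and doubleton counts. shannon is -sum p ln p.
    pielou is shannon / ln(S_obs) and is undefined for a single taxon.
    faith_pd sums the branch lengths connecting the present tips to the root.
    """
    x = np.asarray(counts)
    if x.ndim != 1:
        raise AsvTableError("alpha_diversity expects a single sample vector")
    if (x < 0).any():
        raise AsvTableError("negative count")
    if x.sum() == 0:
        raise AsvTableError("all-zero count vector")
    present = x[x > 0]
    s_obs = len(present)
    if index == "chao1":
        f1 = int((present == 1).sum())
        f2 = int((present == 2).sum())
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    if index == "shannon":
        p = present / present.sum()
        return float(-(p * np.log(p)).sum())
    if index == "pielou":
        if s_obs < 2:
            raise AsvTableError("pielou undefined for a single observed taxon")
        p = present / present.sum()
        return float(-(p * np.log(p)).sum() / np.log(s_obs))
    if index == "faith_pd":
        if tree is None or taxon_ids is None:
            raise AsvTableError("faith_pd requires tree and taxon_ids")
        if len(taxon_ids) != len(x):
            raise AsvTableError("taxon_ids length must match counts")
        tips = {t.name for t in tree.tips()}
        absent = [t for t, c in zip(taxon_ids, x) if c > 0 and t not in tips]
        if absent:
            raise AsvTableError(f"taxa absent from tree: {absent[:10]}")
        return float(_skbio_faith_pd(x, taxon_ids, tree))
    raise AsvTableError(f"unknown alpha index: {index!r}")


def alpha_diversity_table(
    t: AsvTable,
    indices: tuple[str, ...] = ("chao1", "shannon", "pielou"),
    tree: TreeNode | None = None,
) -> pd.DataFrame:
    """Per-sample alpha diversity for several indices at once."""
    rows = {}
    for sid in t.sample_ids:
        counts = t.data.loc[sid].to_numpy()
        rows[sid] = {
            idx: alpha_diversity(counts, idx, tree=tree, taxon_ids=t.asv_ids)
            for idx in indices
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(indices)]


def bray_curtis_matrix(t: AsvTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = sum|x-y| / sum(x+y)."""
    if t.n_samples < 2:
        raise AsvTableError("need at least 2 samples")
    counts = t.counts.astype(float)
    zero = counts.sum(axis=1) == 0
    if zero.any():
        bad = [s for s, z in zip(t.sample_ids, zero) if z]
        raise AsvTableError(f"all-zero sample(s): {bad}")
    condensed = pdist(counts, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=t.sample_ids)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering.

    B = -1/2 J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by the square root of their (positive) eigenvalues. Negative
    eigenvalues are reported but not corrected.
    """
    if n_axes < 1:
        raise AsvTableError("n_axes must be >= 1")
    dist = np.asarray(d.data, dtype=float)
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    eigvals, eigvecs = scipy.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise AsvTableError("no positive eigenvalues; degenerate distance matrix")
    k = min(n_axes, n_pos)
    if n_axes > n_pos:
        import warnings

        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncated"
        )
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    # deterministic axis signs: largest-magnitude loading is positive
    for a in range(k):
        i_max = np.argmax(np.abs(coords[:, a]))
        if coords[i_max, a] < 0:
            coords[:, a] = -coords[:, a]
    pos_sum = eigvals[pos].sum()
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PcoaResult(
        coordinates=frame,
        eigenvalues=eigvals[:k],
        proportion_explained=eigvals[:k] / pos_sum,
        eigenvalues_all=eigvals,
    )


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    df_between = n_groups - 1
    df_within = n - n_groups
    denom = ss_within / df_within
    if denom <= 0:
        raise AsvTableError("constant distance matrix; pseudo-F undefined")
    return ((ss_total - ss_within) / df_between) / denom


def permanova(
    d: DistanceMatrix,
    groups: list[str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (Adonis) on a distance matrix.

    The pseudo-F follows Anderson's formulation: total sum of squares from
    all pairs, within-group sums from same-group pairs; the p-value is
    (#{F_perm >= F_obs} + 1) / (n_perm + 1) over label permutations.
    """
    if isinstance(groups, pd.Series):
        groups = list(groups.loc[list(d.ids)])
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != len(d.ids):
        raise AsvTableError("group labels must match distance matrix samples")
    labels, codes = np.unique(groups, return_inverse=True)
    n_groups = len(labels)
    if n_groups < 2:
        raise AsvTableError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = labels[sizes < 2].tolist()
        raise AsvTableError(f"group(s) with fewer than 2 samples: {small}")
    n = len(codes)
    d2 = np.asarray(d.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, codes, n_groups)

    rng = np.random.default_rng(seed)
    perm_codes = np.array([rng.permutation(codes) for _ in range(n_perm)])
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(n_perm)
    for g in range(n_groups):
        m = (perm_codes == g).astype(float)
        ss_within += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * sizes[g])
    df_between = n_groups - 1
    df_within = n - n_groups
    f_perm = ((ss_total - ss_within) / df_between) / (ss_within / df_within)
    p = (np.sum(f_perm >= f_obs) + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        df_between=df_between,
        df_within=df_within,
    )


def compare_groups(
    values_a: np.ndarray, values_b: np.ndarray, test: str = "welch_t"
) -> tuple[float, float]:
    """Two-group comparison: Welch's t or Wilcoxon rank-sum.

    Welch's t uses Satterthwaite degrees of freedom. The rank-sum test uses
    exact enumeration when both groups have at most 10 observations and the
    pooled data are tie-free, otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "welch_t":
        if len(a) < 2 or len(b) < 2:
            raise AsvTableError("welch_t needs at least 2 values per group")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            raise AsvTableError("zero variance in both groups")
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        if len(a) < 1 or len(b) < 1:
            raise AsvTableError("wilcoxon needs at least 1 value per group")
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            # fully tied data carry no ordering information
            return float(len(a) * len(b) / 2.0), 1.0
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) else "asymptotic"
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise AsvTableError(f"unknown test: {test!r}")
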