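"""Spatial and environmental structure: distance matrices, distance-decay,
spatial eigenfunctions (PCNM/dbMEM) and variation partitioning.

Variation partitioning decomposes Hellinger-transformed community variance
into pure environmental [a], shared [b], pure spatial [c] and unexplained
[d] adjusted-R-squared fractions via redundancy analysis, the standard
two-matrix inclusion-exclusion scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.csgraph
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from plankton_assembly.diversity import pcoa
from plankton_assembly.io_tables import AsvTable, AsvTableError, SampleMetadata

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class DecayFit:
    """Linear distance-decay fit of community similarity on a distance predictor."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    predictor: str
    mantel_p: float | None = None


@dataclass(frozen=True)
class VpaResult:
    """Adjusted-R^2 fractions from two-matrix variation partitioning.

    ``pure_env`` [a], ``shared`` [b], ``pure_spa`` [c] and ``unexplained``
    [d] always sum to 1; negative fractions are reported as-is.
    """

    pure_env: float
    shared: float
    pure_spa: float
    unexplained: float
    r2adj_env: float
    r2adj_spa: float
    r2adj_both: float


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between coordinate pairs (decimal degrees)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def geographic_distance_matrix(meta: SampleMetadata) -> DistanceMatrix:
    """Pairwise great-circle (haversine) distances between samples, in km."""
    coords = meta.coords()
    lat = coords["lat"].to_numpy()
    lon = coords["lon"].to_numpy()
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=meta.sample_ids)


def environmental_distance_matrix(
    meta: SampleMetadata, standardize: str = "zscore"
) -> DistanceMatrix:
    """Euclidean distance of z-score-standardized environmental variables.

    Zero-variance variables are dropped with a warning (they carry no
    between-sample information and would divide by zero).
    """
    if standardize != "zscore":
        raise AsvTableError(f"unknown standardization: {standardize!r}")
    env = meta.env_matrix()
    sd = env.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        warnings.warn(f"dropping zero-variance environmental variable(s): {constant}")
        env = env.drop(columns=constant)
        sd = sd.drop(constant)
    if env.shape[1] == 0:
        raise AsvTableError("no environmental variables with variance")
    z = (env - env.mean()) / sd
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, ids=meta.sample_ids)


def _condensed(d: DistanceMatrix, ids: list[str]) -> np.ndarray:
    mat = pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids))
    mat = mat.loc[ids, ids].to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    return mat[iu]


def distance_decay_fit(
    community_d: DistanceMatrix,
    predictor_d: DistanceMatrix,
    predictor: str = "geographic",
    mantel_permutations: int | None = None,
    seed: int | None = None,
) -> DecayFit:
    """OLS fit of community similarity (1 - Bray-Curtis) on pairwise distance.

    The reported p-value is the OLS slope t-test on the n(n-1)/2 vectorized
    pairs, mirroring a plain ``lm`` fit; pairs sharing a sample are not
    independent, so a Mantel permutation p-value over sample-label
    permutations is optionally reported alongside.
    """
    ids = list(community_d.ids)
    if set(ids) != set(predictor_d.ids):
        raise AsvTableError("community and predictor distance labels differ")
    if len(ids) < 4:
        raise AsvTableError("need at least 4 samples")
    sim = 1.0 - _condensed(community_d, ids)
    dist = _condensed(predictor_d, ids)
    if np.all(dist == dist[0]):
        raise AsvTableError("constant predictor distances")
    fit = scipy.stats.linregress(dist, sim)
    mantel_p = None
    if mantel_permutations:
        rng = np.random.default_rng(seed)
        pred_mat = pd.DataFrame(
            predictor_d.data, index=list(predictor_d.ids), columns=list(predictor_d.ids)
        ).loc[ids, ids].to_numpy()
        n = len(ids)
        iu = np.triu_indices(n, k=1)
        r_obs = abs(fit.rvalue)
        count = 0
        for _ in range(mantel_permutations):
            perm = rng.permutation(n)
            r_perm = np.corrcoef(pred_mat[np.ix_(perm, perm)][iu], sim)[0, 1]
            if abs(r_perm) >= r_obs:
                count += 1
        mantel_p = (count + 1) / (mantel_permutations + 1)
    return DecayFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_pairs=len(sim),
        predictor=predictor,
        mantel_p=mantel_p,
    )


def pcnm_vectors(geo_d: DistanceMatrix) -> pd.DataFrame:
    """Spatial eigenfunctions (PCNM/dbMEM) from a geographic distance matrix.

    Distances above the truncation threshold t (the longest edge of the
    minimum spanning tree) are replaced by 4t; principal coordinates of the
    truncated matrix with positive eigenvalues form the spatial predictors.
    """
    n = len(geo_d.ids)
    if n < 4:
        raise AsvTableError("need at least 4 samples for PCNM")
    d = np.asarray(geo_d.data, dtype=float)
    mst = scipy.sparse.csgraph.minimum_spanning_tree(d).toarray()
    t = mst.max()
    if t <= 0:
        raise AsvTableError("degenerate coordinates: zero-length spanning tree")
    trunc = np.where(d > t, 4.0 * t, d)
    np.fill_diagonal(trunc, 0.0)
    res = pcoa(DistanceMatrix(trunc, ids=list(geo_d.ids)), n_axes=n)
    if res.coordinates.shape[1] < 1:
        raise AsvTableError("no positive PCNM eigenvalues")
    cols = [f"PCNM{i + 1}" for i in range(res.coordinates.shape[1])]
    out = res.coordinates.copy()
    out.columns = cols
    out.attrs["eigenvalues"] = res.eigenvalues
    return out


def hellinger(counts: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of per-sample relative abundances."""
    counts = np.asarray(counts, dtype=float)
    row_sums = counts.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise AsvTableError("all-zero sample")
    return np.sqrt(counts / row_sums)


def _rda_r2(y_centered: np.ndarray, x: np.ndarray) -> float:
    """R^2 of multivariate least squares of centered Y on centered X."""
    xc = x - x.mean(axis=0)
    beta, *_ = np.linalg.lstsq(xc, y_centered, rcond=None)
    fitted = xc @ beta
    ss_total = (y_centered**2).sum()
    return float((fitted**2).sum() / ss_total)


def _check_rank(x: pd.DataFrame, what: str) -> None:
    xc = x.to_numpy(dtype=float)
    xc = xc - xc.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        collinear = []
        for i in range(1, xc.shape[1] + 1):
            if np.linalg.matrix_rank(xc[:, :i]) < i:
                collinear.append(str(x.columns[i - 1]))
        raise AsvTableError(f"rank-deficient {what} predictors; collinear column(s): {collinear}")


def variation_partition(
    t: AsvTable, env: pd.DataFrame, spa: pd.DataFrame
) -> VpaResult:
    """Two-matrix variation partitioning of a community table.

    The response is the Hellinger-transformed count table; each predictor
    set's RDA R^2 is Ezekiel-adjusted, and fractions follow the standard
    inclusion-exclusion: a = R2adj(E+S) - R2adj(S), c = R2adj(E+S) -
    R2adj(E), b = R2adj(E) + R2adj(S) - R2adj(E+S), d = 1 - R2adj(E+S).
    """
    env = env.loc[t.sample_ids]
    spa = spa.loc[t.sample_ids]
    n = t.n_samples
    p_env, p_spa = env.shape[1], spa.shape[1]
    if p_env + p_spa >= n - 1:
        raise AsvTableError(
            f"too many predictors ({p_env}+{p_spa}) for {n} samples"
        )
    combined = pd.concat([env, spa], axis=1)
    _check_rank(env, "environmental")
    _check_rank(spa, "spatial")
    identical = p_env == p_spa and np.allclose(
        env.to_numpy(dtype=float), spa.to_numpy(dtype=float)
    )
    if not identical:
        # fully shared predictors are legal (total confounding); only a
        # genuinely rank-deficient combination beyond that is an error
        xc = combined.to_numpy(dtype=float)
        xc = xc - xc.mean(axis=0)
        rank = np.linalg.matrix_rank(xc)
        expected = max(
            np.linalg.matrix_rank(env.to_numpy(dtype=float) - env.to_numpy(dtype=float).mean(axis=0)),
            np.linalg.matrix_rank(spa.to_numpy(dtype=float) - spa.to_numpy(dtype=float).mean(axis=0)),
        )
        if rank < expected:
            raise AsvTableError("rank-deficient combined predictors")

    y = hellinger(t.counts)
    yc = y - y.mean(axis=0)

    def adj(r2: float, p: int) -> float:
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    r2_env = adj(_rda_r2(yc, env.to_numpy(dtype=float)), p_env)
    r2_spa = adj(_rda_r2(yc, spa.to_numpy(dtype=float)), p_spa)
    if identical:
        r2_both = r2_env
    else:
        r2_both = adj(_rda_r2(yc, combined.to_numpy(dtype=float)), p_env + p_spa)
    a = r2_both - r2_spa
    c = r2_both - r2_env
    b = r2_env + r2_spa - r2_both
    d = 1.0 - r2_both
    if min(a, b, c) < 0:
        warnings.warn(
            f"negative VPA fraction(s): a={a:.4f}, b={b:.4f}, c={c:.4f} (reported as-is)"
        )
    return VpaResult(
        pure_env=float(a),
        shared=float(b),
        pure_spa=float(c),
        unexplained=float(d),
        r2adj_env=float(r2_env),
        r2adj_spa=float(r2_spa),
        r2adj_both=float(r2_both),
    )
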