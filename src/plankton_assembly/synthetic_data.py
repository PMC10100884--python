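"""Synthetic plankton community generators.

Two generating regimes bracket the assembly mechanisms the analysis is
meant to distinguish:

* **Neutral**: each sample's true composition is a Dirichlet draw with
  concentration N*m*p around lognormal source abundances p, so each
  taxon's marginal local relative abundance is exactly the
  Beta(N m p, N m (1-p)) distribution assumed by the Sloan neutral
  community model; observed counts are a multinomial read sample at fixed
  depth. Fitting the NCM to such tables is therefore a well-posed
  parameter-recovery problem, not a model-mismatch exercise.

* **Niche-structured**: taxa carry Gaussian response curves along an
  environmental gradient laid out on a spatial transect; expected
  abundance follows exp(-(e_i - mu_j)^2 / (2 sigma_j^2)). Environmental
  and spatial signals are collinear by construction unless
  ``spatial_noise`` decouples the gradient from position.

Defaults (S=300 taxa, 30 samples, depth 5000) are sized so a full
parameter-recovery sweep runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from plankton_assembly.io_tables import AsvTable, AsvTableError, SampleMetadata


@dataclass(frozen=True)
class NeutralSimConfig:
    """Parameters of the neutral (Dirichlet-multinomial) generator."""

    S: int = 300
    n_samples: int = 30
    depth: int = 5000
    m: float = 0.3
    lognormal_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2 or self.n_samples < 1 or self.depth < 1:
            raise AsvTableError("S, n_samples and depth must be positive")
        if not 0.0 < self.m <= 1.0:
            raise AsvTableError("m must be in (0, 1]")
        if self.lognormal_sigma < 0:
            raise AsvTableError("lognormal_sigma must be >= 0")


@dataclass(frozen=True)
class NicheSimConfig:
    """Parameters of the niche-structured (Gaussian response) generator."""

    S: int = 300
    n_samples: int = 30
    depth: int = 5000
    seed: int = 0
    env_gradient: np.ndarray | None = None
    niche_optima: np.ndarray | None = None
    niche_tolerances: np.ndarray | None = None
    spatial_noise: float = 0.0
    region: str = "SIM"

    def __post_init__(self) -> None:
        if self.S < 2 or self.n_samples < 1 or self.depth < 1:
            raise AsvTableError("S, n_samples and depth must be positive")
        if self.spatial_noise < 0:
            raise AsvTableError("spatial_noise must be >= 0")
        if self.env_gradient is not None and len(self.env_gradient) != self.n_samples:
            raise AsvTableError("env_gradient length must equal n_samples")
        if self.niche_tolerances is not None and np.any(
            np.asarray(self.niche_tolerances) <= 0
        ):
            raise AsvTableError("niche tolerances must be > 0")


def simulate_metacommunity(S: int, lognormal_sigma: float, seed: int) -> np.ndarray:
    """Lognormal source relative abundances of length S, summing to 1."""
    if S < 2:
        raise AsvTableError("need at least 2 taxa")
    if lognormal_sigma < 0:
        raise AsvTableError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, lognormal_sigma, size=S))
    return raw / raw.sum()


def simulate_neutral_table(
    cfg: NeutralSimConfig, p: np.ndarray | None = None
) -> AsvTable:
    """Sample a neutral community table under the Sloan model's assumptions.

    Each sample's true proportions are Dirichlet(depth * m * p) — marginals
    Beta(N m p_j, N m (1 - p_j)) — and its counts a Multinomial(depth)
    draw, so every row sums to ``cfg.depth``.
    """
    rng = np.random.default_rng(cfg.seed)
    if p is None:
        p = simulate_metacommunity(cfg.S, cfg.lognormal_sigma, cfg.seed)
    p = np.asarray(p, dtype=float)
    if len(p) != cfg.S:
        raise AsvTableError("source vector length must equal cfg.S")
    conc = cfg.depth * cfg.m * p
    if np.all(conc < 1e-12):
        raise AsvTableError(
            "Dirichlet concentration underflow; increase depth, m or source evenness"
        )
    counts = np.empty((cfg.n_samples, cfg.S), dtype=np.int64)
    for i in range(cfg.n_samples):
        local = rng.dirichlet(conc)
        counts[i] = rng.multinomial(cfg.depth, local)
    df = pd.DataFrame(
        counts,
        index=[f"S{i + 1:02d}" for i in range(cfg.n_samples)],
        columns=[f"ASV{j + 1:04d}" for j in range(cfg.S)],
    )
    return AsvTable(df)


def simulate_structured_table(
    cfg: NicheSimConfig,
) -> tuple[AsvTable, SampleMetadata]:
    """Sample a niche-structured table along a spatially laid-out gradient.

    Expected abundance of taxon j in sample i is proportional to
    exp(-(e_i - mu_j)^2 / (2 sigma_j^2)); counts are a multinomial read
    sample. Sample coordinates sit on a south-west to north-east transect
    so environment and space are collinear; positive ``spatial_noise``
    (in units of the gradient's standard deviation) perturbs the
    environmental values against position.
    """
    rng = np.random.default_rng(cfg.seed)
    n, S = cfg.n_samples, cfg.S
    position = np.linspace(0.0, 1.0, n)
    e = (
        np.asarray(cfg.env_gradient, dtype=float)
        if cfg.env_gradient is not None
        else np.linspace(-2.0, 2.0, n)
    )
    if cfg.spatial_noise > 0:
        e = e + rng.normal(0.0, cfg.spatial_noise * np.std(e), size=n)
    mu = (
        np.asarray(cfg.niche_optima, dtype=float)
        if cfg.niche_optima is not None
        else rng.uniform(e.min(), e.max(), size=S)
    )
    sigma = (
        np.asarray(cfg.niche_tolerances, dtype=float)
        if cfg.niche_tolerances is not None
        else rng.uniform(0.3, 1.0, size=S) * np.std(e)
    )
    lam = np.exp(-((e[:, None] - mu[None, :]) ** 2) / (2.0 * sigma[None, :] ** 2))
    row_tot = lam.sum(axis=1)
    if (row_tot <= 0).any() or not np.isfinite(row_tot).all():
        raise AsvTableError("degenerate niche responses: a sample has no taxa")
    counts = np.empty((n, S), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(cfg.depth, lam[i] / row_tot[i])
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    df = pd.DataFrame(
        counts, index=sample_ids, columns=[f"ASV{j + 1:04d}" for j in range(S)]
    )
    meta = pd.DataFrame(
        {
            "region": cfg.region,
            "lat": 39.5 + 0.5 * position,
            "lon": 121.5 + 3.0 * position,
            "env1": e,
        },
        index=sample_ids,
    )
    return AsvTable(df), SampleMetadata(meta, ("env1",))


def simulate_tree(asv_ids: list[str], seed: int) -> TreeNode:
    """Random coalescent-topology tree with exponential branch lengths."""
    ids = list(asv_ids)
    if len(ids) < 2:
        raise AsvTableError("need at least 2 tip ids")
    if len(set(ids)) != len(ids):
        raise AsvTableError("duplicate tip ids")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=i, length=float(rng.exponential(1.0))) for i in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def simulate_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_per_region: int = 12,
    s_phyto: int = 120,
    s_zoo: int = 120,
    depth: int = 3000,
    m_phyto: float = 0.5,
    write_tree: bool = True,
) -> dict[str, Path]:
    """Write a complete synthetic analysis bundle (table, taxonomy, metadata, tree).

    Two regions (LH, YLJ) sit on consecutive halves of one transect. The
    phytoplankton block is neutrally assembled (immigration ``m_phyto``)
    while the microzooplankton block tracks the environmental gradient, so
    downstream analyses see the dispersal-versus-selection contrast the
    pipeline is designed to detect.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n = 2 * n_per_region
    phyto_cfg = NeutralSimConfig(
        S=s_phyto, n_samples=n, depth=depth, m=m_phyto,
        lognormal_sigma=1.5, seed=int(rng.integers(2**31)),
    )
    phyto = simulate_neutral_table(phyto_cfg)
    zoo_cfg = NicheSimConfig(
        S=s_zoo, n_samples=n, depth=depth, seed=int(rng.integers(2**31))
    )
    zoo, meta_sim = simulate_structured_table(zoo_cfg)

    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    phyto_ids = [f"P_{j + 1:04d}" for j in range(s_phyto)]
    zoo_ids = [f"Z_{j + 1:04d}" for j in range(s_zoo)]
    counts = pd.concat(
        [
            pd.DataFrame(phyto.counts, index=sample_ids, columns=phyto_ids),
            pd.DataFrame(zoo.counts, index=sample_ids, columns=zoo_ids),
        ],
        axis=1,
    )

    e = meta_sim.data["env1"].to_numpy()
    meta = pd.DataFrame(
        {
            "region": ["LH"] * n_per_region + ["YLJ"] * n_per_region,
            "lat": meta_sim.data["lat"].to_numpy()
            + rng.normal(0, 0.01, size=n),
            "lon": meta_sim.data["lon"].to_numpy()
            + rng.normal(0, 0.01, size=n),
            "temperature": 22.0 + 2.0 * e + rng.normal(0, 0.5, size=n),
            "salinity": 28.0 - 1.5 * e + rng.normal(0, 0.5, size=n),
            "nitrate": np.round(rng.lognormal(1.0, 0.4, size=n), 3),
            "phosphate": np.round(rng.lognormal(-1.0, 0.4, size=n), 4),
            "env1": e,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    phyto_lineages = ["Pyrrophyta", "Bacillariophyta", "Chlorophyta", "Charophyta"]
    zoo_lineages = ["Ciliophora", "Copepoda", "Trachylinae", "Pteriomorphia"]
    tax = pd.DataFrame(
        {
            "group": ["phytoplankton"] * s_phyto + ["microzooplankton"] * s_zoo,
            "lineage": [phyto_lineages[j % len(phyto_lineages)] for j in range(s_phyto)]
            + [zoo_lineages[j % len(zoo_lineages)] for j in range(s_zoo)],
            "genus": "unknown",
            "species": "unknown",
        },
        index=pd.Index(phyto_ids + zoo_ids, name="asv_id"),
    )

    paths = {
        "asv_table": out_dir / "asv_table.tsv",
        "taxonomy": out_dir / "taxonomy.tsv",
        "metadata": out_dir / "metadata.tsv",
    }
    counts.T.rename_axis("asv_id").to_csv(paths["asv_table"], sep="\t")
    tax.to_csv(paths["taxonomy"], sep="\t")
    meta.to_csv(paths["metadata"], sep="\t", float_format="%.6f")
    if write_tree:
        tree = simulate_tree(phyto_ids + zoo_ids, seed=int(rng.integers(2**31)))
        paths["tree"] = out_dir / "tree.nwk"
        tree.write(str(paths["tree"]), format="newick")
    return paths


# round-trip helpers used by the bundle consumers
def bundle_env_columns() -> list[str]:
    """Environmental variable names written by :func:`simulate_bundle`."""
    return ["temperature", "salinity", "nitrate", "phosphate", "env1"]
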