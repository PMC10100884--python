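"""End-to-end orchestration: from input tables to tidy result files.

The pipeline mirrors the analysis flow of a two-region plankton community
survey: normalize the ASV table, split by plankton group, then per group
(and where appropriate per region) compute alpha diversity, ordination and
PERMANOVA, distance-decay fits, variation partitioning, the neutral
community model with its above/neutral/below partition, and niche breadth
/ dispersal summaries. Every stochastic step derives its seed from the
single configured seed, so re-running an identical configuration
reproduces byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from plankton_assembly import __version__
from plankton_assembly.assembly_ncm import (
    fit_ncm,
    occurrence_stats,
    partition_asvs,
    partition_summary,
)
from plankton_assembly.diversity import (
    alpha_diversity_table,
    bray_curtis_matrix,
    compare_groups,
    pcoa,
    permanova,
)
from plankton_assembly.io_tables import (
    AsvTable,
    AsvTableError,
    SampleMetadata,
    filter_singletons,
    rarefy,
    read_asv_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    split_by_group,
)
from plankton_assembly.niche_dispersal import (
    community_breadth,
    dispersal_proxy,
    levins_breadth,
)
from plankton_assembly.spatial_env import (
    distance_decay_fit,
    environmental_distance_matrix,
    geographic_distance_matrix,
    pcnm_vectors,
    variation_partition,
)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full analysis run; all paths and knobs explicit."""

    asv_table: str
    taxonomy: str
    metadata: str
    env_columns: list[str]
    out_dir: str
    seed: int
    tree: str | None = None
    orientation: str = "asvs_as_rows"
    rarefaction_depth: int | str = "min"
    n_permutations: int = 999
    ncm_alpha: float = 0.05
    region_column: str = "region"
    max_pcnm_axes: int = 3
    alpha_indices: tuple[str, ...] = ("chao1", "shannon", "pielou")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise PipelineError("config must set an explicit seed")
        if "alpha_indices" in raw:
            raw["alpha_indices"] = tuple(raw["alpha_indices"])
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(
        path, sep="\t", float_format=_FLOAT_FMT, lineterminator="\n",
        index_label=index_label,
    )


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every analysis stage and write one TSV per result family.

    Returns a mapping from result-family name to written path. Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(cfg.out_dir)
    written: dict[str, Path] = {}

    # --- stage: validate inputs ------------------------------------------
    for name in ("asv_table", "taxonomy", "metadata"):
        p = getattr(cfg, name)
        if not Path(p).is_file():
            raise PipelineError(f"stage input-validation: missing {name} file: {p}")
    if cfg.tree is not None and not Path(cfg.tree).is_file():
        raise PipelineError(f"stage input-validation: missing tree file: {cfg.tree}")
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (AsvTableError, ValueError) as exc:
            raise PipelineError(f"stage {name}: {exc}") from exc

    # --- stage: read ------------------------------------------------------
    table = stage("read-asv-table", read_asv_table, cfg.asv_table, cfg.orientation)
    tax = stage("read-taxonomy", read_taxonomy, cfg.taxonomy)
    meta = stage("read-metadata", read_metadata, cfg.metadata, cfg.env_columns)
    tree = stage("read-tree", read_tree, cfg.tree) if cfg.tree else None
    missing = [s for s in table.sample_ids if s not in meta.data.index]
    if missing:
        raise PipelineError(f"stage read-metadata: samples without metadata: {missing}")

    # --- stage: normalize -------------------------------------------------
    table = stage("singleton-filter", filter_singletons, table)
    groups = stage("split-by-group", split_by_group, table, tax)
    rarefied: dict[str, AsvTable] = {}
    depths: dict[str, int] = {}
    for gi, (g, gt) in enumerate(sorted(groups.items())):
        rt = stage("rarefaction", rarefy, gt, cfg.rarefaction_depth, cfg.seed + gi)
        rarefied[g] = rt
        depths[g] = int(rt.data.sum(axis=1).iloc[0])

    regions = meta.regions
    region_labels = sorted(pd.unique(regions.loc[table.sample_ids]))

    # --- stage: alpha diversity ------------------------------------------
    indices = cfg.alpha_indices
    if tree is not None and "faith_pd" not in indices:
        indices = (*indices, "faith_pd")
    alpha_frames, alpha_tests = [], []
    for g, rt in sorted(rarefied.items()):
        adf = stage("alpha-diversity", alpha_diversity_table, rt, indices, tree)
        adf.insert(0, "group", g)
        adf.insert(1, "region", regions.loc[adf.index].to_numpy())
        alpha_frames.append(adf)
        if len(region_labels) == 2:
            r0, r1 = region_labels
            for idx in indices:
                a = adf.loc[adf["region"] == r0, idx].to_numpy()
                b = adf.loc[adf["region"] == r1, idx].to_numpy()
                stat, p = stage("alpha-tests", compare_groups, a, b, "welch_t")
                alpha_tests.append(
                    {"group": g, "index": idx, "test": "welch_t",
                     "statistic": stat, "p_value": p}
                )
    alpha_all = pd.concat(alpha_frames)
    _write(alpha_all, out_dir / "alpha_diversity.tsv", index_label="sample_id")
    written["alpha_diversity"] = out_dir / "alpha_diversity.tsv"
    if alpha_tests:
        _write(pd.DataFrame(alpha_tests).set_index("group"),
               out_dir / "alpha_tests.tsv", index_label="group")
        written["alpha_tests"] = out_dir / "alpha_tests.tsv"

    # --- stage: beta diversity + ordination ------------------------------
    adonis_rows = []
    bc_mats = {}
    for gi, (g, rt) in enumerate(sorted(rarefied.items())):
        bc = stage("bray-curtis", bray_curtis_matrix, rt)
        bc_mats[g] = bc
        _write(pd.DataFrame(bc.data, index=list(bc.ids), columns=list(bc.ids)),
               out_dir / f"bray_curtis_{g}.tsv", index_label="sample_id")
        written[f"bray_curtis_{g}"] = out_dir / f"bray_curtis_{g}.tsv"
        ord_res = stage("pcoa", pcoa, bc, 2)
        coords = ord_res.coordinates.copy()
        coords.insert(0, "region", regions.loc[coords.index].to_numpy())
        for ax, prop in enumerate(ord_res.proportion_explained):
            coords[f"PC{ax + 1}_prop"] = prop
        _write(coords, out_dir / f"pcoa_{g}.tsv", index_label="sample_id")
        written[f"pcoa_{g}"] = out_dir / f"pcoa_{g}.tsv"
        if len(region_labels) >= 2:
            res = stage(
                "permanova", permanova, bc, regions.loc[list(bc.ids)],
                cfg.n_permutations, cfg.seed + 100 + gi,
            )
            adonis_rows.append(
                {"group": g, "pseudo_F": res.pseudo_f, "p_value": res.p_value,
                 "n_permutations": res.n_permutations,
                 "df_between": res.df_between, "df_within": res.df_within}
            )
    if adonis_rows:
        _write(pd.DataFrame(adonis_rows).set_index("group"),
               out_dir / "adonis.tsv", index_label="group")
        written["adonis"] = out_dir / "adonis.tsv"

    # --- per region x group stages ---------------------------------------
    decay_rows, vpa_rows, ncm_rows = [], [], []
    part_summaries, part_lineages = [], []
    niche_rows, levins_rows = [], []
    for g, rt in sorted(rarefied.items()):
        for region in region_labels:
            rsamples = [s for s in rt.sample_ids if regions.loc[s] == region]
            if len(rsamples) < 4:
                continue
            sub = stage("region-subset", rt.subset_samples, rsamples)
            sub_meta_df = meta.data.loc[rsamples]
            env_cols = [
                c for c in cfg.env_columns
                if sub_meta_df[c].astype(float).std(ddof=1) > 0
            ]
            sub_meta = SampleMetadata(sub_meta_df, tuple(env_cols))

            # distance-decay (geographic and environmental predictors)
            bc = stage("bray-curtis", bray_curtis_matrix, sub)
            geo = stage("geographic-distance", geographic_distance_matrix, sub_meta)
            env_d = stage(
                "environmental-distance", environmental_distance_matrix, sub_meta
            )
            for pred_name, pred_d in (("geographic", geo), ("environmental", env_d)):
                fit = stage(
                    "distance-decay", distance_decay_fit, bc, pred_d, pred_name
                )
                decay_rows.append(
                    {"group": g, "region": region, "predictor": pred_name,
                     "slope": fit.slope, "intercept": fit.intercept,
                     "r_squared": fit.r_squared, "p_value": fit.p_value,
                     "n_pairs": fit.n_pairs}
                )

            # variation partitioning
            try:
                spa = pcnm_vectors(geo)
                spa = spa.iloc[:, : cfg.max_pcnm_axes]
                env_mat = sub_meta.env_matrix()
                vpa = variation_partition(sub, env_mat, spa)
                vpa_rows.append(
                    {"group": g, "region": region,
                     "pure_env": vpa.pure_env, "shared": vpa.shared,
                     "pure_spa": vpa.pure_spa, "unexplained": vpa.unexplained,
                     "r2adj_env": vpa.r2adj_env, "r2adj_spa": vpa.r2adj_spa,
                     "r2adj_both": vpa.r2adj_both}
                )
            except AsvTableError as exc:
                raise PipelineError(f"stage vpa ({region}/{g}): {exc}") from exc

            # neutral community model
            try:
                stats = occurrence_stats(sub)
                fit = fit_ncm(stats, N=depths[g], alpha=cfg.ncm_alpha)
                labels = partition_asvs(fit, alpha=cfg.ncm_alpha)
                part = partition_summary(labels, sub, tax)
            except AsvTableError as exc:
                raise PipelineError(f"stage ncm ({region}/{g}): {exc}") from exc
            ncm_rows.append(
                {"group": g, "region": region, "m": fit.m,
                 "r_squared": fit.r_squared, "N": fit.N,
                 "n_samples": fit.n_samples, "n_asvs": len(fit.table)}
            )
            asv_frame = fit.table.copy()
            asv_frame["partition"] = labels
            _write(asv_frame, out_dir / f"ncm_asvs_{region}_{g}.tsv",
                   index_label="asv_id")
            written[f"ncm_asvs_{region}_{g}"] = out_dir / f"ncm_asvs_{region}_{g}.tsv"
            s = part.summary.copy()
            s.insert(0, "group", g)
            s.insert(1, "region", region)
            part_summaries.append(s.reset_index(names="partition"))
            if part.by_lineage is not None:
                bl = part.by_lineage.copy()
                bl.insert(0, "group", g)
                bl.insert(1, "region", region)
                part_lineages.append(bl)

            # niche breadth and dispersal
            try:
                b = levins_breadth(sub)
                bcom = community_breadth(sub, b)
                disp = dispersal_proxy(sub)
            except AsvTableError as exc:
                raise PipelineError(f"stage niche ({region}/{g}): {exc}") from exc
            for taxon, bval in b.items():
                levins_rows.append(
                    {"group": g, "region": region, "asv_id": taxon, "levins_b": bval}
                )
            for sid in sub.sample_ids:
                niche_rows.append(
                    {"group": g, "region": region, "sample_id": sid,
                     "bcom": bcom.loc[sid], "dispersal": disp.loc[sid]}
                )

    _write(pd.DataFrame(decay_rows).set_index("group"),
           out_dir / "distance_decay.tsv", index_label="group")
    written["distance_decay"] = out_dir / "distance_decay.tsv"
    _write(pd.DataFrame(vpa_rows).set_index("group"),
           out_dir / "vpa.tsv", index_label="group")
    written["vpa"] = out_dir / "vpa.tsv"
    _write(pd.DataFrame(ncm_rows).set_index("group"),
           out_dir / "ncm_params.tsv", index_label="group")
    written["ncm_params"] = out_dir / "ncm_params.tsv"
    _write(pd.concat(part_summaries, ignore_index=True).set_index("partition"),
           out_dir / "partition_summary.tsv", index_label="partition")
    written["partition_summary"] = out_dir / "partition_summary.tsv"
    if part_lineages:
        _write(pd.concat(part_lineages, ignore_index=True).set_index("partition"),
               out_dir / "partition_by_lineage.tsv", index_label="partition")
        written["partition_by_lineage"] = out_dir / "partition_by_lineage.tsv"
    _write(pd.DataFrame(levins_rows).set_index("group"),
           out_dir / "levins_b.tsv", index_label="group")
    written["levins_b"] = out_dir / "levins_b.tsv"
    niche_df = pd.DataFrame(niche_rows)
    _write(niche_df.set_index("group"),
           out_dir / "niche_dispersal.tsv", index_label="group")
    written["niche_dispersal"] = out_dir / "niche_dispersal.tsv"

    # between-group (e.g. phytoplankton vs microzooplankton) tests per region
    group_names = sorted(rarefied)
    if len(group_names) == 2 and not niche_df.empty:
        g0, g1 = group_names
        test_rows = []
        for region in region_labels:
            for metric in ("bcom", "dispersal"):
                a = niche_df.query("group == @g0 and region == @region")[metric]
                b = niche_df.query("group == @g1 and region == @region")[metric]
                if len(a) >= 2 and len(b) >= 2:
                    stat, p = compare_groups(a.to_numpy(), b.to_numpy(), "welch_t")
                    test_rows.append(
                        {"region": region, "metric": metric,
                         "group_a": g0, "group_b": g1,
                         "statistic": stat, "p_value": p}
                    )
        if test_rows:
            _write(pd.DataFrame(test_rows).set_index("region"),
                   out_dir / "niche_tests.tsv", index_label="region")
            written["niche_tests"] = out_dir / "niche_tests.tsv"

    # --- run log ----------------------------------------------------------
    log_lines = [
        f"plankton-assembly version: {__version__}",
        f"seed: {cfg.seed}",
        f"orientation: {cfg.orientation}",
        f"rarefaction_depth: {cfg.rarefaction_depth}",
        *[f"depth[{g}]: {d}" for g, d in sorted(depths.items())],
        f"n_permutations: {cfg.n_permutations}",
        f"ncm_alpha: {cfg.ncm_alpha}",
        f"max_pcnm_axes: {cfg.max_pcnm_axes}",
        f"env_columns: {','.join(cfg.env_columns)}",
        f"regions: {','.join(map(str, region_labels))}",
        f"groups: {','.join(group_names)}",
    ]
    log_path = out_dir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    written["run_log"] = log_path
    return written
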