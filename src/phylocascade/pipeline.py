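"""End-to-end orchestration: rarefy → βMNTD → nulls → classify → summarize → stats.

The pipeline mirrors the cascade-study analysis: within each season the
sample table is the metacommunity; βNTI is computed for the cascade-adjacent
reservoir pairs of each sampling event, pairs not attributed to selection go
through the Raup-Crick stage, and the resulting labels are aggregated into
Local / Regional / Stochastic percentages per season and in total. PERMANOVA
(season grouping over all samples; reservoir grouping within each season),
NMDS for significant groupings, and a PCA of the environmental table round
out the statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InputFormatError, PhylocascadeError
from .inference import (
    CascadeDesign,
    classify_table,
    connected_pairs,
    summarize_processes,
)
from .io import (
    OtuTable,
    SampleMetadata,
    prune_table_to_tree,
    rarefy,
    read_env_table,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    read_tree,
    extract_subcommunity,
)
from .nulls import beta_nti, raup_crick_bray
from .stats import nmds, pca, permanova
from .turnover import beta_mntd, cophenetic_distances

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "summarize_table1"]


@dataclass
class PipelineConfig:
    """Everything one run needs; serialized into the run manifest."""

    otu_table: str
    tree: str
    metadata: str
    out_dir: str | None = None
    taxonomy: str | None = None
    env_table: str | None = None
    subcommunity_rank: str | None = None
    subcommunity_value: str | None = None
    rarefaction_depth: int | str | None = "min"  # "min", integer, or None to skip
    n_iter_bnti: int = 999
    n_iter_rc: int = 999
    bnti_cut: float = 2.0
    rc_cut: float = 0.95
    cascade: tuple[str, ...] = ("BB", "Pr", "NA", "TI")
    seed: int = 0
    abundance_weighted: bool = True
    exhaustive_rc: bool = False  # compute RC for every pair (diagnostics)
    prune_to_tree: bool = False
    n_perm: int = 999
    nmds_restarts: int = 20
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.bnti_cut < 0 or self.rc_cut < 0:
            raise InputFormatError("thresholds must be non-negative")
        if len(self.cascade) < 2:
            raise InputFormatError("cascade needs at least 2 reservoirs")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key: value`` configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InputFormatError(f"{path}: config must be flat key: value pairs")
    if "cascade" in raw and isinstance(raw["cascade"], str):
        raw["cascade"] = tuple(x.strip() for x in raw["cascade"].split(","))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InputFormatError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


def _derive_seed(master: int, *keys: str) -> int:
    seq = np.random.SeedSequence([int(master)] + [zlib.crc32(k.encode()) for k in keys])
    return int(seq.generate_state(1)[0] % 2**31)


def _stage(name: str):
    """Wrap stage errors with the stage name for actionable messages."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, PhylocascadeError):
                exc.args = (f"[{name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx()


def run_pipeline(
    config: PipelineConfig,
    table: OtuTable | None = None,
    tree=None,
    metadata: SampleMetadata | None = None,
    env: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis; returns the result bundle (and writes it if
    ``config.out_dir`` is set).

    In-memory inputs may be passed directly (the CLI passes file paths via
    the config instead).
    """
    with _stage("read"):
        if table is None:
            table = read_otu_table(config.otu_table)
        if tree is None:
            tree = read_tree(config.tree)
        if metadata is None:
            metadata = read_metadata(config.metadata)
        if env is None and config.env_table:
            env = read_env_table(config.env_table)
        if config.subcommunity_rank:
            if not config.taxonomy:
                raise InputFormatError("subcommunity extraction requires a taxonomy table")
            taxonomy = read_taxonomy(config.taxonomy)
            table = extract_subcommunity(
                table, taxonomy, config.subcommunity_rank, config.subcommunity_value
            )
        table = prune_table_to_tree(table, tree, allow_prune=config.prune_to_tree)
        metadata.require_samples(table.sample_ids)

    with _stage("rarefy"):
        if config.rarefaction_depth is not None:
            depth = (
                None
                if config.rarefaction_depth == "min"
                else int(config.rarefaction_depth)
            )
            table = rarefy(table, depth=depth, seed=_derive_seed(config.seed, "rarefy"))
            metadata = metadata.subset(table.sample_ids)
        else:
            metadata = metadata.subset(table.sample_ids)

    with _stage("turnover"):
        dist = cophenetic_distances(tree)
        bmntd_all = beta_mntd(table, dist, abundance_weighted=config.abundance_weighted)

    design = CascadeDesign(reservoirs=tuple(config.cascade))
    seasons = sorted(metadata.frame["season"].unique())
    per_pair_frames = []
    summaries: dict[str, dict] = {}

    for season in seasons:
        sample_ids = list(metadata.frame.index[metadata.frame["season"] == season])
        sub = table.select_samples(sample_ids).drop_empty_taxa()
        sub_meta = metadata.subset(sample_ids)
        events = [e for e in design.events.get(season, ()) if e in set(sub_meta.frame["event"])]
        if not events:  # non-standard designs: take whatever events are present
            events = sorted(sub_meta.frame["event"].unique())
        with _stage(f"pairs[{season}]"):
            pairs_df = connected_pairs(design, sub_meta, events=events)
        pair_list = list(zip(pairs_df["sample_a"], pairs_df["sample_b"]))

        with _stage(f"bnti[{season}]"):
            nti = beta_nti(
                sub,
                dist,
                n_iter=config.n_iter_bnti,
                seed=_derive_seed(config.seed, "bnti", season),
                pairs=pair_list,
                abundance_weighted=config.abundance_weighted,
            )
        merged = pairs_df.merge(nti, on=["sample_a", "sample_b"])

        with _stage(f"rc[{season}]"):
            selected = merged["bnti"].abs() > config.bnti_cut
            need_rc = (
                pair_list
                if config.exhaustive_rc
                else [p for p, s in zip(pair_list, selected.fillna(False)) if not s]
            )
            if need_rc:
                rc = raup_crick_bray(
                    sub,
                    pairs=need_rc,
                    n_iter=config.n_iter_rc,
                    seed=_derive_seed(config.seed, "rc", season),
                )
                merged = merged.merge(
                    rc[["sample_a", "sample_b", "bc_obs", "rc_bray"]],
                    on=["sample_a", "sample_b"],
                    how="left",
                )
            else:
                merged["bc_obs"] = np.nan
                merged["rc_bray"] = np.nan

        with _stage(f"classify[{season}]"):
            merged = classify_table(merged, bnti_cut=config.bnti_cut, rc_cut=config.rc_cut)
        per_pair_frames.append(merged)
        summaries[season] = summarize_processes(list(merged["process"])).to_dict()

    classified = pd.concat(per_pair_frames, ignore_index=True)
    summaries["total"] = summarize_processes(list(classified["process"])).to_dict()

    stats_results: dict[str, dict] = {"permanova": {}, "nmds": {}, "pca": None}
    with _stage("stats"):
        if len(seasons) > 1:
            res = permanova(
                bmntd_all,
                metadata.frame["season"],
                n_perm=config.n_perm,
                seed=_derive_seed(config.seed, "permanova", "season"),
                grouping_name="season",
            )
            stats_results["permanova"]["season"] = res.to_dict()
        nmds_inputs = {}
        for season in seasons:
            sample_ids = list(metadata.frame.index[metadata.frame["season"] == season])
            if len(set(metadata.frame.loc[sample_ids, "reservoir"])) < 2:
                continue
            sub = table.select_samples(sample_ids).drop_empty_taxa()
            bm = beta_mntd(sub, dist, abundance_weighted=config.abundance_weighted)
            res = permanova(
                bm,
                metadata.frame.loc[sample_ids, "reservoir"],
                n_perm=config.n_perm,
                seed=_derive_seed(config.seed, "permanova", season),
                grouping_name=f"reservoir[{season}]",
            )
            stats_results["permanova"][f"reservoir_{season}"] = res.to_dict()
            if res.p_value < config.alpha:
                nmds_inputs[season] = bm
        for season, bm in nmds_inputs.items():
            res = nmds(
                bm,
                k=2,
                n_restarts=config.nmds_restarts,
                seed=_derive_seed(config.seed, "nmds", season),
            )
            stats_results["nmds"][season] = {
                "stress": res.stress,
                "coordinates": res.coords_frame().to_dict(orient="index"),
            }
        if env is not None:
            env_use = env.loc[[s for s in table.sample_ids if s in env.index]]
            pca_res = pca(env_use)
            stats_results["pca"] = {
                "explained_variance_ratio": pca_res.explained_variance_ratio.tolist(),
                "scores": pca_res.scores_frame().iloc[:, :2].to_dict(orient="index"),
            }

    table1, table1_summary = summarize_table1(classified, design)

    bundle = {
        "config": dataclasses.asdict(config),
        "table": table,
        "metadata": metadata,
        "bmntd": bmntd_all,
        "per_pair": classified,
        "summaries": summaries,
        "stats": stats_results,
        "table1": table1,
        "table1_summary": table1_summary,
    }
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def summarize_table1(classified: pd.DataFrame, design: CascadeDesign):
    """Arrange per-pair labels as a pair x event grid plus percentage rows.

    Returns ``(grid, summary)`` where ``grid`` is a DataFrame (rows = adjacent
    reservoir pairs, columns = events) and ``summary`` maps each season and
    ``"total"`` to its Local/Regional/Stochastic percentages.
    """
    required = {"event", "season", "reservoir_a", "reservoir_b", "process"}
    missing = required - set(classified.columns)
    if missing:
        raise InputFormatError(f"classified frame missing columns: {sorted(missing)}")
    events = [e for evs in design.events.values() for e in evs
              if e in set(classified["event"])]
    pair_names = [f"{a} - {b}" for a, b in design.adjacent_reservoirs]
    grid = pd.DataFrame(index=pair_names, columns=events, dtype=object)
    for row in classified.itertuples():
        name = f"{row.reservoir_a} - {row.reservoir_b}"
        if name in grid.index and row.event in grid.columns:
            grid.loc[name, row.event] = row.process
    if grid.isna().any().any():
        holes = [
            f"({i}, {c})" for i in grid.index for c in grid.columns
            if pd.isna(grid.loc[i, c])
        ]
        raise InputFormatError(f"missing label cells: {', '.join(holes)}")

    summary = {}
    for season in sorted(classified["season"].unique()):
        labs = list(classified.loc[classified["season"] == season, "process"])
        summary[season] = summarize_processes(labs).to_dict()
    summary["total"] = summarize_processes(list(classified["process"])).to_dict()
    return grid, summary


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["per_pair"].to_csv(out_dir / "per_pair.tsv", sep="\t", index=False)
    bundle["bmntd"].write_tsv(out_dir / "bmntd.tsv")
    bundle["table1"].to_csv(out_dir / "table1.tsv", sep="\t", index_label="pair")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(
            {"processes": bundle["summaries"], "table1": bundle["table1_summary"]},
            fh, indent=2,
        )
    with open(out_dir / "stats.json", "w") as fh:
        json.dump(bundle["stats"], fh, indent=2)
    manifest = {
        "package": "phylocascade",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": bundle["config"],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("results written to %s", out_dir)
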