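"""Full-analysis orchestration: rarefy -> partition -> beta statistics ->
environmental screens -> assembly processes, driven by one YAML config.

Each stage derives its seed from the master ``rng_seed`` by stable hashing of
the stage name, writes deterministic TSV outputs under the run directory, and
records its status in a :class:`RunManifest` (written as ``manifest.json``).
A stage whose inputs are unavailable (e.g. no tree for the assembly stage) is
skipped with a recorded reason; downstream stages that do not depend on it
still run.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import assembly as assembly_mod
from . import beta as beta_mod
from . import diversity, environment, partition
from .io import (AnalysisConfig, CommunityTable, ValidationError, derive_seed,
                 logger, read_community_table, read_metadata, read_newick,
                 write_frame, write_results)
from .simulate import SyntheticScenario, scenario_presets, simulate_communities

__all__ = ["RunManifest", "run_pipeline"]

DEFAULT_CONTROLS = ("temperature", "depth", "salinity", "geographic")


@dataclass
class RunManifest:
    config: dict[str, Any]
    seeds: dict[str, int] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, list[str]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True,
                      default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, Mapping):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh) or {}


def run_pipeline(config: str | Path | Mapping[str, Any]) -> RunManifest:
    """Execute the full analysis described by a config file or dict.

    Config keys: ``output_dir`` (required); either ``inputs`` (paths
    ``table``, ``metadata``, optional ``tree``, optional ``orientation``) or
    ``scenario`` (a preset name or a dict of :class:`SyntheticScenario`
    fields) to self-generate data; ``analysis`` (AnalysisConfig fields);
    ``variables`` / ``controls`` for the Mantel screen.
    """
    cfg = _load_config(config)
    if "output_dir" not in cfg:
        raise ValidationError("config must name an output_dir")
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig.from_dict(cfg.get("analysis", {}))
    manifest = RunManifest(config=cfg)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        _run_stages(cfg, analysis, outdir, manifest)
    finally:
        logger.removeHandler(handler)
        handler.close()
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _emit(manifest: RunManifest, stage: str, outdir: Path,
          named: dict[str, Any]) -> None:
    paths = []
    for name, obj in named.items():
        path = outdir / name
        write_results(obj, path)
        paths.append(str(path))
    manifest.outputs[stage] = paths
    manifest.status[stage] = "ok"


def _run_stages(cfg: Mapping[str, Any], analysis: AnalysisConfig,
                outdir: Path, manifest: RunManifest) -> None:
    seed = analysis.rng_seed
    table = tree = meta = None

    # -- stage: inputs -----------------------------------------------------
    if "scenario" in cfg:
        requested = cfg["scenario"]
        if isinstance(requested, str):
            presets = scenario_presets(seed=derive_seed(seed, "scenario"))
            if requested not in presets:
                raise ValidationError(f"unknown scenario preset {requested!r}")
            scenario = presets[requested]
        else:
            fields = dict(requested)
            fields.setdefault("seed", derive_seed(seed, "scenario"))
            scenario = SyntheticScenario(**fields)
        table, meta, tree = simulate_communities(scenario)
        write_frame(meta.reset_index(), outdir / "metadata.tsv", index=False)
        _emit(manifest, "inputs", outdir, {"community.tsv": table})
        manifest.outputs["inputs"].append(str(outdir / "metadata.tsv"))
        tree_path = outdir / "tree.nwk"
        tree_path.write_text(tree.as_string(schema="newick"))
        manifest.outputs["inputs"].append(str(tree_path))
        for p in manifest.outputs["inputs"]:
            manifest.input_digests[Path(p).name] = _digest(Path(p))
    else:
        inputs = cfg.get("inputs")
        if not inputs or "table" not in inputs:
            raise ValidationError("config needs 'inputs: {table: ...}' "
                                  "or a 'scenario'")
        table = read_community_table(
            inputs["table"], inputs.get("orientation", "samples_as_rows"))
        manifest.input_digests["table"] = _digest(Path(inputs["table"]))
        if inputs.get("metadata"):
            meta = read_metadata(inputs["metadata"])
            manifest.input_digests["metadata"] = _digest(
                Path(inputs["metadata"]))
        if inputs.get("tree"):
            tree = read_newick(inputs["tree"])
            manifest.input_digests["tree"] = _digest(Path(inputs["tree"]))
        manifest.status["inputs"] = "ok"
        manifest.outputs["inputs"] = []

    groups = None
    if meta is not None and "group" in meta.columns:
        groups = meta["group"].astype(str)

    # -- stage: rarefy + alpha --------------------------------------------
    depth = analysis.rarefaction_depth or int(table.sample_sums().min())
    manifest.seeds["rarefy"] = derive_seed(seed, "rarefy")
    # OTUs that lose every read in the subsample are dropped downstream
    rarefied = diversity.rarefy(table, depth,
                                manifest.seeds["rarefy"]).drop_empty_otus()
    manifest.seeds["alpha"] = derive_seed(seed, "alpha")
    alpha = diversity.mean_alpha_over_resamples(
        table, depth, analysis.rarefaction_replicates,
        manifest.seeds["alpha"], analysis.shannon_base)
    _emit(manifest, "rarefy", outdir,
          {"rarefied.tsv": rarefied, "alpha_diversity.tsv": alpha})

    # -- stage: partition --------------------------------------------------
    part = partition.partition_all(
        rarefied, analysis.abundant_threshold, analysis.rare_threshold,
        analysis.per_sample_abundant_threshold,
        analysis.per_sample_rare_threshold)
    crat = pd.DataFrame({"otu_id": sorted(part.crat_otus)})
    _emit(manifest, "partition", outdir, {
        "partition_global.tsv": part.global_category.to_frame(),
        "partition_summary.tsv": part.summary,
        "partition_local.tsv": part.local_category,
        "crat.tsv": crat})

    # -- stage: beta -------------------------------------------------------
    dm = beta_mod.bray_curtis(rarefied)
    named: dict[str, Any] = {"bray_curtis.tsv": dm}
    ordination = beta_mod.pcoa(dm)
    named["pcoa_coordinates.tsv"] = ordination.coordinates
    named["pcoa_eigenvalues.tsv"] = pd.DataFrame({
        "eigenvalue": ordination.eigenvalues})
    dendro = beta_mod.upgma(dm)
    if groups is not None:
        manifest.seeds["anosim"] = derive_seed(seed, "anosim")
        named["anosim.tsv"] = pd.DataFrame([vars(r) for r in beta_mod.anosim(
            dm, groups, analysis.n_perm_anosim, manifest.seeds["anosim"])])
        simper_rows = []
        for res in beta_mod.simper(rarefied, groups,
                                   analysis.simper_cumulative_cut):
            df = res.contributions.reset_index()
            df.insert(0, "comparison", res.comparison)
            df["selected"] = df["otu_id"].isin(res.selected)
            simper_rows.append(df)
        named["simper.tsv"] = pd.concat(simper_rows, ignore_index=True)
    _emit(manifest, "beta", outdir, named)
    dendro_path = outdir / "upgma.nwk"
    dendro_path.write_text(dendro.newick + "\n")
    manifest.outputs["beta"].append(str(dendro_path))
    if groups is None:
        manifest.status["beta"] = "ok (anosim/simper skipped: no group labels)"

    # -- stage: environmental screens -------------------------------------
    if meta is None:
        manifest.status["environment"] = "skipped: no metadata"
    else:
        variables = cfg.get("variables") or [
            c for c in meta.columns
            if c != "group" and pd.api.types.is_numeric_dtype(meta[c])
            and meta[c].notna().sum() >= 4]
        controls = [c for c in cfg.get("controls", DEFAULT_CONTROLS)
                    if c == "geographic" or c in variables]
        if "latitude" in meta.columns and "longitude" in meta.columns:
            variables = list(variables) + ["geographic"] \
                if "geographic" not in variables else variables
        dms = {"total": dm}
        if part.global_category is not None:
            for name, cats in (("abundant", {"abundant"}),
                               ("rare", {"rare"})):
                otus = [o for o, c in part.global_category.items()
                        if c in cats]
                if len(otus) >= 2:
                    sub = rarefied.subset_otus(otus, drop_empty_samples=True)
                    if sub.n_samples >= 4:
                        dms[name] = beta_mod.bray_curtis(sub)
        manifest.seeds["mantel"] = derive_seed(seed, "mantel")
        screen = environment.mantel_screen(
            dms, meta, variables, controls,
            n_perm=analysis.n_perm_mantel, seed=manifest.seeds["mantel"])
        spear = environment.spearman_screen(
            alpha[["richness", "shannon"]], meta,
            [v for v in variables if v != "geographic"])
        _emit(manifest, "environment", outdir, {
            "mantel_screen.tsv": screen,
            "spearman_rho.tsv": spear.rho,
            "spearman_p.tsv": spear.p})

    # -- stage: assembly ---------------------------------------------------
    if tree is None:
        manifest.status["assembly"] = "skipped: no phylogeny supplied"
    else:
        manifest.seeds["assembly"] = derive_seed(seed, "assembly")
        pairs, summary = assembly_mod.assembly_analysis(
            rarefied, tree, analysis.n_null, manifest.seeds["assembly"],
            analysis.bnti_cut, analysis.rc_cut)
        summary_df = pd.DataFrame(
            {"process": list(summary.percent),
             "percent": list(summary.percent.values())})
        _emit(manifest, "assembly", outdir, {
            "assembly_pairs.tsv": pairs,
            "assembly_summary.tsv": summary_df})
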