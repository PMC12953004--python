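"""End-to-end orchestration: simulate/load -> rarefy -> diversity ->
assembly -> correlation -> per-stage networks -> stability, with a run
manifest capturing every parameter, seed and input checksum so any output
can be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .assembly import stage_fractions
from .containers import AbundanceTable, BiocrustError, DegenerateInputError
from .diversity import alpha_diversity, rarefy
from .io import (
    read_inputs,
    write_gephi_csvs,
    write_graphml,
    write_json,
    write_table,
    write_tree,
)
from .network import (
    build_network,
    classify_roles,
    compare_with_without_group,
    detect_modules,
    extract_focal_subnetwork,
    filter_taxa,
    keystone_nodes,
    robustness_random,
    robustness_targeted,
    topology_summary,
    vulnerability,
    zipi,
)
from .simulate import SimulationConfig, simulate_communities, simulate_tree
from .sparcc import sparcc_with_pvalues

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineStageError(BiocrustError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Every knob of the full pipeline, with the study's printed defaults."""

    # input paths (None -> simulate a fixture instead)
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    outdir: str = "biocrustnet_out"
    strict: bool = True

    # simulation fallback
    n_taxa: int = 150
    seq_depth: int = 10_000
    selection_regime: str = "homogeneous"
    selection_strength: float = 8.0
    cyano_fraction: float = 0.2

    # stage parameters
    do_rarefy: bool = True
    rarefaction_depth: int = 1648
    min_rel_abund: float = 0.001
    min_prevalence: int = 7
    sparcc_pseudocount: float = 1.0
    sparcc_exclusion_iter: int = 10
    sparcc_exclusion_threshold: float = 0.1
    n_boot: int = 100
    r_min: float = 0.65
    p_max: float = 0.05
    n_null: int = 999
    removal_fraction: float = 0.5
    n_perm: int = 100
    rng_seed: int = 42

    # stage toggles
    run_assembly: bool = True
    run_networks: bool = True

    def validate(self) -> None:
        if not 0 <= self.min_rel_abund < 1:
            raise BiocrustError("min_rel_abund must lie in [0, 1)")
        if not 0 < self.r_min <= 1 or not 0 < self.p_max <= 1:
            raise BiocrustError("network thresholds out of range")
        if not 0 < self.removal_fraction <= 1:
            raise BiocrustError("removal_fraction must lie in (0, 1]")
        if self.rarefaction_depth < 1:
            raise BiocrustError("rarefaction_depth must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise BiocrustError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


class _Stage:
    """Context manager that renames a failed stage's outputs to .partial."""

    def __init__(self, name: str, manifest: dict):
        self.name = name
        self.manifest = manifest
        self.outputs: list[Path] = []

    def emit(self, path) -> Path:
        p = Path(path)
        self.outputs.append(p)
        return p

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is None:
            self.manifest.setdefault("outputs", {})[self.name] = [str(p) for p in self.outputs]
            return False
        for p in self.outputs:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise PipelineStageError(f"stage '{self.name}' failed: {exc}") from exc


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every requested stage and write the result bundle to disk.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Deterministic for a fixed config and seed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "biocrustnet",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "versions": _library_versions(),
    }

    # ---- inputs ----------------------------------------------------------
    with _Stage("inputs", manifest) as st:
        if config.counts_path:
            table, tree = read_inputs(
                config.counts_path,
                config.taxonomy_path,
                config.metadata_path,
                config.tree_path,
                strict=config.strict,
            )
            manifest["input_checksums"] = {
                name: _sha256(p)
                for name, p in (
                    ("counts", config.counts_path),
                    ("taxonomy", config.taxonomy_path),
                    ("metadata", config.metadata_path),
                    ("tree", config.tree_path),
                )
                if p
            }
        else:
            sim = SimulationConfig(
                n_taxa=config.n_taxa,
                seq_depth=config.seq_depth,
                selection_regime=config.selection_regime,
                selection_strength=config.selection_strength,
                cyano_fraction=config.cyano_fraction,
                rng_seed=config.rng_seed,
            )
            tree = simulate_tree(sim.n_taxa, sim.rng_seed)
            table = simulate_communities(tree, sim)
            paths = write_table(table, outdir, prefix="simulated_")
            tree_path = st.emit(outdir / "simulated_tree.nwk")
            write_tree(tree, tree_path)
            for p in paths.values():
                st.emit(p)
            manifest["input_checksums"] = {
                name: _sha256(p) for name, p in {**paths, "tree": tree_path}.items()
            }
        if config.run_assembly and tree is None:
            raise BiocrustError("assembly stage requested but no tree provided")
        manifest["n_samples"] = table.n_samples
        manifest["n_taxa_input"] = table.n_taxa

    # ---- rarefaction -----------------------------------------------------
    if config.do_rarefy:
        with _Stage("rarefy", manifest) as st:
            table = rarefy(table, config.rarefaction_depth, rng_seed=config.rng_seed)
            manifest["n_samples_rarefied"] = table.n_samples

    # ---- diversity -------------------------------------------------------
    with _Stage("diversity", manifest) as st:
        div = alpha_diversity(table)
        _write_tsv(div.table, st.emit(outdir / "diversity.tsv"), index=False)

    # ---- assembly --------------------------------------------------------
    if config.run_assembly:
        with _Stage("assembly", manifest) as st:
            res = stage_fractions(
                table, tree, n_null=config.n_null, rng_seed=config.rng_seed
            )
            _write_tsv(res.pairs, st.emit(outdir / "bnti_pairs.tsv"), index=False)
            _write_tsv(res.stage_fractions, st.emit(outdir / "assembly_fractions.tsv"))

    # ---- per-stage networks + stability ---------------------------------
    if config.run_networks:
        with _Stage("networks", manifest) as st:
            topo_rows, stab_rows, role_frames = [], [], []
            for stage in table.stages():
                try:
                    stage_table = filter_taxa(
                        table, config.min_rel_abund, config.min_prevalence, stage=stage
                    )
                except DegenerateInputError:
                    logger.warning("stage %s: no taxa pass the filter; skipped", stage)
                    continue
                corr = sparcc_with_pvalues(
                    stage_table,
                    n_boot=config.n_boot,
                    rng_seed=config.rng_seed,
                    n_exclusion_iter=config.sparcc_exclusion_iter,
                    exclusion_threshold=config.sparcc_exclusion_threshold,
                    pseudocount=config.sparcc_pseudocount,
                )
                mean_rel = stage_table.relative_abundance().mean(axis=1)
                try:
                    net = build_network(
                        corr, stage_table.taxon_meta, config.r_min, config.p_max, mean_rel
                    )
                except DegenerateInputError:
                    logger.warning("stage %s: no edges pass thresholds; skipped", stage)
                    continue
                partition = detect_modules(net, rng_seed=config.rng_seed)
                roles = classify_roles(zipi(net, partition))
                roles.insert(0, "stage", stage)
                role_frames.append(roles)
                topo = topology_summary(net, partition)
                topo["stage"] = stage
                topo_rows.append(topo)
                write_graphml(net, st.emit(outdir / f"network_{stage}.graphml"))
                write_gephi_csvs(
                    net,
                    st.emit(outdir / f"network_{stage}_nodes.csv"),
                    st.emit(outdir / f"network_{stage}_edges.csv"),
                )

                rob = robustness_random(
                    net, config.removal_fraction, config.n_perm, config.rng_seed
                )
                try:
                    vul = vulnerability(net)
                except BiocrustError:
                    vul = float("nan")
                stab_rows.append(
                    {
                        "stage": stage,
                        "network": "Ctr",
                        "robustness_mean": rob.mean(),
                        "robustness_sd": rob.std(ddof=1),
                        "vulnerability": vul,
                        "p_vs_without_cyano": np.nan,
                    }
                )
                ks = keystone_nodes(roles)
                if ks:
                    curve = robustness_targeted(net, ks)
                    stab_rows[-1]["robustness_after_keystone_removal"] = curve[-1]
                has_cyano = any(
                    d.get("is_cyanobacterium") for _, d in net.nodes(data=True)
                )
                if has_cyano:
                    try:
                        cmp_res = compare_with_without_group(
                            net,
                            "is_cyanobacterium",
                            fraction=config.removal_fraction,
                            n_perm=config.n_perm,
                            rng_seed=config.rng_seed,
                        )
                    except (BiocrustError, DegenerateInputError):
                        cmp_res = None
                    if cmp_res is not None:
                        stab_rows[-1]["p_vs_without_cyano"] = cmp_res.p_value
                        rob_o = cmp_res.stability_without.robustness_samples["random"]
                        stab_rows.append(
                            {
                                "stage": stage,
                                "network": "Cyr",
                                "robustness_mean": rob_o.mean(),
                                "robustness_sd": rob_o.std(ddof=1),
                                "vulnerability": cmp_res.stability_without.vulnerability,
                                "p_vs_without_cyano": cmp_res.p_value,
                            }
                        )
                    _, sub_summary = extract_focal_subnetwork(net, "is_cyanobacterium")
                    manifest.setdefault("focal_subnetworks", {})[str(stage)] = sub_summary
            if role_frames:
                _write_tsv(
                    pd.concat(role_frames).rename_axis("taxon"),
                    st.emit(outdir / "roles.tsv"),
                )
            if topo_rows:
                _write_tsv(
                    pd.DataFrame(topo_rows).set_index("stage"),
                    st.emit(outdir / "topology.tsv"),
                )
            if stab_rows:
                _write_tsv(
                    pd.DataFrame(stab_rows).set_index(["stage", "network"]),
                    st.emit(outdir / "stability.tsv"),
                )

    write_json(manifest, outdir / "manifest.json")
    return manifest


def _library_versions() -> dict:
    import networkx
    import scipy
    import skbio

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "scikit-bio": skbio.__version__,
    }
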