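"""End-to-end pipeline orchestration from a single configuration mapping.

A pipeline run generates (or loads) a dataset, then executes the analysis
stages in dependency order, writing each stage's tabular outputs plus a run
manifest (parameters, seed, package version, output checksums) so any stage
can be reproduced in isolation. Stage parameters live under per-stage blocks
of the config; one global seed drives every stochastic stage through
deterministic offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cnv as tcnv
from . import genotyping, io, repertoire, scoring, simulate, spatial

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "default_config"]


def default_config(out_dir: str = "pipeline_out", seed: int = 0) -> dict:
    """A small but complete synthetic end-to-end configuration."""
    return {
        "out_dir": out_dir,
        "seed": seed,
        "synthesize": {
            "n_tumor": 300,
            "n_normal": 500,
            "clone_fraction": 1.0,
            "single_chain_fraction": 0.3,
            "cnv_chrom": "chr5",
            "cnv_dosage": 1.5,
            "cnv_carrier_fraction": 0.5,
            "mutation_locus": "RHOA_G17V",
            "capture_prob": 0.6,
            "mean_coverage": 5.0,
        },
        "repertoire": {"min_major_fraction": 0.05, "min_minor_fraction": 0.01},
        "genotyper": {"min_total_coverage": 100, "min_mut_cells": 20},
        "cnv": {"window": 51, "gain_threshold": 0.1, "loss_threshold": -0.1,
                "min_window_fraction": 0.5, "n_subclones": 2},
        "spatial": {"radius": 15.0, "n_perm": 200, "alpha": 0.01},
        "stages": ["synthesize", "repertoire", "genotyper", "cnv", "scores", "spatial"],
    }


def _sim_config(block: dict, seed: int) -> simulate.SimConfig:
    program = tuple(f"G{i:04d}" for i in range(10))
    return simulate.SimConfig(
        populations=(
            simulate.PopulationSpec("tumor_TFH", block["n_tumor"], program_genes=program,
                                    program_fc=3.0, is_tumor=True),
            simulate.PopulationSpec("normal_T", block["n_normal"]),
        ),
        tumor_clone_specs=(
            simulate.CloneSpec("clone1", fraction=block["clone_fraction"],
                               single_chain_fraction=block["single_chain_fraction"]),
        ),
        cnv_events=(
            simulate.CNVEvent(block["cnv_chrom"], block["cnv_dosage"],
                              block["cnv_carrier_fraction"]),
        ),
        mutation_specs=(
            simulate.MutationSpec(block["mutation_locus"], True,
                                  block["capture_prob"], block["mean_coverage"]),
        ),
        spatial_spec=simulate.SpatialSpec(
            n_images=2,
            background_counts={"Tumor": 120, "CD8_TEFF": 120},
            attraction_pairs=(simulate.AttractionPair("Tumor", "CD8_TDYS"),),
        ),
        seed=seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict) -> Path:
    """Run the configured stages; returns the output directory.

    Stage failures raise with the stage name; outputs of completed stages are
    retained. A stage is skipped when absent from ``config['stages']``.
    """
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages") or ["synthesize"]
    manifest = {"version": __version__, "seed": seed, "config": {
        k: v for k, v in config.items() if k != "stages"}, "stages": {}}

    state: dict = {}
    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            _STAGES[stage](config, seed, out, state)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*")) if p.is_file()},
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _stage_synthesize(config, seed, out, state):
    block = config["synthesize"]
    sim = _sim_config(block, seed)
    simulate.write_dataset(sim, out)
    state["sim"] = sim
    state["matrix"], state["truth"] = simulate.generate_expression(sim)
    state["contigs"] = simulate.generate_contigs(sim, state["truth"])
    state["pileup"] = simulate.generate_pileups(sim, state["truth"])
    state["positions"] = sim.gene_table()


def _load_inputs(config, out, state):
    if "matrix" not in state:
        state["matrix"] = io.read_count_matrix(out)
        state["contigs"] = io.read_contigs(out / "filtered_contig_annotations.csv")
        state["pileup"] = io.read_pileup(out / "pileup.tsv")
        state["positions"] = io.read_gene_positions(out / "gene_positions.tsv")


def _stage_repertoire(config, seed, out, state):
    _load_inputs(config, out, state)
    params = config.get("repertoire", {})
    assign = repertoire.assemble_clonotypes(state["contigs"])
    calls = repertoire.call_tumor_clones(
        assign,
        min_major_fraction=params.get("min_major_fraction", 0.05),
        min_minor_fraction=params.get("min_minor_fraction", 0.01),
    )
    assign.to_csv(out / "clonotypes.tsv", sep="\t")
    calls.cell_is_tumor.rename("is_tumor").to_csv(out / "tumor_calls.tsv", sep="\t")
    state["assignments"] = assign
    state["tumor_calls"] = calls


def _stage_genotyper(config, seed, out, state):
    _load_inputs(config, out, state)
    params = config.get("genotyper", {})
    kept = genotyping.filter_loci(
        state["pileup"],
        min_total_coverage=params.get("min_total_coverage", 100),
        min_mut_cells=params.get("min_mut_cells", 20),
    )
    frames = []
    for locus_id in kept:
        locus = genotyping.Locus(locus_id, genotyping.MUTANT_BY_WES)
        frames.append(genotyping.call_genotypes(state["pileup"], locus))
    calls = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    calls.to_csv(out / "genotype_calls.tsv", sep="\t", index=False)
    if not calls.empty:
        genotyping.genotype_fraction_summary(calls).to_csv(
            out / "locus_summary.tsv", sep="\t", index=False)
    state["genotype_calls"] = calls


def _stage_cnv(config, seed, out, state):
    _load_inputs(config, out, state)
    params = config.get("cnv", {})
    tumor = state["tumor_calls"].cell_is_tumor
    reference = [b for b in state["matrix"].barcodes if not tumor.get(b, False)]
    rel, genes, chroms = tcnv.compute_relative_expression(
        state["matrix"], state["positions"], reference)
    profile = tcnv.smooth_by_position(rel, genes, chroms, state["matrix"].barcodes,
                                      window=params.get("window", 101))
    calls = tcnv.call_chromosome_cnv(
        profile,
        gain_threshold=params.get("gain_threshold", 0.1),
        loss_threshold=params.get("loss_threshold", -0.1),
        min_window_fraction=params.get("min_window_fraction", 0.5),
    )
    calls.to_csv(out / "cnv_calls.tsv", sep="\t", index=False)
    scores = tcnv.cnv_score(profile)
    scores.to_csv(out / "cnv_scores.tsv", sep="\t")
    tumor_barcodes = [b for b in state["matrix"].barcodes if tumor.get(b, False)]
    if len(tumor_barcodes) >= 2:
        tumor_idx = [profile.barcodes.index(b) for b in tumor_barcodes]
        tumor_profile = tcnv.CNVProfile(profile.values[tumor_idx], tumor_barcodes,
                                        profile.genes, profile.chroms, profile.window)
        labels = tcnv.cluster_subclones(tumor_profile, k=params.get("n_subclones", 2))
        means = pd.DataFrame(tumor_profile.values, index=tumor_barcodes).groupby(labels).mean()
        means.index = [f"subclone{i}" for i in means.index]
        tree = tcnv.build_clone_tree(means)
        tree.write(str(out / "clone_tree.nwk"))
        labels.to_csv(out / "subclones.tsv", sep="\t")
    state["cnv_profile"] = profile
    state["cnv_calls"] = calls


def _stage_scores(config, seed, out, state):
    _load_inputs(config, out, state)
    program = scoring.GeneSet("tumor_program", tuple(f"G{i:04d}" for i in range(10)))
    scores = scoring.signature_score(state["matrix"], program)
    scores.to_csv(out / "signature_scores.tsv", sep="\t")
    state["signature_scores"] = scores


def _stage_spatial(config, seed, out, state):
    params = config.get("spatial", {})
    path = out / "spatial_cells.csv"
    if not path.exists():
        logger.info("no spatial table; skipping spatial stage")
        return
    cells = io.read_spatial(path)
    graphs = spatial.build_neighbor_graph(cells, rule="radius",
                                          param=params.get("radius", 15.0))
    results = spatial.all_pairs_interactions(
        graphs, n_perm=params.get("n_perm", 1000), seed=seed,
        alpha=params.get("alpha", 0.01))
    per_image = pd.DataFrame([r.__dict__ for r in results])
    per_image.to_csv(out / "per_image_results.tsv", sep="\t", index=False)
    spatial.summarize_across_images(results).to_csv(
        out / "interaction_matrix.tsv", sep="\t", index=False)
    state["spatial_results"] = results


_STAGES = {
    "synthesize": _stage_synthesize,
    "repertoire": _stage_repertoire,
    "genotyper": _stage_genotyper,
    "cnv": _stage_cnv,
    "scores": _stage_scores,
    "spatial": _stage_spatial,
}
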