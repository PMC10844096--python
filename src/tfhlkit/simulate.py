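"""Synthetic single-cell TFHL datasets with known ground truth.

The generator plants every structure the downstream analytics are built to
detect: a dominant tumor TCR clone (optionally two clones sharing a TRB chain
but differing in TRA), a configurable fraction of single-chain tumor cells,
expanded background clonotypes shared across clusters, a chromosome-dosage
gain in a tumor subpopulation, point mutations subject to per-cell capture
dropout, tumor-restricted marker genes, a gene-program expression gradient,
and spatially attracting or avoiding cell-type pairs.

UMI counts follow a negative binomial with mean
``baseline x program-fold-change x marker-fold-change x dosage`` and a shared
dispersion; ``dispersion = inf`` gives the Poisson limit. Identical configs
(including the seed) reproduce outputs bit for bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as tio

__all__ = [
    "PopulationSpec",
    "CloneSpec",
    "ExpandedCloneSpec",
    "CNVEvent",
    "MutationSpec",
    "AttractionPair",
    "AvoidancePair",
    "SpatialSpec",
    "SimConfig",
    "SyntheticTruth",
    "generate_expression",
    "generate_contigs",
    "generate_pileups",
    "generate_spatial",
    "write_dataset",
    "random_cdr3_nt",
]

_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
V_GENES_TRA = ["TRAV1-2", "TRAV8-4", "TRAV12-1", "TRAV19"]
J_GENES_TRA = ["TRAJ33", "TRAJ20", "TRAJ49"]
V_GENES_TRB = ["TRBV20-1", "TRBV19", "TRBV5-1", "TRBV7-9"]
J_GENES_TRB = ["TRBJ2-1", "TRBJ2-7", "TRBJ1-2"]


def random_cdr3_nt(rng: np.random.Generator, lo: int = 30, hi: int = 45) -> str:
    """Random CDR3 nucleotide string, length uniform in [lo, hi], multiple of 3."""
    length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
    return "".join(rng.choice(_NT, size=length))


def _random_aa(rng: np.random.Generator, n_codons: int) -> str:
    return "C" + "".join(rng.choice(_AA, size=max(n_codons - 2, 1))) + "F"


@dataclass
class PopulationSpec:
    """A cell population with an optional up-regulated gene program."""

    name: str
    n_cells: int
    program_genes: tuple = ()
    program_fc: float = 1.0
    is_tumor: bool = False
    tissue: str = "LN"


@dataclass
class CloneSpec:
    """A planted tumor clonotype.

    ``fraction`` is the fraction of tumor cells carrying the clone;
    ``single_chain_fraction`` of those cells lose one chain (alpha or beta,
    chosen at random) to emulate single-chain TCR tumor cells.
    """

    clone_id: str
    fraction: float
    single_chain_fraction: float = 0.0
    tra_nt: Optional[str] = None
    trb_nt: Optional[str] = None


@dataclass
class ExpandedCloneSpec:
    """A shared non-tumor clonotype (e.g., an expanded CD8 clone) planted
    across the listed populations with the given cell count."""

    clone_id: str
    n_cells: int
    populations: tuple = ()


@dataclass
class CNVEvent:
    chrom: str
    dosage: float  # multiplicative effect on the mean, >= 0
    carrier_fraction: float = 1.0  # fraction of tumor cells carrying the event
    #: events with the same group index affect the same carrier cells, letting
    #: nested events (e.g., chr5 gain plus chr21 gain in a subset) be planted.
    group: Optional[str] = None


@dataclass
class MutationSpec:
    locus_id: str
    mutant_patient: bool = True
    capture_prob: float = 0.6
    mean_coverage: float = 5.0


@dataclass
class AttractionPair:
    type_a: str
    type_b: str
    cluster_radius: float = 20.0
    n_parents: int = 30
    mean_offspring: float = 6.0


@dataclass
class AvoidancePair:
    type_a: str
    type_b: str
    n_cells_each: int = 150


@dataclass
class SpatialSpec:
    n_images: int = 3
    field_size: float = 600.0  # square field edge, micrometres
    #: homogeneous Poisson background: cell type -> expected count per image
    background_counts: dict = field(default_factory=dict)
    attraction_pairs: tuple = ()
    avoidance_pairs: tuple = ()


def _default_chromosomes() -> dict:
    # chromosomes recurrently gained in TFHL (5, 7, 19, 21, 22) are included;
    # 150 genes per chromosome approximates the per-chromosome information of
    # a filtered real transcriptome at this library depth
    chroms = ["chr1", "chr2", "chr3", "chr4", "chr5", "chr6", "chr7", "chr19", "chr21", "chr22"]
    return {c: 150 for c in chroms}


@dataclass
class SimConfig:
    """Full description of one synthetic sample."""

    populations: tuple
    tumor_clone_specs: tuple = ()
    expanded_clones: tuple = ()
    cnv_events: tuple = ()
    mutation_specs: tuple = ()
    marker_genes: tuple = ()
    #: marker genes are tumor-restricted: near-silent baseline in every cell,
    #: strongly induced in tumor cells (the tumor-specific-marker phenotype)
    marker_baseline: float = 0.05
    marker_fc: float = 30.0
    chromosomes: dict = field(default_factory=_default_chromosomes)
    nb_mean: float = 5.0  # per-gene baseline; ~7.5k UMIs/cell at the default panel
    nb_dispersion: float = 10.0  # inf => Poisson
    spatial_spec: Optional[SpatialSpec] = None
    sample_id: str = "S1"
    patient_id: str = "P1"
    tissue: str = "LN"
    status: str = "ND"
    seed: int = 0

    def __post_init__(self):
        if not self.populations:
            raise ValueError("populations must be nonempty")
        for clone in self.tumor_clone_specs:
            for frac, label in (
                (clone.fraction, "fraction"),
                (clone.single_chain_fraction, "single_chain_fraction"),
            ):
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"clone {clone.clone_id}: {label}={frac} outside [0, 1]")
        for ev in self.cnv_events:
            if ev.dosage < 0:
                raise ValueError(f"dosage must be >= 0, got {ev.dosage}")
            if not 0.0 <= ev.carrier_fraction <= 1.0:
                raise ValueError("carrier_fraction outside [0, 1]")
            if ev.chrom not in self.chromosomes:
                raise ValueError(f"CNV event on unknown chromosome {ev.chrom!r}")
        for mut in self.mutation_specs:
            if not 0.0 <= mut.capture_prob <= 1.0:
                raise ValueError(f"capture probability {mut.capture_prob} outside [0, 1]")
        if self.spatial_spec is not None:
            att = {frozenset((p.type_a, p.type_b)) for p in self.spatial_spec.attraction_pairs}
            avo = {frozenset((p.type_a, p.type_b)) for p in self.spatial_spec.avoidance_pairs}
            clash = att & avo
            if clash:
                raise ValueError(f"pairs both attracted and avoided: {sorted(map(sorted, clash))}")

    def gene_table(self) -> pd.DataFrame:
        """Gene universe with genomic positions (1-based, 10 kb spacing)."""
        rows = []
        i = 0
        for chrom, n in self.chromosomes.items():
            for j in range(n):
                start = j * 10_000 + 1
                rows.append((f"G{i:04d}", chrom, start, start + 2_000))
                i += 1
        return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


@dataclass
class SyntheticTruth:
    """Ground-truth labels for every generated cell."""

    cells: pd.DataFrame  # barcode, population, is_tumor, clone_id, tissue
    cnv_carriers: pd.DataFrame  # barcode x event columns (bool)
    mutation_status: pd.DataFrame  # barcode x locus columns (bool)
    spatial_groups: Optional[pd.DataFrame] = None  # spatial cell -> construction label

    def to_json(self) -> str:
        payload = {
            "cells": self.cells.to_dict(orient="list"),
            "cnv_carriers": self.cnv_carriers.to_dict(orient="list"),
            "mutation_status": self.mutation_status.to_dict(orient="list"),
        }
        if self.spatial_groups is not None:
            payload["spatial_groups"] = self.spatial_groups.to_dict(orient="list")
        return json.dumps(payload)


def _rng_for(config: SimConfig, stream: str) -> np.random.Generator:
    # independent deterministic streams so each generator is reproducible on
    # its own regardless of which others have been called
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def _nb_sample(rng, mean, dispersion):
    """Negative binomial with mean/dispersion parameterization via
    gamma-Poisson mixing; infinite dispersion is the Poisson limit."""
    if np.isinf(dispersion):
        return rng.poisson(mean)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def generate_expression(config: SimConfig) -> tuple[tio.CountMatrix, SyntheticTruth]:
    """Sample the UMI count matrix and assign all cell-level truth labels."""
    rng = _rng_for(config, "expression")
    genes_df = config.gene_table()
    gene_names = genes_df["gene"].tolist()
    gene_pos = pd.Index(gene_names)
    n_genes = len(gene_names)

    for pop in config.populations:
        unknown = [g for g in pop.program_genes if g not in gene_pos]
        if unknown:
            raise ValueError(f"population {pop.name!r}: unknown program genes {unknown[:5]}")
    unknown_markers = [g for g in config.marker_genes if g not in gene_pos]
    if unknown_markers:
        raise ValueError(f"unknown marker genes {unknown_markers[:5]}")

    # --- assemble the cell roster
    rows = []
    for pop in config.populations:
        for _ in range(pop.n_cells):
            rows.append((pop.name, pop.is_tumor, pop.tissue))
    cells = pd.DataFrame(rows, columns=["population", "is_tumor", "tissue"])
    cells.insert(0, "barcode", [f"CELL{i:05d}-1" for i in range(len(cells))])

    # --- tumor clone assignment (multinomial over configured fractions)
    clone_ids = np.full(len(cells), "", dtype=object)
    tumor_idx = np.flatnonzero(cells["is_tumor"].to_numpy())
    if config.tumor_clone_specs and tumor_idx.size:
        fracs = np.array([c.fraction for c in config.tumor_clone_specs])
        if fracs.sum() > 1.0 + 1e-9:
            raise ValueError("tumor clone fractions sum to more than 1")
        u = rng.random(tumor_idx.size)
        edges = np.concatenate([[0.0], np.cumsum(fracs)])
        for k, clone in enumerate(config.tumor_clone_specs):
            take = (u >= edges[k]) & (u < edges[k + 1])
            clone_ids[tumor_idx[take]] = clone.clone_id
    cells["clone_id"] = clone_ids

    # --- CNV carrier flags: events sharing a group label hit nested subsets
    # of the same carrier pool so clone trees have a known topology
    carrier_flags = {}
    group_order = {}
    for ev in config.cnv_events:
        key = ev.group or f"{ev.chrom}:{ev.dosage}"
        if key not in group_order:
            group_order[key] = rng.permutation(tumor_idx)
        pool = group_order[key]
        n_carriers = int(round(ev.carrier_fraction * pool.size))
        flags = np.zeros(len(cells), dtype=bool)
        flags[pool[:n_carriers]] = True
        carrier_flags[f"{ev.chrom}|{ev.dosage}"] = flags
    cnv_carriers = pd.DataFrame(carrier_flags, index=cells["barcode"]) if carrier_flags else \
        pd.DataFrame(index=cells["barcode"])
    cnv_carriers.index.name = "barcode"

    # --- mutation truth: tumor cells of a mutant patient carry the mutation
    mut_flags = {}
    for mut in config.mutation_specs:
        mut_flags[mut.locus_id] = cells["is_tumor"].to_numpy() & mut.mutant_patient
    mutation_status = pd.DataFrame(mut_flags, index=cells["barcode"]) if mut_flags else \
        pd.DataFrame(index=cells["barcode"])
    mutation_status.index.name = "barcode"

    # --- per-cell x per-gene mean matrix (genes x cells), multiplicative
    means = np.full((n_genes, len(cells)), float(config.nb_mean))
    pop_col = cells["population"].to_numpy()
    for pop in config.populations:
        if pop.program_genes and pop.program_fc != 1.0:
            gidx = gene_pos.get_indexer(list(pop.program_genes))
            cidx = np.flatnonzero(pop_col == pop.name)
            means[np.ix_(gidx, cidx)] *= pop.program_fc
    if config.marker_genes:
        gidx = gene_pos.get_indexer(list(config.marker_genes))
        means[gidx, :] = config.marker_baseline
        means[np.ix_(gidx, tumor_idx)] = config.marker_baseline * config.marker_fc
    chrom_series = genes_df.set_index("gene")["chrom"]
    for key, flags in carrier_flags.items():
        chrom, dosage = key.split("|")
        gidx = np.flatnonzero((chrom_series == chrom).to_numpy())
        cidx = np.flatnonzero(flags)
        means[np.ix_(gidx, cidx)] *= float(dosage)

    counts = _nb_sample(rng, means, config.nb_dispersion)
    matrix = tio.CountMatrix(gene_names, cells["barcode"].tolist(), sp.csr_matrix(counts))
    truth = SyntheticTruth(cells=cells, cnv_carriers=cnv_carriers, mutation_status=mutation_status)
    return matrix, truth


def generate_contigs(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Sample a 10x-style contig table consistent with the clone truth.

    Tumor cells of a clone share identical productive TRA/TRB nucleotide
    CDR3s; a configured fraction keep only one chain. Non-tumor cells receive
    unique clonotypes except planted expanded clones shared across the listed
    populations.
    """
    rng = _rng_for(config, "contigs")
    clone_by_id = {c.clone_id: c for c in config.tumor_clone_specs}

    # materialize fixed chains per clone
    chains = {}
    for clone in config.tumor_clone_specs:
        tra = clone.tra_nt or random_cdr3_nt(rng)
        trb = clone.trb_nt or random_cdr3_nt(rng)
        chains[clone.clone_id] = {
            "TRA": (rng.choice(V_GENES_TRA), rng.choice(J_GENES_TRA), tra),
            "TRB": (rng.choice(V_GENES_TRB), rng.choice(J_GENES_TRB), trb),
        }
    for exp in config.expanded_clones:
        chains[exp.clone_id] = {
            "TRA": (rng.choice(V_GENES_TRA), rng.choice(J_GENES_TRA), random_cdr3_nt(rng)),
            "TRB": (rng.choice(V_GENES_TRB), rng.choice(J_GENES_TRB), random_cdr3_nt(rng)),
        }

    # pick cells for expanded background clones
    cells = truth.cells
    expanded_assignment = {}
    used = set()
    for exp in config.expanded_clones:
        pool = cells.index[~cells["is_tumor"]]
        if exp.populations:
            pool = pool[cells.loc[pool, "population"].isin(exp.populations)]
        pool = [i for i in pool if i not in used]
        if len(pool) < exp.n_cells:
            raise ValueError(f"not enough non-tumor cells for expanded clone {exp.clone_id}")
        chosen = rng.choice(len(pool), size=exp.n_cells, replace=False)
        for i in chosen:
            expanded_assignment[pool[i]] = exp.clone_id
            used.add(pool[i])

    rows = []

    def emit(barcode, chain, v, j, nt):
        aa = _random_aa(rng, len(nt) // 3)
        umis = 1 + int(rng.poisson(3))
        rows.append((barcode, chain, v, j, aa, nt, True, umis))

    for i, row in cells.iterrows():
        barcode = row["barcode"]
        if row["is_tumor"] and row["clone_id"]:
            clone = clone_by_id[row["clone_id"]]
            ch = chains[row["clone_id"]]
            drop = None
            if clone.single_chain_fraction > 0 and rng.random() < clone.single_chain_fraction:
                drop = "TRA" if rng.random() < 0.5 else "TRB"
            for chain in ("TRA", "TRB"):
                if chain != drop:
                    emit(barcode, chain, *ch[chain])
        elif i in expanded_assignment:
            ch = chains[expanded_assignment[i]]
            for chain in ("TRA", "TRB"):
                emit(barcode, chain, *ch[chain])
        else:
            # unique singleton clonotype
            emit(barcode, "TRA", rng.choice(V_GENES_TRA), rng.choice(J_GENES_TRA),
                 random_cdr3_nt(rng))
            emit(barcode, "TRB", rng.choice(V_GENES_TRB), rng.choice(J_GENES_TRB),
                 random_cdr3_nt(rng))

    contigs = pd.DataFrame(
        rows,
        columns=["barcode", "chain", "v_gene", "j_gene", "cdr3_aa", "cdr3_nt", "productive", "umis"],
    )
    return contigs


def generate_pileups(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Per-cell read pileups at each configured locus.

    Coverage is Poisson(mean_coverage). A true-mutant cell yields alternate
    reads only if its transcript is captured (Bernoulli(capture_prob)) and it
    has coverage; non-mutant cells never receive alternate reads.
    """
    if not config.mutation_specs:
        raise ValueError("mutation_specs is empty")
    rng = _rng_for(config, "pileups")
    barcodes = truth.cells["barcode"].to_numpy()
    frames = []
    for mut in config.mutation_specs:
        n = len(barcodes)
        coverage = rng.poisson(mut.mean_coverage, size=n)
        is_mut = truth.mutation_status[mut.locus_id].to_numpy()
        captured = rng.random(n) < mut.capture_prob
        alt = np.zeros(n, dtype=int)
        sel = is_mut & captured & (coverage > 0)
        # heterozygous-like allele fraction; at least one alt read if captured
        alt[sel] = 1 + rng.binomial(coverage[sel] - 1, 0.5)
        ref = coverage - alt
        frames.append(pd.DataFrame({
            "barcode": barcodes,
            "locus": mut.locus_id,
            "ref_reads": ref,
            "alt_reads": alt,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["total"] = out["ref_reads"] + out["alt_reads"]
    return out


def generate_spatial(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Spatial cell tables with planted attraction and avoidance.

    Background types follow a homogeneous Poisson point process; attraction
    pairs a parent-offspring (Neyman-Scott) process in which both types
    scatter around shared parents within the cluster radius; avoidance pairs
    occupy disjoint half-fields.
    """
    spec = config.spatial_spec
    if spec is None:
        raise ValueError("spatial_spec not configured")
    if spec.field_size <= 0:
        raise ValueError("field size must be positive")
    rng = _rng_for(config, "spatial")
    L = spec.field_size
    rows = []
    groups = []

    for img in range(spec.n_images):
        image_id = f"IMG{img}"
        for ctype, mean_count in spec.background_counts.items():
            n = rng.poisson(mean_count)
            xy = rng.random((n, 2)) * L
            for x, y in xy:
                rows.append((image_id, x, y, ctype))
                groups.append("background")
        for pair in spec.attraction_pairs:
            parents = rng.random((pair.n_parents, 2)) * L
            for pi, (px, py) in enumerate(parents):
                for ctype in (pair.type_a, pair.type_b):
                    n_off = rng.poisson(pair.mean_offspring)
                    r = pair.cluster_radius * np.sqrt(rng.random(n_off))
                    theta = rng.random(n_off) * 2 * np.pi
                    xs = np.clip(px + r * np.cos(theta), 0, L)
                    ys = np.clip(py + r * np.sin(theta), 0, L)
                    for x, y in zip(xs, ys):
                        rows.append((image_id, x, y, ctype))
                        groups.append(f"attract:{pair.type_a}-{pair.type_b}:parent{pi}")
        # opposite bands separated by a quarter-field guard gap, so the two
        # types share no neighbors at any radius below field/4
        for pair in spec.avoidance_pairs:
            for ctype, (lo, hi) in ((pair.type_a, (0.0, 0.375)), (pair.type_b, (0.625, 1.0))):
                xs = (lo + rng.random(pair.n_cells_each) * (hi - lo)) * L
                ys = rng.random(pair.n_cells_each) * L
                for x, y in zip(xs, ys):
                    rows.append((image_id, x, y, ctype))
                    groups.append(f"avoid:{pair.type_a}-{pair.type_b}")

    cells = pd.DataFrame(rows, columns=["image_id", "x_um", "y_um", "cell_type"])
    spatial_groups = pd.DataFrame({"group": groups})
    truth = SyntheticTruth(
        cells=pd.DataFrame(columns=["barcode", "population", "is_tumor", "clone_id", "tissue"]),
        cnv_carriers=pd.DataFrame(),
        mutation_status=pd.DataFrame(),
        spatial_groups=spatial_groups,
    )
    return cells, truth


def cell_metadata(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """CellMeta table for the generated sample (cluster = population name)."""
    cells = truth.cells
    return pd.DataFrame({
        "barcode": cells["barcode"],
        "sample": config.sample_id,
        "patient": config.patient_id,
        "tissue": cells["tissue"],
        "status": config.status,
        "cluster": cells["population"],
    })


def write_dataset(config: SimConfig, out_dir) -> Path:
    """Generate the full fixture set and write it under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(config)
    tio.write_count_matrix(matrix, out)
    tio.write_gene_positions(config.gene_table(), out / "gene_positions.tsv")
    tio.write_cellmeta(cell_metadata(config, truth), out / "cells.tsv")
    contigs = generate_contigs(config, truth)
    tio.write_contigs(contigs, out / "filtered_contig_annotations.csv")
    if config.mutation_specs:
        tio.write_pileup(generate_pileups(config, truth), out / "pileup.tsv")
    if config.spatial_spec is not None:
        spatial, sp_truth = generate_spatial(config)
        tio.write_spatial(spatial, out / "spatial_cells.csv")
        truth.spatial_groups = sp_truth.spatial_groups
    (out / "truth.json").write_text(truth.to_json())
    return out
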