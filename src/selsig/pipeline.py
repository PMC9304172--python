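"""End-to-end orchestration: align/filter orthologs -> divergence -> MK ->
SFS -> classify -> randomise -> fitness association.

A run consumes a dataset directory (as written by
:func:`selsig.simulate.generate_full_dataset`, or assembled from real
per-gene inputs in the same layout) and writes TSV outputs plus a
line-oriented run log.  Every exclusion is logged with its rule name and
count; outputs are deterministic in (config, seed) and carry no timestamps.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import fitness as fit_mod
from . import mk as mk_mod
from . import selection as sel_mod
from . import sfs as sfs_mod
from .alignment import ScoringParams, global_align, reciprocal_identity
from .divergence import DivergenceEstimate, ng86_dnds
from .io_formats import (
    GeneModel,
    SnpRecord,
    complement,
    read_fasta,
    read_fitness_table,
    read_gene_models,
)
from .sfs import HaplotypeAlignment


@dataclass
class PipelineConfig:
    """Resolved run parameters; defaults are the study's printed values."""

    input_dir: str = "."
    seed: int = 0
    # ortholog retention
    min_identity: float = 75.0
    ds_lower: float = 0.02
    ds_upper: float = 2.0
    dn_upper: float = 2.0
    # accession-sequence sanity check
    min_accession_identity: float = 75.0
    # SFS
    min_seg_sites: int = 50
    h_variant: str = "unnormalized"
    accession_subset: Optional[list[str]] = None
    # selection calls
    mode: str = "threshold"  # threshold | outlier5pct
    randomisation_draws: int = 10000
    # fitness
    min_obs: int = 4
    area_ratio_max: float = 1.5
    apply_area_ratio_filter: bool = False
    scoring: ScoringParams = field(default_factory=ScoringParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        scoring = data.pop("scoring", None)
        cfg = cls(**data)
        if scoring:
            cfg.scoring = ScoringParams(**scoring)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


class RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def log(self, stage: str, message: str) -> None:
        self.lines.append(f"[{stage}] {message}")

    def write(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _gene_model_map(path: Path) -> dict[str, GeneModel]:
    return {m.gene_id: m for m in read_gene_models(path)}


def divergence_stage(
    config: PipelineConfig, ortholog_dir: Path, log: RunLog
) -> pd.DataFrame:
    """Align each ortholog pair, estimate NG86 dN/dS and apply the filters."""
    rows = []
    files = sorted(ortholog_dir.glob("*.fasta"))
    n_kept = 0
    for path in files:
        seqs = read_fasta(path)
        if len(seqs) != 2:
            log.log("divergence", f"{path.name}: expected 2 sequences; skipped")
            continue
        (id_a, seq_a), (id_b, seq_b) = seqs.items()
        gene_id = path.stem
        aln = global_align(seq_a, seq_b, config.scoring, id_a=id_a, id_b=id_b)
        ident = reciprocal_identity(aln)
        est = ng86_dnds(aln, gene_id=gene_id)
        keep = (
            est.ds is not None
            and est.dn is not None
            and ident >= config.min_identity
            and config.ds_lower < est.ds < config.ds_upper
            and est.dn < config.dn_upper
        )
        if keep:
            n_kept += 1
        rows.append(
            {
                "gene_id": gene_id,
                "reciprocal_identity": ident,
                "S_sites": est.syn_sites,
                "N_sites": est.nonsyn_sites,
                "Sd": est.syn_diffs,
                "Nd": est.nonsyn_diffs,
                "dS": est.ds if est.ds is not None else np.nan,
                "dN": est.dn if est.dn is not None else np.nan,
                "omega": est.omega if est.omega is not None else np.nan,
                "retained": keep,
                "flags": ",".join(est.flags),
            }
        )
    log.log(
        "divergence",
        f"{len(rows)} pairs aligned; {n_kept} retained by "
        f"identity>={config.min_identity} and {config.ds_lower}<dS<{config.ds_upper}, "
        f"dN<{config.dn_upper}",
    )
    return pd.DataFrame(rows).set_index("gene_id")


def _columnwise_identity(a: str, b: str) -> float:
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


def _load_haplotype_alignment(
    path: Path, subset: Optional[list[str]]
) -> HaplotypeAlignment:
    seqs = read_fasta(path)
    outgroup = seqs.pop("outgroup", None)
    if subset:
        seqs = {k: v for k, v in seqs.items() if k in set(subset)}
    return HaplotypeAlignment(gene_id=path.stem, haplotypes=seqs, outgroup=outgroup)


def sfs_stage(
    config: PipelineConfig, haplotype_dir: Path, log: RunLog
) -> pd.DataFrame:
    """Per-gene SFS statistics with the accession-identity and site filters.

    Accession rows are checked against the first (reference) row; same-length
    rows are compared column-wise, which equals alignment identity for the
    end-to-end CDS alignments this stage consumes.
    """
    rows = []
    n_dropped_acc = 0
    n_invalid = 0
    for path in sorted(haplotype_dir.glob("*.fasta")):
        aln = _load_haplotype_alignment(path, config.accession_subset)
        names = sorted(aln.haplotypes)
        ref = aln.haplotypes[names[0]]
        kept = {}
        for name in names:
            ident = _columnwise_identity(ref, aln.haplotypes[name])
            if ident < config.min_accession_identity:
                n_dropped_acc += 1
                continue
            kept[name] = aln.haplotypes[name]
        aln = HaplotypeAlignment(
            gene_id=aln.gene_id, haplotypes=kept, outgroup=aln.outgroup
        )
        prof = sfs_mod.profile_gene(
            aln, min_seg_sites=config.min_seg_sites, h_variant=config.h_variant
        )
        if not prof.valid:
            n_invalid += 1
        rows.append(
            {
                "gene_id": prof.gene_id,
                "n": prof.n,
                "seg_sites": prof.seg_sites,
                "polarized_sites": prof.polarized_sites,
                "tajima_d": prof.tajima_d,
                "fu_li_d_star": prof.fu_li_d_star,
                "fay_wu_h": prof.fay_wu_h,
                "zeng_e": prof.zeng_e,
                "valid": prof.valid,
            }
        )
    log.log(
        "sfs",
        f"{len(rows)} genes profiled; {n_invalid} invalid (<{config.min_seg_sites} "
        f"segregating sites); {n_dropped_acc} accession rows dropped "
        f"(<{config.min_accession_identity}% identity)",
    )
    return pd.DataFrame(rows).set_index("gene_id")


def mk_stage(
    config: PipelineConfig,
    haplotype_dir: Path,
    models: dict[str, GeneModel],
    divergence: pd.DataFrame,
    log: RunLog,
) -> pd.DataFrame:
    """Classify segregating sites and assemble per-gene MK tables.

    The first (reference) haplotype provides the codon context; each
    biallelic segregating site is classified once.  Dn/Ds come from the
    NG86 pathway sums of the divergence stage, rounded half away from zero.
    """
    rows = []
    n_ambiguous = 0
    for path in sorted(haplotype_dir.glob("*.fasta")):
        gene_id = path.stem
        if gene_id not in models or gene_id not in divergence.index:
            continue
        aln = _load_haplotype_alignment(path, config.accession_subset)
        model = models[gene_id]
        tx = model.longest_cds_id
        names = sorted(aln.haplotypes)
        ref = aln.haplotypes[names[0]]
        mat = np.array([list(aln.haplotypes[nm]) for nm in names], dtype="U1")
        classes = {}
        for col in range(mat.shape[1]):
            alleles = [a for a in np.unique(mat[:, col]) if a in "ACGT"]
            if len(alleles) != 2:
                continue
            ref_base = ref[col]
            if ref_base not in alleles:
                continue  # reference carries neither allele (N/gap)
            alt_base = alleles[0] if alleles[1] == ref_base else alleles[1]
            pos = model.genomic_position(tx, col)
            snp = SnpRecord(
                chrom=model.chrom,
                pos=pos,
                ref=ref_base if model.strand == "+" else complement(ref_base),
                alt=alt_base if model.strand == "+" else complement(alt_base),
                accession_id=names[0],
            )
            cls = mk_mod.classify_snp(snp, model, {tx: ref})
            if cls is mk_mod.SnpClass.AMBIGUOUS:
                n_ambiguous += 1
            classes[(model.chrom, pos)] = cls
        div = divergence.loc[gene_id]
        table = mk_mod.count_mk_table(
            gene_id,
            classes,
            DivergenceEstimate(
                gene_id=gene_id,
                nonsyn_diffs=float(div["Nd"]),
                syn_diffs=float(div["Sd"]),
            ),
        )
        dos = mk_mod.direction_of_selection(table)
        rows.append(
            {
                "gene_id": gene_id,
                "Dn": table.dn,
                "Ds": table.ds,
                "Pn": table.pn,
                "Ps": table.ps,
                "ni": mk_mod.neutrality_index(table),
                "dos": dos if dos is not None else np.nan,
            }
        )
    log.log("mk", f"{len(rows)} MK tables; {n_ambiguous} ambiguous sites excluded")
    return pd.DataFrame(rows).set_index("gene_id")


def run_all(config: PipelineConfig, outdir: str | Path, overwrite: bool = False) -> Path:
    """Run every stage on one dataset directory; returns the output dir."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog(outdir / "run.log")
    indir = Path(config.input_dir)

    models = _gene_model_map(indir / "gene_models.tsv")
    log.log("io", f"{len(models)} gene models read")

    divergence = divergence_stage(config, indir / "orthologs", log)
    mk_table = mk_stage(config, indir / "haplotypes", models, divergence, log)
    sfs_table = sfs_stage(config, indir / "haplotypes", log)

    profiles = pd.DataFrame(index=sorted(set(divergence.index) | set(sfs_table.index)))
    profiles.index.name = "gene_id"
    profiles["omega"] = divergence["omega"].where(divergence["retained"])
    profiles["ni"] = mk_table["ni"]
    profiles["dos"] = mk_table["dos"]
    for col in ("tajima_d", "fu_li_d_star", "fay_wu_h", "zeng_e"):
        profiles[col] = sfs_table[col].where(sfs_table["valid"])
    n_complete = int(profiles.notna().all(axis=1).sum())
    log.log("profiles", f"{len(profiles)} genes; {n_complete} with all seven statistics")

    flags = sel_mod.classify_selection(profiles, mode=config.mode)
    intersection = sel_mod.intersect_methods(flags, profiles)
    log.log("classify", f"mode={config.mode}; {len(intersection)} genes flagged by all seven")
    rho, rho_p = sel_mod.estimator_correlations(profiles)

    essential_path = indir / "essential_genes.tsv"
    randomisation = None
    if essential_path.exists():
        essential = set(pd.read_csv(essential_path, sep="\t")["gene_id"].astype(str))
        if not essential:
            log.log("randomise", "essential list empty; randomisation skipped")
    if essential_path.exists() and essential:
        randomisation = sel_mod.randomisation_suite(
            profiles,
            essential,
            s=config.randomisation_draws,
            seed=config.seed,
        )
        log.log(
            "randomise",
            f"{len(essential)} essential genes; s={config.randomisation_draws}",
        )

    fitness_path = indir / "fitness.tsv"
    fitness_assoc = None
    gene_fitness = None
    if fitness_path.exists():
        table = read_fitness_table(fitness_path)
        genes = fit_mod.aggregate_gene_fitness(table, min_obs=config.min_obs)
        log.log("fitness", f"{len(genes)} genes with >= {config.min_obs} observations")
        if config.apply_area_ratio_filter:
            before = len(genes)
            genes = fit_mod.area_ratio_filter(genes, max_ratio=config.area_ratio_max)
            log.log(
                "fitness",
                f"area ratio filter (> {config.area_ratio_max}): {before} -> {len(genes)}",
            )
        gene_fitness = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "w": [g.w for g in genes],
                "n_obs": [g.n_obs for g in genes],
                "area_ratio": [g.area_ratio for g in genes],
            }
        ).set_index("gene_id")
        assoc_rows = []
        for stat in sel_mod.STATISTICS:
            if stat not in flags.columns:
                continue
            res = fit_mod.compare_fitness_by_class(genes, flags[stat])
            if res is None:
                log.log("fitness", f"{stat}: a class is empty; test skipped")
                continue
            assoc_rows.append({"statistic": stat, **res})
        kw = pd.DataFrame(assoc_rows)
        corr = fit_mod.correlate_fitness_with_stats(genes, profiles)
        fitness_assoc = kw.merge(corr, on="statistic", how="outer", suffixes=("_kw", ""))

    float_fmt = "%.6g"
    profiles.to_csv(outdir / "profiles.tsv", sep="\t", float_format=float_fmt)
    divergence.to_csv(outdir / "divergence.tsv", sep="\t", float_format=float_fmt)
    mk_table.to_csv(outdir / "mk.tsv", sep="\t", float_format=float_fmt)
    sfs_table.to_csv(outdir / "sfs.tsv", sep="\t", float_format=float_fmt)
    flags.to_csv(outdir / "selection_calls.tsv", sep="\t")
    (outdir / "intersection.txt").write_text("\n".join(intersection) + "\n")
    rho.to_csv(outdir / "correlations_rho.tsv", sep="\t", float_format=float_fmt)
    rho_p.to_csv(outdir / "correlations_p.tsv", sep="\t", float_format=float_fmt)
    if randomisation is not None:
        randomisation.to_csv(
            outdir / "randomisation.tsv", sep="\t", index=False, float_format="%.6g"
        )
    if gene_fitness is not None:
        gene_fitness.to_csv(outdir / "gene_fitness.tsv", sep="\t", float_format=float_fmt)
    if fitness_assoc is not None:
        fitness_assoc.to_csv(
            outdir / "fitness_association.tsv", sep="\t", index=False, float_format=float_fmt
        )
    config.to_yaml(outdir / "config_resolved.yaml")
    log.write()
    return outdir
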