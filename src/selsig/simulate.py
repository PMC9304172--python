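"""Synthetic-data generators with known ground truth for every pipeline stage.

The neutral generator is the standard n-coalescent with infinite-sites
mutation: coalescence times are exponential with rate C(k,2), mutations
fall as a Poisson process of rate theta/2 per lineage per unit time, and
every mutation hits a distinct CDS position.  Outgroup divergence mutations
are placed on positions untouched by ingroup mutations, so outgroup
polarization is exact by construction (mispolarization is exercised with
hand-built fixtures, not the simulator).

The ortholog-pair generator evolves a stop-free CDS along a branch by
acceptance-ratio thinning: candidate single-base changes are accepted with
relative rate 1 (synonymous) or omega_true (nonsynonymous); stop codons are
rejected.  This is sufficient for NG86 recovery and ordering checks; it is
not a full codon rate matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .divergence import ALL_CODONS, CODON_TO_AA, STOP_CODONS
from .io_formats import write_fasta
from .mk import MKTable
from .sfs import HaplotypeAlignment, SiteFrequencySpectrum

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]


@dataclass
class SimConfig:
    """Study-scale defaults for the full synthetic dataset.

    Defaults mirror the shape of the real study at desk scale: 500 genes
    stand in for the genome-wide ortholog set, 24 haplotypes plus one
    outgroup per gene, per-locus theta high enough that most genes clear
    the 50-segregating-site filter, a lognormal omega distribution with
    median 0.2 placing ~5% of genes above omega = 1, an essential fraction
    of 591/17,630, five fitness replicates per line (1852/379 data points
    per gene in the source data) and no fitness-selection link by default.
    """

    seed: int = 0
    n_genes: int = 500
    n_haplotypes: int = 24
    theta: float = 25.0
    L_codons: int = 200
    omega_log_median: float = 0.2
    omega_log_sigma: float = 1.0
    branch_length: float = 0.2
    outgroup_divergence: float = 0.05
    sfs_skew_mode: str = "neutral"  # neutral | singleton_excess | high_freq_excess
    sfs_skew_intensity: float = 0.0
    essential_fraction: float = 591.0 / 17630.0
    essential_shift: float = 0.1
    n_fitness_genes: int = 379
    candidate_fraction: float = 0.2
    fitness_effect: float = 0.0
    noise_sd: float = 0.2
    n_replicates: int = 5
    n_chambers: int = 3
    wt_mean_fruits: float = 40.0
    area_ratio_high_fraction: float = 0.38

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.L_codons < 50:
            raise ValueError("L_codons must be >= 50")
        if self.n_haplotypes < 4:
            raise ValueError("n_haplotypes must be >= 4")


def _coalescent_branch_lengths(n: int, rng: np.random.Generator):
    """Simulate one genealogy; return (leaf-set list, branch length list).

    Each entry is the set of leaf indices subtended by a lineage and the
    total time that lineage existed.
    """
    lineages = [frozenset([i]) for i in range(n)]
    lengths: dict[frozenset, float] = {ls: 0.0 for ls in lineages}
    k = n
    while k > 1:
        rate = k * (k - 1) / 2.0
        t = rng.exponential(1.0 / rate)
        for ls in lineages:
            lengths[ls] = lengths.get(ls, 0.0) + t
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        merged = lineages[i] | lineages[j]
        lineages = [ls for idx, ls in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        lengths.setdefault(merged, 0.0)
        k -= 1
    return lengths


def simulate_sfs_counts(
    n: int, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Unfolded spectrum counts S_i, i = 1..n-1, under the neutral coalescent.

    Mutations are Poisson with rate theta/2 per lineage-time unit; a
    mutation on a branch subtending i leaves contributes to class i.  This
    is the sequence-free fast path used for calibration at scale.
    """
    lengths = _coalescent_branch_lengths(n, rng)
    unfolded = np.zeros(n - 1, dtype=np.int64)
    for leafset, length in lengths.items():
        c = len(leafset)
        if c >= n:
            continue
        unfolded[c - 1] += rng.poisson(theta / 2.0 * length)
    return unfolded


def simulate_coalescent_gene(
    n: int,
    theta: float,
    L_sites: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    outgroup_divergence: float = 0.0,
    gene_id: str = "gene",
) -> tuple[HaplotypeAlignment, str]:
    """One neutral gene: aligned ingroup haplotypes, outgroup row, ancestor.

    Returns ``(alignment, ancestral_sequence)``.  Raises ValueError when
    the genealogy carries more mutations than there are sites (increase L).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = _coalescent_branch_lengths(n, rng)
    branches = sorted(lengths.items(), key=lambda kv: sorted(kv[0]))
    mut_counts = [
        rng.poisson(theta / 2.0 * length) if len(ls) < n else 0
        for ls, length in branches
    ]
    n_ingroup_muts = int(sum(mut_counts))
    n_out_muts = int(rng.poisson(outgroup_divergence * L_sites))
    if n_ingroup_muts + n_out_muts > L_sites:
        raise ValueError(
            f"{n_ingroup_muts + n_out_muts} mutations exceed {L_sites} sites; "
            "increase L"
        )
    ancestral = "".join(rng.choice(_BASES, size=L_sites))
    positions = rng.choice(L_sites, size=n_ingroup_muts + n_out_muts, replace=False)
    seqs = np.tile(np.array(list(ancestral), dtype="U1"), (n, 1))
    p = 0
    for (leafset, _), m in zip(branches, mut_counts):
        idx = sorted(leafset)
        for _ in range(m):
            pos = int(positions[p])
            p += 1
            anc = ancestral[pos]
            derived = rng.choice([b for b in "ACGT" if b != anc])
            seqs[idx, pos] = derived
    out_seq = np.array(list(ancestral), dtype="U1")
    for _ in range(n_out_muts):
        pos = int(positions[p])
        p += 1
        anc = ancestral[pos]
        out_seq[pos] = rng.choice([b for b in "ACGT" if b != anc])
    haplotypes = {
        f"acc{i:03d}": "".join(seqs[i]) for i in range(n)
    }
    aln = HaplotypeAlignment(
        gene_id=gene_id, haplotypes=haplotypes, outgroup="".join(out_seq)
    )
    return aln, ancestral


def skew_spectrum(
    aln: HaplotypeAlignment,
    mode: str,
    intensity: float,
    rng: np.random.Generator,
) -> HaplotypeAlignment:
    """Push derived-allele counts toward 1 (sweep-like singleton excess) or
    n-1 (high-frequency-derived excess), preserving the site count.

    Each polarizable segregating site is re-assigned with probability
    ``intensity``; at intensity 0 the alignment is returned unchanged.
    """
    if mode == "neutral" or intensity <= 0:
        return aln
    if mode not in {"singleton_excess", "high_freq_excess"}:
        raise ValueError(f"unknown skew mode {mode!r}")
    if aln.outgroup is None:
        raise ValueError("skew requires a polarizable alignment (outgroup)")
    names = sorted(aln.haplotypes)
    mat = np.array([list(aln.haplotypes[nm]) for nm in names], dtype="U1")
    out = np.array(list(aln.outgroup), dtype="U1")
    n = aln.n
    target = 1 if mode == "singleton_excess" else n - 1
    for col in range(mat.shape[1]):
        column = mat[:, col]
        alleles = np.unique(column)
        if len(alleles) != 2 or out[col] not in alleles:
            continue
        if rng.random() >= intensity:
            continue
        ancestral = out[col]
        derived = alleles[0] if alleles[1] == ancestral else alleles[1]
        carriers = rng.choice(n, size=target, replace=False)
        mat[:, col] = ancestral
        mat[carriers, col] = derived
    haplotypes = {nm: "".join(mat[i]) for i, nm in enumerate(names)}
    return HaplotypeAlignment(
        gene_id=aln.gene_id, haplotypes=haplotypes, outgroup=aln.outgroup
    )


def _random_cds(L_codons: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_NONSTOP_CODONS, size=L_codons))


def simulate_ortholog_pair(
    L_codons: int,
    omega_true: float,
    branch_length: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, str]:
    """A stop-free CDS and its descendant after ``branch_length`` expected
    neutral substitutions per site, with nonsynonymous changes accepted at
    relative rate ``omega_true``."""
    if omega_true < 0:
        raise ValueError("omega_true must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    ancestor = _random_cds(L_codons, rng)
    seq = list(ancestor)
    L = 3 * L_codons
    w_max = max(1.0, omega_true)
    n_events = int(rng.poisson(branch_length * L * w_max))
    positions = rng.integers(L, size=n_events)
    alt_idx = rng.integers(3, size=n_events)
    unif = rng.random(size=n_events)
    alternatives = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    aa = CODON_TO_AA
    for e in range(n_events):
        pos = int(positions[e])
        codon_i = 3 * (pos // 3)
        within = pos % 3
        codon = seq[codon_i] + seq[codon_i + 1] + seq[codon_i + 2]
        new_base = alternatives[seq[pos]][alt_idx[e]]
        mutant = codon[:within] + new_base + codon[within + 1 :]
        if mutant in STOP_CODONS:
            continue
        accept_p = (1.0 if aa[codon] == aa[mutant] else omega_true) / w_max
        if unif[e] < accept_p:
            seq[pos] = new_base
    return ancestor, "".join(seq)


def simulate_mk_counts(
    rates: tuple[float, float, float, float],
    rng: np.random.Generator,
    gene_id: str = "gene",
) -> MKTable:
    """Independent Poisson draws per MK cell (Dn, Ds, Pn, Ps order)."""
    if any(r < 0 for r in rates):
        raise ValueError("rates must be >= 0")
    dn, ds, pn, ps = (int(rng.poisson(r)) for r in rates)
    return MKTable(gene_id=gene_id, dn=dn, ds=ds, pn=pn, ps=ps)


def simulate_fitness_table(
    gene_ids: Sequence[str],
    candidate: Sequence[bool],
    effect: float,
    noise_sd: float,
    n_replicates: int,
    n_chambers: int,
    rng: np.random.Generator,
    wt_mean_fruits: float = 40.0,
    area_ratio_high_fraction: float = 0.0,
) -> pd.DataFrame:
    """Replicate-structured knockout fitness table with known effect.

    WT fruit counts are Poisson around a chamber-specific mean; KO counts
    are Poisson around the paired WT plant's realized count x (1 + gene
    effect), where the gene effect is -``effect`` for candidate genes and
    0 otherwise, multiplied by mean-one lognormal gene-level noise of SD
    ~``noise_sd``.  Conditioning the KO mean on the paired WT count keeps
    the per-replicate relative fitness unbiased (E[ko/wt] equals the scale)
    and emulates plants sharing replicate growing conditions.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    chamber_mult = np.exp(rng.normal(0.0, 0.1, size=n_chambers))
    rows = []
    for g, (gid, is_cand) in enumerate(zip(gene_ids, candidate)):
        gene_effect = -effect if is_cand else 0.0
        gene_noise = float(
            np.exp(rng.normal(-0.5 * noise_sd**2, noise_sd))
        )
        ko_mean_scale = max(1e-9, (1.0 + gene_effect) * gene_noise)
        if rng.random() < area_ratio_high_fraction:
            area_ratio = float(rng.uniform(1.51, 2.5))
        else:
            area_ratio = float(rng.uniform(0.7, 1.5))
        for rep in range(n_replicates):
            chamber = int(rng.integers(n_chambers))
            mean_c = wt_mean_fruits * chamber_mult[chamber]
            wt = int(rng.poisson(mean_c))
            ko_mean = (wt if wt > 0 else mean_c) * ko_mean_scale
            ko = int(rng.poisson(ko_mean))
            rows.append(
                {
                    "line_id": f"L{g:04d}",
                    "gene_id": gid,
                    "replicate_id": f"rep{rep + 1}",
                    "chamber_id": f"ch{chamber + 1}",
                    "ko_fruit_count": ko,
                    "wt_fruit_count": wt,
                    "area_ratio": area_ratio,
                }
            )
    return pd.DataFrame(rows)


def simulate_neutrality_profiles(
    n_genes: int,
    rng: np.random.Generator,
    n_haplotypes: int = 25,
    theta: float = 10.0,
    omega_log_median: float = 0.2,
    omega_log_sigma: float = 1.0,
    omega_noise_sd: float = 0.2,
    mk_rates: tuple[float, float, float, float] = (10.0, 10.0, 10.0, 10.0),
) -> pd.DataFrame:
    """Fast per-gene table of the seven statistics (no sequences).

    dN/dS is a lognormal true omega with multiplicative estimation noise;
    NI and DOS come from Poisson MK tables; D, D*, H and E from coalescent
    spectrum counts.  Used for association-stage calibration at the scale
    of the real study, where full sequence simulation is unnecessary.
    """
    from . import mk as mk_mod
    from . import sfs as sfs_mod

    rows = []
    mu = math.log(omega_log_median)
    for g in range(n_genes):
        omega_true = float(np.exp(rng.normal(mu, omega_log_sigma)))
        omega_est = omega_true * float(np.exp(rng.normal(0.0, omega_noise_sd)))
        table = simulate_mk_counts(mk_rates, rng, gene_id=f"G{g:05d}")
        ni = mk_mod.neutrality_index(table)
        dos = mk_mod.direction_of_selection(table)
        counts = simulate_sfs_counts(n_haplotypes, theta, rng)
        sfs = SiteFrequencySpectrum.from_unfolded(n_haplotypes, counts)
        rows.append(
            {
                "gene_id": f"G{g:05d}",
                "omega": omega_est,
                "ni": ni,
                "dos": dos if dos is not None else np.nan,
                "tajima_d": sfs_mod.tajimas_d(sfs),
                "fu_li_d_star": sfs_mod.fu_li_d_star(sfs),
                "fay_wu_h": sfs_mod.fay_wu_h(sfs),
                "zeng_e": sfs_mod.zeng_e(sfs),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def generate_full_dataset(
    config: SimConfig, outdir: str | Path, overwrite: bool = False
) -> pd.DataFrame:
    """Write every input the pipeline consumes, plus a ground-truth manifest.

    Layout: ``haplotypes/<gene>.fasta`` (ingroup rows + ``outgroup``),
    ``orthologs/<gene>.fasta`` (ingroup/outgroup CDS pair),
    ``gene_models.tsv``, ``fitness.tsv``, ``essential_genes.tsv`` and
    ``manifest.tsv`` with all true parameters.  Deterministic in
    (config, seed): the same config writes byte-identical files.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists; pass overwrite=True")
    (outdir / "haplotypes").mkdir(parents=True, exist_ok=True)
    (outdir / "orthologs").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    mu = math.log(config.omega_log_median)
    omega_true = np.exp(rng.normal(mu, config.omega_log_sigma, size=n))
    n_essential = int(round(config.essential_fraction * n))
    essential_idx = rng.choice(n, size=n_essential, replace=False)
    essential = np.zeros(n, dtype=bool)
    essential[essential_idx] = True
    omega_true[essential] = np.maximum(omega_true[essential] - config.essential_shift, 0.01)
    # candidate label: the top candidate_fraction of true omega
    n_cand = int(round(config.candidate_fraction * n))
    cand_idx = np.argsort(-omega_true)[:n_cand]
    candidate = np.zeros(n, dtype=bool)
    candidate[cand_idx] = True

    L_sites = 3 * config.L_codons
    model_rows = []
    for gid, omega in zip(gene_ids, omega_true):
        aln, _ = simulate_coalescent_gene(
            n=config.n_haplotypes,
            theta=config.theta,
            L_sites=L_sites,
            rng=rng,
            outgroup_divergence=config.outgroup_divergence,
            gene_id=gid,
        )
        aln = skew_spectrum(aln, config.sfs_skew_mode, config.sfs_skew_intensity, rng)
        seqs = dict(sorted(aln.haplotypes.items()))
        seqs["outgroup"] = aln.outgroup
        write_fasta(seqs, outdir / "haplotypes" / f"{gid}.fasta")
        anc, derived = simulate_ortholog_pair(
            config.L_codons, float(omega), config.branch_length, rng=rng
        )
        write_fasta(
            {f"{gid}_ingroup": anc, f"{gid}_outgroup": derived},
            outdir / "orthologs" / f"{gid}.fasta",
        )
        model_rows.append(
            {
                "gene_id": gid,
                "transcript_id": f"{gid}.1",
                "chrom": gid,
                "strand": "+",
                "start": 1,
                "end": L_sites,
            }
        )
    pd.DataFrame(model_rows).to_csv(outdir / "gene_models.tsv", sep="\t", index=False)

    n_fit = min(config.n_fitness_genes, n)
    fit_idx = rng.choice(n, size=n_fit, replace=False)
    fit_genes = [gene_ids[i] for i in sorted(fit_idx)]
    fit_cand = [bool(candidate[i]) for i in sorted(fit_idx)]
    fitness = simulate_fitness_table(
        fit_genes,
        fit_cand,
        effect=config.fitness_effect,
        noise_sd=config.noise_sd,
        n_replicates=config.n_replicates,
        n_chambers=config.n_chambers,
        rng=rng,
        wt_mean_fruits=config.wt_mean_fruits,
        area_ratio_high_fraction=config.area_ratio_high_fraction,
    )
    fitness.to_csv(outdir / "fitness.tsv", sep="\t", index=False)

    pd.DataFrame({"gene_id": [g for g, e in zip(gene_ids, essential) if e]}).to_csv(
        outdir / "essential_genes.tsv", sep="\t", index=False
    )
    manifest = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "omega_true": omega_true,
            "theta": config.theta,
            "essential": essential,
            "candidate": candidate,
            "has_fitness": [g in set(fit_genes) for g in gene_ids],
            "fitness_effect": config.fitness_effect,
        }
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
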