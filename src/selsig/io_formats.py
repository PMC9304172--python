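"""Readers/writers for the standard formats the pipeline touches.

Coordinates follow the usual two conventions: GFF3 and VCF are 1-based
inclusive on disk, everything in memory is 0-based half-open.  Minus-strand
genes store their CDS 5'->3' of the mRNA; allele complementing happens at
substitution time.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN-")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FITNESS_COLUMNS = [
    "line_id",
    "gene_id",
    "replicate_id",
    "chamber_id",
    "ko_fruit_count",
    "wt_fruit_count",
    "area_ratio",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass
class GeneModel:
    """Gene with per-transcript CDS coordinates (1-based inclusive intervals).

    ``transcripts`` maps transcript id to an ordered list of ``(start, end)``
    CDS intervals on the genome.  ``longest_cds_id`` is the transcript with
    the largest summed CDS length (ties broken by smallest transcript id).
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[tuple[int, int]]]
    longest_cds_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for tx, ivs in self.transcripts.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping CDS intervals in {tx}")
        if not self.longest_cds_id:
            self.longest_cds_id = min(
                self.transcripts, key=lambda t: (-self.cds_length(t), t)
            )

    def cds_length(self, transcript_id: str) -> int:
        return sum(e - s + 1 for s, e in self.transcripts[transcript_id])

    def cds_offset(self, transcript_id: str, pos: int) -> Optional[int]:
        """Map a 1-based genomic position to a 0-based CDS offset (mRNA 5'->3').

        Returns None when the position falls outside the transcript's CDS.
        """
        ivs = self.transcripts[transcript_id]
        off = 0
        if self.strand == "+":
            for s, e in ivs:
                if s <= pos <= e:
                    return off + (pos - s)
                off += e - s + 1
        else:
            for s, e in reversed(ivs):
                if s <= pos <= e:
                    return off + (e - pos)
                off += e - s + 1
        return None

    def genomic_position(self, transcript_id: str, offset: int) -> int:
        """Inverse of :meth:`cds_offset`: 1-based genomic position of a
        0-based CDS offset."""
        ivs = self.transcripts[transcript_id]
        remaining = offset
        if self.strand == "+":
            for s, e in ivs:
                length = e - s + 1
                if remaining < length:
                    return s + remaining
                remaining -= length
        else:
            for s, e in reversed(ivs):
                length = e - s + 1
                if remaining < length:
                    return e - remaining
                remaining -= length
        raise IndexError(f"CDS offset {offset} outside {transcript_id}")


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide variant carried by one accession."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    accession_id: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"non-SNP alleles {self.ref}>{self.alt}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into ``{id: sequence}``.

    Sequences are upper-cased and U is mapped to T.  Duplicate ids, empty
    records and characters outside ``ACGTN-`` raise :class:`FormatError`.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out: dict[str, str] = {}
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in out:
                raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise FormatError(f"empty record {rec.id!r} in {path}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"record {rec.id!r} contains invalid characters {sorted(bad)}"
                )
            out[rec.id] = seq
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _finalise_gene_models(
    raw: dict[str, dict],
) -> list[GeneModel]:
    models = []
    for gid, info in raw.items():
        transcripts = {}
        for tx, ivs in info["transcripts"].items():
            length = sum(e - s + 1 for s, e in ivs)
            if length % 3 != 0:
                logger.warning(
                    "gene %s transcript %s: CDS length %d not a multiple of 3; "
                    "transcript excluded",
                    gid,
                    tx,
                    length,
                )
                continue
            transcripts[tx] = sorted(ivs)
        if not transcripts:
            logger.warning("gene %s has no in-frame transcript; gene excluded", gid)
            continue
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=info["chrom"],
                strand=info["strand"],
                transcripts=transcripts,
            )
        )
    return models


def _read_gff3_gene_models(path: Path) -> list[GeneModel]:
    raw: dict[str, dict] = {}
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            tx = attr.get("Parent", attr.get("transcript_id", ""))
            gid = attr.get("gene_id", "")
            if not gid:
                # conventional transcript ids look like <gene>.<n>
                gid = tx.split(".")[0]
            entry = raw.setdefault(
                gid, {"chrom": chrom, "strand": strand, "transcripts": {}}
            )
            entry["transcripts"].setdefault(tx, []).append((int(start), int(end)))
    return _finalise_gene_models(raw)


def _read_tsv_gene_models(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "transcript_id", "chrom", "strand", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"exon TSV missing columns {sorted(missing)}")
    raw: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        entry = raw.setdefault(
            row.gene_id,
            {"chrom": str(row.chrom), "strand": row.strand, "transcripts": {}},
        )
        entry["transcripts"].setdefault(row.transcript_id, []).append(
            (int(row.start), int(row.end))
        )
    return _finalise_gene_models(raw)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 or from the exon-coordinate TSV dialect.

    Transcripts whose summed CDS length is not a positive multiple of 3 are
    excluded with a log entry; a gene with no surviving transcript is dropped.
    """
    path = Path(path)
    suffixes = {s.lower() for s in path.suffixes}
    if ".gff3" in suffixes or ".gff" in suffixes:
        return _read_gff3_gene_models(path)
    return _read_tsv_gene_models(path)


def read_vcf_snps(
    path: str | Path, region: Optional[str] = None
) -> tuple[list[SnpRecord], dict[str, int]]:
    """Read biallelic SNPs with a non-reference call from a VCF.

    Returns the records and a counter dict with the numbers of skipped
    indel/multiallelic records and of heterozygous calls resolved to ALT
    (A. thaliana is highly selfing; heterozygotes are rare and resolved to
    the alternate allele).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    counts = {"indel": 0, "multiallelic": 0, "het_resolved_alt": 0, "snp": 0}
    records: list[SnpRecord] = []
    iterator = vcf(region) if region else vcf
    for var in iterator:
        if len(var.ALT) != 1:
            counts["multiallelic"] += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            counts["indel"] += 1
            continue
        counts["snp"] += 1
        gts = var.genotypes  # [allele_a, allele_b, phased]
        for sample, gt in zip(samples, gts):
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles or not any(a > 0 for a in alleles):
                continue
            if len(set(alleles)) > 1:
                counts["het_resolved_alt"] += 1
            records.append(
                SnpRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=ref,
                    alt=alt,
                    accession_id=sample,
                )
            )
    return records, counts


def build_accession_haplotype(
    reference_cds: str,
    snps: list[SnpRecord],
    model: GeneModel,
    transcript_id: Optional[str] = None,
) -> str:
    """Apply an accession's SNP alleles to the reference CDS of one gene.

    ``reference_cds`` is the mRNA-orientation CDS of ``transcript_id``
    (default: the longest transcript).  Minus-strand genes substitute the
    complemented ALT allele.  SNPs outside the CDS are ignored; a REF allele
    disagreeing with the CDS raises ValueError naming the position.
    """
    tx = transcript_id or model.longest_cds_id
    if len(reference_cds) != model.cds_length(tx):
        raise ValueError(
            f"reference CDS length {len(reference_cds)} != model length "
            f"{model.cds_length(tx)} for {model.gene_id}/{tx}"
        )
    seq = list(reference_cds)
    mismatches = []
    for snp in snps:
        if snp.chrom != model.chrom:
            continue
        off = model.cds_offset(tx, snp.pos)
        if off is None:
            continue
        ref, alt = snp.ref, snp.alt
        if model.strand == "-":
            ref, alt = complement(ref), complement(alt)
        if seq[off] != ref:
            mismatches.append(snp.pos)
            continue
        seq[off] = alt
    if mismatches:
        raise ValueError(
            f"{model.gene_id}: SNP REF allele mismatch at positions {mismatches}"
        )
    return "".join(seq)


def check_accession_identity(
    reference_cds: str, accession_cds: str, min_identity: float = 75.0
) -> tuple[float, bool]:
    """Percent identity of the global alignment of the two CDS, and keep/drop.

    Identity is matching columns / alignment length x 100; sequences below
    ``min_identity`` (strictly) are dropped, exactly 75.0 is kept.
    """
    from .alignment import global_align

    if not reference_cds or not accession_cds:
        raise ValueError("empty sequence")
    aln = global_align(reference_cds, accession_cds)
    matches = sum(
        a == b and a != "-" for a, b in zip(aln.aligned_a, aln.aligned_b)
    )
    identity = 100.0 * matches / len(aln.aligned_a)
    return identity, identity >= min_identity


def read_fitness_table(path: str | Path) -> pd.DataFrame:
    """Read an unPAK-style knockout fitness table.

    Columns: line_id, gene_id, replicate_id, chamber_id, ko_fruit_count,
    wt_fruit_count, area_ratio.  Fruit counts must be non-negative integers;
    missing area_ratio is preserved as NaN (distinct from 0).
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "gene_id": str})
    missing = set(FITNESS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"fitness table missing columns {sorted(missing)}")
    for col in ("ko_fruit_count", "wt_fruit_count"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any():
            raise FormatError(f"negative values in {col}")
        if not (vals == vals.round()).all():
            raise FormatError(f"non-integer values in {col}")
        df[col] = vals.astype(int)
    df["area_ratio"] = pd.to_numeric(df["area_ratio"], errors="coerce")
    if (df["area_ratio"].dropna() < 0).any():
        raise FormatError("negative area_ratio")
    return df[FITNESS_COLUMNS]
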