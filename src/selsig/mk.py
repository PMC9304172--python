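"""McDonald-Kreitman tables and the NI / DOS summary statistics.

NI follows Haldane's log-odds of the MK contingency table with the +1/x2
pseudo-count correction, log([2Ds+1][2Pn+1] / [2Dn+1][2Ps+1]); DOS is
Dn/(Dn+Ds) - Pn/(Pn+Ps).  Polymorphisms are counted per segregating site
(not per accession-allele copy); substitution counts come from the NG86
fractional pathway sums rounded half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .divergence import CODON_TO_AA, STOP_CODONS, DivergenceEstimate
from .io_formats import GeneModel, SnpRecord, complement


class SnpClass(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    AMBIGUOUS = "ambiguous"
    NONCODING = "noncoding"


@dataclass
class MKTable:
    gene_id: str
    dn: int
    ds: int
    pn: int
    ps: int

    def __post_init__(self) -> None:
        for v in (self.dn, self.ds, self.pn, self.ps):
            if v < 0 or int(v) != v:
                raise ValueError("MK counts must be non-negative integers")


def classify_snp(
    snp: SnpRecord,
    model: GeneModel,
    reference_cds: dict[str, str],
) -> SnpClass:
    """Synonymous/nonsynonymous status of one SNP across all transcripts.

    ``reference_cds`` maps transcript id to its mRNA-orientation CDS.  The
    SNP is mapped to a codon in every transcript whose CDS contains it; if
    the status differs between transcripts the SNP is ambiguous (different
    reading frames), outside all CDS it is noncoding.
    """
    if snp.chrom != model.chrom:
        return SnpClass.NONCODING
    statuses = set()
    for tx, cds in reference_cds.items():
        off = model.cds_offset(tx, snp.pos)
        if off is None:
            continue
        ref, alt = snp.ref, snp.alt
        if model.strand == "-":
            ref, alt = complement(ref), complement(alt)
        if cds[off] != ref:
            raise ValueError(
                f"{model.gene_id}/{tx}: REF {snp.ref} at {snp.chrom}:{snp.pos} "
                f"disagrees with CDS base {cds[off]}"
            )
        codon_start = 3 * (off // 3)
        codon = cds[codon_start : codon_start + 3]
        mutant = list(codon)
        mutant[off % 3] = alt
        mutant = "".join(mutant)
        aa_ref = CODON_TO_AA.get(codon, "*" if codon in STOP_CODONS else None)
        aa_alt = CODON_TO_AA.get(mutant, "*" if mutant in STOP_CODONS else None)
        if aa_ref is None or aa_alt is None:
            continue
        statuses.add(
            SnpClass.SYNONYMOUS if aa_ref == aa_alt else SnpClass.NONSYNONYMOUS
        )
    if not statuses:
        return SnpClass.NONCODING
    if len(statuses) > 1:
        return SnpClass.AMBIGUOUS
    return statuses.pop()


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def count_mk_table(
    gene_id: str,
    snp_classes: dict[tuple[str, int], SnpClass],
    divergence: DivergenceEstimate,
) -> MKTable:
    """Assemble the MK table for one gene.

    ``snp_classes`` maps a segregating site key (chrom, pos) to its class so
    each site is counted once regardless of how many accessions carry it.
    Ambiguous and noncoding sites are excluded.  Dn/Ds are the NG86
    fractional pathway sums rounded half away from zero.
    """
    pn = sum(1 for c in snp_classes.values() if c is SnpClass.NONSYNONYMOUS)
    ps = sum(1 for c in snp_classes.values() if c is SnpClass.SYNONYMOUS)
    return MKTable(
        gene_id=gene_id,
        dn=_round_half_away(divergence.nonsyn_diffs),
        ds=_round_half_away(divergence.syn_diffs),
        pn=pn,
        ps=ps,
    )


def neutrality_index(table: MKTable, log_base: float = math.e) -> float:
    """Pseudo-count-corrected log-odds of the MK table; finite for all counts."""
    odds = ((2 * table.ds + 1) * (2 * table.pn + 1)) / (
        (2 * table.dn + 1) * (2 * table.ps + 1)
    )
    return math.log(odds) / math.log(log_base)


def direction_of_selection(table: MKTable) -> Optional[float]:
    """Dn/(Dn+Ds) - Pn/(Pn+Ps); None when either margin is empty."""
    d_tot = table.dn + table.ds
    p_tot = table.pn + table.ps
    if d_tot == 0 or p_tot == 0:
        return None
    return table.dn / d_tot - table.pn / p_tot
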