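"""Pairwise dN/dS by Nei-Gojobori (1986) counting with Jukes-Cantor correction.

Synonymous/nonsynonymous site fractions per codon exclude paths to stop
codons from the denominator; observed differences are partitioned by
averaging over all mutational orderings between the two codons, excluding
orderings that pass through a stop codon.  dS and dN apply the Jukes-Cantor
correction d = -(3/4) ln(1 - (4/3) p) and are undefined ("saturated") when
p >= 3/4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .alignment import PairwiseAlignment

logger = logging.getLogger(__name__)

_BASES = "ACGT"
STOP_CODONS = set(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

ALL_CODONS = ["".join((a, b, c)) for a in _BASES for b in _BASES for c in _BASES]
CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}


def codon_site_partition(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    For each position the synonymous fraction is the share of single-base
    changes that preserve the amino acid, among changes not producing a stop
    codon; the nonsynonymous fraction is its complement to 1.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_legal = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            n_legal += 1
            if CODON_TO_AA[mutant] == aa:
                n_syn += 1
        if n_legal:
            syn += n_syn / n_legal
    return syn, 3.0 - syn


def codon_diff_partition(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Partition the differences between two codons into (Sd, Nd).

    Averages over all orderings of the differing positions, excluding
    orderings that pass through a stop codon.  Raises ValueError when no
    stop-free path exists (the codon pair is then skipped by the caller).
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c}")
        if len(c) != 3 or any(b not in _BASES for b in c):
            raise ValueError(f"invalid codon {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        current = codon_a
        path_syn = 0
        path_nonsyn = 0
        legal = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                legal = False
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                path_syn += 1
            else:
                path_nonsyn += 1
            current = nxt
        if legal:
            n_paths += 1
            syn_total += path_syn
            nonsyn_total += path_nonsyn
    if n_paths == 0:
        raise ValueError(f"no stop-free path between {codon_a} and {codon_b}")
    return syn_total / n_paths, nonsyn_total / n_paths


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precompute per-codon site counts and the 64x64 difference partition."""
    syn_sites = np.full(64, np.nan)
    nonsyn_sites = np.full(64, np.nan)
    for i, codon in enumerate(ALL_CODONS):
        if codon in STOP_CODONS:
            continue
        s, n = codon_site_partition(codon)
        syn_sites[i], nonsyn_sites[i] = s, n
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for i, a in enumerate(ALL_CODONS):
        if a in STOP_CODONS:
            continue
        for j, b in enumerate(ALL_CODONS):
            if b in STOP_CODONS:
                continue
            try:
                sd[i, j], nd[i, j] = codon_diff_partition(a, b)
            except ValueError:
                pass  # no stop-free path; stays NaN and is skipped
    return syn_sites, nonsyn_sites, sd, nd


_SYN_SITES, _NONSYN_SITES, _SD_TABLE, _ND_TABLE = _build_tables()


@dataclass
class DivergenceEstimate:
    gene_id: str
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0
    ds: Optional[float] = None
    dn: Optional[float] = None
    omega: Optional[float] = None
    n_codons: int = 0
    flags: list[str] = field(default_factory=list)


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def _codon_indices(seq: str) -> np.ndarray:
    """Codon index per triplet; -1 marks unusable (gap/N/stop) triplets."""
    n = len(seq) // 3
    idx = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        codon = seq[3 * k : 3 * k + 3]
        i = CODON_INDEX.get(codon, -1)
        if i >= 0 and codon not in STOP_CODONS:
            idx[k] = i
    return idx


def ng86_dnds(aln: PairwiseAlignment, gene_id: str = "") -> DivergenceEstimate:
    """NG86 dN/dS for one aligned ortholog pair.

    The alignment is chunked into consecutive column triplets; triplets with
    a gap, N or stop codon in either row are skipped, as are pairs with no
    stop-free mutational path.  Site counts are averaged over the two
    sequences; pS >= 3/4 (or pN) leaves the corresponding distance undefined
    with a "saturated" flag.
    """
    gene_id = gene_id or aln.id_a
    a, b = aln.aligned_a, aln.aligned_b
    usable = min(len(a), len(b)) // 3
    ia = _codon_indices(a[: 3 * usable])
    ib = _codon_indices(b[: 3 * usable])
    ok = (ia >= 0) & (ib >= 0)
    ia, ib = ia[ok], ib[ok]
    est = DivergenceEstimate(gene_id=gene_id, n_codons=int(ok.sum()))
    if est.n_codons == 0:
        est.flags.append("no_codons")
        return est
    sd = _SD_TABLE[ia, ib]
    nd = _ND_TABLE[ia, ib]
    path_ok = ~np.isnan(sd)
    n_skipped = int((~path_ok).sum())
    if n_skipped:
        logger.info("%s: %d codon pairs with no stop-free path skipped", gene_id, n_skipped)
        ia, ib, sd, nd = ia[path_ok], ib[path_ok], sd[path_ok], nd[path_ok]
        est.n_codons = len(ia)
    s_sites = 0.5 * (_SYN_SITES[ia].sum() + _SYN_SITES[ib].sum())
    n_sites = 0.5 * (_NONSYN_SITES[ia].sum() + _NONSYN_SITES[ib].sum())
    est.syn_sites = float(s_sites)
    est.nonsyn_sites = float(n_sites)
    est.syn_diffs = float(sd.sum())
    est.nonsyn_diffs = float(nd.sum())
    ps = est.syn_diffs / s_sites if s_sites > 0 else 0.0
    pn = est.nonsyn_diffs / n_sites if n_sites > 0 else 0.0
    est.ds = _jukes_cantor(ps)
    est.dn = _jukes_cantor(pn)
    if est.ds is None or est.dn is None:
        est.flags.append("saturated")
    if est.ds is not None and est.dn is not None:
        if est.ds > 0:
            est.omega = est.dn / est.ds
        else:
            est.flags.append("zero_ds")
    return est
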