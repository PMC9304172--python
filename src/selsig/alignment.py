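"""Global pairwise alignment of ortholog CDS pairs and the retention filters.

Scoring mimics the EMBOSS needle defaults (match +5, mismatch -4, gap open
10, gap extend 0.5) with end gaps penalised, i.e. a true end-to-end global
alignment.  A gap of length k costs open + (k - 1) * extend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align


@dataclass(frozen=True)
class ScoringParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5


DEFAULT_SCORING = ScoringParams()


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        if any(a == "-" == b for a, b in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("column gapped in both rows")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")

    @property
    def matches(self) -> int:
        return sum(
            a == b and a != "-" for a, b in zip(self.aligned_a, self.aligned_b)
        )


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    reciprocal_identity: float
    alignment: PairwiseAlignment

    def __post_init__(self) -> None:
        if not 0.0 <= self.reciprocal_identity <= 100.0:
            raise ValueError("reciprocal identity outside [0, 100]")


def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    params: ScoringParams = DEFAULT_SCORING,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal end-to-end global alignment under affine-gap scoring.

    The traceback is deterministic (the aligner's first co-optimal
    alignment), so repeated calls return byte-identical rows.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(params)
    aln = next(iter(aligner.align(seq_a, seq_b)))
    aligned_a, aligned_b = aln[0], aln[1]
    return PairwiseAlignment(
        id_a=id_a,
        id_b=id_b,
        aligned_a=str(aligned_a),
        aligned_b=str(aligned_b),
        score=float(aln.score),
    )


def reciprocal_identity(aln: PairwiseAlignment) -> float:
    """min(matches / len(seq_a), matches / len(seq_b)) x 100."""
    m = aln.matches
    return 100.0 * min(m / len(aln.seq_a), m / len(aln.seq_b))


def filter_orthologs(
    pairs: list[OrthologPair],
    estimates: dict[str, "object"],
    min_identity: float = 75.0,
    ds_lower: float = 0.02,
    ds_upper: float = 2.0,
    dn_upper: float = 2.0,
) -> list[OrthologPair]:
    """Retain pairs with identity >= 75 and 0.02 < dS < 2 and dN < 2.

    ``estimates`` maps ``gene_a`` to a divergence estimate exposing ``ds``
    and ``dn`` attributes (None/NaN when saturated or undivergent).  All
    divergence bounds are strict, as printed.
    """
    kept = []
    for pair in pairs:
        est = estimates.get(pair.gene_a)
        if est is None:
            continue
        ds, dn = est.ds, est.dn
        if ds is None or dn is None:
            continue
        if (
            pair.reciprocal_identity >= min_identity
            and ds_lower < ds < ds_upper
            and dn < dn_upper
        ):
            kept.append(pair)
    return kept
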