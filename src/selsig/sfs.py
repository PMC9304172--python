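"""Site-frequency-spectrum statistics on per-gene haplotype alignments.

Computes the unfolded spectrum (outgroup-polarized) plus four frequency
spectrum neutrality tests:

* Tajima's D (Tajima 1989) on all biallelic ingroup segregating sites
  (no polarization needed);
* Fu & Li's D* (Fu & Li 1993, constants as corrected by Simonsen,
  Churchill & Aquadro 1995), singletons being variants carried by exactly
  one sequence;
* Fay & Wu's H, by default the unnormalized theta_pi - theta_H, with the
  normalized variant of Zeng, Fu, Shi & Wu (2006) available;
* Zeng's E, (theta_L - theta_W) / sqrt(Var), variance per Zeng et al. (2006).

H and E require polarizable sites; D and D* do not.  Profiles are flagged
invalid below 50 biallelic segregating sites, the reliability cutoff used
throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

MIN_SEG_SITES = 50

_AMBIG = set("N-")


@dataclass
class HaplotypeAlignment:
    """Aligned ingroup haplotypes for one gene, plus an optional outgroup row."""

    gene_id: str
    haplotypes: dict[str, str]
    outgroup: Optional[str] = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.haplotypes.values()}
        if self.outgroup is not None:
            lengths.add(len(self.outgroup))
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: rows differ in length")
        if self.n < 2:
            raise ValueError(f"{self.gene_id}: need >= 2 ingroup haplotypes")

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    @property
    def length(self) -> int:
        return len(next(iter(self.haplotypes.values())))


@dataclass
class SiteFrequencySpectrum:
    """Per-gene spectrum summary.

    ``unfolded`` holds S_i for derived count i = 1..n-1 over polarized
    sites; ``site_counts`` holds, for every biallelic segregating site, the
    count of one allele (the derived allele where the site is polarized) --
    enough to evaluate theta_pi and singleton counts over the full site set.
    """

    n: int
    unfolded: np.ndarray  # length n-1, S_i at index i-1
    site_counts: np.ndarray  # one count per biallelic segregating site
    polarized_mask: np.ndarray  # bool per site in site_counts
    multiallelic_sites: int = 0

    def __post_init__(self) -> None:
        self.unfolded = np.asarray(self.unfolded, dtype=np.int64)
        self.site_counts = np.asarray(self.site_counts, dtype=np.int64)
        self.polarized_mask = np.asarray(self.polarized_mask, dtype=bool)
        if len(self.unfolded) != self.n - 1:
            raise ValueError("unfolded spectrum must have n-1 classes")
        if int(self.unfolded.sum()) != int(self.polarized_mask.sum()):
            raise ValueError("unfolded mass != polarized site count")

    @classmethod
    def from_unfolded(cls, n: int, unfolded: np.ndarray) -> "SiteFrequencySpectrum":
        """Build a fully polarized spectrum directly from class counts S_i."""
        unfolded = np.asarray(unfolded, dtype=np.int64)
        counts = np.repeat(np.arange(1, n), unfolded)
        return cls(
            n=n,
            unfolded=unfolded,
            site_counts=counts,
            polarized_mask=np.ones(len(counts), dtype=bool),
        )

    @property
    def seg_sites(self) -> int:
        """All biallelic ingroup segregating sites (polarized or not)."""
        return len(self.site_counts)

    @property
    def polarized_sites(self) -> int:
        return int(self.polarized_mask.sum())

    @property
    def unpolarized_sites(self) -> int:
        return self.seg_sites - self.polarized_sites

    @property
    def eta(self) -> int:
        """Total mutations; equals seg_sites since multiallelic sites are excluded."""
        return self.seg_sites

    @property
    def eta_s(self) -> int:
        """Singletons: sites where one allele is carried by exactly one sequence."""
        c = self.site_counts
        return int(((c == 1) | (c == self.n - 1)).sum())


@dataclass(frozen=True)
class SpectrumConstants:
    """Sample-size constants of the four statistics."""

    n: int
    a1: float
    a2: float
    a1n: float  # harmonic sum to n
    a2n: float  # squared harmonic sum to n
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    u_star: float
    v_star: float
    # Var(theta_L - theta_W) = e_u * theta + e_v * theta^2  (Zeng's E)
    e_u: float
    e_v: float
    # Var(theta_pi - theta_L) = h_u * theta + h_v * theta^2  (normalized H)
    h_u: float
    h_v: float


@lru_cache(maxsize=None)
def spectrum_constants(n: int) -> SpectrumConstants:
    if n < 2:
        raise ValueError("n >= 2 required")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    a1n = a1 + 1.0 / n
    a2n = a2 + 1.0 / n**2
    # Tajima (1989)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    # Fu & Li (1993) D*, constants per the Simonsen et al. (1995) correction
    if n > 2:
        cn = 2.0 * (n * a1 - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
        dn = (
            cn
            + (n - 2) / (n - 1) ** 2
            + (2.0 / (n - 1)) * (1.5 - (2.0 * a1n - 3.0) / (n - 2) - 1.0 / n)
        )
    else:
        cn = dn = float("nan")
    v_star = (
        (n / (n - 1.0)) ** 2 * a2 + a1**2 * dn - 2.0 * (n * a1 * (a1 + 1)) / (n - 1.0) ** 2
    ) / (a1**2 + a2)
    u_star = (n / (n - 1.0)) * (a1 - n / (n - 1.0)) - v_star
    # Zeng et al. (2006): Var(theta_L - theta_W)
    e_u = n / (2.0 * (n - 1)) - 1.0 / a1
    e_v = (
        a2 / a1**2
        + 2.0 * (n / (n - 1.0)) ** 2 * a2
        - 2.0 * (n * a2 - n + 1) / ((n - 1.0) * a1)
        - (3.0 * n + 1) / (n - 1.0)
    )
    # Zeng et al. (2006): Var(theta_pi - theta_L) for normalized Fay & Wu H
    h_u = (n - 2) / (6.0 * (n - 1.0))
    h_v = (
        18.0 * n**2 * (3.0 * n + 2) * a2n - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6)
    ) / (9.0 * n * (n - 1.0) ** 2)
    return SpectrumConstants(
        n=n, a1=a1, a2=a2, a1n=a1n, a2n=a2n, b1=b1, b2=b2, c1=c1, c2=c2,
        e1=e1, e2=e2, u_star=u_star, v_star=v_star, e_u=e_u, e_v=e_v,
        h_u=h_u, h_v=h_v,
    )


@dataclass
class ThetaEstimates:
    theta_w: float
    theta_pi: float
    theta_h: float
    theta_l: float


def build_sfs(aln: HaplotypeAlignment, require_outgroup: bool = True) -> SiteFrequencySpectrum:
    """Tally the spectrum from an aligned gene.

    Columns with a gap or N in any used row (ingroup and outgroup) are
    excluded; only biallelic ingroup sites are kept.  The ancestral state is
    the outgroup allele when it matches one ingroup allele; otherwise the
    site stays unpolarized (kept for D and D*, excluded from the unfolded
    spectrum used by H and E).
    """
    if require_outgroup and aln.outgroup is None:
        raise ValueError(f"{aln.gene_id}: outgroup row required for polarization")
    names = sorted(aln.haplotypes)
    mat = np.array(
        [list(aln.haplotypes[name]) for name in names], dtype="U1"
    )
    n = aln.n
    rows = [mat]
    if aln.outgroup is not None:
        out_row = np.array(list(aln.outgroup), dtype="U1")
        rows.append(out_row[None, :])
    stacked = np.vstack(rows)
    ok_cols = ~np.isin(stacked, ["N", "-"]).any(axis=0)
    mat = mat[:, ok_cols]
    out = stacked[-1, ok_cols] if aln.outgroup is not None else None

    site_counts: list[int] = []
    polarized: list[bool] = []
    unfolded = np.zeros(n - 1, dtype=np.int64)
    multi = 0
    for col in range(mat.shape[1]):
        column = mat[:, col]
        alleles, counts = np.unique(column, return_counts=True)
        if len(alleles) == 1:
            continue
        if len(alleles) > 2:
            multi += 1
            continue
        if out is not None and out[col] in alleles:
            ancestral = out[col]
            derived_idx = 0 if alleles[1] == ancestral else 1
            dcount = int(counts[derived_idx])
            unfolded[dcount - 1] += 1
            site_counts.append(dcount)
            polarized.append(True)
        else:
            site_counts.append(int(counts[0]))
            polarized.append(False)
    return SiteFrequencySpectrum(
        n=n,
        unfolded=unfolded,
        site_counts=np.array(site_counts, dtype=np.int64),
        polarized_mask=np.array(polarized, dtype=bool),
        multiallelic_sites=multi,
    )


def theta_estimators(sfs: SiteFrequencySpectrum) -> ThetaEstimates:
    """The four theta estimators over the polarized unfolded spectrum."""
    n = sfs.n
    k = spectrum_constants(n)
    i = np.arange(1, n)
    s_i = sfs.unfolded
    s_pol = float(s_i.sum())
    theta_w = s_pol / k.a1
    theta_pi = float(np.sum(2.0 * i * (n - i) * s_i)) / (n * (n - 1))
    theta_h = float(np.sum(2.0 * i**2 * s_i)) / (n * (n - 1))
    theta_l = float(np.sum(i * s_i)) / (n - 1)
    return ThetaEstimates(theta_w=theta_w, theta_pi=theta_pi, theta_h=theta_h, theta_l=theta_l)


def _theta_pi_all(sfs: SiteFrequencySpectrum) -> float:
    """theta_pi over ALL biallelic segregating sites (orientation-free)."""
    n = sfs.n
    c = sfs.site_counts
    return float(np.sum(2.0 * c * (n - c))) / (n * (n - 1))


def _theta_sq_plugin(s: int, k: SpectrumConstants) -> float:
    """Unbiased plug-in for theta^2: S(S-1) / (a1^2 + a2)."""
    return s * (s - 1) / (k.a1**2 + k.a2)


def tajimas_d(sfs: SiteFrequencySpectrum) -> float:
    """Tajima's D on all biallelic ingroup segregating sites."""
    n = sfs.n
    s = sfs.seg_sites
    if n < 4 or s < 1:
        return float("nan")
    k = spectrum_constants(n)
    var = k.e1 * s + k.e2 * s * (s - 1)
    if var <= 0:
        return float("nan")
    theta_pi = _theta_pi_all(sfs)
    theta_w = s / k.a1
    return (theta_pi - theta_w) / math.sqrt(var)


def fu_li_d_star(sfs: SiteFrequencySpectrum) -> float:
    """Fu & Li's D* from total mutations and ingroup singletons."""
    n = sfs.n
    eta = sfs.eta
    if n < 4 or eta < 1:
        return float("nan")
    k = spectrum_constants(n)
    var = k.u_star * eta + k.v_star * eta**2
    if var <= 0:
        return float("nan")
    num = (n / (n - 1.0)) * eta - k.a1 * sfs.eta_s
    return num / math.sqrt(var)


def fay_wu_h(sfs: SiteFrequencySpectrum, variant: str = "unnormalized") -> float:
    """Fay & Wu's H on polarized sites.

    ``unnormalized`` (default) is theta_pi - theta_H; ``normalized`` is
    (theta_pi - theta_L) / sqrt(Var) per Zeng et al. (2006).
    """
    if sfs.polarized_sites < 1:
        return float("nan")
    th = theta_estimators(sfs)
    if variant == "unnormalized":
        return th.theta_pi - th.theta_h
    if variant != "normalized":
        raise ValueError(f"unknown H variant {variant!r}")
    n = sfs.n
    if n < 4:
        return float("nan")
    k = spectrum_constants(n)
    s = sfs.polarized_sites
    theta = s / k.a1
    var = k.h_u * theta + k.h_v * _theta_sq_plugin(s, k)
    if var <= 0:
        return float("nan")
    return (th.theta_pi - th.theta_l) / math.sqrt(var)


def zeng_e(sfs: SiteFrequencySpectrum) -> float:
    """Zeng's E: (theta_L - theta_W) / sqrt(Var), on polarized sites."""
    n = sfs.n
    s = sfs.polarized_sites
    if n < 4 or s < 1:
        return float("nan")
    k = spectrum_constants(n)
    th = theta_estimators(sfs)
    theta = s / k.a1
    var = k.e_u * theta + k.e_v * _theta_sq_plugin(s, k)
    if var <= 0:
        return float("nan")
    return (th.theta_l - theta) / math.sqrt(var)


@dataclass
class NeutralityProfile:
    gene_id: str
    n: int
    seg_sites: int
    polarized_sites: int
    tajima_d: float = float("nan")
    fu_li_d_star: float = float("nan")
    fay_wu_h: float = float("nan")
    zeng_e: float = float("nan")
    valid: bool = False


def profile_gene(
    aln: HaplotypeAlignment,
    min_seg_sites: int = MIN_SEG_SITES,
    h_variant: str = "unnormalized",
) -> NeutralityProfile:
    """All four SFS statistics for one gene, blanked below the site cutoff.

    Profiles with fewer than ``min_seg_sites`` biallelic segregating sites
    are marked invalid and carry no statistic values (the estimates are
    unreliable at low mutation counts).
    """
    sfs = build_sfs(aln, require_outgroup=True)
    prof = NeutralityProfile(
        gene_id=aln.gene_id,
        n=sfs.n,
        seg_sites=sfs.seg_sites,
        polarized_sites=sfs.polarized_sites,
    )
    if sfs.seg_sites < min_seg_sites:
        return prof
    prof.valid = True
    prof.tajima_d = tajimas_d(sfs)
    prof.fu_li_d_star = fu_li_d_star(sfs)
    prof.fay_wu_h = fay_wu_h(sfs, variant=h_variant)
    prof.zeng_e = zeng_e(sfs)
    return prof
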