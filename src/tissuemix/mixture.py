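"""Two-tissue mixture algebra.

A whole-body male library is modelled as a mixture of diploid soma
(autosomes at coverage c_A, X at c_A/2) and a haploid sperm fraction f_h
whose cells carry one autosomal haplotype plus the X. Under this model the
observed X (1n) peak sits at

    c_X = c_A / (2 - f_h)

so the haploid-tissue fraction follows from the peak ratio r = c_X / c_A:

    f_h = 2 - 1/r = (2 r - 1) / r

Under PGE the sperm haplotype is the maternal one, which lifts the
expected coverage of maternal autosomal alleles above the paternal:

    c_maternal = c_AA / (2 - f_h)        c_paternal = c_AA - c_maternal

where c_AA is the total allele depth of homozygous autosomal variants. The
paternal allele then carries the minority share

    p_p = (1 - f_h) / (2 - f_h)

of reads at any heterozygous autosomal position, which inverts to the
pileup-based estimator f_h = (1 - 2 p_p) / (1 - p_p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Optional

from tissuemix.formats import (
    CHROM_AUTOSOME,
    GENOTYPE_HOM_ALT,
    AlleleDepthRecord,
)

__all__ = [
    "TissueMixture",
    "sperm_fraction_from_peaks",
    "expected_parental_coverages",
    "sperm_fraction_from_minor_ratio",
    "paternal_ratio_from_sperm_fraction",
    "estimate_c_aa",
]


def sperm_fraction_from_peaks(c_x: float, c_a: float) -> float:
    """Haploid-tissue (sperm) fraction from the 1n and 2n coverage peaks.

    Parameters
    ----------
    c_x : float
        Coverage of the X-chromosome (1n) peak.
    c_a : float
        Coverage of the autosomal (2n) peak.

    Returns
    -------
    float
        f_h = 2 - c_a/c_x, clipped to 0 (with a warning) when the observed
        ratio falls below 1/2 through sampling noise.

    Raises
    ------
    ValueError
        If either coverage is non-positive, or c_x >= c_a (no valid
        two-tissue mixture produces a 1n peak at or above the 2n peak).
    """
    if c_x <= 0 or c_a <= 0:
        raise ValueError(f"peak coverages must be positive, got c_x={c_x}, c_a={c_a}")
    r = c_x / c_a
    if r >= 1.0:
        raise ValueError(
            f"1n peak ({c_x}) at or above 2n peak ({c_a}): no valid two-tissue mixture"
        )
    if r < 0.5:
        warnings.warn(
            f"peak ratio {r:.4f} < 0.5; clipping sperm fraction to 0 "
            "(consistent with a pure diploid library plus sampling noise)",
            stacklevel=2,
        )
        return 0.0
    return (2.0 * r - 1.0) / r


def expected_parental_coverages(c_aa: float, fh: float) -> tuple[float, float]:
    """Expected maternal and paternal autosomal allele coverages under PGE.

    c_maternal = c_aa / (2 - fh); c_paternal is the remainder, so the two
    always sum exactly to c_aa.
    """
    if c_aa <= 0:
        raise ValueError(f"c_aa must be positive, got {c_aa}")
    _check_fh(fh)
    c_maternal = c_aa / (2.0 - fh)
    return c_maternal, c_aa - c_maternal


def sperm_fraction_from_minor_ratio(p_p: float) -> float:
    """Sperm fraction from the paternal (minor) allele-coverage ratio.

    f_h = (1 - 2 p_p) / (1 - p_p), the inverse of
    :func:`paternal_ratio_from_sperm_fraction`; valid for p_p in (0, 0.5].
    """
    if not 0.0 < p_p <= 0.5:
        raise ValueError(f"minor allele ratio must be in (0, 0.5], got {p_p}")
    return (1.0 - 2.0 * p_p) / (1.0 - p_p)


def paternal_ratio_from_sperm_fraction(fh: float) -> float:
    """Expected paternal allele share p_p = (1 - fh)/(2 - fh) of read depth."""
    _check_fh(fh)
    return (1.0 - fh) / (2.0 - fh)


def estimate_c_aa(records: Iterable[AlleleDepthRecord]) -> float:
    """Mean total allele depth of homozygous-alternate autosomal variants."""
    depths = [
        r.depth_ref + r.depth_alt
        for r in records
        if r.genotype_class == GENOTYPE_HOM_ALT and r.chrom_class == CHROM_AUTOSOME
    ]
    if not depths:
        raise ValueError("no homozygous-alternate autosomal records to estimate c_AA")
    return fmean(depths)


def _check_fh(fh: float) -> None:
    if not 0.0 <= fh < 1.0:
        raise ValueError(f"sperm fraction must be in [0, 1), got {fh}")


@dataclass(frozen=True)
class TissueMixture:
    """Sperm fraction together with the coverage quantities it links.

    Attributes
    ----------
    fh : float
        Haploid-tissue fraction of the library, in [0, 1).
    c_x, c_a : float, optional
        1n and 2n coverage-peak estimates the fraction was derived from.
    c_aa : float, optional
        Mean allele depth of homozygous autosomal variants.
    c_maternal, c_paternal : float, optional
        Expected maternal/paternal autosomal allele coverages (set when
        c_aa is available).
    p_p : float
        Expected paternal (minor) allele-coverage ratio.
    """

    fh: float
    c_x: Optional[float] = None
    c_a: Optional[float] = None
    c_aa: Optional[float] = None
    c_maternal: Optional[float] = None
    c_paternal: Optional[float] = None
    p_p: float = field(default=0.5)

    def __post_init__(self) -> None:
        _check_fh(self.fh)

    @classmethod
    def from_peaks(
        cls, c_x: float, c_a: float, c_aa: Optional[float] = None
    ) -> "TissueMixture":
        """Build the full mixture report from peak coverages (and c_AA)."""
        fh = sperm_fraction_from_peaks(c_x, c_a)
        c_maternal = c_paternal = None
        if c_aa is not None:
            c_maternal, c_paternal = expected_parental_coverages(c_aa, fh)
        return cls(
            fh=fh,
            c_x=c_x,
            c_a=c_a,
            c_aa=c_aa,
            c_maternal=c_maternal,
            c_paternal=c_paternal,
            p_p=paternal_ratio_from_sperm_fraction(fh),
        )

    @classmethod
    def from_minor_ratio(cls, p_p: float) -> "TissueMixture":
        fh = sperm_fraction_from_minor_ratio(p_p)
        return cls(fh=fh, p_p=paternal_ratio_from_sperm_fraction(fh))

    def to_dict(self) -> dict:
        return {
            "fh": self.fh,
            "c_x": self.c_x,
            "c_a": self.c_a,
            "c_aa": self.c_aa,
            "c_maternal": self.c_maternal,
            "c_paternal": self.c_paternal,
            "p_p": self.p_p,
        }
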