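"""Coverage-based sample-sex inference and scaffold chromosome assignment.

In an X0 system a male sequencing library covers X-linked scaffolds at
(roughly) half the autosomal depth while a female library covers both
equally, so the male per-scaffold coverage distribution is bimodal and
the female one unimodal. Sex is inferred from that modality; scaffolds
are assigned autosome/X by where their normalised male and female
coverages fall relative to the two male modes. In a male with a haploid
sperm fraction the 1n mode sits above half the 2n mode — at ratio
1/(2 - f_h) — which the windowing accommodates automatically because the
windows are derived from the fitted modes, not from a fixed 1:2 ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = ["ScaffoldAssignment", "infer_sex", "classify_scaffolds"]

CLASS_AUTOSOME = "autosome"
CLASS_X = "X"
CLASS_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ScaffoldAssignment:
    scaffold: str
    length: int
    chrom_class: str
    male_norm_cov: float
    female_norm_cov: float


def _weighted_log2_cov(
    table: pd.DataFrame, min_length: int, weight_cap: int = 100
) -> np.ndarray:
    """Length-weighted log2 coverages: each scaffold repeated ~length/min_length."""
    sub = table[(table["length"] >= min_length) & (table["coverage"] > 0)]
    reps = np.clip((sub["length"] // min_length).to_numpy(), 1, weight_cap)
    return np.repeat(np.log2(sub["coverage"].to_numpy()), reps)


def _fit_modes(x: np.ndarray) -> tuple[float, float, Optional[tuple[float, float]]]:
    """BIC comparison of 1- vs 2-component Gaussian mixtures on log2 coverage.

    Returns (bic1, bic2, (mu_low, mu_high) of the 2-component fit).
    """
    X = x.reshape(-1, 1)
    gm1 = GaussianMixture(n_components=1, random_state=0).fit(X)
    gm2 = GaussianMixture(n_components=2, n_init=3, random_state=0).fit(X)
    means = np.sort(gm2.means_.ravel())
    return float(gm1.bic(X)), float(gm2.bic(X)), (float(means[0]), float(means[1]))


def infer_sex(
    cov_table: pd.DataFrame,
    min_length: int = 20_000,
    min_scaffolds: int = 50,
    log2_tol: float = 0.35,
) -> str:
    """Infer sample sex from the modality of per-scaffold coverage.

    ``cov_table`` needs columns scaffold, length, coverage. The sample is
    called male iff a 2-component Gaussian mixture on length-weighted log2
    coverages beats the 1-component model by BIC *and* the minor mode sits
    about one log2 unit (i.e. half coverage) below the major, within
    ``log2_tol``.
    """
    usable = cov_table[cov_table["length"] >= min_length]
    if len(usable) < min_scaffolds:
        raise ValueError(
            f"only {len(usable)} scaffolds of length >= {min_length}; "
            f"need at least {min_scaffolds}"
        )
    x = _weighted_log2_cov(cov_table, min_length)
    bic1, bic2, (mu_low, mu_high) = _fit_modes(x)
    if bic2 < bic1 and abs((mu_high - mu_low) - 1.0) <= log2_tol:
        return "male"
    return "female"


def _male_modes(
    x: np.ndarray, log2_tol: float = 0.35
) -> Optional[tuple[float, float]]:
    """(2n, 1n) coverage modes of a male library, or None if unimodal."""
    bic1, bic2, (mu_low, mu_high) = _fit_modes(x)
    if bic2 < bic1 and abs((mu_high - mu_low) - 1.0) <= log2_tol:
        return float(2.0 ** mu_high), float(2.0 ** mu_low)
    return None


def classify_scaffolds(
    male_cov: pd.DataFrame,
    female_cov: pd.DataFrame,
    min_length: int = 20_000,
    min_scaffolds: int = 50,
    log2_tol: float = 0.35,
) -> list[ScaffoldAssignment]:
    """Assign shared scaffolds to autosome / X from male and female coverage.

    Coverages are normalised by each library's autosomal mode (male: the
    higher of its two modes; female: the single mode). A scaffold is
    autosomal iff both normalised coverages are ~1, X-linked iff the
    female coverage is ~1 while the male coverage falls in a window around
    the male 1n mode; the window boundary is the midpoint between the two
    male modes, so everything else — including duplicated scaffolds —
    stays unassigned. The assignment is invariant to global depth
    rescaling of either library.
    """
    merged = male_cov.merge(
        female_cov, on="scaffold", suffixes=("_m", "_f"), how="inner"
    )
    if len(merged) < min_scaffolds:
        raise ValueError(
            f"only {len(merged)} shared scaffolds; need at least {min_scaffolds}"
        )
    merged["length"] = merged[["length_m", "length_f"]].max(axis=1)

    male_w = _weighted_log2_cov(
        merged.rename(columns={"coverage_m": "coverage"}), min_length
    )
    modes = _male_modes(male_w, log2_tol)
    female_w = _weighted_log2_cov(
        merged.rename(columns={"coverage_f": "coverage"}), min_length
    )
    gm1 = GaussianMixture(n_components=1, random_state=0).fit(female_w.reshape(-1, 1))
    female_mode = float(2.0 ** gm1.means_.ravel()[0])

    if modes is None:
        logger.warning(
            "male coverage distribution is unimodal; all scaffolds left unassigned"
        )
        male_mode_2n = float(
            2.0
            ** GaussianMixture(n_components=1, random_state=0)
            .fit(male_w.reshape(-1, 1))
            .means_.ravel()[0]
        )
        rho = None
    else:
        male_mode_2n, male_mode_1n = modes
        rho = male_mode_1n / male_mode_2n

    out: list[ScaffoldAssignment] = []
    for row in merged.itertuples(index=False):
        x = row.coverage_m / male_mode_2n
        f = row.coverage_f / female_mode
        cls = CLASS_UNASSIGNED
        if rho is not None and row.length >= min_length:
            half = (1.0 - rho) / 2.0
            if abs(f - 1.0) <= half:
                if abs(x - 1.0) <= half:
                    cls = CLASS_AUTOSOME
                elif (3.0 * rho - 1.0) / 2.0 <= x <= (1.0 + rho) / 2.0:
                    cls = CLASS_X
        out.append(
            ScaffoldAssignment(
                scaffold=row.scaffold,
                length=int(row.length),
                chrom_class=cls,
                male_norm_cov=float(x),
                female_norm_cov=float(f),
            )
        )
    return out
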