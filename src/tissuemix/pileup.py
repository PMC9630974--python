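"""SNP-call-free replication of the sperm-fraction estimate from raw pileups.

Variant calling can lose power or introduce bias at unusual allele
ratios, so this module works directly on pileup base counts: every
genomic position carrying exactly two nucleotide states with coverage > 1
("bistate") contributes an unordered pair of state depths. Under PGE the
paternal allele is the minority state at every truly heterozygous
position, so minor-state ratios pile up around
p_p = (1 - f_h)/(2 - f_h) and the estimated ratio inverts to a
sperm-fraction estimate. Scaffolds with copy-number differences between
samples are excluded first, since CNVs create bistate-like coverage
ratios unrelated to the tissue mixture.

Because only min/max depths are observable (the parental identity of a
state is unknown), the per-site minor ratio min/(min+max) is a *folded*
quantity: sites where the paternal draw happens to exceed the maternal
are reflected below 0.5. At realistic overdispersion the folded density
is nearly flat between p_p and 0.5, so its raw mode is a poor estimator.
The ratio is therefore estimated by maximum likelihood under the
label-symmetric two-component negative-binomial depth model, which
unfolds the reflection exactly; the kernel-density mode of the folded
ratios is retained as a descriptive statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Set

import numpy as np
from scipy import optimize, stats

from tissuemix.formats import PileupSite
from tissuemix.mixture import sperm_fraction_from_minor_ratio

__all__ = [
    "BistateSummary",
    "filter_cnv_scaffolds",
    "bistate_minor_frequencies",
    "estimate_minor_ratio_mle",
]


@dataclass(frozen=True)
class BistateSummary:
    """Minor-state ratio distribution of bistate pileup positions.

    ``mode_pp`` is the maximum-likelihood estimate of the minority-state
    coverage ratio p_p (the location the folded ratios accumulate
    around); ``kde_mode`` is the raw argmax of a Gaussian kernel density
    of the folded per-site ratios, kept for diagnostics.
    """

    frequencies: np.ndarray
    mode_pp: float
    kde_mode: float
    fh_estimate: float
    n_sites: int

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "mode_pp": self.mode_pp,
            "kde_mode": self.kde_mode,
            "fh_estimate": self.fh_estimate,
        }


def filter_cnv_scaffolds(
    cov_a: Mapping[str, float],
    cov_b: Mapping[str, float],
    log2_threshold: float = 0.25,
) -> Set[str]:
    """Scaffolds without evidence of copy-number variation between samples.

    Each sample's per-scaffold coverage is normalised by its own median;
    a scaffold is kept iff the absolute log2 ratio of the normalised
    coverages is at most ``log2_threshold`` (default 0.25, half-way to a
    single-copy change).
    """
    shared = sorted(set(cov_a) & set(cov_b))
    if not shared:
        raise ValueError("coverage tables share no scaffolds")
    a = np.array([cov_a[s] for s in shared], dtype=np.float64)
    b = np.array([cov_b[s] for s in shared], dtype=np.float64)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("coverages must be positive")
    ratio = np.log2((a / np.median(a)) / (b / np.median(b)))
    return {s for s, r in zip(shared, ratio) if abs(r) <= log2_threshold}


def _nb_logpmf(k: np.ndarray, mean: float, size: float) -> np.ndarray:
    return stats.nbinom.logpmf(k, size, size / (size + mean))


def estimate_minor_ratio_mle(
    lo: np.ndarray, hi: np.ndarray, size_init: float = 10.0, lrt_crit: "float | None" = None
) -> float:
    """MLE of the minority-state ratio from unordered depth pairs.

    The model: one state's depth is NB(c_minor, s), the other's
    NB(c_major, s), independent, with the labels unobservable. The
    likelihood of an unordered pair {x, y} is therefore the symmetrised
    product; maximising over (c_minor, c_major, s) with c_minor <=
    c_major and returning c_minor / (c_minor + c_major) undoes the
    folding of the per-site ratios at 0.5.

    Two robustness devices guard the estimate. A uniform "junk" mixture
    component with fitted weight absorbs pairs the depth model cannot
    produce (residual sequencing-error bistates, CNV leftovers), which
    would otherwise masquerade as a coverage split. And because equal
    means put the split on a parameter boundary — a singular point where
    the likelihood is even in the split and the unconstrained MLE drifts
    to a spurious small split — the split model must beat the equal-means
    null on a likelihood-ratio statistic. By default the BIC rule
    2*dLL > ln(n_sites) is used (chi-square critical values are
    anti-conservative at such singular boundaries); pass ``lrt_crit`` to
    override with a fixed threshold. Splits smaller than roughly
    fh ~ 0.15 sit below this selection floor at typical site counts and
    are reported as 0.5.
    """
    lo = np.asarray(lo, dtype=np.int64)
    hi = np.asarray(hi, dtype=np.int64)
    pairs, weights = np.unique(np.column_stack([lo, hi]), axis=0, return_counts=True)
    x, y = pairs[:, 0].astype(float), pairs[:, 1].astype(float)
    w = weights.astype(float)
    tie = x == y

    total = float(np.mean(lo + hi))
    f_bar = float(np.mean(lo / (lo + hi)))
    # moments give a starting point biased towards 0.5-folding; that is fine
    p0 = np.clip(f_bar, 0.05, 0.49)

    # uniform outlier density over the observed unordered-pair support
    m_max = float(hi.max())
    log_junk = -np.log((m_max + 1.0) * (m_max + 2.0) / 2.0)

    def _mix(ll_model: np.ndarray, logit_eps: float) -> np.ndarray:
        eps = 1.0 / (1.0 + np.exp(-logit_eps))
        return np.logaddexp(np.log1p(-eps) + ll_model, np.log(eps) + log_junk)

    def negll(theta: np.ndarray) -> float:
        c_min, delta, s = np.exp(theta[:3])
        c_maj = c_min + delta
        la = _nb_logpmf(x, c_min, s) + _nb_logpmf(y, c_maj, s)
        lb = _nb_logpmf(y, c_min, s) + _nb_logpmf(x, c_maj, s)
        ll = np.where(tie, la, np.logaddexp(la, lb))
        return -float(w @ _mix(ll, theta[3]))

    def negll_null(theta: np.ndarray) -> float:
        c, s = np.exp(theta[:2])
        ll = _nb_logpmf(x, c, s) + _nb_logpmf(y, c, s)
        # unordered pairs {x, y} with x != y arise two ways, matching the
        # logaddexp in the alternative model
        ll = np.where(tie, ll, ll + np.log(2.0))
        return -float(w @ _mix(ll, theta[2]))

    opts = {"xatol": 1e-7, "fatol": 1e-7, "maxiter": 6000}
    logit_eps0 = -6.0  # ~0.25% outliers
    theta0 = np.concatenate(
        [np.log([p0 * total, max((1 - 2 * p0) * total, 1e-3), size_init]), [logit_eps0]]
    )
    res = optimize.minimize(negll, theta0, method="Nelder-Mead", options=opts)
    res_null = optimize.minimize(
        negll_null,
        np.concatenate([np.log([total / 2.0, size_init]), [logit_eps0]]),
        method="Nelder-Mead",
        options=opts,
    )
    crit = float(np.log(w.sum())) if lrt_crit is None else lrt_crit
    if 2.0 * (res_null.fun - res.fun) < crit:
        return 0.5
    c_min, delta, _ = np.exp(res.x[:3])
    c_maj = c_min + delta
    return float(np.clip(c_min / (c_min + c_maj), 1e-6, 0.5))


def bistate_minor_frequencies(
    sites: Iterable[PileupSite],
    kept_scaffolds: Optional[Set[str]] = None,
    min_depth: int = 10,
    grid_size: int = 512,
) -> BistateSummary:
    """Minor-state ratios of bistate positions and the estimated ratio p_p.

    A position qualifies iff exactly 2 of its 4 nucleotide counts exceed 1
    (N and deletion counts are ignored) and the two states together reach
    ``min_depth`` reads (sequencing errors otherwise flood the low-ratio
    end). ``mode_pp`` comes from :func:`estimate_minor_ratio_mle`; the
    descriptive ``kde_mode`` is the argmax of a Gaussian kernel density
    (Silverman bandwidth) on a ``grid_size``-point grid over (0, 0.5].
    The sperm fraction follows as f_h = (1 - 2 p_p)/(1 - p_p).
    """
    los: list[int] = []
    his: list[int] = []
    for site in sites:
        if kept_scaffolds is not None and site.scaffold not in kept_scaffolds:
            continue
        nuc = np.asarray(site.counts[:4])
        states = nuc[nuc > 1]
        if states.size != 2:
            continue
        total = int(states.sum())
        if total < min_depth:
            continue
        los.append(int(states.min()))
        his.append(int(states.max()))
    if not los:
        raise ValueError("no qualifying bistate positions")
    lo = np.asarray(los, dtype=np.int64)
    hi = np.asarray(his, dtype=np.int64)
    frequencies = lo / (lo + hi)

    if np.ptp(frequencies) == 0.0:
        kde_mode = float(frequencies[0])
    else:
        kde = stats.gaussian_kde(frequencies, bw_method="silverman")
        grid = np.linspace(0.5 / grid_size, 0.5, grid_size)
        kde_mode = float(grid[int(np.argmax(kde(grid)))])

    mode_pp = estimate_minor_ratio_mle(lo, hi)
    fh = sperm_fraction_from_minor_ratio(mode_pp)
    return BistateSummary(
        frequencies=frequencies,
        mode_pp=mode_pp,
        kde_mode=kde_mode,
        fh_estimate=fh,
        n_sites=int(frequencies.size),
    )
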