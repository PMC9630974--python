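"""Two-peak coverage-spectrum model.

The k-mer multiplicity histogram of a diploid male library shows a
monoploid (1n) peak — X-linked and heterozygous k-mers — and a diploid
(2n) peak. The model fitted here is a sum of two negative-binomial
components,

    h(m) = a1 * NB(m; mean = r * c2n, size = s1)
         + a2 * NB(m; mean = c2n,     size = s2)

parameterised directly by the peak ratio r = c1n / c2n, so that the
asymptotic covariance of the nonlinear least-squares fit yields a standard
error and 0.95 confidence interval for r. A ratio whose interval excludes
1/2 signals unevenly spaced peaks, the footprint of a tissue mixture with
different ploidies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal, stats

from tissuemix.formats import KmerHistogram

__all__ = [
    "TwoPeakFit",
    "RatioDeviation",
    "SinglePeakError",
    "fit_two_peak_model",
    "test_ratio_deviation",
]

Z_95 = 1.959963984540054  # two-sided 0.95 normal quantile


class SinglePeakError(ValueError):
    """Raised when only one peak is detectable in the fit range."""


@dataclass(frozen=True)
class TwoPeakFit:
    """Fitted 1n/2n peak parameters and the peak-position ratio.

    ``ratio_r`` is c1n/c2n; ``ratio_ci`` is the 0.95 asymptotic interval
    ratio_r +/- 1.96 * ratio_se. ``fit_range`` is the (inclusive)
    multiplicity window the model was fitted over.
    """

    c2n: float
    ratio_r: float
    amp_1n: float
    amp_2n: float
    disp_1n: float
    disp_2n: float
    ratio_se: float
    ratio_ci: Optional[tuple[float, float]]
    fit_range: tuple[int, int]
    converged: bool

    @property
    def c1n(self) -> float:
        return self.ratio_r * self.c2n

    def to_dict(self) -> dict:
        return {
            "c2n": self.c2n,
            "c1n": self.c1n,
            "ratio_r": self.ratio_r,
            "amp_1n": self.amp_1n,
            "amp_2n": self.amp_2n,
            "disp_1n": self.disp_1n,
            "disp_2n": self.disp_2n,
            "ratio_se": self.ratio_se,
            "ratio_ci": list(self.ratio_ci) if self.ratio_ci is not None else None,
            "fit_range": list(self.fit_range),
            "converged": self.converged,
        }


@dataclass(frozen=True)
class RatioDeviation:
    """Outcome of testing the peak ratio against the naive 1:2 expectation."""

    deviates: bool
    consistent_with_half: bool
    ratio_r: float
    ratio_ci: tuple[float, float]


def _nb_pmf(m: np.ndarray, mean: float, size: float) -> np.ndarray:
    # mean/size parameterisation: p = size / (size + mean)
    return stats.nbinom.pmf(m, size, size / (size + mean))


def _model(m: np.ndarray, theta: np.ndarray) -> np.ndarray:
    ratio, c2n, a1, a2, s1, s2 = theta
    return a1 * _nb_pmf(m, ratio * c2n, s1) + a2 * _nb_pmf(m, c2n, s2)


def _smooth(counts: np.ndarray, window: int = 3) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(counts, kernel, mode="same")


def _detect_peaks(
    mult: np.ndarray, smoothed: np.ndarray, m_lo: int
) -> list[tuple[int, float]]:
    """(multiplicity, height) of prominent smoothed local maxima above m_lo."""
    mask = mult >= m_lo
    y = smoothed[mask]
    x = mult[mask]
    if y.size < 3:
        return []
    prominence = 0.02 * float(y.max())
    idx, _ = signal.find_peaks(y, prominence=prominence)
    peaks = [(int(x[i]), float(y[i])) for i in idx]
    # a maximum at the very edge of the range is not seen by find_peaks
    if y.size and y[0] >= y[1:].max(initial=0.0) and not peaks:
        peaks.append((int(x[0]), float(y[0])))
    return peaks


def _initial_guess(
    mult: np.ndarray, counts: np.ndarray, fit_range: Optional[tuple[int, int]]
) -> tuple[np.ndarray, tuple[int, int]]:
    smoothed = _smooth(counts)

    if fit_range is not None:
        m_lo, m_hi = int(fit_range[0]), int(fit_range[1])
        if m_lo >= m_hi:
            raise ValueError(f"invalid fit_range {fit_range}")
    else:
        # error-peak truncation: first local minimum of the smoothed histogram
        m_lo = int(mult[0])
        for i in range(1, len(smoothed) - 1):
            if smoothed[i] <= smoothed[i - 1] and smoothed[i] < smoothed[i + 1]:
                m_lo = int(mult[i])
                break
        else:
            if len(smoothed) > 1 and smoothed[1] > smoothed[0]:
                m_lo = int(mult[0])  # no error peak at all
        m_hi = int(mult[-1])

    peaks = _detect_peaks(mult, smoothed, m_lo)
    peaks.sort(key=lambda p: p[1], reverse=True)
    if len(peaks) >= 2:
        top = sorted(peaks[:2])  # by multiplicity
        c1n0, c2n0 = float(top[0][0]), float(top[1][0])
        ratio0 = float(np.clip(c1n0 / c2n0, 0.25, 0.85))
    elif len(peaks) == 1:
        # overlapping peaks can merge into a shoulder; start from the single
        # maximum as the 2n peak and let the fit resolve (or reject) the 1n one
        c2n0 = float(peaks[0][0])
        ratio0 = 0.5
    else:
        raise SinglePeakError(
            "no detectable coverage peak above the error region; pass an "
            "explicit fit_range to fit manually"
        )

    if fit_range is None:
        m_hi = min(int(mult[-1]), int(round(3.0 * c2n0)))

    in_range = (mult >= m_lo) & (mult <= m_hi)
    if int(in_range.sum()) < 10:
        raise ValueError(
            f"fewer than 10 histogram bins inside fit range ({m_lo}, {m_hi})"
        )

    def _amp_at(center: float, size0: float = 15.0) -> float:
        j = int(np.argmin(np.abs(mult - center)))
        pmf = _nb_pmf(np.array([int(round(center))]), center, size0)[0]
        return max(float(smoothed[j]) / max(pmf, 1e-12), 1e-6)

    theta0 = np.array(
        [ratio0, c2n0, _amp_at(ratio0 * c2n0), _amp_at(c2n0), 15.0, 15.0]
    )
    return theta0, (int(m_lo), int(m_hi))


def fit_two_peak_model(
    hist: KmerHistogram,
    fit_range: Optional[Sequence[int]] = None,
    variance: str = "sandwich",
) -> TwoPeakFit:
    """Fit the two-peak negative-binomial model by nonlinear least squares.

    Parameters
    ----------
    hist : KmerHistogram
        Multiplicity spectrum (k-mer or per-base mapping coverage — the
        histogram source is the caller's concern).
    fit_range : (int, int), optional
        Inclusive multiplicity window. By default the window starts at the
        first local minimum of the smoothed histogram (truncating the
        sequencing-error peak) and ends at 3x the initial 2n peak guess.
    variance : {"sandwich", "rss"}
        Estimator for the asymptotic covariance of the unweighted fit.
        "sandwich" (default) uses model-based Poisson bin variances,
        Var(count_i) = fitted_i, in a heteroscedasticity-consistent
        sandwich, scaled by the Pearson dispersion (floored at 1) — the
        appropriate choice for count histograms, whose noise scales with
        the expected count. "rss" is the classical homoscedastic scalar
        s^2 (J'J)^-1, which understates the uncertainty near the peaks.

    Returns
    -------
    TwoPeakFit
        With ``converged=False`` and no confidence interval if the
        optimiser fails.

    Raises
    ------
    SinglePeakError
        If fewer than two peaks are detectable and no fit_range is given.
    """
    if variance not in ("sandwich", "rss"):
        raise ValueError(f"unknown variance estimator {variance!r}")
    mult, counts = hist.arrays()
    theta0, (m_lo, m_hi) = _initial_guess(
        mult, counts, tuple(fit_range) if fit_range is not None else None
    )

    mask = (mult >= m_lo) & (mult <= m_hi)
    x = mult[mask].astype(np.int64)
    y = counts[mask]

    lower = np.array([0.05, max(m_lo, 1.0), 1e-9, 1e-9, 0.2, 0.2])
    upper = np.array([0.95, 1.5 * m_hi, np.inf, np.inf, 1e4, 1e4])
    theta0 = np.clip(theta0, lower * 1.0000001, np.minimum(upper, 1e12))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _model(x, theta) - y

    res = optimize.least_squares(
        residuals, theta0, bounds=(lower, upper), method="trf", max_nfev=20000
    )

    ratio, c2n, a1, a2, s1, s2 = res.x
    n_obs, n_par = x.size, 6
    converged = bool(res.success) and n_obs > n_par

    # a vanishing 1n component, a ratio pinned to its bounds, or two nearly
    # coincident components all mean only a single peak is supported
    if fit_range is None and converged:
        if (
            a1 < 1e-3 * a2
            or ratio <= lower[0] * 1.02
            or ratio >= upper[0] * 0.998
            or ratio > 0.85
        ):
            raise SinglePeakError(
                "the 1n component collapsed during fitting: only one coverage "
                "peak is supported; pass an explicit fit_range to force a fit"
            )

    ratio_se = float("nan")
    ratio_ci: Optional[tuple[float, float]] = None
    if converged:
        jac = res.jac
        r = res.fun
        try:
            # invert J'J through the SVD of J itself: squaring the Jacobian
            # first would overflow float64 conditioning (amplitudes ~1e7
            # against a ratio ~0.6) and silently truncate the covariance
            U, S, VT = np.linalg.svd(jac, full_matrices=False)
            keep = S > np.finfo(float).eps * max(jac.shape) * S[0]
            jtj_inv = (VT[keep].T / S[keep] ** 2) @ VT[keep]
            if variance == "rss":
                s2_hat = float(r @ r) / (n_obs - n_par)
                cov = s2_hat * jtj_inv
            else:
                fitted = np.maximum(_model(x, res.x), 1e-9)
                middle = jac.T @ (fitted[:, None] * jac)
                phi = max(float(np.mean(r**2 / fitted)), 1.0)
                cov = phi * (jtj_inv @ middle @ jtj_inv)
            ratio_se = float(np.sqrt(max(cov[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            converged = False
        if np.isfinite(ratio_se) and ratio_se > 0:
            ratio_ci = (ratio - Z_95 * ratio_se, ratio + Z_95 * ratio_se)
        else:
            converged = False

    return TwoPeakFit(
        c2n=float(c2n),
        ratio_r=float(ratio),
        amp_1n=float(a1),
        amp_2n=float(a2),
        disp_1n=float(s1),
        disp_2n=float(s2),
        ratio_se=ratio_se,
        ratio_ci=ratio_ci,
        fit_range=(m_lo, m_hi),
        converged=converged,
    )


def test_ratio_deviation(fit: TwoPeakFit) -> RatioDeviation:
    """Does the fitted peak ratio deviate from the naive 1:2 expectation?

    The ratio deviates iff 0.5 lies outside the 0.95 asymptotic confidence
    interval of ratio_r.
    """
    if not fit.converged or fit.ratio_ci is None or not np.isfinite(fit.ratio_se):
        raise ValueError("ratio deviation test requires a converged fit with finite SE")
    lo, hi = fit.ratio_ci
    deviates = not (lo <= 0.5 <= hi)
    return RatioDeviation(
        deviates=deviates,
        consistent_with_half=not deviates,
        ratio_r=fit.ratio_r,
        ratio_ci=fit.ratio_ci,
    )
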