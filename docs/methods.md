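# Methods

## The two-tissue mixture model

A male X0 body whose cells are all diploid soma yields autosomal coverage
`c_A` and X coverage `c_A/2`. If a fraction `f_h` of cells is haploid
germline — each contributing one (maternal, under PGE) autosomal
haplotype and one X — the per-haplotype contributions change: autosomes
receive `2(1 - f_h) + f_h = 2 - f_h` genome copies per cell on average
and the X receives `(1 - f_h) + f_h = 1`. Normalising, the X peak sits at
`c_X = c_A/(2 - f_h)` and

    f_h = 2 - c_A/c_X = (2r - 1)/r,       r = c_X/c_A  in [1/2, 1).

All downstream quantities are algebraic functions of `f_h`:
`c_maternal = c_AA/(2 - f_h)`, `c_paternal = c_AA - c_maternal` (their sum
is exact by construction), and the paternal minority read share
`p_p = (1 - f_h)/(2 - f_h)` with inverse `f_h = (1 - 2p_p)/(1 - p_p)`.
The model assumes only two cell populations, no somatic aneuploidy, and
sex chromosomes that are monoploid in soma (X0 or equivalent); `f_h` is a
*cell-count* fraction, not biomass.

Noisy peak ratios slightly below 1/2 are clipped to `f_h = 0` with a
warning rather than rejected, so the estimator can run as a naive scan
over many libraries; ratios at or above 1 are errors (no mixture of the
two assumed karyotypes produces them).

## Coverage-spectrum fitting

The multiplicity histogram (k-mer spectrum or per-base mapping coverage —
the source is the caller's concern) is modelled as

    h(m) = a_1 NB(m; mean = r c_2n, size = s_1) + a_2 NB(m; mean = c_2n, size = s_2)

and fitted by unweighted nonlinear least squares over a fit window,
parameterised directly by the ratio `r` so that its asymptotic standard
error and 0.95 interval come straight from the fit.

Numerical choices:

* **Fit window.** The left edge defaults to the first local minimum of
  the 3-bin-smoothed histogram (truncating the sequencing-error peak);
  the right edge to 3× the initial 2n-peak guess. Both can be overridden
  with `fit_range`.
* **Initialisation.** Prominent smoothed local maxima seed the peaks; if
  two exist, the right one of the two tallest seeds `c_2n` and their
  position ratio seeds `r` (the 1n peak is narrower than the 2n peak and
  can be the taller of the two at high sperm fractions, so "tallest =
  2n" would misfire). If the peaks have merged into a single maximum —
  which is exactly what happens at `r = 1/2` — the fit starts from a
  shoulder initialisation (`r = 0.5`) at that maximum. Dispersions start
  at 15, amplitudes at the smoothed height over the component pmf.
* **Single-peak detection.** A histogram is declared single-peaked
  *after* fitting, when the 1n amplitude collapses below 10⁻³ of the 2n
  amplitude, the ratio pins at its optimisation bounds, or the two
  components come out nearly coincident (r > 0.85, where a genuine
  second peak is unresolvable). This raises an error advising a manual
  `fit_range`.
* **Covariance.** `J'J` is inverted through the SVD of the Jacobian
  itself; squaring first would push the conditioning (amplitudes ~10⁷
  against a ratio ~0.6) past float64 and silently truncate the
  covariance. The default variance estimator is a model-based sandwich
  with Poisson bin variances Var(h_i) = fitted_i, scaled by the Pearson
  dispersion floored at 1. The classical residual-sum-of-squares scalar
  (`variance="rss"`) is kept as an option but understates the ratio SE:
  count noise is largest in the peak bins that carry the information
  about `r`, and in replicate simulations the RSS intervals covered the
  truth ~87% of the time against ~95% for the sandwich.
* A fitted `r` weakly identified by overlapping peaks (the X0 regime)
  simply reports a wide interval; the deviation test (`1/2` outside the
  0.95 CI) is then correctly negative.

## The PGE test

Phasing is unavailable in fragmented short-read assemblies, so
heterozygous autosomal sites are decomposed per site into the
higher-depth ("major") and lower-depth ("minor") allele; ties contribute
to both components, keeping the operation deterministic and invariant to
ref/alt label swaps. Under PGE the major component is almost entirely
maternal, and its depth distribution should coincide with the haploid
maternal distribution observed directly as alternate-allele depths of
homozygous X-linked variants. In a non-PGE X0 male both alleles come
from one distribution and the X sits exactly between the decomposed
components.

The comparison is formalised by two statistics on depths normalised by
the median X-homozygous depth (making them coverage-scale-free):
first-Wasserstein distances `d(major, X)` and `d(minor, X)`, and a
median **position index**
`|median(X) - median(major)| / |median(major) - median(minor)|`, clipped
to [0, 1]. The verdict is *PGE-like* when the index is ≤ 0.25 and major
is closer to X than minor; *non-PGE-like* when the index is ≥ 0.4 (or
there is no major/minor asymmetry at all); otherwise *inconclusive*.
The 0.25/0.4 thresholds separate the two simulated regimes (index ~0.1
vs ~0.5 at study conditions) with margin on both sides and are exposed
as configuration.

Coverage decomposition misassigns the small fraction of sites where the
paternal draw exceeds the maternal. This probability,
`P(N_pat > N_mat) + P(N_pat = N_mat)/2` for independent negative
binomials with common size, is computed exactly by summation over a
support truncated at tail mass 10⁻¹², and equals 1/2 by symmetry when
the means coincide (the non-PGE case, where decomposition flips half the
sites by definition). In the test report the maternal mean is estimated
by the X-homozygous mean and the paternal mean by the residual of the
total heterozygous depth.

## The pileup route

An independent estimate of `f_h` avoids variant calling entirely: every
pileup position with exactly two nucleotide states of coverage > 1
contributes an unordered pair of state depths. A minimum total depth
(default 10, configurable) suppresses spurious error bistates at low
coverage.

Because the parental identity of a state is unobservable, the per-site
minor ratio min/(min+max) is *folded* at 1/2. At realistic
overdispersion (size 15, depth ~29×) about a fifth of truly paternal
shares fall above 1/2 and reflect back, leaving the folded density
nearly flat between `p_p` and 1/2 — the raw kernel-density mode is then
an unstable estimator (it landed at 0.47 for a true 0.39 in
simulation). The ratio is therefore estimated by maximum likelihood
under the label-symmetric model: one state ~ NB(c_minor, s), the other
~ NB(c_major, s), likelihood symmetrised over the unknown labels, with
two safeguards:

* a uniform outlier component with fitted weight absorbs pairs the depth
  model cannot produce (residual sequencing-error bistates, CNV
  leftovers), which would otherwise masquerade as a coverage split;
* equal means are a singular boundary (the likelihood is even in the
  split), where χ² critical values for the split-vs-no-split comparison
  are anti-conservative; the split model is accepted by the BIC rule
  2ΔLL > ln(n). Splits below roughly `f_h ≈ 0.15` sit under this
  selection floor at 10⁴–10⁵ sites and report as `p_p = 0.5`,
  `f_h = 0` — the estimator is deliberately conservative near zero.

The KDE argmax of the folded ratios (Silverman bandwidth, 512-point
grid on (0, 0.5]) is retained as a descriptive `kde_mode`.

Scaffolds showing copy-number differences between two males are excluded
first: each library's per-scaffold coverage is normalised by its own
median and scaffolds with |log₂ ratio| > 0.25 (half-way to a single-copy
change) are dropped.

## Sex inference and scaffold assignment

Sample sex comes from the modality of length-weighted log₂ per-scaffold
coverage: a 2-component Gaussian mixture must beat the 1-component model
by BIC *and* place its minor mode about one log₂ unit below the major
(±0.35) for a male call. Scaffold classes come from male and female
coverages normalised by each library's autosomal mode: autosome if both
are ≈1, X if the female is ≈1 while the male falls in a window around
its 1n mode, otherwise unassigned (this catches duplicated scaffolds
automatically). Window half-widths equal half the distance between the
two male modes, so the procedure adapts to the 1n-mode shift caused by
the sperm fraction and is invariant to global depth rescaling. Scaffolds
shorter than 20 kb (configurable) stay unassigned — short-scaffold
coverage medians are too noisy — and unassigned scaffolds are excluded
downstream.

## The synthetic-data generator

`SimulationConfig` defaults encode the study conditions of the sperm-rich
springtail male: diploid coverage 28.7×, sperm fraction 0.35,
negative-binomial size 15, autosomal heterozygosity 2.5/kb, X spanning
30% of a 20-Mb assembly fragmented into 200 log-normal scaffolds (tests
use 8 Mb, which still yields >10⁴ heterozygous sites). Per heterozygous
autosomal site the maternal and paternal depths are independent
NB(c_maternal, 15) and NB(c_paternal, 15); X-linked sites draw from the
maternal (1n-shifted) distribution. The generator emits every input the
pipeline consumes — a VCF with RO/AO depths, a sync pileup (true het
bistates plus invariant sites with Binomial(depth, 0.002) error
bistates), per-scaffold coverage tables for the male, an all-diploid
female and a second male with 5% of scaffolds amplified 1.5×, an
assignment table, a k-mer-histogram analogue (error + 1n + 2n
components, multinomially sampled), and a ground-truth JSON. Identical
seeds give byte-identical bundles.

What it does **not** emulate: read-level artefacts (mapping bias, base
quality, duplicates), repeat content, k-mer-level error structure
(errors only decay over multiplicities 1–3), linked inheritance along
scaffolds (sites are independent), and real per-scaffold coverage noise
(log-normal with σ = 0.03). Passing tests therefore demonstrate the
statistical machinery under the declared generative model, not
robustness to alignment or library artefacts.

A bias probe (`fh_bias_probe`) refits replicate histograms and reports
the median of `f_h_hat − f_h_true` with its sign. At the default 28.7×
conditions the median bias is indistinguishable from zero (|median| <
0.005 across replicate batches; the suite asserts < 0.02), so the
systematic conservative underestimation expected when error and
repeat k-mers contaminate real spectra is *not* reproduced by this
idealised generator — at 15× the probe instead shows a positive bias
from peak overlap. Conclusions about bias on real data must come from
real spectra.

The power grid defaults to 3 X-fractions × 2 heterozygosities × 3
depths × 4 sperm fractions × 2 replicates = 144 cells; detection means
the fitted ratio differs from 1/2 at level α under the asymptotic
normal interval. Per-cell failures (single-peak spectra at degenerate
corners) are recorded, not fatal.

## Known limitations

* The verdict thresholds (0.25/0.4) are design choices validated on the
  simulated regimes, not calibrated p-values; no formal hypothesis test
  accompanies the verdict.
* The pileup route cannot distinguish sperm fractions below ~0.15 from
  zero at typical site counts (BIC selection floor).
* Parent-of-origin is not determined: the pipeline shows that one
  haplotype co-segregates with the X into the germline, not that it is
  maternal — that requires crosses.
* X₁ vs X₂ cannot be separated by coverage, and germline-restricted
  chromosomes are out of scope.
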