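"""Ground-truth simulator for the two-tissue PGE male and its X0 control.

Every input the pipeline consumes can be generated here with known truth:
allele-depth tables (VCF), sync pileups, per-scaffold coverage tables for
a male / a female / a second male with CNV scaffolds, and a k-mer
histogram analogue with error, 1n and 2n components.

The generative model mirrors the two-tissue mixture: a diploid soma
(autosomes 2n, X 1n) mixed with a haploid sperm fraction ``fh_true``
carrying one autosomal haplotype plus the X. Read depths are
negative-binomial with a common dispersion (size) parameter, default 15.
Per autosomal heterozygous site,

    maternal depth ~ NB(mean = depth_2n / (2 - fh),            size)
    paternal depth ~ NB(mean = depth_2n * (1 - fh) / (2 - fh), size)

and X-linked sites are covered at the maternal (1n-shifted) mean. An X0
control is simply ``fh_true = 0``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tissuemix.formats import (
    CHROM_AUTOSOME,
    CHROM_X,
    GENOTYPE_HET,
    GENOTYPE_HOM_ALT,
    AlleleDepthRecord,
    KmerHistogram,
    PileupSite,
    write_assignment_table,
    write_coverage_table,
    write_kmer_histogram,
    write_sync,
)
from tissuemix.spectra import SinglePeakError, fit_two_peak_model
from tissuemix.mixture import sperm_fraction_from_peaks

__all__ = [
    "SimulationConfig",
    "TwoTissueSample",
    "simulate_two_tissue_sample",
    "simulate_kmer_histogram",
    "run_power_grid",
    "default_power_grid",
    "fh_bias_probe",
]

_BASES = "ACGT"
_SYNC_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated whole-body male library.

    Defaults correspond to the BH3-2-like study conditions: diploid
    coverage 28.7x, sperm fraction 0.35, negative-binomial size 15,
    heterozygosity 2.5 per kb on autosomes and an X spanning 30% of the
    genome, on a fragmented 20-Mb assembly of 200 scaffolds.
    """

    genome_size: int = 20_000_000
    n_scaffolds: int = 200
    x_fraction: float = 0.30
    het_rate: float = 0.0025
    depth_2n: float = 28.7
    fh_true: float = 0.35
    nb_size: float = 15.0
    cnv_fraction: float = 0.05
    cnv_ratio: float = 1.5
    error_bistate_rate: float = 0.002
    kmer_k: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_fraction < 1.0:
            raise ValueError(f"x_fraction must be in [0, 1), got {self.x_fraction}")
        if not 0.0 <= self.fh_true < 1.0:
            raise ValueError(f"fh_true must be in [0, 1), got {self.fh_true}")
        if self.depth_2n <= 0:
            raise ValueError(f"depth_2n must be positive, got {self.depth_2n}")
        if self.nb_size <= 0:
            raise ValueError(f"nb_size must be positive, got {self.nb_size}")
        if self.genome_size < self.n_scaffolds:
            raise ValueError("genome_size must be at least n_scaffolds")
        if not 0.0 <= self.het_rate < 0.5:
            raise ValueError(f"het_rate must be in [0, 0.5), got {self.het_rate}")

    @property
    def c_x(self) -> float:
        """Expected 1n (X / sperm-haplotype) coverage."""
        return self.depth_2n / (2.0 - self.fh_true)

    @property
    def c_maternal(self) -> float:
        return self.depth_2n / (2.0 - self.fh_true)

    @property
    def c_paternal(self) -> float:
        return self.depth_2n * (1.0 - self.fh_true) / (2.0 - self.fh_true)

    @property
    def p_p(self) -> float:
        return (1.0 - self.fh_true) / (2.0 - self.fh_true)


@dataclass
class TwoTissueSample:
    """In-memory fixture bundle with ground truth."""

    config: SimulationConfig
    scaffolds: pd.DataFrame  # scaffold, length, is_x
    records: list[AlleleDepthRecord]
    maternal_depths: np.ndarray  # all het sites, including zero-depth draws
    paternal_depths: np.ndarray
    xhom_depths: np.ndarray
    sync_sites: list[PileupSite]
    sync_ref_bases: list[str]
    cov_male: pd.DataFrame
    cov_female: pd.DataFrame
    cov_male2: pd.DataFrame
    cnv_scaffolds: set[str]
    vcf_text: str
    truth: dict


def _nb_draws(rng: np.random.Generator, mean: float, size: float, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    p = size / (size + mean)
    return rng.negative_binomial(size, p, n).astype(np.int64)


def _simulate_scaffolds(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    # log-normal lengths mimic a fragmented assembly
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_scaffolds)
    lengths = np.maximum((raw / raw.sum() * cfg.genome_size).astype(np.int64), 1000)
    names = [f"scaffold_{i + 1}" for i in range(cfg.n_scaffolds)]
    order = rng.permutation(cfg.n_scaffolds)
    is_x = np.zeros(cfg.n_scaffolds, dtype=bool)
    target = cfg.x_fraction * lengths.sum()
    acc = 0
    for i in order:
        if acc >= target:
            break
        is_x[i] = True
        acc += lengths[i]
    return pd.DataFrame({"scaffold": names, "length": lengths, "is_x": is_x})


def _site_positions(
    rng: np.random.Generator, scaffolds: pd.DataFrame, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Scaffold indices (length-weighted) and 1-based positions for n sites."""
    if n == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    lengths = scaffolds["length"].to_numpy()
    probs = lengths / lengths.sum()
    idx = rng.choice(len(scaffolds), size=n, p=probs)
    pos = rng.integers(1, lengths[idx] + 1)
    return idx, pos


def _vcf_text(cfg: SimulationConfig, scaffolds: pd.DataFrame, rows: list[tuple]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=tissuemix-simulator"]
    for row in scaffolds.itertuples(index=False):
        lines.append(f"##contig=<ID={row.scaffold},length={row.length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference allele observations">',
        '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observations">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsim",
    ]
    for chrom, pos, ref, alt, qual, gt, ro, ao in rows:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual:.1f}\t.\t.\t"
            f"GT:DP:RO:AO\t{gt}:{ro + ao}:{ro}:{ao}"
        )
    return "\n".join(lines) + "\n"


def simulate_two_tissue_sample(
    cfg: SimulationConfig, outdir: Optional[str] = None
) -> TwoTissueSample:
    """Generate the full fixture bundle for one simulated male.

    Autosomal heterozygous and homozygous-alternate sites and X-linked
    homozygous sites are placed at rate ``het_rate`` per bp of the
    respective span. The sync pileup holds every autosomal heterozygous
    site (two true states) plus an equal number of invariant positions
    whose second state is a Binomial(depth, ``error_bistate_rate``)
    sequencing-error count. Coverage tables are written for this male, an
    all-diploid female, and a second male in which a ``cnv_fraction`` of
    scaffolds is amplified by ``cnv_ratio``.

    With ``outdir`` given, writes sample.vcf, sample.sync, sample.histo,
    cov_male.tsv, cov_female.tsv, cov_male2.tsv, assignment.tsv and
    truth.json; identical seeds give byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    scaffolds = _simulate_scaffolds(cfg, rng)
    lengths = scaffolds["length"].to_numpy()
    is_x = scaffolds["is_x"].to_numpy()
    aut_span = int(lengths[~is_x].sum())
    x_span = int(lengths[is_x].sum())

    n_het = int(round(cfg.het_rate * aut_span))
    n_hom_aut = n_het
    n_hom_x = int(round(cfg.het_rate * x_span))

    aut = scaffolds[~scaffolds["is_x"]].reset_index(drop=True)
    xsc = scaffolds[scaffolds["is_x"]].reset_index(drop=True)

    maternal = _nb_draws(rng, cfg.c_maternal, cfg.nb_size, n_het)
    paternal = _nb_draws(rng, cfg.c_paternal, cfg.nb_size, n_het)
    hom_aut_depth = _nb_draws(rng, cfg.depth_2n, cfg.nb_size, n_hom_aut)
    xhom = _nb_draws(rng, cfg.c_x, cfg.nb_size, n_hom_x)

    het_idx, het_pos = _site_positions(rng, aut, n_het)
    hom_idx, hom_pos = _site_positions(rng, aut, n_hom_aut)
    x_idx, x_pos = _site_positions(rng, xsc, n_hom_x)

    # which parental allele is the VCF alternate (exercises label-swap symmetry)
    alt_is_paternal = rng.random(n_het) < 0.5
    quals = np.round(rng.uniform(25.0, 60.0, n_het + n_hom_aut + n_hom_x), 1)
    base_pairs = rng.integers(0, 4, size=(n_het + n_hom_aut + n_hom_x, 2))
    base_pairs[:, 1] = (base_pairs[:, 0] + 1 + base_pairs[:, 1] % 3) % 4

    records: list[AlleleDepthRecord] = []
    vcf_rows: list[tuple] = []
    qi = 0
    for i in range(n_het):
        mat, pat = int(maternal[i]), int(paternal[i])
        ro, ao = (mat, pat) if alt_is_paternal[i] else (pat, mat)
        ref_b, alt_b = _BASES[base_pairs[qi, 0]], _BASES[base_pairs[qi, 1]]
        qual = float(quals[qi])
        qi += 1
        if ro == 0 or ao == 0:
            continue  # a caller would not emit a het call without both alleles
        scf = aut["scaffold"].iloc[het_idx[i]]
        records.append(
            AlleleDepthRecord(scf, int(het_pos[i]), GENOTYPE_HET, ro, ao, qual,
                              CHROM_AUTOSOME)
        )
        vcf_rows.append((scf, int(het_pos[i]), ref_b, alt_b, qual, "0/1", ro, ao))
    for i in range(n_hom_aut):
        d = int(hom_aut_depth[i])
        ref_b, alt_b = _BASES[base_pairs[qi, 0]], _BASES[base_pairs[qi, 1]]
        qual = float(quals[qi])
        qi += 1
        if d == 0:
            continue
        scf = aut["scaffold"].iloc[hom_idx[i]]
        records.append(
            AlleleDepthRecord(scf, int(hom_pos[i]), GENOTYPE_HOM_ALT, 0, d, qual,
                              CHROM_AUTOSOME)
        )
        vcf_rows.append((scf, int(hom_pos[i]), ref_b, alt_b, qual, "1/1", 0, d))
    for i in range(n_hom_x):
        d = int(xhom[i])
        ref_b, alt_b = _BASES[base_pairs[qi, 0]], _BASES[base_pairs[qi, 1]]
        qual = float(quals[qi])
        qi += 1
        if d == 0:
            continue
        scf = xsc["scaffold"].iloc[x_idx[i]]
        records.append(
            AlleleDepthRecord(scf, int(x_pos[i]), GENOTYPE_HOM_ALT, 0, d, qual, CHROM_X)
        )
        vcf_rows.append((scf, int(x_pos[i]), ref_b, alt_b, qual, "1/1", 0, d))

    vcf_rows.sort(key=lambda r: (r[0], r[1]))
    vcf = _vcf_text(cfg, scaffolds, vcf_rows)

    # sync pileup: true het bistates plus invariant sites with error bistates
    sync_sites: list[PileupSite] = []
    sync_refs: list[str] = []
    for i in range(n_het):
        mat, pat = int(maternal[i]), int(paternal[i])
        counts = [0, 0, 0, 0, 0, 0]
        b_ref, b_alt = base_pairs[i]
        counts[_SYNC_INDEX[_BASES[b_ref]]] = mat
        counts[_SYNC_INDEX[_BASES[b_alt]]] = pat
        sync_sites.append(
            PileupSite(aut["scaffold"].iloc[het_idx[i]], int(het_pos[i]),
                       tuple(counts))
        )
        sync_refs.append(_BASES[b_ref])
    inv_idx, inv_pos = _site_positions(rng, aut, n_het)
    inv_depth = _nb_draws(rng, cfg.depth_2n, cfg.nb_size, n_het)
    inv_err = rng.binomial(inv_depth, cfg.error_bistate_rate)
    inv_base = rng.integers(0, 4, size=n_het)
    inv_err_base = (inv_base + 1 + rng.integers(0, 3, size=n_het)) % 4
    for i in range(n_het):
        counts = [0, 0, 0, 0, 0, 0]
        counts[_SYNC_INDEX[_BASES[inv_base[i]]]] = int(inv_depth[i]) - int(inv_err[i])
        counts[_SYNC_INDEX[_BASES[inv_err_base[i]]]] += int(inv_err[i])
        sync_sites.append(
            PileupSite(aut["scaffold"].iloc[inv_idx[i]], int(inv_pos[i]),
                       tuple(counts))
        )
        sync_refs.append(_BASES[inv_base[i]])

    # per-scaffold coverage tables (lognormal multiplicative noise)
    def _cov(expected: np.ndarray, noise_rng: np.random.Generator) -> np.ndarray:
        return expected * noise_rng.lognormal(0.0, 0.03, len(expected))

    male_expect = np.where(is_x, cfg.c_x, cfg.depth_2n)
    female_expect = np.full(len(scaffolds), cfg.depth_2n)
    n_cnv = int(round(cfg.cnv_fraction * len(scaffolds)))
    cnv_mask = np.zeros(len(scaffolds), dtype=bool)
    cnv_mask[rng.choice(len(scaffolds), size=n_cnv, replace=False)] = True
    male2_expect = np.where(cnv_mask, male_expect * cfg.cnv_ratio, male_expect)

    def _cov_df(cov: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": scaffolds["scaffold"],
                "length": scaffolds["length"],
                "coverage": np.round(cov, 4),
            }
        )

    cov_male = _cov_df(_cov(male_expect, rng))
    cov_female = _cov_df(_cov(female_expect, rng))
    cov_male2 = _cov_df(_cov(male2_expect, rng))
    cnv_scaffolds = set(scaffolds["scaffold"][cnv_mask])

    truth = {
        "config": asdict(cfg),
        "c_x": cfg.c_x,
        "c_maternal": cfg.c_maternal,
        "c_paternal": cfg.c_paternal,
        "p_p": cfg.p_p,
        "n_het_sites": n_het,
        "n_hom_autosomal_sites": n_hom_aut,
        "n_xhom_sites": n_hom_x,
        "n_records": len(records),
        "aut_span": aut_span,
        "x_span": x_span,
        "cnv_scaffolds": sorted(cnv_scaffolds),
    }

    sample = TwoTissueSample(
        config=cfg,
        scaffolds=scaffolds,
        records=records,
        maternal_depths=maternal,
        paternal_depths=paternal,
        xhom_depths=xhom,
        sync_sites=sync_sites,
        sync_ref_bases=sync_refs,
        cov_male=cov_male,
        cov_female=cov_female,
        cov_male2=cov_male2,
        cnv_scaffolds=cnv_scaffolds,
        vcf_text=vcf,
        truth=truth,
    )
    if outdir is not None:
        _write_bundle(sample, Path(outdir))
    return sample


def _write_bundle(sample: TwoTissueSample, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "sample.vcf").write_text(sample.vcf_text)
    write_sync(sample.sync_sites, outdir / "sample.sync", sample.sync_ref_bases)
    write_coverage_table(sample.cov_male, outdir / "cov_male.tsv")
    write_coverage_table(sample.cov_female, outdir / "cov_female.tsv")
    write_coverage_table(sample.cov_male2, outdir / "cov_male2.tsv")
    assignment = {
        row.scaffold: (CHROM_X if row.is_x else CHROM_AUTOSOME)
        for row in sample.scaffolds.itertuples(index=False)
    }
    write_assignment_table(assignment, outdir / "assignment.tsv")
    write_kmer_histogram(
        simulate_kmer_histogram(sample.config), outdir / "sample.histo"
    )
    (outdir / "truth.json").write_text(
        json.dumps(sample.truth, indent=2, sort_keys=True) + "\n"
    )


def simulate_kmer_histogram(cfg: SimulationConfig) -> KmerHistogram:
    """Multiplicity histogram with error, 1n and 2n components.

    The 1n component sits at depth_2n / (2 - fh) and carries the X span
    plus the heterozygous k-mers (each het SNP converts ~k diploid k-mers
    into 2k monoploid ones); the 2n component sits at depth_2n; the error
    component decays exponentially over multiplicities 1-3. Counts are a
    multinomial sample of ``genome_size`` k-mers from the mixture.
    """
    rng = np.random.default_rng(cfg.seed)
    c2n = cfg.depth_2n
    c1n = cfg.c_x
    h = min(cfg.kmer_k * cfg.het_rate, 0.45)
    w1 = cfg.x_fraction + 2.0 * h * (1.0 - cfg.x_fraction)
    w2 = (1.0 - cfg.x_fraction) * (1.0 - h)
    err_weight = 0.05

    var2n = c2n + c2n**2 / cfg.nb_size
    m_max = int(np.ceil(c2n + 10.0 * np.sqrt(var2n)))
    m = np.arange(1, m_max + 1)

    err = np.where(m <= 3, np.exp(-2.0 * (m - 1.0)), 0.0)
    err /= err.sum()
    p1 = stats.nbinom.pmf(m, cfg.nb_size, cfg.nb_size / (cfg.nb_size + c1n))
    p2 = stats.nbinom.pmf(m, cfg.nb_size, cfg.nb_size / (cfg.nb_size + c2n))
    genomic = w1 * p1 + w2 * p2
    total = genomic.sum()
    if total > 0:
        genomic = genomic / total
    p = err_weight * err + (1.0 - err_weight) * genomic
    p /= p.sum()
    counts = rng.multinomial(cfg.genome_size, p)
    return KmerHistogram(tuple(int(x) for x in m), tuple(int(c) for c in counts))


def default_power_grid(
    base_seed: int = 0,
    x_fractions: Sequence[float] = (0.05, 0.10, 0.20),
    het_rates: Sequence[float] = (0.001, 0.005),
    depths: Sequence[float] = (15.0, 25.0, 35.0),
    fh_values: Sequence[float] = (0.05, 0.15, 0.25, 0.35),
    replicates: int = 2,
    genome_size: int = 20_000_000,
) -> list[SimulationConfig]:
    """Factorial grid of simulation configs (default 3 x 2 x 3 x 4 x 2 = 144)."""
    configs = []
    cells = itertools.product(x_fractions, het_rates, depths, fh_values,
                              range(replicates))
    for i, (xf, hr, d, fh, _) in enumerate(cells):
        configs.append(
            SimulationConfig(
                genome_size=genome_size,
                x_fraction=xf,
                het_rate=hr,
                depth_2n=d,
                fh_true=fh,
                seed=base_seed + i,
            )
        )
    return configs


def run_power_grid(
    configs: Sequence[SimulationConfig], alpha: float = 0.05
) -> pd.DataFrame:
    """Simulate a histogram per cell, fit it, and record ratio-deviation detection.

    Detection means the fitted peak ratio differs from 1/2 at level
    ``alpha`` under the asymptotic normal interval. Per-cell failures
    (non-convergence, undetectable peaks) are recorded, not fatal.
    """
    if len(configs) == 0:
        raise ValueError("empty simulation grid")
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    rows = []
    for cfg in configs:
        converged = False
        detected = False
        ratio_hat = np.nan
        error = ""
        try:
            hist = simulate_kmer_histogram(cfg)
            fit = fit_two_peak_model(hist)
            converged = fit.converged
            ratio_hat = fit.ratio_r
            if converged:
                detected = abs(fit.ratio_r - 0.5) > z * fit.ratio_se
        except (SinglePeakError, ValueError) as exc:
            error = str(exc)
        rows.append(
            {
                "x_fraction": cfg.x_fraction,
                "het_rate": cfg.het_rate,
                "depth_2n": cfg.depth_2n,
                "fh_true": cfg.fh_true,
                "seed": cfg.seed,
                "converged": converged,
                "deviation_detected": detected,
                "ratio_hat": ratio_hat,
                "error": error,
            }
        )
    return pd.DataFrame(rows)


def fh_bias_probe(
    cfg: SimulationConfig, n_replicates: int = 200, base_seed: int = 1000
) -> dict:
    """Median bias of the histogram-route sperm-fraction estimate.

    Refits ``n_replicates`` independently simulated histograms and reports
    median(fh_hat - fh_true) with its sign, probing whether the
    coverage-peak estimator is conservative (negative bias) or not.
    """
    biases = []
    for i in range(n_replicates):
        rep = SimulationConfig(**{**asdict(cfg), "seed": base_seed + i})
        try:
            fit = fit_two_peak_model(simulate_kmer_histogram(rep))
        except (SinglePeakError, ValueError):
            continue
        if not fit.converged:
            continue
        fh_hat = sperm_fraction_from_peaks(fit.ratio_r, 1.0) if fit.ratio_r >= 0.5 else 0.0
        biases.append(fh_hat - cfg.fh_true)
    if not biases:
        raise ValueError("no replicate produced a converged fit")
    med = float(np.median(biases))
    return {
        "n_converged": len(biases),
        "median_bias": med,
        "sign": "underestimate" if med < 0 else ("overestimate" if med > 0 else "unbiased"),
    }
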