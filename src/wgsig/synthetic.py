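"""Synthetic chromosome-scale cohorts with LD and a rare-skewed MAF spectrum.

A founder haplotype panel is drawn from a truncated power-law frequency
spectrum; study individuals are sums of two mosaic haplotypes built by a
template-copying process (switch founder with a per-site probability), which
induces linkage disequilibrium that decays with inter-site distance.
Phenotypes are i.i.d. standard normal, independent of genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np

from wgsig.genotypes import GenotypeMatrix

_SITE_CHUNK = 8192
_HAP_CHUNK = 256


@dataclass
class CohortSpec:
    """Parameters of the generator; ``seed`` fully determines all output."""

    n_individuals: int = 500
    n_sites: int = 50_000
    n_founder_haplotypes: int = 400
    copy_switch_rate: float = 0.005
    maf_spectrum_exponent: float = 1.2
    freq_min: float = 5e-4
    freq_max: float = 0.5
    founder_ld_scale: float = 100.0  # latent AR(1) scale in sites; 0 = no founder LD
    mean_gap_bp: int = 100
    chrom: str = "3"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_sites, self.n_founder_haplotypes) < 1:
            raise ValueError("all counts must be positive")
        if not 0 < self.copy_switch_rate <= 1:
            raise ValueError("copy_switch_rate must lie in (0, 1]")
        if not 0 < self.freq_min < self.freq_max <= 0.5:
            raise ValueError("require 0 < freq_min < freq_max <= 0.5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class FounderPanel:
    haplotypes: np.ndarray  # (n_founder_haplotypes, n_sites) uint8 in {0, 1}
    positions: np.ndarray  # (n_sites,) 1-based, strictly increasing
    target_freq: np.ndarray  # spectrum draw per site, before discretisation

    @property
    def founder_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class PhenotypeSet:
    """``values`` is N x R; replicate columns are independent null draws."""

    values: np.ndarray
    seed: int

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]


def sample_spectrum(
    u: np.ndarray, exponent: float, fmin: float, fmax: float
) -> np.ndarray:
    """Inverse-CDF transform of uniforms to density ∝ f^-exponent on [fmin, fmax]."""
    if fmin >= fmax or fmin <= 0:
        raise ValueError("degenerate spectrum range")
    a = exponent
    if abs(a - 1.0) < 1e-12:
        return fmin * (fmax / fmin) ** u
    b = 1.0 - a
    return ((fmax**b - fmin**b) * u + fmin**b) ** (1.0 / b)


def spectrum_cdf(t: float, exponent: float, fmin: float, fmax: float) -> float:
    """P(f < t) for the truncated power-law spectrum (closed form)."""
    t = min(max(t, fmin), fmax)
    a = exponent
    if abs(a - 1.0) < 1e-12:
        return np.log(t / fmin) / np.log(fmax / fmin)
    b = 1.0 - a
    return (t**b - fmin**b) / (fmax**b - fmin**b)


def solve_spectrum_exponent(
    target_fraction: float, threshold: float, fmin: float, fmax: float
) -> float:
    """Exponent such that P(f < threshold) equals ``target_fraction``."""
    from scipy.optimize import brentq

    return float(
        brentq(
            lambda a: spectrum_cdf(threshold, a, fmin, fmax) - target_fraction,
            0.01,
            8.0,
        )
    )


def generate_founders(spec: CohortSpec) -> FounderPanel:
    """Draw the founder haplotype panel and site positions.

    Per site, a target frequency f is drawn from the spectrum.  Each founder
    haplotype is an independent latent AR(1) Gaussian chain along the sites,
    thresholded at the f-quantile (Gaussian copula), so marginally founder
    alleles are Bernoulli(f) while nearby sites are in LD.  Thresholding at
    extreme quantiles attenuates the latent correlation, so realized LD is
    weaker between rare variants than between common ones.  Sites that come
    out monomorphic among founders are forced to carry exactly one minor
    allele so every site is usable downstream.
    """
    from scipy import stats as _stats

    rng = np.random.default_rng([spec.seed, 0])
    m, h = spec.n_sites, spec.n_founder_haplotypes
    target = sample_spectrum(
        rng.random(m), spec.maf_spectrum_exponent, spec.freq_min, spec.freq_max
    )
    cutoffs = _stats.norm.isf(target)
    rho = math.exp(-1.0 / spec.founder_ld_scale) if spec.founder_ld_scale > 0 else 0.0
    haps = np.empty((h, m), dtype=np.uint8)
    carry = None  # latent state at the end of the previous chunk, (h, 1)
    for lo in range(0, m, _SITE_CHUNK):
        hi = min(lo + _SITE_CHUNK, m)
        eps = rng.standard_normal((h, hi - lo))
        if rho == 0.0:
            z = eps
        else:
            from scipy.signal import lfilter

            x = eps * math.sqrt(1.0 - rho**2)
            if carry is None:
                x[:, 0] = eps[:, 0]  # stationary start
                zi = np.zeros((h, 1))
            else:
                zi = rho * carry
            z, zf = lfilter([1.0], [1.0, -rho], x, axis=1, zi=zi)
            carry = z[:, -1:]
        haps[:, lo:hi] = z > cutoffs[lo:hi]
    counts = haps.sum(axis=0)
    # force polymorphic founders: at least one carrier, at most h - 1
    empty = np.flatnonzero(counts == 0)
    for j in empty:
        haps[rng.integers(h), j] = 1
    full = np.flatnonzero(counts == h)
    for j in full:
        haps[rng.integers(h), j] = 0
    gaps = rng.geometric(1.0 / spec.mean_gap_bp, size=m)
    positions = np.cumsum(gaps).astype(np.int64)
    return FounderPanel(haplotypes=haps, positions=positions, target_freq=target)


def _mosaic_haplotypes(
    founders: np.ndarray, n_haps: int, switch_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Build ``n_haps`` mosaic haplotypes by the template-copying process."""
    h, m = founders.shape
    out = np.empty((n_haps, m), dtype=np.uint8)
    for lo in range(0, n_haps, _HAP_CHUNK):
        hi = min(lo + _HAP_CHUNK, n_haps)
        k = hi - lo
        switch = rng.random((k, m)) < switch_rate
        switch[:, 0] = True
        templates = rng.integers(0, h, size=(k, m), dtype=np.int32)
        # forward-fill the template chosen at the latest switch point
        idx = np.where(switch, np.arange(m, dtype=np.int32), 0)
        np.maximum.accumulate(idx, axis=1, out=idx)
        tmpl = np.take_along_axis(templates, idx, axis=1)
        out[lo:hi] = founders[tmpl, np.arange(m)[None, :]]
    return out


def sample_cohort(founders: FounderPanel, spec: CohortSpec) -> GenotypeMatrix:
    """Sample diploid individuals as sums of two mosaic haplotypes.

    Realised-monomorphic sites are dropped; columns whose alternate allele
    ends up being the major one are flipped to minor-allele coding, so the
    result matches what :func:`wgsig.genotypes.read_genotypes` would return
    from the written VCF.
    """
    rng = np.random.default_rng([spec.seed, 1])
    haps = _mosaic_haplotypes(
        founders.haplotypes, 2 * spec.n_individuals, spec.copy_switch_rate, rng
    )
    dosages = (
        haps[: spec.n_individuals].astype(np.int16)
        + haps[spec.n_individuals :].astype(np.int16)
    ).astype(float)
    p = dosages.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    dosages = dosages[:, keep]
    p = p[keep]
    flip = p > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    maf = np.minimum(p, 1.0 - p)
    sample_ids = [f"S{i:05d}" for i in range(spec.n_individuals)]
    return GenotypeMatrix(
        dosages=dosages,
        positions=founders.positions[keep],
        maf=maf,
        sample_ids=sample_ids,
        chrom=spec.chrom,
    )


def simulate_cohort(spec: CohortSpec) -> GenotypeMatrix:
    """Convenience: founders + cohort in one call."""
    return sample_cohort(generate_founders(spec), spec)


def simulate_null_phenotypes(n: int, replicates: int, seed: int) -> PhenotypeSet:
    """R independent standard-normal phenotype vectors (null: no association)."""
    if n < 1 or replicates < 1:
        raise ValueError("n and replicates must be positive")
    rng = np.random.default_rng([seed, 2])
    return PhenotypeSet(values=rng.standard_normal((n, replicates)), seed=seed)


def inject_effect(
    phenos: PhenotypeSet,
    g: GenotypeMatrix,
    variant_idx: int,
    beta: float,
) -> PhenotypeSet:
    """Add a genetic effect to every replicate (power demos; off by default)."""
    values = phenos.values + beta * g.dosages[:, [variant_idx]]
    return PhenotypeSet(values=values, seed=phenos.seed)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the cohort as a plain-text VCF 4.2 (GT only, unphased)."""
    d = np.rint(g.dosages).astype(int)
    if np.any((d < 0) | (d > 2)):
        raise ValueError("cannot write imputed/fractional dosages as GT")
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={g.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j in range(g.n_variants):
            gts = "\t".join(gt_str[v] for v in d[:, j])
            fh.write(f"{g.chrom}\t{g.positions[j]}\tv{j}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def write_phenotypes(phenos: PhenotypeSet, sample_ids: list[str], path: str | Path) -> None:
    """Write phenotypes as TSV; first replicate in column ``phenotype``."""
    v = phenos.values
    with open(path, "w") as fh:
        header = ["sample_id", "phenotype"] + [
            f"phenotype_r{r}" for r in range(1, v.shape[1])
        ]
        fh.write("\t".join(header) + "\n")
        for i, sid in enumerate(sample_ids):
            fh.write(sid + "\t" + "\t".join(f"{x:.10g}" for x in v[i]) + "\n")
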