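"""Empirical significance thresholds: section, take minima, percentile,
regress against the Bonferroni scale, extrapolate genome-wide."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from wgsig.store import PValueStore

DEFAULT_GENOME_LENGTH = 3.096e9
DEFAULT_REGION_LENGTH = 198e6  # chromosome 3


@dataclass
class SectionScheme:
    """Contiguous near-equal partition of m ordered tests into S sections."""

    n_sections: int
    sizes: np.ndarray  # (S,) test counts; differ by at most 1
    m: int

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.sum() != self.m:
            raise ValueError("section sizes must sum to the test count")
        if self.sizes.size != self.n_sections:
            raise ValueError("sizes length must equal n_sections")
        if np.ptp(self.sizes) > 1:
            raise ValueError("section sizes may differ by at most 1")

    @property
    def boundaries(self) -> np.ndarray:
        """Start offsets of each section into the ordered test list."""
        return np.concatenate(([0], np.cumsum(self.sizes)[:-1]))

    @property
    def nominal_size(self) -> float:
        return self.m / self.n_sections


def partition_sections(m: int, n_sections: int) -> SectionScheme:
    """Split m contiguous tests into S sections; the first ``m mod S`` sections
    get the extra test."""
    if n_sections < 1 or n_sections > m:
        raise ValueError(f"need 1 <= S <= m, got S={n_sections}, m={m}")
    base, extra = divmod(m, n_sections)
    sizes = np.full(n_sections, base, dtype=np.int64)
    sizes[:extra] += 1
    return SectionScheme(n_sections=n_sections, sizes=sizes, m=m)


def section_min_p(
    store: PValueStore, scheme: SectionScheme, test_class: str = "windows"
) -> np.ndarray:
    """(S, R) matrix of per-section minimum P-values for the chosen class.

    The scheme must have been built for the same class (its m must equal the
    class's test count); sections with no finite P-values are flagged NaN.
    """
    idx = store.select(test_class)
    if idx.size != scheme.m:
        raise ValueError(
            f"scheme covers {scheme.m} tests but class {test_class!r} has {idx.size}"
        )
    p = store.pvalues[:, idx]  # (R, m) in genomic order
    bounds = scheme.boundaries
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        # NaN entries (undefined tests) are ignored; a section that is all-NaN
        # in a replicate stays NaN and is excluded downstream
        minima = np.fmin.reduceat(p, bounds, axis=1).T  # (S, R)
    return minima


def empirical_alpha(minima: np.ndarray, percentile: float = 5.0) -> np.ndarray:
    """Nearest-rank percentile of replicate minima, per section.

    Uses k = ceil(percentile/100 * R) on the ascending sorted minima; this is
    the empirical per-section level controlling FWER at ``percentile``%.
    """
    minima = np.atleast_2d(np.asarray(minima, dtype=float))
    r = minima.shape[1]
    if r == 0:
        raise ValueError("no replicates")
    if r < 20:
        warnings.warn(f"only {r} replicates; the {percentile}th percentile is degenerate")
    k = max(int(math.ceil(percentile / 100.0 * r)), 1)
    part = np.sort(minima, axis=1)
    return part[:, k - 1]


@dataclass
class ThresholdPoint:
    """One point of the threshold-vs-Bonferroni regression."""

    x: float  # -log10(alpha / m) for the nominal section test count
    y: float  # mean over sections of -log10(empirical threshold)
    n_sections_averaged: int
    sd: float
    section_size: float = 0.0


@dataclass
class ThresholdPrediction:
    b0: float
    b1: float
    x_star: float
    y_star: float
    alpha_c: float
    m_e_genomewide: float
    length_ratio: float
    m_max: int
    points: list[ThresholdPoint] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "b0": self.b0,
            "b1": self.b1,
            "x_star": self.x_star,
            "y_star": self.y_star,
            "alpha_c": self.alpha_c,
            "m_e_genomewide": self.m_e_genomewide,
            "length_ratio": self.length_ratio,
            "m_max": self.m_max,
            "points": [
                {
                    "x": p.x,
                    "y": p.y,
                    "sd": p.sd,
                    "n_sections": p.n_sections_averaged,
                    "section_size": p.section_size,
                }
                for p in self.points
            ],
        }


def aggregate_points(
    thresholds_by_scheme: Sequence[np.ndarray],
    schemes: Sequence[SectionScheme],
    alpha: float = 0.05,
) -> list[ThresholdPoint]:
    """One ThresholdPoint per section scheme (distinct section size).

    x uses the nominal common size m/S; y averages -log10(threshold) over all
    sections of the scheme (NaN-flagged sections excluded).
    """
    if len(thresholds_by_scheme) != len(schemes):
        raise ValueError("one threshold vector per scheme required")
    points = []
    for thr, scheme in zip(thresholds_by_scheme, schemes):
        thr = np.asarray(thr, dtype=float)
        ok = np.isfinite(thr) & (thr > 0)
        logs = -np.log10(thr[ok])
        m_bar = scheme.nominal_size
        points.append(
            ThresholdPoint(
                x=-math.log10(alpha / m_bar),
                y=float(logs.mean()),
                n_sections_averaged=int(ok.sum()),
                sd=float(logs.std(ddof=1)) if ok.sum() > 1 else 0.0,
                section_size=m_bar,
            )
        )
    return points


def extrapolate_genomewide(
    points: Sequence[ThresholdPoint],
    length_ratio: float,
    m_max: int,
    alpha: float = 0.05,
) -> ThresholdPrediction:
    """OLS of y on x over the points, evaluated at x* = -log10(alpha/(R m_max)).

    alpha_c = 10^(-y*) is the predicted genome-wide threshold and
    m_e = alpha / alpha_c the implied effective number of independent tests,
    capped at R * m_max (no more independent tests than actual tests).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for the regression")
    if length_ratio < 1:
        raise ValueError("length ratio must be >= 1")
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate points: no spread in x")
    b1, b0 = np.polyfit(x, y, 1)
    x_star = -math.log10(alpha / (length_ratio * m_max))
    y_star = b0 + b1 * x_star
    alpha_c = 10.0 ** (-y_star)
    m_e = alpha / alpha_c
    cap = length_ratio * m_max
    if m_e > cap:
        m_e = cap
        alpha_c = alpha / m_e
        y_star = -math.log10(alpha_c)
    return ThresholdPrediction(
        b0=float(b0),
        b1=float(b1),
        x_star=x_star,
        y_star=float(y_star),
        alpha_c=float(alpha_c),
        m_e_genomewide=float(m_e),
        length_ratio=length_ratio,
        m_max=m_max,
        points=list(points),
    )


def default_section_series(m: int, min_tests_per_section: int = 64) -> list[int]:
    """Powers of two 1, 2, 4, ... capped so sections keep a workable test count."""
    series = []
    s = 1
    while s <= m and m / s >= min_tests_per_section:
        series.append(s)
        s *= 2
    if len(series) < 3:  # tiny inputs: relax the floor so the regression is fit
        series = [s for s in (1, 2, 4) if s <= m]
    return sorted(series, reverse=True)


def simulate_independent_prediction(
    m: int,
    replicates: int,
    section_series: Sequence[int],
    length_ratio: float,
    seed: int,
    alpha: float = 0.05,
    percentile: float = 5.0,
    chunk: int = 50_000,
) -> ThresholdPrediction:
    """Calibration run of the pipeline on i.i.d. Uniform(0,1) P-values.

    Streams replicates in chunks so very large replicate counts fit in
    memory; used to check the Bonferroni fixed point (independent tests must
    recover slope 1, intercept 0 and m_e = R * m).
    """
    rng = np.random.default_rng(seed)
    schemes = [partition_sections(m, s) for s in section_series]
    bounds = [s.boundaries for s in schemes]
    minima = [np.empty((s.n_sections, replicates)) for s in schemes]
    done = 0
    while done < replicates:
        take = min(chunk, replicates - done)
        p = rng.random((take, m))
        for i, b in enumerate(bounds):
            minima[i][:, done : done + take] = np.minimum.reduceat(p, b, axis=1).T
        done += take
    thresholds = [empirical_alpha(mn, percentile) for mn in minima]
    points = aggregate_points(thresholds, schemes, alpha=alpha)
    return extrapolate_genomewide(points, length_ratio, m, alpha=alpha)


def threshold_pipeline(
    store: PValueStore,
    test_class: str = "windows",
    section_series: Optional[Sequence[int]] = None,
    length_ratio: float = DEFAULT_GENOME_LENGTH / DEFAULT_REGION_LENGTH,
    alpha: float = 0.05,
    percentile: float = 5.0,
) -> ThresholdPrediction:
    """Full section -> minimum -> percentile -> regress -> extrapolate pipeline."""
    m = store.select(test_class).size
    if m == 0:
        raise ValueError(f"no tests of class {test_class!r} in the store")
    if section_series is None:
        section_series = default_section_series(m)
    schemes = [partition_sections(m, s) for s in section_series if s <= m]
    thresholds = [
        empirical_alpha(section_min_p(store, scheme, test_class), percentile)
        for scheme in schemes
    ]
    points = aggregate_points(thresholds, schemes, alpha=alpha)
    return extrapolate_genomewide(points, length_ratio, m, alpha=alpha)
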