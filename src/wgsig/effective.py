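"""Effective number of independent tests from correlation-matrix eigenvalues."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MAX_EIG_WINDOWS = 2000  # dense eigendecompositions beyond this are chunked


@dataclass
class Spectrum:
    """Nonnegative eigenvalues of an m x m correlation matrix, descending."""

    eigenvalues: np.ndarray
    m: int
    clamped_mass: float = 0.0  # |sum of negatives| zeroed out (banding artifacts)

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.eigenvalues.size != self.m:
            raise ValueError("spectrum must have m eigenvalues")
        if np.any(self.eigenvalues < 0):
            raise ValueError("eigenvalues must be nonnegative after clamping")
        # trace identity; banding may shift it by at most the clamped mass
        tol = max(1e-6 * self.m, 2.0 * self.clamped_mass + 1e-9)
        if abs(float(self.eigenvalues.sum()) - self.m) > tol:
            raise ValueError("eigenvalue sum deviates from the matrix trace")


@dataclass
class MeEstimate:
    m_e: float
    method: str
    m: int

    def __post_init__(self) -> None:
        if not 0 < self.m_e <= self.m + 1e-9:
            raise ValueError("m_e must lie in (0, m]")


def spectrum_of(corr: np.ndarray) -> Spectrum:
    """Eigendecompose a (band-completed) correlation matrix.

    Small negative eigenvalues, which arise when a banded matrix is completed
    with zeros, are clamped to 0 and their mass logged.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.linalg.eigvalsh(corr)
    neg = lam[lam < 0]
    clamped = float(-neg.sum()) if neg.size else 0.0
    if clamped > 0:
        logger.debug("clamped negative eigenvalue mass %.3g", clamped)
    lam = np.clip(lam, 0.0, None)[::-1].copy()
    return Spectrum(eigenvalues=lam, m=corr.shape[0], clamped_mass=clamped)


def me_li_ji(s: Spectrum) -> MeEstimate:
    """m_e = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]."""
    lam = s.eigenvalues
    if lam.size == 0:
        raise ValueError("empty spectrum")
    m_e = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return MeEstimate(m_e=min(m_e, s.m), method="li_ji", m=s.m)


def me_li_et_al(s: Spectrum) -> MeEstimate:
    """m_e = m - sum_i I(lambda_i > 1)(lambda_i - 1)."""
    lam = s.eigenvalues
    if lam.size == 0:
        raise ValueError("empty spectrum")
    excess = lam[lam > 1] - 1.0
    m_e = float(s.m - excess.sum())
    return MeEstimate(m_e=max(min(m_e, s.m), 1e-12), method="li_et_al", m=s.m)


def significance_threshold(m_e: float, alpha: float = 0.05, form: str = "exact") -> float:
    """Per-test level controlling FWER at ``alpha`` across ``m_e`` independent tests."""
    if m_e < 1:
        raise ValueError("m_e must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if form == "exact":
        return 1.0 - (1.0 - alpha) ** (1.0 / m_e)
    if form == "approx":
        return alpha / m_e
    raise ValueError("form must be 'exact' or 'approx'")


def me_of_band(corr_band, method: str = "li_ji", chunk: int = MAX_EIG_WINDOWS) -> float:
    """m_e for a whole banded correlation matrix.

    Dense eigendecomposition is capped at ``chunk`` windows; larger matrices
    are split into consecutive blocks whose m_e values are summed (windows in
    different far-apart blocks are treated as independent, consistent with
    the band being effectively zero there).
    """
    est = me_li_ji if method == "li_ji" else me_li_et_al
    n = corr_band.n_windows
    full = corr_band.to_full()
    total = 0.0
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        total += est(spectrum_of(full[lo:hi, lo:hi])).m_e
    return total


def correlation_study_table(
    corr_band,
    section_sizes: Sequence[int],
    alpha: float = 0.05,
    methods: Sequence[str] = ("li_ji", "li_et_al"),
):
    """Mean -log10(alpha/m_e) by estimator for consecutive sections of each size.

    Returns a list of dict rows: one per (section size, method), the data
    behind a thresholds-vs-region-size table.
    """
    full = corr_band.to_full()
    n = corr_band.n_windows
    rows = []
    for m in section_sizes:
        if m > n:
            continue
        n_sections = n // m
        per_method: dict[str, list[float]] = {meth: [] for meth in methods}
        for s in range(n_sections):
            block = full[s * m : (s + 1) * m, s * m : (s + 1) * m]
            spec = spectrum_of(block)
            for meth in methods:
                est = me_li_ji(spec) if meth == "li_ji" else me_li_et_al(spec)
                per_method[meth].append(est.m_e)
        for meth in methods:
            m_es = np.array(per_method[meth])
            rows.append(
                {
                    "section_size": m,
                    "method": meth,
                    "mean_m_e": float(m_es.mean()),
                    "bonferroni_neglog10": -math.log10(alpha / m),
                    "mean_threshold_neglog10": float(
                        np.mean(-np.log10(alpha / m_es))
                    ),
                }
            )
    return rows


def write_study_table(rows, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "section_size\tmethod\tmean_m_e\tbonferroni_neglog10\t"
            "mean_threshold_neglog10\n"
        )
        for r in rows:
            fh.write(
                f"{r['section_size']}\t{r['method']}\t{r['mean_m_e']:.6g}\t"
                f"{r['bonferroni_neglog10']:.6g}\t{r['mean_threshold_neglog10']:.6g}\n"
            )
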