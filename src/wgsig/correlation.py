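"""Analytic null correlations between window test statistics.

For SKAT statistics Q_k = e' K_k e with e ~ N(0, sigma^2 P), the covariance
of Gaussian quadratic forms gives

    corr(Q_i, Q_j) = tr(A_i A_j) / sqrt(tr(A_i^2) tr(A_j^2)),  A_k = P K_k P.

For burden statistics (squared projected scores),

    corr(T_i, T_j) = (x_i' P x_j)^2 / ((x_i' P x_i) (x_j' P x_j)).

All traces are evaluated through the N x k factors B_k = P G_k W_k, so cost
scales with window size rather than sample size squared.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from wgsig.association import NullModel, WeightScheme, _projected_weighted
from wgsig.genotypes import GenotypeMatrix, MafPartition, Window, WindowSet

logger = logging.getLogger(__name__)

DEFAULT_BAND = 1000
_CLAMP_TOL = 1e-8


@dataclass
class CorrelationBand:
    """Banded symmetric correlation matrix between window statistics.

    ``values[i, d]`` holds corr(T_i, T_{i+d}) for offsets d = 0..band; the
    diagonal column is identically 1.  Entries beyond the band are treated
    as zero downstream.
    """

    values: np.ndarray  # (n_windows, band + 1)
    band: int
    kind: str
    maf_threshold: Optional[float] = None

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def corr(self, i: int, j: int) -> float:
        d = abs(i - j)
        if d > self.band:
            return 0.0
        return float(self.values[min(i, j), d])

    def to_full(self) -> np.ndarray:
        """Complete to a dense symmetric matrix with zeros outside the band."""
        n = self.n_windows
        full = np.zeros((n, n))
        for d in range(self.band + 1):
            vals = self.values[: n - d, d]
            full[np.arange(n - d), np.arange(d, n)] = vals
            full[np.arange(d, n), np.arange(n - d)] = vals
        return full

    def to_tsv(self, path: str | Path) -> None:
        header = {
            "kind": self.kind,
            "band": self.band,
            "n_windows": self.n_windows,
            "maf_threshold": self.maf_threshold,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            fh.write("i\tj\tcorr\n")
            for d in range(self.band + 1):
                for i in range(self.n_windows - d):
                    fh.write(f"{i}\t{i + d}\t{self.values[i, d]:.8g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CorrelationBand":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            fh.readline()
            n, band = header["n_windows"], header["band"]
            values = np.zeros((n, band + 1))
            for line in fh:
                i, j, c = line.split("\t")
                values[int(i), int(j) - int(i)] = float(c)
        return cls(
            values=values,
            band=band,
            kind=header["kind"],
            maf_threshold=header.get("maf_threshold"),
        )

    def plot_heatmap(self, path: str | Path, max_windows: int = 500) -> None:
        """Convenience PNG of the leading block of the band (optional matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = min(self.n_windows, max_windows)
        block = self.to_full()[:n, :n]
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(block, vmin=0, vmax=1, cmap="viridis", origin="lower")
        ax.set_xlabel("window")
        ax.set_ylabel("window")
        ax.set_title(f"{self.kind} null correlations")
        fig.colorbar(im, ax=ax)
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _clamp(value: float) -> float:
    if value < 0.0:
        if value < -_CLAMP_TOL:
            warnings.warn(f"clamping negative correlation {value:.3g} to 0")
        return 0.0
    return min(value, 1.0)


def skat_null_correlation_from_factors(b_i: np.ndarray, b_j: np.ndarray) -> float:
    """corr(Q_i, Q_j) from the projected weighted factors B_k = P G_k W_k."""
    cross = np.sum((b_i.T @ b_j) ** 2)
    t_i = np.sum((b_i.T @ b_i) ** 2)
    t_j = np.sum((b_j.T @ b_j) ** 2)
    if t_i <= 0 or t_j <= 0:
        raise ValueError("zero kernel in one of the windows")
    return _clamp(cross / np.sqrt(t_i * t_j))


def skat_null_correlation(
    g: GenotypeMatrix,
    partition: MafPartition,
    window_i: Window,
    window_j: Window,
    weights: WeightScheme,
    null_model: NullModel,
) -> float:
    """Analytic null correlation of two SKAT statistics on the same genotypes."""
    rare = g.dosages[:, partition.rare_idx]
    w = weights.weights

    def factor(win: Window) -> np.ndarray:
        sl = slice(win.start_rank, win.end_rank)
        return _projected_weighted(
            rare[:, sl], WeightScheme("custom", w[sl]), null_model
        )

    return skat_null_correlation_from_factors(factor(window_i), factor(window_j))


def burden_null_correlation_from_scores(
    x_i: np.ndarray, x_j: np.ndarray, null_model: NullModel
) -> float:
    """Squared correlation of the projected burden scores."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    xi = null_model.project(x_i)
    xj = null_model.project(x_j)
    vi = float(xi @ xi)
    vj = float(xj @ xj)
    if vi <= 1e-12 * max(float(x_i @ x_i), 1.0) or vj <= 1e-12 * max(float(x_j @ x_j), 1.0):
        raise ValueError("constant projected burden score")
    return _clamp(float(xi @ xj) ** 2 / (vi * vj))


def burden_null_correlation(
    g: GenotypeMatrix,
    partition: MafPartition,
    window_i: Window,
    window_j: Window,
    null_model: NullModel,
) -> float:
    rare = g.dosages[:, partition.rare_idx]
    x_i = rare[:, window_i.start_rank : window_i.end_rank].sum(axis=1)
    x_j = rare[:, window_j.start_rank : window_j.end_rank].sum(axis=1)
    return burden_null_correlation_from_scores(x_i, x_j, null_model)


def build_correlation_band(
    g: GenotypeMatrix,
    partition: MafPartition,
    ws: WindowSet,
    kind: str,
    null_model: NullModel,
    weights: Optional[WeightScheme] = None,
    band: int = DEFAULT_BAND,
) -> CorrelationBand:
    """Pairwise null correlations for all window pairs within ``band`` offsets."""
    if band < 1:
        raise ValueError("band must be >= 1 (diagonal-only is meaningless)")
    if kind not in ("skat", "burden"):
        raise ValueError("kind must be 'skat' or 'burden'")
    n = len(ws)
    if band >= n:
        logger.warning("band %d exceeds window count %d; clipping", band, n)
        band = n - 1
    rare = g.dosages[:, partition.rare_idx]
    values = np.zeros((n, band + 1))
    values[:, 0] = 1.0

    if kind == "burden":
        scores = np.column_stack(
            [
                null_model.project(rare[:, w.start_rank : w.end_rank].sum(axis=1))
                for w in ws
            ]
        )
        norms = (scores**2).sum(axis=0)
        for d in range(1, band + 1):
            dots = (scores[:, : n - d] * scores[:, d:]).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = dots**2 / (norms[: n - d] * norms[d:])
            values[: n - d, d] = np.clip(np.nan_to_num(vals), 0.0, 1.0)
        return CorrelationBand(values=values, band=band, kind=kind,
                               maf_threshold=partition.threshold)

    if weights is None:
        raise ValueError("weights are required for SKAT correlations")
    w_all = weights.weights
    cache: OrderedDict[int, tuple[np.ndarray, float]] = OrderedDict()

    def factor(idx: int) -> tuple[np.ndarray, float]:
        if idx in cache:
            cache.move_to_end(idx)
            return cache[idx]
        win = ws[idx]
        sl = slice(win.start_rank, win.end_rank)
        b = _projected_weighted(
            rare[:, sl], WeightScheme("custom", w_all[sl]), null_model
        )
        t = float(np.sum((b.T @ b) ** 2))
        cache[idx] = (b, t)
        while len(cache) > band + 1:
            cache.popitem(last=False)
        return b, t

    for i in range(n):
        b_i, t_i = factor(i)
        for d in range(1, min(band, n - 1 - i) + 1):
            b_j, t_j = factor(i + d)
            if t_i <= 0 or t_j <= 0:
                values[i, d] = 0.0
                continue
            cross = float(np.sum((b_i.T @ b_j) ** 2))
            values[i, d] = min(max(cross / np.sqrt(t_i * t_j), 0.0), 1.0)
    return CorrelationBand(values=values, band=band, kind=kind,
                           maf_threshold=partition.threshold)
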