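"""Replicate x test tables of null P-values, and the vectorized batch runner."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from wgsig.association import (
    DEFAULT_RHO_GRID,
    WeightScheme,
    beta_weights,
    fit_null_model,
    quad_form_pvalue_info,
    skato_test,
    _MIN_P,
    _liu_pvalue_batch,
)
from wgsig.genotypes import GenotypeMatrix, MafPartition, WindowSet

_COL_CHUNK = 2048


@dataclass
class PValueStore:
    """Null P-values for every test (columns) and replicate (rows).

    ``kinds[t]`` is ``"window"`` or ``"single"``; ``positions[t]`` anchors the
    test on the chromosome so that contiguous sectioning respects genomic
    order.
    """

    pvalues: np.ndarray  # (R, T)
    kinds: np.ndarray  # (T,)
    test_ids: np.ndarray  # (T,)
    positions: np.ndarray  # (T,)
    test_kind: str = ""  # which window statistic produced the window columns

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.kinds = np.asarray(self.kinds)
        self.test_ids = np.asarray(self.test_ids)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        t = self.pvalues.shape[1]
        if not (self.kinds.size == self.test_ids.size == self.positions.size == t):
            raise ValueError("metadata length must match the test count")

    @property
    def n_replicates(self) -> int:
        return self.pvalues.shape[0]

    @property
    def n_tests(self) -> int:
        return self.pvalues.shape[1]

    def select(self, test_class: str) -> np.ndarray:
        """Column indices of a test class, in genomic order."""
        if test_class == "windows":
            mask = self.kinds == "window"
        elif test_class == "single":
            mask = self.kinds == "single"
        elif test_class == "combined":
            mask = np.ones(self.n_tests, dtype=bool)
        else:
            raise ValueError(f"unknown test class {test_class!r}")
        idx = np.flatnonzero(mask)
        return idx[np.argsort(self.positions[idx], kind="stable")]

    def to_tsv(self, path: str | Path) -> None:
        """Tall TSV: replicate, test_id, kind, position, p."""
        with open(path, "w") as fh:
            fh.write(f"#test_kind={self.test_kind}\n")
            fh.write("replicate\ttest_id\tkind\tposition\tp\n")
            for r in range(self.n_replicates):
                row = self.pvalues[r]
                for t in range(self.n_tests):
                    fh.write(
                        f"{r}\t{self.test_ids[t]}\t{self.kinds[t]}\t"
                        f"{self.positions[t]}\t{row[t]:.10g}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PValueStore":
        import pandas as pd

        with open(path) as fh:
            first = fh.readline().strip()
        test_kind = first.split("=", 1)[1] if first.startswith("#test_kind=") else ""
        df = pd.read_csv(path, sep="\t", comment="#")
        wide = df.pivot_table(
            index="replicate", columns="test_id", values="p", sort=False
        )
        meta = df.drop_duplicates("test_id").set_index("test_id")
        order = np.argsort(meta.loc[wide.columns, "position"].to_numpy(), kind="stable")
        cols = wide.columns.to_numpy()[order]
        return cls(
            pvalues=wide[cols].to_numpy(),
            kinds=meta.loc[cols, "kind"].to_numpy(),
            test_ids=cols,
            positions=meta.loc[cols, "position"].to_numpy(),
            test_kind=test_kind,
        )


# ---------------------------------------------------------------------------
# Vectorized batches
# ---------------------------------------------------------------------------


def _batch_f_pvalues(x_cols: np.ndarray, y_mat: np.ndarray) -> np.ndarray:
    """F(1, N-2) P-values of every predictor column against every y column.

    Intercept-only null.  Returns an (R, M) array.  Constant predictors give
    p = NaN (flagged, not silently 1).
    """
    n = y_mat.shape[0]
    e = y_mat - y_mat.mean(axis=0)
    rss0 = (e**2).sum(axis=0)  # (R,)
    out = np.empty((y_mat.shape[1], x_cols.shape[1]))
    for lo in range(0, x_cols.shape[1], _COL_CHUNK):
        hi = min(lo + _COL_CHUNK, x_cols.shape[1])
        xc = x_cols[:, lo:hi] - x_cols[:, lo:hi].mean(axis=0)
        xx = (xc**2).sum(axis=0)  # (m,)
        a = xc.T @ e  # (m, R)
        with np.errstate(divide="ignore", invalid="ignore"):
            num = a**2 / xx[:, None]
            denom = (rss0[None, :] - num) / (n - 2)
            f = num / denom
        p = stats.f.sf(f, 1, n - 2)
        p[np.isinf(f)] = _MIN_P
        p = np.clip(p, _MIN_P, 1.0)
        p[xx <= 0, :] = np.nan
        out[:, lo:hi] = p.T
    return out


def _burden_scores(g: GenotypeMatrix, partition: MafPartition, ws: WindowSet) -> np.ndarray:
    """Per-individual minor-allele counts for every window (N x W)."""
    rare = g.dosages[:, partition.rare_idx]
    csum = np.concatenate(
        [np.zeros((rare.shape[0], 1)), np.cumsum(rare, axis=1)], axis=1
    )
    starts = np.array([w.start_rank for w in ws])
    ends = np.array([w.end_rank for w in ws])
    return csum[:, ends] - csum[:, starts]


def run_batch(
    g: GenotypeMatrix,
    partition: MafPartition,
    ws: WindowSet,
    pheno_values: np.ndarray,
    test: str = "burden",
    weights: Optional[WeightScheme] = None,
    include_single: bool = True,
    skat_pvalue_method: str = "hybrid",
    rho_grid=DEFAULT_RHO_GRID,
) -> PValueStore:
    """Run one window statistic over all windows (plus single-marker tests of
    common variants) for every null replicate, returning a :class:`PValueStore`.

    ``skat_pvalue_method`` selects the batch SKAT tail evaluation: ``liu`` is
    vectorized and fast, ``hybrid`` (default) refines P-values below 0.05 by
    characteristic-function inversion, ``auto`` inverts for every statistic
    (slow at scale, exact-style).
    """
    y_mat = np.asarray(pheno_values, dtype=float)
    if y_mat.ndim == 1:
        y_mat = y_mat[:, None]
    n, n_rep = y_mat.shape
    if n != g.n_individuals:
        raise ValueError("phenotype rows must match individuals")

    rare_pos = g.positions[partition.rare_idx]
    win_pos = np.array([rare_pos[w.start_rank] for w in ws])

    if test == "burden":
        x = _burden_scores(g, partition, ws)
        p_win = _batch_f_pvalues(x, y_mat)
    elif test == "single":
        raise ValueError("'single' is not a window statistic; use include_single")
    elif test in ("skat", "skato"):
        if weights is None:
            weights = beta_weights(g.maf[partition.rare_idx])
        p_win = _batch_quadform(
            g, partition, ws, y_mat, weights, test, skat_pvalue_method, rho_grid
        )
    else:
        raise ValueError(f"unknown test {test!r}")

    blocks = [p_win]
    kinds = [np.full(len(ws), "window")]
    ids = [np.array([f"win{i:06d}" for i in range(len(ws))])]
    pos = [win_pos]
    if include_single and partition.n_common:
        p_single = _batch_f_pvalues(g.dosages[:, partition.common_idx], y_mat)
        blocks.append(p_single)
        kinds.append(np.full(partition.n_common, "single"))
        ids.append(np.array([f"snp{j:07d}" for j in partition.common_idx]))
        pos.append(g.positions[partition.common_idx])

    pvalues = np.concatenate(blocks, axis=1)
    store = PValueStore(
        pvalues=pvalues,
        kinds=np.concatenate(kinds),
        test_ids=np.concatenate(ids),
        positions=np.concatenate(pos),
        test_kind=test,
    )
    order = store.select("combined")
    return PValueStore(
        pvalues=store.pvalues[:, order],
        kinds=store.kinds[order],
        test_ids=store.test_ids[order],
        positions=store.positions[order],
        test_kind=test,
    )


def _batch_quadform(
    g: GenotypeMatrix,
    partition: MafPartition,
    ws: WindowSet,
    y_mat: np.ndarray,
    weights: WeightScheme,
    test: str,
    pvalue_method: str,
    rho_grid,
) -> np.ndarray:
    n, n_rep = y_mat.shape
    e = y_mat - y_mat.mean(axis=0)
    sigma2 = (e**2).sum(axis=0) / (n - 1)  # (R,)
    rare = g.dosages[:, partition.rare_idx]
    w_all = weights.weights
    if w_all.size != partition.n_rare:
        raise ValueError("weights must cover all rare variants")
    out = np.empty((n_rep, len(ws)))
    for i, w in enumerate(ws):
        sl = slice(w.start_rank, w.end_rank)
        gw = rare[:, sl]
        b = (gw - gw.mean(axis=0)) * w_all[sl]
        if test == "skat":
            scores = b.T @ e  # (k, R)
            q = (scores**2).sum(axis=0)
            lam = np.linalg.eigvalsh(b.T @ b)
            lam = lam[lam > 1e-10 * lam.max(initial=0.0)]
            if lam.size == 0:
                out[:, i] = np.nan
                continue
            q_std = q / sigma2
            if pvalue_method == "liu":
                out[:, i] = _liu_pvalue_batch(lam, q_std)
            elif pvalue_method == "hybrid":
                # moment matching everywhere, CF inversion where the tail
                # matters (small P-values drive the section minima)
                p = _liu_pvalue_batch(lam, q_std)
                refine = np.flatnonzero(p < 0.05)
                for r in refine:
                    p[r] = quad_form_pvalue_info(lam, q_std[r])[0]
                out[:, i] = p
            else:
                out[:, i] = [
                    quad_form_pvalue_info(lam, q_std[r])[0] for r in range(n_rep)
                ]
        else:  # skato: per-replicate min-P combination
            for r in range(n_rep):
                nm = fit_null_model(y_mat[:, r])
                res = skato_test(gw, y_mat[:, r], WeightScheme("custom", w_all[sl]), nm, rho_grid)
                out[r, i] = res.p_value
    return np.clip(out, _MIN_P, 1.0)
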