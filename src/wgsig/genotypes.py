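"""Genotype matrices, MAF partitions and overlapping rare-variant windows."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

DEFAULT_WINDOW_SIZE = 50
DEFAULT_STEP = 25


class EmptyRegionError(ValueError):
    """Raised when a VCF region query yields no usable variants."""


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with per-variant metadata.

    ``dosages`` is an ``(N, M)`` array of minor-allele counts in ``{0, 1, 2}``
    (missing genotypes are mean-imputed, so entries may be fractional).
    ``positions`` are 1-based base-pair coordinates, strictly increasing
    within the contig.  ``maf[j] = min(p, 1 - p)`` with
    ``p = sum(dosages[:, j]) / (2 N)``.
    """

    dosages: np.ndarray
    positions: np.ndarray
    maf: np.ndarray
    sample_ids: list[str]
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x variants array")
        n, m = self.dosages.shape
        if self.positions.shape != (m,) or self.maf.shape != (m,):
            raise ValueError("positions/maf length must match the variant count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match the individual count")
        if m > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any((self.maf < 0) | (self.maf > 0.5)):
            raise ValueError("maf values must lie in [0, 0.5]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class MafPartition:
    """Indices of rare (``maf < threshold``) and common variants."""

    threshold: float
    rare_idx: np.ndarray
    common_idx: np.ndarray

    def __post_init__(self) -> None:
        self.rare_idx = np.asarray(self.rare_idx, dtype=np.int64)
        self.common_idx = np.asarray(self.common_idx, dtype=np.int64)

    @property
    def n_rare(self) -> int:
        return self.rare_idx.size

    @property
    def n_common(self) -> int:
        return self.common_idx.size


@dataclass
class Window:
    """Half-open rank interval ``[start_rank, end_rank)`` into the rare set.

    ``span_bp`` (1-based inclusive) is attached once genomic positions are
    known; it is ``None`` for windows built from a bare count.
    """

    start_rank: int
    end_rank: int
    span_bp: Optional[tuple[int, int]] = None

    @property
    def n_variants(self) -> int:
        return self.end_rank - self.start_rank


@dataclass
class WindowSet:
    """Ordered half-overlapping windows over the rare-variant ranks."""

    windows: list[Window]
    window_size: int = DEFAULT_WINDOW_SIZE
    step: int = DEFAULT_STEP

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i: int) -> Window:
        return self.windows[i]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def attach_spans(self, rare_positions: Sequence[int]) -> None:
        """Fill ``span_bp`` from the positions of the rare variants (rank order)."""
        pos = np.asarray(rare_positions)
        for w in self.windows:
            w.span_bp = (int(pos[w.start_rank]), int(pos[w.end_rank - 1]))


def split_by_maf(g: GenotypeMatrix, threshold: float) -> MafPartition:
    """Partition variants into rare (``maf < threshold``, strict) and common."""
    if not 0 < threshold <= 0.5:
        raise ValueError(f"MAF threshold must lie in (0, 0.5], got {threshold}")
    rare = np.flatnonzero(g.maf < threshold)
    common = np.flatnonzero(g.maf >= threshold)
    return MafPartition(threshold=threshold, rare_idx=rare, common_idx=common)


def build_windows(
    n_rare: int,
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
) -> WindowSet:
    """Tile ``n_rare`` rank-ordered rare variants with half-overlapping windows.

    Windows start at ranks ``0, step, 2*step, ...`` and contain up to
    ``window_size`` variants; the terminal partial window (ending at
    ``n_rare``) is retained.  For ``n_rare > window_size`` this yields exactly
    ``ceil(n_rare / step) - 1`` windows, otherwise a single window.
    """
    if n_rare < 1:
        raise ValueError("n_rare must be positive")
    if window_size < 1 or step < 1 or step > window_size:
        raise ValueError("require 0 < step <= window_size")
    if n_rare <= window_size:
        windows = [Window(0, n_rare)]
    else:
        # equals ceil(n_rare / step) - 1 for the default half-overlap tiling
        # (window_size = 2 * step) while guaranteeing coverage for any step
        count = math.ceil((n_rare - window_size) / step) + 1
        windows = [
            Window(k * step, min(k * step + window_size, n_rare))
            for k in range(count)
        ]
    return WindowSet(windows=windows, window_size=window_size, step=step)


def _minor_allele_flip(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip columns whose alternate allele is the major one; return (dosages, maf)."""
    p = dosages.mean(axis=0) / 2.0
    flip = p > 0.5
    if np.any(flip):
        dosages = dosages.copy()
        dosages[:, flip] = 2.0 - dosages[:, flip]
    maf = np.minimum(p, 1.0 - p)
    return dosages, maf


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, 2**62
    start, _, end = span.partition("-")
    return chrom, int(start), int(end) if end else 2**62


def read_genotypes(vcf_path: str | Path, region: Optional[str] = None) -> GenotypeMatrix:
    """Load diploid genotypes from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into one bi-allelic dosage column per
    alternate allele.  Missing genotypes are imputed to the variant mean
    dosage; sites where no minor allele is observed are excluded.  Dosages
    are re-coded to count the *minor* allele, so MAF never exceeds 0.5.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    if n == 0:
        raise ValueError(f"no samples in VCF {vcf_path}")

    want: Optional[tuple[str, int, int]] = _parse_region(region) if region else None

    columns: list[np.ndarray] = []
    positions: list[int] = []
    chrom_seen: Optional[str] = None
    for variant in vcf:
        if want is not None:
            c, s, e = want
            if variant.CHROM != c or not (s <= variant.POS <= e):
                continue
        if chrom_seen is None:
            chrom_seen = variant.CHROM
        elif variant.CHROM != chrom_seen:
            raise ValueError(
                "multiple contigs in one read; process one contig at a time "
                "or pass a region"
            )
        gts = np.asarray(variant.genotypes, dtype=np.int16)
        if gts.shape[1] > 3:
            raise ValueError(f"non-diploid genotype at {variant.CHROM}:{variant.POS}")
        alleles = gts[:, :2]
        n_alt = len(variant.ALT)
        for alt_i in range(1, n_alt + 1):
            missing = np.any(alleles < 0, axis=1)
            dose = (alleles == alt_i).sum(axis=1).astype(float)
            if missing.all():
                continue
            if missing.any():
                dose[missing] = dose[~missing].mean()
            if np.ptp(dose) == 0 and (dose[0] == 0 or dose[0] == 2):
                continue  # monomorphic: no minor allele observed
            columns.append(dose)
            positions.append(variant.POS)
    vcf.close()

    if not columns:
        raise EmptyRegionError(
            f"no polymorphic variants found in {vcf_path}"
            + (f" region {region}" if region else "")
        )

    dosages = np.column_stack(columns)
    pos = np.asarray(positions, dtype=np.int64)
    # Split multi-allelics may share a position; nudge duplicates so the
    # strictly-increasing invariant holds while preserving order.
    if pos.size > 1 and np.any(np.diff(pos) <= 0):
        for j in range(1, pos.size):
            if pos[j] <= pos[j - 1]:
                pos[j] = pos[j - 1] + 1
    dosages, maf = _minor_allele_flip(dosages)
    return GenotypeMatrix(
        dosages=dosages,
        positions=pos,
        maf=maf,
        sample_ids=sample_ids,
        chrom=chrom_seen or "1",
    )


def read_phenotypes(path: str | Path, sample_ids: Sequence[str]) -> np.ndarray:
    """Read a ``sample_id<TAB>phenotype`` TSV, ordered to match ``sample_ids``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "phenotype" not in df.columns:
        raise ValueError("phenotype TSV must have columns sample_id, phenotype")
    lookup = dict(zip(df["sample_id"], df["phenotype"]))
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"phenotypes missing for samples: {missing[:5]}")
    return np.asarray([lookup[s] for s in sample_ids], dtype=float)


def write_window_table(
    path: str | Path,
    ws: WindowSet,
    chrom: str,
) -> None:
    """Write windows as a BED-like TSV (chrom, start0, end, id, n_variants, start_rank)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart0\tend\twindow_id\tn_variants\tstart_rank\n")
        for i, w in enumerate(ws):
            if w.span_bp is None:
                start0, end = -1, -1
            else:
                start0, end = w.span_bp[0] - 1, w.span_bp[1]
            fh.write(f"{chrom}\t{start0}\t{end}\twin{i:06d}\t{w.n_variants}\t{w.start_rank}\n")
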