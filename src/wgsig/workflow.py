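"""Orchestration of the two studies: correlation-based and simulation-based."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from wgsig import __version__
from wgsig.association import beta_weights, flat_weights
from wgsig.correlation import build_correlation_band
from wgsig.effective import correlation_study_table, write_study_table
from wgsig.genotypes import GenotypeMatrix, build_windows, read_genotypes, split_by_maf
from wgsig.store import run_batch
from wgsig.synthetic import CohortSpec, simulate_cohort, simulate_null_phenotypes
from wgsig.threshold import (
    DEFAULT_GENOME_LENGTH,
    DEFAULT_REGION_LENGTH,
    ThresholdPrediction,
    threshold_pipeline,
)
from wgsig.association import fit_null_model

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable description of one run; seed + config reproduce outputs."""

    vcf: Optional[str] = None
    pheno: Optional[str] = None
    synthetic: Optional[dict] = None  # CohortSpec fields
    maf_threshold: float = 0.01
    test: str = "burden"
    weights: str = "beta_1_25"
    replicates: int = 1000
    sections: int = 1024
    band: int = 1000
    genome_length: float = DEFAULT_GENOME_LENGTH
    region_length: float = DEFAULT_REGION_LENGTH
    window_size: int = 50
    step: int = 25
    seed: int = 1
    out_dir: str = "wgsig_out"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _load_inputs(cfg: RunConfig) -> GenotypeMatrix:
    if cfg.synthetic is not None:
        spec = CohortSpec(**{**cfg.synthetic, "seed": cfg.synthetic.get("seed", cfg.seed)})
        return simulate_cohort(spec)
    if cfg.vcf is None:
        raise ValueError("config needs either a vcf path or a synthetic block")
    return read_genotypes(cfg.vcf)


def _weights_for(cfg: RunConfig, maf: np.ndarray):
    if cfg.weights == "flat":
        return flat_weights(maf.size)
    return beta_weights(maf)


def run_correlation_study(cfg: RunConfig) -> list[dict]:
    """Correlation-based thresholds by region size (table behind the
    estimator-comparison figure)."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = _load_inputs(cfg)
    part = split_by_maf(g, cfg.maf_threshold)
    ws = build_windows(part.n_rare, cfg.window_size, cfg.step)
    # the analytic correlations use only the null projection, not y itself
    rng = np.random.default_rng(cfg.seed)
    nm = fit_null_model(rng.standard_normal(g.n_individuals))
    kind = "burden" if cfg.test == "burden" else "skat"
    band = min(cfg.band, max(len(ws) - 1, 1))
    weights = _weights_for(cfg, g.maf[part.rare_idx]) if kind == "skat" else None
    corr = build_correlation_band(g, part, ws, kind, nm, weights=weights, band=band)
    sizes = []
    s = 25
    while s <= len(ws):
        sizes.append(s)
        s *= 2
    if not sizes:
        sizes = [len(ws)]
    rows = correlation_study_table(corr, sizes)
    path = out / f"correlation_study_{cfg.config_hash()}.tsv"
    write_study_table(rows, path)
    corr.to_tsv(out / f"correlation_band_{cfg.config_hash()}.tsv")
    _write_log(cfg, out, "correlation_study", time.time() - t0)
    return rows


def run_simulation_study(cfg: RunConfig, test_class: str = "windows") -> ThresholdPrediction:
    """Full simulate -> test -> section -> percentile -> regress -> extrapolate."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = _load_inputs(cfg)
    part = split_by_maf(g, cfg.maf_threshold)
    ws = build_windows(part.n_rare, cfg.window_size, cfg.step)
    phenos = simulate_null_phenotypes(g.n_individuals, cfg.replicates, cfg.seed)
    weights = _weights_for(cfg, g.maf[part.rare_idx])
    store = run_batch(
        g, part, ws, phenos.values, test=cfg.test, weights=weights,
        include_single=(test_class != "windows"),
    )
    m = store.select(test_class).size
    series = []
    s = cfg.sections
    while s >= 1:
        if s <= m and (m / s >= 8 or s <= 4):
            series.append(s)
        s //= 2
    if 1 not in series:
        series.append(1)
    pred = threshold_pipeline(
        store,
        test_class=test_class,
        section_series=series,
        length_ratio=cfg.genome_length / cfg.region_length,
    )
    report = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "seed": cfg.seed,
        "test": cfg.test,
        "test_class": test_class,
        "maf_threshold": cfg.maf_threshold,
        "n_windows": len(ws),
        "n_tests": m,
        **pred.to_dict(),
    }
    with open(out / f"threshold_{cfg.config_hash()}.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(out / f"points_{cfg.config_hash()}.tsv", "w") as fh:
        fh.write("x\ty\tsd\tn_sections\tsection_size\n")
        for p in pred.points:
            fh.write(
                f"{p.x:.6g}\t{p.y:.6g}\t{p.sd:.6g}\t"
                f"{p.n_sections_averaged}\t{p.section_size:.6g}\n"
            )
    _write_log(cfg, out, "simulation_study", time.time() - t0)
    return pred


def _write_log(cfg: RunConfig, out: Path, stage: str, elapsed: float) -> None:
    entry = {
        "stage": stage,
        "elapsed_s": round(elapsed, 3),
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
    }
    with open(out / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")
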