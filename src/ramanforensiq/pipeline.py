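"""End-to-end orchestration: generate -> preprocess -> signatures ->
classifiers -> validation -> robustness, with machine-readable reports.

A run is fully described by an :class:`ExperimentConfig`; the same config
and seed always produce byte-identical reports (timings go to the logger,
never into the report).  Every report carries the config hash and seed so
any number in it can be traced back to the run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import signature as sig_mod
from .chemometrics import CvScheme
from .discriminators import (
    classification_metrics,
    classify_unknowns,
    lda_predict,
    lda_train,
    plsda_evaluate,
    plsda_predict,
    plsda_train,
    simca_classify,
    simca_train,
    _fit_compressor,
)
from .spectral_core import (
    FLUIDS,
    SpectralDataset,
    average_per_sample,
    despike,
    normalize_dataset,
)
from .synthetic import SimulationConfig, inject_corruption, simulate_dataset

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "robustness_study",
    "preprocess",
]

log = logging.getLogger("ramanforensiq")


@dataclass
class ExperimentConfig:
    """Everything an end-to-end run needs, with sane defaults."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    do_despike: bool = False          # generator injects no cosmic rays
    normalize_mode: str = "vector"
    signature_ranks: dict = field(
        default_factory=lambda: dict(sig_mod.DEFAULT_RANKS)
    )
    simca_a: int = 3
    simca_alpha: float = 0.95
    lda_compression: str = "pca"
    lda_a: int | None = None          # None: 99 % variance, capped at 20
    plsda_a: int | None = None        # None: CV-selected
    plsda_max_a: int = 10
    cv_method: str = "venetian_blind"
    cv_folds: int = 10
    robustness_noise: tuple = (0.0, 0.05, 0.2, 0.5)
    robustness_background: tuple = (0.0, 1.0)
    n_blind_donors: int = 4
    n_blind_spectra: int = 25
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sim = d["simulation"]
        if isinstance(sim["spots_per_sample"], tuple):
            sim["spots_per_sample"] = list(sim["spots_per_sample"])
        d["robustness_noise"] = list(self.robustness_noise)
        d["robustness_background"] = list(self.robustness_background)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        if isinstance(sim_raw.get("spots_per_sample"), list):
            sim_raw["spots_per_sample"] = tuple(sim_raw["spots_per_sample"])
        cfg = cls(simulation=SimulationConfig(**sim_raw))
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, tuple(val) if isinstance(val, list) else val)
        return cfg


def preprocess(d: SpectralDataset, cfg: ExperimentConfig) -> SpectralDataset:
    """Despike (optional) and normalize every spectrum."""
    if cfg.do_despike:
        d = d.map_rows(lambda s: despike(s))
    return normalize_dataset(d, cfg.normalize_mode)


def _timed(stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception:
        log.exception("stage %s failed", stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from None
    log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    return out


def _signature_stage(d: SpectralDataset, cfg: ExperimentConfig) -> dict:
    """Per-fluid ALS signatures and self-fit quality summaries."""
    out = {}
    for fluid in d.classes:
        sub = d.select(fluid)
        k = cfg.signature_ranks.get(fluid, 3)
        als = sig_mod.als_decompose(sub, k)
        signature = sig_mod.build_signature(fluid, als, d.wavenumbers)
        _, quals = sig_mod.fit_dataset(sub, signature)
        out[fluid] = {
            "signature": signature,
            "k": k,
            "converged": bool(als.converged),
            "mean_sse": float(np.mean([q.sse for q in quals])),
            "mean_r_square": float(np.mean([q.r_square for q in quals])),
            "mean_rmse": float(np.mean([q.rmse for q in quals])),
        }
    return out


def _simca_stage(d: SpectralDataset, cfg: ExperimentConfig) -> dict:
    """SIMCA on spot-level spectra vs on per-sample averages."""
    model_spot = simca_train(d, cfg.simca_a, cfg.simca_alpha)
    _, m_spot = simca_classify(model_spot, d)
    averaged = average_per_sample(d)
    model_avg = simca_train(averaged, cfg.simca_a, cfg.simca_alpha)
    _, m_avg = simca_classify(model_avg, averaged)
    return {
        "spot_level": m_spot.to_dict(),
        "sample_averaged": m_avg.to_dict(),
    }


def _blind_test_stage(d: SpectralDataset, cfg: ExperimentConfig) -> dict:
    """Donor-held-out blind test: unknowns never share a donor with training.

    Holds out ``n_blind_donors`` donors spanning the fluids, takes
    ``n_blind_spectra`` of their spot spectra as unknowns, trains SIMCA,
    LDA and PLS-DA on everything else and reports the consensus votes.
    """
    rng = np.random.default_rng(cfg.simulation.seed + 1)
    held: list[tuple[str, str]] = []
    fluids = [f for f in FLUIDS if f in d.classes]
    f_idx = 0
    while len(held) < cfg.n_blind_donors:
        fluid = fluids[f_idx % len(fluids)]
        donors = sorted(set(d.donors[d.labels == fluid]))
        pick = donors[len(held) % len(donors)]
        if (fluid, pick) not in held:
            held.append((fluid, pick))
        f_idx += 1
    mask_held = np.zeros(d.n_spectra, dtype=bool)
    for fluid, donor in held:
        mask_held |= (d.labels == fluid) & (d.donors == donor)
    held_idx = np.flatnonzero(mask_held)
    if held_idx.size > cfg.n_blind_spectra:
        held_idx = rng.choice(held_idx, cfg.n_blind_spectra, replace=False)
        held_idx.sort()
    train = d.subset(np.flatnonzero(~mask_held))
    unknowns = d.subset(held_idx)
    truth = list(unknowns.labels)

    simca = simca_train(train, cfg.simca_a, cfg.simca_alpha)
    transform = _fit_compressor(
        train.matrix, train.labels, tuple(train.classes),
        cfg.lda_compression, cfg.lda_a,
    )
    lda = lda_train(transform(train.matrix), train.labels, tuple(train.classes))
    plsda = plsda_train(train, a=cfg.plsda_a, max_a=cfg.plsda_max_a)
    records = classify_unknowns(
        {"simca": simca, "lda": (lda, transform), "plsda": plsda}, unknowns
    )
    consensus = [r["consensus"] for r in records]
    lda_votes = [r["votes"]["lda"] for r in records]
    return {
        "held_out_donors": [list(h) for h in held],
        "n_unknowns": len(truth),
        "consensus_accuracy": float(
            np.mean([c == t for c, t in zip(consensus, truth)])
        ),
        "lda_accuracy": float(
            np.mean([v == t for v, t in zip(lda_votes, truth)])
        ),
        "n_ambiguous": int(sum(c == "ambiguous" for c in consensus)),
    }


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the full pipeline; returns the (JSON-serializable) report."""
    from . import __version__
    from .discriminators import lda_loo

    raw = _timed("generate", simulate_dataset, cfg.simulation)
    data = _timed("preprocess", preprocess, raw, cfg)
    signatures = _timed("signatures", _signature_stage, data, cfg)
    simca_report = _timed("simca", _simca_stage, data, cfg)

    def _lda():
        _, metrics = lda_loo(data, cfg.lda_compression, cfg.lda_a)
        return metrics

    lda_metrics = _timed("lda_loo", _lda)

    def _plsda():
        model = plsda_train(
            data, a=cfg.plsda_a,
            scheme=CvScheme(cfg.cv_method, cfg.cv_folds),
            max_a=cfg.plsda_max_a,
        )
        cal, cv = plsda_evaluate(
            model, data, CvScheme(cfg.cv_method, cfg.cv_folds)
        )
        return model, cal, cv

    plsda_model, plsda_cal, plsda_cv = _timed("plsda", _plsda)
    blind = _timed("blind_test", _blind_test_stage, data, cfg)

    report = {
        "provenance": {
            "seed": cfg.simulation.seed,
            "config_hash": cfg.config_hash(),
            "version": __version__,
            "n_spectra": data.n_spectra,
        },
        "signature_fit": {
            f: {k: v for k, v in info.items() if k != "signature"}
            for f, info in signatures.items()
        },
        "simca": simca_report,
        "lda_loo": lda_metrics.to_dict(),
        "plsda": {
            "n_latent_variables": plsda_model.a,
            "calibration": plsda_cal.to_dict(),
            "cross_validation": plsda_cv.to_dict(),
        },
        "blind_test": blind,
    }
    if cfg.out_dir:
        _write_report(report, cfg)
    return report


def _write_report(report: dict, cfg: ExperimentConfig) -> str:
    os.makedirs(cfg.out_dir, exist_ok=True)
    path = os.path.join(cfg.out_dir, f"report_{cfg.config_hash()}.json")
    blob = json.dumps(report, indent=2, sort_keys=True)
    if os.path.exists(path):
        with open(path, "r", encoding="utf-8") as fh:
            if fh.read() != blob:
                raise FileExistsError(
                    f"{path} exists with different content; refusing to overwrite"
                )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(blob)
    return path


# ---------------------------------------------------------------------------
# Robustness study
# ---------------------------------------------------------------------------

def _split_by_donor(d: SpectralDataset, eval_fraction: float = 1 / 3):
    """Deterministic donor-level split: every third donor of each fluid
    goes to the evaluation set (no donor straddles the split)."""
    eval_mask = np.zeros(d.n_spectra, dtype=bool)
    step = max(int(round(1 / eval_fraction)), 2)
    for fluid in d.classes:
        donors = sorted(set(d.donors[d.labels == fluid]))
        for j, donor in enumerate(donors):
            if j % step == 0:
                eval_mask |= (d.labels == fluid) & (d.donors == donor)
    return (
        d.subset(np.flatnonzero(~eval_mask)),
        d.subset(np.flatnonzero(eval_mask)),
    )


def robustness_study(
    cfg: ExperimentConfig,
    grid: Sequence[tuple[float, float]] | None = None,
    data: SpectralDataset | None = None,
) -> list[dict]:
    """Accuracy of every engine on corrupted copies of an evaluation split.

    Engines are trained once on the clean training split; at each
    (noise_factor, background_factor) grid point a fresh corrupted copy of
    the evaluation split is re-normalized and classified.  Returns one
    record per grid point with per-engine and consensus accuracies.
    """
    if grid is None:
        grid = [
            (nf, bf)
            for nf in cfg.robustness_noise
            for bf in cfg.robustness_background
        ]
    if not grid:
        raise ValueError("robustness grid must be non-empty")
    if data is None:
        data = preprocess(simulate_dataset(cfg.simulation), cfg)
    train, holdout = _split_by_donor(data)
    classes = tuple(train.classes)
    simca = simca_train(train, cfg.simca_a, cfg.simca_alpha)
    transform = _fit_compressor(
        train.matrix, train.labels, classes, cfg.lda_compression, cfg.lda_a
    )
    lda = lda_train(transform(train.matrix), train.labels, classes)
    plsda = plsda_train(train, a=cfg.plsda_a, max_a=cfg.plsda_max_a)

    results = []
    for gi, (nf, bf) in enumerate(grid):
        corrupted = inject_corruption(
            holdout, nf, bf, seed=cfg.simulation.seed + 1000 + gi
        )
        corrupted = normalize_dataset(corrupted, cfg.normalize_mode)
        truth = list(corrupted.labels)
        _, simca_metrics = simca_classify(simca, corrupted)
        lda_pred = lda_predict(lda, transform(corrupted.matrix))
        plsda_pred = plsda_predict(plsda, corrupted.matrix)[0]
        records = classify_unknowns(
            {"simca": simca, "lda": (lda, transform), "plsda": plsda},
            corrupted,
        )
        consensus = [r["consensus"] for r in records]
        acc = {
            "simca": simca_metrics.accuracy,
            "lda": classification_metrics(truth, lda_pred, classes).accuracy,
            "plsda": classification_metrics(truth, plsda_pred, classes).accuracy,
        }
        acc["consensus"] = float(
            np.mean([c == t for c, t in zip(consensus, truth)])
        )
        results.append(
            {"noise_factor": nf, "background_factor": bf, "accuracy": acc}
        )
    return results


def robustness_to_csv(results: list[dict], path: str) -> None:
    """Write a robustness surface as a flat CSV."""
    engines = sorted(results[0]["accuracy"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("noise_factor,background_factor," + ",".join(engines) + "\n")
        for rec in results:
            vals = ",".join(f"{rec['accuracy'][e]:.6f}" for e in engines)
            fh.write(f"{rec['noise_factor']},{rec['background_factor']},{vals}\n")
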