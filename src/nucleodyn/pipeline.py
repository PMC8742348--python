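"""End-to-end orchestration: simulate/load → correlate → fit → compare.

Two pipelines mirror the two experimental read-outs:

* FCS: one correlation curve per cell (one measurement per cell), fitted
  with the diffusion + two-binding-population model; per-cell parameters
  are pooled per condition (mean ± bootstrap SE) and each treatment is
  compared against the control condition.
* Morphometry: denoise → segment → measure per stack; per-nucleus volume
  and sphericity pooled per condition (median ± bootstrap SE), median
  tests versus control, and the cube-root radius increment per treated
  condition.

Every stochastic stage derives its seed deterministically from the master
seed, the stage name and the item index, so reruns with the same config
and seed are bit-identical regardless of execution order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .correlator import autocorrelate
from .fcs_fit import AcfModelFitter, evaluate_acf_model
from .stats import median_test, radius_increment, summarize_groups
from .synthetic import (
    NucleusShapeSpec,
    TraceSimConfig,
    generate_acf_curves,
    generate_nucleus_image,
    simulate_trace,
)
from .types import CorrelationCurve, FcsParams

logger = logging.getLogger("nucleodyn")

__all__ = ["RunConfig", "stage_seed", "run_fcs_pipeline", "run_morphometry_pipeline"]

FCS_METRICS = ("f_diff", "f_short", "f_long", "tau_short", "tau_long")
MORPHO_METRICS = ("volume_um3", "sphericity")


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed from (master seed, stage name, index)."""
    digest = hashlib.blake2b(
        f"{master_seed}/{stage}/{index}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "little") % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``conditions`` maps a condition label to its generator spec:

    * FCS mode — either model parameters (FcsParams field names) for
      fast ACF-curve cells, or ``{"trace": {...TraceSimConfig fields}}``
      for full Monte-Carlo traces.
    * morphometry mode — NucleusShapeSpec field names.

    ``control`` names the reference condition; all comparisons are
    treatment versus control.
    """

    mode: str  # "fcs" | "morphometry"
    conditions: Dict[str, dict]
    control: str
    n_per_condition: int = 12
    seed: int = 0
    alpha: Optional[float] = None  # defaults: 0.01 for FCS, 0.05 for morphometry
    n_boot: int = 1000
    omega: float = 5.0
    lag_grid: Tuple[float, float, int] = (1e-5, 10.0, 160)  # log-spaced
    noise_fraction: float = 0.05  # ACF noise SD as a fraction of amplitude
    fit_components: Tuple[str, ...] = ("diffusion", "short", "long")
    segmentation: dict = field(default_factory=dict)
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("fcs", "morphometry"):
            raise ValueError("mode must be 'fcs' or 'morphometry'")
        if self.control not in self.conditions:
            raise ValueError("control condition missing from conditions")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "outdir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.blake2b(payload.encode(), digest_size=8).hexdigest()


def _curve_for_cell(config: RunConfig, label: str, spec: dict, index: int):
    """One correlation curve for one synthetic cell."""
    seed = stage_seed(config.seed, f"fcs/{label}", index)
    if "trace" in spec:
        tcfg = TraceSimConfig(**{**spec["trace"], "seed": seed})
        trace, _truth = simulate_trace(tcfg)
        curve = autocorrelate(trace, scheme="multi_tau")
        # trim estimator-bias region at long lags
        keep = curve.lags <= trace.duration / 10
        return CorrelationCurve(lags=curve.lags[keep], g=curve.g[keep], condition=label)
    params = FcsParams(**{"omega": config.omega, **spec})
    lo, hi, n = config.lag_grid
    lags = np.geomspace(lo, hi, int(n))
    # heteroscedastic noise, proportional to the curve: matches the 1/SD
    # residual weighting of the fitter and real averaged-ACF dispersion
    noise_sd = config.noise_fraction * evaluate_acf_model(params, lags)
    return generate_acf_curves(params, lags, noise_sd, n_curves=1, seed=seed)[0]


def run_fcs_pipeline(config: RunConfig):
    """Per-cell fit table + treatment-vs-control comparisons.

    Returns ``(table, comparisons, skipped)``: the per-cell parameter
    DataFrame, the comparisons DataFrame (one row per condition ×
    metric), and a list of (condition, cell index, reason) for curves
    that could not be fitted (logged, never silently dropped).
    """
    if config.mode != "fcs":
        raise ValueError("config mode must be 'fcs'")
    rows, skipped = [], []
    for label, spec in config.conditions.items():
        logger.info("condition %s: fitting %d cells", label, config.n_per_condition)
        for i in range(config.n_per_condition):
            curve = _curve_for_cell(config, label, spec, i)
            fitter = AcfModelFitter(
                omega=config.omega, components=config.fit_components
            )
            try:
                fitter.fit(curve)
            except (ValueError, RuntimeError) as exc:
                logger.warning("condition %s cell %d unfittable: %s", label, i, exc)
                skipped.append((label, i, str(exc)))
                continue
            row = fitter.result().as_row()
            row.update(condition=label, cell_id=f"{label}-{i:03d}")
            rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError("no cell could be fitted")

    alpha = 0.01 if config.alpha is None else config.alpha
    comparisons = []
    for metric in FCS_METRICS:
        groups = {
            g.label: g
            for g in summarize_groups(
                table,
                metric,
                "condition",
                statistic="mean",
                n_boot=config.n_boot,
                seed=stage_seed(config.seed, f"boot/{metric}"),
            )
        }
        for label in config.conditions:
            if label == config.control:
                continue
            cmp_res = median_test(
                groups[label], groups[config.control], alpha=alpha, metric=metric
            )
            comparisons.append(cmp_res.as_row())
    comp_df = pd.DataFrame(comparisons)
    _write_outputs(config, {"fcs_parameters.csv": table, "comparisons.csv": comp_df})
    return table, comp_df, skipped


def run_morphometry_pipeline(config: RunConfig):
    """Per-nucleus table, comparisons and radius increments vs control.

    Returns ``(table, comparisons, increments)`` where ``increments``
    maps each treated condition to the percent radius change implied by
    its median-volume ratio to control. Border-flagged nuclei are
    excluded from statistics.
    """
    from .morphometry import NucleusSegmenter

    if config.mode != "morphometry":
        raise ValueError("config mode must be 'morphometry'")
    segmenter = NucleusSegmenter(**config.segmentation)
    rows = []
    for label, spec in config.conditions.items():
        logger.info("condition %s: measuring %d stacks", label, config.n_per_condition)
        for i in range(config.n_per_condition):
            seed = stage_seed(config.seed, f"morpho/{label}", i)
            item = dict(spec)
            # biological cell-to-cell size dispersion: per-nucleus lognormal
            # scale on the semi-axes (volume CV ~ 3x the radius CV)
            size_cv = item.pop("size_cv", 0.0)
            if size_cv:
                scale_rng = np.random.default_rng(
                    stage_seed(config.seed, f"morpho-size/{label}", i)
                )
                factor = float(np.exp(scale_rng.normal(0.0, size_cv)))
                item["semi_axes"] = tuple(s * factor for s in item["semi_axes"])
            shape = NucleusShapeSpec(**{**item, "seed": seed})
            image, _truth = generate_nucleus_image(shape)
            try:
                records = segmenter.measure(image, condition=label)
            except ValueError as exc:
                logger.warning("condition %s stack %d skipped: %s", label, i, exc)
                continue
            for rec in records:
                row = rec.as_row()
                row["stack_id"] = f"{label}-{i:03d}"
                rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError("no nucleus could be segmented")
    stats_table = table[~table["border_flag"]]

    alpha = 0.05 if config.alpha is None else config.alpha
    comparisons = []
    medians: Dict[str, Dict[str, float]] = {}
    for metric in MORPHO_METRICS:
        groups = {
            g.label: g
            for g in summarize_groups(
                stats_table,
                metric,
                "condition",
                statistic="median",
                n_boot=config.n_boot,
                seed=stage_seed(config.seed, f"boot/{metric}"),
            )
        }
        medians[metric] = {k: g.estimate for k, g in groups.items()}
        for label in config.conditions:
            if label == config.control:
                continue
            cmp_res = median_test(
                groups[label], groups[config.control], alpha=alpha, metric=metric
            )
            comparisons.append(cmp_res.as_row())
    comp_df = pd.DataFrame(comparisons)

    increments = {
        label: radius_increment(
            medians["volume_um3"][config.control], medians["volume_um3"][label]
        )
        for label in config.conditions
        if label != config.control
    }
    _write_outputs(
        config,
        {"morphometry.csv": table, "comparisons.csv": comp_df},
        extra_json={"radius_increment_pct": increments},
    )
    return table, comp_df, increments


def _write_outputs(config: RunConfig, tables: Dict[str, pd.DataFrame], extra_json=None):
    if config.outdir is None:
        return
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / name, index=False)
    info = {
        "mode": config.mode,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "control": config.control,
        "conditions": list(config.conditions),
    }
    if extra_json:
        info.update(extra_json)
    (outdir / "run_info.json").write_text(json.dumps(info, indent=1))
    logger.info("outputs written to %s", outdir)
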