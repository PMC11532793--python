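"""Evaluation metrics for the divided-count pipeline against simulation truth.

Power, observed FDR, type-I error and false-discovery curves, plus the
resample-budget sweep that traces statistical performance as a function of
the pooled residual degrees of freedom N(B-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dte import DTEResult, run_dte_pipeline
from .ecquant import InputError
from .simulate import SimConfig, SimTruth, simulate_experiment

__all__ = [
    "BenchmarkResult",
    "observed_power_fdr",
    "type1_error",
    "fd_curve",
    "resample_budget_sweep",
    "evaluate_replicates",
]

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkResult:
    """Summary metrics of one analysed simulation."""

    power: float
    observed_fdr: float
    type1: float | None
    n_called: int
    n_tested: int


def observed_power_fdr(
    result: DTEResult,
    is_de: np.ndarray,
    level: float = 0.05,
) -> tuple[float, float]:
    """Observed power and FDR of the calls at an FDR threshold.

    ``is_de`` must be aligned to the tested transcripts (apply the pipeline's
    keep-mask first). Power is the fraction of truly DE transcripts called;
    observed FDR is the fraction of calls that are truly non-DE (0 when
    nothing is called).
    """
    is_de = np.asarray(is_de, dtype=bool)
    if is_de.shape != result.p.shape:
        raise InputError("truth vector does not align with the tested transcripts")
    calls = result.fdr <= level
    n_calls = int(calls.sum())
    n_de = int(is_de.sum())
    power = float((calls & is_de).sum() / n_de) if n_de else 0.0
    fdr = float((calls & ~is_de).sum() / max(n_calls, 1))
    return power, fdr


def type1_error(result: DTEResult, level: float = 0.05) -> float:
    """Proportion of raw p-values below ``level`` (run on a null simulation)."""
    return float(np.mean(result.p < level))


def fd_curve(result: DTEResult, is_de: np.ndarray, max_rank: int | None = None) -> np.ndarray:
    """Cumulative false discoveries by p-value rank.

    Transcripts are sorted by p ascending, ties broken by |logFC| descending
    and then by index, so the curve is reproducible. Entry ``r`` (0-based
    ``r-1``) is the number of truly non-DE transcripts among the top ``r``.
    """
    is_de = np.asarray(is_de, dtype=bool)
    if is_de.shape != result.p.shape:
        raise InputError("truth vector does not align with the tested transcripts")
    m = result.p.size
    if max_rank is None:
        max_rank = m
    if max_rank > m:
        raise InputError("max_rank exceeds the number of tested transcripts")
    absfc = np.abs(np.where(np.isfinite(result.logFC), result.logFC, 0.0))
    order = np.lexsort((np.arange(m), -absfc, result.p))
    false = ~is_de[order[:max_rank]]
    return np.cumsum(false)


def evaluate_replicates(
    config: SimConfig,
    seeds: list[int] | np.ndarray,
    level: float = 0.05,
    route: str = "direct",
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Run simulate + pipeline over replicate seeds and collect the metrics."""
    rows = []
    for seed in seeds:
        exp = simulate_experiment(config, seed=int(seed), route=route)
        out = run_dte_pipeline(
            exp.counts, exp.resamples, exp.group, **pipeline_kwargs
        )
        keep = out["keep"]
        res = out["result"]
        is_de = exp.truth.is_de[keep]
        power, fdr = observed_power_fdr(res, is_de, level)
        rows.append(
            {
                "seed": int(seed),
                "n_tested": int(keep.sum()),
                "n_called": int((res.fdr <= level).sum()),
                "power": power,
                "observed_fdr": fdr,
                "type1": type1_error(res, level),
                "mean_tau": float(out["rta"].tau.mean()),
                "phi": out["phi"],
            }
        )
    return pd.DataFrame(rows)


def resample_budget_sweep(
    base_config: SimConfig,
    n_grid: list[int],
    B_grid: list[int],
    seeds: list[int],
    level: float = 0.05,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Power and observed FDR over a grid of samples per group and resamples.

    For every grid cell the full pipeline runs on matched seeds, so the
    simulated truth is identical across B values within a sample size. Cells
    with ``B = 1`` are skipped with a logged reason: the pooled residual
    degrees of freedom N(B-1) are zero and the RTA dispersion is inestimable.
    """
    if not n_grid or not B_grid:
        raise InputError("the (n, B) grid must be non-empty")
    rows = []
    for n in n_grid:
        for B in B_grid:
            if B < 2:
                logger.info(
                    "skipping n=%d B=%d: N(B-1)=0 leaves no residual df "
                    "for RTA-dispersion estimation",
                    n,
                    B,
                )
                continue
            config = replace(base_config, n_per_group=int(n), B=int(B))
            df = evaluate_replicates(config, seeds, level, **pipeline_kwargs)
            rows.append(
                {
                    "n_per_group": int(n),
                    "B": int(B),
                    "pooled_df": 2 * int(n) * (int(B) - 1),
                    "power": float(df["power"].mean()),
                    "observed_fdr": float(df["observed_fdr"].mean()),
                }
            )
    return pd.DataFrame(rows)
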