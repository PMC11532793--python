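"""Read-to-transcript-ambiguity (RTA) dispersion estimation and count scaling.

Technical resamples (bootstrap or Gibbs) of the same library measure how
precisely each transcript's count is quantified. Under quasi-Poisson
repeatability the variance of a resampled count equals ``tau_t`` times its
mean, with ``tau_t >= 1`` the RTA dispersion of transcript ``t``. This module
estimates ``tau`` by pooling the quasi-Poisson Pearson statistic over all
samples and resamples, divides it out of the counts, and reads/writes the
on-disk quantification layout (a ``quant.sf``-dialect table per sample plus a
gzipped resample matrix and a one-line JSON metadata file).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ecquant import InputError, ResampleArray, TranscriptCatalog

__all__ = [
    "RTAEstimate",
    "DividedCounts",
    "InsufficientReplicatesError",
    "estimate_rta_dispersion",
    "divide_counts",
    "residual_df",
    "write_quant_dir",
    "read_quant_dir",
    "read_kallisto_h5",
]

QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


class InsufficientReplicatesError(ValueError):
    """Fewer technical resamples than dispersion estimation requires."""


@dataclass(frozen=True)
class RTAEstimate:
    """Per-transcript RTA dispersion estimates.

    ``tau`` is the moderated, floored estimate (always >= 1); ``raw_stat`` is
    the pooled quasi-Poisson Pearson statistic per residual degree of freedom
    before moderation and flooring (NaN where no sample had a positive
    resample mean); ``pooled_df`` is the nominal pooled residual degrees of
    freedom N(B-1).
    """

    tau: np.ndarray
    pooled_df: int
    raw_stat: np.ndarray
    prior_df: float
    method: str = "unknown"


@dataclass(frozen=True)
class DividedCounts:
    """Counts scaled by the RTA dispersion: ``z_ti = y_ti / tau_t``."""

    z: np.ndarray
    source_tau: RTAEstimate


def residual_df(N: int, B: int) -> int:
    """Pooled residual degrees of freedom N(B-1) for RTA estimation.

    ``B = 1`` yields 0 and dispersion estimation must refuse such input.
    """
    if N < 1 or B < 1:
        raise InputError("N and B must both be >= 1")
    return N * (B - 1)


def estimate_rta_dispersion(
    resamples: ResampleArray | np.ndarray,
    prior_df: float = 3.0,
) -> RTAEstimate:
    """Estimate per-transcript RTA dispersions from technical resamples.

    For transcript ``t``, the quasi-Poisson Pearson statistic
    ``sum_i sum_b (y_tib - ybar_ti)^2 / ybar_ti`` is pooled over all samples
    ``i`` and resamples ``b`` and divided by the pooled residual degrees of
    freedom ``N(B-1)``. A (transcript, sample) cell whose resample mean is
    zero contributes nothing to either the numerator or the degrees of
    freedom. The raw statistic is then moderated toward 1 with weight
    ``prior_df`` (light empirical-Bayes stabilization for very small counts)
    and floored at 1.
    """
    if isinstance(resamples, ResampleArray):
        values = resamples.values
        method = resamples.method
    else:
        values = np.asarray(resamples, dtype=float)
        method = "unknown"
    if values.ndim != 3:
        raise InputError("resamples must have shape (T, N, B)")
    T, N, B = values.shape
    if B < 2:
        raise InsufficientReplicatesError(
            f"dispersion estimation needs B >= 2 resamples per sample, got B={B}"
        )
    if prior_df < 0:
        raise InputError("prior_df must be non-negative")

    mean = values.mean(axis=2)  # (T, N)
    positive = mean > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.where(
            positive[:, :, None],
            (values - mean[:, :, None]) ** 2 / np.where(positive, mean, 1.0)[:, :, None],
            0.0,
        )
    num = pearson.sum(axis=(1, 2))
    df = positive.sum(axis=1) * (B - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(df > 0, num / np.maximum(df, 1), np.nan)
    tau = (num + prior_df) / (df + prior_df) if prior_df > 0 else raw.copy()
    tau = np.where(np.isfinite(tau), tau, 1.0)
    tau = np.maximum(tau, 1.0)
    return RTAEstimate(
        tau=tau,
        pooled_df=residual_df(N, B),
        raw_stat=raw,
        prior_df=float(prior_df),
        method=method,
    )


def divide_counts(y: np.ndarray, est: RTAEstimate) -> DividedCounts:
    """Divide counts by the estimated RTA dispersion, row by row.

    The output is fractional and intentionally not rounded: downstream
    quasi-likelihood fitting accepts fractional counts directly.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise InputError("y must be a transcripts x samples matrix")
    if y.shape[0] != est.tau.shape[0]:
        raise InputError(
            f"count matrix has {y.shape[0]} rows but tau has {est.tau.shape[0]} entries"
        )
    return DividedCounts(z=y / est.tau[:, None], source_tau=est)


# ---------------------------------------------------------------------------
# on-disk layout


def write_quant_dir(
    out_dir: str | Path,
    catalog: TranscriptCatalog,
    counts: np.ndarray,
    resamples: ResampleArray | None = None,
    sample_names: list[str] | None = None,
) -> list[Path]:
    """Write one quantification directory per sample.

    Each sample directory contains ``quant.sf`` (columns Name, Length,
    EffectiveLength, TPM, NumReads), and, when resamples are given,
    ``resamples.tsv.gz`` (T rows x B columns) plus ``resample_meta.json``
    with the resampling method and B.
    """
    out_dir = Path(out_dir)
    counts = np.asarray(counts, dtype=float)
    T, N = counts.shape
    if T != len(catalog):
        raise InputError("counts rows must match catalog")
    if sample_names is None:
        sample_names = [f"sample{j + 1}" for j in range(N)]
    eff = catalog.effective_length
    paths = []
    for j, name in enumerate(sample_names):
        sdir = out_dir / name
        sdir.mkdir(parents=True, exist_ok=True)
        dens = counts[:, j] / eff
        tpm = dens / dens.sum() * 1e6 if dens.sum() > 0 else np.zeros(T)
        df = pd.DataFrame(
            {
                "Name": catalog.transcript_id,
                "Length": np.round(eff).astype(int) + 200,
                "EffectiveLength": eff,
                "TPM": tpm,
                "NumReads": counts[:, j],
            }
        )
        df.to_csv(sdir / "quant.sf", sep="\t", index=False, float_format="%.6f")
        if resamples is not None:
            with gzip.open(sdir / "resamples.tsv.gz", "wt") as fh:
                np.savetxt(fh, resamples.values[:, j, :], delimiter="\t", fmt="%.6f")
            meta = {"method": resamples.method, "B": int(resamples.n_resamples)}
            (sdir / "resample_meta.json").write_text(json.dumps(meta) + "\n")
        paths.append(sdir)
    return paths


def read_quant_dir(
    paths: list[str | Path] | str | Path,
) -> tuple[np.ndarray, ResampleArray | None, TranscriptCatalog]:
    """Read per-sample quantification directories.

    ``paths`` may be a list of sample directories or a parent directory whose
    immediate subdirectories each contain a ``quant.sf``. All samples must
    share an identical transcript ordering and, when present, a consistent
    resampling method and number of resamples B. Returns fractional NumReads
    as the count matrix, the detected resamples (or None), and a catalog with
    ``gene_id`` set to the transcript id (the quant table carries no gene
    annotation).
    """
    if isinstance(paths, (str, Path)):
        parent = Path(paths)
        paths = sorted(p for p in parent.iterdir() if (p / "quant.sf").exists())
        if not paths:
            raise InputError(f"no sample directories with quant.sf under {parent}")
    paths = [Path(p) for p in paths]

    names = None
    eff = None
    counts_cols = []
    res_slices: list[np.ndarray | None] = []
    meta_ref: dict | None = None
    for p in paths:
        df = pd.read_csv(p / "quant.sf", sep="\t")
        if list(df.columns) != QUANT_COLUMNS:
            raise InputError(f"{p}/quant.sf does not have the expected columns")
        if names is None:
            names = list(df["Name"])
            eff = df["EffectiveLength"].to_numpy(dtype=float)
        elif list(df["Name"]) != names:
            raise InputError(f"transcript ids in {p} do not match the first sample")
        counts_cols.append(df["NumReads"].to_numpy(dtype=float))

        meta_path = p / "resample_meta.json"
        res_path = p / "resamples.tsv.gz"
        if meta_path.exists() and res_path.exists():
            meta = json.loads(meta_path.read_text())
            if meta_ref is None:
                meta_ref = meta
            elif meta != meta_ref:
                raise InputError("inconsistent resample metadata across samples")
            with gzip.open(res_path, "rt") as fh:
                mat = np.loadtxt(fh, delimiter="\t", ndmin=2)
            if mat.shape != (len(names), meta["B"]):
                raise InputError(f"resample matrix in {p} has unexpected shape")
            res_slices.append(mat)
        else:
            res_slices.append(None)

    counts = np.column_stack(counts_cols)
    catalog = TranscriptCatalog(
        transcript_id=tuple(names),
        effective_length=eff,
        gene_id=tuple(names),
    )
    has_res = [s is not None for s in res_slices]
    if any(has_res):
        if not all(has_res):
            raise InputError("some samples have resamples and some do not")
        resamples = ResampleArray(
            values=np.stack(res_slices, axis=1), method=meta_ref["method"]
        )
    else:
        resamples = None
    return counts, resamples, catalog


def read_kallisto_h5(path: str | Path) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Read a kallisto-style HDF5 abundance file for one sample.

    Returns (est_counts, bootstraps (T, B) or None, transcript ids). The
    expected datasets are ``est_counts``, ``aux/ids`` and
    ``bootstrap/bs0 ... bs{B-1}``.
    """
    import h5py

    with h5py.File(path, "r") as fh:
        est = np.asarray(fh["est_counts"], dtype=float)
        ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["aux/ids"]]
        boot = None
        if "bootstrap" in fh:
            keys = sorted(fh["bootstrap"].keys(), key=lambda k: int(k[2:]))
            if keys:
                boot = np.column_stack(
                    [np.asarray(fh["bootstrap"][k], dtype=float) for k in keys]
                )
    return est, boot, ids
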