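"""Miniature transcript quantifier over equivalence classes.

Lightweight RNA-seq quantifiers collapse reads into equivalence classes (ECs):
sets of transcripts compatible with the same read sequence. This module
implements the three algorithms needed to exercise the divided-count pipeline
end to end on EC data:

* :func:`em_quantify` — maximum-likelihood abundances by expectation-
  maximization on the EC-count multinomial likelihood;
* :func:`bootstrap_resample` — parametric multinomial bootstrap over EC
  counts, re-running the EM for every replicate (the technical-resampling
  scheme used by both kallisto and Salmon);
* :func:`gibbs_resample` — uncollapsed Gibbs sampling that alternates a
  posterior multinomial read-allocation step with a posterior gamma abundance
  step, emitting integer transcript-count draws.

The internal abundance parameter is the per-transcript proportion of reads
``rho``. With ``theta`` the nucleotide-fraction abundance of transcript ``t``
and ``l_t`` its effective length, ``rho_t`` is proportional to
``theta_t / l_t``, so the class probability is the length-normalized sum of
member-transcript abundances and the within-class allocation weight of the EM
and Gibbs steps is ``theta_t / l_t`` renormalized within the class.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TranscriptCatalog",
    "ECStructure",
    "ECCounts",
    "AbundanceEstimate",
    "ResampleArray",
    "em_quantify",
    "ec_log_likelihood",
    "bootstrap_resample",
    "gibbs_resample",
    "write_ec_tsv",
    "read_ec_tsv",
]


class InputError(ValueError):
    """Invalid or inconsistent user input."""


class DegenerateInputError(ValueError):
    """Input that is formally valid but has no usable information."""


@dataclass(frozen=True)
class TranscriptCatalog:
    """Reference transcriptome annotation used by the quantifier.

    Parameters
    ----------
    transcript_id
        Unique transcript identifiers.
    effective_length
        Positive effective lengths in bases.
    gene_id
        Gene identifier for every transcript (each transcript belongs to
        exactly one gene).
    """

    transcript_id: tuple[str, ...]
    effective_length: np.ndarray
    gene_id: tuple[str, ...]

    def __post_init__(self) -> None:
        eff = np.asarray(self.effective_length, dtype=float)
        object.__setattr__(self, "effective_length", eff)
        if len(set(self.transcript_id)) != len(self.transcript_id):
            raise InputError("transcript ids must be unique")
        if eff.shape != (len(self.transcript_id),):
            raise InputError("effective_length must align with transcript_id")
        if np.any(eff <= 0) or not np.all(np.isfinite(eff)):
            raise InputError("effective lengths must be positive and finite")
        if len(self.gene_id) != len(self.transcript_id):
            raise InputError("gene_id must align with transcript_id")

    def __len__(self) -> int:
        return len(self.transcript_id)


@dataclass(frozen=True)
class ECStructure:
    """Equivalence classes as ordered transcript-index subsets.

    Membership is unweighted: a transcript is either in a class or not.
    """

    classes: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        cleaned = []
        seen = set()
        for cls in self.classes:
            key = tuple(sorted(int(i) for i in cls))
            if len(key) == 0:
                raise InputError("equivalence classes must be non-empty")
            if len(set(key)) != len(key):
                raise InputError("duplicate transcript within a class")
            if key in seen:
                raise InputError(f"duplicate equivalence class {key}")
            seen.add(key)
            cleaned.append(key)
        object.__setattr__(self, "classes", tuple(cleaned))

    def validate_against(self, catalog: TranscriptCatalog) -> None:
        n = len(catalog)
        for cls in self.classes:
            if cls[0] < 0 or cls[-1] >= n:
                raise InputError(
                    f"class {cls} references a transcript outside the catalog"
                )

    def __len__(self) -> int:
        return len(self.classes)


@dataclass(frozen=True)
class ECCounts:
    """Per-sample non-negative integer read counts, one entry per class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(c < 0):
            raise InputError("EC counts must be non-negative")
        if not np.allclose(c, np.round(c)):
            raise InputError("EC counts must be integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AbundanceEstimate:
    """Point estimate of transcript abundances.

    ``est_count`` is the (fractional) number of reads attributed to each
    transcript; ``theta`` is the corresponding proportion of reads.
    """

    est_count: np.ndarray
    theta: np.ndarray
    n_iter: int = 0
    converged: bool = True


@dataclass
class ResampleArray:
    """Technical resamples: transcripts x samples x B replicate counts."""

    values: np.ndarray  # (T, N, B), non-negative
    method: str  # "bootstrap" or "gibbs"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise InputError("ResampleArray values must be 3-dimensional (T, N, B)")
        if np.any(v < 0):
            raise InputError("resampled counts must be non-negative")
        if self.method not in ("bootstrap", "gibbs"):
            raise InputError("method must be 'bootstrap' or 'gibbs'")
        self.values = v

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_resamples(self) -> int:
        return self.values.shape[2]

    def check_conservation(self, totals: np.ndarray, rtol: float = 1e-6) -> None:
        """Check that each (sample, resample) conserves that sample's reads."""
        got = self.values.sum(axis=0)  # (N, B)
        want = np.asarray(totals, dtype=float)[:, None]
        if not np.allclose(got, want, rtol=rtol, atol=1e-9):
            raise InputError("resamples do not conserve per-sample total reads")


def _check_inputs(
    structure: ECStructure, counts: ECCounts, catalog: TranscriptCatalog
) -> None:
    if len(counts.counts) != len(structure):
        raise InputError(
            f"{len(counts.counts)} class counts for {len(structure)} classes"
        )
    structure.validate_against(catalog)


def _flatten(structure: ECStructure) -> tuple[np.ndarray, np.ndarray]:
    """Flat (class index, transcript index) arrays over all memberships."""
    rows = np.concatenate(
        [np.full(len(c), i, dtype=np.int64) for i, c in enumerate(structure.classes)]
    )
    cols = np.concatenate([np.asarray(c, dtype=np.int64) for c in structure.classes])
    return rows, cols


def ec_log_likelihood(
    structure: ECStructure, counts: ECCounts, theta: np.ndarray
) -> float:
    """Multinomial EC-count log-likelihood of read proportions ``theta``.

    Classes with zero reads contribute nothing. Classes with reads whose
    member proportions are all zero have likelihood zero (-inf).
    """
    theta = np.asarray(theta, dtype=float)
    rows, cols = _flatten(structure)
    class_p = np.bincount(rows, weights=theta[cols], minlength=len(structure))
    n = counts.counts
    active = n > 0
    if np.any(class_p[active] <= 0):
        return -np.inf
    return float(np.sum(n[active] * np.log(class_p[active])))


def em_quantify(
    structure: ECStructure,
    counts: ECCounts,
    catalog: TranscriptCatalog,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> AbundanceEstimate:
    """Maximum-likelihood transcript abundances by EM over EC counts.

    Starting from uniform read proportions, each iteration allocates every
    class's reads to its member transcripts proportionally to the current
    length-normalized abundances and renormalizes. The multinomial
    log-likelihood is non-decreasing across iterations; iteration stops when
    the largest absolute change in ``theta`` falls below ``tol``.
    """
    if max_iter < 1:
        raise InputError("max_iter must be >= 1")
    if tol <= 0:
        raise InputError("tol must be positive")
    _check_inputs(structure, counts, catalog)
    T = len(catalog)
    n = counts.counts.astype(float)
    total = float(n.sum())
    if total == 0:
        zero = np.zeros(T)
        return AbundanceEstimate(est_count=zero, theta=zero, n_iter=0)

    rows, cols = _flatten(structure)
    ncls = len(structure)
    rho = np.full(T, 1.0 / T)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = rho[cols]
        denom = np.bincount(rows, weights=w, minlength=ncls)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(denom[rows] > 0, w / denom[rows], 0.0)
        est = np.bincount(cols, weights=share * n[rows], minlength=T)
        rho_new = est / total
        delta = np.max(np.abs(rho_new - rho))
        rho = rho_new
        if delta < tol:
            converged = True
            break
    return AbundanceEstimate(
        est_count=rho * total, theta=rho, n_iter=it, converged=converged
    )


def bootstrap_resample(
    structure: ECStructure,
    counts: ECCounts,
    catalog: TranscriptCatalog,
    B: int,
    seed: int | np.random.Generator,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Multinomial bootstrap over EC counts for one sample.

    For each of ``B`` replicates, class counts are redrawn multinomially with
    size ``total_reads`` and probabilities equal to the observed class
    proportions; the EM quantifier is then re-run on the resampled class
    counts. Returns a ``(T, B)`` array of estimated transcript counts, the
    per-sample slice of a bootstrap-tagged :class:`ResampleArray`.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    _check_inputs(structure, counts, catalog)
    total = counts.total_reads
    if total == 0:
        raise DegenerateInputError("cannot bootstrap a sample with zero reads")
    rng = np.random.default_rng(seed)
    p = counts.counts / total
    out = np.empty((len(catalog), B))
    for b in range(B):
        resampled = ECCounts(rng.multinomial(total, p))
        est = em_quantify(structure, resampled, catalog, max_iter=max_iter, tol=tol)
        out[:, b] = est.est_count
    return out


def gibbs_resample(
    structure: ECStructure,
    counts: ECCounts,
    catalog: TranscriptCatalog,
    B: int,
    seed: int | np.random.Generator,
    prior_count: float = 1.0,
    burn_in: int = 100,
    thin: int = 4,
) -> np.ndarray:
    """Uncollapsed Gibbs sampling of transcript counts for one sample.

    Each sweep (i) allocates every class's reads among its member transcripts
    multinomially with weights proportional to the current length-normalized
    abundance ``theta_t / l_t`` within the class, and (ii) draws per-transcript
    abundance rates from the gamma posterior with shape ``allocated count +
    prior_count``. On the read-rate scale the two steps reduce to multinomial
    allocation with weights proportional to gamma variates
    ``Gamma(k_t + prior_count, 1)``. Every ``thin``-th sweep after ``burn_in``
    is emitted until ``B`` draws are collected.

    The positive prior gives every member transcript of an observed class a
    non-zero allocation probability, so Gibbs draws vary even when the EM
    assigns all reads of a shared class to a single transcript — the scenario
    in which the bootstrap shows no variation at all.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    if burn_in < 0:
        raise InputError("burn_in must be >= 0")
    if thin < 1:
        raise InputError("thin must be >= 1")
    if prior_count <= 0:
        raise InputError("prior_count must be positive")
    _check_inputs(structure, counts, catalog)
    T = len(catalog)
    rng = np.random.default_rng(seed)
    n = counts.counts

    # read-rate state, initialized from the EM solution plus the prior
    est = em_quantify(structure, counts, catalog)
    gamma_rate = est.est_count + prior_count

    active = [
        (np.asarray(cls, dtype=np.int64), int(cnt))
        for cls, cnt in zip(structure.classes, n)
        if cnt > 0
    ]
    singles = np.zeros(T)
    multi = []
    for members, cnt in active:
        if len(members) == 1:
            singles[members[0]] += cnt
        else:
            multi.append((members, cnt))

    out = np.empty((T, B))
    collected = 0
    sweep = 0
    alloc = np.zeros(T)
    while collected < B:
        sweep += 1
        alloc[:] = singles
        for members, cnt in multi:
            w = gamma_rate[members]
            s = w.sum()
            if s <= 0 or not np.isfinite(s):
                p = np.full(len(members), 1.0 / len(members))
            else:
                p = w / s
            alloc[members] += rng.multinomial(cnt, p)
        gamma_rate = rng.gamma(alloc + prior_count)
        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            out[:, collected] = alloc
            collected += 1
    return out


def write_ec_tsv(
    path: str | Path,
    structure: ECStructure,
    counts_per_sample: list[ECCounts],
    catalog: TranscriptCatalog,
) -> None:
    """Serialize EC structure and per-sample counts as TSV.

    One row per class: comma-separated member transcript ids, then one count
    column per sample.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        header = ["transcripts"] + [f"sample{j + 1}" for j in range(len(counts_per_sample))]
        fh.write("\t".join(header) + "\n")
        for i, cls in enumerate(structure.classes):
            ids = ",".join(catalog.transcript_id[t] for t in cls)
            row = [ids] + [str(int(c.counts[i])) for c in counts_per_sample]
            fh.write("\t".join(row) + "\n")


def read_ec_tsv(
    path: str | Path, catalog: TranscriptCatalog
) -> tuple[ECStructure, list[ECCounts]]:
    """Read the TSV layout written by :func:`write_ec_tsv`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    index = {tid: i for i, tid in enumerate(catalog.transcript_id)}
    classes = []
    columns: list[list[int]] = []
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        nsamp = len(header) - 1
        columns = [[] for _ in range(nsamp)]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            try:
                members = tuple(index[t] for t in parts[0].split(","))
            except KeyError as err:
                raise InputError(f"unknown transcript id {err}") from None
            classes.append(members)
            for j in range(nsamp):
                columns[j].append(int(parts[1 + j]))
    structure = ECStructure(tuple(classes))
    return structure, [ECCounts(np.asarray(col)) for col in columns]
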