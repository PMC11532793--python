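"""Synthetic two-group RNA-seq experiments with transcript-level ambiguity.

The generator reproduces the statistical structure of a designed two-group
bulk RNA-seq study at the count level: negative-binomial biological variation
with an abundance-dependent biological coefficient of variation (BCV) and
chi-square heterogeneity between transcripts, a random subset of transcripts
with a symmetric two-fold change, alternating library sizes, and
read-to-transcript ambiguity arising from multi-transcript gene topologies.

Two routes produce technical resamples:

* the *direct* route applies each transcript's true RTA dispersion as
  quasi-Poisson technical noise to the counts and to B per-sample resamples —
  fast, used for calibration studies at full desk scale;
* the *equivalence-class* route distributes each transcript's reads over its
  compatible equivalence classes and re-quantifies with the EM/bootstrap/Gibbs
  engines — slower, used to exercise the quantifier end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ecquant import (
    ECCounts,
    ECStructure,
    InputError,
    ResampleArray,
    TranscriptCatalog,
    bootstrap_resample,
    em_quantify,
    gibbs_resample,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimExperiment",
    "PRESETS",
    "draw_dispersions",
    "assign_de",
    "simulate_counts",
    "generate_ec_experiment",
    "simulate_experiment",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated experiment.

    Defaults mirror a designed small-scale experiment with genetically
    identical model organisms: baseline BCV 0.2 with prior degrees of freedom
    40, a two-fold change for the differentially expressed subset, and
    library sizes alternating between samples. Library sizes default to a
    desk-scale 0.25/1.0 million reads, preserving the alternating pattern of
    the 25/100 million read full-scale design.
    """

    n_per_group: int = 5
    T: int = 10_000
    n_de: int = 1_000
    fold_change: float = 2.0
    bcv0: float = 0.2
    prior_df: float = 40.0
    lib_sizes: tuple[float, ...] = (250_000.0, 1_000_000.0)
    B: int = 30
    resample_method: str = "gibbs"
    seed: int | None = None
    # abundance model
    log_abundance_sd: float = 1.8
    # topology of genes / equivalence classes
    transcripts_per_gene_probs: tuple[float, ...] = (0.45, 0.25, 0.2, 0.1)
    shared_class_prob: float = 0.6
    degenerate_gene_prob: float = 0.05
    # RTA dispersion of ambiguous transcripts: tau = 2**|N(0, sd)|
    rta_log2_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_de > self.T:
            raise InputError("n_de cannot exceed T")
        if self.bcv0 <= 0 or self.prior_df <= 0:
            raise InputError("bcv0 and prior_df must be positive")
        if any(l <= 0 for l in self.lib_sizes):
            raise InputError("library sizes must be positive")
        if self.resample_method not in ("bootstrap", "gibbs"):
            raise InputError("resample_method must be 'bootstrap' or 'gibbs'")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_group

    def sample_lib_sizes(self) -> np.ndarray:
        """Per-sample intended totals, alternating over the configured pattern."""
        pat = np.asarray(self.lib_sizes, dtype=float)
        return pat[np.arange(self.n_samples) % len(pat)]


PRESETS: dict[str, SimConfig] = {
    # desk-scale version of the designed-experiment simulation
    "small_scale": SimConfig(),
    "small_scale_null": SimConfig(n_de=0),
    # large observational studies: 100 samples per group, BCV 0.6,
    # two resamples per sample suffice since N(B-1) = 200
    "large_scale_bcv06": SimConfig(n_per_group=100, bcv0=0.6, B=2),
    "large_scale_null": SimConfig(n_per_group=100, bcv0=0.6, B=2, n_de=0),
    # printed full-scale design: 41 372 transcripts, 3000 DE, 25/100 Mi reads
    "full_scale": SimConfig(
        T=41_372,
        n_de=3_000,
        lib_sizes=(25e6, 100e6),
        B=100,
    ),
}


@dataclass(frozen=True)
class Topology:
    """Gene membership and equivalence-class layout of the transcriptome."""

    gene_id: tuple[str, ...]  # per transcript
    classes: tuple[tuple[int, ...], ...]
    # per transcript: compatible class indices and read-split weights
    class_of: tuple[tuple[int, ...], ...]
    weight_of: tuple[tuple[float, ...], ...]
    effective_length: np.ndarray

    def catalog(self) -> TranscriptCatalog:
        return TranscriptCatalog(
            transcript_id=tuple(f"tx{i + 1}" for i in range(len(self.gene_id))),
            effective_length=self.effective_length,
            gene_id=self.gene_id,
        )

    def structure(self) -> ECStructure:
        return ECStructure(self.classes)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated experiment."""

    is_de: np.ndarray
    true_log2fc: np.ndarray
    true_bcv: np.ndarray
    rel_abundance: np.ndarray
    topology: Topology


@dataclass
class SimExperiment:
    """A simulated experiment ready for the divided-count pipeline."""

    counts: np.ndarray  # observed transcript counts, technical noise included
    resamples: ResampleArray
    truth: SimTruth
    group: np.ndarray
    lib_size: np.ndarray
    true_tau: np.ndarray
    config: SimConfig


# ---------------------------------------------------------------------------
# dispersions and truth


def _bcv2_trend(expected_count: np.ndarray, bcv0: float) -> np.ndarray:
    """Smooth BCV^2 trend: plateau bcv0^2 at high abundance, inflated below."""
    c = np.maximum(expected_count, 1e-6)
    return (bcv0 + 1.0 / np.sqrt(c + 1.0)) ** 2


def draw_dispersions(
    config: SimConfig,
    rel_abundance: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-transcript BCV^2 around the abundance trend.

    ``BCV^2_t = trend(abundance_t) * prior_df / chi2_{prior_df,t}``; the
    inverse chi-square factor creates the inter-transcript heterogeneity
    controlled by ``prior_df`` (heterogeneity vanishes as prior_df -> inf).
    """
    mean_lib = float(np.exp(np.mean(np.log(config.sample_lib_sizes()))))
    expected = rel_abundance * mean_lib
    trend = _bcv2_trend(expected, config.bcv0)
    if np.isinf(config.prior_df):
        return trend
    chi2 = rng.chisquare(config.prior_df, size=trend.shape)
    chi2 = np.maximum(chi2, 1e-8)
    return trend * config.prior_df / chi2


def _make_topology(config: SimConfig, rng: np.random.Generator) -> Topology:
    """Genes with 1-4 transcripts; singleton and shared equivalence classes.

    Multi-transcript genes emit one singleton class per transcript and, with
    probability ``shared_class_prob``, one class shared by all of the gene's
    transcripts; reads of a transcript split 60/40 between its singleton and
    the shared class. A fraction ``degenerate_gene_prob`` of the
    multi-transcript genes have a *single* shared class and no singletons, the
    scenario in which bootstrap resampling sees no ambiguity at all.
    """
    T = config.T
    sizes = []
    total = 0
    probs = np.asarray(config.transcripts_per_gene_probs, dtype=float)
    probs = probs / probs.sum()
    while total < T:
        k = int(rng.choice(len(probs), p=probs)) + 1
        k = min(k, T - total)
        sizes.append(k)
        total += k

    gene_id: list[str] = []
    classes: list[tuple[int, ...]] = []
    class_of: list[list[int]] = [[] for _ in range(T)]
    weight_of: list[list[float]] = [[] for _ in range(T)]
    start = 0
    for g, k in enumerate(sizes):
        members = tuple(range(start, start + k))
        start += k
        gene_id.extend([f"gene{g + 1}"] * k)
        if k == 1:
            cid = len(classes)
            classes.append(members)
            class_of[members[0]].append(cid)
            weight_of[members[0]].append(1.0)
            continue
        degenerate = rng.random() < config.degenerate_gene_prob
        if degenerate:
            cid = len(classes)
            classes.append(members)
            for t in members:
                class_of[t].append(cid)
                weight_of[t].append(1.0)
            continue
        shared = rng.random() < config.shared_class_prob
        shared_cid = None
        if shared:
            shared_cid = len(classes)
            classes.append(members)
        for t in members:
            cid = len(classes)
            classes.append((t,))
            if shared_cid is None:
                class_of[t].append(cid)
                weight_of[t].append(1.0)
            else:
                class_of[t].extend([cid, shared_cid])
                weight_of[t].extend([0.6, 0.4])
    eff = np.exp(rng.normal(np.log(1500.0), 0.5, size=T))
    return Topology(
        gene_id=tuple(gene_id),
        classes=tuple(classes),
        class_of=tuple(tuple(c) for c in class_of),
        weight_of=tuple(tuple(w) for w in weight_of),
        effective_length=eff,
    )


def assign_de(config: SimConfig, seed: int | np.random.Generator | None = None) -> SimTruth:
    """Draw the ground truth: abundances, dispersions, DE flags, topology.

    ``n_de`` transcripts are sampled uniformly without replacement; half are
    up-regulated and half down-regulated (ties to up when ``n_de`` is odd),
    each with ``|log2 fold change| = log2(fold_change)``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.T
    topology = _make_topology(config, rng)
    log_ab = rng.normal(0.0, config.log_abundance_sd, size=T)
    rel = np.exp(log_ab)
    rel = rel / rel.sum()
    bcv2 = draw_dispersions(config, rel, rng)

    is_de = np.zeros(T, dtype=bool)
    log2fc = np.zeros(T)
    if config.n_de > 0:
        de_idx = rng.choice(T, size=config.n_de, replace=False)
        is_de[de_idx] = True
        n_up = (config.n_de + 1) // 2
        sign = np.full(config.n_de, -1.0)
        sign[:n_up] = 1.0
        log2fc[de_idx] = sign * np.log2(config.fold_change)
    return SimTruth(
        is_de=is_de,
        true_log2fc=log2fc,
        true_bcv=np.sqrt(bcv2),
        rel_abundance=rel,
        topology=topology,
    )


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    config: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Gamma-Poisson biological counts for every transcript and sample.

    The mean of transcript ``t`` in sample ``i`` is proportional to the
    baseline relative abundance times the group fold change, renormalized per
    sample and scaled by the sample's library size; the gamma shape is
    ``1 / BCV^2_t``. Returns (counts, per-sample library sizes).
    """
    lib = config.sample_lib_sizes()
    n = config.n_samples
    group = np.repeat([0, 1], config.n_per_group)
    fc = np.exp2(np.outer(truth.true_log2fc, group))  # (T, N)
    base = truth.rel_abundance[:, None] * fc
    base = base / base.sum(axis=0, keepdims=True)
    mean = base * lib[None, :]
    bcv2 = truth.true_bcv**2
    lam = mean.copy()
    pos = bcv2 > 0
    if np.any(pos):
        shape = (1.0 / bcv2[pos])[:, None]
        lam[pos] = mean[pos] * rng.gamma(shape, size=(int(pos.sum()), n)) / shape
    counts = rng.poisson(lam).astype(float)
    return counts, lib


def _draw_true_tau(config: SimConfig, truth: SimTruth, rng: np.random.Generator) -> np.ndarray:
    """True RTA dispersions: 1 for unambiguous transcripts, heavy-tailed above 1
    for transcripts whose gene topology creates read ambiguity."""
    T = config.T
    ambiguous = np.array(
        [len(cls) > 1 or len(truth.topology.classes[cls[0]]) > 1
         for cls in truth.topology.class_of]
    )
    tau = np.ones(T)
    n_amb = int(ambiguous.sum())
    tau[ambiguous] = np.exp2(np.abs(rng.normal(0.0, config.rta_log2_sd, size=n_amb)))
    return tau


def _quasi_poisson(rng: np.random.Generator, mean: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Draws with mean ``mean`` and variance ``tau * mean`` (scaled Poisson)."""
    return tau * rng.poisson(mean / tau)


def simulate_experiment(
    config: SimConfig,
    seed: int | None = None,
    route: str = "direct",
) -> SimExperiment:
    """Generate one complete experiment: counts, resamples and truth.

    ``route='direct'`` draws observed counts with quasi-Poisson technical
    noise of dispersion ``tau_t`` around the biological counts and produces B
    technical resamples per sample the same way. ``route='ec'`` distributes
    reads over equivalence classes and re-quantifies with the EM plus the
    configured resampling engine (slow; intended for small T).
    """
    if route not in ("direct", "ec"):
        raise InputError("route must be 'direct' or 'ec'")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = assign_de(config, rng)
    bio, lib = simulate_counts(config, truth, rng)
    group = np.repeat([0, 1], config.n_per_group)
    tau = _draw_true_tau(config, truth, rng)

    if route == "direct":
        taucol = tau[:, None]
        observed = _quasi_poisson(rng, np.maximum(bio, 1e-12), taucol)
        res = np.empty((config.T, config.n_samples, config.B))
        for b in range(config.B):
            res[:, :, b] = _quasi_poisson(rng, np.maximum(observed, 1e-12), taucol)
        resamples = ResampleArray(values=res, method=config.resample_method)
    else:
        catalog = truth.topology.catalog()
        structure = truth.topology.structure()
        structure_counts = generate_ec_experiment(config, truth, bio, rng)
        observed = np.empty((config.T, config.n_samples))
        res = np.empty((config.T, config.n_samples, config.B))
        for j, ec_counts in enumerate(structure_counts):
            est = em_quantify(structure, ec_counts, catalog)
            observed[:, j] = est.est_count
            child = rng.integers(0, 2**31 - 1)
            if config.resample_method == "bootstrap":
                res[:, j, :] = bootstrap_resample(
                    structure, ec_counts, catalog, config.B, int(child)
                )
            else:
                res[:, j, :] = gibbs_resample(
                    structure, ec_counts, catalog, config.B, int(child)
                )
        resamples = ResampleArray(values=res, method=config.resample_method)

    return SimExperiment(
        counts=observed,
        resamples=resamples,
        truth=truth,
        group=group,
        lib_size=lib,
        true_tau=tau,
        config=config,
    )


def generate_ec_experiment(
    config: SimConfig,
    truth: SimTruth,
    counts: np.ndarray,
    rng: np.random.Generator,
) -> list[ECCounts]:
    """Distribute transcript reads over compatible equivalence classes.

    Each transcript's reads in each sample are split multinomially over its
    compatible classes with the topology's split weights. Returns one
    :class:`ECCounts` per sample, aligned to ``truth.topology.structure()``.
    """
    topo = truth.topology
    T, N = counts.shape
    ncls = len(topo.classes)
    out = []
    counts_int = np.round(counts).astype(np.int64)
    for j in range(N):
        cls_counts = np.zeros(ncls, dtype=np.int64)
        col = counts_int[:, j]
        for t in range(T):
            y = col[t]
            if y == 0:
                continue
            cids = topo.class_of[t]
            if len(cids) == 1:
                cls_counts[cids[0]] += y
            else:
                split = rng.multinomial(y, topo.weight_of[t])
                for cid, s in zip(cids, split):
                    cls_counts[cid] += s
        out.append(ECCounts(cls_counts))
    return out
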