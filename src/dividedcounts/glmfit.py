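"""Vectorized negative-binomial GLMs with moment-matched adjusted deviances.

The divided-count model is a quasi-negative-binomial GLM with log link and
library-size offsets: ``log mu_ti = x_i' beta_t + log L_i`` with variance
``sigma2_t (nu + phi nu^2)``, ``phi`` a common NB dispersion and ``sigma2_t``
the per-transcript quasi-dispersion. The classical chi-square approximation to
the residual deviance is biased for small counts, which biases the
quasi-dispersion estimates ``D / (N - p)``. This module computes *adjusted*
deviances and degrees of freedom whose first two moments match a chi-square
law under the fitted model, via two backends:

* an exact conditional backend for one-way layouts with integer counts and
  equal within-group offsets: conditionally on the group sums the counts are
  multinomial (Poisson limit) or Dirichlet-multinomial (NB), so the moments of
  the residual deviance are free of the unknown means and can be tabulated
  exactly;
* a general backend for fractional counts, arbitrary designs or unequal
  offsets: per-observation unit-deviance moments evaluated at the fitted
  means, down-weighted by the hat-matrix leverages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from scipy.stats import betabinom, binom, nbinom, poisson

from .ecquant import InputError

__all__ = ["CountModel", "ModelFit", "fit_nb_glm", "nb_unit_deviance", "nb_loglik"]

_POISSON_EPS = 1e-10  # phi below this is treated as Poisson
_MU_FLOOR = 1e-8


@dataclass
class CountModel:
    """A count matrix with its experimental design and normalization.

    ``counts`` may be fractional (divided counts are never rounded).
    ``offsets`` default to ``log(lib_size * norm_factor)`` per sample.
    """

    counts: np.ndarray  # (T, N)
    lib_size: np.ndarray  # (N,)
    design: np.ndarray  # (N, p), full rank
    norm_factor: np.ndarray | None = None
    offsets: np.ndarray | None = None  # (N,) or (T, N)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.lib_size = np.asarray(self.lib_size, dtype=float)
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        T, N = self.counts.shape
        if self.lib_size.shape != (N,):
            raise InputError("lib_size must have one entry per sample")
        if np.any(self.lib_size <= 0):
            raise InputError("library sizes must be positive")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise InputError("counts must be finite and non-negative")
        if self.design.shape[0] != N:
            raise InputError("design must have one row per sample")
        p = self.design.shape[1]
        if np.linalg.matrix_rank(self.design) < p or p > N:
            raise InputError("design matrix must have full column rank with p <= N")
        if self.norm_factor is None:
            self.norm_factor = np.ones(N)
        else:
            self.norm_factor = np.asarray(self.norm_factor, dtype=float)
            if np.any(self.norm_factor <= 0):
                raise InputError("normalization factors must be positive")
            logmean = np.mean(np.log(self.norm_factor))
            if abs(logmean) > 1e-8:
                raise InputError("normalization factors must have geometric mean 1")
        if self.offsets is None:
            self.offsets = np.log(self.lib_size * self.norm_factor)
        else:
            self.offsets = np.asarray(self.offsets, dtype=float)

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class ModelFit:
    """Per-transcript NB GLM fit with moment-matched adjusted deviances."""

    beta: np.ndarray  # (T, p), natural-log scale
    mu: np.ndarray  # (T, N) fitted means
    deviance: np.ndarray  # (T,) raw residual deviance
    adj_deviance: np.ndarray  # (T,) bias-adjusted deviance
    adj_df: np.ndarray  # (T,) adjusted residual df, in (0, N - p]
    nb_dispersion: float
    converged: np.ndarray  # (T,) bool
    dev_scale: np.ndarray  # (T,) factor mapping raw deviance drops to adjusted scale
    moment_backend: str  # "conditional-exact", "leverage", or "mixed"
    model: CountModel = field(repr=False)

    @property
    def s2(self) -> np.ndarray:
        """Raw quasi-dispersion adj_deviance / adj_df (NaN when df is 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.adj_df > 0, self.adj_deviance / self.adj_df, np.nan)


# ---------------------------------------------------------------------------
# unit deviance and likelihood


def nb_unit_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB unit deviance; reduces to the Poisson deviance when phi ~ 0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    with np.errstate(invalid="ignore", divide="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    if phi < _POISSON_EPS:
        return 2.0 * (ylogy - (y - mu))
    r = 1.0 / phi
    return 2.0 * (ylogy - (y + r) * np.log((1.0 + phi * y) / (1.0 + phi * mu)))


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB log-likelihood, extended to fractional counts via gamma functions."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    if phi < _POISSON_EPS:
        return y * np.log(mu) - mu - gammaln(y + 1.0)
    r = 1.0 / phi
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - r * np.log1p(phi * mu)
    )


# ---------------------------------------------------------------------------
# IRLS


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fisher scoring with step-halving for many transcripts at once.

    Returns (beta, mu, deviance, converged).
    """
    T, N = y.shape
    p = X.shape[1]
    if offset.ndim == 1:
        offset = np.broadcast_to(offset, (T, N))
    ridge = 1e-10 * np.eye(p)

    # start from the common-rate fit blended with the data
    L = np.exp(offset)
    rate = y.sum(axis=1) / L.sum(axis=1)
    mu = 0.5 * (y + rate[:, None] * L)
    mu = np.maximum(mu, _MU_FLOOR)
    eta = np.log(mu)
    dev = nb_unit_deviance(y, mu, phi).sum(axis=1)
    beta = np.zeros((T, p))
    have_beta = False
    converged = np.zeros(T, dtype=bool)

    for _ in range(max_iter):
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        A = np.einsum("tn,ni,nj->tij", w, X, X) + ridge
        b = np.einsum("tn,ni->ti", w * z, X)
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        if have_beta:
            # step-halve transcripts whose deviance would increase
            for _half in range(12):
                eta_new = np.clip(beta_new @ X.T + offset, -45.0, 45.0)
                mu_new = np.maximum(np.exp(eta_new), _MU_FLOOR)
                dev_new = nb_unit_deviance(y, mu_new, phi).sum(axis=1)
                bad = dev_new > dev + 1e-6
                if not np.any(bad):
                    break
                beta_new[bad] = 0.5 * (beta_new[bad] + beta[bad])
        eta_new = np.clip(beta_new @ X.T + offset, -45.0, 45.0)
        mu_new = np.maximum(np.exp(eta_new), _MU_FLOOR)
        dev_new = nb_unit_deviance(y, mu_new, phi).sum(axis=1)
        converged = np.abs(dev_new - dev) < tol * (np.abs(dev_new) + 1.0)
        beta, eta, mu, dev = beta_new, eta_new, mu_new, dev_new
        have_beta = True
        if np.all(converged):
            break
    return beta, mu, np.maximum(dev, 0.0), converged


# ---------------------------------------------------------------------------
# unit-deviance moments under the NB model (general backend)


class _DevianceMoments:
    """Interpolated E and Var of the NB unit deviance as functions of mu."""

    def __init__(self, phi: float, mu_max: float, n_grid: int = 192):
        self.phi = phi
        mu_max = float(np.clip(mu_max, 1.0, 5e4))
        grid = np.geomspace(1e-4, mu_max, n_grid)
        e = np.empty(n_grid)
        v = np.empty(n_grid)
        for k, mu in enumerate(grid):
            e[k], v[k] = _exact_unit_moments(mu, phi)
        self._log_mu = np.log(grid)
        self._log_e = np.log(np.maximum(e, 1e-300))
        self._log_v = np.log(np.maximum(v, 1e-300))

    def e(self, mu: np.ndarray) -> np.ndarray:
        lm = np.log(np.maximum(mu, 1e-12))
        return np.exp(np.interp(lm, self._log_mu, self._log_e))

    def v(self, mu: np.ndarray) -> np.ndarray:
        lm = np.log(np.maximum(mu, 1e-12))
        return np.exp(np.interp(lm, self._log_mu, self._log_v))


def _exact_unit_moments(mu: float, phi: float) -> tuple[float, float]:
    """Exact first two moments of the unit deviance at a single mean."""
    if mu <= 0:
        return 0.0, 0.0
    if phi < _POISSON_EPS:
        hi = int(poisson.ppf(1.0 - 1e-12, mu)) + 5
        yy = np.arange(hi + 1)
        pp = poisson.pmf(yy, mu)
    else:
        r = 1.0 / phi
        pq = 1.0 / (1.0 + phi * mu)
        hi = int(nbinom.ppf(1.0 - 1e-12, r, pq)) + 5
        yy = np.arange(hi + 1)
        pp = nbinom.pmf(yy, r, pq)
    d = nb_unit_deviance(yy, np.full_like(yy, mu, dtype=float), phi)
    e = float(pp @ d)
    v = float(pp @ (d * d) - e * e)
    return e, max(v, 0.0)


# ---------------------------------------------------------------------------
# conditional moments for one-way layouts (exact backend)


@lru_cache(maxsize=16)
def _conditional_table(n: int, phi_key: float, s_max: int) -> tuple[np.ndarray, np.ndarray]:
    """E[D|S] and Var[D|S] for one group of ``n`` integer counts summing to S.

    Conditionally on the sum S, Poisson counts are multinomial(S, 1/n) and NB
    counts are Dirichlet-multinomial with equal shapes 1/phi, so the residual
    deviance of the saturated group mean has moments free of the unknown mean.
    """
    phi = float(phi_key)
    E = np.zeros(s_max + 1)
    V = np.zeros(s_max + 1)
    if n < 2:
        return E, V
    a = None if phi < _POISSON_EPS else 1.0 / phi
    for S in range(1, s_max + 1):
        yy = np.arange(S + 1)
        d = nb_unit_deviance(yy, np.full(S + 1, S / n), phi)
        if a is None:
            p1 = binom.pmf(yy, S, 1.0 / n)
        else:
            p1 = betabinom.pmf(yy, S, a, (n - 1) * a)
        e1 = p1 @ d
        e2 = p1 @ (d * d)
        if n == 2:
            cross = p1 @ (d * d[::-1])
        else:
            rem = (S - yy)[:, None]  # remaining reads after y1
            y2 = yy[None, :]
            if a is None:
                P2 = binom.pmf(y2, rem, 1.0 / (n - 1))
            else:
                P2 = betabinom.pmf(y2, rem, a, (n - 2) * a)
            cross = float(p1 @ (P2 @ d * d))
        ED = n * e1
        VD = n * (e2 - e1 * e1) + n * (n - 1) * (cross - e1 * e1)
        E[S] = ED
        V[S] = max(VD, 0.0)
    return E, V


def _oneway_groups(X: np.ndarray) -> np.ndarray | None:
    """Group labels when the design is equivalent to a one-way layout."""
    rows = [tuple(np.round(r, 10)) for r in X]
    patterns = sorted(set(rows))
    if len(patterns) != X.shape[1]:
        return None
    lut = {pat: g for g, pat in enumerate(patterns)}
    return np.array([lut[r] for r in rows])


def _leverages(mu: np.ndarray, X: np.ndarray, phi: float) -> np.ndarray:
    """Hat-matrix diagonals of the working weighted least squares, per transcript."""
    w = mu / (1.0 + phi * mu)  # (T, N)
    A = np.einsum("tn,ni,nj->tij", w, X, X)
    Ainv = np.linalg.pinv(A)
    # h_tn = w_tn * x_n' Ainv_t x_n
    h = w * np.einsum("ni,tij,nj->tn", X, Ainv, X)
    return np.clip(h, 0.0, 1.0)


def _adjusted_moments(
    y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    exact_s_cap: int = 300,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Per-transcript E and Var of the residual deviance under the fitted model."""
    T, N = y.shape
    moments = _DevianceMoments(phi, float(mu.max(initial=1.0)))

    groups = _oneway_groups(X)
    exact_ok = groups is not None and np.allclose(y, np.round(y), atol=1e-9)
    if exact_ok and offset.ndim == 2 and not np.allclose(offset, offset[0]):
        exact_ok = False
    off1 = offset[0] if offset.ndim == 2 else offset
    if exact_ok:
        for g in np.unique(groups):
            if np.ptp(off1[groups == g]) > 1e-10:
                exact_ok = False
                break

    if not exact_ok:
        h = _leverages(mu, X, phi)
        e = moments.e(mu)
        v = moments.v(mu)
        E = ((1.0 - h) * e).sum(axis=1)
        V = ((1.0 - h) * v).sum(axis=1)
        return E, V, "leverage"

    yi = np.round(y).astype(np.int64)
    E = np.zeros(T)
    V = np.zeros(T)
    phi_key = round(float(phi), 12)
    used_fallback = False
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        n_g = len(idx)
        if n_g < 2:
            continue  # a single-sample group is fitted exactly
        S = yi[:, idx].sum(axis=1)
        cap = min(int(S.max(initial=0)), exact_s_cap)
        Etab, Vtab = _conditional_table(n_g, phi_key, cap)
        small = S <= cap
        E[small] += Etab[S[small]]
        V[small] += Vtab[S[small]]
        big = ~small
        if np.any(big):
            used_fallback = True
            mug = mu[np.ix_(big, idx)]
            fac = 1.0 - 1.0 / n_g
            E[big] += fac * moments.e(mug).sum(axis=1)
            V[big] += fac * moments.v(mug).sum(axis=1)
    backend = "mixed" if used_fallback else "conditional-exact"
    return E, V, backend


# ---------------------------------------------------------------------------
# public fit


def fit_nb_glm(model: CountModel, phi: float, max_iter: int = 50, tol: float = 1e-8) -> ModelFit:
    """Fit per-transcript NB GLMs and moment-matched adjusted deviances.

    The adjusted deviance and adjusted degrees of freedom are chosen so that,
    under the fitted model, ``adj_deviance`` has the mean and variance of a
    chi-square variable with ``adj_df`` degrees of freedom. The raw
    quasi-dispersion ``adj_deviance / adj_df`` therefore estimates the
    quasi-dispersion without the small-count bias of the classical
    ``deviance / (N - p)``. ``adj_df`` is capped at the nominal residual
    degrees of freedom ``N - p``.
    """
    if phi < 0:
        raise InputError("phi must be non-negative")
    y = model.counts
    X = model.design
    T, N = y.shape
    p = X.shape[1]
    offset = np.asarray(model.offsets, dtype=float)

    beta, mu, dev, converged = _irls(y, X, offset, phi, max_iter=max_iter, tol=tol)

    if p >= N:  # saturated design: zero residual deviance by construction
        zeros = np.zeros(T)
        return ModelFit(
            beta=beta,
            mu=mu,
            deviance=zeros,
            adj_deviance=zeros,
            adj_df=zeros,
            nb_dispersion=float(phi),
            converged=converged,
            dev_scale=np.zeros(T),
            moment_backend="saturated",
            model=model,
        )

    E, V, backend = _adjusted_moments(y, mu, X, offset, phi)

    ok = (E > 1e-12) & (V > 1e-24)
    with np.errstate(invalid="ignore", divide="ignore"):
        adj_df = np.where(ok, 2.0 * E * E / np.where(ok, V, 1.0), 0.0)
    adj_df = np.minimum(adj_df, float(N - p))
    s2 = np.where(ok, dev / np.where(ok, E, 1.0), 0.0)
    adj_dev = s2 * adj_df
    dev_scale = np.where(ok, adj_df / np.where(ok, E, 1.0), 0.0)

    return ModelFit(
        beta=beta,
        mu=mu,
        deviance=dev,
        adj_deviance=adj_dev,
        adj_df=adj_df,
        nb_dispersion=float(phi),
        converged=converged,
        dev_scale=dev_scale,
        moment_backend=backend,
        model=model,
    )


# ---------------------------------------------------------------------------
# common NB dispersion by adjusted profile likelihood


def common_dispersion_apl(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi_grid_bounds: tuple[float, float] = (1e-6, 5.0),
) -> float:
    """Common NB dispersion maximizing the Cox-Reid adjusted profile likelihood."""
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, dtype=float)

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        _, mu, _, _ = _irls(y, X, offset, phi)
        ll = nb_loglik(y, mu, phi).sum()
        w = mu / (1.0 + phi * mu)
        A = np.einsum("tn,ni,nj->tij", w, X, X)
        sign, logdet = np.linalg.slogdet(A + 1e-12 * np.eye(X.shape[1]))
        cr = 0.5 * np.sum(np.where(sign > 0, logdet, 0.0))
        return -(ll - cr)

    lo, hi = np.log(phi_grid_bounds[0]), np.log(phi_grid_bounds[1])
    res = minimize_scalar(neg_apl, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3})
    return float(np.exp(res.x))
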