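"""Empirical null estimation for balance scores and output transforms.

Under the competitive null hypothesis — taxa in a set are, as a group, no
more abundant than taxa outside it within the same sample — the distribution
of the balance statistic depends on the data (sparsity skews it, inter-taxa
correlation flattens it), so instead of assuming a theoretical null we
estimate one empirically.  Taxa-permutation gives null scores for sets of the
same size with randomly drawn members; a parametric family (normal or
two-component normal mixture) is fitted to the pooled permuted scores.

Permuting taxa destroys the correlation structure inside a set, and
correlation inflates the variance of the statistic, so a permutation null
underestimates the spread for correlated sets.  The optional correlation
adjustment keeps the location (and mixing weights) of the permuted fit but
takes the spread from a fit to the *unpermuted* scores, where the correlation
structure is intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .core import (
    CompositionTable,
    InvalidInputError,
    ScoreMatrix,
    SetCollection,
    closure,
    replace_zeros,
    score_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NormalParams",
    "Mixture2Params",
    "NullModel",
    "EnrichmentResult",
    "permute_taxa",
    "fit_normal",
    "fit_mixture2",
    "pooled_permutation_scores",
    "build_null",
    "transform",
    "cbea",
]

OUTPUT_TYPES = ("raw", "cdf", "zscore", "pval")
FAMILIES = ("normal", "mixture2")


class DegenerateFitError(ValueError):
    """Raised when a distribution fit is not identifiable (e.g. zero spread)."""


@dataclass(frozen=True)
class NormalParams:
    mu: float
    sigma: float

    def cdf(self, x):
        return stats.norm.cdf(x, loc=self.mu, scale=self.sigma)

    def zscore(self, x):
        return (np.asarray(x, dtype=float) - self.mu) / self.sigma

    def rvs(self, size, rng):
        return rng.normal(self.mu, self.sigma, size=size)


@dataclass(frozen=True)
class Mixture2Params:
    """Two-component univariate Gaussian mixture, components sorted by mean."""

    w1: float
    mu1: float
    sigma1: float
    w2: float
    mu2: float
    sigma2: float
    converged: bool = True
    loglik: float = np.nan
    n_iter: int = 0

    def __post_init__(self):
        if not (0.0 < self.w1 < 1.0) or abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise DegenerateFitError("mixture weights must lie in (0,1) and sum to 1")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise DegenerateFitError("mixture component sigmas must be positive")
        if self.mu1 > self.mu2:
            raise DegenerateFitError("components must be ordered by ascending mean")

    def cdf(self, x):
        return (self.w1 * stats.norm.cdf(x, self.mu1, self.sigma1)
                + self.w2 * stats.norm.cdf(x, self.mu2, self.sigma2))

    def zscore(self, x):
        # probit of the mixture CDF: rank-preserving, reduces to (x-mu)/sigma
        # when the two components coincide
        c = np.clip(self.cdf(x), 1e-300, 1 - 1e-16)
        return ndtri(c)

    def rvs(self, size, rng):
        comp = rng.random(size) < self.w2
        out = rng.normal(self.mu1, self.sigma1, size=size)
        out[comp] = rng.normal(self.mu2, self.sigma2, size=size)[comp]
        return out


@dataclass(frozen=True)
class NullModel:
    """Per-set fitted null distributions with adjustment provenance."""

    family: str
    params: tuple  # per-set NormalParams | Mixture2Params, aligned with set_names
    set_names: tuple[str, ...]
    adjusted: bool
    n_perm: int
    diagnostics: tuple  # per-set dicts: converged, loglik, fallback, ...

    def param(self, set_name: str):
        return self.params[self.set_names.index(set_name)]


@dataclass(frozen=True)
class EnrichmentResult:
    """Samples x sets enrichment output in one of four scales.

    ``cdf`` is the fitted null CDF at each raw score, ``pval = 1 - cdf`` is
    the one-sided enrichment p-value, ``zscore`` is the probit of the CDF
    (equivalently (x-mu)/sigma under the normal family), ``raw`` passes the
    balance scores through untouched.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    set_names: tuple[str, ...]
    output_type: str
    null_model: NullModel | None = None

    def __post_init__(self):
        if self.output_type not in OUTPUT_TYPES:
            raise InvalidInputError(f"output_type must be one of {OUTPUT_TYPES}")
        values = np.asarray(self.values, dtype=float)
        if self.output_type in ("cdf", "pval"):
            if np.any(values < 0) or np.any(values > 1):
                raise InvalidInputError(f"{self.output_type} values must lie in [0, 1]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "set_names", tuple(self.set_names))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.set_names))


def permute_taxa(table: CompositionTable, seed) -> CompositionTable:
    """Apply one uniform random reordering of the columns to all samples.

    Taxon identifiers keep their original positions, so each identifier now
    labels another taxon's abundances: scoring a fixed set on the permuted
    table is scoring a random set of the same size on the original data.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n_taxa)
    return CompositionTable(table.values[:, perm], table.sample_ids, table.taxon_ids)


def fit_normal(scores) -> NormalParams:
    """Maximum-likelihood normal fit: sample mean and 1/N-variance sd."""
    x = np.asarray(scores, dtype=float).ravel()
    if x.size < 2:
        raise InvalidInputError("need at least 2 scores to fit a normal")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("scores must be finite")
    mu = float(np.mean(x))
    sigma = float(np.std(x))  # ddof=0: the MLE
    if sigma == 0.0:
        raise DegenerateFitError("all scores identical; normal fit degenerate")
    return NormalParams(mu, sigma)


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(x, mu, sigma):
    # inlined normal log-density: the EM inner loop is the hot path
    z = (x - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI


def _em_once(x, w1, mu1, s1, mu2, s2, max_iter, tol):
    """Vectorized EM for a univariate 2-component Gaussian mixture."""
    n = x.size
    ll_old = -np.inf
    converged = False
    ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        log_p1 = np.log(w1) + _norm_logpdf(x, mu1, s1)
        log_p2 = np.log1p(-w1) + _norm_logpdf(x, mu2, s2)
        log_norm = np.logaddexp(log_p1, log_p2)
        ll = float(np.sum(log_norm))
        r1 = np.exp(log_p1 - log_norm)
        n1 = r1.sum()
        n2 = n - n1
        if n1 < 1e-10 or n2 < 1e-10:
            break  # one component emptied out; caller flags degeneracy
        w1 = n1 / n
        mu1 = float(np.dot(r1, x) / n1)
        mu2 = float(np.dot(1.0 - r1, x) / n2)
        s1 = float(np.sqrt(np.dot(r1, (x - mu1) ** 2) / n1))
        s2 = float(np.sqrt(np.dot(1.0 - r1, (x - mu2) ** 2) / n2))
        s1 = max(s1, 1e-12)
        s2 = max(s2, 1e-12)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return w1, mu1, s1, mu2, s2, ll, converged, it


def fit_mixture2(scores, seed=0, max_iter: int = 1000, tol: float = 1e-6,
                 n_init: int = 3) -> Mixture2Params:
    """EM fit of a two-component Gaussian mixture, best of seeded restarts.

    The first start splits the data at the median and uses each half's
    moments; further starts jitter the component means.  Convergence is
    declared when the log-likelihood improves by less than ``tol``; hitting
    ``max_iter`` is flagged in the result, not fatal, since heavily
    overlapping components converge slowly.  Components are returned sorted
    by ascending mean so the fit is invariant to label swaps.
    """
    x = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("scores must be finite")
    if x.size < 10:
        raise InvalidInputError("need at least 10 scores for a mixture fit")
    rng = np.random.default_rng(seed)
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # massive ties at the median
        lo, hi = x, x
    sd = float(np.std(x)) or 1.0
    starts = [(0.5, float(np.mean(lo)), max(float(np.std(lo)), 1e-3 * sd),
               float(np.mean(hi)), max(float(np.std(hi)), 1e-3 * sd))]
    for _ in range(n_init - 1):
        m1, m2 = sorted(rng.normal(np.mean(x), sd, size=2))
        starts.append((0.5, m1, sd, m2, sd))

    # short-run selection: burn each start in briefly, then run only the
    # best-scoring one to convergence
    burn_in = min(25, max_iter)
    best = None
    for w1, mu1, s1, mu2, s2 in starts:
        fit = _em_once(x, w1, mu1, s1, mu2, s2, burn_in, tol)
        if best is None or fit[5] > best[5]:
            best = fit
    w1, mu1, s1, mu2, s2, ll, converged, it = best
    if not converged and max_iter > burn_in:
        w1, mu1, s1, mu2, s2, ll, converged, it2 = _em_once(
            x, w1, mu1, s1, mu2, s2, max_iter - burn_in, tol)
        it += it2
    if mu1 > mu2:
        w1, mu1, s1, mu2, s2 = 1.0 - w1, mu2, s2, mu1, s1
    w1 = float(np.clip(w1, 1e-12, 1 - 1e-12))
    return Mixture2Params(w1, mu1, s1, 1.0 - w1, mu2, s2,
                          converged=converged, loglik=ll, n_iter=it)


def _is_degenerate(fit: Mixture2Params) -> bool:
    return (min(fit.w1, fit.w2) < 0.01
            or min(fit.sigma1, fit.sigma2) < 1e-8
            or not np.isfinite(fit.loglik))


def _fit_family(x, family, seed):
    if family == "normal":
        return fit_normal(x), {"converged": True, "fallback": False}
    fit = fit_mixture2(x, seed=seed)
    if _is_degenerate(fit):
        # collapse to the single-normal fit rather than report an
        # unidentifiable mixture
        norm = fit_normal(x)
        return norm, {"converged": fit.converged, "fallback": True,
                      "loglik": fit.loglik}
    return fit, {"converged": fit.converged, "fallback": False,
                 "loglik": fit.loglik, "n_iter": fit.n_iter}


def _swap_spread(perm_fit, unperm_fit):
    """Keep location/weights of the permuted fit, spread of the unpermuted one."""
    if isinstance(perm_fit, NormalParams) and isinstance(unperm_fit, NormalParams):
        return NormalParams(perm_fit.mu, unperm_fit.sigma)
    if isinstance(perm_fit, Mixture2Params) and isinstance(unperm_fit, Mixture2Params):
        # both fits are already ordered by ascending mean, which is the
        # component-matching rule
        return dc_replace(perm_fit, sigma1=unperm_fit.sigma1,
                          sigma2=unperm_fit.sigma2)
    # mixed kinds arise when one side fell back to a normal fit; match
    # on the overall spread instead
    perm_sig = (perm_fit.sigma if isinstance(perm_fit, NormalParams)
                else None)
    if isinstance(unperm_fit, NormalParams):
        unperm_sigma = unperm_fit.sigma
        if perm_sig is not None:
            return NormalParams(perm_fit.mu, unperm_sigma)
        return dc_replace(perm_fit, sigma1=unperm_sigma, sigma2=unperm_sigma)
    # permuted side is normal, unpermuted is a mixture: use the mixture's
    # total sd as the spread
    m = unperm_fit.w1 * unperm_fit.mu1 + unperm_fit.w2 * unperm_fit.mu2
    var = (unperm_fit.w1 * (unperm_fit.sigma1 ** 2 + (unperm_fit.mu1 - m) ** 2)
           + unperm_fit.w2 * (unperm_fit.sigma2 ** 2 + (unperm_fit.mu2 - m) ** 2))
    return NormalParams(perm_fit.mu, float(np.sqrt(var)))


def pooled_permutation_scores(table: CompositionTable, sets: SetCollection,
                              n_perm: int, seed) -> np.ndarray:
    """Null scores of every set under ``n_perm`` taxa permutations, pooled.

    Returns an ``(n * n_perm) x m`` matrix: rows ``r*n:(r+1)*n`` hold the
    scores of permutation replicate ``r``.  Permuting the table's columns and
    scoring a set is the same as scoring the permuted set indices on the
    original table, so the log transform is applied once, not once per
    permutation.
    """
    if np.any(table.values <= 0):
        raise InvalidInputError(
            "table must be strictly positive; apply replace_zeros first")
    rng = np.random.default_rng(seed)
    n, m = table.n_samples, sets.n_sets
    L = np.log(table.values)
    row_sum = L.sum(axis=1)
    p = table.n_taxa
    K = sets.set_sizes.astype(float)
    coef = np.sqrt(K * (p - K) / p)
    set_idx = [np.flatnonzero(sets.membership[:, k]) for k in range(m)]
    pooled = np.empty((n * n_perm, m))
    for r in range(n_perm):
        perm = rng.permutation(p)
        for k in range(m):
            in_sum = L[:, perm[set_idx[k]]].sum(axis=1)
            pooled[r * n:(r + 1) * n, k] = coef[k] * (
                in_sum / K[k] - (row_sum - in_sum) / (p - K[k]))
    return pooled


def build_null(table: CompositionTable, sets: SetCollection, family: str = "mixture2",
               adjust: bool = False, n_perm: int = 100, seed=None) -> NullModel:
    """Fit the per-set empirical null from pooled taxa-permutation scores.

    For each set, ``n_perm`` independent column permutations yield
    ``n * n_perm`` null scores which are pooled and fitted with ``family``.
    With ``adjust=True`` the same family is additionally fitted to the set's
    unpermuted scores and the spread parameters of the permuted fit are
    replaced by the unpermuted ones (components matched by ascending mean for
    the mixture), retaining the variance inflation that inter-taxa
    correlation induces.  The table must be strictly positive and closed.
    """
    if family not in FAMILIES:
        raise InvalidInputError(f"family must be one of {FAMILIES}")
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n, m = table.n_samples, sets.n_sets
    pooled = pooled_permutation_scores(table, sets, n_perm, rng)
    unperm = score_matrix(table, sets).values if adjust else None

    params, diags = [], []
    for k, name in enumerate(sets.set_names):
        fit_seed = int(rng.integers(2 ** 31))
        try:
            perm_fit, diag = _fit_family(pooled[:, k], family, fit_seed)
        except DegenerateFitError as exc:
            params.append(None)
            diags.append({"set": name, "error": str(exc)})
            logger.warning("null fit failed for set %r: %s", name, exc)
            continue
        diag = {"set": name, **diag}
        if adjust:
            try:
                unperm_fit, udiag = _fit_family(unperm[:, k], family, fit_seed + 1)
                perm_fit = _swap_spread(perm_fit, unperm_fit)
                diag["unperm_converged"] = udiag["converged"]
                diag["unperm_fallback"] = udiag["fallback"]
            except DegenerateFitError as exc:
                diag["adjust_error"] = str(exc)
                logger.warning("adjustment failed for set %r (%s); "
                               "keeping unadjusted fit", name, exc)
        params.append(perm_fit)
        diags.append(diag)
    return NullModel(family=family, params=tuple(params), set_names=sets.set_names,
                     adjusted=adjust, n_perm=n_perm, diagnostics=tuple(diags))


def transform(raw: ScoreMatrix, null: NullModel | None, output_type: str) -> EnrichmentResult:
    """Map raw balance scores through the fitted null to the requested scale."""
    if output_type not in OUTPUT_TYPES:
        raise InvalidInputError(f"output_type must be one of {OUTPUT_TYPES}")
    if output_type == "raw":
        return EnrichmentResult(raw.values.copy(), raw.sample_ids, raw.set_names, "raw")
    if null is None:
        raise InvalidInputError(f"output_type {output_type!r} requires a null model")
    if raw.set_names != null.set_names:
        raise InvalidInputError("set names of the scores and null model differ")
    out = np.empty_like(raw.values)
    for k, par in enumerate(null.params):
        if par is None:
            raise DegenerateFitError(
                f"no usable null fit for set {null.set_names[k]!r}"
            )
        x = raw.values[:, k]
        if output_type == "zscore":
            out[:, k] = par.zscore(x)
        else:
            c = par.cdf(x)
            out[:, k] = c if output_type == "cdf" else 1.0 - c
    return EnrichmentResult(out, raw.sample_ids, raw.set_names, output_type,
                            null_model=null)


def cbea(table: CompositionTable, sets: SetCollection, family: str = "mixture2",
         adjust: bool = False, output_type: str = "cdf", n_perm: int = 100,
         pseudocount: float = 1e-5, seed=None) -> EnrichmentResult:
    """End-to-end enrichment scoring.

    Pipeline: zero replacement -> closure -> balance scores -> empirical null
    (skipped for ``output_type='raw'``) -> transform.  Deterministic for a
    fixed ``seed``.
    """
    prepped = closure(replace_zeros(table, pseudocount))
    raw = score_matrix(prepped, sets)
    if output_type == "raw":
        return transform(raw, None, "raw")
    null = build_null(prepped, sets, family=family, adjust=adjust,
                      n_perm=n_perm, seed=seed)
    return transform(raw, null, output_type)
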