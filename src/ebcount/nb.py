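"""Negative-binomial likelihoods and Monte-Carlo marginal likelihoods.

Parametrization: a count u in a library of size l, with rate mu (mean per
unit library size) and dispersion phi, has mean m = l*mu and variance
m*(1 + m*phi). phi = 0 is the Poisson limit. Writing r = 1/phi,

    log P(u; l, phi, mu) = lgamma(u + r) - lgamma(r) - lgamma(u + 1)
                           + u*(log m - log(m + r)) - r*log1p(m/r)

The marginal likelihood of a tuple under a model M partitioning the samples
into sets E_1..E_m is approximated by averaging the within-set likelihood
over an empirical sample Theta_q of (mu, phi) pairs, independently per set:

    P(D_c | M) ~= prod_q (1/|Theta_q|) sum_{theta in Theta_q}
                  prod_{i in E_q} P(u_ic; l_i, theta)

All arithmetic is carried out in log space with log-sum-exp; the product
form underflows for realistic prior sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .data import CountData, ModelDefinition

__all__ = ["NBParams", "PriorSample", "nb_log_pmf", "marginal_likelihood",
           "marginal_log_likelihoods"]


@dataclass(frozen=True)
class NBParams:
    """Mean rate per unit library size and dispersion of one NB distribution."""

    mu: float
    phi: float

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")


@dataclass
class PriorSample:
    """Empirical prior Theta_q for every set of one model.

    ``mus[q]`` holds the sampled per-set mean rates mu_qc (one entry per
    sampled tuple) for set q of ``model``; ``phis`` holds the matching
    dispersions phi_c, shared across sets because each sampled tuple
    contributes one jointly-estimated (mu_1c..mu_mc, phi_c) record.
    ``provenance`` records which data tuples the pairs came from.
    """

    model: ModelDefinition
    mus: list[np.ndarray]
    phis: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.phis = np.asarray(self.phis, dtype=float)
        self.mus = [np.asarray(m, dtype=float) for m in self.mus]
        n = self.phis.shape[0]
        if n < 1:
            raise ValueError("prior sample must contain at least one pair")
        if len(self.mus) != self.model.n_sets:
            raise ValueError("one mu vector required per model set")
        for q, m in enumerate(self.mus):
            if m.shape != (n,):
                raise ValueError(
                    f"mu sample for set {q} has size {m.shape}, expected {n}"
                )
            if not np.all(m > 0):
                raise ValueError(f"mu sample for set {q} must be positive")
        if np.any(self.phis < 0):
            raise ValueError("dispersions must be >= 0")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance)

    @property
    def size(self) -> int:
        return self.phis.shape[0]


def nb_log_pmf(u, lib_size, params: NBParams | None = None, *, mu=None, phi=None):
    """Log pmf of the NB distribution with mean ``lib_size*mu``.

    Accepts either an :class:`NBParams` or explicit ``mu``/``phi`` keyword
    arrays (broadcast together). ``phi = 0`` evaluates the exact Poisson
    log-pmf rather than a small-phi NB approximation.
    """
    if params is not None:
        mu, phi = params.mu, params.phi
    u = np.asarray(u)
    if np.any(u < 0) or np.any(u != np.floor(u)):
        raise ValueError("u must be a non-negative integer")
    u = u.astype(np.int64)
    lib_size = np.asarray(lib_size, dtype=float)
    if np.any(lib_size <= 0):
        raise ValueError("lib_size must be positive")
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)

    m = lib_size * mu
    u_b, m_b, phi_b = np.broadcast_arrays(u, m, phi)
    out = np.empty(u_b.shape, dtype=float)

    pois = phi_b == 0.0
    if np.any(pois):
        up, mp = u_b[pois], m_b[pois]
        out[pois] = up * np.log(mp) - mp - gammaln(up + 1.0)
    nb = ~pois
    if np.any(nb):
        un, mn, r = u_b[nb], m_b[nb], 1.0 / phi_b[nb]
        out[nb] = (
            gammaln(un + r) - gammaln(r) - gammaln(un + 1.0)
            + un * (np.log(mn) - np.log(mn + r))
            - r * np.log1p(mn / r)
        )
    return out if out.ndim else float(out)


def _set_log_matrix(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    mus: np.ndarray,
    phis: np.ndarray,
) -> np.ndarray:
    """Joint log-likelihood of one model set for every (tuple, prior pair).

    Parameters: ``counts`` (C, k) for the k samples of the set,
    ``lib_sizes`` (k,), ``mus``/``phis`` (T,). Returns (C, T) with entry
    sum over the set's samples of nb_log_pmf(u_ic; l_i, mu_t, phi_t).

    The only genuinely two-dimensional special-function work is
    lgamma(u + 1/phi); counts repeat heavily, so it is evaluated on the
    unique counts of each column and gathered. The u*log(...) term is a
    matrix product.
    """
    C, k = counts.shape
    T = mus.shape[0]
    out = np.zeros((C, T))

    pois = phis == 0.0
    nb = ~pois
    m = lib_sizes[None, :] * mus[:, None]  # (T, k)

    if np.any(nb):
        r = 1.0 / phis[nb]  # (Tn,)
        m_nb = m[nb]  # (Tn, k)
        # u-by-column lgamma via unique counts
        acc = np.zeros((C, r.shape[0]))
        for j in range(k):
            uu, inv = np.unique(counts[:, j], return_inverse=True)
            g = gammaln(uu[:, None] + r[None, :])  # (U, Tn)
            acc += g[inv]
        # per-t terms independent of u
        const_t = -k * gammaln(r) - np.sum(r[:, None] * np.log1p(m_nb / r[:, None]), axis=1)
        # u * (log m - log(m + r)) summed over columns: matmul
        w = (np.log(m_nb) - np.log(m_nb + r[:, None])).T  # (k, Tn)
        acc += counts @ w
        acc += const_t[None, :]
        acc -= np.sum(gammaln(counts + 1.0), axis=1)[:, None]
        out[:, nb] = acc

    if np.any(pois):
        m_p = m[pois]  # (Tp, k)
        ll = counts @ np.log(m_p).T  # (C, Tp)
        ll -= np.sum(m_p, axis=1)[None, :]
        ll -= np.sum(gammaln(counts + 1.0), axis=1)[:, None]
        out[:, pois] = ll
    return out


def marginal_log_likelihoods(
    data: CountData,
    model: ModelDefinition,
    priors: PriorSample,
    chunk_size: int = 4096,
) -> np.ndarray:
    """Log marginal likelihood log P(D_c | M) for every tuple of ``data``.

    Monte-Carlo average over the empirical prior, performed independently
    per model set and combined in log space. Tuples are processed in
    chunks to bound the (chunk, |Theta|) working matrices.
    """
    if priors.model.sets != model.sets:
        raise ValueError("prior sample was built for a different model")
    T = priors.size
    logT = np.log(T)
    C = data.n_tuples
    phis_by_set = getattr(priors, "phis_by_set", None)
    out = np.zeros(C)
    for start in range(0, C, chunk_size):
        stop = min(C, start + chunk_size)
        total = np.zeros(stop - start)
        for q, s in enumerate(model.sets):
            idx = list(s)
            mat = _set_log_matrix(
                data.counts[start:stop, idx],
                data.lib_sizes[idx],
                priors.mus[q],
                priors.phis if phis_by_set is None else phis_by_set[q],
            )
            total += logsumexp(mat, axis=1) - logT
        out[start:stop] = total
    return out


def marginal_likelihood(
    tuple_counts,
    lib_sizes,
    model: ModelDefinition,
    priors: PriorSample,
) -> float:
    """Log marginal likelihood of a single tuple under one model.

    ``tuple_counts`` is the tuple's count vector across all samples.
    """
    counts = np.atleast_2d(np.asarray(tuple_counts, dtype=np.int64))
    data = CountData(counts=counts, lib_sizes=np.asarray(lib_sizes, dtype=float))
    return float(marginal_log_likelihoods(data, model, priors)[0])
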