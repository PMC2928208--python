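"""Empirical prior construction: per-tuple dispersion and per-set means.

For each sampled tuple the dispersion phi_c is estimated by quasi-likelihood:
phi_c is chosen so that the negative-binomial deviance, computed against the
per-replicate-group fitted means, equals n - 1 (n = number of samples).
Starting means are the within-group averages of u_ic/l_i; means and
dispersion are then refined alternately (maximum-likelihood means at fixed
phi, deviance root at fixed means) until the dispersion stabilises.

Holding phi_c fixed, the mean mu_qc of each model set E_q is then estimated
by maximum likelihood over the set's samples. Repeating over many sampled
tuples yields the empirical prior sample Theta_q = {(mu_qc, phi_c)} used by
the marginal-likelihood integral.

The deviance is monotone non-increasing in phi, so the root is unique when
it exists; tuples whose data are under-dispersed relative to the Poisson
(deviance below target even at phi_min) are clamped at phi_min, and
over-dispersion beyond phi_max is clamped at phi_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CountData, ModelDefinition, ReplicateStructure
from .nb import PriorSample

__all__ = [
    "TupleDispersionFit",
    "estimate_dispersion",
    "estimate_dispersions",
    "estimate_set_means",
    "build_priors",
    "PHI_MIN",
    "PHI_MAX",
    "MU_FLOOR",
]

PHI_MIN = 1e-6
PHI_MAX = 1e3
MU_FLOOR = 1e-8

_REL_TOL = 1e-4
_MAX_ITER = 50
_BISECT_ITER = 60


@dataclass
class TupleDispersionFit:
    """Quasi-likelihood dispersion fit for one tuple."""

    phi: float
    mu_hat: np.ndarray  # fitted mean rate per replicate group
    converged: bool
    iterations: int
    reason: str = "converged"


def _nb_deviance(counts, lib_sizes, mu_sample, phi):
    """NB deviance 2*sum[u log(u/(l*mu)) - (u+1/phi) log((u+1/phi)/(l*mu+1/phi))].

    ``counts`` (C, n), ``lib_sizes`` (n,), ``mu_sample`` (C, n) per-sample
    fitted means (the group mean expanded to its samples), ``phi`` (C,).
    Terms with u = 0 use the 0*log 0 = 0 convention; all-zero groups
    (mu = 0) contribute 0.
    """
    u = counts
    m = lib_sizes[None, :] * mu_sample
    r = 1.0 / phi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(u > 0, u * np.log(np.where(u > 0, u, 1) / np.where(m > 0, m, 1)), 0.0)
        ratio = (u + r) / (m + r)
        t2 = (u + r) * np.log(ratio)
    # mu = 0 only when every count in the group is 0: exact contribution 0
    t2 = np.where(m > 0, t2, 0.0)
    return 2.0 * np.sum(t1 - t2, axis=1)


def _ml_mean_groups(counts, lib_sizes, phi, group_cols):
    """Maximum-likelihood NB mean rate per group at fixed dispersion.

    Solves sum_i u_i = sum_i (u_i + 1/phi) * l_i*mu / (l_i*mu + 1/phi)
    for mu by bisection (the right side rises monotonically from 0 past
    the left side). phi = 0 rows use the closed form sum(u)/sum(l).
    Returns (C, n_groups); all-zero groups get mu = 0.
    """
    C = counts.shape[0]
    out = np.zeros((C, len(group_cols)))
    for g, cols in enumerate(group_cols):
        u = counts[:, cols]
        l = lib_sizes[list(cols)]
        usum = u.sum(axis=1).astype(float)
        pois_mu = usum / l.sum()
        mu = pois_mu.copy()
        active = (usum > 0) & (phi > 0)
        if np.any(active):
            ua = u[active]
            ra = 1.0 / phi[active]
            target = usum[active]
            lo = np.full(target.shape, np.log(1e-12))
            hi = np.log(np.max(ua / l[None, :], axis=1) + 1e-12)
            # right side at mu = max(u/l) already >= sum(u); bracket is valid
            for _ in range(_BISECT_ITER):
                mid = 0.5 * (lo + hi)
                mmid = np.exp(mid)[:, None] * l[None, :]
                rhs = np.sum((ua + ra[:, None]) * mmid / (mmid + ra[:, None]), axis=1)
                too_high = rhs > target
                hi = np.where(too_high, mid, hi)
                lo = np.where(too_high, lo, mid)
            mu[active] = np.exp(0.5 * (lo + hi))
        out[:, g] = mu
    return out


def _expand_groups(values, group_cols, n_samples):
    """Scatter per-group values (C, G) to per-sample columns (C, n)."""
    out = np.empty((values.shape[0], n_samples))
    for g, cols in enumerate(group_cols):
        out[:, list(cols)] = values[:, [g]]
    return out


def _solve_dispersion(counts, lib_sizes, mu_sample, target):
    """Root of deviance(phi) = target per tuple, clamped to [PHI_MIN, PHI_MAX].

    Returns (phi, reason codes): 0 root found, 1 clamped low (data
    under-dispersed), 2 clamped high.
    """
    C = counts.shape[0]
    phi = np.full(C, PHI_MIN)
    reason = np.zeros(C, dtype=np.int8)

    dev_lo = _nb_deviance(counts, lib_sizes, mu_sample, np.full(C, PHI_MIN))
    dev_hi = _nb_deviance(counts, lib_sizes, mu_sample, np.full(C, PHI_MAX))
    below = dev_lo <= target
    above = dev_hi >= target
    reason[below] = 1
    reason[above & ~below] = 2
    phi[above & ~below] = PHI_MAX

    active = ~(below | above)
    if np.any(active):
        lo = np.full(int(active.sum()), np.log(PHI_MIN))
        hi = np.full(int(active.sum()), np.log(PHI_MAX))
        ua, la, ma = counts[active], lib_sizes, mu_sample[active]
        for _ in range(_BISECT_ITER):
            mid = 0.5 * (lo + hi)
            dev = _nb_deviance(ua, la, ma, np.exp(mid))
            # deviance decreases in phi: dev > target means root is above mid
            go_up = dev > target
            lo = np.where(go_up, mid, lo)
            hi = np.where(go_up, hi, mid)
        phi[active] = np.exp(0.5 * (lo + hi))
    return phi, reason


def estimate_dispersions(
    data: CountData,
    reps: ReplicateStructure,
    indices: np.ndarray | None = None,
):
    """Batch quasi-likelihood dispersion fit for many tuples at once.

    Returns (phi (C,), mu_hat (C, n_groups), iterations, reason codes).
    """
    reps.validate(data.n_samples)
    counts = data.counts if indices is None else data.counts[indices]
    counts = counts.astype(float)
    lib = data.lib_sizes
    n = data.n_samples
    target = float(n - 1)
    group_cols = [list(g) for g in reps.groups]

    # starting means: within-group average of u/l
    ratios = counts / lib[None, :]
    mu = np.column_stack([ratios[:, cols].mean(axis=1) for cols in group_cols])

    phi = np.full(counts.shape[0], PHI_MIN)
    reason = np.zeros(counts.shape[0], dtype=np.int8)
    iterations = 0
    for iterations in range(1, _MAX_ITER + 1):
        mu_sample = _expand_groups(mu, group_cols, n)
        phi_new, reason = _solve_dispersion(counts, lib, mu_sample, target)
        delta = np.abs(phi_new - phi) / np.maximum(phi_new, 1e-6)
        phi = phi_new
        mu = _ml_mean_groups(counts, lib, phi, group_cols)
        if np.max(delta) < _REL_TOL:
            break
    return phi, mu, iterations, reason


_REASONS = {0: "converged", 1: "deviance below target at phi_min",
            2: "deviance above target at phi_max"}


def estimate_dispersion(tuple_counts, lib_sizes, reps: ReplicateStructure) -> TupleDispersionFit:
    """Quasi-likelihood dispersion estimate for a single tuple.

    Alternates solving the deviance equation for phi (at fixed group means)
    with maximum-likelihood re-estimation of the group means (at fixed phi)
    until phi stabilises.
    """
    counts = np.atleast_2d(np.asarray(tuple_counts, dtype=np.int64))
    data = CountData(counts=counts, lib_sizes=np.asarray(lib_sizes, dtype=float))
    phi, mu, iters, reason = estimate_dispersions(data, reps)
    code = int(reason[0])
    return TupleDispersionFit(
        phi=float(phi[0]),
        mu_hat=mu[0],
        converged=True if code else iters < _MAX_ITER,
        iterations=iters,
        reason=_REASONS[code] if code else ("converged" if iters < _MAX_ITER else "max iterations"),
    )


def estimate_set_means(
    tuple_counts, lib_sizes, model: ModelDefinition, phi: float
) -> np.ndarray:
    """ML mean rate mu_qc for each set of ``model`` at fixed dispersion.

    At phi = 0 this is the Poisson closed form sum(u)/sum(l); all-zero sets
    are floored at MU_FLOOR so the NB pmf stays defined.
    """
    counts = np.atleast_2d(np.asarray(tuple_counts, dtype=float))
    lib = np.asarray(lib_sizes, dtype=float)
    mus = _ml_mean_groups(
        counts, lib, np.asarray([phi], dtype=float), [list(s) for s in model.sets]
    )
    return np.maximum(mus[0], MU_FLOOR)


def _sample_indices(n_tuples: int, sample_size: int, seed) -> np.ndarray:
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if sample_size >= n_tuples:
        return np.arange(n_tuples)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_tuples, size=sample_size, replace=False))


def build_priors(
    data: CountData,
    model: ModelDefinition,
    reps: ReplicateStructure,
    sample_size: int = 5000,
    seed: int | None = 0,
    dispersion_by_set: bool = False,
) -> PriorSample:
    """Construct the empirical prior Theta_q for one model.

    Selects min(sample_size, n_tuples) tuples uniformly at random without
    replacement under ``seed`` (all tuples when sample_size covers them),
    fits each tuple's dispersion under the replicate structure, then the
    per-set maximum-likelihood means at that fixed dispersion.

    With ``dispersion_by_set`` the dispersion is instead re-estimated per
    model set from the set's own samples (replicate structure restricted to
    the set); the default shares one dispersion per tuple across all sets.
    """
    idx = _sample_indices(data.n_tuples, sample_size, seed)
    counts = data.counts[idx].astype(float)
    lib = data.lib_sizes
    group_cols_model = [list(s) for s in model.sets]

    if not dispersion_by_set:
        phi, _, _, _ = estimate_dispersions(data, reps, idx)
        mus = _ml_mean_groups(counts, lib, phi, group_cols_model)
        mus = [np.maximum(mus[:, q], MU_FLOOR) for q in range(model.n_sets)]
        return PriorSample(model=model, mus=mus, phis=phi, provenance=idx)

    # per-set variant: restrict data and replicate structure to each set
    mus = []
    phis_per_set = []
    for q, s in enumerate(model.sets):
        cols = list(s)
        if len(cols) < 2:
            # single-sample set: no residual df, dispersion pinned at floor
            phi_q = np.full(idx.shape[0], PHI_MIN)
        else:
            sub_groups = [
                [cols.index(i) for i in g if i in s] for g in reps.groups
            ]
            sub_groups = [g for g in sub_groups if g]
            sub = CountData(
                counts=data.counts[idx][:, cols], lib_sizes=lib[cols]
            )
            phi_q, _, _, _ = estimate_dispersions(
                sub, ReplicateStructure(sub_groups)
            )
        mu_q = _ml_mean_groups(counts, lib, phi_q, [cols])[:, 0]
        mus.append(np.maximum(mu_q, MU_FLOOR))
        phis_per_set.append(phi_q)
    return _PerSetPriorSample(
        model=model, mus=mus, phis=phis_per_set[0], provenance=idx,
        phis_by_set=phis_per_set,
    )


def build_priors_shared(
    data: CountData,
    models,
    reps: ReplicateStructure,
    sample_size: int = 5000,
    seed: int | None = 0,
) -> list[PriorSample]:
    """Empirical priors for several models from one shared dispersion pass.

    Equivalent to calling :func:`build_priors` per model with the same seed
    (the sampled tuples and their dispersions are identical across models);
    the per-tuple dispersion fit is simply computed once.
    """
    idx = _sample_indices(data.n_tuples, sample_size, seed)
    counts = data.counts[idx].astype(float)
    phi, _, _, _ = estimate_dispersions(data, reps, idx)
    out = []
    for model in models:
        mus = _ml_mean_groups(
            counts, data.lib_sizes, phi, [list(s) for s in model.sets]
        )
        out.append(
            PriorSample(
                model=model,
                mus=[np.maximum(mus[:, q], MU_FLOOR) for q in range(model.n_sets)],
                phis=phi,
                provenance=idx,
            )
        )
    return out


class _PerSetPriorSample(PriorSample):
    """Prior sample with set-specific dispersions (optional variant)."""

    def __init__(self, model, mus, phis, provenance, phis_by_set):
        super().__init__(model=model, mus=mus, phis=phis, provenance=provenance)
        self.phis_by_set = [np.asarray(p, dtype=float) for p in phis_by_set]
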