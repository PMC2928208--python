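"""Posterior probabilities of models and empirical model-prior estimation.

Given per-tuple log marginal likelihoods log P(D_c | M) for a finite set of
mutually exclusive models, Bayes' rule gives

    P(M | D_c) = P(D_c | M) P(M) / sum_M' P(D_c | M') P(M')

The model priors P(M) are estimated by iterating p' = <P(M | D_c)>_c — each
model's prior is replaced by its mean posterior across all tuples — until
the prior vector stabilises. Because models are mutually exclusive,
posteriors of any subset of models may be summed, e.g. all models describing
differential expression of any kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "PosteriorTable",
    "posterior_given_priors",
    "estimate_model_priors",
    "combine_models",
    "rank_tuples",
]


@dataclass
class PosteriorTable:
    """Per-tuple posterior probabilities of each model plus converged priors."""

    log_marginals: np.ndarray  # (tuples, models)
    model_priors: np.ndarray  # (models,)
    posteriors: np.ndarray  # (tuples, models)
    model_names: list[str]
    tuple_ids: np.ndarray
    iterations: int = 0
    converged: bool = True
    prior_history: list[np.ndarray] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.posteriors,
            index=pd.Index(self.tuple_ids, name="tuple_id"),
            columns=self.model_names,
        )

    def priors_series(self) -> pd.Series:
        return pd.Series(self.model_priors, index=self.model_names, name="prior")


def _check_priors(priors, n_models):
    p = np.asarray(priors, dtype=float)
    if p.shape != (n_models,):
        raise ValueError(f"expected {n_models} model priors, got shape {p.shape}")
    if np.any(p <= 0):
        raise ValueError("model priors must be positive")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("model priors must sum to 1")
    return p / p.sum()


def posterior_given_priors(log_marginals, model_priors, tuple_ids=None):
    """Posterior P(M | D_c) per tuple: softmax of log marginals plus log priors.

    Rows sum to 1 exactly (up to float rounding). A tuple whose marginal is
    -inf under every model has an undefined posterior and raises.
    """
    lm = np.atleast_2d(np.asarray(log_marginals, dtype=float))
    p = _check_priors(model_priors, lm.shape[1])
    z = lm + np.log(p)[None, :]
    norm = logsumexp(z, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        which = np.nonzero(bad)[0]
        label = tuple_ids[which[0]] if tuple_ids is not None else which[0]
        raise ValueError(
            f"tuple {label!r} has zero marginal likelihood under every model"
        )
    return np.exp(z - norm[:, None])


def estimate_model_priors(
    log_marginals,
    model_names=None,
    tuple_ids=None,
    init_priors=None,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> PosteriorTable:
    """Estimate model priors as converged mean posteriors across tuples.

    Starting from ``init_priors`` (uniform by default), alternately computes
    posteriors at the current priors and replaces each prior by the mean
    posterior of its model, until the largest prior change drops below
    ``tol``. The trajectory is recorded in ``prior_history`` — a steadily
    drifting trajectory is the positive-feedback diagnostic worth inspecting.
    """
    lm = np.atleast_2d(np.asarray(log_marginals, dtype=float))
    C, M = lm.shape
    if model_names is None:
        model_names = [f"M{j}" for j in range(M)]
    if tuple_ids is None:
        tuple_ids = np.arange(C)
    p = (
        np.full(M, 1.0 / M)
        if init_priors is None
        else _check_priors(init_priors, M)
    )
    history = [p.copy()]
    converged = False
    post = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        post = posterior_given_priors(lm, p, tuple_ids)
        p_new = post.mean(axis=0)
        # keep priors strictly positive so log P(M) stays finite
        p_new = np.clip(p_new, 1e-12, None)
        p_new = p_new / p_new.sum()
        history.append(p_new.copy())
        delta = np.max(np.abs(p_new - p))
        p = p_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"model-prior iteration did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    post = posterior_given_priors(lm, p, tuple_ids)
    return PosteriorTable(
        log_marginals=lm,
        model_priors=p,
        posteriors=post,
        model_names=list(model_names),
        tuple_ids=np.asarray(tuple_ids),
        iterations=iterations,
        converged=converged,
        prior_history=history,
    )


def combine_models(table: PosteriorTable, model_subset) -> pd.Series:
    """Sum posterior columns of a subset of (mutually exclusive) models.

    Summing all models that describe differential expression yields the
    per-tuple probability of differential expression of any type.
    """
    subset = list(model_subset)
    if not subset:
        raise ValueError("model subset must be non-empty")
    idx = []
    for name in subset:
        if name not in table.model_names:
            raise KeyError(f"unknown model {name!r}")
        idx.append(table.model_names.index(name))
    combined = table.posteriors[:, idx].sum(axis=1)
    return pd.Series(
        combined, index=pd.Index(table.tuple_ids, name="tuple_id"),
        name="+".join(subset),
    )


def rank_tuples(probabilities, tuple_ids=None, descending: bool = True):
    """Order tuple ids by probability; ties broken lexicographically by id.

    Accepts a pandas Series (ids from its index) or an array plus
    ``tuple_ids``. Returns a DataFrame with columns tuple_id, score, rank.
    """
    if isinstance(probabilities, pd.Series):
        ids = probabilities.index.to_numpy(dtype=object)
        scores = probabilities.to_numpy(dtype=float)
    else:
        scores = np.asarray(probabilities, dtype=float)
        ids = (
            np.asarray(tuple_ids, dtype=object)
            if tuple_ids is not None
            else np.arange(scores.shape[0]).astype(object)
        )
    # lexsort: last key is primary; ids ascending break ties deterministically
    key = -scores if descending else scores
    order = np.lexsort((ids.astype(str), key))
    return pd.DataFrame(
        {
            "tuple_id": ids[order],
            "score": scores[order],
            "rank": np.arange(1, scores.shape[0] + 1),
        }
    )
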