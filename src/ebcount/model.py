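"""Model/Results interface for the empirical Bayes count analysis.

:class:`EmpiricalBayesNB` bundles a count table with an experimental
structure (condition labels, replicate groups, candidate models of
differential expression). Its :meth:`~EmpiricalBayesNB.fit` runs the full
pipeline — empirical prior sampling, Monte-Carlo marginal likelihoods,
iterative model-prior estimation — and returns an
:class:`EmpiricalBayesNBResults` holding per-tuple posterior probabilities
of every model.

Example
-------
>>> from ebcount import EmpiricalBayesNB, simulate_pairwise_random_dispersion
>>> sim = simulate_pairwise_random_dispersion(SimulationConfig(
...     n_tuples=1000, n_libs=(2, 2), fold=8, seed=11))
>>> res = EmpiricalBayesNB(sim.data, conditions=["A", "A", "B", "B"]).fit(
...     prior_sample_size=500, seed=1)
>>> res.prob_de().head()
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    CountData,
    ModelDefinition,
    ReplicateStructure,
    enumerate_models,
    validate_model,
)
from .nb import PriorSample, marginal_log_likelihoods
from .posterior import (
    PosteriorTable,
    combine_models,
    estimate_model_priors,
    posterior_given_priors,
    rank_tuples,
)
from .priors import build_priors_shared

__all__ = ["EmpiricalBayesNB", "EmpiricalBayesNBResults"]


class EmpiricalBayesNB:
    """Empirical Bayes negative-binomial model selection for count tuples.

    Parameters
    ----------
    data : CountData
        Counts and library sizes.
    conditions : sequence, optional
        One condition label per sample. Candidate models default to every
        set partition of the distinct conditions (minus ``exclusions``);
        replicate groups default to samples sharing a condition.
    models : list of ModelDefinition, optional
        Explicit candidate models; overrides enumeration.
    replicates : ReplicateStructure, optional
        Replicate grouping used for dispersion estimation.
    exclusions : list of condition partitions, optional
        Biologically implausible patterns to drop from the enumeration.
    """

    def __init__(
        self,
        data: CountData,
        conditions: Sequence | None = None,
        models: list[ModelDefinition] | None = None,
        replicates: ReplicateStructure | None = None,
        exclusions=None,
    ):
        self.data = data
        self.conditions = list(conditions) if conditions is not None else None
        if models is None:
            if self.conditions is None:
                raise ValueError("provide either conditions or explicit models")
            if len(self.conditions) != data.n_samples:
                raise ValueError(
                    f"expected {data.n_samples} condition labels, "
                    f"got {len(self.conditions)}"
                )
            models = enumerate_models(self.conditions, exclude=exclusions)
        self.models = [validate_model(m, data.n_samples) for m in models]
        if len({m.name for m in self.models}) != len(self.models):
            raise ValueError("model names must be unique")
        if replicates is None:
            if self.conditions is None:
                raise ValueError("provide either conditions or replicates")
            replicates = ReplicateStructure.from_labels(self.conditions)
        self.replicates = replicates.validate(data.n_samples)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        conditions: Sequence,
        lib_sizes=None,
        **kwargs,
    ) -> "EmpiricalBayesNB":
        """Build from a tuples-by-samples DataFrame.

        Library sizes default to column totals.
        """
        return cls(
            CountData.from_dataframe(df, lib_sizes=lib_sizes),
            conditions=conditions,
            **kwargs,
        )

    @property
    def null_model(self) -> ModelDefinition | None:
        """The single-set (no differential expression) model, if present."""
        for m in self.models:
            if m.n_sets == 1:
                return m
        return None

    def fit(
        self,
        prior_sample_size: int = 5000,
        seed: int | None = 0,
        model_priors=None,
        tol: float = 1e-5,
        max_iter: int = 1000,
        chunk_size: int = 4096,
    ) -> "EmpiricalBayesNBResults":
        """Run the empirical Bayes analysis.

        Parameters
        ----------
        prior_sample_size : int
            Number of tuples sampled to form the empirical prior |Theta_q|.
        seed : int
            Seed for the prior tuple subsample (the only randomness).
        model_priors : array, optional
            Fixed model priors P(M); skips the mean-posterior iteration.
        tol, max_iter
            Convergence control for the prior iteration.
        """
        priors = build_priors_shared(
            self.data,
            self.models,
            self.replicates,
            sample_size=prior_sample_size,
            seed=seed,
        )
        lm = np.column_stack(
            [
                marginal_log_likelihoods(self.data, m, p, chunk_size=chunk_size)
                for m, p in zip(self.models, priors)
            ]
        )
        names = [m.name for m in self.models]
        if model_priors is not None:
            p = np.asarray(model_priors, dtype=float)
            post = posterior_given_priors(lm, p, self.data.tuple_ids)
            table = PosteriorTable(
                log_marginals=lm,
                model_priors=p / p.sum(),
                posteriors=post,
                model_names=names,
                tuple_ids=self.data.tuple_ids,
                iterations=0,
                converged=True,
                prior_history=[p / p.sum()],
            )
        else:
            table = estimate_model_priors(
                lm,
                model_names=names,
                tuple_ids=self.data.tuple_ids,
                tol=tol,
                max_iter=max_iter,
            )
        return EmpiricalBayesNBResults(
            model=self, table=table, prior_samples=priors,
            prior_sample_size=min(prior_sample_size, self.data.n_tuples),
            seed=seed,
        )


@dataclass
class EmpiricalBayesNBResults:
    """Posterior probabilities of each candidate model for every tuple."""

    model: EmpiricalBayesNB
    table: PosteriorTable
    prior_samples: list[PriorSample] = field(repr=False, default=None)
    prior_sample_size: int = 0
    seed: int | None = None

    @property
    def posteriors(self) -> pd.DataFrame:
        """Tuples-by-models posterior probabilities (rows sum to 1)."""
        return self.table.to_frame()

    @property
    def model_priors(self) -> pd.Series:
        return self.table.priors_series()

    @property
    def log_marginals(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.table.log_marginals,
            index=pd.Index(self.table.tuple_ids, name="tuple_id"),
            columns=self.table.model_names,
        )

    @property
    def converged(self) -> bool:
        return self.table.converged

    @property
    def iterations(self) -> int:
        return self.table.iterations

    @property
    def prior_history(self) -> pd.DataFrame:
        return pd.DataFrame(self.table.prior_history, columns=self.table.model_names)

    def combine(self, model_subset) -> pd.Series:
        """Summed posterior probability of a subset of models per tuple."""
        return combine_models(self.table, model_subset)

    def prob_de(self) -> pd.Series:
        """Probability of differential expression of any type.

        The posterior sum of every model except the single-set (no-DE)
        model.
        """
        null = self.model.null_model
        if null is None:
            raise ValueError("no single-set model among the candidates")
        subset = [n for n in self.table.model_names if n != null.name]
        s = self.combine(subset)
        s.name = "any_de"
        return s

    def rank_by(self, what: str = "any_de") -> pd.DataFrame:
        """Ranked tuple list by a model's posterior or by ``"any_de"``."""
        if what == "any_de":
            return rank_tuples(self.prob_de())
        if what not in self.table.model_names:
            raise KeyError(f"unknown model {what!r}")
        return rank_tuples(self.posteriors[what])

    def expected_de_count(self) -> float:
        """Expected number of tuples showing any differential expression."""
        return float(self.prob_de().sum())

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        d = self.model.data
        lines = [
            "Empirical Bayes NB model selection",
            "==================================",
            f"tuples: {d.n_tuples}    samples: {d.n_samples}    "
            f"models: {len(self.model.models)}",
            f"prior sample size |Theta|: {self.prior_sample_size}"
            f"    seed: {self.seed}",
            f"prior iterations: {self.iterations}"
            f"    converged: {self.converged}",
            "",
            "model priors P(M) and expected tuple counts:",
        ]
        for name, p in self.model_priors.items():
            lines.append(f"  {name:<30s} {p:8.4f}   ({p * d.n_tuples:9.1f} tuples)")
        if self.model.null_model is not None:
            lines.append("")
            lines.append(
                f"expected differentially expressed tuples: "
                f"{self.expected_de_count():.1f}"
            )
        return "\n".join(lines)

    def to_tsv(self, path, include_counts: bool = False, combined: dict | None = None):
        """Write the posterior table as TSV.

        Converged priors appear as ``# prior:<model>=<value>`` header
        comments; ``combined`` maps extra column names to model subsets.
        Adds an ``any_de`` column automatically when a no-DE model exists.
        """
        df = self.posteriors.copy()
        if include_counts:
            df = pd.concat([self.model.data.to_dataframe(), df], axis=1)
        if combined is None and self.model.null_model is not None:
            combined = {"any_de": [
                n for n in self.table.model_names
                if n != self.model.null_model.name
            ]}
        for col, subset in (combined or {}).items():
            df[col] = combine_models(self.table, subset).to_numpy()
        with open(path, "w", encoding="utf-8") as fh:
            for name, p in self.model_priors.items():
                fh.write(f"# prior:{name}={p:.10g}\n")
            df.to_csv(fh, sep="\t", float_format="%.10g")
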