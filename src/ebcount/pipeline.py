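"""End-to-end runs: analyze a counts table, or simulate-and-benchmark.

``run_analysis`` composes the pipeline: model enumeration, empirical prior
sampling, marginal likelihoods, model-prior iteration, posterior TSV and a
machine-readable run manifest. ``run_benchmark`` loops simulate -> analyze ->
rank -> FDR/ROC over seeded replicates and writes mean curves with standard
errors plus a false-positive summary at chosen depths. All randomness flows
from the config seed, so re-runs are byte-identical.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np

from . import __version__
from .evaluate import fdr_curve, mean_curves, roc_curve
from .io import RunConfig, read_counts
from .model import EmpiricalBayesNB
from .simulate import (
    SimulationConfig,
    simulate_fixed_dispersion,
    simulate_pairwise_random_dispersion,
    simulate_three_group,
)

__all__ = ["run_analysis", "run_benchmark", "replicate_seeds", "DESIGNS"]

DESIGNS = {
    "pairwise_random": simulate_pairwise_random_dispersion,
    "fixed_dispersion": simulate_fixed_dispersion,
    "three_group": simulate_three_group,
}


def _log(msg: str) -> None:
    print(f"[ebcount] {msg}", file=sys.stderr)


def replicate_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def _write_manifest(outdir: Path, config: RunConfig, extra: dict) -> None:
    manifest = {"ebcount_version": __version__, "config": config.to_dict()}
    manifest.update(extra)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
    )


def run_analysis(config: RunConfig):
    """Analyze a counts TSV and write posteriors + manifest to the outdir."""
    if not config.counts:
        raise ValueError("config.counts (path to counts TSV) is required")
    if not config.conditions:
        raise ValueError("config.conditions (one label per sample) is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    data = read_counts(config.counts, lib_sizes_path=config.lib_sizes)
    _log(f"read {data.n_tuples} tuples x {data.n_samples} samples from {config.counts}")
    eb = EmpiricalBayesNB(
        data, conditions=config.conditions, exclusions=config.exclusions or None
    )
    _log(f"candidate models: {[m.name for m in eb.models]}")
    res = eb.fit(
        prior_sample_size=config.sample_size,
        seed=config.seed,
        tol=config.prior_tol,
        max_iter=config.prior_max_iter,
    )
    _log(
        f"prior iteration: {res.iterations} steps, converged={res.converged}; "
        "priors "
        + ", ".join(f"{n}={p:.4f}" for n, p in res.model_priors.items())
    )
    res.to_tsv(outdir / "posteriors.tsv")
    _write_manifest(
        outdir,
        config,
        {
            "mode": "analyze",
            "models": [m.name for m in eb.models],
            "model_priors": {
                n: float(p) for n, p in res.model_priors.items()
            },
            "prior_iterations": res.iterations,
            "prior_converged": bool(res.converged),
            "prior_sample_size": res.prior_sample_size,
        },
    )
    return res


def _simulate(config: RunConfig, seed: int):
    if config.design not in DESIGNS:
        raise ValueError(
            f"unknown design {config.design!r}; choose from {sorted(DESIGNS)}"
        )
    sim_cfg = SimulationConfig(
        n_tuples=config.n_tuples,
        n_libs=tuple(config.n_libs),
        fold=config.fold,
        de_fraction=config.de_fraction,
        dispersion=config.dispersion,
        seed=seed,
    )
    return DESIGNS[config.design](sim_cfg)


def run_simulation(config: RunConfig):
    """Simulate one dataset and write counts + truth TSVs to the outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = _simulate(config, config.seed)
    sim.write(outdir / "counts.tsv", outdir / "truth.tsv")
    _write_manifest(outdir, config, {"mode": "simulate"})
    _log(f"wrote {sim.data.n_tuples} tuples to {outdir / 'counts.tsv'}")
    return sim


def analyze_simulated(sim, sample_size: int, seed: int, tol: float = 1e-5,
                      max_iter: int = 1000):
    """Fit the empirical Bayes model to a simulated dataset."""
    eb = EmpiricalBayesNB(sim.data, conditions=sim.conditions)
    return eb.fit(prior_sample_size=sample_size, seed=seed, tol=tol,
                  max_iter=max_iter)


def run_benchmark(config: RunConfig) -> dict:
    """Replicate simulate -> analyze -> rank -> curves; write averages.

    Writes per-replicate and mean FDR/ROC curves (TSV) for the any-DE
    ranking and a summary table of mean false-positive counts at the
    requested depths. Returns the summary as a dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = replicate_seeds(config.seed, 2 * config.replicates)
    sim_seeds, fit_seeds = seeds[::2], seeds[1::2]

    depths = np.arange(1, min(3000, config.n_tuples) + 1)
    fdrs, rocs = [], []
    for r in range(config.replicates):
        sim = _simulate(config, sim_seeds[r])
        res = analyze_simulated(
            sim, config.sample_size, fit_seeds[r],
            tol=config.prior_tol, max_iter=config.prior_max_iter,
        )
        scores = res.prob_de()
        ranking = res.rank_by("any_de")["tuple_id"]
        f = fdr_curve(ranking, sim.is_de, depths)
        roc = roc_curve(scores, sim.is_de)
        fdrs.append(f)
        rocs.append(roc)
        f.to_frame().to_csv(outdir / f"fdr_rep{r:03d}.tsv", sep="\t", index=False)
        roc.to_frame().to_csv(outdir / f"roc_rep{r:03d}.tsv", sep="\t", index=False)
        _log(
            f"replicate {r + 1}/{config.replicates}: "
            f"fp@200={f.fp_count[np.searchsorted(depths, min(200, depths[-1]))]:.0f} "
            f"auc={roc.auc:.4f}"
        )

    mean_fdr = mean_curves(fdrs)
    mean_roc = mean_curves(rocs)
    mean_fdr.to_frame().to_csv(outdir / "fdr_mean.tsv", sep="\t", index=False)
    mean_roc.to_frame().to_csv(outdir / "roc_mean.tsv", sep="\t", index=False)

    summary = {"design": config.design, "replicates": config.replicates,
               "mean_auc": float(np.mean([r.auc for r in rocs])),
               "fp_count": {}}
    with open(outdir / "summary.tsv", "w", encoding="utf-8") as fh:
        fh.write("depth\tmean_fp\tse_fp\tmean_fdr\n")
        for d in config.summary_depths:
            if d < 1 or d > depths[-1]:
                continue
            i = int(np.searchsorted(depths, d))
            summary["fp_count"][int(d)] = float(mean_fdr.fp_count[i])
            fh.write(
                f"{d}\t{mean_fdr.fp_count[i]:.4f}\t{mean_fdr.se[i]:.4f}"
                f"\t{mean_fdr.fdr[i]:.6f}\n"
            )
    _write_manifest(outdir, config, {"mode": "benchmark", "summary": summary,
                                     "sim_seeds": sim_seeds,
                                     "fit_seeds": fit_seeds})
    return summary
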