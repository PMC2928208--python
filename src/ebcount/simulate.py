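"""Seeded simulation designs for benchmarking the analysis.

Three designs with known differential-expression labels:

* ``simulate_pairwise_random_dispersion`` — two conditions; library sizes
  uniform on [30000, 90000]; per-tuple dispersions from Gamma(shape 0.85,
  scale 0.5); 10% of tuples differentially expressed, with means
  lambda*l/b versus lambda*l*b and the direction chosen at random per tuple.
* ``simulate_fixed_dispersion`` — ten libraries, one common dispersion
  (e.g. 0.17 / 0.42 / 0.95), rate lambda = 0.0002, half the tuples
  over-expressed fourfold in libraries 6-10 only (unidirectional).
* ``simulate_three_group`` — three conditions of n libraries; for each of
  the three one-vs-two patterns 5% of tuples, plus 5% where all three
  conditions differ (roles X1 = lambda*l, X2 = lambda*l/(2b),
  X3 = lambda*l*2b allocated at random).

Baseline expression rates lambda_c are drawn from a heavy-tailed log-normal
surrogate (meanlog ln 2e-4, sdlog 1.5 by default), spanning expected counts
from ~0 to ~10^4 at these library sizes; a user-supplied empirical rate
vector may be substituted. All randomness flows from the config seed, and
label counts are exact, not random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CountData

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_pairwise_random_dispersion",
    "simulate_fixed_dispersion",
    "simulate_three_group",
]

DEFAULT_LAMBDA_MEANLOG = math.log(2e-4)
DEFAULT_LAMBDA_SDLOG = 1.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated dataset.

    ``n_libs`` holds the number of libraries per condition; ``fold`` is the
    fold-change parameter b (differentially expressed means are lambda*l/b
    versus lambda*l*b, a b**2 ratio). ``dispersion`` fixes a common phi;
    when None, dispersions are drawn from Gamma(dispersion_shape,
    dispersion_scale). ``lambda_values`` (a vector of empirical rates)
    overrides the log-normal rate surrogate.
    """

    n_tuples: int = 10000
    n_libs: tuple[int, ...] = (2, 2)
    fold: float = 4.0
    de_fraction: float = 0.1
    lib_size_range: tuple[float, float] = (30000.0, 90000.0)
    lambda_meanlog: float = DEFAULT_LAMBDA_MEANLOG
    lambda_sdlog: float = DEFAULT_LAMBDA_SDLOG
    lambda_values: tuple[float, ...] | None = None
    dispersion: float | None = None
    dispersion_shape: float = 0.85
    dispersion_scale: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_tuples < 1 or any(n < 1 for n in self.n_libs):
            raise ValueError("n_tuples and n_libs entries must be positive")
        if self.fold < 1:
            raise ValueError("fold parameter b must be >= 1")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ValueError("lib_size_range must satisfy 0 < low <= high")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must be in [0, 1]")
        if self.dispersion is not None and self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SimulatedDataset:
    """Simulated counts plus per-tuple ground truth.

    ``truth`` has columns tuple_id, pattern ('none' or the generating
    partition of conditions, e.g. 'A|B'), lam, phi, direction.
    """

    data: CountData
    truth: pd.DataFrame
    conditions: list
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def is_de(self) -> pd.Series:
        s = self.truth.set_index("tuple_id")["pattern"] != "none"
        s.name = "is_de"
        return s

    def write(self, counts_path, truth_path=None):
        """Write counts (and optionally truth labels) as TSV."""
        from .io import write_counts

        write_counts(self.data, counts_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def _draw_lib_sizes(rng, config, n):
    lo, hi = config.lib_size_range
    return np.round(rng.uniform(lo, hi, size=n))


def _draw_lambdas(rng, config, n):
    if config.lambda_values is not None:
        vals = np.asarray(config.lambda_values, dtype=float)
        if np.any(vals <= 0):
            raise ValueError("lambda_values must be positive")
        return rng.choice(vals, size=n, replace=True)
    return rng.lognormal(config.lambda_meanlog, config.lambda_sdlog, size=n)


def _draw_phis(rng, config, n):
    if config.dispersion is not None:
        return np.full(n, float(config.dispersion))
    return rng.gamma(config.dispersion_shape, config.dispersion_scale, size=n)


def _nb_counts(rng, means, phis):
    """NB draws with mean ``means[c, i]`` and per-tuple dispersion phi_c.

    phi below 1e-8 is drawn as Poisson (the NB is numerically Poisson
    there and the generator avoids huge shape parameters).
    """
    means = np.asarray(means, dtype=float)
    phis = np.broadcast_to(np.asarray(phis, dtype=float)[:, None], means.shape)
    out = np.empty(means.shape, dtype=np.int64)
    pois = phis < 1e-8
    if np.any(pois):
        out[pois] = rng.poisson(means[pois])
    nb = ~pois
    if np.any(nb):
        r = 1.0 / phis[nb]
        p = r / (r + means[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def _finish(counts, lib_sizes, truth_rows, conditions, config):
    width = max(6, len(str(counts.shape[0])))
    ids = np.array([f"t{i:0{width}d}" for i in range(counts.shape[0])], dtype=object)
    names = []
    tally: dict = {}
    for c in conditions:
        tally[c] = tally.get(c, 0) + 1
        names.append(f"{c}{tally[c]}")
    data = CountData(
        counts=counts,
        lib_sizes=lib_sizes,
        tuple_ids=ids,
        sample_names=np.array(names, dtype=object),
    )
    truth = pd.DataFrame(truth_rows)
    truth.insert(0, "tuple_id", ids)
    return SimulatedDataset(data=data, truth=truth, conditions=list(conditions),
                            config=config)


def simulate_pairwise_random_dispersion(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Two-condition benchmark with per-tuple random dispersions.

    Exactly ``round(de_fraction * n_tuples)`` tuples (the first rows) are
    differentially expressed with means lambda*l/b in one condition and
    lambda*l*b in the other, the direction chosen at random per tuple.
    """
    config = config or SimulationConfig()
    if len(config.n_libs) != 2:
        raise ValueError("pairwise design needs exactly two conditions")
    n1, n2 = config.n_libs
    n = n1 + n2
    C = config.n_tuples
    n_de = int(round(config.de_fraction * C))
    rng = np.random.default_rng(config.seed)

    lib = _draw_lib_sizes(rng, config, n)
    lam = _draw_lambdas(rng, config, C)
    phi = _draw_phis(rng, config, C)
    up_in_b = rng.integers(0, 2, size=n_de).astype(bool)

    b = config.fold
    factors = np.ones((C, n))
    factors[:n_de, :n1] = np.where(up_in_b, 1.0 / b, b)[:, None]
    factors[:n_de, n1:] = np.where(up_in_b, b, 1.0 / b)[:, None]
    means = lam[:, None] * lib[None, :] * factors
    counts = _nb_counts(rng, means, phi)

    direction = np.array([""] * C, dtype=object)
    direction[:n_de] = np.where(up_in_b, "up_in_B", "down_in_B")
    pattern = np.array(["none"] * C, dtype=object)
    pattern[:n_de] = "A|B"
    truth = {"pattern": pattern, "lam": lam, "phi": phi, "direction": direction}
    return _finish(counts, lib, truth, ["A"] * n1 + ["B"] * n2, config)


def simulate_fixed_dispersion(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Ten-library constant-dispersion benchmark with unidirectional DE.

    Half the tuples are over-expressed by ``fold`` in libraries 6-10 only;
    the rate is fixed at lambda = 0.0002 and the dispersion is the config's
    ``dispersion`` (0.17 by default here).
    """
    if config is None:
        config = SimulationConfig(
            n_libs=(5, 5), de_fraction=0.5, dispersion=0.17,
            lambda_values=(2e-4,),
        )
    else:
        if config.dispersion is None:
            raise ValueError("fixed-dispersion design requires config.dispersion")
        if config.lambda_values is None:
            config = replace(config, lambda_values=(2e-4,))
    if len(config.n_libs) != 2:
        raise ValueError("fixed-dispersion design needs two conditions")
    n1, n2 = config.n_libs
    n = n1 + n2
    C = config.n_tuples
    n_de = int(round(config.de_fraction * C))
    rng = np.random.default_rng(config.seed)

    lib = _draw_lib_sizes(rng, config, n)
    lam = _draw_lambdas(rng, config, C)
    phi = _draw_phis(rng, config, C)

    factors = np.ones((C, n))
    factors[:n_de, n1:] = config.fold  # over-expression of libraries 6-10 only
    means = lam[:, None] * lib[None, :] * factors
    counts = _nb_counts(rng, means, phi)

    pattern = np.array(["none"] * C, dtype=object)
    pattern[:n_de] = "A|B"
    direction = np.array([""] * C, dtype=object)
    direction[:n_de] = "up_in_B"
    truth = {"pattern": pattern, "lam": lam, "phi": phi, "direction": direction}
    return _finish(counts, lib, truth, ["A"] * n1 + ["B"] * n2, config)


_THREE_GROUP_PATTERNS = ("A,B|C", "A,C|B", "A|B,C", "A|B|C")


def simulate_three_group(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Three-condition benchmark covering all five expression patterns.

    With the default 10000 tuples: 500 tuples for each pattern in which one
    condition differs from the other two, 500 in which all three conditions
    differ, and 8000 with no differential expression. Pattern labels use the
    canonical partition notation ('A,B|C' means A and B equivalent, C
    different).
    """
    config = config or SimulationConfig(n_libs=(2, 2, 2), fold=8.0)
    if len(config.n_libs) != 3:
        raise ValueError("three-group design needs exactly three conditions")
    C = config.n_tuples
    per_pattern = int(round(0.05 * C))
    n_de = 4 * per_pattern
    if n_de > C:
        raise ValueError("n_tuples too small for the three-group pattern counts")
    rng = np.random.default_rng(config.seed)

    conds = ["A"] * config.n_libs[0] + ["B"] * config.n_libs[1] + ["C"] * config.n_libs[2]
    cols = {c: [i for i, x in enumerate(conds) if x == c] for c in "ABC"}
    n = len(conds)

    lib = _draw_lib_sizes(rng, config, n)
    lam = _draw_lambdas(rng, config, C)
    phi = _draw_phis(rng, config, C)
    b = config.fold

    factors = np.ones((C, n))
    pattern = np.array(["none"] * C, dtype=object)
    direction = np.array([""] * C, dtype=object)
    row = 0
    # one condition differs from the other two
    for pat, (pair, single) in zip(
        _THREE_GROUP_PATTERNS[:3], [("AB", "C"), ("AC", "B"), ("BC", "A")]
    ):
        up_single = rng.integers(0, 2, size=per_pattern).astype(bool)
        sl = slice(row, row + per_pattern)
        pair_cols = cols[pair[0]] + cols[pair[1]]
        f_pair = np.where(up_single, 1.0 / b, b)
        f_single = np.where(up_single, b, 1.0 / b)
        factors[sl, :][:, pair_cols] = f_pair[:, None]
        factors[sl, :][:, cols[single]] = f_single[:, None]
        pattern[sl] = pat
        direction[sl] = np.where(up_single, f"up_in_{single}", f"down_in_{single}")
        row += per_pattern
    # all three conditions differ: roles X1 = 1, X2 = 1/(2b), X3 = 2b
    roles = np.array([1.0, 1.0 / (2 * b), 2 * b])
    perms = np.array([rng.permutation(3) for _ in range(per_pattern)])
    sl = slice(row, row + per_pattern)
    for k, c in enumerate("ABC"):
        factors[sl, :][:, cols[c]] = roles[perms[:, k]][:, None]
    pattern[sl] = "A|B|C"
    direction[sl] = [
        "X" + "X".join(str(p + 1) for p in perm) for perm in perms
    ]
    row += per_pattern

    means = lam[:, None] * lib[None, :] * factors
    counts = _nb_counts(rng, means, phi)
    truth = {"pattern": pattern, "lam": lam, "phi": phi, "direction": direction}
    return _finish(counts, lib, truth, conds, config)
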