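"""Core data containers: count tables, model partitions, replicate structure.

A *tuple* is one row of count data (a sequence tag, or an aggregated group
of tags such as a locus), with one non-negative integer count per sample.
A *model* is a partition of the samples into non-overlapping sets; samples
within a set are assumed to share the parameters of their underlying count
distribution, so each partition expresses one pattern of (non-)differential
expression. The *replicate structure* is the partition of samples into
biological replicate groups, used only when estimating per-tuple dispersions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountData",
    "ModelDefinition",
    "ReplicateStructure",
    "ModelValidationError",
    "validate_model",
    "enumerate_models",
    "set_partitions",
]


class ModelValidationError(ValueError):
    """A model's sets fail to form a partition of the samples."""


def _canonical_sets(sets: Iterable[Iterable[int]]) -> tuple[tuple[int, ...], ...]:
    """Sort members ascending within sets, then sets by smallest member."""
    inner = [tuple(sorted(int(i) for i in s)) for s in sets]
    return tuple(sorted(inner, key=lambda s: s[0] if s else -1))


@dataclass(frozen=True)
class ModelDefinition:
    """A pattern of differential expression: a partition of sample indices.

    Parameters
    ----------
    name : str
        Label for the model (e.g. ``"A|B"`` for pairwise differential
        expression, ``"A,B"`` for none).
    sets : tuple of tuples of int
        Non-overlapping, exhaustive sets of 0-based sample indices. Samples
        in the same set share the same underlying negative-binomial
        parameters.
    """

    name: str
    sets: tuple[tuple[int, ...], ...]

    def __init__(self, name: str, sets: Iterable[Iterable[int]]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "sets", _canonical_sets(sets))

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def samples(self) -> tuple[int, ...]:
        return tuple(sorted(i for s in self.sets for i in s))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = " | ".join("{" + ",".join(map(str, s)) + "}" for s in self.sets)
        return f"ModelDefinition({self.name!r}: {body})"


@dataclass(frozen=True)
class ReplicateStructure:
    """Partition of samples into biological replicate groups F_1..F_s."""

    groups: tuple[tuple[int, ...], ...]

    def __init__(self, groups: Iterable[Iterable[int]]):
        object.__setattr__(self, "groups", _canonical_sets(groups))

    @classmethod
    def from_labels(cls, labels: Sequence) -> "ReplicateStructure":
        """Group samples sharing a label into one replicate group."""
        seen: dict = {}
        for i, lab in enumerate(labels):
            seen.setdefault(lab, []).append(i)
        return cls(seen.values())

    @property
    def n_samples(self) -> int:
        return sum(len(g) for g in self.groups)

    def validate(self, n_samples: int) -> "ReplicateStructure":
        _check_partition(self.groups, n_samples, what="replicate group")
        return self


def _check_partition(sets, n_samples: int, what: str = "set") -> None:
    seen: dict[int, int] = {}
    for k, s in enumerate(sets):
        if len(s) == 0:
            raise ModelValidationError(f"{what} {k} is empty")
        for i in s:
            if not (0 <= i < n_samples):
                raise ModelValidationError(
                    f"{what} {k} contains sample index {i}, "
                    f"outside 0..{n_samples - 1}"
                )
            if i in seen:
                raise ModelValidationError(
                    f"sample {i} appears in {what}s {seen[i]} and {k}"
                )
            seen[i] = k
    missing = sorted(set(range(n_samples)) - set(seen))
    if missing:
        raise ModelValidationError(
            f"samples {missing} are not assigned to any {what}"
        )


def validate_model(model: ModelDefinition, n_samples: int) -> ModelDefinition:
    """Check that ``model.sets`` is a partition of ``0..n_samples-1``.

    Returns the model (already canonically ordered by construction) or
    raises :class:`ModelValidationError` naming the offending set.
    """
    _check_partition(model.sets, n_samples)
    return model


@dataclass
class CountData:
    """A tuples-by-samples table of sequencing counts with library sizes.

    Parameters
    ----------
    counts : (n_tuples, n_samples) integer array
        Non-negative counts u_ic.
    lib_sizes : (n_samples,) positive array
        Library size scaling factors l_i (total counts per library or a
        surrogate).
    tuple_ids : sequence of unique str
        Row labels. Defaults to ``t000000`` style.
    sample_names : sequence of str, optional
        Column labels. Defaults to ``s0..``.
    """

    counts: np.ndarray
    lib_sizes: np.ndarray
    tuple_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_names: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 1 or c.shape[1] < 2:
            raise ValueError(
                "counts must be 2-D with >=1 tuple and >=2 samples, "
                f"got shape {c.shape}"
            )
        if not np.issubdtype(c.dtype, np.integer):
            f = np.asarray(c, dtype=float)
            if not np.all(np.isfinite(f)) or np.any(f != np.floor(f)):
                raise ValueError("counts must be integers")
            c = f.astype(np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = np.ascontiguousarray(c, dtype=np.int64)

        l = np.asarray(self.lib_sizes, dtype=float)
        if l.shape != (c.shape[1],):
            raise ValueError(
                f"lib_sizes must have length {c.shape[1]}, got shape {l.shape}"
            )
        if not np.all(l > 0):
            raise ValueError("lib_sizes must be positive")
        self.lib_sizes = l

        if self.tuple_ids is None:
            width = max(6, len(str(c.shape[0])))
            self.tuple_ids = np.array(
                [f"t{i:0{width}d}" for i in range(c.shape[0])], dtype=object
            )
        else:
            ids = np.asarray(self.tuple_ids, dtype=object)
            if ids.shape != (c.shape[0],):
                raise ValueError("tuple_ids length must match number of tuples")
            if len(set(ids)) != len(ids):
                raise ValueError("tuple_ids must be unique")
            self.tuple_ids = ids

        if self.sample_names is None:
            self.sample_names = np.array(
                [f"s{i}" for i in range(c.shape[1])], dtype=object
            )
        else:
            names = np.asarray(self.sample_names, dtype=object)
            if names.shape != (c.shape[1],):
                raise ValueError("sample_names length must match samples")
            self.sample_names = names

    @property
    def n_tuples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, lib_sizes: Sequence[float] | None = None
    ) -> "CountData":
        """Build from a DataFrame (rows = tuples, columns = samples).

        Library sizes default to column totals.
        """
        counts = df.to_numpy()
        if lib_sizes is None:
            lib_sizes = np.asarray(df.sum(axis=0), dtype=float)
        return cls(
            counts=counts,
            lib_sizes=np.asarray(lib_sizes, dtype=float),
            tuple_ids=df.index.astype(str).to_numpy(dtype=object),
            sample_names=df.columns.astype(str).to_numpy(dtype=object),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.tuple_ids, name="tuple_id"),
            columns=list(self.sample_names),
        )


def set_partitions(items: Sequence) -> list[tuple[tuple, ...]]:
    """All set partitions of ``items``, canonically ordered.

    Recursive construction: each item is either added to an existing block
    or opens a new one, which enumerates each partition exactly once.
    The count is the Bell number of ``len(items)``.
    """
    items = list(items)
    if not items:
        return [()]
    out: list[tuple[tuple, ...]] = []

    def rec(idx: int, blocks: list[list]):
        if idx == len(items):
            out.append(tuple(tuple(b) for b in blocks))
            return
        for b in blocks:
            b.append(items[idx])
            rec(idx + 1, blocks)
            b.pop()
        blocks.append([items[idx]])
        rec(idx + 1, blocks)
        blocks.pop()

    rec(0, [])
    return out


def _condition_partition_key(partition: Iterable[Iterable]) -> frozenset:
    return frozenset(frozenset(block) for block in partition)


def _model_name(partition: tuple[tuple, ...]) -> str:
    return "|".join(",".join(str(c) for c in block) for block in partition)


def enumerate_models(
    condition_labels: Sequence,
    exclude: Sequence[Iterable[Iterable]] | None = None,
) -> list[ModelDefinition]:
    """Enumerate every pattern of differential expression between conditions.

    One :class:`ModelDefinition` is produced per set partition of the
    distinct condition labels (samples grouped by condition within each
    block), minus any excluded condition partitions — e.g. patterns ruled
    out on biological grounds. With k conditions and no exclusions the
    result has Bell(k) models.

    Parameters
    ----------
    condition_labels : sequence
        One condition label per sample column.
    exclude : sequence of partitions of condition labels, optional
        Each exclusion is an iterable of blocks of condition labels,
        e.g. ``[[["A", "C"], ["B"]]]``.
    """
    labels = list(condition_labels)
    if not labels:
        raise ValueError("need at least one condition label")
    by_cond: dict = {}
    for i, lab in enumerate(labels):
        by_cond.setdefault(lab, []).append(i)
    conds = sorted(by_cond, key=str)

    excluded_keys = set()
    for part in exclude or ():
        blocks = [list(b) for b in part]
        for b in blocks:
            for c in b:
                if c not in by_cond:
                    raise ValueError(
                        f"exclusion references unknown condition {c!r}"
                    )
        excluded_keys.add(_condition_partition_key(blocks))

    models = []
    for part in set_partitions(conds):
        if _condition_partition_key(part) in excluded_keys:
            continue
        sets = [
            [i for c in block for i in by_cond[c]] for block in part
        ]
        model = ModelDefinition(_model_name(part), sets)
        models.append(validate_model(model, len(labels)))
    models.sort(key=lambda m: (m.n_sets, m.name))
    return models
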