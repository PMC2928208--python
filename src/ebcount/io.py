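"""Reading and writing the tool's plain-text formats.

Counts travel as TSV: header row of sample names, first column tuple ids,
integer cells. Library sizes default to column totals (or a surrogate
measure supplied as a two-column sample/size TSV). Run configuration is
YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .data import CountData

__all__ = ["read_counts", "write_counts", "read_lib_sizes", "RunConfig",
           "CountsParseError"]


class CountsParseError(ValueError):
    """A malformed cell or row in a counts TSV, with its line number."""


def read_lib_sizes(path) -> dict[str, float]:
    """Read a two-column (sample, size) TSV, with or without a header."""
    out: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CountsParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            name, val = parts
            try:
                size = float(val)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise CountsParseError(
                    f"{path}:{lineno}: library size {val!r} is not a number"
                ) from None
            if size <= 0:
                raise CountsParseError(
                    f"{path}:{lineno}: library size must be positive"
                )
            out[name] = size
    return out


def read_counts(path, lib_sizes_path=None) -> CountData:
    """Read a counts TSV into a :class:`CountData`.

    Library sizes are the column totals unless ``lib_sizes_path`` supplies a
    surrogate per sample. Non-integer or negative cells, duplicate tuple
    ids, and ragged rows raise :class:`CountsParseError` with the offending
    line number.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not lines:
        raise CountsParseError(f"{path}: empty file")
    header_no, header = lines[0]
    cols = header.split("\t")
    sample_names = cols[1:]
    n = len(sample_names)
    if n < 2:
        raise CountsParseError(f"{path}:{header_no}: need at least 2 sample columns")

    ids: list[str] = []
    rows = np.empty((len(lines) - 1, n), dtype=np.int64)
    seen: dict[str, int] = {}
    for r, (lineno, line) in enumerate(lines[1:]):
        parts = line.split("\t")
        if len(parts) != n + 1:
            raise CountsParseError(
                f"{path}:{lineno}: expected {n + 1} fields, got {len(parts)}"
            )
        tid = parts[0]
        if tid in seen:
            raise CountsParseError(
                f"{path}:{lineno}: duplicate tuple id {tid!r} "
                f"(first seen on line {seen[tid]})"
            )
        seen[tid] = lineno
        ids.append(tid)
        for j, cell in enumerate(parts[1:]):
            try:
                v = int(cell)
            except ValueError:
                raise CountsParseError(
                    f"{path}:{lineno}: column {sample_names[j]!r}: "
                    f"{cell!r} is not a non-negative integer"
                ) from None
            if v < 0:
                raise CountsParseError(
                    f"{path}:{lineno}: column {sample_names[j]!r}: "
                    "counts must be non-negative"
                )
            rows[r, j] = v

    if lib_sizes_path is not None:
        sizes = read_lib_sizes(lib_sizes_path)
        missing = [s for s in sample_names if s not in sizes]
        if missing:
            raise CountsParseError(
                f"{lib_sizes_path}: no library size for samples {missing}"
            )
        lib = np.array([sizes[s] for s in sample_names], dtype=float)
    else:
        lib = rows.sum(axis=0).astype(float)
        if np.any(lib <= 0):
            raise CountsParseError(
                f"{path}: some columns sum to 0; supply explicit library sizes"
            )
    return CountData(
        counts=rows,
        lib_sizes=lib,
        tuple_ids=np.array(ids, dtype=object),
        sample_names=np.array(sample_names, dtype=object),
    )


def write_counts(data: CountData, path) -> None:
    """Write counts as TSV (inverse of :func:`read_counts` given the same
    library sizes)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tuple_id\t" + "\t".join(map(str, data.sample_names)) + "\n")
        for tid, row in zip(data.tuple_ids, data.counts):
            fh.write(str(tid) + "\t" + "\t".join(map(str, row)) + "\n")


@dataclass
class RunConfig:
    """Everything needed to reproduce an analysis or benchmark run."""

    counts: str | None = None
    lib_sizes: str | None = None
    truth: str | None = None
    conditions: list = field(default_factory=list)
    exclusions: list = field(default_factory=list)
    sample_size: int = 5000
    seed: int = 0
    prior_tol: float = 1e-5
    prior_max_iter: int = 1000
    outdir: str = "ebcount_out"
    # benchmark settings
    design: str = "pairwise_random"
    replicates: int = 10
    n_tuples: int = 10000
    n_libs: list = field(default_factory=lambda: [2, 2])
    fold: float = 4.0
    de_fraction: float = 0.1
    dispersion: float | None = None
    summary_depths: list = field(default_factory=lambda: [100, 200, 500, 1000])

    def __post_init__(self):
        if self.prior_tol <= 0:
            raise ValueError("prior_tol must be > 0")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def save(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )
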