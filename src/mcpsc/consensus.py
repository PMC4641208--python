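"""Consensus scoring: assemble the P x M score matrix, invert similarities,
min-max normalize each method column and average rows.

The normalization is per column j: X'[i,j] = (X[i,j] - min_j) / (max_j - min_j),
with a degenerate (constant) column mapped to all zeros. Smaller consensus
means more similar.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mcpsc.methods import Kind, MethodScore

__all__ = [
    "ScoreMatrix",
    "ConsensusResult",
    "build_score_matrix",
    "to_dissimilarity",
    "minmax_normalize_columns",
    "consensus_scores",
    "consensus_pipeline",
    "write_scores_tsv",
    "read_scores_tsv",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Raw method scores for P ordered pairs under M methods."""

    pair_index: tuple  # ((query_id, db_id), ...) length P
    methods: tuple  # method names, length M
    values: np.ndarray  # (P, M) floats
    kinds: tuple  # per-method "similarity" | "distance"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.pair_index), len(self.methods)):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"{len(self.pair_index)} pairs x {len(self.methods)} methods"
            )
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("score matrix contains non-finite values")
        if len(self.kinds) != len(self.methods):
            raise ValueError("one kind per method required")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pair_index", tuple(tuple(p) for p in self.pair_index))
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "kinds", tuple(self.kinds))

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)


@dataclass(frozen=True)
class ConsensusResult:
    """Raw matrix together with its normalized form and the consensus vector."""

    pair_index: tuple
    methods: tuple
    raw: np.ndarray  # (P, M) dissimilarities prior to normalization
    normalized: np.ndarray  # (P, M) in [0, 1]
    consensus: np.ndarray  # (P,) row means, in [0, 1]

    def __post_init__(self) -> None:
        normalized = np.asarray(self.normalized, dtype=float)
        consensus = np.asarray(self.consensus, dtype=float)
        if normalized.size and (normalized.min() < 0 or normalized.max() > 1):
            raise ValueError("normalized scores must lie in [0, 1]")
        if consensus.size and not np.allclose(consensus, normalized.mean(axis=1)):
            raise ValueError("consensus must equal per-pair mean of normalized scores")
        for arr in ("raw", "normalized", "consensus"):
            a = np.asarray(getattr(self, arr), dtype=float)
            a.setflags(write=False)
            object.__setattr__(self, arr, a)
        object.__setattr__(self, "pair_index", tuple(tuple(p) for p in self.pair_index))
        object.__setattr__(self, "methods", tuple(self.methods))


def build_score_matrix(
    scores: list[MethodScore],
    pairs: list[tuple[str, str]] | None = None,
    methods: list[str] | None = None,
) -> ScoreMatrix:
    """Arrange a flat score list into the declared pair x method grid.

    Pair and method order default to first appearance in ``scores``. Exactly
    one score per (pair, method) cell is required; offenders are listed.
    """
    if pairs is None:
        seen: dict[tuple[str, str], None] = {}
        for s in scores:
            seen.setdefault((s.query_id, s.db_id), None)
        pairs = list(seen)
    if methods is None:
        seen_m: dict[str, None] = {}
        for s in scores:
            seen_m.setdefault(s.method, None)
        methods = list(seen_m)

    pair_pos = {tuple(p): i for i, p in enumerate(pairs)}
    method_pos = {m: j for j, m in enumerate(methods)}
    values = np.full((len(pairs), len(methods)), np.nan)
    kinds: dict[str, Kind] = {}
    duplicates = []
    for s in scores:
        key = (s.query_id, s.db_id)
        if key not in pair_pos or s.method not in method_pos:
            raise ValueError(f"score for undeclared cell ({key}, {s.method})")
        i, j = pair_pos[key], method_pos[s.method]
        if not np.isnan(values[i, j]):
            duplicates.append((key, s.method))
        values[i, j] = s.value
        prev = kinds.setdefault(s.method, s.kind)
        if prev != s.kind:
            raise ValueError(f"method {s.method!r} mixes score kinds")
    if duplicates:
        raise ValueError(f"duplicate scores for cells: {duplicates}")
    missing = [
        (pairs[i], methods[j])
        for i, j in zip(*np.nonzero(np.isnan(values)))
    ]
    if missing:
        raise ValueError(f"missing scores for cells: {missing}")
    return ScoreMatrix(
        pair_index=tuple(pairs),
        methods=tuple(methods),
        values=values,
        kinds=tuple(kinds[m] for m in methods),
    )


def to_dissimilarity(matrix: ScoreMatrix) -> ScoreMatrix:
    """Replace every similarity column s (bounded in [0, 1]) by 1 - s.

    Distance columns pass through unchanged. Calling this on a matrix with
    no similarity columns is an error, which guards against double
    inversion.
    """
    if "similarity" not in matrix.kinds:
        raise ValueError("no similarity columns remain; already converted?")
    values = matrix.values.copy()
    for j, kind in enumerate(matrix.kinds):
        if kind != "similarity":
            continue
        col = values[:, j]
        if col.size and (col.min() < 0 or col.max() > 1):
            raise ValueError(
                f"similarity column {matrix.methods[j]!r} outside [0, 1]; cannot invert"
            )
        values[:, j] = 1.0 - col
    return ScoreMatrix(
        pair_index=matrix.pair_index,
        methods=matrix.methods,
        values=values,
        kinds=tuple("distance" for _ in matrix.kinds),
    )


def minmax_normalize_columns(matrix: ScoreMatrix) -> np.ndarray:
    """Feature-scale each column to [0, 1]; constant columns become zeros."""
    if "similarity" in matrix.kinds:
        raise ValueError("normalize after converting similarities to dissimilarities")
    values = matrix.values
    if values.size == 0:
        return values.copy()
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    out = np.zeros_like(values)
    ok = span > 0
    out[:, ok] = (values[:, ok] - lo[ok]) / span[ok]
    return out


def consensus_scores(normalized: np.ndarray) -> np.ndarray:
    """Per-pair mean of the normalized dissimilarities (0 = most similar)."""
    normalized = np.asarray(normalized, dtype=float)
    if normalized.size and (normalized.min() < 0 or normalized.max() > 1):
        raise ValueError("normalized matrix must lie in [0, 1]")
    return normalized.mean(axis=1)


def consensus_pipeline(matrix: ScoreMatrix) -> ConsensusResult:
    """Full consensus chain: invert similarities, normalize, average."""
    diss = to_dissimilarity(matrix) if "similarity" in matrix.kinds else matrix
    normalized = minmax_normalize_columns(diss)
    return ConsensusResult(
        pair_index=matrix.pair_index,
        methods=matrix.methods,
        raw=diss.values,
        normalized=normalized,
        consensus=consensus_scores(normalized),
    )


def write_scores_tsv(result: ConsensusResult, path: str | os.PathLike) -> None:
    """Write pair ids, raw and normalized per-method scores and consensus.

    Fixed column order: query_id, db_id, <m>_raw..., <m>_norm..., consensus;
    numbers at 6 decimal places.
    """
    columns: dict[str, object] = {
        "query_id": [p[0] for p in result.pair_index],
        "db_id": [p[1] for p in result.pair_index],
    }
    for j, m in enumerate(result.methods):
        columns[f"{m}_raw"] = result.raw[:, j]
    for j, m in enumerate(result.methods):
        columns[f"{m}_norm"] = result.normalized[:, j]
    columns["consensus"] = result.consensus
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scores_tsv(path: str | os.PathLike) -> ConsensusResult:
    """Read back a file produced by :func:`write_scores_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "db_id": str})
    required = {"query_id", "db_id", "consensus"}
    if not required <= set(df.columns):
        raise ValueError(f"score file missing column(s): {sorted(required - set(df.columns))}")
    methods = [c[:-4] for c in df.columns if c.endswith("_raw")]
    for m in methods:
        if f"{m}_norm" not in df.columns:
            raise ValueError(f"score file missing normalized column for {m!r}")
    numeric_cols = [f"{m}_raw" for m in methods] + [f"{m}_norm" for m in methods] + ["consensus"]
    numeric = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise ValueError("score file contains NaN or non-numeric cells")
    pairs = tuple(zip(df["query_id"], df["db_id"]))
    raw = numeric[[f"{m}_raw" for m in methods]].to_numpy()
    normalized = numeric[[f"{m}_norm" for m in methods]].to_numpy()
    consensus = numeric["consensus"].to_numpy()
    # Guard against rounding drift in the stored row means.
    if consensus.size and not np.allclose(consensus, normalized.mean(axis=1), atol=5e-6):
        raise ValueError("consensus column inconsistent with normalized scores")
    return ConsensusResult(
        pair_index=pairs,
        methods=tuple(methods),
        raw=raw,
        normalized=normalized,
        consensus=normalized.mean(axis=1) if consensus.size else consensus,
    )
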