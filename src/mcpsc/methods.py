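"""Pairwise structure-comparison methods.

Three built-in methods are registered:

``usm``
    Normalized compression distance between canonical contact-map
    serializations, with gzip as the complexity approximator.
``tm`` / ``rmsd``
    A rigid-superposition aligner (sequence alignment + iterative Kabsch
    refinement) producing a length-normalized similarity in [0, 1] and an
    RMSD distance. Both scores come from one alignment pass. These are
    stand-ins for external structure aligners; externally computed scores
    can be ingested via :func:`load_external_scores`.
"""

from __future__ import annotations

import gzip
import os
import threading
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, TYPE_CHECKING

import numpy as np
import pandas as pd

from mcpsc.structio import ContactMap, ProteinDomain, contact_map, serialize_contact_map

if TYPE_CHECKING:  # pragma: no cover
    from mcpsc.scheduling import PSCJob

__all__ = [
    "MethodScore",
    "AlignmentResult",
    "CompressionSizes",
    "MethodRegistry",
    "DomainStore",
    "ContactMapCache",
    "AlignmentCache",
    "DEFAULT_REGISTRY",
    "GZIP_OVERHEAD_BOUND",
    "usm_distance",
    "compression_sizes",
    "kabsch_superpose",
    "align_sequences",
    "tm_d0",
    "tm_like_compare",
    "run_method",
    "load_external_scores",
]

Kind = Literal["similarity", "distance"]

# Slack allowed on the subadditivity check C(xy) <= C(x) + C(y) + bound:
# a gzip member carries a ~18-byte header/trailer plus Huffman table noise.
GZIP_OVERHEAD_BOUND = 64


@dataclass(frozen=True)
class MethodScore:
    """One method's score for one ordered domain pair."""

    query_id: str
    db_id: str
    method: str
    value: float
    kind: Kind

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"score for ({self.query_id}, {self.db_id}) not finite")
        if self.value < 0:
            raise ValueError(f"score for ({self.query_id}, {self.db_id}) negative")
        if self.kind not in ("similarity", "distance"):
            raise ValueError(f"unknown score kind {self.kind!r}")


@dataclass(frozen=True)
class CompressionSizes:
    """Compressed byte sizes of two objects and their concatenation."""

    c_x: int
    c_y: int
    c_xy: int

    def __post_init__(self) -> None:
        if min(self.c_x, self.c_y, self.c_xy) <= 0:
            raise ValueError("degenerate compressor output (zero size)")
        if self.c_xy > self.c_x + self.c_y + GZIP_OVERHEAD_BOUND:
            raise ValueError("concatenation compressed worse than parts plus overhead bound")


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a rigid-superposition comparison of two domains.

    ``rotation`` / ``translation`` map the second domain's coordinates onto
    the first: ``b_fit = b @ rotation.T + translation``. ``tm_score`` is
    normalized by the length of the second (reference) domain.
    """

    correspondence: tuple
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    tm_score: float
    d0: float

    def __post_init__(self) -> None:
        if len(self.correspondence) < 1:
            raise ValueError("correspondence must contain at least one pair")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")
        if not (0.0 <= self.tm_score <= 1.0):
            raise ValueError(f"tm_score {self.tm_score} outside [0, 1]")
        if self.d0 < 0.5:
            raise ValueError("d0 below the 0.5 A floor")


def _gzip_size(data: bytes) -> int:
    # mtime pinned to 0 so output is byte-stable across calls.
    return len(gzip.compress(data, compresslevel=9, mtime=0))


def compression_sizes(cm_a: ContactMap, cm_b: ContactMap) -> CompressionSizes:
    """Gzip sizes of two serialized maps and their canonical concatenation.

    The concatenation orders the two serializations lexicographically by
    their bytes, which makes the downstream distance exactly symmetric.
    """
    x = serialize_contact_map(cm_a)
    y = serialize_contact_map(cm_b)
    first, second = (x, y) if x <= y else (y, x)
    return CompressionSizes(
        c_x=_gzip_size(x),
        c_y=_gzip_size(y),
        c_xy=_gzip_size(first + second),
    )


def usm_distance(cm_a: ContactMap, cm_b: ContactMap) -> MethodScore:
    """Normalized compression distance between two contact maps.

    value = (C(xy) - min(C(x), C(y))) / max(C(x), C(y)), clamped to >= 0,
    where C is the gzip-compressed size of the canonical serialization and
    xy the canonical (byte-lexicographic) concatenation.
    """
    sizes = compression_sizes(cm_a, cm_b)
    value = (sizes.c_xy - min(sizes.c_x, sizes.c_y)) / max(sizes.c_x, sizes.c_y)
    return MethodScore(
        query_id=cm_a.domain_id,
        db_id=cm_b.domain_id,
        method="usm",
        value=max(0.0, value),
        kind="distance",
    )


def kabsch_superpose(
    coords_p: np.ndarray, coords_q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set Q onto point set P.

    Returns (rotation, translation, rmsd) with det(rotation) = +1 and
    ``q_fit = coords_q @ rotation.T + translation``.
    """
    p = np.asarray(coords_p, dtype=float)
    q = np.asarray(coords_q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"point sets differ in shape: {p.shape} vs {q.shape}")
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 1:
        raise ValueError("expected non-empty (N, 3) coordinate arrays")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = pc - qc @ rot.T
    fitted = q @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - p) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def align_sequences(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> list[tuple[int, int]]:
    """Global (Needleman-Wunsch) alignment; returns matched index pairs.

    Linear gap penalty; traceback ties resolved diagonal > up > left, so the
    result is deterministic. Matched pairs include mismatched columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    sub = np.where(a[:, None] == b[None, :], match, mismatch)

    score = np.empty((n + 1, m + 1))
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        row = score[i]
        prev = score[i - 1]
        # left-dependency forces a scan within the row
        acc = row[0]
        for j in range(1, m + 1):
            acc = max(diag[j - 1], prev[j] + gap, acc + gap)
            row[j] = acc

    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def tm_d0(l_ref: int) -> float:
    """Length-dependent distance scale, floored at 0.5 A."""
    return max(0.5, 1.24 * np.cbrt(l_ref - 15.0) - 1.8)


def _seed_windows(n_pairs: int) -> list[slice]:
    """Candidate starting subsets: full correspondence plus fragments of
    length n/2 and n/4 anchored at each quarter offset."""
    windows = [slice(0, n_pairs)]
    for frac in (2, 4):
        w = max(4, n_pairs // frac)
        for k in range(4):
            start = min((k * n_pairs) // 4, max(0, n_pairs - w))
            windows.append(slice(start, start + w))
    return windows


def tm_like_compare(a: ProteinDomain, b: ProteinDomain) -> AlignmentResult:
    """Superposition-based similarity of two domains.

    The residue correspondence comes from a global sequence alignment; an
    iterative refinement then alternates superposition on the current pair
    subset with re-selection of pairs closer than 2*d0, starting from the
    full correspondence and from several seed fragments, keeping the result
    with the highest similarity. tm_score averages 1/(1 + (d_i/d0)^2) over
    all corresponded pairs and divides by len(b); rmsd is reported over the
    finally kept pair subset.
    """
    if a.length < 5 or b.length < 5:
        raise ValueError("domains must have length >= 5")
    corr = align_sequences(a.sequence, b.sequence)
    if not corr:  # pragma: no cover - global alignment always matches >= 1
        raise ValueError("empty correspondence")
    idx_a = np.array([i for i, _ in corr])
    idx_b = np.array([j for _, j in corr])
    pa = a.ca_coords[idx_a]
    pb = b.ca_coords[idx_b]
    n_pairs = len(corr)
    l_ref = b.length
    d0 = tm_d0(l_ref)

    best: tuple[float, float, np.ndarray, np.ndarray] | None = None
    for window in _seed_windows(n_pairs):
        keep = np.zeros(n_pairs, dtype=bool)
        keep[window] = True
        for _ in range(20):
            if keep.sum() < 3:
                keep = np.ones(n_pairs, dtype=bool)  # fall back to full set
            rot, trans, _ = kabsch_superpose(pa[keep], pb[keep])
            dist = np.sqrt(((pb @ rot.T + trans - pa) ** 2).sum(axis=1))
            new_keep = dist < 2.0 * d0
            if new_keep.sum() < 3:
                break
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
        rot, trans, kept_rmsd = kabsch_superpose(pa[keep], pb[keep])
        dist = np.sqrt(((pb @ rot.T + trans - pa) ** 2).sum(axis=1))
        tm = float((1.0 / (1.0 + (dist / d0) ** 2)).sum() / l_ref)
        if best is None or tm > best[0]:
            best = (tm, kept_rmsd, rot, trans)

    tm, rmsd, rot, trans = best
    return AlignmentResult(
        correspondence=tuple(corr),
        rotation=rot,
        translation=trans,
        rmsd=rmsd,
        tm_score=min(1.0, tm),
        d0=d0,
    )


# ---------------------------------------------------------------------------
# Registry, caches and dispatch


class DomainStore:
    """Caches parsed domains so each one is loaded exactly once per run."""

    def __init__(self, loader: Callable[[str], ProteinDomain] | None = None,
                 domains: Iterable[ProteinDomain] = ()):
        self._loader = loader
        self._cache: dict[str, ProteinDomain] = {d.id: d for d in domains}
        self._lock = threading.Lock()
        self.load_count = len(self._cache)

    def get(self, domain_id: str) -> ProteinDomain:
        with self._lock:
            if domain_id not in self._cache:
                if self._loader is None:
                    raise KeyError(f"unknown domain {domain_id!r} and no loader configured")
                self._cache[domain_id] = self._loader(domain_id)
                self.load_count += 1
            return self._cache[domain_id]


class ContactMapCache:
    """Computes each domain's contact map at most once."""

    def __init__(self, store: DomainStore, threshold_angstrom: float = 8.0,
                 min_separation: int = 2):
        self.store = store
        self.threshold_angstrom = threshold_angstrom
        self.min_separation = min_separation
        self._cache: dict[str, ContactMap] = {}
        self._lock = threading.Lock()
        self.compute_count = 0

    def get(self, domain_id: str) -> ContactMap:
        with self._lock:
            if domain_id not in self._cache:
                self._cache[domain_id] = contact_map(
                    self.store.get(domain_id),
                    threshold_angstrom=self.threshold_angstrom,
                    min_separation=self.min_separation,
                )
                self.compute_count += 1
            return self._cache[domain_id]


class AlignmentCache:
    """Shares one superposition pass between the tm and rmsd methods."""

    def __init__(self, store: DomainStore):
        self.store = store
        self._cache: dict[tuple[str, str], AlignmentResult] = {}
        self._lock = threading.Lock()

    def get(self, query_id: str, db_id: str) -> AlignmentResult:
        key = (query_id, db_id)
        with self._lock:
            cached = self._cache.get(key)
        if cached is not None:
            return cached
        result = tm_like_compare(self.store.get(query_id), self.store.get(db_id))
        with self._lock:
            self._cache[key] = result
        return result


@dataclass(frozen=True)
class MethodSpec:
    name: str
    kind: Kind
    routing: Literal["sequential", "parallel"]
    fn: Callable


class MethodRegistry:
    """Name -> method implementation, score kind and routing flag."""

    def __init__(self) -> None:
        self._methods: dict[str, MethodSpec] = {}

    def register(self, name: str, kind: Kind, routing: str, fn: Callable) -> None:
        if routing not in ("sequential", "parallel"):
            raise ValueError(f"invalid routing {routing!r}")
        self._methods[name] = MethodSpec(name=name, kind=kind, routing=routing, fn=fn)

    def __contains__(self, name: str) -> bool:
        return name in self._methods

    def __getitem__(self, name: str) -> MethodSpec:
        try:
            return self._methods[name]
        except KeyError:
            raise KeyError(
                f"method {name!r} not registered (known: {sorted(self._methods)})"
            ) from None

    def names(self) -> list[str]:
        return list(self._methods)

    def kind(self, name: str) -> Kind:
        return self[name].kind

    def routing(self, name: str) -> str:
        return self[name].routing


def _usm_impl(job, domain_store, cmap_cache, alignment_cache) -> MethodScore:
    score = usm_distance(cmap_cache.get(job.query_id), cmap_cache.get(job.db_id))
    return MethodScore(job.query_id, job.db_id, "usm", score.value, "distance")


def _tm_impl(job, domain_store, cmap_cache, alignment_cache) -> MethodScore:
    res = alignment_cache.get(job.query_id, job.db_id)
    return MethodScore(job.query_id, job.db_id, "tm", res.tm_score, "similarity")


def _rmsd_impl(job, domain_store, cmap_cache, alignment_cache) -> MethodScore:
    res = alignment_cache.get(job.query_id, job.db_id)
    return MethodScore(job.query_id, job.db_id, "rmsd", res.rmsd, "distance")


def default_registry() -> MethodRegistry:
    """The built-in methods: usm (sequential), tm and rmsd (parallel)."""
    reg = MethodRegistry()
    reg.register("usm", "distance", "sequential", _usm_impl)
    reg.register("tm", "similarity", "parallel", _tm_impl)
    reg.register("rmsd", "distance", "parallel", _rmsd_impl)
    return reg


DEFAULT_REGISTRY = default_registry()


def run_method(
    job: "PSCJob",
    registry: MethodRegistry,
    domain_store: DomainStore,
    cmap_cache: ContactMapCache,
    alignment_cache: AlignmentCache | None = None,
) -> MethodScore:
    """Dispatch one job to its method implementation.

    Domain structures and contact maps are loaded/computed once per domain
    id and reused across every job that mentions the domain.
    """
    spec = registry[job.method]
    if alignment_cache is None:
        alignment_cache = AlignmentCache(domain_store)
    score = spec.fn(job, domain_store, cmap_cache, alignment_cache)
    if score.kind != spec.kind:
        raise ValueError(
            f"method {job.method!r} returned kind {score.kind!r}, registered {spec.kind!r}"
        )
    return score


def load_external_scores(tsv_path: str | os.PathLike, method_name: str,
                         kind: Kind) -> list[MethodScore]:
    """Adapter: read externally computed pairwise scores from a TSV.

    Expected columns: query_id, db_id, value. Every row becomes a
    MethodScore with the declared method name and kind; duplicated
    (query, db) pairs are rejected.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"query_id": str, "db_id": str})
    missing = {"query_id", "db_id", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"external score file missing column(s): {sorted(missing)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna()].iloc[0]
        raise ValueError(
            f"non-numeric value for pair ({bad['query_id']}, {bad['db_id']})"
        )
    dup = df.duplicated(subset=["query_id", "db_id"], keep=False)
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValueError(f"duplicate pair ({bad['query_id']}, {bad['db_id']})")
    return [
        MethodScore(str(q), str(d), method_name, float(v), kind)
        for q, d, v in zip(df["query_id"], df["db_id"], values)
    ]

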