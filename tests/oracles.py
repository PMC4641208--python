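"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exhaustive
enumeration for global alignments and worker assignments, and a
coarse-to-fine rotation-grid search for rigid superposition.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation


def best_alignment_score(seq_a: str, seq_b: str, match=1.0, mismatch=0.0, gap=-1.0) -> float:
    """Maximum global-alignment score by exhaustive recursion (short seqs)."""

    def rec(i: int, j: int) -> float:
        if i == len(seq_a):
            return (len(seq_b) - j) * gap
        if j == len(seq_b):
            return (len(seq_a) - i) * gap
        diag = rec(i + 1, j + 1) + (match if seq_a[i] == seq_b[j] else mismatch)
        return max(diag, rec(i + 1, j) + gap, rec(i, j + 1) + gap)

    return rec(0, 0)


def enumerate_alignments(seq_a: str, seq_b: str):
    """All global alignments as lists of matched (i, j) pairs."""

    def rec(i: int, j: int):
        if i == len(seq_a) and j == len(seq_b):
            yield []
            return
        if i < len(seq_a) and j < len(seq_b):
            for rest in rec(i + 1, j + 1):
                yield [(i, j)] + rest
        if i < len(seq_a):
            yield from rec(i + 1, j)
        if j < len(seq_b):
            yield from rec(i, j + 1)

    return list(rec(0, 0))


def alignment_score(pairs, seq_a, seq_b, match=1.0, mismatch=0.0, gap=-1.0) -> float:
    matched = sum(match if seq_a[i] == seq_b[j] else mismatch for i, j in pairs)
    gaps = (len(seq_a) - len(pairs)) + (len(seq_b) - len(pairs))
    return matched + gaps * gap


def grid_search_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD of q onto p by coarse-to-fine Euler-angle grid search.

    Centroids are aligned (optimal for any fixed rotation), so only the
    rotation is searched. Three refinement passes reach ~0.1 degree, well
    inside 1e-3 RMSD of the optimum for unit-scale point sets.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def rmsd_for(angles: np.ndarray) -> np.ndarray:
        rots = Rotation.from_euler("zyx", angles).as_matrix()  # (B, 3, 3)
        fitted = np.einsum("bij,nj->bni", rots, qc)
        return np.sqrt(((fitted - pc) ** 2).sum(axis=2).mean(axis=1))

    coarse_step = 9.0
    offsets = np.arange(-180.0, 180.0, coarse_step)
    coarse = np.array(list(itertools.product(offsets, offsets, offsets)))
    r = rmsd_for(coarse)
    candidates = coarse[np.argsort(r)[:20]]

    best_rmsd = float(r.min())
    for start in candidates:
        center = start
        prev_step = coarse_step
        for step in (3.0, 1.0, 0.3, 0.1, 0.03):
            local = np.arange(-1.5 * prev_step, 1.5 * prev_step + 1e-9, step)
            grid = np.array(list(itertools.product(local, local, local)))
            angles = center + grid
            rr = rmsd_for(angles)
            k = int(np.argmin(rr))
            center = angles[k]
            prev_step = step
        best_rmsd = min(best_rmsd, float(rmsd_for(center[None, :])[0]))
    return best_rmsd


def optimal_makespan(weights, n_workers: int) -> float:
    """Exact minimum makespan by branch-and-bound over all assignments."""
    weights = sorted(weights, reverse=True)
    best = [sum(weights)]
    loads = [0.0] * n_workers

    def rec(k: int) -> None:
        if k == len(weights):
            best[0] = min(best[0], max(loads))
            return
        seen = set()
        for w in range(n_workers):
            if loads[w] in seen:  # symmetric branch
                continue
            seen.add(loads[w])
            if loads[w] + weights[k] >= best[0]:
                continue
            loads[w] += weights[k]
            rec(k + 1)
            loads[w] -= weights[k]

    rec(0)
    return best[0]
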