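"""Shared fixtures: tiny PDB texts, synthetic domains, and a session-scoped
full-pipeline run on the standard 5x7 benchmark (reused by the acceptance
suite to stay inside the runtime budget)."""

from __future__ import annotations

import numpy as np
import pytest

from mcpsc.consensus import build_score_matrix, consensus_pipeline
from mcpsc.methods import ContactMapCache, DomainStore, default_registry
from mcpsc.scheduling import execute_parallel, generate_jobs
from mcpsc.structio import ProteinDomain
from mcpsc.synthetic import FamilySpec, make_benchmark, make_family_template


def make_pdb_text(coords, resnames=None, chain="A", altlocs=None) -> str:
    """Hand-rolled PDB ATOM text for small fixtures."""
    lines = []
    for k, (x, y, z) in enumerate(coords, start=1):
        resname = (resnames or ["ALA"] * len(coords))[k - 1]
        altloc = (altlocs or [" "] * len(coords))[k - 1]
        lines.append(
            f"ATOM  {k:5d}  CA {altloc}{resname} {chain}{k:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def collinear_domain() -> ProteinDomain:
    """5 C-alphas on a line, 3.8 A apart."""
    coords = np.array([[3.8 * i, 0.0, 0.0] for i in range(5)])
    return ProteinDomain(id="lin5", chain_id="A", sequence="AAAAA", ca_coords=coords)


@pytest.fixture
def helix_domain() -> ProteinDomain:
    spec = FamilySpec("hx", "helix", 50, 1, 0.0, 0.0, seed=11)
    return make_family_template(spec)


@pytest.fixture
def extended_domain() -> ProteinDomain:
    spec = FamilySpec("ex", "extended", 50, 1, 0.0, 0.0, seed=12)
    return make_family_template(spec)


@pytest.fixture(scope="session")
def benchmark_5x7():
    """The standard synthetic benchmark: 5 families x 7 members, noise 0.3."""
    domains, labels = make_benchmark(5, 7, seed=1)
    return domains, dict(labels)


@pytest.fixture(scope="session")
def benchmark_pipeline(benchmark_5x7):
    """Full method run + consensus on the 5x7 benchmark (computed once)."""
    domains, labels = benchmark_5x7
    registry = default_registry()
    store = DomainStore(domains=domains)
    jobs = generate_jobs(
        domains, domains, [(n, registry.routing(n)) for n in ("usm", "tm", "rmsd")]
    )
    scores = execute_parallel(jobs, 1, registry, store, ContactMapCache(store))
    matrix = build_score_matrix(scores)
    result = consensus_pipeline(matrix)
    return {
        "domains": domains,
        "labels": labels,
        "jobs": jobs,
        "scores": scores,
        "matrix": matrix,
        "result": result,
    }
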