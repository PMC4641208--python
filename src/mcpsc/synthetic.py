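"""Synthetic labeled structure datasets and simulated job runtimes.

Families are built from deterministic C-alpha backbone templates (ideal
helix, extended zigzag strand, or a mixed layout), then members are sampled
by adding Gaussian coordinate noise, an optional sprinkling of deletions,
and a random rigid transform. All generators are pure functions of their
seed, so fixtures regenerate byte-identically and no data files need to be
shipped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from mcpsc.scheduling import CostModel, PSCJob, job_attribute
from mcpsc.structio import ONE_TO_THREE, ProteinDomain

__all__ = [
    "FamilySpec",
    "make_family_template",
    "sample_family_member",
    "make_benchmark",
    "write_labels_tsv",
    "simulate_runtimes",
    "write_pdb",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Ideal alpha-helix C-alpha parameters (rise per residue, turn per residue,
# helix radius), giving consecutive C-alpha spacing close to 3.8 A.
HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0
HELIX_RADIUS = 2.3

# Extended (strand-like) zigzag: 3.3 A along the axis with alternating
# lateral offset, again spacing consecutive C-alphas ~3.8 A apart.
EXTENDED_STEP = 3.3
EXTENDED_OFFSET = 1.878


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic fold family."""

    family_id: str
    geometry: str  # "helix" | "extended" | "mixed"
    n_residues: int
    n_members: int
    noise_sd: float
    indel_rate: float
    seed: int
    turn_deg: float = HELIX_TURN_DEG
    rise: float = HELIX_RISE
    radius: float = HELIX_RADIUS

    def __post_init__(self) -> None:
        if self.geometry not in ("helix", "extended", "mixed"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_residues < 10:
            raise ValueError("n_residues must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.indel_rate < 0.2):
            raise ValueError("indel_rate must be in [0, 0.2)")


def _helix_coords(n: int, rise: float, turn_deg: float, radius: float) -> np.ndarray:
    theta = np.deg2rad(turn_deg) * np.arange(n)
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n)]
    )


def _extended_coords(n: int) -> np.ndarray:
    x = EXTENDED_STEP * np.arange(n)
    y = EXTENDED_OFFSET * (np.arange(n) % 2)
    return np.column_stack([x, y, np.zeros(n)])


def make_family_template(spec: FamilySpec) -> ProteinDomain:
    """Deterministic C-alpha backbone plus a seeded random sequence."""
    n = spec.n_residues
    if spec.geometry == "helix":
        coords = _helix_coords(n, spec.rise, spec.turn_deg, spec.radius)
    elif spec.geometry == "extended":
        coords = _extended_coords(n)
    else:  # mixed: helix for the first half, strand continuing from its end
        n1 = n // 2
        head = _helix_coords(n1, spec.rise, spec.turn_deg, spec.radius)
        tail = _extended_coords(n - n1 + 1)[1:] + head[-1]
        coords = np.vstack([head, tail])
    rng = np.random.default_rng(spec.seed)
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    return ProteinDomain(
        id=f"{spec.family_id}_template",
        chain_id="A",
        sequence=sequence,
        ca_coords=coords,
        fold_label=spec.family_id,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def sample_family_member(
    template: ProteinDomain,
    noise_sd: float,
    indel_rate: float,
    seed: int,
    member_id: str | None = None,
) -> ProteinDomain:
    """Draw one family member from a template.

    Coordinates receive i.i.d. Gaussian noise (sigma = noise_sd) followed by
    a random rigid transform; each residue is deleted independently with
    probability ``indel_rate`` (at least 5 residues always survive). The
    member inherits the template's fold label.
    """
    rng = np.random.default_rng(seed)
    n = template.length
    keep = rng.random(n) >= indel_rate
    if keep.sum() < 5:
        keep[:] = True
    coords = template.ca_coords[keep] + rng.normal(0.0, noise_sd, size=(int(keep.sum()), 3))
    rot = _random_rotation(rng)
    trans = rng.uniform(-20.0, 20.0, size=3)
    coords = coords @ rot.T + trans
    sequence = "".join(c for c, k in zip(template.sequence, keep) if k)
    if member_id is None:
        member_id = f"{template.id}_m{seed}"
    return ProteinDomain(
        id=member_id,
        chain_id="A",
        sequence=sequence,
        ca_coords=coords,
        fold_label=template.fold_label,
    )


# Geometry/size rotation used when make_benchmark invents family specs:
# distinct shapes and lengths keep families structurally separable.
_FAMILY_RECIPES = (
    ("helix", 48, 100.0),
    ("extended", 64, 100.0),
    ("mixed", 56, 100.0),
    ("helix", 72, 130.0),
    ("mixed", 40, 80.0),
    ("extended", 80, 100.0),
    ("helix", 60, 60.0),
)


def make_benchmark(
    n_families: int,
    members_per_family: int,
    base_spec: FamilySpec | None = None,
    seed: int = 0,
) -> tuple[list[ProteinDomain], list[tuple[str, str]]]:
    """Generate a labeled multi-family benchmark.

    Families cycle through distinct template geometries and lengths (scaled
    copies beyond the built-in recipes). Returns the member domains and a
    (domain_id, fold_label) table; write it with :func:`write_labels_tsv`.
    """
    if n_families < 2:
        raise ValueError("n_families must be >= 2")
    if members_per_family < 1:
        raise ValueError("members_per_family must be >= 1")
    noise_sd = base_spec.noise_sd if base_spec is not None else 0.3
    indel_rate = base_spec.indel_rate if base_spec is not None else 0.0

    domains: list[ProteinDomain] = []
    labels: list[tuple[str, str]] = []
    for fam in range(n_families):
        geometry, n_res, turn = _FAMILY_RECIPES[fam % len(_FAMILY_RECIPES)]
        n_res += 10 * (fam // len(_FAMILY_RECIPES))  # keep later families distinct
        spec = FamilySpec(
            family_id=f"fam{fam:02d}",
            geometry=geometry,
            n_residues=n_res,
            n_members=members_per_family,
            noise_sd=noise_sd,
            indel_rate=indel_rate,
            seed=seed * 1000 + fam,
            turn_deg=turn,
        )
        template = make_family_template(spec)
        for m in range(members_per_family):
            member = sample_family_member(
                template,
                noise_sd=spec.noise_sd,
                indel_rate=spec.indel_rate,
                seed=seed * 100000 + fam * 1000 + m,
                member_id=f"{spec.family_id}_d{m:02d}",
            )
            domains.append(member)
            labels.append((member.id, spec.family_id))
    return domains, labels


def write_labels_tsv(labels: list[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write the domain_id -> fold_label table (tab-separated, with header)."""
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("domain_id\tfold_label\n")
        for domain_id, label in labels:
            fh.write(f"{domain_id}\t{label}\n")


def simulate_runtimes(
    jobs: list[PSCJob],
    cost_model: CostModel,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulated per-job costs: model(attr) times a lognormal factor.

    cost_j = model(attr_j) * exp(eps_j), eps_j ~ N(0, noise_sd^2), clamped
    to a small positive floor.
    """
    rng = np.random.default_rng(seed)
    attrs = np.array([job_attribute(j, cost_model.attribute) for j in jobs], dtype=float)
    base = cost_model.predict(attrs)
    noise = rng.normal(0.0, noise_sd, size=len(jobs)) if noise_sd > 0 else np.zeros(len(jobs))
    return np.maximum(base * np.exp(noise), 1e-9)


def write_pdb(domain: ProteinDomain, path: str | os.PathLike) -> None:
    """Write a minimal PDB v3 file (C-alpha-only ATOM records, chain A).

    Round-trips exactly through the reader at the format's 3-decimal
    coordinate precision.
    """
    coords = domain.ca_coords
    if coords.max() > 9999.999 or coords.min() < -999.999:
        raise ValueError("coordinates exceed PDB fixed-width field range")
    lines = []
    for k, (aa, (x, y, z)) in enumerate(zip(domain.sequence, coords), start=1):
        res3 = ONE_TO_THREE.get(aa, "UNK")
        lines.append(
            f"ATOM  {k:5d}  CA  {res3} A{k:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
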