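"""PDB domain reading and contact-map extraction.

A domain is reduced to the C-alpha trace of a single chain (the first chain
appearing in ATOM records unless overridden). Contact maps are sets of
residue index pairs whose C-alpha atoms lie within a distance threshold, at
a minimum sequence separation; they carry a canonical byte serialization so
that compression-based distances are reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProteinDomain",
    "ContactMap",
    "PDBParseError",
    "EmptyDomainError",
    "read_pdb_domain",
    "contact_map",
    "serialize_contact_map",
]

# Standard three-letter -> one-letter residue codes. Non-standard residues
# (MSE, UNK, ...) map to 'X' so length always matches the C-alpha trace.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class PDBParseError(ValueError):
    """Raised for malformed ATOM records; carries the offending line number."""


class EmptyDomainError(ValueError):
    """Raised when the selected chain contains no C-alpha atoms."""


@dataclass(frozen=True)
class ProteinDomain:
    """A parsed protein domain: id, one-letter sequence, ordered C-alpha trace.

    Parameters
    ----------
    id : str
        Domain identifier (typically the file stem).
    chain_id : str
        Chain the trace was taken from.
    sequence : str
        One-letter amino-acid string, same length as the trace.
    ca_coords : numpy.ndarray, shape (L, 3)
        Ordered C-alpha coordinates in Angstrom.
    fold_label : str, optional
        Ground-truth fold class, when known.
    """

    id: str
    chain_id: str
    sequence: str
    ca_coords: np.ndarray
    fold_label: str | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"ca_coords must be (L, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("domain must contain at least one residue")
        if coords.shape[0] != len(self.sequence):
            raise ValueError(
                f"sequence length {len(self.sequence)} != number of "
                f"coordinates {coords.shape[0]}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        coords.setflags(write=False)
        object.__setattr__(self, "ca_coords", coords)

    @property
    def length(self) -> int:
        return self.ca_coords.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinDomain):
            return NotImplemented
        return (
            self.id == other.id
            and self.chain_id == other.chain_id
            and self.sequence == other.sequence
            and np.array_equal(self.ca_coords, other.ca_coords)
            and self.fold_label == other.fold_label
        )

    def __hash__(self) -> int:
        return hash((self.id, self.chain_id, self.sequence))


@dataclass(frozen=True)
class ContactMap:
    """Residue-contact set of a domain plus the parameters that produced it.

    Contacts are 0-based index pairs (i, j) with i < j and
    j - i >= min_separation; indexing follows order of appearance in the
    C-alpha trace, independent of PDB residue numbering.
    """

    domain_id: str
    n_residues: int
    contacts: frozenset = field(default_factory=frozenset)
    threshold_angstrom: float = 8.0
    min_separation: int = 2

    def __post_init__(self) -> None:
        contacts = frozenset((int(i), int(j)) for i, j in self.contacts)
        for i, j in contacts:
            if not (0 <= i < j < self.n_residues):
                raise ValueError(f"contact ({i}, {j}) out of range for n={self.n_residues}")
            if j - i < self.min_separation:
                raise ValueError(
                    f"contact ({i}, {j}) violates min_separation={self.min_separation}"
                )
        object.__setattr__(self, "contacts", contacts)


def _parse_float(text: str, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record ({what}: {text!r})") from exc


def read_pdb_domain(
    pdb_text_or_path: str | os.PathLike,
    chain_override: str | None = None,
    domain_id: str | None = None,
) -> ProteinDomain:
    """Read a PDB file (or text) into a single-chain C-alpha domain.

    Only ATOM records of the first MODEL are considered; HETATM is ignored.
    The chain is the first one appearing in ATOM records unless
    ``chain_override`` is given. One C-alpha is kept per residue (first
    altloc encountered wins); residues lacking a C-alpha are skipped.

    Raises
    ------
    EmptyDomainError
        If the selected chain has no C-alpha atoms.
    PDBParseError
        On a malformed ATOM line (the message names the line number).
    """
    path_like = isinstance(pdb_text_or_path, os.PathLike) or (
        isinstance(pdb_text_or_path, str) and "\n" not in pdb_text_or_path
    )
    if path_like:
        path = os.fspath(pdb_text_or_path)
        with open(path, "r", encoding="ascii", errors="replace") as fh:
            text = fh.read()
        if domain_id is None:
            domain_id = os.path.splitext(os.path.basename(path))[0]
    else:
        text = str(pdb_text_or_path)
        if domain_id is None:
            domain_id = "domain"

    chain: str | None = chain_override
    seen: set[tuple[str, str]] = set()  # (resseq, icode) already holding a CA
    seq: list[str] = []
    coords: list[tuple[float, float, float]] = []

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record.strip() == "ENDMDL":
            break  # first model only
        if record != "ATOM  ":
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record too short ({len(line)} chars)")
        chain_id = line[21]
        if chain is None:
            chain = chain_id
        if chain_id != chain:
            continue
        atom_name = line[12:16].strip()
        if atom_name != "CA":
            continue
        res_key = (line[22:26], line[26])
        if res_key in seen:
            continue  # later altloc of a residue we already have
        seen.add(res_key)
        resname = line[17:20].strip()
        x = _parse_float(line[30:38], lineno, "x")
        y = _parse_float(line[38:46], lineno, "y")
        z = _parse_float(line[46:54], lineno, "z")
        seq.append(THREE_TO_ONE.get(resname, "X"))
        coords.append((x, y, z))

    if not coords:
        selected = chain if chain is not None else "<none>"
        raise EmptyDomainError(
            f"empty domain: no C-alpha atoms found in chain {selected!r} of {domain_id!r}"
        )

    return ProteinDomain(
        id=domain_id,
        chain_id=chain,
        sequence="".join(seq),
        ca_coords=np.array(coords, dtype=float),
    )


def contact_map(
    domain: ProteinDomain,
    threshold_angstrom: float = 8.0,
    min_separation: int = 2,
) -> ContactMap:
    """Compute the C-alpha contact map of a domain.

    A contact is any ordered index pair (i, j), j - i >= min_separation,
    whose Euclidean C-alpha distance is <= threshold_angstrom. Deterministic
    for a given domain and parameter set.
    """
    if threshold_angstrom <= 0:
        raise ValueError("threshold_angstrom must be > 0")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    coords = domain.ca_coords
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    ii, jj = np.triu_indices(n, k=min_separation)
    keep = dist[ii, jj] <= threshold_angstrom
    contacts = frozenset(zip(ii[keep].tolist(), jj[keep].tolist()))
    return ContactMap(
        domain_id=domain.id,
        n_residues=n,
        contacts=contacts,
        threshold_angstrom=threshold_angstrom,
        min_separation=min_separation,
    )


def serialize_contact_map(cm: ContactMap) -> bytes:
    """Canonical byte serialization of a contact map.

    Header line ``n=<n_residues>`` followed by one ``i<TAB>j`` line per
    contact, sorted by (i, j). ASCII, newline-terminated lines; injective on
    (n_residues, contacts) so distinct maps never collide.
    """
    lines = [f"n={cm.n_residues}"]
    lines.extend(f"{i}\t{j}" for i, j in sorted(cm.contacts))
    return ("\n".join(lines) + "\n").encode("ascii")
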