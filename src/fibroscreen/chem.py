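"""Minimal chemistry support: SDF V2000 connection tables, path
fingerprints, Tanimoto similarity.

Structures enter as MDL SDF V2000 records; only the atom and bond blocks are
read (coordinates are ignored — similarity here is topological).  The
fingerprint hashes all linear atom-bond paths of 1..7 heavy atoms: explicit
hydrogens are suppressed, each simple path is written as an atom/bond-symbol
string (e.g. ``C-C=O``), canonicalized as the lexicographic minimum of the
string and its reverse, and hashed onto a fixed-length bit set (default 1024
bits).  The construction is deterministic and invariant to atom input order.
Precomputed fingerprints from any external tool can be substituted via
:meth:`Fingerprint.from_bits`.

Tanimoto similarity is |A ∩ B| / |A ∪ B| on the bit sets; two empty
fingerprints score 0 by convention.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Molecule", "Fingerprint", "SdfError", "read_sdf", "parse_sdf",
           "fingerprint", "tanimoto", "tanimoto_matrix"]

BOND_SYMBOL = {1: "-", 2: "=", 3: "#", 4: ":"}


class SdfError(ValueError):
    """Malformed SDF record (reported with its record index)."""


@dataclass(frozen=True)
class Molecule:
    """A connection table: atom symbols and (i, j, order) bonds, 0-based."""

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, int], ...]
    name: str = ""


def _parse_record(lines: list[str], index: int) -> Molecule:
    if len(lines) < 4:
        raise SdfError(f"record {index}: too short for a V2000 header")
    name = lines[0].strip()
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise SdfError(f"record {index}: unreadable counts line {counts!r}") from None
    atom_lines = lines[4:4 + n_atoms]
    bond_lines = lines[4 + n_atoms:4 + n_atoms + n_bonds]
    if len(atom_lines) < n_atoms or len(bond_lines) < n_bonds:
        raise SdfError(f"record {index}: truncated atom/bond block")
    atoms = []
    for ln in atom_lines:
        sym = ln[31:34].strip()
        if not sym:
            raise SdfError(f"record {index}: atom line without element symbol: {ln!r}")
        atoms.append(sym)
    bonds = []
    for ln in bond_lines:
        try:
            a = int(ln[0:3]) - 1
            b = int(ln[3:6]) - 1
            order = int(ln[6:9])
        except (ValueError, IndexError):
            raise SdfError(f"record {index}: unreadable bond line {ln!r}") from None
        if not (0 <= a < n_atoms and 0 <= b < n_atoms) or a == b:
            raise SdfError(f"record {index}: bond references invalid atoms: {ln!r}")
        bonds.append((a, b, order))
    return Molecule(tuple(atoms), tuple(bonds), name)


def parse_sdf(text: str) -> list[Molecule]:
    """Parse SDF text (one or more ``$$$$``-separated V2000 records)."""
    mols = []
    chunk: list[str] = []
    index = 0
    for line in text.splitlines():
        if line.strip() == "$$$$":
            if any(s.strip() for s in chunk):
                mols.append(_parse_record(chunk, index))
                index += 1
            chunk = []
        else:
            chunk.append(line)
    if any(s.strip() for s in chunk):
        mols.append(_parse_record(chunk, index))
    return mols


def read_sdf(path) -> list[Molecule]:
    with open(path) as fh:
        return parse_sdf(fh.read())


@dataclass(frozen=True)
class Fingerprint:
    """A folded binary fingerprint: set bit positions plus the fold length."""

    bits: frozenset[int]
    length: int = 1024

    def __post_init__(self):
        if any(not 0 <= b < self.length for b in self.bits):
            raise ValueError("bit positions must lie in [0, length)")

    @classmethod
    def from_bits(cls, bits, length: int = 1024) -> "Fingerprint":
        return cls(frozenset(int(b) for b in bits), length)

    @property
    def n_set(self) -> int:
        return len(self.bits)


def _path_strings(mol: Molecule, max_atoms: int) -> set[str]:
    heavy = [i for i, a in enumerate(mol.atoms) if a != "H"]
    heavy_set = set(heavy)
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in heavy}
    for a, b, order in mol.bonds:
        if a in heavy_set and b in heavy_set:
            adj[a].append((b, order))
            adj[b].append((a, order))
    paths: set[str] = set()

    def walk(node: int, visited: list[int], label: str):
        canonical = min(label, label[::-1])
        paths.add(canonical)
        if len(visited) == max_atoms:
            return
        for nxt, order in adj[node]:
            if nxt in visited:
                continue
            sym = BOND_SYMBOL.get(order, f"~{order}~")
            walk(nxt, visited + [nxt], label + sym + mol.atoms[nxt])

    for start in heavy:
        walk(start, [start], mol.atoms[start])
    return paths


def fingerprint(mol: Molecule, *, n_bits: int = 1024, max_path_atoms: int = 7) -> Fingerprint:
    """Hashed linear-path fingerprint (hydrogen-suppressed, folded).

    Every simple path of 1..``max_path_atoms`` heavy atoms contributes one
    bit: the canonical path string is hashed (BLAKE2b) and folded modulo
    ``n_bits``.
    """
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    bits = set()
    for s in _path_strings(mol, max_path_atoms):
        digest = hashlib.blake2b(s.encode(), digest_size=8).digest()
        bits.add(int.from_bytes(digest, "big") % n_bits)
    return Fingerprint(frozenset(bits), n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A ∩ B| / |A ∪ B|; 0.0 when both fingerprints are empty."""
    if a.length != b.length:
        raise ValueError(f"fingerprint length mismatch: {a.length} vs {b.length}")
    union = a.bits | b.bits
    if not union:
        return 0.0
    return len(a.bits & b.bits) / len(union)


def tanimoto_matrix(fps: Mapping[str, Fingerprint]) -> pd.DataFrame:
    """Symmetric pairwise Tanimoto matrix over a compound set."""
    ids = list(fps)
    n = len(ids)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tanimoto(fps[ids[i]], fps[ids[j]])
    for i, cid in enumerate(ids):
        if not fps[cid].bits:
            m[i, i] = 0.0
    return pd.DataFrame(m, index=ids, columns=ids)
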