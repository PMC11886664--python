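"""Canonical bond-type keys, the bci antisymmetry convention, and formal charges.

A bond charge increment is antisymmetric under swapping the two atom types
(omega_IJ = -omega_JI), so each unordered type pair carries exactly one
unknown and a homotype pair (I,I) carries none.  The canonical key orders
the two labels lexicographically; the stored omega is, by this package's
convention, the charge increment *received by the atom of the smaller
(type_lo) label*, while the type_hi atom receives -omega.  For the
platinum-complex keys (Cl,Pt), (N,Pt) and (H,N) this makes the stored
value the increment received by the ligand-side atom, which is the
orientation the field reports for "bci Pt-N" and friends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mol2 import Molecule

__all__ = [
    "BondTypeKey",
    "FormalChargeScheme",
    "SchemeError",
    "canonical_key",
    "enumerate_bond_types",
    "homotype_bond_types",
    "formal_charge_vector",
    "to_element_types",
]


class SchemeError(KeyError):
    """A strict formal-charge scheme failed to resolve an atom type."""


@dataclass(frozen=True, order=True)
class BondTypeKey:
    """Canonically ordered pair of atom-type labels: one bci unknown."""

    type_lo: str
    type_hi: str

    def __post_init__(self) -> None:
        if not self.type_lo or not self.type_hi:
            raise ValueError("bond-type labels must be non-empty")
        if self.type_lo > self.type_hi:
            raise ValueError(
                f"non-canonical key ({self.type_lo},{self.type_hi}); "
                "use canonical_key()"
            )

    @property
    def degenerate(self) -> bool:
        """True for homotype pairs (I,I), which carry no unknown."""
        return self.type_lo == self.type_hi

    def __str__(self) -> str:
        return f"{self.type_lo}-{self.type_hi}"


def canonical_key(type_a: str, type_b: str) -> tuple[BondTypeKey, int]:
    """Canonicalize a type pair; return the key and the orientation of atom a.

    The orientation is +1 when ``type_a`` is the type_lo side (atom a
    receives +omega) and -1 when the pair was swapped.  Homotype pairs
    return orientation +1 with a degenerate key, since antisymmetry forces
    omega_II = 0.
    """
    if not type_a or not type_b:
        raise ValueError("bond-type labels must be non-empty")
    if type_a <= type_b:
        return BondTypeKey(type_a, type_b), +1
    return BondTypeKey(type_b, type_a), -1


def enumerate_bond_types(m: Molecule) -> list[BondTypeKey]:
    """Unique non-degenerate keys in first-appearance order over the bond list."""
    seen: dict[BondTypeKey, None] = {}
    for bond in m.bonds:
        key, _ = canonical_key(m.atoms[bond.a - 1].atom_type, m.atoms[bond.b - 1].atom_type)
        if not key.degenerate and key not in seen:
            seen[key] = None
    return list(seen)


def homotype_bond_types(m: Molecule) -> list[BondTypeKey]:
    """Degenerate (I,I) keys present in the bond list; their omega is 0 by symmetry."""
    seen: dict[BondTypeKey, None] = {}
    for bond in m.bonds:
        key, _ = canonical_key(m.atoms[bond.a - 1].atom_type, m.atoms[bond.b - 1].atom_type)
        if key.degenerate and key not in seen:
            seen[key] = None
    return list(seen)


@dataclass
class FormalChargeScheme:
    """Mapping atom-type label -> formal charge q0 (e).

    The default scheme is all-zero.  A non-strict scheme falls back to 0
    for unlisted types; a strict scheme raises :class:`SchemeError`.
    """

    values: dict[str, float] = field(default_factory=dict)
    strict: bool = False

    def resolve(self, atom_type: str) -> float:
        if atom_type in self.values:
            return float(self.values[atom_type])
        if self.strict:
            raise SchemeError(
                f"strict formal-charge scheme does not resolve atom type {atom_type!r}"
            )
        return 0.0

    @classmethod
    def from_text(cls, text: str, strict: bool = False) -> "FormalChargeScheme":
        """Parse rows of ``atom_type  q0`` with '#' comments."""
        values: dict[str, float] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"line {lineno}: expected 'atom_type q0', got {raw!r}")
            values[fields[0]] = float(fields[1].replace("−", "-").replace("–", "-"))
        return cls(values=values, strict=strict)

    @classmethod
    def from_file(cls, path, strict: bool = False) -> "FormalChargeScheme":
        with open(path, encoding="utf-8") as fh:
            return cls.from_text(fh.read(), strict=strict)


ZERO_SCHEME = FormalChargeScheme()


def formal_charge_vector(m: Molecule, scheme: FormalChargeScheme | None = None) -> np.ndarray:
    """q0 vector aligned with atom order; the default scheme is all zeros."""
    scheme = scheme or ZERO_SCHEME
    return np.array([scheme.resolve(a.atom_type) for a in m.atoms], dtype=float)


def to_element_types(m: Molecule) -> Molecule:
    """Copy of the molecule with atom types collapsed to element symbols.

    Useful when mol2 files carry SYBYL types (N.4, ...) but the increments
    should be fitted at the chemical-identity level (Pt-Cl, Pt-N, N-H).
    """
    atoms = [replace(a, atom_type=a.element) for a in m.atoms]
    return Molecule(
        name=m.name,
        atoms=atoms,
        bonds=list(m.bonds),
        has_charges=m.has_charges,
        mol_type=m.mol_type,
        charge_type=m.charge_type,
    )
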