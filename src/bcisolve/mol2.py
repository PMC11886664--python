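"""TRIPOS mol2 reading/writing and external charge-table parsing.

Only the MOLECULE, ATOM and BOND record types are interpreted; any other
record type (SUBSTRUCTURE, CRYSIN, ...) is carried past with a logged
notice.  Coordinates are parsed and written back but never used by the
solver.  Atom indices are 1-based externally (the mol2 convention); all
in-memory containers hold atoms in file order and :class:`Bond` stores the
1-based endpoint indices as written.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "Mol2ParseError",
    "MoleculeValidationError",
    "ChargeTableError",
    "parse_mol2",
    "read_mol2",
    "write_mol2",
    "read_charge_override",
    "read_charge_override_file",
]

logger = logging.getLogger(__name__)


class Mol2ParseError(ValueError):
    """Raised when a mol2 document is structurally malformed."""


class MoleculeValidationError(ValueError):
    """Raised when parsed records violate molecular invariants."""


class ChargeTableError(ValueError):
    """Raised for malformed external charge tables."""


def _infer_element(atom_type: str, atom_name: str) -> str:
    """Element symbol from the SYBYL type (text before '.'), else the name.

    Pt carries no standard SYBYL type, so user-supplied labels such as
    ``Pt`` pass through untouched; names like ``Cl3`` fall back to ``Cl``.
    """
    for source in (atom_type.split(".")[0], atom_name):
        m = re.match(r"[A-Za-z]+", source)
        if m:
            sym = m.group(0)
            return sym[0].upper() + sym[1:].lower()
    return atom_type


@dataclass
class Atom:
    """One atom row: label, type, and charges in elementary-charge units."""

    index: int  # 1-based file-order position
    name: str
    element: str
    atom_type: str
    partial_charge: float = 0.0
    formal_charge: float = 0.0
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0

    def __post_init__(self) -> None:
        if not self.atom_type:
            raise MoleculeValidationError(f"atom {self.index}: empty atom_type")
        if not (math.isfinite(self.partial_charge) and math.isfinite(self.formal_charge)):
            raise MoleculeValidationError(f"atom {self.index}: non-finite charge")


@dataclass(frozen=True)
class Bond:
    """Undirected bond between 1-based atom indices a and b.

    ``order_label`` is the mol2 bond-type column, carried through verbatim
    and never interpreted.
    """

    a: int
    b: int
    order_label: str = "1"


@dataclass
class Molecule:
    """A labeled chemical structure: ordered atoms plus a bond list."""

    name: str
    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    has_charges: bool = True
    mol_type: str = "SMALL"
    charge_type: str = "USER_CHARGES"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def total_charge(self) -> float:
        """Sum of partial charges (e); recomputed, never stored."""
        return float(sum(a.partial_charge for a in self.atoms))

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def with_charges(self, q: np.ndarray, name: str | None = None) -> "Molecule":
        """Copy of this molecule with the partial-charge column replaced."""
        q = np.asarray(q, dtype=float)
        if q.shape != (self.n_atoms,):
            raise ChargeTableError(
                f"charge vector of length {q.size} applied to "
                f"{self.n_atoms}-atom molecule {self.name!r}"
            )
        atoms = [replace(a, partial_charge=float(c)) for a, c in zip(self.atoms, q)]
        return Molecule(
            name=name if name is not None else self.name,
            atoms=atoms,
            bonds=list(self.bonds),
            has_charges=True,
            mol_type=self.mol_type,
            charge_type="USER_CHARGES" if self.charge_type == "NO_CHARGES" else self.charge_type,
        )

    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if bond.a == bond.b:
                raise MoleculeValidationError(
                    f"molecule {self.name!r}: self-bond on atom {bond.a}"
                )
            if not (1 <= bond.a <= n and 1 <= bond.b <= n):
                raise MoleculeValidationError(
                    f"molecule {self.name!r}: bond ({bond.a},{bond.b}) "
                    f"references a nonexistent atom (n_atoms={n})"
                )
            pair = (min(bond.a, bond.b), max(bond.a, bond.b))
            if pair in seen:
                raise MoleculeValidationError(
                    f"molecule {self.name!r}: duplicate bond {pair}"
                )
            seen.add(pair)

    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 adjacency matrix in atom order."""
        A = np.zeros((self.n_atoms, self.n_atoms), dtype=int)
        for bond in self.bonds:
            A[bond.a - 1, bond.b - 1] = 1
            A[bond.b - 1, bond.a - 1] = 1
        return A


# --- parsing -----------------------------------------------------------------

_RECORD = re.compile(r"^@<TRIPOS>(\w+)\s*$", re.IGNORECASE)


def _sections(text: str):
    """Yield (record_name, list-of-lines) in document order."""
    name = None
    lines: list[str] = []
    for raw in text.splitlines():
        line = raw.rstrip()
        m = _RECORD.match(line.strip())
        if m:
            if name is not None:
                yield name, lines
            name = m.group(1).upper()
            lines = []
        elif name is not None:
            lines.append(line)
    if name is not None:
        yield name, lines


def _data_lines(lines: list[str]) -> list[str]:
    return [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]


def parse_mol2(text: str) -> list[Molecule]:
    """Parse a mol2 document into one :class:`Molecule` per MOLECULE record.

    Atom and bond order are preserved verbatim.  When the MOLECULE record
    declares ``NO_CHARGES`` (or the ATOM rows carry no 9th column) the
    charges are set to zero and ``has_charges`` is False, so that "no data"
    is distinguishable from "neutral".
    """
    groups: list[dict] = []
    current: dict | None = None
    for name, lines in _sections(text):
        if name == "MOLECULE":
            current = {"MOLECULE": lines}
            groups.append(current)
        elif current is None:
            raise Mol2ParseError(f"@<TRIPOS>{name} record before any MOLECULE record")
        elif name in ("ATOM", "BOND"):
            current[name] = lines
        else:
            logger.info("ignoring @<TRIPOS>%s record", name)
    if not groups:
        raise Mol2ParseError("no @<TRIPOS>MOLECULE record found")
    return [_build_molecule(g) for g in groups]


def _build_molecule(group: dict) -> Molecule:
    header = _data_lines(group["MOLECULE"])
    if len(header) < 2:
        raise Mol2ParseError("MOLECULE record shorter than two lines")
    mol_name = header[0].strip()
    counts = header[1].split()
    try:
        n_atoms = int(counts[0])
        n_bonds = int(counts[1]) if len(counts) > 1 else 0
    except (ValueError, IndexError) as exc:
        raise Mol2ParseError(
            f"molecule {mol_name!r}: unreadable atom/bond counts {header[1]!r}"
        ) from exc
    mol_type = header[2].strip() if len(header) > 2 else "SMALL"
    charge_type = header[3].strip() if len(header) > 3 else "NO_CHARGES"

    atom_lines = _data_lines(group.get("ATOM", []))
    bond_lines = _data_lines(group.get("BOND", []))
    if len(atom_lines) != n_atoms:
        raise Mol2ParseError(
            f"molecule {mol_name!r}: MOLECULE record declares {n_atoms} atoms "
            f"but the ATOM section lists {len(atom_lines)}"
        )
    if len(bond_lines) != n_bonds:
        raise Mol2ParseError(
            f"molecule {mol_name!r}: MOLECULE record declares {n_bonds} bonds "
            f"but the BOND section lists {len(bond_lines)}"
        )

    no_charges = charge_type.upper() == "NO_CHARGES"
    has_charges = not no_charges
    atoms: list[Atom] = []
    for pos, line in enumerate(atom_lines, start=1):
        f = line.split()
        if len(f) < 6:
            raise Mol2ParseError(
                f"molecule {mol_name!r}: ATOM row {pos} has {len(f)} fields (need >= 6)"
            )
        atom_name, atom_type = f[1], f[5]
        try:
            x, y, z = float(f[2]), float(f[3]), float(f[4])
            charge = 0.0
            if not no_charges and len(f) >= 9:
                charge = float(f[8])
            elif not no_charges and len(f) < 9:
                has_charges = False
        except ValueError as exc:
            raise Mol2ParseError(
                f"molecule {mol_name!r}: unreadable numeric field in ATOM row {pos}"
            ) from exc
        atoms.append(
            Atom(
                index=pos,
                name=atom_name,
                element=_infer_element(atom_type, atom_name),
                atom_type=atom_type,
                partial_charge=charge,
                x=x,
                y=y,
                z=z,
            )
        )
    if not has_charges:
        # a mixed section (some rows with, some without a charge column)
        # is treated as chargeless as a whole
        atoms = [replace(a, partial_charge=0.0) for a in atoms]

    bonds: list[Bond] = []
    for pos, line in enumerate(bond_lines, start=1):
        f = line.split()
        if len(f) < 3:
            raise Mol2ParseError(
                f"molecule {mol_name!r}: BOND row {pos} has {len(f)} fields (need >= 3)"
            )
        try:
            a, b = int(f[1]), int(f[2])
        except ValueError as exc:
            raise Mol2ParseError(
                f"molecule {mol_name!r}: unreadable atom index in BOND row {pos}"
            ) from exc
        bonds.append(Bond(a=a, b=b, order_label=f[3] if len(f) > 3 else "1"))

    return Molecule(
        name=mol_name,
        atoms=atoms,
        bonds=bonds,
        has_charges=has_charges,
        mol_type=mol_type,
        charge_type=charge_type,
    )


def read_mol2(path) -> list[Molecule]:
    with open(path, encoding="utf-8") as fh:
        return parse_mol2(fh.read())


def write_mol2(m: Molecule) -> str:
    """Serialize a molecule to a mol2 document.

    Charges are written with six decimals so that a write -> parse round
    trip reproduces them to 1e-6 e; a chargeless molecule writes 0.000000
    under a NO_CHARGES tag.
    """
    charge_type = m.charge_type if m.has_charges else "NO_CHARGES"
    out = [
        "@<TRIPOS>MOLECULE",
        m.name,
        f"{m.n_atoms:>5d} {len(m.bonds):>5d} 0 0 0",
        m.mol_type,
        charge_type,
        "@<TRIPOS>ATOM",
    ]
    for a in m.atoms:
        q = a.partial_charge if m.has_charges else 0.0
        out.append(
            f"{a.index:>7d} {a.name:<8s} {a.x:>10.4f} {a.y:>10.4f} {a.z:>10.4f} "
            f"{a.atom_type:<8s} 1 RES1 {q:>12.6f}"
        )
    out.append("@<TRIPOS>BOND")
    for i, b in enumerate(m.bonds, start=1):
        out.append(f"{i:>6d} {b.a:>6d} {b.b:>6d} {b.order_label}")
    return "\n".join(out) + "\n"


def write_mol2_file(m: Molecule, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_mol2(m))


# --- external charge tables ---------------------------------------------------


def read_charge_override(text: str) -> np.ndarray:
    """Parse a plain-text charge table into a charge vector (e).

    Two layouts are accepted: two columns ``atom_index charge`` (indices
    must form a permutation of 1..n) or a bare column of charges in atom
    order.  Separators are whitespace or commas; ``#`` starts a comment.
    """
    rows: list[list[str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f for f in re.split(r"[,\s]+", line) if f]
        rows.append(fields)
        if len(fields) not in (1, 2):
            raise ChargeTableError(
                f"line {lineno}: expected 1 or 2 columns, found {len(fields)}"
            )
    if not rows:
        raise ChargeTableError("empty charge table")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ChargeTableError("mixed 1- and 2-column rows in charge table")

    n = len(rows)
    charges = np.empty(n, dtype=float)
    if widths == {1}:
        for i, (val,) in enumerate(rows):
            charges[i] = _parse_charge(val)
        return charges

    seen: set[int] = set()
    for idx_s, val in rows:
        try:
            idx = int(idx_s)
        except ValueError as exc:
            raise ChargeTableError(f"non-integer atom index {idx_s!r}") from exc
        if idx in seen:
            raise ChargeTableError(f"duplicate atom index {idx}")
        if not (1 <= idx <= n):
            raise ChargeTableError(
                f"atom index {idx} outside 1..{n}; indices must be a permutation"
            )
        seen.add(idx)
        charges[idx - 1] = _parse_charge(val)
    return charges


def _parse_charge(token: str) -> float:
    # tables copied from publications often use U+2212 for the minus sign
    try:
        value = float(token.replace("−", "-").replace("–", "-"))
    except ValueError as exc:
        raise ChargeTableError(f"non-numeric charge {token!r}") from exc
    if not math.isfinite(value):
        raise ChargeTableError(f"non-finite charge {token!r}")
    return value


def read_charge_override_file(path) -> np.ndarray:
    with open(path, encoding="utf-8") as fh:
        return read_charge_override(fh.read())
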