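"""Inverse least-squares fitting of bond charge increments.

The MMFF94 charge model writes the partial charge of atom j as

    q_j = q0_j + sum over bonds j-k of omega(I_k, I_j)

where q0 is the formal charge of the atom type and omega is the bond
charge increment, antisymmetric in its two types.  Given a structure with
known partial charges this becomes a linear system B omega = q - q0 whose
coefficient matrix B has one row per atom and one signed integer column
per non-degenerate bond type: each bond adds +1 to the row of its type_lo
atom and -1 to the row of its type_hi atom.  Every column of B therefore
sums to zero, so the fitted charges always conserve the total formal
charge; for an ion with q0 = 0 the net charge is mathematically forced
into the residuals and is surfaced as a diagnostic rather than silently
redistributed.

The system is solved by SVD-based least squares (minimum-norm solution
for rank-deficient B, relative singular-value cutoff 1e-10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .bondtypes import (
    BondTypeKey,
    FormalChargeScheme,
    canonical_key,
    enumerate_bond_types,
    formal_charge_vector,
)
from .mol2 import Molecule

__all__ = [
    "CoefficientSystem",
    "BciSolution",
    "BciStats",
    "StatEntry",
    "Diagnostics",
    "MissingBondTypeError",
    "build_system",
    "build_pooled_system",
    "solve",
    "solve_molecule",
    "apply_bci",
    "solve_batch",
    "aggregate_stats",
    "diagnostics",
    "write_par",
    "format_par",
    "read_par",
    "NET_CHARGE_WARN_THRESHOLD",
]

#: relative SVD cutoff used for rank determination in the least-squares solve
SVD_RCOND = 1e-10

#: |net charge mismatch| (e) beyond which the system is flagged inconsistent
NET_CHARGE_WARN_THRESHOLD = 1e-3


class MissingBondTypeError(KeyError):
    """An increment table does not resolve every bond type of a molecule."""

    def __init__(self, missing: list[BondTypeKey]):
        self.missing = list(missing)
        super().__init__(
            "increment table missing bond types: "
            + ", ".join(str(k) for k in self.missing)
        )


@dataclass
class CoefficientSystem:
    """The linear system B omega = rhs for one structure or a pooled stack.

    B holds signed bond counts (integers); row j, column (lo,hi) is the
    number of bonds at atom j where j sits on the type_lo side minus the
    number where it sits on the type_hi side.  rhs is q - q0.
    """

    B: np.ndarray  # (n_atoms, n_keys) int
    rhs: np.ndarray  # (n_atoms,) float
    keys: list[BondTypeKey]
    name: str = ""

    @property
    def n_atoms(self) -> int:
        return self.B.shape[0]

    @property
    def n_unknowns(self) -> int:
        return self.B.shape[1]


@dataclass
class BciSolution:
    """Solved increments for one system, with residual diagnostics."""

    omega: dict[BondTypeKey, float]
    residuals: np.ndarray  # B omega - rhs, per atom (e)
    rss: float  # sum of squared residuals (e^2)
    rank: int
    net_charge_mismatch: float  # sum(q) - sum(q0) (e)
    keys: list[BondTypeKey] = field(default_factory=list)
    name: str = ""

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.residuals))) if self.residuals.size else 0.0


@dataclass
class StatEntry:
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass
class BciStats:
    """Per-bond-type aggregate of omega across a set of solutions."""

    per_key: dict[BondTypeKey, StatEntry]

    def to_rows(self) -> list[dict]:
        rows = []
        for key in sorted(self.per_key):
            e = self.per_key[key]
            rows.append(
                {
                    "type_lo": key.type_lo,
                    "type_hi": key.type_hi,
                    "n": e.n,
                    "mean": e.mean,
                    "sd": e.sd,
                    "min": e.min,
                    "max": e.max,
                }
            )
        return rows


def build_system(
    m: Molecule,
    scheme: FormalChargeScheme | None = None,
    keys: list[BondTypeKey] | None = None,
) -> CoefficientSystem:
    """Assemble B and q - q0 for one molecule.

    ``keys`` fixes the column ordering (used for pooled solves); by default
    the molecule's own non-degenerate keys in first-appearance order are
    used.  A molecule whose bonds are all homotype yields a valid 0-column
    system.
    """
    if keys is None:
        keys = enumerate_bond_types(m)
    col = {k: i for i, k in enumerate(keys)}
    B = np.zeros((m.n_atoms, len(keys)), dtype=int)
    for bond in m.bonds:
        ta = m.atoms[bond.a - 1].atom_type
        tb = m.atoms[bond.b - 1].atom_type
        key, orient = canonical_key(ta, tb)
        if key.degenerate:
            continue  # omega_II = 0: the bond contributes only to residuals
        j = col[key]
        B[bond.a - 1, j] += orient
        B[bond.b - 1, j] -= orient
    rhs = m.charges - formal_charge_vector(m, scheme)
    return CoefficientSystem(B=B, rhs=rhs, keys=list(keys), name=m.name)


def build_pooled_system(
    molecules: list[Molecule],
    scheme: FormalChargeScheme | None = None,
) -> CoefficientSystem:
    """Stack the per-molecule systems over the union of their bond types."""
    keys: dict[BondTypeKey, None] = {}
    for m in molecules:
        for k in enumerate_bond_types(m):
            keys.setdefault(k, None)
    key_list = list(keys)
    systems = [build_system(m, scheme, keys=key_list) for m in molecules]
    B = np.vstack([s.B for s in systems]) if systems else np.zeros((0, 0), dtype=int)
    rhs = np.concatenate([s.rhs for s in systems]) if systems else np.zeros(0)
    name = "+".join(m.name for m in molecules)
    return CoefficientSystem(B=B, rhs=rhs, keys=key_list, name=name)


def solve(system: CoefficientSystem) -> BciSolution:
    """Least-squares solve; minimum-norm omega when B is rank-deficient."""
    B = system.B.astype(float)
    if system.n_unknowns == 0:
        omega_vec = np.zeros(0)
        rank = 0
    else:
        omega_vec, _, rank, _ = scipy.linalg.lstsq(
            B, system.rhs, cond=SVD_RCOND, lapack_driver="gelsd"
        )
    residuals = B @ omega_vec - system.rhs
    return BciSolution(
        omega={k: float(w) for k, w in zip(system.keys, omega_vec)},
        residuals=residuals,
        rss=float(residuals @ residuals),
        rank=int(rank),
        net_charge_mismatch=float(np.sum(system.rhs)),
        keys=list(system.keys),
        name=system.name,
    )


def solve_molecule(
    m: Molecule, scheme: FormalChargeScheme | None = None
) -> BciSolution:
    """Convenience: build and solve the system for a single molecule."""
    return solve(build_system(m, scheme))


def apply_bci(
    m: Molecule,
    table: dict[BondTypeKey, float],
    scheme: FormalChargeScheme | None = None,
) -> np.ndarray:
    """Forward MMFF94 charge rule: q = q0 + summed signed increments.

    By the column-sum-zero structure the output always sums to sum(q0)
    exactly (up to floating rounding), whatever the table holds.  Degenerate
    (homotype) bond types contribute zero and need not appear in the table.
    """
    missing = [k for k in enumerate_bond_types(m) if k not in table]
    if missing:
        raise MissingBondTypeError(missing)
    q = formal_charge_vector(m, scheme)
    for bond in m.bonds:
        ta = m.atoms[bond.a - 1].atom_type
        tb = m.atoms[bond.b - 1].atom_type
        key, orient = canonical_key(ta, tb)
        if key.degenerate:
            continue
        w = table[key]
        q[bond.a - 1] += orient * w
        q[bond.b - 1] -= orient * w
    return q


def solve_batch(
    molecules: list[Molecule],
    scheme: FormalChargeScheme | None = None,
    mode: str = "per-structure",
) -> tuple[list[BciSolution], BciStats]:
    """Solve many structures, either independently or as one stacked system.

    Per-structure mode (the default) solves each molecule on its own and
    aggregates statistics over shared keys; pooled mode stacks all atom
    rows into a single system and solves once.
    """
    if not molecules:
        raise ValueError("solve_batch requires at least one molecule")
    if mode == "per-structure":
        solutions = [solve_molecule(m, scheme) for m in molecules]
    elif mode == "pooled":
        solutions = [solve(build_pooled_system(molecules, scheme))]
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'per-structure' or 'pooled'")
    return solutions, aggregate_stats(solutions)


def aggregate_stats(solutions: list[BciSolution]) -> BciStats:
    values: dict[BondTypeKey, list[float]] = {}
    for sol in solutions:
        for key, w in sol.omega.items():
            values.setdefault(key, []).append(w)
    per_key: dict[BondTypeKey, StatEntry] = {}
    for key in sorted(values):
        v = np.array(values[key])
        per_key[key] = StatEntry(
            n=v.size,
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
            min=float(v.min()),
            max=float(v.max()),
        )
    return BciStats(per_key=per_key)


@dataclass
class Diagnostics:
    """Consistency report for one solution."""

    name: str
    n_unknowns: int
    rank: int
    rss: float
    max_abs_residual: float
    net_charge_mismatch: float
    rss_lower_bound: float  # mismatch^2 / n_atoms, forced by column-sum zero
    warnings: list[str]

    def __str__(self) -> str:
        lines = [
            f"structure: {self.name or '<unnamed>'}",
            f"unknowns: {self.n_unknowns}  rank: {self.rank}",
            f"rss: {self.rss:.6g} e^2  max|residual|: {self.max_abs_residual:.6g} e",
            f"net charge mismatch (sum q - sum q0): {self.net_charge_mismatch:.6g} e",
        ]
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)


def diagnostics(sol: BciSolution) -> Diagnostics:
    """Rank, residual and charge-conservation checks for a solved system.

    When |sum(q) - sum(q0)| exceeds ``NET_CHARGE_WARN_THRESHOLD`` the
    system is necessarily inconsistent (every column of B sums to zero,
    so no omega can absorb a net charge) and rss is bounded below by
    mismatch^2 / n_atoms.
    """
    n_atoms = sol.residuals.size
    bound = (sol.net_charge_mismatch**2 / n_atoms) if n_atoms else 0.0
    warnings: list[str] = []
    if sol.rank < len(sol.keys):
        warnings.append(
            f"rank-deficient system (rank {sol.rank} < {len(sol.keys)} unknowns); "
            "reported omega is the minimum-norm solution"
        )
    if abs(sol.net_charge_mismatch) > NET_CHARGE_WARN_THRESHOLD:
        warnings.append(
            f"net charge mismatch {sol.net_charge_mismatch:.4f} e: the system is "
            f"inconsistent and rss >= {bound:.4f} e^2 is unavoidable; consider a "
            "formal-charge scheme carrying the ionic charge"
        )
    return Diagnostics(
        name=sol.name,
        n_unknowns=len(sol.keys),
        rank=sol.rank,
        rss=sol.rss,
        max_abs_residual=sol.max_abs_residual,
        net_charge_mismatch=sol.net_charge_mismatch,
        rss_lower_bound=bound,
        warnings=warnings,
    )


# --- .par parameter files -----------------------------------------------------

_PAR_HEADER = """\
# bci parameter file
# convention: bci is the charge increment received by the type_lo atom of
#   each bond; the type_hi atom receives -bci (antisymmetry)
# columns: type_lo type_hi bci n sd
"""


def format_par(stats_or_solution) -> str:
    """Render a solution or aggregate statistics as a .par document.

    Rows are sorted canonically and formatted with fixed five-decimal
    values so reruns are byte-identical.
    """
    if isinstance(stats_or_solution, BciSolution):
        entries = {
            k: (w, 1, 0.0) for k, w in stats_or_solution.omega.items()
        }
    elif isinstance(stats_or_solution, BciStats):
        entries = {
            k: (e.mean, e.n, e.sd) for k, e in stats_or_solution.per_key.items()
        }
    else:
        entries = {k: (float(w), 1, 0.0) for k, w in dict(stats_or_solution).items()}
    lines = [_PAR_HEADER.rstrip("\n")]
    for key in sorted(entries):
        bci, n, sd = entries[key]
        lines.append(
            f"{key.type_lo:<8s} {key.type_hi:<8s} {bci:>10.5f} {n:>4d} {sd:>10.5f}"
        )
    return "\n".join(lines) + "\n"


def write_par(stats_or_solution, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_par(stats_or_solution))


def read_par(path_or_text) -> dict[BondTypeKey, float]:
    """Read a .par table back into an increment dictionary."""
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        text = path_or_text
    else:
        with open(path_or_text, encoding="utf-8") as fh:
            text = fh.read()
    table: dict[BondTypeKey, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f".par line {lineno}: expected 'type_lo type_hi bci ...'")
        key, orient = canonical_key(fields[0], fields[1])
        value = float(fields[2])
        if not math.isfinite(value):
            raise ValueError(f".par line {lineno}: non-finite bci")
        table[key] = orient * value
    return table
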