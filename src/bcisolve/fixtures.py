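"""Packaged reference structures and published charge sets.

The package ships connectivity-only mol2 files for the worked platinum
complexes — cisplatin (cis-[Pt(NH3)2Cl2]), tetrachloroplatinate(II)
([PtCl4]2-), tetraammineplatinum(II) ([Pt(NH3)4]2+) and the
alpha-cisplatin unit cell (two formula units) — together with published
partial-charge columns (CHELPG/Hirshfeld/Mulliken in the gas phase,
Bader/Hirshfeld/Mulliken for the solid) and the experimental-vs-calculated
lattice parameters of the two cisplatin polymorphs.  Atom types in these
files are plain element symbols, so the fitted increments live at the
chemical-identity level (Pt-Cl, Pt-N, N-H).
"""

from __future__ import annotations

from importlib.resources import files

from .metrics import PairedSeries, read_pairs_csv
from .mol2 import Molecule, parse_mol2, read_charge_override

__all__ = [
    "CHARGE_SETS",
    "charge_set_names",
    "load_structure",
    "load_charges",
    "load_molecule",
    "lattice_series",
    "data_path",
]

_DATA = files("bcisolve.data")

#: structure name -> available charge-set names
CHARGE_SETS: dict[str, tuple[str, ...]] = {
    "cisplatin": (
        "dsdblyp_chelpg",
        "dsdblyp_hirshfeld",
        "dsdblyp_mulliken",
        "tpssh_chelpg",
        "tpssh_hirshfeld",
        "tpssh_mulliken",
    ),
    "tetrachloroplatinate": (
        "pbeqidh_dkhtzvpp_chelpg",
        "pbeqidh_dkhtzvpp_hirshfeld",
        "pbeqidh_dkhtzvpp_mulliken",
        "pbeqidh_def2qzvp_chelpg",
        "pbeqidh_def2qzvp_hirshfeld",
        "pbeqidh_def2qzvp_mulliken",
    ),
    "tetraammineplatinum": (),
    "alpha_cisplatin_solid": ("bader", "hirshfeld", "mulliken"),
}

_FILENAMES = {
    "cisplatin": "cisplatin.mol2",
    "tetrachloroplatinate": "tetrachloroplatinate.mol2",
    "tetraammineplatinum": "tetraammineplatinum.mol2",
    "alpha_cisplatin_solid": "alpha_cisplatin_solid.mol2",
}


def data_path(relative: str):
    """Traversable handle on a packaged data file (for CLI demos and tests)."""
    return _DATA / relative


def charge_set_names(structure: str) -> tuple[str, ...]:
    return CHARGE_SETS[structure]


def load_structure(structure: str) -> Molecule:
    """Connectivity-only molecule (has_charges is False)."""
    try:
        fname = _FILENAMES[structure]
    except KeyError:
        raise KeyError(
            f"unknown structure {structure!r}; available: {sorted(_FILENAMES)}"
        ) from None
    return parse_mol2((_DATA / fname).read_text())[0]


def load_charges(structure: str, charge_set: str):
    """Published charge vector (e) for a structure, in atom order."""
    if charge_set not in CHARGE_SETS.get(structure, ()):
        raise KeyError(
            f"unknown charge set {charge_set!r} for {structure!r}; "
            f"available: {CHARGE_SETS.get(structure, ())}"
        )
    if structure == "alpha_cisplatin_solid":
        fname = f"charges/alpha_solid_{charge_set}.chg"
    else:
        fname = f"charges/{structure}_{charge_set}.chg"
    return read_charge_override((_DATA / fname).read_text())


def load_molecule(structure: str, charge_set: str) -> Molecule:
    """Structure with one of its published charge sets applied."""
    m = load_structure(structure)
    q = load_charges(structure, charge_set)
    return m.with_charges(q, name=f"{structure}@{charge_set}")


def lattice_series(polymorph: str) -> PairedSeries:
    """Experimental vs calculated lattice parameters for one cisplatin polymorph.

    ``polymorph`` is ``"alpha"`` or ``"beta"``; the six entries are the cell
    lengths a, b, c (angstrom) and angles alpha, beta, gamma (degrees).
    """
    if polymorph not in ("alpha", "beta"):
        raise KeyError("polymorph must be 'alpha' or 'beta'")
    with (_DATA / f"{polymorph}_cisplatin_lattice.csv").open() as fh:
        return read_pairs_csv(fh)
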