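"""Unit conversion constants (CODATA 2018).

Internal convention throughout the package: Hartree atomic units —
energies in Hartree, lengths in Bohr, dipoles in e·Bohr, masses in
electron masses, time in ħ/Hartree.
"""

# energy
EV = 1.0 / 27.211386245988        # 1 eV in Hartree
KCAL_MOL = 1.0 / 627.509474063    # 1 kcal/mol in Hartree

# length
ANGSTROM = 1.0 / 0.529177210903   # 1 Å in Bohr

# mass
AMU = 1822.888486209              # 1 u in electron masses

# time
FS = 41.341374575751              # 1 fs in atomic time units

# dipole
DEBYE = 0.3934303                 # 1 Debye in e·Bohr


def to_atomic(value, unit: str, kind: str):
    """Convert ``value`` given in ``unit`` to atomic units.

    ``kind`` identifies the property class (positions, energies, forces,
    nacs, dipoles, masses, time) so compound units resolve unambiguously.
    """
    return value * _factor(unit, kind)


def from_atomic(value, unit: str, kind: str):
    return value / _factor(unit, kind)


_FACTORS = {
    "positions": {"bohr": 1.0, "au": 1.0, "angstrom": ANGSTROM, "a": ANGSTROM},
    "energies": {"hartree": 1.0, "au": 1.0, "ev": EV, "kcal/mol": KCAL_MOL},
    "forces": {"hartree/bohr": 1.0, "au": 1.0, "ev/angstrom": EV / ANGSTROM,
               "ev/a": EV / ANGSTROM},
    "nacs": {"1/bohr": 1.0, "au": 1.0, "1/angstrom": 1.0 / ANGSTROM},
    "smooth_nacs": {"hartree/bohr": 1.0, "au": 1.0, "ev/angstrom": EV / ANGSTROM},
    "dipoles": {"au": 1.0, "debye": DEBYE},
    "masses": {"au": 1.0, "amu": AMU, "u": AMU},
    "time": {"au": 1.0, "fs": FS},
}


def _factor(unit: str, kind: str) -> float:
    try:
        table = _FACTORS[kind]
    except KeyError:
        raise ValueError(f"unknown property kind {kind!r}") from None
    key = unit.strip().lower()
    if key not in table:
        raise ValueError(
            f"unknown unit {unit!r} for {kind}; accepted: {sorted(table)}")
    return table[key]
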