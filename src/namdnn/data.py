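"""Domain types and dataset handling for multi-state molecular data.

One :class:`MultiStateSample` holds a molecular geometry together with its
electronic-state properties: per-state energies ``E_j`` and forces ``F_j``,
per-state-pair nonadiabatic coupling vectors ``C_ij`` (derivative couplings,
which diverge at state degeneracies) and their smoothed counterparts
``C̃_ij = C_ij · (E_j − E_i)``, plus permanent and transition dipoles.

Internal units are atomic (Hartree, Bohr, e·Bohr); files and external tables
declare their units and are converted on load. Pairs are always stored with
``i < j`` in lexicographic order; ``C_ji = −C_ij`` is derived, never stored.
"""

from __future__ import annotations

import io
import shlex
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import units

__all__ = [
    "Geometry", "StateSpace", "MultiStateSample", "Dataset",
    "smooth_nacs", "unsmooth_nacs",
    "write_dataset", "read_dataset", "convert_external_table",
    "split_dataset", "EnergyReference", "fit_energy_reference",
    "DatasetError",
]

GAP_FLOOR_DEFAULT = 1e-8  # Hartree; regularizes un-smoothing near degeneracy

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg",
    "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn",
    "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb",
    "Sr", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In",
    "Sn", "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm",
    "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta",
    "W", "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At",
    "Rn", "Fr", "Ra", "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk",
    "Cf", "Es", "Fm", "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt",
    "Ds", "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
]
_SYMBOL_TO_Z = {s: z for z, s in enumerate(ELEMENTS)}


class DatasetError(ValueError):
    """Raised for malformed datasets or files."""


@dataclass
class Geometry:
    """Atomic numbers and Cartesian positions (Bohr)."""

    atomic_numbers: np.ndarray
    positions: np.ndarray
    total_charge: int = 0

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape != (self.atomic_numbers.shape[0], 3):
            raise DatasetError(
                f"positions shape {self.positions.shape} does not match "
                f"{self.atomic_numbers.shape[0]} atoms")
        if np.any(self.atomic_numbers < 1):
            raise DatasetError("atomic numbers must be >= 1")
        if not np.all(np.isfinite(self.positions)):
            raise DatasetError("positions must be finite")

    @property
    def n_atoms(self) -> int:
        return int(self.atomic_numbers.shape[0])

    def copy(self) -> "Geometry":
        return Geometry(self.atomic_numbers.copy(), self.positions.copy(),
                        self.total_charge)


@dataclass(frozen=True)
class StateSpace:
    """Electronic state space: S singlet states and their ordered pairs."""

    n_states: int

    def __post_init__(self):
        if self.n_states < 1:
            raise DatasetError("need at least one state")

    @property
    def pairs(self) -> list:
        s = self.n_states
        return [(i, j) for i in range(s) for j in range(i + 1, s)]

    @property
    def n_pairs(self) -> int:
        return self.n_states * (self.n_states - 1) // 2

    def pair_index(self, i: int, j: int) -> int:
        if not 0 <= i < j < self.n_states:
            raise DatasetError(f"invalid state pair ({i}, {j})")
        s = self.n_states
        # lexicographic flat index
        return i * s - i * (i + 1) // 2 + (j - i - 1)

    def gaps(self, energies: np.ndarray) -> np.ndarray:
        """E_j − E_i for every ordered pair i < j."""
        energies = np.asarray(energies, dtype=np.float64)
        return np.array([energies[j] - energies[i] for i, j in self.pairs])


PROPERTY_BLOCKS = ("energies", "forces", "nacs", "smooth_nacs",
                   "permanent_dipoles", "transition_dipoles")


@dataclass
class MultiStateSample:
    """One geometry with all available electronic-state property blocks."""

    geometry: Geometry
    energies: Optional[np.ndarray] = None           # [S]
    forces: Optional[np.ndarray] = None             # [S, n, 3]
    nacs: Optional[np.ndarray] = None               # [P, n, 3]
    smooth_nacs: Optional[np.ndarray] = None        # [P, n, 3]
    permanent_dipoles: Optional[np.ndarray] = None  # [S, 3]
    transition_dipoles: Optional[np.ndarray] = None # [P, 3]

    def __post_init__(self):
        for name in PROPERTY_BLOCKS:
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=np.float64))

    @property
    def present(self) -> tuple:
        return tuple(n for n in PROPERTY_BLOCKS if getattr(self, n) is not None)

    def validate(self, space: StateSpace, check_consistency: bool = True):
        n, s, p = self.geometry.n_atoms, space.n_states, space.n_pairs
        expected = {
            "energies": (s,), "forces": (s, n, 3), "nacs": (p, n, 3),
            "smooth_nacs": (p, n, 3), "permanent_dipoles": (s, 3),
            "transition_dipoles": (p, 3),
        }
        for name, shape in expected.items():
            v = getattr(self, name)
            if v is not None and v.shape != shape:
                raise DatasetError(
                    f"{name} has shape {v.shape}, expected {shape}")
        if (check_consistency and self.nacs is not None
                and self.smooth_nacs is not None and self.energies is not None):
            want = smooth_nacs(self.nacs, self.energies, space)
            scale = max(np.max(np.abs(want)), 1.0)
            if np.max(np.abs(want - self.smooth_nacs)) > 1e-12 * scale:
                raise DatasetError(
                    "smooth_nacs inconsistent with nacs * (E_j - E_i)")
        return self


@dataclass
class Dataset:
    """Ordered samples sharing one state space, plus units metadata."""

    samples: list
    state_space: StateSpace
    units: dict = field(default_factory=lambda: {"all": "au"})
    provenance: str = ""

    def __post_init__(self):
        for k, sample in enumerate(self.samples):
            try:
                sample.validate(self.state_space)
            except DatasetError as exc:
                raise DatasetError(f"sample {k}: {exc}") from None

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, idx):
        return self.samples[idx]

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.samples[i] for i in indices], self.state_space,
                       dict(self.units), self.provenance)


# ---------------------------------------------------------------------------
# NAC smoothing
# ---------------------------------------------------------------------------

def smooth_nacs(nacs: np.ndarray, energies: np.ndarray,
                space: StateSpace) -> np.ndarray:
    """Scale each coupling by its energy gap: C̃_ij = C_ij · (E_j − E_i).

    The product stays finite at conical intersections, where the raw
    coupling diverges like the inverse gap.
    """
    nacs = np.asarray(nacs, dtype=np.float64)
    energies = np.asarray(energies, dtype=np.float64)
    if energies.shape != (space.n_states,):
        raise DatasetError(
            f"energies shape {energies.shape} != ({space.n_states},)")
    if nacs.shape[0] != space.n_pairs:
        raise DatasetError(
            f"nacs pair axis {nacs.shape[0]} != {space.n_pairs}")
    gaps = space.gaps(energies)
    return nacs * gaps[:, None, None]


def unsmooth_nacs(smooth: np.ndarray, energies: np.ndarray, space: StateSpace,
                  gap_floor: float = GAP_FLOOR_DEFAULT) -> np.ndarray:
    """Invert the smoothing: divide by the gap, clamped at ``gap_floor``.

    The divisor is ``sign(E_j − E_i) · max(|E_j − E_i|, gap_floor)`` so the
    operation is total even at degeneracies (sign of a zero gap is taken
    as +1). Exact inverse of :func:`smooth_nacs` wherever the absolute gap
    is at least ``gap_floor``.
    """
    if gap_floor <= 0:
        raise ValueError("gap_floor must be positive")
    smooth = np.asarray(smooth, dtype=np.float64)
    if smooth.shape[0] != space.n_pairs:
        raise DatasetError(
            f"smooth_nacs pair axis {smooth.shape[0]} != {space.n_pairs}")
    gaps = space.gaps(energies)
    signs = np.where(gaps >= 0, 1.0, -1.0)
    divisor = signs * np.maximum(np.abs(gaps), gap_floor)
    return smooth / divisor[:, None, None]


# ---------------------------------------------------------------------------
# extended-XYZ storage
# ---------------------------------------------------------------------------

def _fmt(values: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in np.ravel(values))


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as extended-XYZ frames with per-frame property blocks.

    Each frame: atom-count line, a key=value comment line (state count,
    charge, present blocks; frame 0 also carries provenance), ``symbol x y
    z`` atom lines, then one ``KEY= v1 v2 ...`` line per property block
    (row-major, pair order lexicographic i<j). All floats are written with
    full precision, so a round trip is numerically exact.
    """
    space = dataset.state_space
    buf = io.StringIO()
    for k, sample in enumerate(dataset.samples):
        geo = sample.geometry
        buf.write(f"{geo.n_atoms}\n")
        meta = (f"n_states={space.n_states} charge={geo.total_charge} "
                f"units=au blocks={','.join(sample.present) or 'none'}")
        if k == 0 and dataset.provenance:
            meta += f" provenance={shlex.quote(dataset.provenance)}"
        buf.write(meta + "\n")
        for z, pos in zip(geo.atomic_numbers, geo.positions):
            sym = ELEMENTS[z] if z < len(ELEMENTS) else str(int(z))
            buf.write(f"{sym} {_fmt(pos)}\n")
        if sample.energies is not None:
            buf.write(f"energies= {_fmt(sample.energies)}\n")
        if sample.forces is not None:
            for j in range(space.n_states):
                buf.write(f"forces_{j}= {_fmt(sample.forces[j])}\n")
        for name, key in (("nacs", "nacs"), ("smooth_nacs", "smooth_nacs")):
            block = getattr(sample, name)
            if block is not None:
                for (i, j) in space.pairs:
                    buf.write(f"{key}_{i}_{j}= "
                              f"{_fmt(block[space.pair_index(i, j)])}\n")
        if sample.permanent_dipoles is not None:
            for j in range(space.n_states):
                buf.write(f"dipole_{j}= {_fmt(sample.permanent_dipoles[j])}\n")
        if sample.transition_dipoles is not None:
            for (i, j) in space.pairs:
                buf.write(f"trans_dipole_{i}_{j}= "
                          f"{_fmt(sample.transition_dipoles[space.pair_index(i, j)])}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _parse_floats(text: str, frame: int, key: str, count: int) -> np.ndarray:
    try:
        arr = np.array([float(t) for t in text.split()], dtype=np.float64)
    except ValueError:
        raise DatasetError(f"frame {frame}: non-numeric data in {key!r}")
    if arr.size != count:
        raise DatasetError(
            f"frame {frame}: field {key!r} has {arr.size} values, "
            f"expected {count}")
    return arr


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    samples, provenance = [], ""
    space = None
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise DatasetError(
                f"frame {frame}: expected atom count, got {lines[pos]!r}")
        header = dict()
        for tok in shlex.split(lines[pos + 1]):
            if "=" not in tok:
                raise DatasetError(
                    f"frame {frame}: malformed header token {tok!r}")
            k, v = tok.split("=", 1)
            header[k] = v
        n_states = int(header.get("n_states", 1))
        if space is None:
            space = StateSpace(n_states)
        elif n_states != space.n_states:
            raise DatasetError(
                f"frame {frame}: state count {n_states} != {space.n_states}")
        if frame == 0:
            provenance = header.get("provenance", "")
        blocks = [b for b in header.get("blocks", "none").split(",")
                  if b and b != "none"]
        numbers, coords = [], []
        for a in range(n_atoms):
            parts = lines[pos + 2 + a].split()
            if len(parts) != 4:
                raise DatasetError(
                    f"frame {frame}: malformed atom line {a}: "
                    f"{lines[pos + 2 + a]!r}")
            sym = parts[0]
            z = _SYMBOL_TO_Z.get(sym)
            if z is None:
                try:
                    z = int(sym)
                except ValueError:
                    raise DatasetError(
                        f"frame {frame}: unknown element {sym!r}")
            numbers.append(z)
            coords.append([float(x) for x in parts[1:]])
        geo = Geometry(np.array(numbers), np.array(coords),
                       int(header.get("charge", 0)))
        cursor = pos + 2 + n_atoms
        props: dict = {}
        while cursor < len(lines) and "= " in lines[cursor] \
                and not lines[cursor].split("=")[0].strip().isdigit():
            key, _, rest = lines[cursor].partition("=")
            props[key.strip()] = rest.strip()
            cursor += 1
        sample = _assemble_sample(geo, space, blocks, props, frame)
        samples.append(sample)
        pos = cursor
        frame += 1
    if space is None:
        raise DatasetError("empty dataset file")
    return Dataset(samples, space, {"all": "au"}, provenance)


def _assemble_sample(geo, space, blocks, props, frame):
    n, s = geo.n_atoms, space.n_states
    kw = {}
    if "energies" in blocks:
        kw["energies"] = _parse_floats(props.get("energies", ""), frame,
                                       "energies", s)
    if "forces" in blocks:
        kw["forces"] = np.stack([
            _parse_floats(props.get(f"forces_{j}", ""), frame, f"forces_{j}",
                          3 * n).reshape(n, 3) for j in range(s)])
    for name, key in (("nacs", "nacs"), ("smooth_nacs", "smooth_nacs")):
        if name in blocks:
            kw[name] = np.stack([
                _parse_floats(props.get(f"{key}_{i}_{j}", ""), frame,
                              f"{key}_{i}_{j}", 3 * n).reshape(n, 3)
                for i, j in space.pairs])
    if "permanent_dipoles" in blocks:
        kw["permanent_dipoles"] = np.stack([
            _parse_floats(props.get(f"dipole_{j}", ""), frame,
                          f"dipole_{j}", 3) for j in range(s)])
    if "transition_dipoles" in blocks:
        kw["transition_dipoles"] = np.stack([
            _parse_floats(props.get(f"trans_dipole_{i}_{j}", ""), frame,
                          f"trans_dipole_{i}_{j}", 3)
            for i, j in space.pairs])
    try:
        return MultiStateSample(geo, **kw).validate(space)
    except DatasetError as exc:
        raise DatasetError(f"frame {frame}: {exc}") from None


# ---------------------------------------------------------------------------
# external-table conversion
# ---------------------------------------------------------------------------

#: accepted property-name aliases; user-extensible via ``extra_aliases``
ALIASES = {
    "atomic_numbers": {"atomic_numbers", "numbers", "z", "elements"},
    "positions": {"positions", "coordinates", "coords", "r", "xyz"},
    "energies": {"energies", "energy", "e"},
    "forces": {"forces", "f"},
    "nacs": {"nacs", "nac", "couplings", "c"},
    "smooth_nacs": {"smooth_nacs"},
    "permanent_dipoles": {"permanent_dipoles", "dipoles", "mu"},
    "transition_dipoles": {"transition_dipoles", "trans_dipoles", "mu_trans"},
    "total_charge": {"total_charge", "charge", "q"},
}


def _canonical(name: str, aliases: Mapping[str, set]) -> str:
    low = name.lower()
    for canon, names in aliases.items():
        if low in names:
            return canon
    accepted = sorted(set().union(*aliases.values()))
    raise DatasetError(
        f"unknown property name {name!r}; accepted aliases: {accepted}")


def convert_external_table(records: Iterable[Mapping], units_decl: Mapping,
                           add_smooth_nacs: bool = False,
                           extra_aliases: Optional[Mapping] = None,
                           provenance: str = "converted") -> Dataset:
    """Build a :class:`Dataset` from generic per-frame property mappings.

    ``units_decl`` maps canonical property names (plus ``positions``) to
    unit strings; everything is converted to atomic units. With
    ``add_smooth_nacs=True`` the smoothed couplings are computed from the
    raw couplings and energies on the fly.
    """
    aliases = {k: set(v) for k, v in ALIASES.items()}
    if extra_aliases:
        for k, v in extra_aliases.items():
            aliases.setdefault(k, set()).update(
                {v} if isinstance(v, str) else set(v))

    def conv(kind, value):
        unit = units_decl.get(kind, "au")
        return units.to_atomic(np.asarray(value, dtype=np.float64), unit, kind)

    samples = []
    space = None
    for k, rec in enumerate(records):
        canon = {}
        for name, value in rec.items():
            canon[_canonical(name, aliases)] = value
        if "positions" not in canon or "atomic_numbers" not in canon:
            raise DatasetError(
                f"record {k}: coordinates and element numbers are required")
        geo = Geometry(np.asarray(canon["atomic_numbers"], dtype=np.int64),
                       conv("positions", canon["positions"]),
                       int(canon.get("total_charge", 0)))
        kw = {}
        for name in ("energies", "forces", "nacs", "smooth_nacs"):
            if name in canon:
                kw[name] = conv(name, canon[name])
        for name in ("permanent_dipoles", "transition_dipoles"):
            if name in canon:
                kw[name] = conv("dipoles", canon[name])
        if "energies" in kw:
            n_states = int(np.asarray(kw["energies"]).shape[0])
            if space is None:
                space = StateSpace(n_states)
            elif n_states != space.n_states:
                raise DatasetError(
                    f"record {k}: state count {n_states} != "
                    f"{space.n_states}")
        if add_smooth_nacs:
            if "nacs" not in kw or "energies" not in kw:
                raise DatasetError(
                    f"record {k}: smoothing requires nacs and energies")
            kw["smooth_nacs"] = smooth_nacs(kw["nacs"], kw["energies"], space)
        samples.append(MultiStateSample(geo, **kw))
    if space is None:
        space = StateSpace(1)
    return Dataset(samples, space, {"all": "au"}, provenance)


# ---------------------------------------------------------------------------
# splitting and energy scaling
# ---------------------------------------------------------------------------

def split_dataset(dataset: Dataset, fractions=(0.8, 0.1, 0.1),
                  seed: int = 0):
    """Disjoint, exhaustive train/val/test split; deterministic per seed."""
    fractions = np.asarray(fractions, dtype=np.float64)
    if fractions.shape != (3,) or np.any(fractions <= 0):
        raise ValueError("need three positive fractions")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(dataset)
    sizes = np.floor(fractions * n).astype(int)
    # distribute the remainder by largest fractional part
    rem = n - sizes.sum()
    order = np.argsort(-(fractions * n - sizes))
    for i in range(rem):
        sizes[order[i % 3]] += 1
    if np.any(sizes == 0):
        raise ValueError(
            f"split sizes {tuple(sizes)} contain an empty split")
    perm = np.random.default_rng(seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return (dataset.subset(perm[:a]), dataset.subset(perm[a:b]),
            dataset.subset(perm[b:]))


@dataclass
class EnergyReference:
    """Per-state training-mean energy offsets (target scaling)."""

    offsets: np.ndarray

    def apply(self, energies: np.ndarray) -> np.ndarray:
        return np.asarray(energies) - self.offsets

    def invert(self, residuals: np.ndarray) -> np.ndarray:
        return np.asarray(residuals) + self.offsets


def fit_energy_reference(train: Dataset) -> EnergyReference:
    if len(train) == 0:
        raise ValueError("empty training split")
    energies = np.stack([s.energies for s in train.samples])
    return EnergyReference(energies.mean(axis=0))
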