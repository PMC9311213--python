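"""Import molecular orbitals and condense them to per-atom populations.

The NLS screen needs one number per atom per frontier orbital: the fraction
of that MO living on the atom.  For orbitals expressed in an orthonormal
basis (the internal Hückel engine, or imported coefficients without an
overlap matrix) this is the squared coefficient summed over the atom's
basis functions.  When an overlap matrix S is supplied, the Mulliken
condensation ``P_A = sum_{mu in A} sum_nu c_mu S_munu c_nu`` is used
instead; the MO is first renormalized to unit norm in the S metric so the
populations of any MO sum to one.  Individual Mulliken populations may be
negative; the screen consumes them as-is.

Two import formats are supported: a plain orbital-exchange JSON dialect,
and the [MO] section of a Molden file (coefficients are then treated as
orthonormal-basis amplitudes unless an overlap matrix is supplied
separately — an approximation that is logged).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pi_huckel import MOSolution

__all__ = [
    "BasisMap",
    "OrbitalSet",
    "AtomCondensation",
    "read_orbital_json",
    "read_molden_mo",
    "condense",
    "orbital_set_from_huckel",
    "SchemaError",
]


class SchemaError(ValueError):
    """An input file violates the orbital-exchange schema."""


@dataclass(frozen=True)
class BasisMap:
    """Assignment of each basis function to its owning atom."""

    n_basis: int
    owner_atom: np.ndarray  # shape (n_basis,), values in [0, n_atoms)
    n_atoms: int

    def __post_init__(self) -> None:
        owner = np.asarray(self.owner_atom, dtype=int)
        object.__setattr__(self, "owner_atom", owner)
        if owner.shape != (self.n_basis,):
            raise SchemaError("owner_atom length must equal n_basis")
        if owner.size and (owner.min() < 0 or owner.max() >= self.n_atoms):
            raise SchemaError(
                f"basis_owner indices must lie in [0, {self.n_atoms}); "
                f"got range [{owner.min()}, {owner.max()}]"
            )


@dataclass
class OrbitalSet:
    """MO coefficients, energies and occupations over a mapped basis."""

    coefficients: np.ndarray  # (n_mo, n_basis)
    energies: np.ndarray
    energy_unit: str  # "hartree" | "eV" | "beta"
    occupations: np.ndarray
    basis_map: BasisMap
    overlap: np.ndarray | None = None
    orthonormal_flag: bool = True
    name: str = ""
    tagged_atom: int | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, float))
        self.energies = np.asarray(self.energies, float)
        self.occupations = np.asarray(self.occupations, float)
        n_mo, n_basis = self.coefficients.shape
        if n_basis != self.basis_map.n_basis:
            raise SchemaError("coefficient columns must match basis_map.n_basis")
        if self.energies.shape != (n_mo,) or self.occupations.shape != (n_mo,):
            raise SchemaError("energies/occupations must have one entry per MO")
        if np.any(self.occupations < 0) or np.any(self.occupations > 2):
            raise SchemaError("occupations must lie in [0, 2]")
        if self.overlap is not None:
            S = np.asarray(self.overlap, float)
            if S.shape != (n_basis, n_basis):
                raise ValueError("overlap dimension mismatch with basis")
            if not np.allclose(S, S.T, atol=1e-6):
                raise SchemaError("overlap matrix must be symmetric")
            if not np.allclose(np.diag(S), 1.0, atol=1e-6):
                raise SchemaError("overlap matrix must have unit diagonal")
            self.overlap = S
            self.orthonormal_flag = False

    @property
    def n_mo(self) -> int:
        return self.coefficients.shape[0]

    def frontier_indices(self) -> tuple[int, int]:
        """(homo, lumo) by occupation in energy order."""
        order = np.argsort(self.energies, kind="stable")
        occ_sorted = self.occupations[order]
        occupied = np.nonzero(occ_sorted > 0)[0]
        if occupied.size == 0:
            raise ValueError("no occupied orbital present")
        homo_pos = occupied[-1]
        if homo_pos + 1 >= self.n_mo:
            raise ValueError("no LUMO: all orbitals occupied")
        return int(order[homo_pos]), int(order[homo_pos + 1])


@dataclass(frozen=True)
class AtomCondensation:
    """Per-atom populations of one MO; sums to the MO's S-metric norm."""

    mo_index: int
    populations: np.ndarray
    method_tag: str  # "square" | "mulliken"


def read_orbital_json(path) -> OrbitalSet:
    """Read the orbital-exchange JSON dialect.

    Schema: ``{"n_atoms": int, "basis_owner": [...], "mos": [{"energy":
    float, "unit": "hartree"|"eV", "occ": float, "coeffs": [...]}],
    "overlap": optional [[...]]}``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("n_atoms", "basis_owner", "mos"):
        if key not in doc:
            raise SchemaError(f"missing required field {key!r}")
    owner = np.asarray(doc["basis_owner"], dtype=int)
    bmap = BasisMap(n_basis=len(owner), owner_atom=owner, n_atoms=int(doc["n_atoms"]))
    coeffs, energies, occs, units = [], [], [], set()
    for i, mo in enumerate(doc["mos"]):
        if "unit" not in mo:
            raise SchemaError(f"mos[{i}] is missing the energy unit tag 'unit'")
        row = np.asarray(mo["coeffs"], float)
        if row.shape != (bmap.n_basis,):
            raise SchemaError(
                f"mos[{i}].coeffs has {row.size} entries, expected {bmap.n_basis}"
            )
        coeffs.append(row)
        energies.append(float(mo["energy"]))
        occs.append(float(mo["occ"]))
        units.add(str(mo["unit"]))
    if len(units) > 1:
        raise SchemaError(f"mixed energy units {sorted(units)}")
    overlap = np.asarray(doc["overlap"], float) if doc.get("overlap") else None
    return OrbitalSet(
        coefficients=np.array(coeffs),
        energies=np.array(energies),
        energy_unit=units.pop() if units else "hartree",
        occupations=np.array(occs),
        basis_map=bmap,
        overlap=overlap,
        name=str(doc.get("name", "")),
        tagged_atom=doc.get("tagged_atom"),
    )


_MOLDEN_SHELL_SIZE = {"s": 1, "p": 3, "sp": 4, "d": 6, "f": 10}
_MOLDEN_SHELL_SIZE_SPHERICAL = {"s": 1, "p": 3, "sp": 4, "d": 5, "f": 7}


def _molden_owner_map(lines: list[str], spherical: bool) -> np.ndarray:
    """Basis-function ownership from the [GTO] section's atom blocks."""
    sizes = _MOLDEN_SHELL_SIZE_SPHERICAL if spherical else _MOLDEN_SHELL_SIZE
    try:
        start = next(
            i for i, ln in enumerate(lines) if ln.strip().lower().startswith("[gto]")
        )
    except StopIteration:
        raise SchemaError("no [GTO] section and no sidecar owner map given")
    owners: list[int] = []
    atom = None
    i = start + 1
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("["):
            break
        parts = ln.split()
        if len(parts) >= 1 and parts[0].isdigit() and len(parts) <= 2:
            atom = int(parts[0]) - 1  # Molden atom numbering is 1-based
        elif parts and parts[0].lower() in sizes:
            if atom is None:
                raise SchemaError(f"line {i + 1}: shell before any atom header")
            owners.extend([atom] * sizes[parts[0].lower()])
            nprim = int(parts[1])
            i += nprim  # skip primitive exponent/contraction lines
        i += 1
    return np.asarray(owners, dtype=int)


def read_molden_mo(path, owner_map: np.ndarray | None = None) -> OrbitalSet:
    """Parse the [MO] section of a Molden file into an :class:`OrbitalSet`.

    Atom ownership of basis functions comes from the [GTO] section unless an
    explicit ``owner_map`` (array of 0-based atom indices, one per basis
    function) is given.  Coefficients are treated as amplitudes in an
    orthonormalized basis; pair with an overlap matrix via
    :class:`OrbitalSet` construction for a proper Mulliken treatment.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    spherical = any(
        ln.strip().lower() in ("[5d]", "[5d7f]", "[5d10f]") for ln in lines
    )
    try:
        mo_start = next(
            i for i, ln in enumerate(lines) if ln.strip().lower().startswith("[mo]")
        )
    except StopIteration:
        raise SchemaError(f"{path}: no [MO] section found")

    mos: list[dict] = []
    current: dict | None = None
    for lineno, ln in enumerate(lines[mo_start + 1 :], start=mo_start + 2):
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.startswith("["):
            break
        m = re.match(r"(?i)(sym|ene|spin|occup)\s*=\s*(\S+)", stripped)
        if m:
            key = m.group(1).lower()
            if key == "sym" or (key == "ene" and current and current["coeffs"]):
                current = {"ene": 0.0, "occup": 0.0, "coeffs": []}
                mos.append(current)
            if current is None:
                current = {"ene": 0.0, "occup": 0.0, "coeffs": []}
                mos.append(current)
            if key in ("ene", "occup"):
                try:
                    current[key] = float(m.group(2))
                except ValueError:
                    raise SchemaError(f"line {lineno}: bad {key} value {m.group(2)!r}")
            continue
        parts = stripped.split()
        if len(parts) == 2:
            if current is None:
                raise SchemaError(f"line {lineno}: coefficient before MO header")
            try:
                idx, val = int(parts[0]), float(parts[1])
            except ValueError:
                raise SchemaError(f"line {lineno}: unparseable coefficient line")
            current["coeffs"].append((idx, val))
        else:
            raise SchemaError(f"line {lineno}: unexpected content in [MO] section")

    if not mos or not mos[0]["coeffs"]:
        raise SchemaError(f"{path}: [MO] section contains no coefficients")
    n_basis = len(mos[0]["coeffs"])
    coeffs = np.zeros((len(mos), n_basis))
    for r, mo in enumerate(mos):
        if len(mo["coeffs"]) != n_basis:
            raise SchemaError(
                f"MO {r + 1} has {len(mo['coeffs'])} coefficients, "
                f"expected {n_basis} (truncated file?)"
            )
        for i, v in mo["coeffs"]:
            if not (1 <= i <= n_basis):
                raise SchemaError(f"MO {r + 1}: basis index {i} out of range")
            coeffs[r, i - 1] = v
    if owner_map is None:
        owner = _molden_owner_map(lines, spherical)
        if owner.size != n_basis:
            raise SchemaError(
                f"[GTO] implies {owner.size} basis functions but [MO] has {n_basis}"
            )
    else:
        owner = np.asarray(owner_map, dtype=int)
    n_atoms = int(owner.max()) + 1 if owner.size else 0
    return OrbitalSet(
        coefficients=coeffs,
        energies=np.array([mo["ene"] for mo in mos]),
        energy_unit="hartree",
        occupations=np.array([mo["occup"] for mo in mos]),
        basis_map=BasisMap(n_basis=n_basis, owner_atom=owner, n_atoms=n_atoms),
        orthonormal_flag=True,
    )


def orbital_set_from_huckel(solution: MOSolution) -> OrbitalSet:
    """Bridge the Hückel eigensolution into an OrbitalSet (identity overlap)."""
    n = solution.coefficients.shape[1]
    return OrbitalSet(
        coefficients=solution.coefficients,
        energies=solution.energies,
        energy_unit="beta",
        occupations=solution.occupations.astype(float),
        basis_map=BasisMap(n_basis=n, owner_atom=np.arange(n), n_atoms=n),
        name=solution.system.name if solution.system else "",
    )


def condense(orbitals: OrbitalSet, mo_index: int) -> AtomCondensation:
    """Condense one MO to per-atom populations.

    Orthonormal basis: ``P_A = sum_{mu in A} c_mu^2`` ("square").  With an
    overlap matrix: Mulliken, ``P_A = sum_{mu in A} sum_nu c_mu S_munu
    c_nu``, after renormalizing the MO to unit S-metric norm (a
    non-normalized MO triggers a warning, not an error).
    """
    if not (0 <= mo_index < orbitals.n_mo):
        raise IndexError(f"mo_index {mo_index} out of range")
    c = orbitals.coefficients[mo_index]
    S = orbitals.overlap
    norm2 = float(c @ S @ c) if S is not None else float(c @ c)
    if norm2 <= 0:
        raise ValueError("MO has non-positive norm in the S metric")
    if abs(norm2 - 1.0) > 1e-6:
        warnings.warn(
            f"MO {mo_index} has S-metric norm {np.sqrt(norm2):.6g}; renormalizing",
            stacklevel=2,
        )
    c = c / np.sqrt(norm2)
    owner = orbitals.basis_map.owner_atom
    n_atoms = orbitals.basis_map.n_atoms
    if S is None:
        per_basis = c * c
        tag = "square"
    else:
        per_basis = c * (S @ c)
        tag = "mulliken"
    populations = np.zeros(n_atoms)
    np.add.at(populations, owner, per_basis)
    return AtomCondensation(mo_index=mo_index, populations=populations, method_tag=tag)
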