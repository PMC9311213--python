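"""Desk-scale Hückel π-electron engine for cyanine/polymethine chromophores.

The node-to-lobe shift (NLS) that makes a dye a photocage candidate is a
symmetry/topology property of its frontier orbitals: the HOMO of the intact
chromophore must carry (near-)zero amplitude at the meso attachment carbon
while the LUMO carries a large lobe there.  That pattern is already present
at the π-topology level, so a Hückel model is a fast, analytically checkable
stand-in for full quantum-chemistry frontier orbitals.  Imported DFT
orbitals go through :mod:`ppgkit.orbital_condense` instead and feed the same
screen.

Conventions
-----------
Orbital energies are reported as the dimensionless coefficient ``x`` in
``E = alpha + x*beta`` with ``beta < 0``: reported energies are ``-x``
(energy above alpha in units of |beta|), so bonding orbitals are negative,
the most bonding is first, and energies sort ascending.  The matrix is
built with ``H[i,i] = -h_i`` and ``H[i,j] = -k_ij`` for bonded pairs, whose
ascending eigenvalues are exactly those reported energies (an
electronegative heteroatom, ``h > 0``, is stabilized).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ELEMENT_PARAMS",
    "PiAtom",
    "PiBond",
    "PiSystem",
    "MOSolution",
    "count_pi_electrons",
    "build_chain_model",
    "huckel_solve",
    "analytic_chain_coefficient",
    "load_chromophore_json",
    "DEGENERACY_TOL",
]

#: Streitwieser-style default Coulomb shifts (h, in units of beta) and the
#: number of pi electrons each atom type donates to the conjugated system.
ELEMENT_PARAMS: dict[str, tuple[float, int]] = {
    "C_sp2": (0.0, 1),
    "N_pyridine_like": (0.5, 1),
    "N_pyrrole_like": (1.5, 2),
    "O_carbonyl_like": (1.0, 1),
    "custom": (0.0, 1),
}

#: MOs within this energy window (beta units) of a frontier orbital are
#: treated as degenerate with it.
DEGENERACY_TOL = 1e-6


@dataclass(frozen=True)
class PiAtom:
    """One atom of the π system.

    ``h_param`` shifts the on-site Coulomb term (``alpha_X = alpha + h*beta``);
    ``n_pi_electrons_contributed`` is how many electrons the atom donates to
    the π count (0, 1 or 2).
    """

    index: int
    element_type: str = "C_sp2"
    h_param: float = 0.0
    n_pi_electrons_contributed: int = 1

    def __post_init__(self) -> None:
        if self.element_type not in ELEMENT_PARAMS:
            raise ValueError(f"unknown element_type {self.element_type!r}")
        if not math.isfinite(self.h_param):
            raise ValueError("h_param must be finite")
        if self.n_pi_electrons_contributed not in (0, 1, 2):
            raise ValueError("n_pi_electrons_contributed must be 0, 1 or 2")


@dataclass(frozen=True)
class PiBond:
    """A resonance interaction between atoms i and j with strength k*beta."""

    i: int
    j: int
    k_param: float = 1.0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")
        if not self.k_param > 0:
            raise ValueError("k_param must be positive")


@dataclass
class PiSystem:
    """A chromophore model: π-topology graph, electron count, tagged atom.

    ``tagged_atom`` marks the meso/attachment carbon that carries the
    leaving-group-bearing substituent and is interrogated by the NLS screen.
    """

    atoms: list[PiAtom]
    bonds: list[PiBond]
    total_charge: int = 0
    n_electrons: int = 0
    tagged_atom: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ValueError("PiSystem needs at least one atom")
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) references a missing atom")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        if not (0 <= self.tagged_atom < n):
            raise ValueError("tagged_atom out of range")
        if not (0 < self.n_electrons <= 2 * n):
            raise ValueError("n_electrons must satisfy 0 < n_e <= 2*n_atoms")
        if not self._connected():
            raise ValueError("pi system graph must be connected")

    def _connected(self) -> bool:
        n = len(self.atoms)
        adj: list[list[int]] = [[] for _ in range(n)]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == n

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class MOSolution:
    """Eigensolution of a Hückel problem.

    ``energies`` are in beta units relative to alpha, ascending (beta < 0
    convention: most bonding first).  ``coefficients`` has one orthonormal
    row per MO.  ``occupations`` follow aufbau filling.
    """

    energies: np.ndarray
    coefficients: np.ndarray
    occupations: np.ndarray
    homo_index: int
    lumo_index: int | None
    degeneracy_flags: np.ndarray = field(default_factory=lambda: np.array([]))
    system: PiSystem | None = None

    @property
    def n_mo(self) -> int:
        return len(self.energies)


def count_pi_electrons(atoms: list[PiAtom], total_charge: int) -> int:
    """Number of π electrons: per-atom donations minus the net charge.

    For a monocationic symmetric aminopolymethine of N atoms (one amine-type
    nitrogen formally donating a lone pair, rendered as two N_pyrrole_like
    termini minus the +1 charge) this gives N + 1.
    """
    n = sum(a.n_pi_electrons_contributed for a in atoms) - total_charge
    if n < 0:
        raise ValueError(f"negative pi-electron count ({n})")
    return n


def build_chain_model(
    n_atoms: int,
    end_atom_type: str = "N_pyrrole_like",
    interior_type: str = "C_sp2",
    total_charge: int = 1,
    uniform: bool = True,
    name: str | None = None,
) -> PiSystem:
    """Linear odd-length polymethine chain, the streptocyanine surrogate.

    The two terminal positions get ``end_atom_type``, everything else
    ``interior_type``; the central atom (the meso position) is tagged.  With
    ``uniform=True`` (default) all on-site shifts are zero and all bond
    strengths one — the standard symmetric-cyanine picture in which the two
    resonance-equivalent termini share the charge — while electron counting
    still follows the element types.  ``uniform=False`` applies the
    Streitwieser parameters of :data:`ELEMENT_PARAMS` instead.
    """
    if n_atoms < 3 or n_atoms % 2 == 0:
        raise ValueError(
            f"n_atoms must be an odd integer >= 3, got {n_atoms}: the cyanine "
            "surrogate requires an odd methine chain"
        )
    atoms = []
    for i in range(n_atoms):
        etype = end_atom_type if i in (0, n_atoms - 1) else interior_type
        h_default, ne = ELEMENT_PARAMS[etype]
        atoms.append(
            PiAtom(
                index=i,
                element_type=etype,
                h_param=0.0 if uniform else h_default,
                n_pi_electrons_contributed=ne,
            )
        )
    bonds = [PiBond(i, i + 1, 1.0) for i in range(n_atoms - 1)]
    return PiSystem(
        atoms=atoms,
        bonds=bonds,
        total_charge=total_charge,
        n_electrons=count_pi_electrons(atoms, total_charge),
        tagged_atom=(n_atoms - 1) // 2,
        name=name or f"chain{n_atoms}",
    )


def _fix_phase(vec: np.ndarray) -> np.ndarray:
    """Global sign chosen so the largest-magnitude coefficient is positive."""
    idx = int(np.argmax(np.abs(vec)))
    return -vec if vec[idx] < 0 else vec


def huckel_solve(system: PiSystem) -> MOSolution:
    """Diagonalize the Hückel matrix and fill orbitals by aufbau.

    Doubly occupies MOs from the bottom; an odd electron count singly
    occupies the SOMO, which is then reported as the HOMO (with a warning —
    the screen is defined for closed-shell cations).
    """
    n = system.n_atoms
    if system.n_electrons > 2 * n:
        raise ValueError("more electrons than 2 per orbital")
    H = np.zeros((n, n))
    for a in system.atoms:
        H[a.index, a.index] = -a.h_param
    for b in system.bonds:
        H[b.i, b.j] = H[b.j, b.i] = -b.k_param
    evals, evecs = np.linalg.eigh(H)
    # H is built with -k off-diagonal, so its eigenvalues are already the
    # energy in |beta| units relative to alpha: ascending, most bonding first
    energies = evals
    coeffs = np.array([_fix_phase(row) for row in evecs.T])

    occ = np.zeros(n, dtype=int)
    ne = system.n_electrons
    full, odd = divmod(ne, 2)
    occ[:full] = 2
    if odd:
        occ[full] = 1
        warnings.warn(
            "odd electron count: SOMO singly occupied and reported as HOMO",
            stacklevel=2,
        )
    homo = full - 1 + odd if (full or odd) else 0
    lumo = homo + 1 if homo + 1 < n else None

    flags = np.zeros(n, dtype=bool)
    for ref in (homo, lumo):
        if ref is None:
            continue
        close = np.abs(energies - energies[ref]) < DEGENERACY_TOL
        if close.sum() > 1:
            flags |= close
    return MOSolution(
        energies=energies,
        coefficients=coeffs,
        occupations=occ,
        homo_index=homo,
        lumo_index=lumo,
        degeneracy_flags=flags,
        system=system,
    )


def analytic_chain_coefficient(N: int, k: int, j: int) -> float:
    """Closed-form uniform-chain MO coefficient sqrt(2/(N+1))·sin(jkπ/(N+1)).

    ``k`` is the 1-based MO index (ascending energy), ``j`` the 1-based atom
    position.  Independent oracle for :func:`huckel_solve` on uniform chains.
    """
    if not (1 <= k <= N and 1 <= j <= N):
        raise ValueError(f"indices k={k}, j={j} must lie in [1, {N}]")
    return math.sqrt(2.0 / (N + 1)) * math.sin(j * k * math.pi / (N + 1))


def load_chromophore_json(path) -> PiSystem:
    """Read a chromophore model from the JSON dialect.

    Schema: ``{"atoms": [{"element_type":..., "h":..., "ne":...}],
    "bonds": [[i, j, k]], "charge": int, "tagged_atom": int, "name": str}``
    with 0-based indices.  ``h``/``ne`` default to the element's standard
    parameters when omitted.
    """
    with open(path) as fh:
        doc = json.load(fh)
    atoms = []
    for i, a in enumerate(doc["atoms"]):
        etype = a.get("element_type", "C_sp2")
        h_default, ne_default = ELEMENT_PARAMS[etype]
        atoms.append(
            PiAtom(
                index=i,
                element_type=etype,
                h_param=float(a.get("h", h_default)),
                n_pi_electrons_contributed=int(a.get("ne", ne_default)),
            )
        )
    bonds = [PiBond(int(i), int(j), float(k)) for i, j, k in doc["bonds"]]
    charge = int(doc.get("charge", 0))
    return PiSystem(
        atoms=atoms,
        bonds=bonds,
        total_charge=charge,
        n_electrons=int(doc.get("n_electrons", count_pi_electrons(atoms, charge))),
        tagged_atom=int(doc["tagged_atom"]),
        name=str(doc.get("name", "")),
    )
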