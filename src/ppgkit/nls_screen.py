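"""Node-to-Lobe Shift (NLS) scoring — the photocage design criterion.

A dye can be re-engineered into a photolabile protecting group when its
HOMO has a node (near-zero per-atom population) at the meso attachment
carbon while its LUMO has a lobe (substantial population) there: in the
dark no electron density sits beta to the leaving group, but excitation
populates the LUMO lobe and drives heterolysis.  The screen condenses the
frontier orbitals onto atoms, thresholds the tagged-atom populations, and
issues a binary verdict plus a continuous delta score for ranking
candidate libraries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .orbital_condense import (
    AtomCondensation,
    OrbitalSet,
    condense,
    orbital_set_from_huckel,
)
from .pi_huckel import DEGENERACY_TOL, MOSolution, PiSystem, huckel_solve

__all__ = ["NLSThresholds", "NLSReport", "nls_report", "frontier_nls", "screen_candidates"]


@dataclass(frozen=True)
class NLSThresholds:
    """Population cutoffs separating a node from a lobe.

    The defaults (node at <=0.02, lobe at >=0.10 of one MO's population)
    separate symmetry-forced zeros from substantial lobes on delocalized
    systems: the 11-atom cyanine surrogate puts exactly 0 of its HOMO and
    1/6 ~= 0.167 of its LUMO on the meso carbon.
    """

    theta_node: float = 0.02
    theta_lobe: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.theta_node < self.theta_lobe <= 1):
            raise ValueError("require 0 <= theta_node < theta_lobe <= 1")


@dataclass(frozen=True)
class NLSReport:
    """Screening verdict for one candidate at its tagged atom."""

    tagged_atom: int
    p_homo: float
    p_lumo: float
    delta: float
    homo_is_node: bool
    lumo_is_lobe: bool
    nls_present: bool
    degeneracy_warning: bool = False
    candidate_name: str = ""


def nls_report(
    homo_condensation: AtomCondensation,
    lumo_condensation: AtomCondensation,
    tagged_atom: int,
    thresholds: NLSThresholds | None = None,
    degeneracy_warning: bool = False,
    candidate_name: str = "",
) -> NLSReport:
    """Classify the tagged atom's frontier populations as node/lobe.

    ``homo_is_node`` iff p_homo <= theta_node; ``lumo_is_lobe`` iff
    p_lumo >= theta_lobe; the NLS is present iff both hold.  Negative
    Mulliken populations are compared as-is.
    """
    th = thresholds or NLSThresholds()
    ph = homo_condensation.populations
    pl = lumo_condensation.populations
    if ph.shape != pl.shape:
        raise ValueError(
            f"HOMO/LUMO condensations cover {ph.size} vs {pl.size} atoms; "
            "both must come from the same system"
        )
    if not (0 <= tagged_atom < ph.size):
        raise ValueError(f"tagged_atom {tagged_atom} out of range")
    p_homo = float(ph[tagged_atom])
    p_lumo = float(pl[tagged_atom])
    homo_is_node = p_homo <= th.theta_node
    lumo_is_lobe = p_lumo >= th.theta_lobe
    return NLSReport(
        tagged_atom=tagged_atom,
        p_homo=p_homo,
        p_lumo=p_lumo,
        delta=p_lumo - p_homo,
        homo_is_node=homo_is_node,
        lumo_is_lobe=lumo_is_lobe,
        nls_present=homo_is_node and lumo_is_lobe,
        degeneracy_warning=degeneracy_warning,
        candidate_name=candidate_name,
    )


def _degenerate_members(energies: np.ndarray, ref: int) -> list[int]:
    return [
        i for i, e in enumerate(energies) if abs(e - energies[ref]) < DEGENERACY_TOL
    ]


def frontier_nls(
    source: PiSystem | MOSolution | OrbitalSet,
    tagged_atom: int | None = None,
    thresholds: NLSThresholds | None = None,
    candidate_name: str = "",
) -> NLSReport:
    """Solve/ingest, condense the frontier orbitals, and score the NLS.

    Accepts a chromophore model (solved on the fly), a ready Hückel
    solution, or an imported OrbitalSet.  When either frontier level is
    degenerate, every degenerate member is condensed and the least
    favorable combination is scored (max p_homo over the HOMO set, min
    p_lumo over the LUMO set) with ``degeneracy_warning=True`` — being
    conservative about claiming an NLS.
    """
    if isinstance(source, PiSystem):
        if tagged_atom is None:
            tagged_atom = source.tagged_atom
        candidate_name = candidate_name or source.name
        source = huckel_solve(source)
    if isinstance(source, MOSolution):
        if tagged_atom is None and source.system is not None:
            tagged_atom = source.system.tagged_atom
        orbitals = orbital_set_from_huckel(source)
    else:
        orbitals = source
    if tagged_atom is None:
        tagged_atom = getattr(orbitals, "tagged_atom", None)
    if tagged_atom is None:
        raise ValueError("tagged_atom must be given for imported orbitals")

    homo, lumo = orbitals.frontier_indices()
    homo_set = _degenerate_members(orbitals.energies, homo)
    lumo_set = _degenerate_members(orbitals.energies, lumo)
    degeneracy = len(homo_set) > 1 or len(lumo_set) > 1

    def pop(idx: int) -> tuple[AtomCondensation, float]:
        cond = condense(orbitals, idx)
        return cond, float(cond.populations[tagged_atom])

    homo_conds = [pop(i) for i in homo_set]
    lumo_conds = [pop(i) for i in lumo_set]
    worst_homo = max(homo_conds, key=lambda cp: cp[1])[0]
    worst_lumo = min(lumo_conds, key=lambda cp: cp[1])[0]
    return nls_report(
        worst_homo,
        worst_lumo,
        tagged_atom,
        thresholds,
        degeneracy_warning=degeneracy,
        candidate_name=candidate_name or orbitals.name,
    )


def load_candidate(path) -> PiSystem | OrbitalSet:
    """Load one candidate file: chromophore JSON, orbital JSON, or Molden."""
    from .orbital_condense import read_molden_mo, read_orbital_json
    from .pi_huckel import load_chromophore_json

    p = Path(path)
    if p.suffix.lower() in (".molden", ".mold", ".input"):
        return read_molden_mo(p)
    with open(p) as fh:
        doc = json.load(fh)
    if "mos" in doc:
        return read_orbital_json(p)
    return load_chromophore_json(p)


def screen_candidates(
    candidates: list,
    thresholds: NLSThresholds | None = None,
) -> pd.DataFrame:
    """Score a candidate library and rank it by descending delta.

    ``candidates`` may mix chromophore models, orbital sets and
    ``(name, source)`` pairs.  A candidate whose evaluation fails
    contributes an error row instead of aborting the batch.  Ties in delta
    break lexicographically by name, so the table is deterministic.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    rows = []
    for i, cand in enumerate(candidates):
        name = ""
        try:
            if isinstance(cand, tuple):
                name, cand = cand
            if isinstance(cand, (str, Path)):
                name = name or Path(cand).stem
                cand = load_candidate(cand)
            name = name or getattr(cand, "name", "") or f"candidate{i}"
            rep = frontier_nls(cand, thresholds=thresholds, candidate_name=name)
            rows.append(
                {
                    "name": rep.candidate_name,
                    "p_homo": rep.p_homo,
                    "p_lumo": rep.p_lumo,
                    "delta": rep.delta,
                    "nls_present": rep.nls_present,
                    "warnings": "degenerate_frontier" if rep.degeneracy_warning else "",
                }
            )
        except Exception as exc:  # per-row failure, batch continues
            rows.append(
                {
                    "name": name or f"candidate{i}",
                    "p_homo": np.nan,
                    "p_lumo": np.nan,
                    "delta": np.nan,
                    "nls_present": False,
                    "warnings": f"error: {exc}",
                }
            )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["delta", "name"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return table
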