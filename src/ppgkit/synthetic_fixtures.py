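"""Deterministic generators for every input class the pipeline consumes.

Everything here is a pure function of its parameters and seed: chromophore
chain series with *analytically known* NLS labels, orbital-exchange and
Molden fixture files that round-trip through the readers, noisy photolysis
traces with embedded ground truth, and mixed screening libraries.  The
truth labels are re-derived from the sine closed form *inside this module*
(deliberately duplicating, not importing, the eigensolver path) so they
constitute an independent oracle for the screen.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .photochem_kinetics import IrradiationSetup, KineticsTrace, simulate_photolysis
from .pi_huckel import PiSystem, build_chain_model

__all__ = [
    "chain_nls_truth",
    "make_chain_series",
    "make_orbital_file",
    "make_molden_file",
    "make_noisy_trace",
    "make_screen_library",
    "default_setup",
]

#: Figure-of-merit irradiation context used by the kinetics fixtures:
#: NIR LED at 760 nm, 5 mW into a 3 mL cuvette with a 1 cm path.
def default_setup(power_W: float = 5e-3) -> IrradiationSetup:
    return IrradiationSetup(
        wavelength_nm=760.0,
        incident_power_W=power_W,
        volume_L=3e-3,
        path_length_cm=1.0,
    )


def chain_nls_truth(n_atoms: int) -> bool:
    """Analytic NLS label for the uniform aminopolymethine monocation.

    For an N-atom chain carrying N+1 π electrons the HOMO is MO
    k = (N+1)/2 and the meso atom is j = (N+1)/2 (both 1-based).  The NLS
    is present iff the HOMO amplitude sin(j·k·π/(N+1)) vanishes at the meso
    atom while the LUMO amplitude does not — evaluated here directly from
    the sine closed form, independent of any eigensolver.
    """
    if n_atoms < 3 or n_atoms % 2 == 0:
        raise ValueError("chain length must be odd and >= 3")
    homo = (n_atoms + 1) // 2
    lumo = homo + 1
    j = (n_atoms + 1) // 2
    amp = lambda k: math.sin(j * k * math.pi / (n_atoms + 1))
    return abs(amp(homo)) < 1e-12 and abs(amp(lumo)) > 1e-6


def make_chain_series(lengths: list[int]) -> list[tuple[PiSystem, bool]]:
    """Aminopolymethine monocation models with analytic truth labels."""
    return [
        (build_chain_model(n, name=f"aminopolymethine{n:02d}"), chain_nls_truth(n))
        for n in lengths
    ]


def make_orbital_file(
    n_atoms: int,
    mo_specs: list[dict],
    path,
    overlap: np.ndarray | None = None,
    basis_owner: list[int] | None = None,
    name: str = "synthetic",
    tagged_atom: int | None = None,
) -> Path:
    """Write an orbital-exchange JSON fixture.

    ``mo_specs`` entries: {"energy": float, "occ": float, "coeffs": [...]};
    one basis function per atom unless ``basis_owner`` says otherwise.
    """
    owner = basis_owner if basis_owner is not None else list(range(n_atoms))
    doc = {
        "name": name,
        "n_atoms": n_atoms,
        "basis_owner": owner,
        "mos": [
            {
                "energy": float(mo["energy"]),
                "unit": mo.get("unit", "hartree"),
                "occ": float(mo["occ"]),
                "coeffs": [float(c) for c in mo["coeffs"]],
            }
            for mo in mo_specs
        ],
    }
    if overlap is not None:
        doc["overlap"] = np.asarray(overlap, float).tolist()
    if tagged_atom is not None:
        doc["tagged_atom"] = tagged_atom
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def make_molden_file(path, mo_specs: list[dict] | None = None, n_atoms: int = 4) -> Path:
    """Write a minimal Molden fixture: one s basis function per carbon atom.

    Default content: the 4 MOs of a 4-atom chain with occupations summing
    to the electron count implied by the specs.
    """
    if mo_specs is None:
        # uniform 4-chain eigensolution, 4 pi electrons
        ks = range(1, n_atoms + 1)
        norm = math.sqrt(2.0 / (n_atoms + 1))
        mo_specs = [
            {
                "energy": -2.0 * math.cos(k * math.pi / (n_atoms + 1)),
                "occ": 2.0 if k <= n_atoms // 2 else 0.0,
                "coeffs": [
                    norm * math.sin(j * k * math.pi / (n_atoms + 1))
                    for j in range(1, n_atoms + 1)
                ],
            }
            for k in ks
        ]
    lines = ["[Molden Format]", "[Atoms] Angs"]
    for i in range(n_atoms):
        lines.append(f"C {i + 1} 6 {1.4 * i:.6f} 0.000000 0.000000")
    lines.append("[GTO]")
    for i in range(n_atoms):
        lines.append(f"  {i + 1} 0")
        lines.append("  s 1 1.00")
        lines.append("  1.0 1.0")
        lines.append("")
    lines.append("[MO]")
    for m, mo in enumerate(mo_specs, start=1):
        lines.append(f" Sym= A{m}")
        lines.append(f" Ene= {mo['energy']:.10f}")
        lines.append(" Spin= Alpha")
        lines.append(f" Occup= {mo['occ']:.6f}")
        for b, c in enumerate(mo["coeffs"], start=1):
            lines.append(f"   {b}   {c:.10f}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def make_noisy_trace(
    phi_true: float,
    epsilon: float = 2.76e5,
    c0: float = 1e-6,
    setup: IrradiationSetup | None = None,
    n_points: int = 20,
    noise_frac: float = 0.0,
    seed: int = 0,
    t_span_halflives: float = 4.0,
) -> KineticsTrace:
    """Photolysis trace with multiplicative lognormal noise and known truth.

    The grid is log-spaced over roughly ``t_span_halflives`` low-absorbance
    half-lives; concentrations are multiplied by lognormal noise of the
    stated fraction (keeping them positive).  The generating parameters are
    embedded in ``meta`` for recovery tests.
    """
    if not (0 < phi_true <= 1):
        raise ValueError("phi_true must lie in (0, 1]")
    if n_points < 5:
        raise ValueError("need at least 5 points")
    setup = setup or default_setup()
    k_obs = (
        phi_true
        * setup.flux
        * math.log(10.0)
        * epsilon
        * setup.path_length_cm
        / setup.volume_L
    )
    t_end = t_span_halflives * math.log(2.0) / k_obs
    t_grid = np.geomspace(t_end / 200.0, t_end, n_points)
    trace = simulate_photolysis(phi_true, epsilon, c0, setup, t_grid)
    values = trace.values
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_frac**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.size)
        values = values * noise
    return KineticsTrace(
        times=t_grid,
        values=values,
        mode="concentration_M",
        setup=setup,
        c0_M=c0,
        noise_sigma=noise_frac,
        meta={
            "phi_true": phi_true,
            "epsilon": epsilon,
            "noise_frac": noise_frac,
            "seed": seed,
        },
    )


#: Chain lengths by analytic label: N ≡ 3 (mod 4) has the NLS, N ≡ 1 (mod 4)
#: does not (both checked against chain_nls_truth at generation time).
_POSITIVE_LENGTHS = (3, 7, 11, 15, 19, 23, 27, 31)
_NEGATIVE_LENGTHS = (5, 9, 13, 17, 21, 25, 29, 33)


def make_screen_library(
    n_candidates: int,
    fraction_nls_positive: float = 0.5,
    seed: int = 0,
    out_dir=None,
) -> list[tuple[PiSystem, bool]]:
    """Mixed-length candidate library with analytic truth labels.

    Candidate order and end-group decoration are shuffled by ``seed``;
    labels come from :func:`chain_nls_truth`.  When ``out_dir`` is given,
    each candidate is also written as a chromophore-model JSON and a
    ``labels.json`` manifest is emitted, for end-to-end CLI tests.
    """
    if n_candidates < 2:
        raise ValueError("need at least 2 candidates")
    rng = np.random.default_rng(seed)
    n_pos = round(fraction_nls_positive * n_candidates)
    lengths = [
        _POSITIVE_LENGTHS[i % len(_POSITIVE_LENGTHS)] for i in range(n_pos)
    ] + [
        _NEGATIVE_LENGTHS[i % len(_NEGATIVE_LENGTHS)]
        for i in range(n_candidates - n_pos)
    ]
    end_types = [
        str(rng.choice(["N_pyrrole_like", "N_pyridine_like"])) for _ in lengths
    ]
    order = rng.permutation(len(lengths))
    library: list[tuple[PiSystem, bool]] = []
    for rank, idx in enumerate(order):
        n = lengths[idx]
        # uniform Hückel parameters keep the sine closed form (and hence the
        # analytic label) exact; the end-group type varies the electron count
        # bookkeeping and naming only
        charge = 1 if end_types[idx] == "N_pyrrole_like" else -1
        system = build_chain_model(
            n,
            end_atom_type=end_types[idx],
            total_charge=charge,
            name=f"candidate{rank:02d}_len{n:02d}",
        )
        library.append((system, chain_nls_truth(n)))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        labels = {}
        for system, label in library:
            doc = {
                "name": system.name,
                "atoms": [
                    {
                        "element_type": a.element_type,
                        "h": a.h_param,
                        "ne": a.n_pi_electrons_contributed,
                    }
                    for a in system.atoms
                ],
                "bonds": [[b.i, b.j, b.k_param] for b in system.bonds],
                "charge": system.total_charge,
                "n_electrons": system.n_electrons,
                "tagged_atom": system.tagged_atom,
            }
            (out / f"{system.name}.json").write_text(
                json.dumps(doc, indent=1, sort_keys=True)
            )
            labels[system.name] = label
        (out / "labels.json").write_text(json.dumps(labels, indent=1, sort_keys=True))
    return library
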