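"""Heterolysis barrier bookkeeping and the dark-stability/photoactivity verdict.

A viable photocage must be inert in the dark — a prohibitively high
ground-state (S0) heterolysis barrier — yet release its payload from an
excited state, i.e. a modest S1 (or, after intersystem crossing, T1)
barrier.  This module stores externally computed free-energy barriers,
converts them to Eyring transition-state rate constants, and applies
configurable pass/fail thresholds encoding that reasoning.  The barriers
themselves come from excited-state quantum chemistry and are inputs here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .constants import (
    BOLTZMANN_J_K,
    DEFAULT_TEMPERATURE_K,
    GAS_CONSTANT_KCAL_MOL_K,
    PLANCK_J_S,
)

__all__ = ["StateBarriers", "VerdictConfig", "PhotochemVerdict", "eyring_rate", "heterolysis_verdict"]


@dataclass(frozen=True)
class StateBarriers:
    """Heterolysis free-energy barriers (kcal/mol) per electronic state.

    ``None`` marks a state that was not computed; at least one excited
    state is needed for a verdict.  ``level_tag`` records the provenance
    (e.g. the electronic-structure level the numbers came from).
    """

    dG_S0: float
    dG_S1: float | None = None
    dG_T1: float | None = None
    level_tag: str = ""

    def __post_init__(self) -> None:
        for label, val in (("S0", self.dG_S0), ("S1", self.dG_S1), ("T1", self.dG_T1)):
            if val is not None and not (math.isfinite(val) and val >= 0):
                raise ValueError(f"dG_{label} must be finite and >= 0, got {val}")


@dataclass(frozen=True)
class VerdictConfig:
    """Thresholds for the qualitative verdict, kcal/mol.

    Defaults: a ground-state barrier of at least 30 kcal/mol means heterolysis
    is negligible in the dark (half-life far beyond any experiment), and an
    excited-state barrier of at most 25 kcal/mol is surmountable during the
    excited-state lifetime (with vibrationally hot excitation further lowering
    the effective barrier, representable via ``barrier_offset``).
    """

    dark_stable_min: float = 30.0
    photoactive_max: float = 25.0
    temperature: float = DEFAULT_TEMPERATURE_K
    barrier_offset: float = 0.0  # subtracted from excited-state barriers

    def __post_init__(self) -> None:
        if not (self.dark_stable_min > self.photoactive_max > 0):
            raise ValueError("require dark_stable_min > photoactive_max > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class PhotochemVerdict:
    """Boolean verdicts plus Eyring rates (s^-1) for each supplied state."""

    dark_stable: bool
    photoactive_S1: bool | None
    photoactive_T1: bool | None
    k_S0: float
    k_S1: float | None
    k_T1: float | None
    overall_pass: bool
    config: VerdictConfig = field(default_factory=VerdictConfig)

    def to_dict(self) -> dict:
        return {
            "dark_stable": self.dark_stable,
            "photoactive_S1": self.photoactive_S1,
            "photoactive_T1": self.photoactive_T1,
            "k_S0_per_s": self.k_S0,
            "k_S1_per_s": self.k_S1,
            "k_T1_per_s": self.k_T1,
            "overall_pass": self.overall_pass,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def eyring_rate(dG_kcal_mol: float, temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Transition-state rate constant k = (k_B T / h) exp(-dG / RT), s^-1."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    prefactor = BOLTZMANN_J_K * temperature_K / PLANCK_J_S
    return prefactor * math.exp(
        -dG_kcal_mol / (GAS_CONSTANT_KCAL_MOL_K * temperature_K)
    )


def heterolysis_verdict(
    barriers: StateBarriers, config: VerdictConfig | None = None
) -> PhotochemVerdict:
    """Dark-stability and photoactivity from per-state barriers.

    ``dark_stable`` iff the S0 barrier reaches ``dark_stable_min``;
    each present excited state is photoactive iff its (offset-corrected)
    barrier is at most ``photoactive_max``.  Overall pass = dark-stable and
    at least one photoactive excited channel.
    """
    cfg = config or VerdictConfig()
    if barriers.dG_S1 is None and barriers.dG_T1 is None:
        raise ValueError("at least one excited-state barrier (S1 or T1) is required")

    def excited(dG: float | None) -> tuple[bool | None, float | None]:
        if dG is None:
            return None, None
        eff = max(dG - cfg.barrier_offset, 0.0)
        return eff <= cfg.photoactive_max, eyring_rate(eff, cfg.temperature)

    dark_stable = barriers.dG_S0 >= cfg.dark_stable_min
    act_s1, k_s1 = excited(barriers.dG_S1)
    act_t1, k_t1 = excited(barriers.dG_T1)
    return PhotochemVerdict(
        dark_stable=dark_stable,
        photoactive_S1=act_s1,
        photoactive_T1=act_t1,
        k_S0=eyring_rate(barriers.dG_S0, cfg.temperature),
        k_S1=k_s1,
        k_T1=k_t1,
        overall_pass=dark_stable and (bool(act_s1) or bool(act_t1)),
        config=cfg,
    )
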