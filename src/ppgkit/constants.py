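"""Physical constants and unit conventions shared across the toolkit.

All photochemistry is carried out in a fixed unit system: nm for
wavelengths, M for concentrations, cm for path lengths, L for volumes,
s for time, W for radiant power, einstein/s (mol photons per second)
for photon flux, and kcal/mol for free energies.  Constants are CODATA
values truncated to six significant figures.
"""

PLANCK_J_S = 6.62607e-34
"""Planck constant h, J s."""

BOLTZMANN_J_K = 1.38065e-23
"""Boltzmann constant k_B, J/K."""

SPEED_OF_LIGHT_M_S = 2.99792e8
"""Speed of light c, m/s."""

AVOGADRO_PER_MOL = 6.02214e23
"""Avogadro constant N_A, 1/mol."""

GAS_CONSTANT_KCAL_MOL_K = 1.98720e-3
"""Molar gas constant R, kcal mol^-1 K^-1."""

DEFAULT_TEMPERATURE_K = 298.15
"""Default temperature for rate bookkeeping, K."""

THERAPEUTIC_WINDOW_NM = (700.0, 800.0)
"""NIR wavelength range of deepest penetration into human tissue, nm."""

IDEAL_CROSS_SECTION_MIN = 100.0
"""Minimum uncaging cross-section epsilon*Phi_het regarded as ideal, M^-1 cm^-1."""
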