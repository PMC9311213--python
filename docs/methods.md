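# Methods

## The design problem

A photolabile protecting group (PPG) must satisfy two antagonistic
conditions: it must be inert toward heterolysis in the dark, yet release
its payload efficiently when irradiated — ideally with 700–800 nm light,
the range of deepest tissue penetration.  ppgkit operationalizes the
frontier-orbital criterion that reconciles the two: a dye whose HOMO has a
node at the payload attachment (meso) carbon places no electron density β
to the leaving group in the ground state, while a LUMO lobe at the same
atom means that excitation does.  This *node-to-lobe shift* (NLS) is the
screening criterion; barrier bookkeeping and photokinetics quantify the
resulting photochemistry.

## Hückel π-electron surrogate

Production screening of real dyes uses imported DFT orbitals (below).  The
built-in engine instead solves the Hückel eigenproblem on the π topology
graph, which is sufficient for the NLS because the node/lobe pattern at
the meso carbon of a symmetric polymethine is forced by alternant symmetry,
not by the level of theory.  The model:

- Hamiltonian in units of β relative to α, reported as energy above α in
  |β| units (β < 0): the matrix has `−h_i` on the diagonal and `−k_ij` for
  bonded pairs, so ascending eigenvalues run from most bonding to most
  antibonding and an electronegative heteroatom (h > 0) is stabilized.
  The two-site dimer gives energies {−1, +1} with coefficients ±1/√2.
- Heteroatom defaults (Streitwieser-style): h = 1.5 for an amine-type
  (pyrrole-like) N contributing 2 electrons, 0.5 for an imine-type
  (pyridine-like) N contributing 1, 1.0 for carbonyl-type O contributing 1;
  k = 1 for C–C and C–N.  All overridable per atom/bond.
- π-electron count = Σ per-atom contributions − total charge.  A
  monocationic symmetric aminopolymethine of N atoms therefore carries
  N + 1 electrons.
- Chain models default to **uniform** parameters (h = 0, k = 1) even with
  nitrogen termini: in the symmetric cyanine cation the two end groups are
  resonance-equivalent and the classic uniform-chain model applies, with
  the element types retained for electron counting.  This keeps the sine
  closed form `c_kj = sqrt(2/(N+1))·sin(jkπ/(N+1))` exact; that closed
  form is implemented separately and used as the test oracle for the
  eigensolver (N ∈ {3,…,15}, agreement to 1e-8 after sign alignment).
- Aufbau occupation, 2 electrons per MO; an odd count singly occupies the
  SOMO, which is reported as the HOMO with a warning (the screen is
  defined for closed-shell cations).
- Frontier orbitals within 1e-6 |β| of each other are flagged degenerate;
  the screen then evaluates every degenerate member and keeps the *least
  favorable* combination (largest HOMO population, smallest LUMO
  population at the tagged atom), so degeneracy can only make the verdict
  more conservative.
- Eigenvector phases are fixed (largest-magnitude coefficient positive);
  populations are sign-invariant regardless.

For the 11-atom chain with 12 electrons — the heptamethine surrogate — the
HOMO (k = 6) amplitude at the central atom j = 6 is sin(3π) = 0 and the
LUMO population there is 1/6: node to lobe.  The 9-atom/10-electron chain
reverses the roles (HOMO population 0.2, LUMO 0), illustrating that the
NLS is a property of the specific chain length/electron count, with the
general rule: uniform monocationic chains show the NLS iff N ≡ 3 (mod 4).

## Imported orbitals and per-atom condensation

Orbitals computed elsewhere enter through an orbital-exchange JSON dialect
or the `[MO]` section of a Molden file (ownership of basis functions from
the `[GTO]` atom blocks or an explicit map).  Each MO is condensed to
per-atom populations:

- orthonormal basis (no overlap supplied): `P_A = Σ_{μ∈A} c_μ²`;
- with an overlap matrix S: Mulliken condensation
  `P_A = Σ_{μ∈A} Σ_ν c_μ S_μν c_ν`, after renormalizing the MO to unit
  S-metric norm (non-normalized input warns rather than errors), so
  populations always sum to 1.

Individual Mulliken populations may legitimately be negative; the screen
compares them to the thresholds as-is.  Molden coefficients are treated as
orthonormal-basis amplitudes unless an overlap matrix is supplied — an
approximation adequate for node/lobe classification, not for charge
analysis.  Visual isosurface inspection, cube-file analysis and natural
orbitals are out of scope.

## NLS thresholds and ranking

Node/lobe language is inherently qualitative; the quantitative defaults
are θ_node = 0.02 and θ_lobe = 0.10 (fractions of one MO's population).
They separate symmetry-forced zeros (≲1e-10 numerically) from substantial
lobes on delocalized systems — the 11-chain surrogate gives 0 vs
1/6 ≈ 0.167, comfortably straddling both — and are configurable.  The
verdict is the conjunction `p_homo ≤ θ_node ∧ p_lumo ≥ θ_lobe`; the
continuous score δ = p_lumo − p_homo ranks a library (ties broken by
candidate name, so tables are byte-reproducible).  Raising θ_lobe can only
demote candidates, never promote them (tested as a property).  Per-candidate
failures become error rows rather than aborting a batch; the CLI signals
partial failure with exit code 3.

## Barrier verdict and Eyring rates

`StateBarriers` holds ΔG‡ (kcal/mol) for S0 and optionally S1/T1 from
external excited-state thermochemistry.  Defaults: dark-stable iff
ΔG‡(S0) ≥ 30 kcal/mol (Eyring half-life ≫ years at 298.15 K) and
photoactive iff an excited-state barrier ≤ 25 kcal/mol.  The thresholds
encode the qualitative judgment that ~41 kcal/mol is prohibitive while
~19–21 kcal/mol is surmountable during an excited-state lifetime assisted
by vibrational excitation; they are deliberately configurable because no
sharp literature cutoff exists.  Vibrationally hot excitation is modeled
only as an optional constant `barrier_offset` subtracted from excited-state
barriers (default 0) — no dynamics.  Rates use
k = (k_B·T/h)·exp(−ΔG‡/RT) with CODATA constants to six significant
figures, R = 1.98720e-3 kcal mol⁻¹ K⁻¹.  For 41.4/21.4/19.0 kcal/mol this
gives 2.8e-18, 1.3e-3 and 7.3e-2 s⁻¹.

## Photokinetics

Single absorbing species, photoproducts transparent at the irradiation
wavelength, stirred volume V (L), path l (cm), photon flux I₀ (einstein/s,
from radiant power via flux = P·λ/(h·c·N_A)):

    dC/dt = −Φ · (I₀/V) · (1 − 10^(−ε·l·C)).

The equation is separable, so it is evaluated through its exact solution

    C(t) = ln(1 + (e^(b·C₀) − 1)·e^(−a·b·t)) / b,
    a = Φ·I₀/V,  b = ln(10)·ε·l,

implemented with `log1p`/`expm1` for small-absorbance stability.  In the
low-absorbance limit this reduces to exponential decay with
k_obs = Φ·I₀·ln10·ε·l/V (verified to 0.1 % at ε·l·C₀ = 1e-3), and the
exact photon/mass balance (moles released = Φ × cumulative absorbed
einsteins at every time) holds by construction and is tested against
independent numerical quadrature and against scipy's ODE integrator.

**Quantum-yield fitting.**  Trust-region least squares with Φ the single
free parameter bounded to [0, 1]; residuals are scaled by C₀ so the
optimizer tolerances (1e-14) are meaningful at micromolar concentrations.
The initial guess is the initial-rate estimate
Φ ≈ (−dC/dt|₀·V)/(I₀·(1 − 10^(−A₀))) from the ≤10 % conversion window,
which is also reported.  Confidence intervals come from a seeded residual
bootstrap (resample residuals with replacement, refit; 200 resamples by
default, 2.5/97.5 percentiles).  Non-monotone traces warn but are still
fitted; fewer than 5 points is an error.

**Derived scalar quantities.**  Uncaging cross-section ε·Φ_het reported to
3 significant figures with the ideality flag at ≥ 100 M⁻¹cm⁻¹ (boundary
inclusive); Stokes shift λ_em − λ_abs (negative values flagged anomalous);
the standard relative quantum-yield formula
Φ_s = Φ_ref·(m_s/m_ref)·(f_ref/f_s); tissue-attenuated uncaging as
100·rate_tissue/rate_free to 2 significant figures.  Tissue attenuation is
treated as an empirical relative rate — no radiative-transfer modeling.

## Synthetic data generator

Every fixture is a pure function of its parameters and seed.

- **Chain series / screen libraries** emulate a panel of polymethine dye
  candidates of varying conjugation length.  Truth labels are re-derived
  from the sine closed form *inside the generator* (deliberately
  duplicated code path) so they are independent of the eigensolver under
  test; uniform Hückel parameters are kept on all candidates so the labels
  stay exact.  What they do **not** emulate: ring fusion, substituent
  effects, solvent shifts — so perfect screen accuracy on these libraries
  demonstrates correctness of the pipeline, not predictive power on real
  scaffolds.
- **Kinetics traces** mirror a typical NIR-photolysis experiment: 1 µM
  photocage (ε = 2.76e5 M⁻¹cm⁻¹) in a 3 mL cuvette, 1 cm path, 5 mW of
  760 nm light — minutes-scale uncaging at Φ ≈ 0.3 %.  Noise is
  multiplicative lognormal (concentrations stay positive) with the
  fraction and seed recorded in the trace metadata; the time grid is
  log-spaced over ~4 low-absorbance half-lives.  Real traces additionally
  contain baseline drift, spectral overlap and instrument dead time, none
  of which are modeled.
- **Orbital/Molden files** are minimal but schema-complete and round-trip
  bit-exactly through the readers.

## Problem sizes and numerical choices

The acceptance script and test suite run chains up to 15–33 atoms,
10-candidate libraries, 20-point traces, 50-trace recovery studies and
200-resample bootstraps — sizes chosen so a full run completes in seconds
while every statistical claim (≥ 90 % of seeds within 2 % relative, CI
coverage) still has headroom.  Other numerical commitments: orbital
orthonormality to 1e-10, degeneracy window 1e-6 |β|, Mulliken norm
conservation to 1e-8, closed-form/ODE agreement to 1e-6 relative,
temperatures default 298.15 K, units fixed to nm/M/cm/L/s/W/einstein·s⁻¹/
kcal·mol⁻¹ throughout.

## Known limitations

- The Hückel engine ignores geometry, ring fusion and σ-framework effects;
  it is a screen, not a predictor of absorption wavelengths (explicitly out
  of scope) or absolute orbital energies.
- Molden import without an overlap matrix is approximate (orthonormal-basis
  assumption); spherical/cartesian d-function subtleties are handled only
  at the shell-size level.
- The photokinetic model assumes one absorber, no inner-filter effects from
  products, oxygen-independent chemistry and perfect stirring.
- Barrier thresholds are conventions, not measurements; verdicts should be
  read as bookkeeping of a design argument, not as kinetics predictions.
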