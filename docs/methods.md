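# Methods

## The model

rWAIL is a four-site water potential derived entirely from
first-principles force matching (no parameter was tuned to an
experimental observable).  A molecule carries three physical sites
(O, H1, H2) and one massless virtual site M that holds the negative
charge.  The intermolecular energy of a pair of molecules is

    U = Σ_ij q_i q_j / r_ij                     (charge sites M, H1, H2)
      + A_OO exp(−α r_OO) − C_OO / r_OO⁶        (O–O only)
      + Σ_MH U_HB(r_MH)                         (intermolecular M–H)

with

    U_HB(r) = A_4 (1/r² − 1/r_c²)²   for r < r_c,   0 otherwise,

and the M site placed from the two O–H bond vectors,

    r_M = r_O + a [(r_H1 − r_O) + (r_H2 − r_O)],    a = 0.2.

The flexible variant adds the intramolecular potential

    U_intra = Σ_{b=1,2} ½ (k2 Δr_b² + k3 Δr_b³ + k4 Δr_b⁴)
            + ½ k_θ (θ − θ_e)²,

with quartic bonds and a harmonic angle.  The rigid EG273/EG298
("ensemble geometry") variants freeze the geometry at the *thermal
average* of the flexible model at 273 K / 298 K — averaging distances,
not angles: r_e = ⟨OH⟩ and θ_e = 2 arcsin(⟨HH⟩/2⟨OH⟩).  Rigidity
removes the O–H stretch and allows 2 fs time steps; it also mimics
part of the nuclear-quantum delocalisation that classical flexible
dynamics misses.

### Form reconstruction and conventions

Two closed-form details of the published energy expression required a
choice, and both are isolated behind single definitions and locked by
exact-arithmetic transcription tests:

* **U_HB.**  The printed unit of A_4 (kcal Å⁴/mol) identifies an
  inverse-power form (like C_OO's kcal Å⁶/mol), not a quartic well
  (the bond coefficients k2–k4 are printed kcal/(mol Åⁿ)).  The
  squared-inverse-square form adopted here has exactly those units,
  vanishes with zero slope at r_c (a C⁰-only cutoff would break the
  0.5 fs NVE energy conservation this model is documented to achieve),
  and diverges as +A_4/r⁴ at short range.  The divergence is load
  bearing: M (−1.3464 e) and H (+0.6732 e) attract as −q_M q_H/r, and
  without a steeper repulsive wall between them the pair Hamiltonian
  is unbounded below — an attractive reading of U_HB is dynamically
  catastrophic, which rules it out empirically as well.
* **Intramolecular prefactor.**  A global ½ multiplies every bond and
  angle term.  Evidence: with the ½, the OH-stretch curvature
  (k2 = 1263 kcal/mol/Ų) and the bend curvature (k_θ = 80.81
  kcal/mol/rad²) land on physically correct water force constants
  (≈1100 kcal/mol/Ų and ≈76 kcal/mol/rad² in the ½k convention);
  without it both are about twice too stiff (an OH fundamental near
  5600 cm⁻¹).  The ratios k3/k2 and k4/k2 are Morse-consistent either
  way, so the magnitudes decide.  The constant is
  `forcefield.INTRA_PREFACTOR`.

With these choices a linear hydrogen-bonded dimer binds by ≈6.4
kcal/mol at r_OO ≈ 2.8 Å, and the liquid equilibrates to ≈−13 kcal/mol
per molecule at 298 K — both in the expected range for a
condensed-phase water model.

## Engine

Internal units are kcal/mol, Å, ps, e, amu; SI conversion happens only
in the property estimators and file writers.

* **Electrostatics** is plain Ewald (real + reciprocal + self +
  intramolecular-exclusion terms).  α and the reciprocal cutoff derive
  jointly from one accuracy target (default 10⁻⁷), which makes the
  total independent of the splitting parameter to that accuracy; the
  reciprocal sum uses factorized phase matrices, O(N·K/min(K_d)).
  All intramolecular charge pairs are excluded, as the model requires.
* **Van der Waals**: Born–Mayer + r⁻⁶ on O–O inside r_cut (1.0 nm in
  bulk protocols; 1.75 nm and no tail corrections for slabs), with
  uniform-fluid tail corrections to energy and pressure for the r⁻⁶
  term; the exponential tail is neglected (it decays faster than any
  power).
* **Integration** is velocity Verlet; 0.5 fs for flexible, 2 fs for
  rigid variants.  NVT uses a single Nosé–Hoover thermostat
  (τ = 2 ps NPT / 5 ps NVT in the production protocols).  NPT uses
  isotropic stochastic cell rescaling acting on molecular centres of
  mass (a deterministic weak-coupling mode exists for tests); a full
  Parrinello–Rahman piston was not needed at desk scale and is not
  implemented.
* **Rigid geometry** is maintained by SHAKE/RATTLE on the three
  distance constraints (O–H1, O–H2, H1–H2) to 10⁻¹⁰ — equivalent to
  SETTLE at that tolerance, with an explicit iteration bound.
* **M-site forces** are redistributed by the chain rule of the
  (linear) M rule: F_O += (1−2a)F_M, F_H += aF_M.  This preserves net
  force, torque, and — because the pair virial is accumulated on the
  interaction vectors — the virial tensor exactly.
* **Pressure** uses the molecular-virial route:
  P V = Σ M v_cm⊗v_cm + W_site − Σ_i d_i⊗F_i with d_i the position of
  site i relative to its molecular centre of mass.  Intramolecular
  forces, including constraint forces, cancel identically in this
  route, so no SHAKE-multiplier bookkeeping enters the pressure; the
  route is verified against −dU/dV volume-perturbation differences to
  ~10⁻⁸ relative (isotropic and single-axis).
* **Neighbor search** is brute-force minimum image.  Correctness, not
  speed, is the contract at desk scale (≤ a few hundred molecules);
  the O(N²) cost is irrelevant there and the single code path removes
  a class of cell-list bugs.
* Generated starting configurations are relaxed by L-BFGS (with stiff
  geometry restraints for rigid variants, then an exact constraint
  snap) before dynamics; jittered-lattice starts otherwise demand far
  smaller early time steps.

## Estimators

All estimators are pure functions of (series, parameters), take an
explicit equilibration-discard fraction (default 10%), and report
block-averaged uncertainties (10 blocks by default, never fewer than
5).  Units go SI at this boundary.

* κ_T = ⟨δV²⟩/(k_B T ⟨V⟩) from NPT volume series (MPa⁻¹).
* C_p by finite difference of ⟨H⟩ between two NPT runs (protocol pair
  295/301 K for an average of 298 K), J/(mol K).
* ΔH_vap = ⟨V_gas⟩ − ⟨V_liq⟩/N + RT + ΔE_self, each term exposed in
  the report.  ΔE_self is the classical self-polarization correction
  −(μ_model − μ_gas)²/(2α) with μ_gas = 1.855 D and α = 1.444 Å³; the
  model's equilibrium-geometry dipole is 2.203 D, giving −2.5 kJ/mol.
  The ≈−6 kJ/mol nuclear-quantum correction is attached as an
  annotation, never applied.
* ε from total-dipole fluctuations, ε_raw = 1 + 4π⟨δM²⟩/(3Vk_BT); the
  reported value replaces the vacuum baseline with the high-frequency
  dielectric constant, ε = 1.78 + 4π⟨δM²⟩/(3Vk_BT).  Both raw and
  scaled values are always reported so the additive reading of the
  scaling is auditable (a multiplicative 1.78 would imply an
  implausibly low raw value of ≈44 for this charge distribution).
* D from the Einstein relation, slope of the MSD over a lag window
  excluding the ballistic regime (default 10–50% of the maximum lag),
  D = slope/6.  The uncertainty comes from the slope scatter across
  particle groups — time origins are strongly correlated and would
  understate the error by an order of magnitude.  A +15% quantum
  annotation rides along, never applied.  Wrapped input (jumps >
  box/2) is rejected.
* γ = (L_z/2)(⟨P_Z⟩ − (⟨P_X⟩+⟨P_Y⟩)/2) for two-interface slabs,
  1 bar·Å = 10⁻² mN/m.
* Ensemble geometry: r_e = ⟨OH⟩, θ_e = 2 arcsin(⟨HH⟩/2⟨OH⟩) — distance
  averages, not angle averages; the two differ and the distance-based
  definition is the one that constructs the EG variants.

## Critical-phenomena analysis

* Slab profiles are fitted with a symmetric two-tanh form; plateau
  averages stay ≥ max(5 Å, 4 interface widths) away from the fitted
  interfaces (the 4d term caps the tanh-tail bias below 0.1%).  A
  contrast below 5× the profile noise raises a lost-coexistence error.
* Wegner expansion ρ_l − ρ_v = B0 τ^β (1 + B1 τ^Δ), β = 0.325,
  Δ = 0.5 fixed (3D Ising), T_c and amplitudes free; one correction
  amplitude by default (config knob, recorded in the report).
* Diameter law (ρ_l + ρ_v)/2 = ρ_c + c1 τ^(1−α′) + c2 τ with
  α′ = 0.11 fixed; linear least squares.
* Antoine ln P = A − B/(T + C) by least squares on ln P; P_c is the
  form evaluated at T_c.
* IAPWS-E: γ(T) = B τ^μ (1 + bτ) + γ_s exp(c(T_e − T)), μ = 11/9,
  γ_s = 1 mN/m, T_c supplied from coexistence (never fitted).  Free
  parameters B, b, c, T_e: the γ_s convention pins the exponential's
  amplitude so that the deviation from the classical term equals
  exactly 1 mN/m at T_e — which is the definition of the emergence
  temperature.  Trust-region least squares from 8 seeded
  Latin-hypercube starts, tolerances 10⁻¹⁰; if the fitted exponential
  stays below 0.05 mN/m across the data, T_e is reported as not
  detected.  Identification of T_e needs data reaching well into the
  supercooled regime; with γ noise of ±0.2 mN/m and points down to
  ≈233 K the recovered T_e scatters by ≈2 K — the same order as the
  agreement quoted between independent fits of this quantity.
* LLCP localisation: each isobar of a (T, P) scan is classified as
  continuous (finite κ_T peak — the Widom line) or first-order (one
  adjacent-T density jump that exceeds 5× the pooled block stderr
  *and* carries most (>45%) of the isobar's total density change; a
  steep but continuous crossing spreads its change over several grid
  cells).  The critical point is bracketed between adjacent isobars of
  differing class, T from their κ_T peaks, ρ from the density at the
  estimate; uncertainties are at least the grid spacing.  An
  unbracketed grid returns "no critical point", never a fabricated
  one.  The locator recovers the analytic critical point of a
  van-der-Waals-type test equation of state within one grid cell.
* Melting point: NVE three-phase (ice/liquid/vapor) bisection between
  T_L and T_H (280/260 K flexible, 275/255 K EG273), end states
  classified by the mean tetrahedral order parameter of the oxygen
  network (q ≈ 1 in ice Ih, ≲0.65 in the liquid; thresholds 0.8/0.7).
  Ambiguous end states widen the bracket and flag the estimate.  The
  classifier choice is this package's own — the protocol's original
  description does not fix one.

## Synthetic data

The fixtures module generates every test input deterministically from
(parameters, seed):

* Water boxes on jittered cubic lattices at a target density (O–O
  floor 2.4 Å), slabs with a configurable vacuum gap, and
  proton-disordered ice Ih: a lonsdaleite oxygen lattice (a = 4.5 Å,
  c = 7.32 Å — standard crystallography, giving 0.93 g/cm³) whose
  protons are assigned by seeded zero-temperature Monte Carlo on the
  Bernal–Fowler defect count, verified in tests by an independent
  graph check.
* Gaussian/AR(1) observable series whose moments invert each estimator
  exactly (κ_T, C_p, ε, γ), random walks with prescribed D, and
  closed-form coexistence/surface-tension curves with seeded noise.

What these fixtures emulate is the *estimator inversion problem*, not
water: they have exactly the assumed statistics (Gaussian, stationary,
prescribed autocorrelation).  Passing recovery tests therefore
demonstrates the estimators and fitters are correct inverses of their
generative models at realistic magnitudes; it says nothing about
force-field accuracy, which is probed separately by the desk-scale
dynamics (dimer energetics, liquid cohesion, NVE conservation,
ensemble geometry) and, at full scale, by the experiment scripts.

## Problem sizes and reproducibility

Desk-scale defaults — 32–64 molecules, a few ps, cutoffs just under
half the box — were chosen so the whole test suite and the acceptance
script each run in minutes on one CPU.  At these sizes the r⁻⁶ cutoff
discontinuity dominates NVE energy noise (±0.005 kcal/mol/molecule
over ps runs, versus ≲10⁻³ at the full 1.0 nm protocol cutoff), and
small-box pressure components need block-based error bars because
stress decorrelates slowly.  The full published protocols (343–2139
molecules, 5–15+ ns) are encoded in `scripts/experiments/`, which
accept a `--scale` divisor for smoke runs.

Desk-scale outputs worth recording (from `scripts/acceptance.py`,
seeds 1–7): the flexible model's 298 K ensemble geometry lands at
⟨OH⟩ ≈ 0.979 Å and θ ≈ 105.7–105.9°, i.e. within 1% of the published
EG298 construction (0.9706 Å, 105.25°) from a 32-molecule, ~4 ps run —
the liquid stretches the bond (+0.03 Å from the bare r_e) and closes
the angle (−1°) exactly as the EG construction describes.  The
desk-scale ΔH_vap (≈59 kJ/mol vs the full-protocol ≈50) is overbound,
as expected for a small box with a proportionally long cutoff and
nearly-complete LRC; it is labelled desk-scale in the report.

## Known limitations

* No Parrinello–Rahman piston and no triclinic cells; NPT volume
  fluctuations rely on stochastic cell rescaling.
* No mesh-accelerated Ewald; system sizes beyond ~10³ molecules are
  impractical in this implementation (the cluster protocols are
  encoded for completeness and would normally be delegated to a
  production engine via the exported topologies).
* Nuclear-quantum effects enter only as report annotations (+15% on D,
  −6 kJ/mol on ΔH_vap) and implicitly through the EG construction.
* The Gromacs-dialect topology export encodes the Born–Mayer term in
  Buckingham notation and declares U_HB as a tabulated interaction;
  consuming it in an external engine requires generating that table.
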