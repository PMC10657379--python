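# Methods

This note documents the models implemented in `vsglt`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Five-state transport cycle

The kinetic model is a master equation over five conformational states of
the symporter: outward-facing apo (1), outward with Na⁺ bound (2),
occluded with Na⁺ and galactose (3), inward-facing loaded (4) and
inward-facing apo (5). One Na⁺ and one galactose cross per forward cycle.
Ligand-binding steps are pseudo-first-order: the 1→2 rate carries [Na⁺]ₒ,
2→3 carries [Gal]ₒ, and the 5→4 rebinding step carries [Gal]ᵢ[Na⁺]ᵢ (the
release 4→5 is stochastic, so rebinding needs both ligands). Every
directed rate is scaled by a Boltzmann factor in the membrane potential V
(inside minus outside):

    k_ij = k0_ij * exp(-(eta_ij + eps_ij) F V / (R T))

with η the protein gating-charge movement and ε the coupled-ion movement
attributed to that directed rate.

**Charge bookkeeping.** Physical constraints are expressed on *net*
movements, η(i→j) = η_ij − η_ji: the protein charge must close around the
cycle (Ση = 0) and the ion charge must sum to +1 e (one Na⁺ per cycle).
We adopt the convention that charge transfer influences forward and
reverse rates equally, so `TransportParameters.from_net_charges` splits
each net movement symmetrically (each direction carries ±half). Parameter
files store the per-directed-rate values, so an asymmetric split can be
supplied explicitly if desired; `validate_cycle_charges` always checks the
net sums and warns, never silently repairs.

**Orientations.** Reconstitution puts half the transporters in the
membrane inside-out. Flipped transporters experience the opposite field
(exp(+…)) and their binding steps see the swapped compartments ([Na⁺]ᵢ on
1→2, etc.). Consequently the flipped steady state at voltage V equals the
normal steady state at −V *with compartments exchanged*; only for
symmetric concentrations do the two distributions coincide at V = 0. A
forward cycle of a flipped transporter moves cargo out of the lumen, so
mixed-population net uptake is (1−w)·J_normal − w·J_flipped for flipped
fraction w (default 0.5, matching the measured 50/50 incorporation).

**Steady states.** Two independent solvers are exposed: the SVD null
space of the 5×5 generator, and long-time integration of the master
equation (LSODA, rtol 1e−12), declared converged when the maximum
relative state change over a 1-s model-time window falls below 1e−10
(hard cap 1e6 s). `method="both"` runs both and raises if they disagree
beyond 1e−8. Cycle flux is evaluated on the 2→3 edge and asserted equal
on all five edges (tolerance 1e−9, scaled by the flux magnitude). The
inward-facing fraction is the occupancy of states 4+5.

**Sign conventions.** Voltage is inside-minus-outside, so physiological
potentials are negative. With a negative total gating charge the apo
reset step 5→1 carries positive net η; at negative V this accelerates the
reset and depletes the inward states — negative potentials stabilize the
outward-facing conformation, as observed.

**"k₄₆" rates.** The source model description contains a rate into state
5 labelled with a sixth state; with only five states in the scheme and
the 4→5 release drawn explicitly, we read it as the 4→5 rate (k₄₅).

## Reference parameter set

`src/vsglt/data/reference_rates.tsv` is a documented placeholder, not a
measured table. The base rates were calibrated once, by least squares on
log-rates, so that under assay conditions (73 mM Na⁺, 28 µM galactose
outside, empty lumen, 298.15 K) the model reproduces the reference
steady-state behaviour: ~70% inward-facing at 0 mV and ~30% at −60 mV for
the correct orientation (a 40-point outward gain), ~95% inward for the
inverted orientation at −60 mV, a ~13-point drop of the mixed-population
inward fraction from 0 to −60 mV, monotonically increasing turnover
toward negative potentials, and ≥5-fold turnover suppression below
−100 mV when the gating charge is flipped to +0.7 e. The net charge
distribution assigns the majority of the protein charge movement to
inner-gate opening (η₃₄ = −0.5), smaller shares to Na⁺ binding and the
outer-gate step (η₁₂ = η₂₃ = −0.1), and the full return (+0.7) to the
5→1 reset; the ion movement is split ε₁₂ = +0.3 (binding part-way into
the field) and ε₃₄ = +0.7 (translocation). Swapping in a different table
is a one-line change; all analysis respects the TSV layout.

**Gating-charge variants.** Sweeps over Q_gc rescale the reference η map
proportionally (Q_gc/−0.7); an alternative rule concentrating all protein
charge on 3→4 (with the 5→1 return) is available as
`redistribution="inner-gate"`.

## Uptake time course

`uptake_time_course` integrates the lumen composition of a liposome
served by one (mixed-orientation) transporter, assuming the transporter
relaxes to its cycle steady state much faster than the lumen changes
(quasi-steady-state). Defaults: lumen volume 5e−19 L per transporter
(a ~100-nm liposome with ~1 transporter), first-order Na⁺ leak toward the
bath. With the potential held clamped, a negative voltage sustains
accumulation indefinitely and only the chemical gradient dissipates; the
experimental rise–peak–decline shape at negative potentials additionally
requires the K⁺ diffusion potential to run down, available as
`voltage_decay_per_s`. At 0 mV the leak alone reproduces the shape. The
measured pmol/µg/s magnitudes require a protein-mass-to-transporter
conversion that is not modelled; only the qualitative shape and the
initial-slope identity (slope = steady-state mixed flux within 2%) are
claimed.

## Gating charge from energy–voltage curves

The voltage-dependent part of a conformation's electrostatic energy is
Σᵢ qᵢ·φ(zᵢ). We use a linear slab field: with the membrane-normal
coordinate z increasing toward the extracellular face, the field fraction
f(z) ramps linearly from 0 at z_low = −15 Å to 1 at z_high = +15 Å, and
the local potential is φ(z) = V·(1 − f(z)) (the extracellular bath is
grounded; the cytoplasm sits at V). The outward-minus-inward energy
difference is then exactly linear in V:

    dW(V) = -V * sum_i q_i (f(z_of,i) - f(z_if,i))

`fit_gating_charge` returns q_total = Σ qᵢΔfᵢ = −slope, so q_total < 0
means a negative potential lowers the outward-facing state's energy.
This convention makes the fitted value, the closed-form charge
displacement, and the observed stabilization direction mutually
consistent; energies are kept in e·V so the slope reads directly in
elementary charges. Per-residue contributions are fitted from per-residue
curves the same way and must sum to the total (1e−6). The default
voltage series is 11 points spanning ±150 mV.

The slab ramp replaces a membrane Poisson–Boltzmann calculation; real
continuum-electrostatics ΔW(V) tables can be fed straight into
`fit_gating_charge`. The −0.7 e total used in examples is a reference
constant, not something the toy field model derives from structures; the
synthetic residue sets used in the analysis and acceptance scripts are
engineered stand-ins whose closed-form displacement sums to −0.7 e.

## DEER forward model and global fitting

The orientation-averaged point-dipole kernel
K(t,r) = ∫₀¹ cos[(3x²−1)·ω_dd·t] dx with ω_dd = 2π·52.04 MHz·(r/nm)⁻³ is
evaluated by fixed-order Gauss–Legendre quadrature (513 nodes; matches a
10⁵-point Riemann sum to better than 1e−6 over the 15–60 Å, 0–3.5 µs
working range). Distance distributions are Gaussian mixtures
parameterized by mean and FWHM (σ = FWHM/2√(2 ln 2)), discretized on a
1–80 Å grid at 0.2 Å and renormalized per component; the form factor is
V(t) = (1−λ) + λ·∫K·P dr. No intermolecular background is included by
default (appropriate below ~5 µM protein); power scaling
(signal^(1/(n_spins−1))) is available for multi-spin corrections.

**Global fit.** All conditions are fitted together: component means and
FWHMs are global, fractions and modulation depth local. Fractions are
parameterized as bounded positive weights normalized to 1 (the weight
scale is a gauge; reported quantities are the normalized fractions).
Bounds: means inside the grid interior, FWHM ∈ [2, 30] Å, λ ∈
[0.05, 0.95]. Optimization is trust-region least squares with seeded
multistart (default 50 starts: one deterministic spread start plus
uniform draws); component counts are compared by Akaike weights computed
from Gaussian-likelihood residuals (AIC = n ln(RSS/n) + 2p). Components
closer than 1.5 Å are flagged as degenerate, not merged. Uncertainties
come from a residual-resampling bootstrap (default 1000 replicates,
seeded), reported as central 50% and 95% quantile bands per parameter and
per distance-grid point.

**Populations and dimer correction.** Fitted components are classified
inward/outward (or dimer) by nearest reference distance — intracellular
monitor: 44 Å inward / 37 Å outward; extracellular monitor: 26 Å inward /
39 Å outward; ties are reported, never silently assigned. Two dimer
corrections are implemented because the published arithmetic is not
printed: the default removes fitted dimer components and renormalizes the
monomer fractions; the alternative (`from-inward`) multiplies the raw
inward share by (1 − dimer fraction), treating an externally measured
dimer share as hiding under the inward peak. The synthetic intracellular
preset uses a constant 0.18 dimer share at 55 Å so that renormalization
yields corrected inward populations of 90% (0 mV) and 72% (−60 mV) — an
18-point voltage-driven shift for the pipeline to recover.

## Calibrations

Nernst potentials E = (RT/zF)·ln([K⁺]ₒ/[K⁺]ᵢ) at a default 298.15 K;
Stern–Volmer quenching F₀/F = 1 + K_D[Q] fitted through the fixed point
(0, 1) by default (free intercept optional, negative K_D flagged); oxonol
F₂/F₁ ratios tabulated against the nominal Nernst voltage with a
monotonicity diagnostic that is reported, not enforced. Spectra are
assumed pre-reduced to scalar intensities.

## Synthetic data: what it shows and what it does not

Every generator is seeded (bit-identical reruns) and returns a truth
record; recovery tests compare against that record, never against
hard-coded numbers. Noise is white Gaussian throughout — DEER traces
σ = 0.002 of the normalized amplitude, uptake replicates 10% CV, energy
curves 1% of span, quench ratios 1% relative — scales chosen once as
visually realistic. The DEER time base defaults to 0–3.5 µs at 8 ns.
Not emulated: spin-label rotamer distributions and orientation selection,
liposome size dispersity, instrument phase/baseline artefacts, correlated
noise, and the dye photophysics behind the oxonol response. Passing
recovery tests therefore demonstrate the estimators' correctness and
calibration under the stated noise model, not the full error budget of
the real experiments.

## Problem sizes and numerical defaults

Test and acceptance runs use deliberately modest sizes chosen as adequate
for the statistical claims: DEER fits on 2.5 µs traces at 12 ns (4
conditions), 8–12 multistarts, 60–100 bootstrap replicates in tests (the
API default remains 1000); 100 random generators for the dual-solver
cross-check; 500 seeds for gating-charge recovery; 100 seeds for
Stern–Volmer recovery. Tolerances follow the invariants stated above
(probability sums 1e−9, solver agreement 1e−8, flux homogeneity 1e−9,
kernel accuracy 1e−6, round-trip charge recovery 1e−10).

## Known limitations

- The reference rate table is a calibrated placeholder; absolute turnover
  numbers (cycles/s) are not anchored to a measured per-transporter rate.
- The slab field ignores dielectric focusing by aqueous cavities, which
  in real transporters concentrates the field drop; per-residue
  contributions from the toy model are illustrative.
- The quasi-steady-state uptake integrator ignores single-molecule
  stochasticity and liposome heterogeneity.
- Gaussian mixtures cannot represent strongly non-Gaussian distance
  distributions; no non-parametric (Tikhonov) route is provided.
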