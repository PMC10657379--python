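# vsglt

Quantitative machinery for studying how the transmembrane potential (TMP)
biases the alternating-access cycle of the Na⁺/galactose symporter vSGLT.
Negative membrane potentials — present in essentially all cells — stabilize
the transporter's outward-facing conformation, making the sugar-binding
site more accessible to extracellular substrate and accelerating uptake.
The package is written for membrane-transport biophysicists who want to
run, test or extend the three quantitative legs of that argument:

1. **Five-state kinetic model** (`vsglt.transport_cycle`) — the cycle
   1 (outward apo) → 2 (Na⁺ bound) → 3 (occluded) → 4 (inward loaded) →
   5 (inward apo) → 1, with voltage-dependent rates

   *k*ᵢⱼ = *k*⁰ᵢⱼ · exp(−(ηᵢⱼ + εᵢⱼ) *FV*/*RT*),

   where η is the protein gating-charge movement and ε the coupled-ion
   charge movement of the directed transition. Proteoliposomes contain
   both transporter orientations; flipped transporters see the opposite
   field (exp(+…)) and swapped compartments. Steady states are computed
   two independent ways (null space of the rate matrix, and long-time ODE
   integration) and cross-checked.
2. **Gating-charge extraction** (`vsglt.gating_charge`) — the total and
   per-residue gating charge from the slope of the outward-minus-inward
   energy difference ΔW(V), using a linear slab membrane field as a
   desk-scale surrogate for continuum electrostatics. The reference total
   for vSGLT is Q_gc = −0.7 e.
3. **DEER population analysis** (`vsglt.deer`) — forward-modelling of
   dipolar traces through the point-dipole kernel
   K(t,r) = ∫₀¹ cos[(3x²−1) ω_dd t] dx, ω_dd = 2π·52.04 MHz·(r/nm)⁻³,
   and global multi-Gaussian fitting of multi-condition datasets (means
   and widths shared, fractions and modulation depth per condition), with
   Akaike model selection, residual-resampling bootstrap, inward/outward
   classification against reference distances, and dimer correction.

Supporting modules: `vsglt.calibration` (Nernst potentials, Stern–Volmer
quenching, oxonol ratio tables) and `vsglt.synthetic` (seeded generators
for every input, each with a machine-readable truth record, so the whole
pipeline runs with no downloads).

## Worked example

The numbered scripts under `analysis/` run the full story; each writes
tidy tables under `results/`. For instance:

```bash
$ python analysis/01_voltage_sweep.py
Voltage sweep on the reference parameter set (Qgc = -0.7 e):
  correct orientation at -60 mV: 30.2% inward-facing (outward gain 40.2 points vs 0 mV)
  inverted orientation at -60 mV: 95.6% inward-facing
  mixed population inward drop 0 -> -60 mV: 12.7 points
  mixed uptake gain at -60 mV: 3.38x
  +0.7 e vs 0 e suppression below -100 mV: >= 5.6x
```

Reading: at −60 mV a correctly oriented transporter is mostly
outward-facing (70%), while an inverted one — which experiences the
opposite field — is driven almost completely inward-facing (96%). The
50/50 mixed population therefore shows a more modest ~13-point drop in
inward-facing occupancy, and net uptake accelerates several-fold. A
hypothetical +0.7 e gating charge would instead suppress turnover at
strongly negative potentials by more than five-fold.

The same quantities are available from the CLI, e.g.

```bash
vsglt steady --voltage-mv -60 --orientation normal
vsglt sweep --v-min -200 --v-max 100 --qgc -0.7 --qgc 0 --qgc 0.7 --out sweep.csv
vsglt synth deer --scenario intracellular-like --out deer_data/
vsglt fit-deer --traces deer_data/ --ref-inward 44 --ref-outward 37 --ref-dimer 55 --out pops.csv
vsglt calibrate nernst --k-out-mm 15 --k-in-mm 150
```

`analysis/04_deer_populations.py` runs the DEER pipeline end to end on the
synthetic datasets: the extracellular monitor (39 Å outward / 26 Å inward)
resolves the voltage-driven shift toward the outward-open state, and the
intracellular monitor (37 Å outward / 44 Å inward, with a dimer component)
recovers a ~18-point drop in the dimer-corrected inward population between
0 and −60 mV.

## Parameters

The packaged reference rate table
(`src/vsglt/data/reference_rates.tsv`) is a documented placeholder
calibrated so the model reproduces the reference steady-state behaviour
above; any table in the same ten-row TSV layout (columns `transition, k0,
k0_units, eta, epsilon, note`) can be swapped in via `--params` or
`vsglt.io.read_parameters`, which validates transition labels, units and
the cycle charge sums (Ση = 0, Σε = +1 around the forward cycle).

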