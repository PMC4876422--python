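# Methods

## Constitutive model

The tissue is an Ohmic conductor whose conductivity responds to the local
field history through three element-wise state variables.  The composed law
is multiplicative,

    σ = [σ₀ + (σ_MAX − σ₀)·p] · [1 + A_pg·(1 − e^(−d_p/τ_pg))] · [1 + A_T·(1 − e^(−d_T/τ_T))],

so virgin tissue conducts at σ₀ = 0.065 S/m, fully porated undamaged tissue
at σ_MAX = 0.1483 S/m, and the law is bounded by
σ_MAX·(1+A_pg)·(1+A_T) = 0.22523 S/m.  σ is non-decreasing in each state
variable by construction.

**Level of poration `p`.**  The field magnitude sets a target through the
linear ramp clamped to [0, 1] between E_min = 20 kV/m and E_max = 40 kV/m
(thresholds map inclusively).  Pore creation is treated as instantaneous on
the time-step scale: a rising target is attained within the step.  A falling
target is approached as `p_T + (p_prev − p_T)·e^(−Δt/τ_relax)` with
τ_relax = 100 µs, standing in for pore closing.  This asymmetric rule
reproduces the observation that the current reaches a large fraction of its
final amplitude already at the first pulse rise while relaxing between
pulses.

**Damage indicators `d_p`, `d_T`.**  Both accumulate at rate α·E while a
pulse is applied (α_p = 0.0015 m/V, α_T = 25 m/V) and decay exponentially
between pulses; `d_p` decays with τ_relax (the only printed poration
relaxation time) and `d_T` with τ_T = 1.75 s (thermal diffusion).  The
indicators therefore carry units of seconds (α·E·Δt), and enter the
conductivity through exponential-saturation terms with amplitudes
A_pg = 0.35, A_T = 0.125 and specific times τ_pg = 15 µs, τ_T = 1.75 s.
Thermal effects enter *only* through `d_T`; no temperature PDE is solved.

*Known transcription caveat.*  With these units the saturation arguments
`d/τ` grow at rate α·E/τ: at 50 kV/m this is ~5×10⁶ s⁻¹ for the pore-growth
term and ~7×10⁵ s⁻¹ for the thermal term, i.e. both terms saturate within
about a microsecond of field exposure rather than over the tens of
microseconds (τ_pg) or seconds (τ_T) their specific times suggest.  The
published typeset equations this law paraphrases are not recoverable from
the available source text, so the canonical composition above is committed
as-is and the consequence documented rather than silently re-scaled: under
the defaults, the simulated plateau rise and train envelope are much faster
than the printed time constants alone would imply.  All structural
contracts (baseline, bounds, monotonicity, relaxation) are independent of
this choice.

**Capacitive current `j_C`.**  Charge storage in membranes and interfaces
is modelled as a per-element first-order filter on the local (element-mean)
potential: memory state `m ← u + (m − u)·e^(−Δt/RC)`, current magnitude
`A_C·|u − m|·e^(−Δt/RC)/R` directed along the local field axis with the
sign of `u − m`.  A potential step ΔU launches a spike of amplitude
`A_C·ΔU/R` decaying with R·C = 15 Ω × 0.12 µF = 1.8 µs.  When the field
collapses at pulse fall, the discharge is directed along the previously
charged axis (the last conduction-current direction).  The gain A_C/R has
units (m⁻²/Ω), making the output a current density; localisation to the
element potential is a modelling choice made for dimensional consistency —
an electrode-interface double layer is not modelled separately.

## Field problem and solver

Each time step solves the quasi-static charge-conservation equation
∇·(σ(E)∇u) = ∇·j_C with Dirichlet electrodes (applied voltage / ground) and
zero normal current on the outer boundary, discretised with linear
tetrahedra so the field, conductivity and state are constant per element.
The nonlinearity (σ depends on |∇u| through the within-step poration
response) is solved by full Newton iteration: the Jacobian adds the
symmetric rank-one term `(σ'(|w|)/|w|)·(Gw)(Gw)ᵀ` per element, with
one-sided derivatives at the ramp clamps, safeguarded by step halving and a
Picard fallback (Jacobian without the derivative term) on solver failure.
Convergence is declared at a relative residual of 10⁻⁹ against the
boundary-load scale; linearised systems use a sparse direct solve.  On the
coarse two-needle mesh the median is 2–3 iterations per accepted step.

The capacitive source is explicit in time: the step's source term uses the
filter evaluated from the previous converged potential, which preserves the
e^(−Δt/RC) spike behaviour without a transient PDE; the state's stored j_C
is re-evaluated at the converged potential.  The subsidiary variables get
no inner convergence loop — they are explicit functions of the converged
field.

**Time stepping.**  The schedule hits every trapezoid corner exactly, holds
the minimum step Δt_min = 2 µs inside a 10 µs refinement window after each
corner (Δt ≫ R·C would suppress the capacitive spikes), and elsewhere grows
the step geometrically (factor 2) capped at Δt_max = 0.99 s and at the next
corner.  An 8 × 1000 µs, 1 Hz train (7.001 s) takes 281 steps versus the
~3.5 × 10⁶ of constant minimum-step integration.  The committed window +
geometric-growth scheme is one concrete realisation of adaptive stepping;
published step counts of the same order (~190) are treated as an
order-of-magnitude reference, not a target.

**Observables.**  The simulated current I_S sums |j_tot·n̂|·A_i over the
triangles of one electrode surface, with j_tot = σE + j_C sampled in the
adjacent element — the definition used when comparing against measured
currents.  A signed, discretely conservative variant based on the
consistent nodal flux (reaction, K u − f summed over electrode nodes) is
exposed for conservation checks: electrode-to-electrode balance holds to
solver precision (~10⁻¹⁴ relative).  Per-step results export to CSV and
field snapshots (σ, p, |E|, |j|, u) to legacy VTK.

## Geometry and meshing

The standard configuration is a 60 mm tissue cube with two parallel needle
electrodes (diameter 1.2 mm, centres 10 mm apart) entering from the top
face; the conductive band spans the 10 mm of exposed needle centred at
z = 0 and ends in a flat tip, with the insulated shaft above it an
uncharged (zero-flux) surface.  The mesher triangulates the x-y
cross-section (box minus two circular bores, Delaunay) and extrudes it into
prisms split by the minimum-vertex-index rule, which keeps shared
quadrilateral diagonals consistent between neighbours.  Geometrically
graded concentric rings around each bore and z levels graded toward the
band ends resolve the ~1/ρ near-field and the band-edge singularities; a
`resolve_near_field=False` mode drops this grading for minimal element
counts (~2.8 k tetrahedra at a 5 mm edge length) when only solver behaviour
— not quantitative current — is studied.  Domain size, needle dimensions
and edge length are parameters; the 60 mm default is a choice, as the
original sample dimensions are not recorded.

*Desk-scale accuracy.*  The total current converges slowly under uniform
refinement because of the field singularities at the tip rim and the
insulation junction: between bulk edge lengths 5 → 2.5 → 1.25 mm
(18 k → 51 k → 197 k elements) the consistent-flux baseline current changes
by ~4 % per halving, and the surface-sampled I_S by ~9 → 3 %.  Quantitative
absolute currents on this geometry therefore carry a few-percent
discretisation uncertainty at tractable mesh sizes; the refinement harness
(`fem_engine.refinement_study`) quantifies it.  Self-consistent analyses
(parameter recovery, Run1/Run2 comparisons) are unaffected, as generator
and fit share the discretisation.

A 1-D plate-capacitor oracle (uniform field E = U/gap, identical state
updates, no FEM) provides the independent cross-check: on a box mesh the
piecewise-linear basis represents the uniform-field solution exactly, and
FEM currents match the oracle to ≲10⁻⁶ relative.

## Trace processing and calibration

Raw records are down-sampled by averaging consecutive groups of 1000
samples (times and values; a trailing partial group is averaged over its
own length), and the five replicate acquisitions of a sequence are averaged
pointwise after linear interpolation onto the first replicate's grid, with
the pointwise standard deviation retained.  Voltage drives may be measured
traces (integrated on their own sample times) or ideal trapezoids with
2 µs default edges — instantaneous edges would inject an unphysical
capacitive response.

Calibration follows the two-run protocol: Run1 optimises σ_MAX per sequence
by bounded Brent search (tolerance 10⁻⁴ S/m, default bounds
0.125–0.1675 S/m) on avg ΔI — the mean absolute measured-minus-simulated
current difference at the simulated time points, interpreted as an absolute
difference because a signed mean would vanish under oscillation — and
Run2 re-evaluates all sequences with the mean of the Run1 optima frozen.
I_MAX, the normaliser of the relative deviation, is the maximum *measured*
current over the compared span.

## Synthetic experiments

Because no measured records are distributed, verification uses synthetic
campaigns with known ground truth: trapezoidal drives with seeded Gaussian
plateau ripple (default 0.5 %, mirroring the <1 % spread of applied
voltages), the forward model run on the adaptive schedule, currents
interpolated onto a dense acquisition grid restricted to per-pulse
recording windows (as at low repetition rates, where inter-pulse data were
not recorded), and i.i.d. Gaussian noise added per sample at a fraction
(default 1 %) of the replicate's peak current.  Five replicates per
sequence; per-replicate σ₀ perturbation is available (default off) to
emulate biological variability.  Identical seeds reproduce traces
bit-for-bit.

What passing synthetic tests shows — and what it does not: the pipeline is
self-consistent (σ_MAX is recovered to ≪1 % without noise and well within
5 % at 1 % noise), the waveform features (rise, plateau envelope, RC
discharge at fall) are present, and the Run1 ≥ Run2 ordering holds under
heterogeneous ground truths.  It does not validate the constitutive law
against real tissue: synthetic data inherit the model's own dynamics,
i.i.d. noise, and none of the tissue heterogeneity, electrode-placement
variation or drift of real measurements.

## Verification scales and numerical choices

Test and acceptance runs use deliberately small problems chosen for the
study conditions they exercise: the plate box (10 mm gap, 1 cm² area,
~400 elements) wherever the field is uniform, the minimal-count two-needle
mesh (~2.8 k elements) for Newton-iteration statistics, and two-pulse
variants of the 500 V high-repetition-rate sequence for recovery studies
(the full nine-sequence battery runs through the same code paths).
Defaults throughout: Newton tolerance 10⁻⁹, max 25 iterations, Δt ∈ [2 µs,
0.99 s], refinement window 10 µs, growth factor 2, scalar-fit tolerance
10⁻⁴ S/m, down-sampling group 1000, 5 replicates, noise 1 % of peak.
Degenerate inputs are contracts, not silent fixes: negative fields, damage
or out-of-range poration levels raise; a zero-voltage step with a relaxed
state skips the solve; E exactly at E_min/E_max maps inclusively to 0/1.

## Limitations

Isotropic scalar conductivity only (no anisotropy tensors); no temperature
PDE (thermal effects are folded into `d_T`); no separate electrode–
electrolyte double-layer model; no molecular-scale pore kinetics; the
constitutive law is empirical and calibrated for one tissue type and one
electrode geometry — extrapolation beyond liver-like tissue or the
two-needle configuration is untested.  Voltage is applied single-ended
(U on one electrode, 0 on the other); currents are identical to the
symmetric ±U/2 drive for this boundary-condition structure, though
potential maps shift by a constant.
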