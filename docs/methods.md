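# Methods

This note records the models, the numerical choices and the reasoning
behind the design decisions, in the order the pipeline runs.

## Parameter space and designs

A parameter space is an ordered table of named parameters with roles:
`free` (box bounds), `fixed` (single value), `data-derived` (single
value computed from clinical measurements) and `hm-constrained` (free,
but with bounds that are ultimately defined by a history-matching
cloud; the table must still state explicit fallback bounds so the first
wave has a box to sample).  The full table transcribes the tissue
conduction, ventricular (ToR-ORd-role) and atrial (Courtemanche-role)
cell, Land tension, Guccione stiffness and CircAdapt-role circulation
parameters; 46 of them are sampled, the rest fixed.  Ionic parameters
that act only through the calcium transient are exposed as
*multipliers* of the surrogate transient shape (see below); fixed
conductances are carried in the table for completeness but are inert in
the surrogates.

Latin hypercube designs use `scipy.stats.qmc.LatinHypercube` (exactly
one point per stratum and dimension).  Saltelli designs stack the A and
B blocks and the D radial AB_i blocks, `n_base (D+2)` rows in total,
from a scrambled Sobol' sequence in 2D dimensions; `n_base` must be a
power of two (the base-sequence balance properties only hold there).
Space-filling subsets use greedy farthest-point (maximin) selection in
the unit box; the seed picks the starting row, ties break on the lowest
row index, so subsets are reproducible.

## Gaussian-process emulator

One independent emulator per scalar output (no output correlation is
modelled).  Inputs are affinely mapped to the unit box using the
sampling bounds; outputs are centred and scaled by the training
mean/sd.  The prior mean is linear, β₀ + Σβᵢxᵢ; the kernel is ARD
exponentiated-quadratic (Matérn-5/2 available behind the same flag).
β is profiled out of the marginal likelihood by generalised least
squares, and the kernel hyperparameters maximise the profile likelihood
with analytic gradients, L-BFGS-B, and seeded restarts; one start is
placed near the degenerate linear-trend solution (tiny signal variance,
long lengthscales) so exactly-linear data recovers its generating
coefficients rather than a kernel-dominated local optimum.  A fitted
nugget is allowed up to 1e-4 of the output variance (the simulators are
deterministic, but the nugget regularises ill-conditioned fits); the
final factorisation uses an escalating diagonal jitter starting at
1e-11 so that noise-free training points are reproduced to better than
1e-6 relative.  Predictions include the universal-kriging variance
correction for the uncertainty in β, which makes the posterior standard
deviation grow away from the data even for the degenerate linear case.
A constant training output yields a flagged degenerate emulator (mean =
the constant, sd = 0).

Cross-validation is k-fold (default 5) with per-fold R² = 1 − RSS/TSS
and ISE = % of held-out points with |mean − y| < 2 sd.

## Sobol sensitivity analysis

Total effects use the Jansen estimator on the Saltelli design (it has
lower variance than the original Sobol/Homma-Saltelli form and is the
default of the standard toolchain); first-order indices fall out of the
same evaluations but play no role in retention.  Emulator uncertainty
is propagated by drawing from the posterior *marginally per design
point* and averaging the estimator over draws (mean and sd across
draws are stored).  A joint draw over the full design would need a
Cholesky factor of an `n_base (D+2)` square matrix, which is not
tractable at the design sizes used; for well-trained emulators the
posterior sd is small compared to the output range and the independent
draws change the indices negligibly, which the across-draw sd makes
visible.  Negative Monte-Carlo estimates are kept in the stored
matrices and clipped to zero only for ranking and display.

Ranking takes the maximum total effect across outputs *first* and then
normalises the maxima to sum to one; retention keeps the shortest
prefix whose cumulative share reaches the threshold (default 0.90).

For the screened analysis of the coupled model, the Saltelli base
blocks are assembled per sub-model: history-matched blocks draw their
columns from the sub-model's non-implausible region (Latin-hypercube
bases resampled and screened until enough plausible rows exist),
unconstrained columns come from a Sobol' sequence.  The radial AB_i
rows mix A and B rows and can leave the plausible region, so the
assembled design is screened again and the estimator restricted to base
rows whose entire radial block passed.

## History matching

Implausibility is the max over outputs of the absolute standardised
distance between emulator mean and target, with emulator variance and
observation variance added in the denominator.  A wave trains emulators
on the cumulative successful simulations, evaluates a fresh
Latin-hypercube test cloud, splits it at I_th, and picks the next
simulation batch as a maximin subset of the *non-implausible* points.
(The alternative of simulating in the implausible region is exposed via
a flag but is not the default: refining the emulator where candidate
parameter values survive is what shrinks the plausible region.)  The
final threshold is 3 by the three-sigma rule for unimodal
distributions; schedules must be non-increasing and are corrected with
a warning if they end above 3.

Plausible regions of sub-models over disjoint parameter blocks are
combined by independently shuffling each cloud (seeded) and
concatenating column-wise, truncated to the smallest cloud: each block
keeps its marginal distribution while the joint rows are random
pairings.  Blocks with no history matching contribute a plain
Latin-hypercube block.

## Eikonal activation model

The anisotropic Eikonal equation ∇t_aᵀ V ∇t_a = 1 is solved on regular
2D/3D grids with per-node region labels and fibre unit vectors.  The
squared-velocity tensor is transversely isotropic, V = CV_f² ffᵀ +
(k_ft CV_f)² (I − ffᵀ); the fast endocardial conduction (FEC) layer and
the Bachmann bundle scale the regional CV_f by factors ≥ 1; the
atrioventricular insulation layer is non-conducting, so the AV delay of
the dual-site initiation is exactly the imposed source offset.  Units
are mm and ms throughout.

The solver is a heap-ordered label-correcting fast-iterative scheme.
The local update minimises interpolated travel time over two-point
simplexes of the 8-neighbourhood (2D) and the coordinate-plane
simplexes of the 26-neighbourhood (3D), plus direct rays to every
neighbour; the segment minimisation has a closed form (a quadratic in
the barycentric coordinate).  Because anisotropy can violate strict
fast-marching causality, nodes re-enter the heap until a 1e-6 ms fixed
point; the result is first-order convergent against analytic solutions
and never exceeds the pure edge-graph (Dijkstra) arrival times.  At
shock lines where two wavefronts meet, linear interpolation between
parents of different fronts undershoots by O(h); multi-source maps are
therefore bounded above by the pointwise minimum of single-source maps
and agree with it to a fraction of a percent at the default spacing.

The idealised geometry is a two-slab grid (ventricular slab with a
one-row FEC layer over 70% of the long axis, an insulating AV row, an
atrial slab with a Bachmann-bundle strip), with fibres along the long
axis.

## Cell surrogates

The calcium transient is a double-exponential pulse
Ca(t) = Ca_dias + Ca_amp · amp_scale · g(t), with g normalised to unit
peak and beats superposed additively; steady pacing is declared when
the beat-to-beat peak change drops below 0.1%.  The ionic parameters
retained by the sub-model analyses map monotonically onto the shape:
`amp_scale` stands for the L-type calcium conductance (P_Ca / g_CaL),
`decay_scale` for calcium removal (G_NCX / I_up(max); it divides the
decay time constant), and `buffer_scale` for troponin buffering
([TRPN]; it scales the troponin binding rate in the tension model).
Defaults (diastolic 0.10 µM, amplitude 1.05 µM ventricular / 0.55 µM
atrial, rise 15/10 ms, decay 150/110 ms) give transients with
physiological amplitude and duration at the patient's cycle length of
854 ms and, through the tension model, a ventricular twitch with
~170 ms time to peak and ~440 ms duration at 90% recovery — matching
the measured LV pressure duration scale of 467 ms.

Active tension follows a reduced troponin/tropomyosin/crossbridge
scheme: troponin occupancy relaxes toward a Hill function of calcium
(exponent n_TRPN, sensitivity ca_50); the permissive tropomyosin
fraction relaxes toward a Hill function of occupancy (n_Tm, TRPN_50)
at rate k_u; and an unbound→weak→strong crossbridge pool cycles with
on-rates ν·k₀ and µ·k₀ (k₀ = 0.009 ms⁻¹) whose off-rates are pinned so
the fully-permissive steady state sits exactly at S = r_s and
W/S = r_w.  Tension is T_ref · S / r_s, so saturating calcium drives
tension to T_ref.  The troponin and tropomyosin equations are pure
relaxations whose rates blow up at high calcium; they are integrated
with exact exponential updates (coefficients frozen at the step
midpoint), the bounded crossbridge pair with Heun's method, at a
0.02 ms default step (0.05 ms in the pipeline presets; features change
by < 0.1%).  The length-dependence parameters β₀, β₁ and the
distortion rates γ_s, γ_w are accepted for interface completeness and
are inert in the isometric cell — but see the circulation section for
where β₀ re-enters.  The optional force-velocity factor
(1 − A_eff tanh(φ v)), clamped to [0, 1], applies to an externally
supplied normalised shortening-velocity series.

## Passive mechanics

The transversely isotropic exponential law
Ψ = a/2 (e^Q − 1) + κ/2 (log J)², with
Q = b_f E_ff² + 2 b_ft (E_fs² + E_fn²) + b_t (E_ss² + E_nn² + 2 E_sn²)
and κ = 1000 kPa.  The second Piola–Kirchhoff stress is the exact
analytic gradient with respect to the independent (upper-triangle)
strain components.  Chamber inflation treats the cavity as a thin-wall
sphere with an incompressible wall (h r² conserved): the equibiaxial
membrane stretch solves p = 2 σ(λ) h(λ)/r(λ) by bisection to 1e-8
relative, where σ is the plane-stress in-plane Cauchy stress
λ²S_ff − λ⁻⁴S_nn.  Unloading inverts the inflation by an outer
bisection to 1e-6 relative; the round trip closes to 1e-4.

## Closed-loop circulation

Four chambers, four one-way Bernoulli valves, two always-open venous
inlet orifices, four power-law elastic tubes and two linear peripheral
resistances; all laws are stated in the module docstring.  Specific
choices:

* **Units / constants.**  mmHg–mL–s at the circuit level; blood density
  1.05 g/mL; 1 kPa = 7.50062 mmHg.  The orifice law is regularised near
  zero pressure drop (0.2 mmHg) to keep the vector field Lipschitz.
* **Tube reference pressures.**  92 / 13.25 / 2 / 2 mmHg for aorta,
  pulmonary artery, systemic and pulmonary veins, scaled by the pAo0…
  pPve0 factors; with the patient's q_ref = 82 mL/s and the reference
  pressure drops (90.01 and 11.25 mmHg) these make the resistance
  scalings R_sys, R_pulm dimensionless multipliers of the physiological
  operating point.  Tube reference volumes are the adjacent valve
  orifice area times the tube length.
* **Frank–Starling recruitment.**  The one-fibre active pressure
  (1/3) T ln(1 + V_wall/V) *decreases* with volume; in a closed loop of
  fixed blood volume that feedback is destabilising and makes cardiac
  output — and hence peak pressure — fall when afterload rises, which
  contradicts basic circulatory physiology.  The chamber therefore
  multiplies the active term by the Land length-dependence factor
  [1 + β₀(λ − 1)]₊ with λ = (V/V_unloaded)^{1/3} and β₀ = 2.3, the same
  parameter that is inert in the isometric cell.  With it, raising
  systemic resistance raises LV peak pressure, raising pulmonary
  resistance congests the right side and starves the left atrium, and
  stiffer ventricles empty less — the expected directional behaviour.
* **Pericardium.**  A volume-excess penalty
  p_peri = k_peri max(0, ΣV − 0.85 ΣV_init)/A_peri added to all four
  chambers.  The 15% reserve makes the sac taut through diastole and
  slack in systole; the effective displacement area is a third of the
  spherical envelope of the total cardiac volume (the base is held, the
  free walls and apex move).  This produces diastolic ventricular
  interaction: strengthening the RV drive raises EDV_LV and lowers
  EDV_RV, and the trade-off ratio tightens as k_peri moves to its
  upper bound.
* **Initial conditions.**  Chambers start at low early-diastolic
  pressures (2–4 mmHg) and tubes at fixed nominal pressures
  (75 / 13.25 / 1.8 / 2.5 mmHg), so the total blood volume is identical
  across parameter points and is not a hidden confounder of the
  sensitivity analysis.  Integration is explicit RK4 at a 0.25–1 ms
  substep; 8 beats reach a beat-to-beat volume residual of ~1e-4.
  Runs that reach negative, non-finite or absurd volumes are flagged
  failed and frozen — failures are data, carried through the batch with
  `success=False` and excluded from emulator training.
* **Batching.**  Many parameter points integrate simultaneously
  (`build_circuit_batch`); this is what keeps the 120-point coupled
  design at seconds rather than tens of minutes.

The 20 outputs are the per-chamber end-diastolic and end-systolic
volumes, end-diastolic and peak pressures, dp/dt extrema (centred
differences, mmHg/s), the atrial v-wave maximum volume (while the AV
valve is closed) and the atrial contraction-window pressure maximum;
ventricular end-diastole is read at ventricular activation onset and
the atrial contraction window is where the atrial drive exceeds 5% of
its peak.

## Pipeline and presets

Each sub-model stage runs design → simulate → emulate → cross-validate
→ Sobol ranking with 90% retention; the tissue and the two cell stages
additionally run history-matching waves against *self-consistent*
targets: the stage simulated at the true (default) parameter point with
σ = 5% of each value attached.  This makes closed-loop
parameter-recovery checks possible without external data.  The final
analysis projects the plausible clouds onto the retained columns
(re-fitting the screening emulators on those columns — legitimate
because the dropped inputs are precisely the insensitive ones),
intersects them with a Latin-hypercube block for the non-HM parameters,
simulates a maximin subset through the coupled chain, trains the 20
output emulators, and runs the screened Sobol analysis with signed
effects (the sign of each emulator's βᵢ).

Two presets: `desk` — 12 free parameters, stage designs of 40–48 runs,
2 waves with 50 000-point test clouds, 256 Saltelli base samples, 120
coupled runs; it completes in under three minutes on one CPU and is the
configuration the tests run.  `paper` — the full 46-parameter table,
stage designs of 150–300, 3 waves with 100 000-point clouds, 2048 base
samples and 500 coupled runs; the documented literature-scale
configuration (hours, not tested routinely).  All seeds are explicit;
identical configuration and seeds reproduce every ranking bit-exactly.

## What the surrogates do and do not show

The forward models reproduce the *statistical structure* the analysis
machinery assumes — a deterministic multi-output simulator over a box,
smooth responses with interactions, occasional failed runs, outputs
with the field's names and physiological magnitudes.  They are not the
biophysical ODE/FEM systems they stand in for: the calcium surrogate
has no restitution or rate dependence; the tension scheme omits
length- and velocity-dependent kinetics at the cell level; the
thin-wall chambers have no regional geometry; the circulation has no
valve inertance or regurgitation.  Passing tests therefore demonstrate
the correctness and robustness of the emulation / sensitivity /
history-matching machinery and the qualitative physiology of the
coupled loop, not quantitative agreement with measurements on a real
heart.  Known limitations: the pericardial k_peri sensitivity is
deliberately mild at the default operating point; the Eikonal solver's
O(h) shock artifact (above); and the screened Sobol indices are
conditional on the plausible region, as in any constrained-input
variance decomposition.
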