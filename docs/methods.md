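# Methods

## Physical model

The package simulates ion concentrations `c_k(x, t)` and the electric
potential `phi(x, t)` in brain extracellular space (ECS), treated as a
continuous porous conductive medium. Each species obeys a continuity
equation with the Nernst–Planck flux

    J_k = -D_k (grad c_k + z_k c_k grad(phi) / psi),      psi = RT/F,

plus point source terms representing neuronal membrane currents. The
porous-medium approximation enters twice: effective diffusion
coefficients are `D_k / lambda^2` (tortuosity `lambda = 1.6` by default)
and source densities are divided by the ECS volume fraction
(`alpha = 0.2`), both standard values for cortical tissue. Four species
are packaged — Na+ (150 mM), K+ (3 mM), Ca2+ (1.4 mM) and a lumped anion
X− (155.8 mM) with the mobility of Cl− — forming an electroneutral
baseline.

Four schemes close the system for `phi`:

- **PNP** couples the species equations to Poisson's equation
  `laplacian(phi) = -rho/eps` with `eps = 80 eps0`. It resolves charge
  relaxation, whose time constant `eps/sigma` is about 0.9 ns at the
  baseline conductivity `sigma ≈ 0.77 S/m`, and therefore needs
  sub-nanometre grids and sub-nanosecond steps.
- **KNP** replaces Poisson's equation with the bulk-electroneutrality
  constraint `d(rho)/dt = -i_cap`: the quasi-steady potential solves the
  elliptic equation `div(sigma grad phi + grad b) + F sum_k z_k f_k +
  i_cap = 0`, where `sigma = F sum_k D_k z_k^2 c_k / psi` and
  `b = F sum_k D_k z_k c_k` are recomputed from the evolving
  concentrations. The potential is split into a volume-conductor part
  `phi_VC` (driven by the membrane currents) and a diffusion part
  `phi_diff` (driven by `grad b`), solved as separate elliptic equations
  whose sum equals the single-field solution to solver tolerance.
  Capacitive currents source only the potential equation, never the
  species equations.
- **VC** freezes the concentrations and solves only the `phi_VC`
  equation (optionally with a constant baseline conductivity, the
  classical volume-conductor limit).
- **DO** sets `phi = 0` and diffuses each species independently.

Boundary conditions: `sealed` imposes zero normal species flux; `clamp`
holds boundary concentrations at the baseline (a reservoir). The
potential satisfies zero normal gradient for `phi_VC`, zero normal total
charge flux for `phi_diff` (both natural conditions of the finite-volume
assembly), and a zero-volume-mean constraint fixes the free constant.
The PNP potential uses the same homogeneous-Neumann + zero-mean choice
so the two electrodiffusive schemes are directly comparable; nothing in
the model pins an absolute potential, so only differences are
meaningful.

## Discretisation

Vertex-centred finite volumes on uniform structured grids (1-D or 3-D),
node ordering x-fastest. Two-point face fluxes with arithmetic
averaging of nodal coefficients discretise every `div(a grad u)`
operator; boundary faces are simply dropped, which makes the sealed
scheme conserve each species to round-off (verified to 1e-9 relative
over full runs). The operators are exact for linear fields and converge
at second order on manufactured smooth solutions (tested in 1-D and
3-D). Arithmetic rather than harmonic face averaging was chosen because
the coefficients (`sigma`, `D_k c_k`) vary smoothly on the grid scale;
it also mirrors the behaviour of continuous linear elements.

Point sources are deposited on the single nearest node (ties toward the
smaller flat index) and divided by that node's control volume, so grid
integrals reproduce the prescribed currents exactly. A probe one
spacing from a source node therefore sees the discrete lattice Green's
function rather than `1/(4 pi r)` — about +8% at one spacing, ~1% by
three spacings — which matters when comparing against free-space
formulas (see the VC oracle test, which probes three spacings out).

Time stepping is implicit Euler throughout (chosen for the stability the
PNP system demands; KNP tolerates it easily). Each step of KNP and PNP
solves the fully coupled nonlinear system — species plus potential(s) —
monolithically with Newton's method. The Jacobian is assembled
analytically: `sigma` and `b` are linear in `c`, and the migration term
is bilinear in `c` and `phi`, so `div(a grad u)` differentiates exactly
with respect to both arguments. Residual rows are scaled to be
dimensionless (species rows by `dt/c_scale`, potential rows by
`h^2/(sigma_ref psi)`), and the iteration stops when the scaled RMS
residual falls below `abs_tol = 1e-10`, the residual has dropped by
`rel_tol = 1e-8`, or the scaled update stalls below `step_tol = 1e-12`
(the round-off floor of large systems); `max_iter = 20` failures reject
the step and raise. The factorised Jacobian is reused across iterations
and steps and rebuilt whenever the observed contraction per iteration is
worse than 0.1 — for these weakly nonlinear systems the converged states
are identical to full Newton, at a fraction of the factorisations.

Linear solves: systems up to 60k unknowns use a sparse LU. Larger
coupled systems (the 3-D applications: ~354k unknowns) use GMRES on the
full Jacobian with a block Gauss–Seidel preconditioner — each field's
diagonal block is factorised separately and applied in a lower-
triangular sweep — converging in ~10 iterations to `linear_tol = 1e-8`.
Large single-field elliptic solves use Jacobi-preconditioned conjugate
gradients on the volume-scaled symmetric form, with the constant
nullspace deflated in the all-Neumann case. Negative concentrations
after a step (possible only at round-off level) are clipped to zero with
a logged warning; a clip above 1e-6 of the baseline scale is treated as
a solver failure.

## Sources

Compartment sources carry per-species and capacitive current series on
one uniform time base, treated as piecewise constant; stepping
integrates them exactly over each window rather than sampling. Positive
current means positive charge leaving the cell into the ECS. A closed
cell satisfies `sum_j I^j(t) = 0` at every sample; the loader warns when
a file violates this.

The synthetic neuron generator is a surrogate for an external
compartmental simulation, not a biophysical model. It places a soma at
the origin plus a line of dendritic compartments (default 20
compartments over 1000 um along +y), fires Poisson-timed action
potentials (default 5 AP/s — a typical cortical pyramidal-cell rate),
and emits per event a stereotyped 2 ms biphasic waveform: 1 ms of
triangular Na+ influx followed by 1 ms of K+ efflux, 60% at the soma and
the rest on the nearest dendritic compartments, with 0.5 nA peak-phase
amplitude chosen to give per-AP charge transfers of order 0.5 pC. The
capacitive return current is spread uniformly over all compartments and
defined as minus the total ionic current, so whole-cell balance holds
exactly at every sample. An optional constant K+/Na+ exchange on the
dendrites (off by default) emulates slow synaptic load. Everything is
driven by one seeded generator, so equal seeds give bit-identical source
sets. What the surrogate does not emulate: realistic channel kinetics,
morphology-dependent current distributions, or the ion-species mix of
synaptic currents — conclusions drawn from it are qualitative
(scheme-to-scheme differences), never quantitative magnitudes.

## Packaged applications and the scales used

1. **1-D salt step** (`run_app1`): Na+/X− at 140 mM for x ≤ 0 and
   150 mM for x > 0, sealed box. `short`: [−0.1, 0.1] um, dx = 0.02 nm,
   dt = 0.1 ns (PNP-capable); `long`: [−50, 50] um, dx = 0.01 um,
   dt = 1 ms. The long default end time is 10 s — the timescale on
   which the gradient actually relaxes; diagnostics are evaluated at
   t = 1 s. KNP develops the junction potential
   `psi (D_X - D_Na)/(D_X + D_Na) ln(150/140) ≈ +0.372 mV`
   (high-concentration side positive) instantly; PNP builds it over a
   few nanoseconds; DO separates the species, implying a ~250 kV
   Poisson voltage — the argument for electroneutral bulk schemes.
2. **K+ source/sink pair** (`run_app2`): 400×400×40 um box, 5 um grid,
   clamp boundaries, ±0.1 nA at (120, 200, 20)/(280, 200, 20) um for
   1 s, probes 5 um from each electrode. The diffusion potential
   screens the ohmic potential by several percent within 0.1 s and
   outlives the stimulus. Note that in this thin box the Neumann walls
   raise the probe-to-probe `phi_VC` by ~40% over the free-space
   two-monopole value (method-of-images), and the measured screening at
   t = 0.1 s on this grid is ~7% — grid-halving stable to < 0.1
   percentage points, somewhat above the ~5% a coarse-mesh version of
   the same setup yields.
3. **Surrogate neuron** (`run_app3_surrogate`): the bounding box
   [−500, 500] × [−400, 1100] × [−500, 500] um of a 500 um-radius,
   1500 um-tall tissue cylinder, clamp boundaries, soma at the origin,
   probes at (20, 20, 20) um and (−100, 1100, 0) um. Defaults: 50 um
   spacing, dt = 0.1 s. Tests run a scaled-down version (100 um
   spacing, 2 s) — the properties checked (determinism, charge balance,
   decomposition linearity, the KNP-vs-DO divergence of X− at the soma)
   are scale-free, while absolute magnitudes depend on the surrogate's
   arbitrary amplitudes and are deliberately not asserted.

The acceptance script runs the first two applications at full stated
resolution (10001 nodes / 1000 steps in 1-D; 81×81×9 nodes / 50 steps in
3-D) and the short PNP/KNP comparison for 500 steps of 0.1 ns; the test
suite uses reduced grids (201–2001 nodes, reduced boxes) wherever the
property under test is resolution-independent.

## Numerical choices and degenerate inputs

- Grid spacing that does not divide the extent is rounded up in cell
  count and the spacing adjusted (logged).
- Zero-mean is implemented as solve-with-pinned-node (or deflated CG)
  followed by a volume-weighted mean shift; the shift leaves all
  potential differences unchanged.
- An unbalanced source set under all-Neumann potential boundaries makes
  the elliptic problem inconsistent; this is detected and reported
  rather than silently regularised.
- `probe` is multilinear interpolation and exact for multilinear fields;
  probes are rejected outside the domain; application 2 refuses probes
  that collide with a source node.
- The PNP scheme warns when the grid spacing exceeds 1 nm (Debye layer
  unresolved); application 1 refuses PNP on the long variant outside an
  explicit override.
- Permittivity is used uncorrected by tortuosity (`eps = 80 eps0`); only
  PNP and the implied-Poisson diagnostic depend on it.

## Known limitations

- Structured boxes only: the tissue cylinder of application 3 is
  replaced by its bounding box (the clamp boundary is far from the
  sources, so the shape difference is second order in the probe
  quantities).
- One-way coupling: ECS state never feeds back into the membrane
  sources.
- Nearest-node deposition makes fields within one or two spacings of a
  point source resolution-dependent; probe placement should respect
  that.
- No activity coefficients, temperature dependence, or ion-ion
  correlation corrections; concentrations are ideal-solution.
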