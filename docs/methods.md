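# Methods

`capsim` is an agent-based model of nanoparticle transport in a single
capillary. Three agent families interact in a cylindrical vessel: red
blood cells (moving internal flow boundaries), nanoparticles (spheres
carried by the flow and kicked by thermal noise), and wall fenestrations
(radial pores through the endothelium). This note records the model, its
assumptions, the numerical choices, and what the synthetic conditions do
and do not represent.

## Vessel and red blood cells

The capillary is a hollow cylinder of radius 4000 nm (an 8 um vessel;
capillaries span roughly 5-40 um) and default segment length 50 um, with
no-slip walls and a periodic axial direction: the simulated segment is one
repeat of an effectively infinite vessel, which is the natural frame for a
train of equally spaced cells.

Capillary haematocrit is 10-12% (systemic blood is 38-46%); the model
covers 0-45%. The cell count is `round(H * pi R^2 L / V_cell)` with a
mean corpuscular volume of 94 um^3. In this confinement RBCs adopt the
axisymmetric parachute conformation, centred on the axis and oriented
perpendicular to the flow; deformation dynamics, slipper/bullet shapes,
off-axis positions and cell-cell hydrodynamics are out of scope.

The parachute is a spheroidal-cap shell: a spheroid with radial semi-axis
`a` = 2900 nm (post-deformation effective radius; a configurable
literature stand-in) dented on the upstream face by a mirrored cap of
depth `h` = 1200 nm. The axial semi-axis `c` is solved so the shell volume
equals the cell volume; a *spherical* shell of maximal radius 2900 nm
cannot hold 94 um^3 without closing into a near-ball, whose axial bulk
would make whole-blood haematocrit geometrically impossible in this
vessel, hence the spheroidal generalisation. Identical cells nest
(downstream cap into upstream dent), so a uniformly spaced train reaches
45% without shell overlap. Placement is uniform along the axis
(deterministic); replicate initial conditions jitter the centres within
the nesting slack.

For the flow and for particle excluded volume the cell is represented by
its *filled* spheroidal envelope: at Reynolds number ~1e-3 the plasma
inside the concavity is trapped and co-moves with the cell, so resolving
the dent would add mesh complexity without changing the outer flow. The
dented shell itself is retained for volume bookkeeping, overlap checks and
profile export.

## Flow solver

Plasma is Newtonian and incompressible; the suspension viscosity enters
through a haematocrit relation, by default the polynomial
`mu(H) = mu_p (1 + 2.5 H + 7.35 H^2)` (Einstein's dilute-limit slope plus
a quadratic crowding term; an exponential alternative `mu_p exp(3H)` is
selectable). Plasma viscosity is 1.2e-3 Pa s, density 1025 kg/m^3,
temperature 310 K.

With Re ~ 1e-3 (far below the ~2400 laminar-turbulent transition) the
convective term is negligible, so each flow update solves the quasi-static
axisymmetric Stokes equations. The arteriole-venule pressure difference is
applied as a uniform axial body force `f_z = dp/L` in the periodic domain;
the default drop (82.5 Pa over 50 um) is calibrated so the acellular
centreline speed is 5500 um/s, the working centreline speed of the model
(the corresponding near-wall speed is a few hundred um/s).

Discretisation: linear (P1/P1) triangles on a boundary-fitted mapped
structured grid — each axial station spans radially from the local cell
silhouette s(z) to the wall, so RBC surfaces are meshed exactly and never
cut elements. Equal-order velocity/pressure pairs are stabilised with a
Galerkin/least-squares (PSPG) pressure term `tau (grad p - f, grad q)`,
`tau = 0.1 h^2 / mu`; one pressure dof is pinned; the periodic seam is a
duplicated node column folded onto its master dofs. The saddle system is
solved by direct sparse factorisation. Verified against closed forms: the
Poiseuille profile (max error 0.15% at the default 24x250 grid, converging
quadratically) and the annular drag (log-profile) flow around a
lumen-spanning driven plug (<0.5%). Cross-section volumetric flux
(fluid + moving cells) is conserved to ~2% at default resolution.

RBC speed is not prescribed: cells travel at the speed where the net axial
hydrodynamic traction on the train vanishes. Because Stokes flow is linear
in the boundary data, the force-free speed follows exactly from two trial
solves (a secant step on a linear function), and a third solve verifies
the residual. All cells share one speed — they are identical, axisymmetric
and evenly spaced — so the flow field is steady in the co-moving frame and
later times are rigid axial translations of one solved field. The
`flow_update_every` cadence controls how often the translation offset is
refreshed (default: every 10 particle steps).

## Nanoparticle dynamics

Particles are rigid spheres, 10-160 nm in diameter, dilute (no
particle-particle interactions), and inert (a PEG-like non-adsorbing
surface is assumed). Each step composes two displacement vectors:

* advection `u(x) dt`, with `u` interpolated linearly from the flow field
  (azimuthal components reconstructed from the axisymmetric (v_r, v_z));
* a Brownian kick with per-axis standard deviation
  `sigma = sqrt(2 D_c dt)`, where `D_c = k_B T / (6 pi mu_p r)` is the
  Stokes-Einstein coefficient in plasma (a nanoparticle between cells
  feels plasma, not suspension, viscosity). Gaussian variates come from
  the polar (modified) Box-Muller transformation.

The update is overdamped: a nanoparticle's momentum relaxation time is
nanoseconds, 1e5 times below the default `dt` = 1e-4 s, so integrating
inertia would be numerically meaningless at this step. Either displacement
component can be toggled off, which is how the laminar/Brownian force
decomposition is produced (the runs share noise streams, so the
decomposition is pathwise).

The wall reflects specularly about the accessible cylinder
`rho = R - r_p` (axial coordinate preserved; mirror reflection preserves
the uniform equilibrium distribution of a diffusing population, which
rejection re-draws would not). RBC overlap is resolved geometrically: a
particle intersecting a cell envelope is pushed along the local outward
normal to tangential contact, implemented as projection onto the
Minkowski dilation (by the particle radius) of the envelope cross-section.
Faxén wall corrections, lift, shear-induced migration and rotation are not
modelled.

Randomness is one stream per particle id, derived from the master seed
(plus a second stream per particle for pore transits), so trajectories are
bit-reproducible and independent of how many particles run together.

## Fenestrations

Pores are radial cylindrical channels through the endothelium: diameter
60 nm (normal vessel) or 240 nm (tumour vessel), channel length equal to
the 400 nm wall thickness, placed uniformly over the wall without overlap
at a default density of 1 pore/um^2 (density and geometry are literature
stand-ins, configurable). Entry requires all of: hard-sphere fit
(particle radius strictly below pore radius), particle surface within the
20 nm capture distance of the wall (shared with the binding-range
definition), and wall projection within `pore radius - particle radius`
of the pore centre. An entering particle starts one particle-radius into
the channel (centre at the mouth plane tangency).

Inside the pore the particle performs a Brownian walk at sub-step
`dt_pore` = 1e-7 s (the channel is only a few hundred nm; the lumen-scale
step would jump across it). Crossing the outer end is absorbing
(translocated); re-crossing the inner mouth returns the particle to the
lumen at the pore mouth. The transit outcome is governed by the axial
walk — the classic gambler's-ruin first-passage problem, against which the
implementation is tested; lateral excursions are confined to the
accessible channel radius by radial folding and carry no observable (the
channel wall is neither absorbing nor sticky). Diffusion inside the pore
uses the free `D_c`; hindered (Renkin-type) diffusion is a noted extension
point. Only fully translocated particles count as delivered; particles
still inside a pore at readout are reported separately.

## Derived statistics

* Radial velocity `V_R = sqrt(v_x^2 + v_y^2)`; dispersion factor
  `DF = V_R / v_z` (0 for flow parallel to the wall); average dispersion
  factor ADF = unweighted mean of element-centroid DF over fluid elements.
  Elements with `|v_z|` below 1e-9 of the field maximum are excluded and
  counted, not zero-filled (zero-filling would bias ADF down silently).
  The boundary-fitted mesh contains no RBC-interior elements; a mask hook
  mirrors the sum-over-flow-elements definition.
* MSD `|x(t) - x(0)|^2`, ensemble-averaged, computed on unwrapped axial
  coordinates (periodic wrapping would corrupt displacements).
* Binding-range fraction: percent of particles whose surface is within
  20 nm of the wall; reported both instantaneous and time-averaged over
  the run (the time average is the statistically efficient estimator for
  occupancy of a thin layer).
* Mean radial position of particle centres; for a uniform population over
  an accessible disc of radius R_a the closed form is (2/3) R_a, which is
  the oracle the implementation is validated against.
* Specificity ratio = tumour uptake / normal uptake (infinite when only
  tumours receive; 0/0 not computable). Specificity score =
  ratio x tumour uptake fraction — the minimal form rewarding both
  selectivity and absolute delivery; it is quadratic in tumour uptake at
  fixed normal uptake. The score definition is a package choice (the
  ratio-times-efficiency reading) and is isolated behind one function.
* Delivered volume: sum of `(pi/6) d^3` over translocated particles — the
  cargo-capacity proxy.
* Holm-Sidak step-down adjustment for multiple t-tests, implemented as
  the literal step-down formula (sorted ascending,
  `1 - (1 - p_(i))^(m-i+1)`, monotone-enforced) and cross-checked in the
  tests against statsmodels.

## Synthetic size populations

DLS-style populations are binned diameter distributions (Zetasizer
convention): 26 logarithmically spaced classes over 1-1000 nm with percent
weights. Sampling draws the class by inverse CDF on the weights, then the
diameter within the class from a piecewise-linear density whose endpoint
values interpolate the neighbouring classes' weights (the minimal smooth
reading of neighbour-weighted within-class sampling). The synthetic
generator bins a lognormal with prescribed mean `m` and variance
`pdi * m^2`, treated as number-weighted; measured DLS tables load from CSV
(`lower_nm, upper_nm, percent`, renormalised with a warning when within 1%
of 100). Monodisperse populations are degenerate one-class distributions
returning the exact diameter.

What the generator does *not* emulate: intensity-to-number conversion of
raw autocorrelation data, multimodal populations, and instrument noise.
Passing tests therefore show that the transport and selectivity machinery
responds correctly to polydispersity of the stated width — not that any
particular measured formulation is reproduced.

## Study conditions and problem sizes

Default experiment conditions: capillary haematocrit 10.7%; particle
populations of 200; uptake readout at 0.5 s with `dt` = 1e-4 s; force
balance over 0.003 s; haematocrit sweeps over
{0, 5, 10.7, 15, 20, 25, 30, 38, 45}% with 3 jittered replicates;
polydispersity comparisons over 5 seeds at pdi 0.1. Meshes: 24x250
(default), 16x120 (particle experiments), 14x100 (sweeps) — resolutions at
which the closed-form oracles hold to the tolerances quoted above.

## Known limitations

* Axisymmetry excludes off-axis cells, tumbling and margination physics;
  the dispersion mechanism captured is the axisymmetric squeeze/recovery
  flow around each cell.
* The viscosity-haematocrit curve, RBC effective radius/volume, pore
  density and endothelium thickness are literature stand-ins exposed in
  the config, not fitted values.
* The force-free RBC speed is computed for the train as a whole; cells do
  not exchange momentum individually.
* No glycocalyx, receptor binding, cellular trafficking, transmural
  pressure-driven flow, or particle deformability (flexible particles are
  known to cross pores smaller than themselves; rigid spheres here cannot).
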