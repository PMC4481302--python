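# Methods

This note documents the models implemented in `cortexlfp`, the assumptions
behind them, the numerical choices, what the synthetic fixtures do and do
not emulate, and the package's known limitations.

## Extracellular forward model

The extracellular medium is treated as purely resistive, homogeneous,
isotropic and frequency-independent, with conductivity σ = 0.3 S/m by
default. Under these assumptions the potential is a linear functional of
the compartmental membrane currents. Dendritic compartments are line
sources — the membrane current is assumed uniformly distributed along the
cylinder axis — and somatic compartments are point sources at the cylinder
midpoint. With currents in nA, distances in µm and σ in S/m, potentials
come out in µV through a factor 10³ (1 nA/(1 S/m·1 µm) = 10⁻³ V).

Because the medium is linear and the geometry static, the geometric factor
of every (electrode, compartment) pair is precomputed into a weight matrix
W; each LFP sample is then W·I_mem. A test asserts that this equals direct
per-sample evaluation of the source equations to 1e-9 relative.

Singularities: the perpendicular distance ρ (line sources) and the radial
distance r (point sources) are clamped from below at the compartment
radius, so an electrode placed on or inside a neurite sees the surface
potential rather than a divergence.

Membrane currents are computed as the axial current flowing *into* each
compartment (the sparse graph-Laplacian product A·V). By Kirchhoff's law
this equals the total outward membrane current — capacitive, leak, synaptic,
spike and membrane-modelled drive combined — and it sums to zero over each
neuron by construction (machine precision), which guarantees the dipolar
far-field decay of every cell's contribution. An intracellular electrode
current is the one exception: it enters the cell without crossing the
membrane once, so it appears as an explicit monopole term. Single-compartment
neurons have no axial edges, hence zero membrane current, and are excluded
from the LFP: they can be used as spike-relay ("external input")
populations that do not pollute the field.

Stochastic drive is modelled as a *membrane-crossing* current at its target
compartment by default, so it is part of that compartment's membrane
current and charge conservation holds. The alternative
(`drive_mode="injection"`), which treats drive like an electrode current
and introduces a monopole, is available for sensitivity studies.

## Neuron models

### Equivalent-cable reduction

`reduce_morphology` collapses a reconstructed morphology (SWC point tree)
into few compartments under a user-supplied section plan. For each section:
the compartment length is the mean of the path lengths of the parallel
branches it represents; each branch is first replaced by a single cylinder
of equal length whose diameter preserves the branch's end-to-end axial
resistance; the section's equivalent diameter then conserves the axial
conductance of the parallel branches, d_eq = √(Σ d_b²). The collapsed model
therefore keeps total path length and axial resistance but has a smaller
membrane area and no lateral dendritic spread. No membrane-area correction
factor (rescaling specific capacitance and resistance to restore input
resistance) is applied by default — the smaller membrane area is accepted
as a property of the reduction — because the populations are validated on
the LFP they generate, not on single-cell input resistance.

The soma is modelled as a single cylinder. A single SWC soma sample of
radius r becomes a cylinder with length = diameter chosen to match the
sphere's surface area (L = d = 2r); multi-point somas become a cylinder
with the reconstruction's soma path length and matched lateral area.

### Archetype cells

Seven built-in archetypes cover the slice model's groups: L2/3, L4, L5 and
L6 pyramids (8, 8, 9, 9 compartments), L4 spiny stellate (7), basket and
non-basket interneurons (7 each). Their compartment dimensions are
representative values chosen to give layer-appropriate vertical extents
(L2/3 apical ≈ 310 µm, L5 apical ≈ 950 µm, so that somas placed at
realistic depths keep their tufts below the pia); they are explicitly *not*
a published reconstruction-by-reconstruction data set, and studies needing
particular cells should reduce their own SWC files. Passive parameters are
Cm = 1 µF/cm², Ra = 150 Ω·cm and Rm = 20 kΩ·cm² (τ_m = 20 ms) for
excitatory cells; interneurons use Rm = 8 kΩ·cm² (τ_m = 8 ms), reflecting
the short membrane time constant of fast-spiking cells.

### Dynamics

Each compartment follows the passive cable equation; somas may carry the
standard AdEx mechanism (exponential spike-initiation term with slope ΔT
and threshold V_T, adaptation current w with coupling a, increment b and
time constant τ_w). Spikes are detected when V ≥ V_cut = V_T + 5 mV,
the recorded trace is cut at V_cut, and the reset V→V_r, w→w+b applies
before the next step. The exponential argument is clamped at
(V_cut − V_T)/ΔT + 3, which bounds the within-step overshoot above V_cut to
about a millivolt: an unbounded upswing would couple through the axial
conductances into the dendrites — which have no cutoff — and destabilise
the explicit integrator. A non-finite membrane potential still raises an
integration error naming the neuron and time.

Synapses are single-exponential or alpha, current- or conductance-based.
Conduction delay = inter-soma distance / axonal speed (0.3 m/s) + 0.5 ms
synaptic latency. Per-neuron noisy drive is an Ornstein–Uhlenbeck current
with stationary mean/std and correlation time τ_OU (3 ms in the demos).

## Numerics

* Fixed-step midpoint (second-order Runge–Kutta) integration of the
  coupled V/w equations; dt = 0.03125 ms by default. A convergence test
  verifies O(dt²) error on the closed-form passive relaxation.
* Operator splitting: synaptic conductances and the OU process are held
  constant within a step and advanced with their exact discrete-time
  solutions between steps (for the OU process: exact mean-reverting update
  with stationary-variance-matched noise). This trades formal order for
  stability and makes the decay kinetics exact.
* Events: spikes are emitted at step boundaries; delays are rounded up to
  the next step boundary (exact multiples stay put), so no synaptic effect
  can precede t_spike + delay. Imported spike times are likewise snapped up
  to the next boundary.
* LFP sampling: membrane currents are averaged over the integration
  sub-steps between output samples (a box anti-aliasing filter) before the
  weight-matrix product.
* Determinism: a single seeded generator drives the OU noise; everything
  else (placement, wiring, input trains) is drawn up front from seeded
  generators. Identical seed ⇒ bit-identical spikes and LFPs, which the
  checkpoint/resume path preserves exactly.
* round() on expected connection counts uses half-away-from-zero ties so
  realized counts are platform-reproducible.

## Network construction

N = round(x·y·z·D) neurons are apportioned to groups by largest-remainder
rounding of the group percentages and placed uniformly at random inside
each group's layer slab (z from the white-matter border at 0 to the surface
at z_max). Pyramidal apical axes stay parallel to z; each cell gets a
random azimuthal rotation.

Connectivity: for each presynaptic neuron and each (pre-group → post-group,
layer) rule, the expected efferent count is multiplied by ζ, the integral
of the neuron's isotropic 2-D Gaussian kernel (σ = arborisation radius / 2)
over the slice cross-section — a separable erf product. The realized count
is round(expected·ζ); targets are sampled with replacement among candidate
neurons of the target group with probability proportional to the planar
kernel (candidates beyond 4.5σ are excluded; the truncated mass is < 4e-5).
Multapses are allowed, autapses are not — the expected-count semantics
make repeated contacts natural, and self-innervation is uncommon enough to
exclude outright. The postsynaptic compartment is drawn from the rule's
allowed list with probability proportional to membrane area, mirroring the
uniform-per-area placement used by the validation harness. Basket-cell
projections are restricted to the soma and its two adjacent compartments;
non-basket interneurons target distal dendrites; excitatory projections
target all dendritic compartments.

The ±2σ integration square contains erf(√2)² ≈ 91.1% of the kernel, which
is the package's definition of the in-arbor fraction; the circular 2σ disc
would contain 1 − e⁻² ≈ 86.5%, so the separable-square convention is the
one that matches the quoted ~91%.

## The population validation harness

`run_population_sweep` reproduces the classic passive-population LFP
experiment: N copies of one archetype, uniform in a 1-mm-radius disc at
constant soma depth, 1,000 current-based exponential synapses per neuron
(50 pA, τ = 2 ms) placed per membrane area, each synapse driven by an
independent 5-Hz Poisson train; centre-axis electrodes at five depths
(0, ±150, ±300 µm around the soma plane). Magnitude(r) is obtained in one
simulation by recording per-neuron LFP contributions and accumulating them
in order of radial distance; range is the 95% crossing with linear
interpolation. Variants: pooled input (train identities drawn without
replacement from a finite pool, input correlation = synapses/pool) and
perisomatic placement of all synapses, plus per-layer soma-depth jitter.

The default problem size in the acceptance path is N = 2,000 with 1,250 ms
simulated (first 250 ms discarded) — a deliberate reduction from the
10,000-neuron original so the experiment runs in about a minute; the
qualitative laminar profile (soma-layer magnitude maximal, soma-layer range
smallest) and the < 250 µm soma-layer range are robust at this size.

## The gamma-slice demonstration

The slice preset positions fifteen neuron groups (proportions as in the
package's group table; interneuron per-layer splits are package-chosen so
the total is exactly 100%) in a 4.4 × 0.4 × 2.6 mm cuboid at
38,335 neurons/mm³ — 175,421 neurons at full scale — with layer boundaries
L6 0–0.82, L5 0.82–1.68, L4 1.68–1.90, L2/3 1.90–2.45, L1 2.45–2.6 mm
(L1 aneuronal). A reduced preset (20,000 neurons) and a desk-scale mini
preset (1,440 neurons, P2/3 and B2/3 only — the two groups that generate
the supragranular rhythm) are provided; the mini preset is what the test
suite runs.

The oscillation is weak PING: noisy OU drive makes a subset of P2/3 cells
fire, their convergent AMPA input triggers a basket population volley, and
the resulting perisomatic GABA_A inhibition silences the pyramids until the
most-driven ones recover. Demonstration weights and drives were tuned (and
are recorded in the preset, clearly labelled as package-chosen) to give:
sparse pyramidal firing (≲ 2 Hz), basket firing on most cycles, a 30–80 Hz
field peak at the supragranular electrodes, and sensitivity of the rhythm
to the documented manipulations — either P2/3↔B2/3 coupling reduced to 1%
of its weight, or B2/3 drive mean and std raised ×1.5, abolishes the peak.
Two tuning constraints are worth recording. First, the baseline inhibitory
gain must sit only a small multiple above the oscillation threshold: if
B→P inhibition is grossly overprovisioned, the loop survives a 100-fold
weight reduction by letting basket rates rise to compensate. Second, the
drive manipulation only works if baseline basket drive lies just below
basket rheobase, so the 1.5× increase tips the cells into tonic,
asynchronous firing that suppresses the pyramids.

Spectral peaks are scored with `band_peak_excess`: the log-PSD maximum in
the band above a log-log linear (1/f-like) background fitted outside the
band, in decades; an oscillation scores ≳ 1 decade, a featureless spectrum
≲ 0.5. The phase-inversion signature is the negative zero-lag
cross-correlation between electrodes above versus below the L2/3
sink–source boundary.

## What the synthetic fixtures do and do not show

The generators emulate: Poisson input statistics with controlled pairwise
correlation; uniform spatial placement within layers; Gaussian lateral
connectivity with slice cutting; layered dipole geometry. They do not
emulate: morphological diversity within a group (one archetype each);
patchy or non-isotropic projections; curved layers; spatial inhomogeneity
of synapse density or drive (the experimental gamma-power maps are patchy,
the model's are smooth); active dendritic conductances, gap junctions, or
ephaptic coupling; frequency-dependent tissue impedance. Passing tests
therefore demonstrate correctness of the implemented forward model,
network-construction rules and analysis chain — not that the demo
parameters are a calibrated model of any particular tissue.

## Known limitations

* Explicit RK2 becomes unstable for stiff regimes (many compartments, very
  large conductances); the AdEx clamp removes the most common instability,
  but genuinely stiff models need a smaller dt.
* The multitaper confidence band is pointwise, not simultaneous.
* The 8th-order "symmetrical" Butterworth line-noise filters are realised
  as 4th-order forward–backward passes (zero phase, 8th-order magnitude);
  the FIR band-pass uses a Kaiser window with β = 5 — the phase convention
  and β are package choices where only window type and order are standard.
* Electrode models are ideal points: no impedance, no spatial averaging
  over a contact surface.
* Checkpoint files are Python pickles tied to the package version.
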