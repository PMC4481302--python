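# cortexlfp

Simulation of extracellular local field potentials (LFPs) from large
populations of reduced compartmental spiking neurons in layered cortical
tissue, with the network-construction, validation and signal-analysis
machinery needed to compare simulated multi-electrode recordings with real
ones.

## Who this is for

Researchers who model cortical network dynamics with spiking neurons and
want a biophysically grounded LFP from those models, rather than a proxy
such as summed synaptic input. Point-neuron networks cannot produce a
spatially meaningful extracellular potential; full morphological simulators
produce one, but are too slow for populations of 10⁴–10⁵ cells.
`cortexlfp` occupies the middle ground: equivalent-cable neuron models with
fewer than ten compartments, integrated cheaply, feeding a precomputed
forward model of the extracellular potential at arbitrary virtual
electrodes.

## The model

**Forward model.** In a homogeneous resistive medium of conductivity
σ (0.3 S/m by default), the potential at electrode position *r* is the sum
over dendritic compartments *k* (line sources) and somas *s* (point
sources):

```
Φ(r,t) = Σₖ I_mem,k(t) / (4πσΔsₖ) · ln| (√(hₖ²+ρₖ²) − hₖ) / (√(lₖ²+ρₖ²) − lₖ) |
       + Σₛ I_mem,s(t) / (4πσ rₛ)
```

where Δsₖ is the compartment length, ρₖ the perpendicular distance from its
axis, hₖ and lₖ = Δsₖ + hₖ the longitudinal distances from its ends, and rₛ
the distance to the soma centre. The geometric factors are precomputed once
per network into a weight matrix, so every LFP sample is a single
matrix–vector product with the instantaneous membrane currents. The
membrane current of a compartment is computed as its axial inflow, which
guarantees ΣₖI_mem,k = 0 per neuron (charge conservation) and hence a
dipolar far field.

**Neurons.** Cells are equivalent-cable reductions: compartment length is
the mean length of the branches it represents and the equivalent diameter
conserves axial conductance (d_eq = √Σdᵢ²). A library of layer-specific
archetypes (L2/3, L4, L5, L6 pyramids; spiny stellate; basket and
non-basket interneurons; 7–9 compartments) is included; custom cells can be
read from SWC files and collapsed with a user-supplied section plan.
Dynamics are passive cable plus an adaptive exponential integrate-and-fire
(AdEx) soma, exponential/alpha current- or conductance-based synapses and
Ornstein–Uhlenbeck current drive, integrated with a fixed-step second-order
Runge–Kutta scheme (dt = 0.03125 ms).

**Networks.** A tissue specification (slice dimensions, layer boundaries,
neuron density D) fixes the neuron count N = x·y·z·D and the per-layer
placement of each group. Connectivity uses an isotropic 2-D Gaussian kernel
per presynaptic neuron whose standard deviation is half the axonal
arborisation radius; the expected efferent count is reduced by the fraction
ζ of the kernel that survives the slice boundaries (an erf product), which
reproduces the loss of connections near cut faces.

**Analysis.** LFP magnitude (signal SD) and spatial range (radius at 95% of
the 1-mm-radius magnitude); Thomson multitaper spectra with χ² confidence
bands; band power (20–40 Hz "gamma" by default) and interpolated electrode
maps; lag cross-correlation; and the standard preprocessing chain for real
recordings (common-average reference, 1-kHz resampling, mains-harmonic
subtraction, 2–300 Hz zero-phase FIR, z-normalisation).

## A worked example

`examples/forward_model.py` delivers one excitatory synaptic event to the
apical tuft of a layer-2/3 pyramidal cell and prints the potential at three
electrodes:

```
membrane-current balance |sum_k I_k| (nA): 6.25e-16
electrode soma level : peak +0.0421 uV
electrode tuft level : peak -0.0625 uV
electrode above apex : peak -0.0341 uV
```

The tuft-level electrode sees the synaptic current sink (negative), the
soma-level electrode the passive return source (positive) — the dipole that
makes laminar LFP profiles informative — and the per-cell membrane currents
sum to zero at machine precision.

The other example scripts each exercise one capability: population
magnitude/range curves (`population_range.py`), slice construction and the
slice-cutting correction (`slice_network.py`), the gamma-oscillation demo
with its coupling/drive manipulations (`gamma_oscillation.py`), spike-import
replay (`spike_import.py`) and the recording-analysis chain
(`preprocess_and_spectra.py`). A thin command-line interface (`cortexlfp
init / run / analyze / sweep`) wraps the same library calls for
shell-driven use.

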