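"""Network dynamics: passive cable + AdEx somas + synapses + stochastic drive.

The membrane potential of every compartment obeys the passive cable
equation; somatic compartments may additionally carry an adaptive
exponential integrate-and-fire (AdEx) spiking mechanism (exponential
spike-initiation term plus an adaptation current ``w``).  Synapses are
current- or conductance-based with single-exponential or alpha kinetics;
per-neuron stochastic drive is an Ornstein-Uhlenbeck (OU) current.

Integration uses a fixed-step second-order (midpoint) Runge-Kutta scheme
for the coupled V/w equations; synaptic decay and the OU process are
advanced with their exact discrete-time solutions between steps (operator
splitting, trading formal order for stability).  Spikes are detected after
each step (V >= V_cut, with V_cut = V_T + 5 mV by default), the recorded
trace is cut at V_cut, and the reset (V -> V_r, w -> w + b) applies before
the next step.  Presynaptic events are queued in a step-indexed buffer;
conduction delays are rounded up to the next step boundary, so no synaptic
effect ever precedes t_spike + delay.

Units: mV, ms, nF, uS, nA.  The membrane current of compartment k
(outward-positive, the quantity the LFP engine consumes) equals the axial
current flowing into k, which by construction sums to zero over each neuron
unless an intracellular electrode current is injected.  Stochastic drive is
modelled as a membrane-crossing current by default, preserving charge
conservation and the dipolar far field; ``drive_mode="injection"`` switches
to intracellular-injection semantics (which introduces a current monopole)
for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from .lfp import ElectrodeArray, LFPRecording, compute_weight_matrix
from .morphology import ReducedNeuronModel
from .network import SynapseTable

__all__ = [
    "AdExParams",
    "SynapseSpec",
    "OUParams",
    "SimConfig",
    "Population",
    "NetworkModel",
    "RecordingSet",
    "Simulation",
    "ou_update",
    "run_with_imported_spikes",
    "load_spike_file",
    "save_spike_file",
]




@dataclass(frozen=True)
class AdExParams:
    """Adaptive exponential integrate-and-fire soma parameters.

    The soma's capacitance and leak come from its compartment geometry; this
    structure holds the spiking nonlinearity: slope factor ``delta_T`` (mV),
    threshold ``v_threshold`` (mV), subthreshold adaptation coupling ``a``
    (uS), spike-triggered increment ``b`` (nA), adaptation time constant
    ``tau_w`` (ms), reset ``v_reset`` (mV) and numerical cutoff ``v_cut``
    (defaults to v_threshold + 5 mV).
    """

    delta_T: float = 2.0
    v_threshold: float = -50.0
    a: float = 0.0
    b: float = 0.0
    tau_w: float = 100.0
    v_reset: float = -65.0
    v_cut: float | None = None

    def __post_init__(self) -> None:
        if self.delta_T <= 0 or self.tau_w <= 0:
            raise ValueError("delta_T and tau_w must be positive")

    @property
    def cutoff(self) -> float:
        return self.v_threshold + 5.0 if self.v_cut is None else self.v_cut


@dataclass(frozen=True)
class SynapseSpec:
    """Synapse kinetics: {exp, alpha} x {current, conductance}.

    ``weight`` is the conductance increment (uS) for conductance-based
    synapses or the current amplitude (nA) for current-based ones.
    ``reversal`` (mV) applies to conductance-based synapses only.
    """

    kind: str = "exp"            # "exp" or "alpha"
    basis: str = "conductance"   # "conductance" or "current"
    tau: float = 2.0             # ms
    weight: float = 1e-3
    reversal: float = 0.0        # mV, conductance-based only

    def __post_init__(self) -> None:
        if self.kind not in ("exp", "alpha"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.basis not in ("conductance", "current"):
            raise ValueError(f"unknown synapse basis {self.basis!r}")
        if self.tau <= 0:
            raise ValueError("synapse time constant must be positive")


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck drive current: stationary mean/std (nA), correlation
    time (ms), and the local compartment id it targets."""

    mean: float = 0.0
    std: float = 0.0
    tau: float = 3.0
    target_compartment: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.std < 0:
            raise ValueError("tau must be > 0 and std >= 0")


@dataclass
class SimConfig:
    dt: float = 0.03125          # ms
    duration: float = 1000.0     # ms
    lfp_sample_rate: float = 1000.0  # Hz
    seed: int = 0
    record_v: tuple[int, ...] = ()   # global neuron ids to record at the soma
    discard: float = 0.0         # ms of initial transient to drop from recordings

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.lfp_sample_rate > 1000.0 / self.dt:
            raise ValueError("LFP sample rate cannot exceed the integration rate")
        steps_per_sample = (1000.0 / self.lfp_sample_rate) / self.dt
        if abs(steps_per_sample - round(steps_per_sample)) > 1e-9:
            raise ValueError("1/lfp_sample_rate must be an integer multiple of dt")


@dataclass
class Population:
    """A homogeneous group of positioned neurons sharing one cell template."""

    name: str
    template: ReducedNeuronModel
    positions: np.ndarray            # (n, 3) um
    azimuths: np.ndarray | None = None
    adex: AdExParams | None = None   # None -> purely passive membrane
    ou: OUParams | None = None
    imported_spikes: tuple[np.ndarray, np.ndarray] | None = None  # (local ids, times ms)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.azimuths is None:
            self.azimuths = np.zeros(len(self.positions))

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class NetworkModel:
    """Positioned populations plus synapse kinetics and the realized synapse
    table (global neuron ids follow population order)."""

    populations: list[Population]
    synapse_specs: dict[str, SynapseSpec] = field(default_factory=dict)
    synapse_table: SynapseTable | None = None
    conductivity: float = 0.3        # S/m

    @property
    def n_neurons(self) -> int:
        return sum(p.n for p in self.populations)


@dataclass
class RecordingSet:
    """Simulation output: spikes, selected soma potentials, LFPs, currents."""

    spike_ids: np.ndarray
    spike_times: np.ndarray          # ms
    v_traces: dict[int, np.ndarray] = field(default_factory=dict)
    v_times: np.ndarray | None = None
    lfp: LFPRecording | None = None
    per_neuron_lfp: np.ndarray | None = None   # (n_neurons, n_electrodes, n_samples)
    currents: np.ndarray | None = None         # (n_compartments, n_samples) nA
    duration: float = 0.0

    def spike_counts(self, n_neurons: int) -> np.ndarray:
        return np.bincount(self.spike_ids.astype(int), minlength=n_neurons)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("spikes/ids", data=self.spike_ids)
            f.create_dataset("spikes/times_ms", data=self.spike_times)
            f.attrs["duration_ms"] = self.duration
            if self.v_times is not None:
                f.create_dataset("v/times_ms", data=self.v_times)
                for nid, trace in self.v_traces.items():
                    f.create_dataset(f"v/neuron_{nid}", data=trace)
            if self.lfp is not None:
                f.create_dataset("lfp/data_uV", data=self.lfp.data)
                f.attrs["lfp_sample_rate_Hz"] = self.lfp.sample_rate

    @classmethod
    def load_hdf5(cls, path) -> "RecordingSet":
        import h5py

        with h5py.File(path, "r") as f:
            out = cls(
                spike_ids=f["spikes/ids"][...],
                spike_times=f["spikes/times_ms"][...],
                duration=float(f.attrs["duration_ms"]),
            )
            if "v" in f:
                out.v_times = f["v/times_ms"][...]
                for key in f["v"]:
                    if key.startswith("neuron_"):
                        out.v_traces[int(key[7:])] = f[f"v/{key}"][...]
            if "lfp" in f:
                out.lfp = LFPRecording(f["lfp/data_uV"][...],
                                       float(f.attrs["lfp_sample_rate_Hz"]))
        return out


def save_spike_file(path, spike_ids, spike_times) -> None:
    """Write spikes as a two-column plain-text table (neuron id, time in ms)."""
    np.savetxt(path, np.column_stack([spike_ids, spike_times]),
               fmt=["%d", "%.9g"], header="neuron_id time_ms")


def load_spike_file(path) -> tuple[np.ndarray, np.ndarray]:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # an empty spike file is legitimate
        data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return np.empty(0, dtype=int), np.empty(0)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (neuron id, time ms)")
    return data[:, 0].astype(int), data[:, 1]


def ou_update(value, mean, std, tau, dt, rng) -> np.ndarray:
    """Exact one-step update of an OU process with stationary mean/std.

    x' = mean + (x - mean) e^(-dt/tau) + std sqrt(1 - e^(-2dt/tau)) xi,
    xi ~ N(0, 1).  Deterministic relaxation to the mean when std = 0.
    """
    decay = np.exp(-dt / tau)
    noise = std * np.sqrt(1.0 - decay**2)
    return mean + (np.asarray(value) - mean) * decay + noise * rng.standard_normal(
        np.shape(value)
    )


class Simulation:
    """Flattened state-vector integrator for a :class:`NetworkModel`.

    The per-compartment state of all neurons is packed into flat arrays; the
    axial coupling of every cell is a single sparse matrix ``A`` such that
    ``A @ V`` is the axial current flowing into each compartment — which, by
    charge conservation, is also each compartment's outward membrane current
    ``I_mem`` used by the LFP engine.
    """

    def __init__(
        self,
        model: NetworkModel,
        config: SimConfig,
        electrodes: ElectrodeArray | None = None,
        external_events: dict | None = None,
        step_currents: Sequence[tuple[int, int, float, float, float]] = (),
        drive_mode: str = "membrane",
        record_per_neuron_lfp: bool = False,
        record_currents: bool = False,
    ):
        if drive_mode not in ("membrane", "injection"):
            raise ValueError("drive_mode must be 'membrane' or 'injection'")
        self.model = model
        self.config = config
        self.drive_mode = drive_mode
        self.electrodes = electrodes
        self.record_per_neuron_lfp = record_per_neuron_lfp
        self.record_currents = record_currents
        self._build_flat(model)
        self._build_synapses(model)
        self._build_events(model, external_events)
        self._build_step_currents(step_currents)
        if electrodes is not None:
            single = np.isin(self.neuron_of_comp,
                             np.flatnonzero(self.ncomp_per_neuron == 1))
            self.W = compute_weight_matrix(
                self.comp_starts, self.comp_ends, self.comp_radii,
                self.is_soma, electrodes, model.conductivity,
                zero_columns=single,
            )
        else:
            self.W = None

    # ------------------------------------------------------------------ build
    def _build_flat(self, model: NetworkModel) -> None:
        caps, leaks, e_leaks, radii = [], [], [], []
        starts_all, ends_all = [], []
        neuron_of_comp, soma_comp, ncomp_per_neuron = [], [], []
        edge_rows, edge_cols, edge_g = [], [], []
        adex_soma, adex_par = [], []
        ou_comp, ou_mean, ou_std, ou_tau = [], [], [], []
        self.pop_slices: dict[str, slice] = {}

        comp_off = 0
        neuron_off = 0
        for pop in model.populations:
            tpl = pop.template
            nc = tpl.n_compartments
            n = pop.n
            self.pop_slices[pop.name] = slice(neuron_off, neuron_off + n)

            # vectorized placement: rotate template per neuron, translate
            t_starts, t_ends = tpl.coords()
            az = pop.azimuths
            c, s = np.cos(az), np.sin(az)
            rot = np.zeros((n, 3, 3))
            rot[:, 0, 0] = c
            rot[:, 0, 1] = -s
            rot[:, 1, 0] = s
            rot[:, 1, 1] = c
            rot[:, 2, 2] = 1.0
            ps = np.einsum("nij,kj->nki", rot, t_starts) + pop.positions[:, None, :]
            pe = np.einsum("nij,kj->nki", rot, t_ends) + pop.positions[:, None, :]
            starts_all.append(ps.reshape(-1, 3))
            ends_all.append(pe.reshape(-1, 3))

            caps.append(np.tile(tpl.capacitances, n))
            leaks.append(np.tile(tpl.leak_conductances, n))
            e_leaks.append(np.full(n * nc, tpl.passive.leak_reversal))
            radii.append(np.tile([c_.diameter / 2.0 for c_ in tpl.compartments], n))
            neuron_of_comp.append(np.repeat(np.arange(neuron_off, neuron_off + n), nc))
            soma_comp.append(comp_off + np.arange(n) * nc)
            ncomp_per_neuron.append(np.full(n, nc))

            for par, child, g in tpl.axial_edges:
                p_idx = comp_off + np.arange(n) * nc + par
                c_idx = comp_off + np.arange(n) * nc + child
                edge_rows.extend([p_idx, c_idx])
                edge_cols.extend([c_idx, p_idx])
                edge_g.extend([np.full(n, g), np.full(n, g)])

            if pop.adex is not None and pop.imported_spikes is None:
                adex_soma.append(comp_off + np.arange(n) * nc)
                adex_par.append((pop.adex, n))
            if pop.ou is not None:
                ou_comp.append(comp_off + np.arange(n) * nc + pop.ou.target_compartment)
                ou_mean.append(np.full(n, pop.ou.mean))
                ou_std.append(np.full(n, pop.ou.std))
                ou_tau.append(np.full(n, pop.ou.tau))

            comp_off += n * nc
            neuron_off += n

        self.n_comp = comp_off
        self.n_neurons = neuron_off
        self.comp_starts = np.concatenate(starts_all)
        self.comp_ends = np.concatenate(ends_all)
        self.C = np.concatenate(caps)
        self.gL = np.concatenate(leaks)
        self.EL = np.concatenate(e_leaks)
        self.comp_radii = np.concatenate(radii)
        self.neuron_of_comp = np.concatenate(neuron_of_comp)
        self.soma_comp = np.concatenate(soma_comp)
        self.ncomp_per_neuron = np.concatenate(ncomp_per_neuron)
        self.is_soma = np.zeros(self.n_comp, dtype=bool)
        self.is_soma[self.soma_comp] = True

        if edge_rows:
            rows = np.concatenate(edge_rows)
            cols = np.concatenate(edge_cols)
            g = np.concatenate(edge_g)
            A = sparse.coo_matrix((g, (rows, cols)), shape=(self.n_comp, self.n_comp))
            diag = np.asarray(A.sum(axis=1)).ravel()
            A = A - sparse.diags(diag)
            self.A = A.tocsr()
        else:
            self.A = sparse.csr_matrix((self.n_comp, self.n_comp))

        # AdEx parameter arrays over spiking somas only
        if adex_soma:
            self.adex_soma = np.concatenate(adex_soma)
            pieces = {k: [] for k in ("delta_T", "v_T", "v_cut", "a", "b", "tau_w", "v_r")}
            for par, n in adex_par:
                pieces["delta_T"].append(np.full(n, par.delta_T))
                pieces["v_T"].append(np.full(n, par.v_threshold))
                pieces["v_cut"].append(np.full(n, par.cutoff))
                pieces["a"].append(np.full(n, par.a))
                pieces["b"].append(np.full(n, par.b))
                pieces["tau_w"].append(np.full(n, par.tau_w))
                pieces["v_r"].append(np.full(n, par.v_reset))
            self.adex = {k: np.concatenate(v) for k, v in pieces.items()}
            # clamp the exponential argument just above the cutoff level so a
            # runaway upswing cannot overshoot V_cut by more than ~1 mV within
            # a step (the overshoot would otherwise couple into the dendrites,
            # which have no cutoff, and destabilise the explicit integrator)
            self.adex["arg_max"] = (
                (self.adex["v_cut"] - self.adex["v_T"]) / self.adex["delta_T"] + 3.0
            )
        else:
            self.adex_soma = np.empty(0, dtype=int)
            self.adex = None

        if ou_comp:
            self.ou_comp = np.concatenate(ou_comp)
            self.ou_mean = np.concatenate(ou_mean)
            self.ou_std = np.concatenate(ou_std)
            self.ou_tau = np.concatenate(ou_tau)
        else:
            self.ou_comp = np.empty(0, dtype=int)

    def _build_synapses(self, model: NetworkModel) -> None:
        # synapse-state buckets, one conductance (and alpha auxiliary) array per spec
        table = model.synapse_table
        if table is not None and len(table) and table.spec_names:
            names = list(table.spec_names)
        else:
            names = sorted(model.synapse_specs)
        self.spec_names = names
        self.specs = [model.synapse_specs[n] for n in names] if names else []
        self.g_syn = [np.zeros(self.n_comp) for _ in self.specs]
        self.x_syn = [np.zeros(self.n_comp) if s.kind == "alpha" else None
                      for s in self.specs]

        dt = self.config.dt
        self.syn_decay = [np.exp(-dt / s.tau) for s in self.specs]

        # per-presynaptic-neuron CSR view of the synapse table
        self.delay_steps = None
        if table is not None and len(table):
            order = np.argsort(table.pre, kind="stable")
            self.tab_post_comp = (
                self._global_comp(table.post[order], table.post_compartment[order])
            )
            self.tab_spec = table.spec[order].astype(int)
            steps = np.ceil(np.asarray(table.delay)[order] / dt - 1e-12).astype(int)
            self.delay_steps = np.maximum(steps, 1)
            counts = np.bincount(table.pre.astype(int), minlength=self.n_neurons)
            self.tab_indptr = np.concatenate([[0], np.cumsum(counts)])
            # per-synapse weight from its spec
            w = np.array([s.weight for s in self.specs])
            self.tab_weight = w[self.tab_spec]

    def _global_comp(self, neuron_ids, local_comp) -> np.ndarray:
        offsets = np.concatenate([[0], np.cumsum(self.ncomp_per_neuron)])[:-1]
        local = np.asarray(local_comp, dtype=int)
        nc = self.ncomp_per_neuron[np.asarray(neuron_ids, dtype=int)]
        if np.any(local >= nc):
            raise ValueError("synapse targets a compartment the cell does not have")
        return offsets[np.asarray(neuron_ids, dtype=int)] + local

    def _build_events(self, model: NetworkModel, external_events: dict | None) -> None:
        dt = self.config.dt
        self.n_steps = int(round(self.config.duration / dt))
        self.queue: dict[int, list] = {}

        if external_events is not None:
            steps = np.asarray(external_events["step"], dtype=int)
            comps = np.asarray(external_events["comp"], dtype=int)
            specs = np.asarray(external_events["spec"], dtype=int)
            weights = np.asarray(external_events["weight"], dtype=float)
            order = np.argsort(steps, kind="stable")
            self.ext_steps = steps[order]
            self.ext_comp = comps[order]
            self.ext_spec = specs[order]
            self.ext_weight = weights[order]
            self.ext_indptr = np.searchsorted(self.ext_steps,
                                              np.arange(self.n_steps + 1))
        else:
            self.ext_indptr = None

        # imported spikes routed through the synapse table
        for pop in model.populations:
            if pop.imported_spikes is None:
                continue
            ids, times = pop.imported_spikes
            ids = np.asarray(ids, dtype=int)
            times = np.asarray(times, dtype=float)
            sl = self.pop_slices[pop.name]
            if np.any(ids < 0) or np.any(ids >= sl.stop - sl.start):
                raise ValueError(f"imported spike for unknown neuron id in {pop.name}")
            gids = ids + sl.start
            spike_steps = np.ceil(times / dt - 1e-12).astype(int)
            self._enqueue_spikes(gids, spike_steps)

    def _enqueue_spikes(self, gids, spike_steps) -> None:
        if self.delay_steps is None:
            return
        gids = np.atleast_1d(np.asarray(gids, dtype=int))
        spike_steps = np.atleast_1d(np.asarray(spike_steps, dtype=int))
        los = self.tab_indptr[gids]
        his = self.tab_indptr[gids + 1]
        sizes = his - los
        total = int(sizes.sum())
        if total == 0:
            return
        rows = np.concatenate([np.arange(lo, hi) for lo, hi in zip(los, his)])
        arrivals = np.repeat(spike_steps, sizes) + self.delay_steps[rows]
        order = np.argsort(arrivals, kind="stable")
        rows = rows[order]
        arrivals = arrivals[order]
        bounds = np.flatnonzero(np.diff(arrivals)) + 1
        starts = np.concatenate([[0], bounds])
        for chunk, a in zip(np.split(rows, bounds), arrivals[starts]):
            self.queue.setdefault(int(a), []).append(
                (self.tab_post_comp[chunk], self.tab_spec[chunk],
                 self.tab_weight[chunk])
            )

    def _build_step_currents(self, step_currents) -> None:
        # (neuron id, local compartment, amplitude nA, t_on ms, t_off ms)
        self.step_currents = []
        for nid, comp, amp, t_on, t_off in step_currents:
            gc = int(self._global_comp(np.array([nid]), np.array([comp]))[0])
            self.step_currents.append((gc, amp, t_on, t_off))

    # ------------------------------------------------------------------ core
    def _synaptic_current(self, V: np.ndarray) -> np.ndarray:
        I = np.zeros_like(V)
        for s, g in zip(self.specs, self.g_syn):
            if s.basis == "conductance":
                I += g * (s.reversal - V)
            else:
                I += g
        return I

    def _derivatives(self, V, w, I_extra):
        I = self._synaptic_current(V)
        I += self.A @ V
        I += I_extra
        dV = (-self.gL * (V - self.EL) + I) / self.C
        dw = None
        if self.adex is not None and len(self.adex_soma):
            sm = self.adex_soma
            arg = np.minimum((V[sm] - self.adex["v_T"]) / self.adex["delta_T"],
                             self.adex["arg_max"])
            i_spike = self.gL[sm] * self.adex["delta_T"] * np.exp(arg) - w
            dV[sm] += i_spike / self.C[sm]
            dw = (self.adex["a"] * (V[sm] - self.EL[sm]) - w) / self.adex["tau_w"]
        return dV, dw

    def membrane_currents(self, V, I_inject=None) -> np.ndarray:
        """Outward membrane current per compartment (nA): the axial inflow,
        plus any intracellular injection (which breaks per-neuron charge
        balance, as a real electrode does)."""
        I = self.A @ V
        if I_inject is not None:
            I = I + I_inject
        return I

    # ------------------------------------------------------------------ run
    def _fresh_state(self) -> dict:
        cfg = self.config
        n_sub = int(round((1000.0 / cfg.lfp_sample_rate) / cfg.dt))
        n_samples = self.n_steps // n_sub
        rec_v_ids = np.asarray(cfg.record_v, dtype=int)
        st = {
            "step": 0,
            "rng": np.random.default_rng(cfg.seed),
            "n_sub": n_sub,
            "n_samples": n_samples,
            "V": self.EL.copy(),
            "w": np.zeros(len(self.adex_soma)) if self.adex is not None else None,
            "ou_val": self.ou_mean.copy() if len(self.ou_comp) else None,
            "rec_v_ids": rec_v_ids,
            "v_traces": {int(i): np.empty(self.n_steps) for i in rec_v_ids},
            "spike_ids": [],
            "spike_times": [],
            "lfp_acc": np.zeros(self.n_comp),
            "lfp_out": (np.zeros((self.W.shape[0], n_samples))
                        if self.W is not None else None),
            "pn_out": (np.zeros((self.n_neurons, self.W.shape[0], n_samples),
                                dtype=np.float32)
                       if (self.record_per_neuron_lfp and self.W is not None)
                       else None),
            "cur_out": (np.zeros((self.n_comp, n_samples))
                        if self.record_currents else None),
        }
        return st

    def save_checkpoint(self, path, st: dict) -> None:
        """Write loop state (plus synapse state and event queue) to disk."""
        import pickle

        payload = {"state": st, "g_syn": self.g_syn, "x_syn": self.x_syn,
                   "queue": self.queue}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    def resume(self, checkpoint_path, **run_kwargs) -> RecordingSet:
        """Continue a checkpointed run; outputs match an uninterrupted run."""
        import pickle

        with open(checkpoint_path, "rb") as fh:
            payload = pickle.load(fh)
        self.g_syn = payload["g_syn"]
        self.x_syn = payload["x_syn"]
        self.queue = payload["queue"]
        return self.run(_state=payload["state"], **run_kwargs)

    def run(self, checkpoint_path=None, checkpoint_interval: float | None = None,
            _state: dict | None = None) -> RecordingSet:
        cfg = self.config
        dt = cfg.dt
        st = _state if _state is not None else self._fresh_state()
        rng = st["rng"]
        n_sub, n_samples = st["n_sub"], st["n_samples"]
        V, w, ou_val = st["V"], st["w"], st["ou_val"]
        rec_v_ids, v_traces = st["rec_v_ids"], st["v_traces"]
        spike_ids, spike_times = st["spike_ids"], st["spike_times"]
        lfp_acc = st["lfp_acc"]
        lfp_out, pn_out, cur_out = st["lfp_out"], st["pn_out"], st["cur_out"]
        rec_soma = self.soma_comp[rec_v_ids] if len(rec_v_ids) else None

        inject = np.zeros(self.n_comp) if self.step_currents else None
        ou_decay = np.exp(-dt / self.ou_tau) if ou_val is not None else None
        ou_noise = (self.ou_std * np.sqrt(1.0 - ou_decay**2)
                    if ou_val is not None else None)
        ckpt_steps = (int(round(checkpoint_interval / dt))
                      if checkpoint_interval else None)

        I_extra = np.zeros(self.n_comp)
        for step in range(st["step"], self.n_steps):
            t = step * dt
            # deliver queued synaptic events due at this step
            ev = self.queue.pop(step, None)
            if ev is not None:
                self._apply_events(ev)
            if self.ext_indptr is not None:
                lo, hi = self.ext_indptr[step], self.ext_indptr[step + 1]
                if hi > lo:
                    self._apply_events([(self.ext_comp[lo:hi],
                                         self.ext_spec[lo:hi],
                                         self.ext_weight[lo:hi])])

            # external currents held constant across the step
            I_extra[:] = 0.0
            if inject is not None:
                inject[:] = 0.0
                for gc, amp, t_on, t_off in self.step_currents:
                    if t_on <= t < t_off:
                        inject[gc] += amp
                I_extra += inject
            if ou_val is not None:
                np.add.at(I_extra, self.ou_comp, ou_val)

            # RK2 midpoint step of the V (and w) equations
            dV1, dw1 = self._derivatives(V, w, I_extra)
            Vh = V + 0.5 * dt * dV1
            wh = w + 0.5 * dt * dw1 if w is not None and dw1 is not None else w
            dV2, dw2 = self._derivatives(Vh, wh, I_extra)
            V += dt * dV2
            if w is not None and dw2 is not None:
                w += dt * dw2

            if not np.all(np.isfinite(V)):
                bad = int(self.neuron_of_comp[np.flatnonzero(~np.isfinite(V))[0]])
                raise FloatingPointError(
                    f"membrane potential diverged for neuron {bad} at t={t + dt:.4f} ms"
                )

            # exact updates of the split subsystems
            for si, s in enumerate(self.specs):
                if self.x_syn[si] is not None:
                    g, x, d = self.g_syn[si], self.x_syn[si], self.syn_decay[si]
                    self.g_syn[si] = d * (g + dt * x / s.tau)
                    self.x_syn[si] = x * d
                else:
                    self.g_syn[si] *= self.syn_decay[si]
            if ou_val is not None:
                ou_val = (self.ou_mean + (ou_val - self.ou_mean) * ou_decay
                          + ou_noise * rng.standard_normal(len(ou_val)))
                st["ou_val"] = ou_val

            # spike detection after the step; reset before the next step
            crossed = np.empty(0, dtype=int)
            if self.adex is not None and len(self.adex_soma):
                crossed = np.flatnonzero(V[self.adex_soma] >= self.adex["v_cut"])
                if len(crossed):
                    V[self.adex_soma[crossed]] = self.adex["v_cut"][crossed]

            # record soma potentials (trace cut at V_cut)
            if rec_soma is not None:
                for i, nid in enumerate(rec_v_ids):
                    v_traces[int(nid)][step] = V[rec_soma[i]]

            if len(crossed):
                gids = self.neuron_of_comp[self.adex_soma[crossed]]
                spike_ids.append(gids)
                spike_times.append(np.full(len(gids), t + dt))
                V[self.adex_soma[crossed]] = self.adex["v_r"][crossed]
                w[crossed] += self.adex["b"][crossed]
                self._enqueue_spikes(gids, np.full(len(gids), step + 1))

            # accumulate membrane currents for the (box-filtered) LFP sample
            if lfp_out is not None or cur_out is not None:
                lfp_acc += self.A @ V
                if inject is not None:
                    # an intracellular electrode current crosses the membrane
                    # once, not twice: it adds a monopole term
                    lfp_acc += inject
                if self.drive_mode == "injection" and ou_val is not None:
                    np.add.at(lfp_acc, self.ou_comp, ou_val)
                if (step + 1) % n_sub == 0:
                    i_sample = (step + 1) // n_sub - 1
                    if i_sample < n_samples:
                        i_mean = lfp_acc / n_sub
                        if cur_out is not None:
                            cur_out[:, i_sample] = i_mean
                        if lfp_out is not None:
                            lfp_out[:, i_sample] = self.W @ i_mean
                            if pn_out is not None:
                                contrib = self.W * i_mean[None, :]
                                for e in range(self.W.shape[0]):
                                    pn_out[:, e, i_sample] = np.bincount(
                                        self.neuron_of_comp, weights=contrib[e],
                                        minlength=self.n_neurons,
                                    )
                    lfp_acc[:] = 0.0

            if (ckpt_steps and checkpoint_path is not None
                    and (step + 1) % ckpt_steps == 0 and step + 1 < self.n_steps):
                st["step"] = step + 1
                self.save_checkpoint(checkpoint_path, st)

        ids = np.concatenate(spike_ids) if spike_ids else np.empty(0, dtype=int)
        times = np.concatenate(spike_times) if spike_times else np.empty(0)

        # the initial transient is dropped from the analogue recordings only;
        # spikes keep absolute times so a run can be replayed via spike import
        discard = cfg.discard
        sample_t0 = int(round(discard * cfg.lfp_sample_rate / 1000.0))
        result = RecordingSet(
            spike_ids=ids, spike_times=times, duration=cfg.duration,
        )
        if v_traces:
            step0 = int(round(discard / dt))
            result.v_times = (np.arange(self.n_steps) + 1)[step0:] * dt
            result.v_traces = {k: v[step0:] for k, v in v_traces.items()}
        if lfp_out is not None:
            result.lfp = LFPRecording(lfp_out[:, sample_t0:], cfg.lfp_sample_rate)
        if pn_out is not None:
            result.per_neuron_lfp = pn_out[:, :, sample_t0:]
        if cur_out is not None:
            result.currents = cur_out[:, sample_t0:]
        return result

    def _apply_events(self, batches) -> None:
        for comps, specs, weights in batches:
            for si in np.unique(specs):
                m = specs == si
                tgt = self.x_syn[si] if self.x_syn[si] is not None else self.g_syn[si]
                amp = weights[m] * (np.e if self.x_syn[si] is not None else 1.0)
                np.add.at(tgt, comps[m], amp)


def run_with_imported_spikes(
    model: NetworkModel,
    spikes,
    config: SimConfig,
    electrodes: ElectrodeArray | None = None,
    **sim_kwargs,
) -> RecordingSet:
    """Re-run a network passively, driving it with previously recorded spikes.

    ``spikes`` is either a path to a two-column plain-text spike file or a
    (neuron ids, times ms) pair using global neuron ids.  Every population
    is given purely passive membrane dynamics; the listed spikes are routed
    to their targets through the model's synapse table with the normal
    conduction delays, and all downstream currents and LFPs are computed as
    usual.  Used as the control showing that the somatic spiking mechanism
    has little effect on the simulated LFP.
    """
    if isinstance(spikes, (str, bytes)) or hasattr(spikes, "__fspath__"):
        ids, times = load_spike_file(spikes)
    else:
        ids, times = spikes
    ids = np.asarray(ids, dtype=int)
    if len(ids) and (ids.min() < 0 or ids.max() >= model.n_neurons):
        raise ValueError("spike file references a neuron id outside the network")

    pops = []
    offset = 0
    for pop in model.populations:
        mask = (ids >= offset) & (ids < offset + pop.n)
        pops.append(Population(
            name=pop.name, template=pop.template, positions=pop.positions,
            azimuths=pop.azimuths, adex=None, ou=pop.ou,
            imported_spikes=(ids[mask] - offset, np.asarray(times)[mask]),
        ))
        offset += pop.n
    passive = NetworkModel(pops, model.synapse_specs, model.synapse_table,
                           model.conductivity)
    sim = Simulation(passive, config, electrodes=electrodes, **sim_kwargs)
    return sim.run()
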