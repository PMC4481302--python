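"""Spatial network construction for layered slice models.

Given a tissue specification (slice dimensions, layer boundaries, neuron
density) and per-group connectivity statistics, this module

* computes the total neuron count from the tissue volume and density,
* positions somas uniformly at random inside each group's layer slab,
* realises a synapse table using an isotropic 2-D Gaussian connection
  kernel centred on each presynaptic neuron, with the expected efferent
  count reduced by the fraction of the kernel cut off by the slice
  boundaries (the erf-product factor ``zeta``),
* assigns conduction delays from inter-soma distance and axonal speed, and
* supports the pooled ("correlated input") spike-train assignment used by
  the population validation harness.

Conventions: tissue dimensions in mm, positions and radii in um.  The depth
axis z runs from the white-matter border (z = 0) to the cortical surface
(z = z_max); electrode or soma depths quoted as negative distances from the
surface convert as z = z_max + depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import erf

from .morphology import ReducedNeuronModel

__all__ = [
    "TissueSpec",
    "GroupSpec",
    "ConnectionRule",
    "ConnectivitySpec",
    "SynapseTable",
    "neuron_count",
    "position_neurons",
    "zeta_inside_fraction",
    "build_connectivity",
    "compute_delay",
    "assign_correlated_inputs",
    "connection_matrices",
]

MM = 1000.0  # um per mm


def _round_half_away(x) -> np.ndarray:
    """round() with ties going half away from zero, for reproducible counts."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


@dataclass(frozen=True)
class TissueSpec:
    """Slice geometry, layering, density and extracellular conductivity.

    ``layer_boundaries`` maps layer names to (z_low, z_high) slabs in mm,
    strictly inside [0, z_max].  Layer 1 is aneuronal in the default slice
    model; layers 2 and 3 are merged.
    """

    x_max: float                 # mm, slice width
    y_max: float                 # mm, slice thickness
    z_max: float                 # mm, cortical depth
    density: float               # neurons / mm^3
    layer_boundaries: dict[str, tuple[float, float]] = field(default_factory=dict)
    conductivity: float = 0.3    # S/m
    shape: str = "cuboid"        # or "cylinder" (radius x_max/2 in the x-y plane)

    def __post_init__(self) -> None:
        if min(self.x_max, self.y_max, self.z_max) <= 0:
            raise ValueError("tissue dimensions must be positive")
        if self.conductivity <= 0:
            raise ValueError("conductivity must be positive")
        if self.shape not in ("cuboid", "cylinder"):
            raise ValueError(f"unknown tissue shape {self.shape!r}")
        for name, (lo, hi) in self.layer_boundaries.items():
            if not (0.0 <= lo < hi <= self.z_max):
                raise ValueError(f"layer {name}: bounds ({lo}, {hi}) outside [0, {self.z_max}]")

    def depth_to_z(self, depth_from_surface_um: float) -> float:
        """Convert a (negative) depth below the surface, in um, to z in um."""
        return self.z_max * MM + depth_from_surface_um


@dataclass(frozen=True)
class GroupSpec:
    """One neuron group: archetype, share of the population, placement slab."""

    name: str
    cell: str                    # archetype name (see cortexlfp.cells)
    proportion: float            # % of total model
    layer: str                   # placement layer (key into TissueSpec.layer_boundaries)
    soma_z_range: tuple[float, float] | None = None  # mm, overrides the layer slab
    is_excitatory: bool = True


@dataclass(frozen=True)
class ConnectionRule:
    """Expected efferents from one presynaptic group, per layer, per target group.

    ``expected_count`` is the number of synapses a single presynaptic neuron
    of ``pre`` makes onto the population ``post`` within layer ``layer``
    before any slice-cutting correction.  ``arbor_radius`` (um) is the
    lateral axonal arborisation radius in that layer; the Gaussian kernel
    standard deviation is half of it.  ``allowed_compartments`` lists the
    postsynaptic compartment ids this projection may contact.
    """

    pre: str
    post: str
    layer: str
    expected_count: float
    arbor_radius: float          # um; kernel sigma = arbor_radius / 2
    allowed_compartments: tuple[int, ...]
    synapse_spec: str            # key into the model's synapse-spec table

    def __post_init__(self) -> None:
        if self.expected_count < 0:
            raise ValueError("expected_count must be >= 0")
        if self.arbor_radius <= 0:
            raise ValueError("arbor_radius must be > 0")
        if len(self.allowed_compartments) == 0:
            raise ValueError("allowed_compartments must be non-empty")

    @property
    def sigma(self) -> float:
        return self.arbor_radius / 2.0


@dataclass(frozen=True)
class ConnectivitySpec:
    rules: tuple[ConnectionRule, ...]
    axonal_speed: float = 0.3    # m/s
    latency: float = 0.5         # ms, constant synaptic delay

    def __post_init__(self) -> None:
        if self.axonal_speed <= 0 or self.latency < 0:
            raise ValueError("axonal_speed must be > 0 and latency >= 0")


@dataclass
class SynapseTable:
    """Realized connectivity: one row per synapse.

    ``pre`` / ``post`` are global neuron ids, ``post_compartment`` is the
    local compartment id on the postsynaptic cell, ``spec`` indexes the
    synapse-spec table, ``delay`` is in ms.  Multapses (repeated pre-post
    pairs) are allowed; autapses are not.
    """

    pre: np.ndarray
    post: np.ndarray
    post_compartment: np.ndarray
    spec: np.ndarray
    delay: np.ndarray
    spec_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.pre)
        for name in ("post", "post_compartment", "spec", "delay"):
            if len(getattr(self, name)) != n:
                raise ValueError("synapse table columns must have equal length")
        if n and np.any(self.pre == self.post):
            raise ValueError("autapses are not allowed")

    def __len__(self) -> int:
        return len(self.pre)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "pre": self.pre, "post": self.post,
            "post_compartment": self.post_compartment,
            "spec": self.spec, "delay_ms": self.delay,
        })
        if self.spec_names:
            df["spec_name"] = [self.spec_names[s] for s in self.spec]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def concatenate(cls, tables: Sequence["SynapseTable"]) -> "SynapseTable":
        tables = [t for t in tables if len(t)]
        if not tables:
            return cls(*[np.empty(0, dtype=int)] * 4, np.empty(0))
        return cls(
            np.concatenate([t.pre for t in tables]),
            np.concatenate([t.post for t in tables]),
            np.concatenate([t.post_compartment for t in tables]),
            np.concatenate([t.spec for t in tables]),
            np.concatenate([t.delay for t in tables]),
            tables[0].spec_names,
        )


def neuron_count(tissue: TissueSpec) -> int:
    """Total neuron number N = round(x_max * y_max * z_max * D)."""
    return int(_round_half_away(tissue.x_max * tissue.y_max * tissue.z_max * tissue.density))


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment: round(total*w) corrected to sum exactly to total."""
    raw = total * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    frac = raw - counts
    deficit = total - counts.sum()
    order = np.argsort(-frac)
    counts[order[:deficit]] += 1
    return counts


def position_neurons(
    tissue: TissueSpec,
    groups: Sequence[GroupSpec],
    seed: int | np.random.Generator = 0,
    n_total: int | None = None,
) -> dict[str, np.ndarray]:
    """Place somas uniformly at random inside each group's layer slab.

    Returns a dict group name -> (n_g, 3) soma positions in um.  Group
    counts are round(N * proportion) with a largest-remainder correction so
    that they total round(N * sum(proportions)).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    props = np.array([g.proportion for g in groups], dtype=float)
    if props.sum() > 100.0 + 1e-9:
        raise ValueError("group proportions exceed 100%")
    if n_total is None:
        n_total = neuron_count(tissue)
    budget = int(_round_half_away(n_total * props.sum() / 100.0))
    counts = _largest_remainder(budget, props)

    out: dict[str, np.ndarray] = {}
    for g, n in zip(groups, counts):
        if g.soma_z_range is not None:
            z_lo, z_hi = g.soma_z_range
        else:
            try:
                z_lo, z_hi = tissue.layer_boundaries[g.layer]
            except KeyError:
                raise KeyError(f"group {g.name}: unknown layer {g.layer!r}") from None
        if z_hi <= z_lo:
            raise ValueError(f"group {g.name}: zero-thickness placement slab")
        if tissue.shape == "cylinder":
            r = tissue.x_max / 2.0 * np.sqrt(rng.random(n))
            theta = rng.uniform(0.0, 2 * np.pi, n)
            x = tissue.x_max / 2.0 + r * np.cos(theta)
            y = tissue.y_max / 2.0 + r * np.sin(theta)
        else:
            x = rng.uniform(0.0, tissue.x_max, n)
            y = rng.uniform(0.0, tissue.y_max, n)
        z = rng.uniform(z_lo, z_hi, n)
        out[g.name] = np.column_stack([x, y, z]) * MM
    return out


def zeta_inside_fraction(xy_um, sigma: float, slice_size_um) -> float | np.ndarray:
    """Fraction of the 2-D Gaussian connection kernel inside the slice.

    For a presynaptic neuron at planar position (x, y) inside a slice
    [0, X] x [0, Y] and kernel standard deviation ``sigma`` (all um), the
    kernel integral over the slice separates into an erf product::

        zeta = 1/4 [erf(a_x/√2σ) − erf(b_x/√2σ)] [erf(a_y/√2σ) − erf(b_y/√2σ)]

    with a = −(distance to the low edge) <= 0 and b = distance to the high
    edge >= 0.  zeta lies in (0, 1] and shrinks as the neuron approaches any
    boundary.
    """
    xy = np.asarray(xy_um, dtype=float)
    X, Y = slice_size_um
    x, y = xy[..., 0], xy[..., 1]
    if np.any(x < 0) or np.any(x > X) or np.any(y < 0) or np.any(y > Y):
        raise ValueError("neuron position outside the slice boundaries")
    s = np.sqrt(2.0) * sigma
    ax, bx = -x, X - x
    ay, by = -y, Y - y
    val = 0.25 * (erf(ax / s) - erf(bx / s)) * (erf(ay / s) - erf(by / s))
    return float(val) if val.ndim == 0 else val


def compute_delay(pre_soma_um, post_soma_um, speed_m_per_s: float = 0.3,
                  latency_ms: float = 0.5) -> float | np.ndarray:
    """Conduction delay: inter-soma distance / axonal speed + fixed latency (ms)."""
    if speed_m_per_s <= 0:
        raise ValueError("axonal speed must be positive")
    d = np.linalg.norm(np.asarray(post_soma_um, float) - np.asarray(pre_soma_um, float),
                       axis=-1)
    delay = d * 1e-3 / speed_m_per_s + latency_ms
    return float(delay) if np.ndim(delay) == 0 else delay


def build_connectivity(
    positions: dict[str, np.ndarray],
    templates: dict[str, ReducedNeuronModel],
    spec: ConnectivitySpec,
    tissue: TissueSpec,
    seed: int | np.random.Generator = 0,
    weight_scale: dict[tuple[str, str], float] | None = None,
) -> SynapseTable:
    """Realise the synapse table for positioned neuron groups.

    For every presynaptic neuron and every connection rule from its group,
    the realised efferent count is round(expected * zeta) where zeta is the
    in-slice fraction of the rule's Gaussian kernel at that neuron's planar
    position.  Targets are sampled with replacement among neurons of the
    postsynaptic group, with probability proportional to the planar Gaussian
    kernel (multapses allowed, autapses excluded).  The contacted
    compartment is drawn from the rule's allowed list with probability
    proportional to compartment membrane area.  Neuron ids are global,
    assigned contiguously in the iteration order of ``positions``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = list(positions)
    offsets = {}
    off = 0
    for name in names:
        offsets[name] = off
        off += len(positions[name])
    slice_um = (tissue.x_max * MM, tissue.y_max * MM)

    spec_names = tuple(sorted({r.synapse_spec for r in spec.rules}))
    spec_index = {s: i for i, s in enumerate(spec_names)}

    trees = {name: cKDTree(positions[name][:, :2]) for name in names}
    tables: list[SynapseTable] = []
    for rule in spec.rules:
        if rule.pre not in positions or rule.post not in positions:
            continue
        pre_pos = positions[rule.pre]
        post_pos = positions[rule.post]
        if len(pre_pos) == 0 or len(post_pos) == 0:
            continue
        sigma = rule.sigma
        areas = templates[rule.post].areas[list(rule.allowed_compartments)]
        comp_p = areas / areas.sum()
        comp_ids = np.asarray(rule.allowed_compartments)
        tree = trees[rule.post]
        cutoff = 4.5 * sigma

        zet = zeta_inside_fraction(pre_pos[:, :2], sigma, slice_um)
        n_eff = _round_half_away(rule.expected_count * zet)

        pre_rows, post_rows, comp_rows, delay_rows = [], [], [], []
        for i in range(len(pre_pos)):
            n = int(n_eff[i])
            if n == 0:
                continue
            cand = tree.query_ball_point(pre_pos[i, :2], cutoff)
            cand = np.asarray(cand, dtype=int)
            if rule.pre == rule.post:
                cand = cand[cand != i]
            if len(cand) == 0:
                continue  # shortfall: no candidate targets in range
            d2 = np.sum((post_pos[cand, :2] - pre_pos[i, :2]) ** 2, axis=1)
            w = np.exp(-d2 / (2.0 * sigma**2))
            total = w.sum()
            if total <= 0:
                continue
            tgt = rng.choice(cand, size=n, replace=True, p=w / total)
            comp = comp_ids[rng.choice(len(comp_ids), size=n, p=comp_p)]
            delay = compute_delay(pre_pos[i], post_pos[tgt],
                                  spec.axonal_speed, spec.latency)
            pre_rows.append(np.full(n, offsets[rule.pre] + i))
            post_rows.append(offsets[rule.post] + tgt)
            comp_rows.append(comp)
            delay_rows.append(np.atleast_1d(delay))
        if pre_rows:
            tables.append(SynapseTable(
                np.concatenate(pre_rows), np.concatenate(post_rows),
                np.concatenate(comp_rows),
                np.full(sum(len(p) for p in pre_rows), spec_index[rule.synapse_spec]),
                np.concatenate(delay_rows),
                spec_names,
            ))
    if not tables:
        return SynapseTable(*[np.empty(0, dtype=int)] * 4, np.empty(0), spec_names)
    return SynapseTable.concatenate(tables)


def assign_correlated_inputs(
    n_synapses_per_neuron: int,
    pool_size: int,
    n_neurons: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Assign pooled spike-train identities to each neuron's synapses.

    Each neuron's ``n_synapses_per_neuron`` synapses draw distinct train ids
    without replacement from a shared pool of ``pool_size`` trains.  The
    resulting pairwise input correlation is n_synapses / pool_size, and two
    neurons share on average n_synapses^2 / pool_size common trains.
    Returns an (n_neurons, n_synapses_per_neuron) integer array.
    """
    if pool_size < n_synapses_per_neuron:
        raise ValueError("pool must be at least as large as the per-neuron synapse count")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # row-wise draw without replacement via random-key argpartition
    keys = rng.random((n_neurons, pool_size))
    idx = np.argpartition(keys, n_synapses_per_neuron - 1, axis=1)
    return idx[:, :n_synapses_per_neuron]


def connection_matrices(
    positions: dict[str, np.ndarray],
    spec: ConnectivitySpec,
    tissue: TissueSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-by-group expected connection counts before and after slice cutting.

    Returns (before, after) DataFrames indexed by presynaptic group with
    postsynaptic groups as columns; ``after`` applies the per-neuron zeta
    factor and is elementwise <= ``before``.
    """
    names = list(positions)
    before = pd.DataFrame(0.0, index=names, columns=names)
    after = pd.DataFrame(0.0, index=names, columns=names)
    slice_um = (tissue.x_max * MM, tissue.y_max * MM)
    for rule in spec.rules:
        if rule.pre not in positions or rule.post not in positions:
            continue
        pre_pos = positions[rule.pre]
        n_pre = len(pre_pos)
        before.loc[rule.pre, rule.post] += rule.expected_count * n_pre
        zet = zeta_inside_fraction(pre_pos[:, :2], rule.sigma, slice_um)
        after.loc[rule.pre, rule.post] += float(
            _round_half_away(rule.expected_count * zet).sum()
        )
    return before, after
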