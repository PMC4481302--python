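"""Extracellular potential forward model: line and point current sources.

The extracellular potential at an electrode is the sum of all compartmental
membrane currents weighted by geometry, assuming a purely resistive,
constant and homogeneous extracellular medium of conductivity ``sigma``
(S/m).  Dendritic compartments are treated as line sources (the membrane
current distributed uniformly along the cylinder axis); somatic
compartments as point sources at the soma centre:

    phi_dend = sum_k I_k / (4 pi sigma ds_k) * ln| (sqrt(h^2+rho^2) - h)
                                                   / (sqrt(l^2+rho^2) - l) |
    phi_soma = sum_s I_s / (4 pi sigma r_s)

with ds the compartment length, rho the perpendicular distance from its
axis, h and l the signed longitudinal distances from the compartment's end
and start (l = ds + h), and r_s the soma-centre distance.

Units: currents in nA, distances in um, sigma in S/m, potentials in uV.
The conversion carries a factor 10^3 (1 nA / (1 S/m * 1 um) = 10^-3 V).

Because the medium is linear, the geometry factors are precomputed once per
network/electrode configuration into a weight matrix W[electrode,
compartment] (uV per nA), and every LFP sample is the matrix product of W
with the instantaneous membrane-current vector.  Singularities are avoided
by clamping rho (and the point-source distance) from below at the
compartment radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeArray",
    "LFPRecording",
    "line_source_weight",
    "point_source_weight",
    "compute_weight_matrix",
    "accumulate_lfp",
    "utah_array",
]

_UNIT = 1e3  # nA/(S/m * um) -> uV


@dataclass(frozen=True)
class ElectrodeArray:
    """Virtual electrode positions (um), with an optional grid layout."""

    positions: np.ndarray                      # (n, 3) um
    ids: tuple[int, ...] = ()
    grid_shape: tuple[int, int] | None = None  # (rows, cols) if laid out on a grid
    pitch: float | None = None                 # um, grid spacing

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        if not self.ids:
            object.__setattr__(self, "ids", tuple(range(len(pos))))
        if len(set(self.ids)) != len(pos):
            raise ValueError("electrode ids must be unique and match positions")

    def __len__(self) -> int:
        return len(self.positions)


def utah_array(centre_xy_um=(0.0, 0.0), z_um: float = 0.0,
               shape=(10, 10), pitch: float = 400.0) -> ElectrodeArray:
    """A 10 x 10 grid with 400-um pitch, the standard planar MEA layout."""
    rows, cols = shape
    xs = (np.arange(cols) - (cols - 1) / 2.0) * pitch + centre_xy_um[0]
    zs = (np.arange(rows)[::-1] - (rows - 1) / 2.0) * pitch + z_um
    pos = np.column_stack([
        np.tile(xs, rows),
        np.full(rows * cols, centre_xy_um[1]),
        np.repeat(zs, cols),
    ])
    return ElectrodeArray(pos, grid_shape=(rows, cols), pitch=pitch)


@dataclass
class LFPRecording:
    """Simulated extracellular potentials: (n_electrodes, n_samples) in uV."""

    data: np.ndarray
    sample_rate: float           # Hz
    electrode_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.electrode_ids:
            self.electrode_ids = tuple(range(self.data.shape[0]))

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms (centre of each averaging window)."""
        dt = 1000.0 / self.sample_rate
        return (np.arange(self.data.shape[1]) + 0.5) * dt


def line_source_weight(start, end, radius: float, electrode, sigma: float = 0.3) -> float:
    """Geometric weight (uV per nA) of one cylindrical line-source compartment."""
    return float(
        _line_weights(
            np.asarray(start, float)[None], np.asarray(end, float)[None],
            np.asarray([radius], float), np.asarray(electrode, float)[None], sigma,
        )[0, 0]
    )


def point_source_weight(centre, radius: float, electrode, sigma: float = 0.3) -> float:
    """Geometric weight (uV per nA) of a somatic point source."""
    r = np.linalg.norm(np.asarray(electrode, float) - np.asarray(centre, float))
    r = max(r, radius)
    return _UNIT / (4.0 * np.pi * sigma * r)


def _line_weights(starts, ends, radii, electrodes, sigma) -> np.ndarray:
    """Vectorized line-source weights, shape (n_electrodes, n_compartments)."""
    axis = ends - starts                               # (k, 3)
    ds = np.linalg.norm(axis, axis=1)
    if np.any(ds <= 0):
        raise ValueError("line-source compartments must have positive length")
    u = axis / ds[:, None]
    rel_end = electrodes[:, None, :] - ends[None, :, :]     # (e, k, 3)
    h = np.einsum("ekj,kj->ek", rel_end, u)                 # signed, from the end
    l = h + ds[None, :]                                     # from the start
    perp = rel_end - h[:, :, None] * u[None, :, :]
    rho = np.linalg.norm(perp, axis=2)
    rho = np.maximum(rho, radii[None, :])                   # clamp at compartment radius
    num = np.sqrt(h**2 + rho**2) - h
    den = np.sqrt(l**2 + rho**2) - l
    # both terms are strictly positive once rho >= radius > 0
    val = np.log(np.abs(num / den))
    return _UNIT * val / (4.0 * np.pi * sigma * ds[None, :])


def compute_weight_matrix(
    starts: np.ndarray,
    ends: np.ndarray,
    radii: np.ndarray,
    is_soma: np.ndarray,
    electrodes: ElectrodeArray | np.ndarray,
    sigma: float = 0.3,
    zero_columns: np.ndarray | None = None,
) -> np.ndarray:
    """Precompute W[electrode, compartment] in uV per nA.

    Somatic compartments (``is_soma``) use the point-source rule at the
    cylinder midpoint; all others use the line-source rule.  Columns listed
    in ``zero_columns`` (e.g. compartments of single-compartment neurons,
    which cannot sustain a net return current) are forced to zero.
    """
    if sigma <= 0:
        raise ValueError("conductivity must be positive")
    elec = electrodes.positions if isinstance(electrodes, ElectrodeArray) else np.atleast_2d(electrodes)
    starts = np.asarray(starts, float)
    ends = np.asarray(ends, float)
    radii = np.asarray(radii, float)
    is_soma = np.asarray(is_soma, bool)
    W = np.zeros((len(elec), len(starts)))

    if np.any(~is_soma):
        W[:, ~is_soma] = _line_weights(
            starts[~is_soma], ends[~is_soma], radii[~is_soma], elec, sigma
        )
    if np.any(is_soma):
        centres = 0.5 * (starts[is_soma] + ends[is_soma])
        r = np.linalg.norm(elec[:, None, :] - centres[None, :, :], axis=2)
        r = np.maximum(r, radii[is_soma][None, :])
        W[:, is_soma] = _UNIT / (4.0 * np.pi * sigma * r)
    if zero_columns is not None:
        W[:, zero_columns] = 0.0
    return W


def accumulate_lfp(weights: np.ndarray, currents: np.ndarray,
                   sample_rate: float = 1000.0) -> LFPRecording:
    """Sum weighted membrane currents into electrode potentials.

    ``currents`` is (n_compartments, n_samples) in nA on the compartment
    index shared with ``weights``; the result is (n_electrodes, n_samples)
    in uV.  Linear in the currents, so populations superpose additively.
    """
    weights = np.asarray(weights)
    currents = np.asarray(currents)
    if weights.shape[1] != currents.shape[0]:
        raise ValueError(
            f"weight matrix has {weights.shape[1]} compartments but current "
            f"stream has {currents.shape[0]}"
        )
    return LFPRecording(weights @ currents, sample_rate)
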