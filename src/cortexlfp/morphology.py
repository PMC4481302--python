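"""Compartmental neuron geometry and passive electrical structure.

A neuron is represented at two levels:

* :class:`MorphologyTree` — a raw reconstruction, i.e. the point/parent
  structure read from a standard 7-column SWC file.
* :class:`ReducedNeuronModel` — a small equivalent-cable model (typically
  fewer than ten compartments) obtained either by collapsing a full
  reconstruction with :func:`reduce_morphology`, or built directly from a
  compartment list (the shipped archetype cells in :mod:`cortexlfp.cells`).

All lengths are in micrometres, diameters in micrometres, specific membrane
capacitance in uF/cm^2, specific membrane resistance in Ohm*cm^2, axial
resistivity in Ohm*cm.  Derived per-compartment quantities use nF
(capacitance) and uS (conductance) so that, together with mV and ms, all
currents come out in nA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Compartment",
    "PassiveProperties",
    "MorphologyTree",
    "ReducedNeuronModel",
    "SWCError",
    "load_swc",
    "write_swc",
    "reduce_morphology",
    "place_and_orient",
]

# SWC structure-type codes -> compartment labels
_SWC_LABELS = {1: "soma", 2: "axon-stub", 3: "basal", 4: "apical"}
_LABEL_CODES = {v: k for k, v in _SWC_LABELS.items()}

# unit factors
_UF_PER_UM2 = 1e-8          # um^2 -> cm^2
_NF_PER_UF = 1e3


@dataclass(frozen=True)
class Compartment:
    """One cylindrical compartment of a reduced model.

    ``parent_id`` is the index of the parent compartment (−1 for the
    root/soma).  ``start``/``end`` are the 3-D coordinates of the cylinder
    axis endpoints in the cell template frame (soma centred at the origin).
    """

    id: int
    parent_id: int
    start: tuple[float, float, float]
    end: tuple[float, float, float]
    diameter: float
    label: str = "basal"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"compartment {self.id}: diameter must be > 0")
        if self.label not in _LABEL_CODES:
            raise ValueError(f"compartment {self.id}: unknown label {self.label!r}")
        if self.label != "soma" and self.length <= 0:
            raise ValueError(f"compartment {self.id}: zero-length dendritic compartment")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.end) - np.asarray(self.start)))

    @property
    def area(self) -> float:
        """Lateral membrane area pi*d*L in um^2."""
        return float(np.pi * self.diameter * self.length)


@dataclass(frozen=True)
class PassiveProperties:
    """Specific passive electrical parameters of the membrane and cytoplasm."""

    membrane_capacitance: float = 1.0      # uF/cm^2
    membrane_resistance: float = 20_000.0  # Ohm*cm^2
    axial_resistivity: float = 150.0       # Ohm*cm
    leak_reversal: float = -70.0           # mV

    def __post_init__(self) -> None:
        for name in ("membrane_capacitance", "membrane_resistance", "axial_resistivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


class SWCError(ValueError):
    """Raised for malformed SWC content; the message names the offending line."""


@dataclass
class MorphologyTree:
    """Point/parent representation of a reconstruction (SWC semantics).

    ``parents`` holds, for each point, the *index into the point arrays* of
    its parent (−1 for the root).  ``radii`` are point radii in um; the
    segment between a point and its parent is treated as a cylinder with the
    child point's diameter.
    """

    xyz: np.ndarray          # (n, 3) um
    radii: np.ndarray        # (n,)
    types: np.ndarray        # (n,) SWC integer codes
    parents: np.ndarray      # (n,) indices, −1 for root
    ids: np.ndarray = field(default=None)  # original SWC sample ids

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.types = np.asarray(self.types, dtype=int)
        self.parents = np.asarray(self.parents, dtype=int)
        if self.ids is None:
            self.ids = np.arange(1, len(self.radii) + 1)
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise SWCError(f"tree must have exactly one root, found {len(roots)}")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parents == -1)[0])

    def children(self, idx: int) -> np.ndarray:
        return np.flatnonzero(self.parents == idx)

    def segment_length(self, idx: int) -> float:
        """Length of the segment joining point ``idx`` to its parent (0 for root)."""
        p = self.parents[idx]
        if p < 0:
            return 0.0
        return float(np.linalg.norm(self.xyz[idx] - self.xyz[p]))


def load_swc(path) -> MorphologyTree:
    """Read a standard 7-column SWC file.

    Raises :class:`SWCError` naming the line for malformed rows, dangling
    parent references, or multiple roots.
    """
    ids: list[int] = []
    types: list[int] = []
    xyz: list[list[float]] = []
    radii: list[float] = []
    raw_parents: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            fields = body.split()
            if len(fields) != 7:
                raise SWCError(f"{path}: line {lineno}: expected 7 columns, got {len(fields)}")
            try:
                sid = int(fields[0])
                stype = int(fields[1])
                coords = [float(v) for v in fields[2:5]]
                radius = float(fields[5])
                parent = int(fields[6])
            except ValueError as exc:
                raise SWCError(f"{path}: line {lineno}: {exc}") from None
            if radius <= 0:
                raise SWCError(f"{path}: line {lineno}: non-positive radius {radius}")
            if sid in ids:
                raise SWCError(f"{path}: line {lineno}: duplicate sample id {sid}")
            ids.append(sid)
            types.append(stype)
            xyz.append(coords)
            radii.append(radius)
            raw_parents.append(parent)

    if not ids:
        raise SWCError(f"{path}: no samples")
    index_of = {sid: i for i, sid in enumerate(ids)}
    parents = np.empty(len(ids), dtype=int)
    n_roots = 0
    for i, (sid, par) in enumerate(zip(ids, raw_parents)):
        if par == -1:
            parents[i] = -1
            n_roots += 1
        elif par not in index_of:
            raise SWCError(f"{path}: sample {sid}: dangling parent reference {par}")
        elif index_of[par] >= i:
            raise SWCError(f"{path}: sample {sid}: parent {par} not defined earlier")
        else:
            parents[i] = index_of[par]
    if n_roots != 1:
        raise SWCError(f"{path}: expected exactly one root, found {n_roots}")
    return MorphologyTree(
        xyz=np.array(xyz), radii=np.array(radii), types=np.array(types),
        parents=parents, ids=np.array(ids),
    )


def write_swc(tree: MorphologyTree, path) -> None:
    """Write a :class:`MorphologyTree` as a 7-column SWC file."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(len(tree)):
            p = tree.parents[i]
            parent_id = -1 if p < 0 else int(tree.ids[p])
            x, y, z = tree.xyz[i]
            fh.write(
                f"{int(tree.ids[i])} {int(tree.types[i])} "
                f"{x:.9g} {y:.9g} {z:.9g} {tree.radii[i]:.9g} {parent_id}\n"
            )


@dataclass
class ReducedNeuronModel:
    """Equivalent-cable compartmental model with passive electrical structure.

    Per-compartment membrane area, capacitance and leak conductance, and the
    per-edge axial conductances, are derived from the geometry and the
    specific passive parameters; :meth:`validate` checks the stored arrays
    against a recomputation.
    """

    compartments: list[Compartment]
    passive: PassiveProperties = field(default_factory=PassiveProperties)
    name: str = "cell"

    def __post_init__(self) -> None:
        n = len(self.compartments)
        if not 1 <= n:
            raise ValueError("model needs at least one compartment")
        for i, c in enumerate(self.compartments):
            if c.id != i:
                raise ValueError("compartment ids must be 0..n-1 in order")
            if c.parent_id >= i or (c.parent_id < 0) != (i == 0):
                raise ValueError("compartment graph must be a tree rooted at the soma")
        if self.compartments[0].label != "soma":
            raise ValueError("compartment 0 must be the soma")
        self._recompute()

    # -- derived electrical structure -------------------------------------
    def _recompute(self) -> None:
        p = self.passive
        self.areas = np.array([c.area for c in self.compartments])          # um^2
        self.capacitances = p.membrane_capacitance * self.areas * _UF_PER_UM2 * _NF_PER_UF  # nF
        self.leak_conductances = self.areas * _UF_PER_UM2 / p.membrane_resistance * 1e6     # uS
        edges = []
        for c in self.compartments[1:]:
            par = self.compartments[c.parent_id]
            # series resistance of two half-cylinders, Ohm; lengths in cm
            r = (4.0 * p.axial_resistivity / np.pi) * (
                0.5 * c.length / c.diameter**2 + 0.5 * par.length / par.diameter**2
            ) * 1e4  # um/um^2 -> cm/cm^2
            edges.append((c.parent_id, c.id, 1e6 / r))
        self.axial_edges = edges  # list of (parent, child, g_uS), symmetric per edge

    def validate(self, rtol: float = 1e-9) -> None:
        areas = np.array([np.pi * c.diameter * c.length for c in self.compartments])
        np.testing.assert_allclose(self.areas, areas, rtol=rtol)
        cap = self.passive.membrane_capacitance * areas * _UF_PER_UM2 * _NF_PER_UF
        np.testing.assert_allclose(self.capacitances, cap, rtol=rtol)

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def total_length(self) -> float:
        return float(sum(c.length for c in self.compartments))

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Template-frame (start, end) coordinate arrays, shape (n, 3)."""
        starts = np.array([c.start for c in self.compartments], dtype=float)
        ends = np.array([c.end for c in self.compartments], dtype=float)
        return starts, ends

    def with_passive(self, passive: PassiveProperties) -> "ReducedNeuronModel":
        return ReducedNeuronModel(list(self.compartments), passive, self.name)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "passive": {
                "membrane_capacitance": self.passive.membrane_capacitance,
                "membrane_resistance": self.passive.membrane_resistance,
                "axial_resistivity": self.passive.axial_resistivity,
                "leak_reversal": self.passive.leak_reversal,
            },
            "compartments": [
                {
                    "id": c.id,
                    "parent_id": c.parent_id,
                    "start": list(c.start),
                    "end": list(c.end),
                    "diameter": c.diameter,
                    "label": c.label,
                }
                for c in self.compartments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReducedNeuronModel":
        comps = [
            Compartment(
                id=c["id"], parent_id=c["parent_id"],
                start=tuple(c["start"]), end=tuple(c["end"]),
                diameter=c["diameter"], label=c["label"],
            )
            for c in d["compartments"]
        ]
        return cls(comps, PassiveProperties(**d["passive"]), d.get("name", "cell"))


def _branch_paths(tree: MorphologyTree, section: list[int]) -> tuple[int, list[list[int]]]:
    """Split a section into its attachment point and entry-to-leaf paths.

    A section may hold several parallel branches, all hanging off the same
    external parent point (their common attachment).  Each returned path is
    a chain of point indices from an entry point down to a leaf; every path
    element contributes the segment from its parent, so the entry point
    carries the segment that connects the section to its parent section.
    """
    in_section = set(section)
    entries = [i for i in section if tree.parents[i] not in in_section]
    if not entries:
        raise ValueError("section has no entry point (contains the root?)")
    parents = {int(tree.parents[i]) for i in entries}
    if len(parents) != 1:
        raise ValueError("section branches must share a single attachment point")
    attach = parents.pop()
    leaves = [i for i in section if not any(c in in_section for c in tree.children(i))]
    paths = []
    for leaf in leaves:
        path = []
        node = leaf
        while node != attach:
            if node not in in_section:
                raise ValueError("section is not connected")
            path.append(node)
            node = int(tree.parents[node])
        paths.append(path[::-1])
    return attach, paths


def reduce_morphology(
    tree: MorphologyTree,
    section_plan: Sequence[Sequence[int]],
    passive: PassiveProperties | None = None,
    name: str = "reduced",
) -> ReducedNeuronModel:
    """Collapse a reconstruction into an equivalent-cable reduced model.

    ``section_plan`` partitions the tree's point indices into connected
    sections; each section becomes one compartment.  The first section must
    contain the root and only soma-typed points.  For each dendritic section
    the compartment length is the mean of the path lengths of the parallel
    branches it represents, and the equivalent diameter conserves the axial
    conductance of parallel branches (d_eq = sqrt(sum d_b^2), with each
    branch's series-equivalent diameter d_b chosen to preserve the branch's
    end-to-end axial resistance).  The collapsed model keeps the original
    length along each path but has a smaller total membrane area and no
    lateral spread beyond the mean branch direction.
    """
    n = len(tree)
    seen: set[int] = set()
    for sec in section_plan:
        if len(sec) == 0:
            raise ValueError("empty section in plan")
        overlap = seen.intersection(sec)
        if overlap:
            raise ValueError(f"points covered twice: {sorted(overlap)}")
        seen.update(sec)
    if seen != set(range(n)):
        raise ValueError("section plan must cover every tree point exactly once")

    # map each section to its entry; order sections so parents come first
    sec_of_point = {}
    for si, sec in enumerate(section_plan):
        labels = {_SWC_LABELS.get(int(tree.types[i]), "basal") for i in sec}
        if "soma" in labels and len(labels) > 1:
            raise ValueError(f"section {si} mixes soma and dendrite points")
        for i in sec:
            sec_of_point[i] = si

    root_sec = sec_of_point[tree.root]
    order = [root_sec]
    placed = {root_sec}
    # topological order over the section graph
    while len(order) < len(section_plan):
        progressed = False
        for si, sec in enumerate(section_plan):
            if si in placed:
                continue
            entry = [i for i in sec if sec_of_point.get(int(tree.parents[i])) != si]
            parent_secs = {sec_of_point[int(tree.parents[i])] for i in entry}
            if parent_secs.issubset(placed):
                order.append(si)
                placed.add(si)
                progressed = True
        if not progressed:
            raise ValueError("section plan is not a tree over sections")

    comp_of_sec: dict[int, int] = {}
    compartments: list[Compartment] = []
    for new_id, si in enumerate(order):
        sec = list(section_plan[si])
        labels = {_SWC_LABELS.get(int(tree.types[i]), "basal") for i in sec}
        label = labels.pop() if len(labels) == 1 else "basal"

        if new_id == 0:
            # soma: area-matched cylinder (sphere for a single sample point)
            root = tree.root
            if len(sec) == 1:
                r = tree.radii[root]
                area = 4.0 * np.pi * r**2
                length = diameter = float(np.sqrt(area / np.pi))
            else:
                seg_pts = [i for i in sec if tree.parents[i] in sec]
                length = float(sum(tree.segment_length(i) for i in seg_pts))
                area = float(sum(
                    np.pi * 2 * tree.radii[i] * tree.segment_length(i) for i in seg_pts
                ))
                diameter = area / (np.pi * length)
            centre = tree.xyz[root]
            half = np.array([0.0, 0.0, length / 2.0])
            compartments.append(Compartment(
                id=0, parent_id=-1,
                start=tuple(centre - half), end=tuple(centre + half),
                diameter=diameter, label="soma",
            ))
            comp_of_sec[si] = 0
            continue

        # dendritic (or axon-stub) section
        attach, paths = _branch_paths(tree, sec)
        branch_lengths = []
        branch_d2 = []
        tips = []
        for path in paths:
            seg_l = np.array([tree.segment_length(i) for i in path])
            seg_d = np.array([2.0 * tree.radii[i] for i in path])
            L = float(seg_l.sum())
            if L <= 0:
                raise ValueError("zero-length branch in section")
            # series-equivalent diameter preserving end-to-end axial resistance
            d2 = L / float(np.sum(seg_l / seg_d**2))
            branch_lengths.append(L)
            branch_d2.append(d2)
            tips.append(tree.xyz[path[-1]])
        length = float(np.mean(branch_lengths))
        diameter = float(np.sqrt(np.sum(branch_d2)))

        parent_comp = comp_of_sec[sec_of_point[attach]]
        start = np.asarray(compartments[parent_comp].end, dtype=float)
        if parent_comp == 0:
            start = tree.xyz[tree.root].astype(float)
        direction = np.mean(np.asarray(tips) - tree.xyz[attach], axis=0)
        nrm = np.linalg.norm(direction)
        if nrm < 1e-12:
            direction = np.array([0.0, 0.0, 1.0])
        else:
            direction = direction / nrm
        end = start + direction * length
        compartments.append(Compartment(
            id=new_id, parent_id=parent_comp,
            start=tuple(start), end=tuple(end),
            diameter=diameter, label=label,
        ))
        comp_of_sec[si] = new_id

    return ReducedNeuronModel(compartments, passive or PassiveProperties(), name)


def place_and_orient(
    model: ReducedNeuronModel,
    soma_xyz: Sequence[float],
    azimuth: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly place a cell template: rotate about the z-axis, then translate.

    The rotation is about the vertical axis through the template origin, so
    pyramidal apical dendrites (aligned with +z in the template) stay
    parallel to the depth axis.  Returns (start, end) coordinate arrays in
    tissue coordinates, shape (n_compartments, 3).
    """
    starts, ends = model.coords()
    c, s = np.cos(azimuth), np.sin(azimuth)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    offset = np.asarray(soma_xyz, dtype=float)
    return starts @ rot.T + offset, ends @ rot.T + offset
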