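"""Built-in reduced cell archetypes for the layered-slice model groups.

One representative equivalent-cable model is provided per neuron group of
the slice model: layer 2/3, 4, 5 and 6 pyramidal cells (8, 8, 9 and 9
compartments), layer 4 spiny stellate cells (7), and basket / non-basket
interneurons (7 each).  The compartment dimensions and passive parameters
are representative fixture values chosen to give layer-appropriate total
extents (e.g. an L2/3 pyramid whose apical tuft reaches ~310 um above the
soma, an L5 pyramid reaching ~950 um); they are NOT a published
reconstruction-by-reconstruction reduction, and any study that needs a
specific morphology should supply its own SWC file plus section plan and
use :func:`cortexlfp.morphology.reduce_morphology`.

Pyramidal templates point their apical dendrites along +z (toward the
cortical surface); interneuron and stellate dendrites are arranged
multipolar about the soma.
"""

from __future__ import annotations

import numpy as np

from .morphology import Compartment, PassiveProperties, ReducedNeuronModel

__all__ = ["make_cell", "CELL_BUILDERS"]

_DEFAULT_PASSIVE = PassiveProperties(
    membrane_capacitance=1.0,      # uF/cm^2
    membrane_resistance=20_000.0,  # Ohm*cm^2
    axial_resistivity=150.0,       # Ohm*cm
    leak_reversal=-70.0,           # mV
)

# fast-spiking interneurons have a markedly shorter membrane time constant
# than pyramidal cells; ~8 ms here versus 20 ms for the excitatory cells
_INTERNEURON_PASSIVE = PassiveProperties(
    membrane_capacitance=1.0,
    membrane_resistance=8_000.0,
    axial_resistivity=150.0,
    leak_reversal=-70.0,
)


def _soma(length: float, diameter: float) -> Compartment:
    half = length / 2.0
    return Compartment(0, -1, (0.0, 0.0, -half), (0.0, 0.0, half),
                       diameter=diameter, label="soma")


def _seg(cid, parent, start, direction, length, diameter, label):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    end = np.asarray(start, dtype=float) + d * length
    return Compartment(cid, parent, tuple(start), tuple(end), diameter, label), tuple(end)


def l23_pyramid() -> ReducedNeuronModel:
    """Layer 2/3 pyramidal archetype: 8 compartments, apical extent ~310 um."""
    comps = [_soma(16.0, 16.0)]
    c, e = _seg(1, 0, (0, 0, 8.0), (0, 0, 1), 110.0, 2.6, "apical")     # trunk 1
    comps.append(c)
    c, e = _seg(2, 1, e, (0, 0, 1), 110.0, 2.0, "apical")               # trunk 2
    comps.append(c)
    c, _ = _seg(3, 2, e, (0.35, 0, 1), 95.0, 1.3, "apical")             # tuft a
    comps.append(c)
    c, _ = _seg(4, 2, e, (-0.35, 0, 1), 95.0, 1.3, "apical")            # tuft b
    comps.append(c)
    c, _ = _seg(5, 1, (0, 0, 8.0 + 55.0), (1, 0, 0.1), 90.0, 1.0, "apical")  # oblique
    comps.append(c)
    c, _ = _seg(6, 0, (0, 0, -8.0), (0.5, 0, -1), 130.0, 1.6, "basal")
    comps.append(c)
    c, _ = _seg(7, 0, (0, 0, -8.0), (-0.5, 0, -1), 130.0, 1.6, "basal")
    comps.append(c)
    return ReducedNeuronModel(comps, _DEFAULT_PASSIVE, "l23_pyramid")


def l4_stellate() -> ReducedNeuronModel:
    """Layer 4 spiny stellate archetype: 7 compartments, multipolar ~170 um."""
    comps = [_soma(13.0, 13.0)]
    dirs = [(1, 0, 0.3), (-1, 0, 0.3), (0.5, 0.8, -0.4),
            (-0.5, -0.8, -0.4), (0.2, -0.9, 0.6), (-0.2, 0.9, 0.6)]
    for i, d in enumerate(dirs, start=1):
        c, _ = _seg(i, 0, (0, 0, 0), d, 165.0, 1.2, "basal")
        comps.append(c)
    return ReducedNeuronModel(comps, _DEFAULT_PASSIVE, "l4_stellate")


def l4_pyramid() -> ReducedNeuronModel:
    """Layer 4 pyramidal archetype: 8 compartments, apical extent ~280 um."""
    comps = [_soma(14.0, 14.0)]
    c, e = _seg(1, 0, (0, 0, 7.0), (0, 0, 1), 100.0, 2.2, "apical")
    comps.append(c)
    c, e = _seg(2, 1, e, (0, 0, 1), 100.0, 1.7, "apical")
    comps.append(c)
    c, _ = _seg(3, 2, e, (0.3, 0, 1), 80.0, 1.2, "apical")
    comps.append(c)
    c, _ = _seg(4, 2, e, (-0.3, 0, 1), 80.0, 1.2, "apical")
    comps.append(c)
    c, _ = _seg(5, 1, (0, 0, 57.0), (1, 0, 0), 85.0, 1.0, "apical")
    comps.append(c)
    c, _ = _seg(6, 0, (0, 0, -7.0), (0.5, 0, -1), 120.0, 1.5, "basal")
    comps.append(c)
    c, _ = _seg(7, 0, (0, 0, -7.0), (-0.5, 0, -1), 120.0, 1.5, "basal")
    comps.append(c)
    return ReducedNeuronModel(comps, _DEFAULT_PASSIVE, "l4_pyramid")


def l5_pyramid() -> ReducedNeuronModel:
    """Layer 5 pyramidal archetype: 9 compartments, apical extent ~950 um."""
    comps = [_soma(20.0, 20.0)]
    c, e = _seg(1, 0, (0, 0, 10.0), (0, 0, 1), 260.0, 3.6, "apical")
    comps.append(c)
    c, e = _seg(2, 1, e, (0, 0, 1), 260.0, 2.8, "apical")
    comps.append(c)
    c, e = _seg(3, 2, e, (0, 0, 1), 260.0, 2.2, "apical")
    comps.append(c)
    c, _ = _seg(4, 3, e, (0.4, 0, 1), 160.0, 1.4, "apical")
    comps.append(c)
    c, _ = _seg(5, 3, e, (-0.4, 0, 1), 160.0, 1.4, "apical")
    comps.append(c)
    c, _ = _seg(6, 1, (0, 0, 140.0), (1, 0, 0.1), 120.0, 1.2, "apical")
    comps.append(c)
    c, _ = _seg(7, 0, (0, 0, -10.0), (0.6, 0, -1), 160.0, 1.9, "basal")
    comps.append(c)
    c, _ = _seg(8, 0, (0, 0, -10.0), (-0.6, 0, -1), 160.0, 1.9, "basal")
    comps.append(c)
    return ReducedNeuronModel(comps, _DEFAULT_PASSIVE, "l5_pyramid")


def l6_pyramid() -> ReducedNeuronModel:
    """Layer 6 pyramidal archetype: 9 compartments, apical extent ~620 um."""
    comps = [_soma(17.0, 17.0)]
    c, e = _seg(1, 0, (0, 0, 8.5), (0, 0, 1), 180.0, 2.8, "apical")
    comps.append(c)
    c, e = _seg(2, 1, e, (0, 0, 1), 180.0, 2.2, "apical")
    comps.append(c)
    c, e = _seg(3, 2, e, (0, 0, 1), 150.0, 1.7, "apical")
    comps.append(c)
    c, _ = _seg(4, 3, e, (0.4, 0, 1), 110.0, 1.2, "apical")
    comps.append(c)
    c, _ = _seg(5, 3, e, (-0.4, 0, 1), 110.0, 1.2, "apical")
    comps.append(c)
    c, _ = _seg(6, 1, (0, 0, 98.5), (1, 0, 0.1), 100.0, 1.0, "apical")
    comps.append(c)
    c, _ = _seg(7, 0, (0, 0, -8.5), (0.6, 0, -1), 140.0, 1.7, "basal")
    comps.append(c)
    c, _ = _seg(8, 0, (0, 0, -8.5), (-0.6, 0, -1), 140.0, 1.7, "basal")
    comps.append(c)
    return ReducedNeuronModel(comps, _DEFAULT_PASSIVE, "l6_pyramid")


def basket() -> ReducedNeuronModel:
    """Basket interneuron archetype: 7 compartments, multipolar ~150 um."""
    comps = [_soma(14.0, 14.0)]
    dirs = [(0.3, 0, 1), (-0.3, 0, 1), (1, 0.3, 0),
            (-1, -0.3, 0), (0.4, 0.6, -1), (-0.4, -0.6, -1)]
    for i, d in enumerate(dirs, start=1):
        c, _ = _seg(i, 0, (0, 0, 0), d, 145.0, 1.1, "basal")
        comps.append(c)
    return ReducedNeuronModel(comps, _INTERNEURON_PASSIVE, "basket")


def nonbasket() -> ReducedNeuronModel:
    """Non-basket interneuron archetype: 7 compartments, bitufted ~200 um."""
    comps = [_soma(12.0, 12.0)]
    dirs_up = [(0.25, 0, 1), (-0.25, 0, 1), (0, 0.25, 1)]
    dirs_dn = [(0.25, 0, -1), (-0.25, 0, -1), (0, -0.25, -1)]
    for i, d in enumerate(dirs_up + dirs_dn, start=1):
        c, _ = _seg(i, 0, (0, 0, 0), d, 190.0, 0.9, "basal")
        comps.append(c)
    return ReducedNeuronModel(comps, _INTERNEURON_PASSIVE, "nonbasket")


CELL_BUILDERS = {
    "l23_pyramid": l23_pyramid,
    "l4_stellate": l4_stellate,
    "l4_pyramid": l4_pyramid,
    "l5_pyramid": l5_pyramid,
    "l6_pyramid": l6_pyramid,
    "basket": basket,
    "nonbasket": nonbasket,
}


def make_cell(name: str) -> ReducedNeuronModel:
    """Return a fresh instance of a named archetype cell."""
    try:
        return CELL_BUILDERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown cell archetype {name!r}; available: {sorted(CELL_BUILDERS)}"
        ) from None
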