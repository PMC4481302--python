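"""LFP magnitude and spatial range of a passive pyramidal population.

A scaled version of the population validation experiment: passive layer-2/3
pyramidal models in a 1-mm-radius cylinder, each with 1,000 current-based
synapses (50 pA, tau = 2 ms) driven by independent 5-Hz Poisson trains.
The LFP magnitude (signal standard deviation) is measured at the population
centre as a function of population radius; the spatial range is the radius
at which it reaches 95% of its 1-mm value.  With uncorrelated inputs the
range is smallest — and the magnitude largest — at the soma layer.
"""

from cortexlfp.analysis import run_population_sweep

res = run_population_sweep(
    "l23_pyramid", n_neurons=500, duration=650.0, discard=150.0, seed=7,
)

print("depth (um)   magnitude at 1 mm (uV)   range (um)")
for i, depth in enumerate(res.depths):
    marker = "  <- soma layer" if i == res.soma_depth_index else ""
    print(f"{depth:+9.0f}   {res.magnitudes[i, -1]:20.4f}   {res.ranges[i]:8.1f}{marker}")
print()
print("The soma-layer range is the smallest: with uncorrelated inputs,")
print("distant neurons contribute almost nothing to the centre electrode at")
print("soma depth.  At full scale (thousands of neurons, as in the test")
print("suite) the soma-layer magnitude is also the largest across depths;")
print("at this demonstration size that ordering is still noisy.")
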