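"""Simulate the sequential photocycle and inspect its apparent lifetimes.

Builds the default five-phase inward-pump photocycle (K -> L -> M1 -> M2 ->
P13C -> ground), propagates the populations analytically, and prints the
apparent time constants together with the population of the long-lived
13-cis state at the end of the 2 s observation window.
"""

import numpy as np

import photokin as pk

scheme = pk.default_scheme()
K = pk.build_rate_matrix(scheme)

print("states:", K.states)
print("apparent time constants (s):", pk.apparent_time_constants(K))

p0 = np.zeros(K.n_states)
p0[0] = 1.0  # flash puts every cycling molecule into K
times = pk.kinetics.log_time_grid()
pops = pk.propagate_populations(K, p0, times)

i_p13c = K.states.index("P13C")
print(f"P13C population at t = {times[-1]:.1f} s: {pops[-1, i_p13c]:.4f}")
print("-> all fast phases are complete by 2 s; only the 91 s thermal")
print("   13-cis -> all-trans reversion remains, seen as a standing offset.")
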