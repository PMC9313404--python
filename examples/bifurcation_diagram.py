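"""Equilibrium continuation and bifurcation points versus B/A.

Sweeps the inhibition/excitation ratio, counts fixed points and their
stability, and locates the Andronov-Hopf (AH), saddle-node (SN) and
saddle-saddle (SS) bifurcations that delimit the dynamical regimes.
"""

from epikf import ModelParameters, continue_equilibria, detect_bifurcations

params = ModelParameters()  # A = 5, standard constants
branch = continue_equilibria(params, ratio_range=(1.0, 15.0), n_points=1000)

for kind, ratio in detect_bifurcations(branch):
    print(f"{kind}: B/A = {ratio:.3f}")

counts = branch.counts()
print(f"fixed-point count over the sweep: min {counts.min()}, max {counts.max()}")

# Below AH the single fixed point is stable; between AH and SN a limit
# cycle (rhythmic spiking) exists; between SN and SS three fixed points
# coexist and input noise can kick the state into spiking; beyond SS only
# the stable node remains and activity is normal background fluctuation.
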