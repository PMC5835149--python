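"""Dominant spectrum of the circular seven-well diffusion, two ways.

V(x) = cos(7 atan2(x2, x1)) + 10 (|x| - 1)^2 at beta = 2 has seven wells
on the unit circle.  The transfer-operator spectrum at lag 0.1 shows seven
eigenvalues near one (one per well) separated by a deep gap from the rest;
the implied timescales t_i = -t / log(lambda_i) quantify the well-hopping
kinetics.

Route 1: deterministic finite-difference discretization of the generator
L = -grad V . grad + (1/beta) Laplace on an 80x80 grid.
Route 2: Ulam transition counting on a 10^6-step Euler-Maruyama
trajectory over a 40x40 box partition (about 40 s); this is the estimate
a simulation practitioner would produce, and carries the integrator and
discretization bias of that procedure.
"""

import numpy as np

import tmrc

pot = tmrc.make_potential("circular_well", k=7)
BETA = 2.0

gen = tmrc.generator_spectrum(pot, BETA, [-2, -2], [2, 2], [80, 80], lag=0.1, m=10)
print("generator route:")
print("  eigenvalues:", np.array2string(gen.eigenvalues, precision=4))
print("  timescales :", np.array2string(gen.implied_timescales[1:], precision=3))
print("  dominant count:", gen.dominant_count)

spec = tmrc.IntegratorSpec(dt=1e-2, beta=BETA, seed=42)
traj = tmrc.simulate_trajectory(pot, spec, [1.0, 0.0], 10_000.0, stride=1e-2)
part = tmrc.BoxPartition([-2, -2], [2, 2], [40, 40])
ulam = tmrc.spectrum(tmrc.ulam_full(traj, part, lag=0.1, symmetrize=True), 10)
print("trajectory Ulam route:")
print("  eigenvalues:", np.array2string(ulam.eigenvalues, precision=4))
print("  timescales :", np.array2string(ulam.implied_timescales[1:], precision=3))
print("  dominant count:", ulam.dominant_count)
print()
print("both routes show 7 dominant eigenvalues (the seven wells); the")
print("slowest non-dominant timescale (index 7, intra-well relaxation)")
print("is ~0.05, fixed by the radial curvature 20 of the confinement.")
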