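"""Validate a reaction coordinate by its projected transfer spectrum.

A coordinate is good if projecting the dynamics onto its level sets keeps
the dominant transfer-operator eigenvalues.  Here the double-well
coordinate xi_bar from the burst pipeline is compared against two
hand-picked alternatives, zeta1 = x1 and zeta2 = x1 + x2: each candidate
is binned into 40 intervals, lag-1 transitions of a long equilibrium
trajectory are counted between bins, and the resulting spectra are
compared with the full-space 40x30-box reference.

Runs in about two minutes (reduced grid/burst sizes; the tests use the
full setting).
"""

import numpy as np

import tmrc

BETA = 2.0
pot = tmrc.make_potential("double_well")

config = tmrc.PipelineConfig(
    potential="double_well", beta=BETA, lag=2.0, dt=1e-3, M=300, r=1, r_out=1,
    eval_points={"mode": "grid", "lower": [-2, -1], "upper": [2, 2],
                 "counts": [24, 18]},
    observables={"mode": "explicit",
                 "coefficients": tmrc.DOUBLE_WELL_COEFFICIENTS.tolist()},
    seed=7,
)
field = tmrc.compute_rc(config)

spec = tmrc.IntegratorSpec(dt=1e-2, beta=BETA, seed=123)
traj = tmrc.simulate_trajectory(pot, spec, [1.0, 0.0], 10_000.0, stride=1e-2)

part = tmrc.BoxPartition([-2, -1], [2, 2], [40, 30])
reference = tmrc.spectrum(tmrc.ulam_full(traj, part, 1.0, symmetrize=True), 6)
print("full-space eigenvalues:",
      np.array2string(reference.eigenvalues, precision=4))

table = tmrc.compare_coordinates(
    traj,
    {
        "xi_bar": tmrc.extend_rc(field, traj.states, method="nearest"),
        "zeta1": traj.states[:, 0],
        "zeta2": traj.states[:, 0] + traj.states[:, 1],
    },
    n_bins=40, lag=1.0, m=6, reference=reference,
)
print(table.round(4).to_string())
print()
print("abs_err_1 is the loss of the slow eigenvalue under projection:")
print("xi_bar and zeta1 preserve it to ~0.01, the skewed zeta2 loses ~0.1,")
print("so the computed coordinate matches the best hand-picked one.")
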