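"""Identify the reaction coordinate of a curved double well from bursts.

The curved double well V(x) = (x1^2-1)^2 + 2(x1^2+x2-1)^2 at inverse
temperature beta = 2 has two metastable wells at (+-1, 0) joined by the
parabolic transition path x2 = 1 - x1^2.  The pipeline embeds each grid
point's lag-2 transition density through three fixed linear observables
(Monte-Carlo burst averages), parametrizes the embedded cloud with a
diffusion map, and reads off the one-component coordinate xi_bar.

The analytic reference coordinate xi*(x) = x1 exp(-2 x2) is known to
reproduce the slow dynamics; a |Spearman rho| near 1 against xi_bar means
both order the state space identically, i.e. they share level sets.

Reduced scale for a quick run: 24x18 grid, M = 300 bursts per point
(about half a minute); the package tests use the full 40x30 / M = 1000.
"""

import numpy as np
from scipy.stats import spearmanr

import tmrc

config = tmrc.PipelineConfig(
    potential="double_well",
    beta=2.0,
    lag=2.0,
    dt=1e-3,
    M=300,
    r=1,          # one slow coordinate expected -> 2r+1 = 3 observables
    r_out=1,
    eval_points={"mode": "grid", "lower": [-2, -1], "upper": [2, 2],
                 "counts": [24, 18]},
    observables={"mode": "explicit",
                 "coefficients": tmrc.DOUBLE_WELL_COEFFICIENTS.tolist()},
    seed=7,
)

field = tmrc.compute_rc(config)
gammas = field.dm_model.eigenvalues
pts = field.eval_points
xi_star = pts[:, 0] * np.exp(-2 * pts[:, 1])
rho = spearmanr(field.rc_values[:, 0], xi_star).statistic

print(f"embedded cloud: {field.embedded.points.shape[0]} points in R^3, "
      f"mean MC stderr {field.embedded.mc_stderr.mean():.4f}")
print(f"diffusion-map eigenvalues: {np.array2string(gammas, precision=3)}")
print(f"Spearman(xi_bar, x1*exp(-2 x2)) = {rho:+.4f}")
print()
print("gamma_1 well separated from gamma_2 says the cloud is effectively")
print("one-dimensional; |rho| near 1 says xi_bar shares its level sets")
print("with the analytic reference coordinate.")
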