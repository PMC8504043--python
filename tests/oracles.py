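"""Independent reference computations used to check the model code."""

import numpy as np
from scipy import special

from rxqual.glmm import beta_logpdf_mean_precision


def brute_force_marginal_loglik(y, design, beta, sigma, phi, n_grid=10_001, width=10.0):
    """Marginal log-likelihood by dense trapezoidal integration over b.

    Deliberately naive: loops patients and grid points, integrating the joint
    density of each patient's observations against the normal random-effect
    density on a wide regular grid (±width·sigma).
    """
    eta0 = design.X @ np.asarray(beta, float)
    y = np.asarray(y, float)
    total = 0.0
    grid = np.linspace(-width * sigma, width * sigma, n_grid)
    log_norm = -0.5 * grid**2 / sigma**2 - 0.5 * np.log(2 * np.pi) - np.log(sigma)
    for i in range(design.n_patients):
        mask = design.patient_codes == i
        log_joint = np.array([
            beta_logpdf_mean_precision(y[mask], special.expit(eta0[mask] + b), phi).sum()
            for b in grid
        ])
        total += np.log(np.trapezoid(np.exp(log_joint + log_norm), grid))
    return total
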