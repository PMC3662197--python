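"""Independent reference computations used by several test modules."""

import numpy as np
from scipy.integrate import solve_ivp


def ode_alpha(t_grid, alpha1, k1, k2, rtol=1e-12, atol=1e-14):
    """Residual activity by numerical integration of the two-state system
    E0' = -k1 E0, E1' = k1 E0 - k2 E1 with E0(0) = 1, E1(0) = 0 and
    alpha = E0 + alpha1 E1.  Independent of the closed-form code path."""
    sol = solve_ivp(
        lambda _, y: [-k1 * y[0], k1 * y[0] - k2 * y[1]],
        (0.0, float(np.max(t_grid))), [1.0, 0.0],
        t_eval=np.atleast_1d(t_grid), method="Radau", rtol=rtol, atol=atol,
    )
    return sol.y[0] + alpha1 * sol.y[1]
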