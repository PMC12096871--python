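"""Independent brute-force oracles shared by the test modules."""
import numpy as np
from scipy.optimize import LinearConstraint, minimize


def pol1b_qp(x: np.ndarray, r: float) -> np.ndarray:
    """min ||y - x||^2 s.t. y >= 0, sum y <= r, via a generic QP solver."""
    x = np.asarray(x, dtype=float)
    x0 = np.clip(x, 0, None)
    s = x0.sum()
    if s > r > 0:
        x0 = x0 * (r / s)
    res = minimize(
        lambda y: 0.5 * np.sum((y - x) ** 2),
        x0,
        jac=lambda y: y - x,
        bounds=[(0, None)] * x.size,
        constraints=[LinearConstraint(np.ones((1, x.size)), -np.inf, r)],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.x
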