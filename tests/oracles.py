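"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity from its defining formula by a route
disjoint from the package code: the JZS Bayes factor via Gauss-Legendre
quadrature of the g-prior integral, Cook's distance via explicit
leave-one-out refits, and the moving RMS via naive per-sample windowing.
"""

import math

import numpy as np


def jzs_bf10_g_integral(t: float, n: int, r: float = 0.707, nodes: int = 4000) -> float:
    """JZS BF10 by quadrature of the inverse-gamma mixture over g.

    Marginal likelihood under H1: integral over g of
    (1+Ngr^2)^(-1/2) * (1 + t^2/((1+Ngr^2)*nu))^(-(nu+1)/2) against the
    InvGamma(1/2, 1/2) density, mapped to (0,1) via u = g/(1+g) and
    evaluated with a fine Gauss-Legendre rule.
    """
    nu = n - 1
    x, w = np.polynomial.legendre.leggauss(nodes)
    u = 0.5 * (x + 1.0)
    g = u / (1.0 - u)
    jac = 0.5 / (1.0 - u) ** 2
    a = 1.0 + n * g * r * r
    integrand = (
        a**-0.5
        * (1.0 + t * t / (a * nu)) ** (-(nu + 1) / 2.0)
        * (2.0 * math.pi) ** -0.5
        * g**-1.5
        * np.exp(-1.0 / (2.0 * g))
    )
    numerator = float(np.sum(w * integrand * jac))
    denominator = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return numerator / denominator


def cooks_d_leave_one_out(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's distance from its definition: the scaled shift of all fitted
    values when each point is deleted and the regression refitted."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    fitted = X @ beta
    resid = y - fitted
    p = 2
    s2 = float(resid @ resid) / (n - p)
    d = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
        shift = X @ beta - X @ beta_i
        d[i] = float(shift @ shift) / (p * s2)
    return d


def moving_rms_naive(x: np.ndarray, k: int) -> np.ndarray:
    """Centered moving RMS with edge-truncated windows, one sample at a time."""
    x = np.asarray(x, float)
    n = x.size
    half = k // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i + (k - half), n)
        out[i] = math.sqrt(np.mean(x[lo:hi] ** 2))
    return out
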