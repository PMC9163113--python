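"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different computational route from the
code under test: trapezoidal integration instead of the recursive filter,
continuous nonlinear optimisation instead of the basis grid, and full
enumeration instead of analytic distributions.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize_scalar, nnls


def conv_exp_trapezoid(x: np.ndarray, t: np.ndarray, lam: float) -> np.ndarray:
    """integral_0^t x(s) e^{-lam (t-s)} ds via exp-weighted trapezoids."""
    if lam == 0:
        return cumulative_trapezoid(x, t, initial=0.0)
    # y(t) = e^{-lam t} * integral e^{lam s} x(s) ds  (lam*t <= ~30 here)
    inner = cumulative_trapezoid(np.exp(lam * t) * x, t, initial=0.0)
    return np.exp(-lam * t) * inner


def frame_means(values: np.ndarray, t: np.ndarray, starts, ends) -> np.ndarray:
    out = []
    for s, e in zip(starts, ends):
        sel = (t >= s - 1e-9) & (t < e - 1e-9)
        out.append(values[sel].mean())
    return np.asarray(out)


def brute_force_fit(
    tac: np.ndarray,
    c_a: np.ndarray,
    c_rv: np.ndarray,
    t: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    weights: np.ndarray,
    v_d: float = 0.91,
    mbf_bounds: tuple[float, float] = (0.2, 6.0),
) -> tuple[float, float, float, float]:
    """Continuous nonlinear least-squares fit of the compartment model.

    Profiles the washout rate by bounded scalar minimisation (golden-section
    refinement) with a non-negative linear solve at each candidate rate.
    Returns (mbf, ptf, v_a, v_rv).
    """
    sw = np.sqrt(weights)
    fca = frame_means(c_a, t, starts, ends)
    fcrv = frame_means(c_rv, t, starts, ends)

    def profile(mbf: float) -> tuple[float, np.ndarray]:
        lam = mbf / (60.0 * v_d)
        conv = conv_exp_trapezoid(c_a, t, lam)
        fconv = frame_means(conv, t, starts, ends)
        X = np.column_stack([fconv, fca, fcrv]) * sw[:, None]
        coef, _ = nnls(X, tac * sw)
        resid = tac * sw - X @ coef
        return float(resid @ resid), coef

    res = minimize_scalar(
        lambda m: profile(m)[0],
        bounds=mbf_bounds,
        method="bounded",
        options={"xatol": 1e-6},
    )
    mbf = float(res.x)
    _, coef = profile(mbf)
    a, v_a, v_rv = coef
    ptf = a / (mbf / 60.0) if mbf > 0 else 0.0
    return mbf, ptf, float(v_a), float(v_rv)


def nnls_at_mbf(
    tac: np.ndarray,
    c_a: np.ndarray,
    c_rv: np.ndarray,
    t: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    weights: np.ndarray,
    mbf: float,
    v_d: float = 0.91,
) -> tuple[float, float, float]:
    """Non-negative linear solve of the model at a fixed washout rate.

    Independent route (trapezoid convolution + scipy NNLS) for the linear
    stage of the basis-function method; returns (ptf, v_a, v_rv).
    """
    sw = np.sqrt(weights)
    lam = mbf / (60.0 * v_d)
    conv = conv_exp_trapezoid(c_a, t, lam)
    X = np.column_stack(
        [
            frame_means(conv, t, starts, ends),
            frame_means(c_a, t, starts, ends),
            frame_means(c_rv, t, starts, ends),
        ]
    ) * sw[:, None]
    coef, _ = nnls(X, tac * sw)
    a, v_a, v_rv = coef
    ptf = a / (mbf / 60.0) if mbf > 0 else 0.0
    return float(ptf), float(v_a), float(v_rv)


def wilcoxon_brute_force(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by explicit 2^n enumeration.

    Independent re-derivation (python loop, itertools) of the null
    distribution of the positive-rank sum, midranks for ties.
    """
    from itertools import product

    from scipy.stats import rankdata

    d = np.asarray(y, float) - np.asarray(x, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    hi, lo = max(w, total - w), min(w, total - w)
    count = 0
    for signs in product((0, 1), repeat=n):
        ws = sum(r for s, r in zip(signs, ranks) if s)
        if ws >= hi - 1e-9 or ws <= lo + 1e-9:
            count += 1
    return w, min(count / 2.0**n, 1.0)


def icc_a1_pingouin(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(A,1) via pingouin's ICC2 (two-way random, absolute agreement)."""
    import pandas as pd
    import pingouin as pg

    n = len(x)
    df = pd.DataFrame(
        {
            "subject": list(range(n)) * 2,
            "rater": ["a"] * n + ["b"] * n,
            "score": np.concatenate([x, y]),
        }
    )
    icc = pg.intraclass_corr(
        data=df, targets="subject", raters="rater", ratings="score"
    )
    icc = icc.set_index("Type")
    key = "ICC(A,1)" if "ICC(A,1)" in icc.index else "ICC2"
    return float(icc.loc[key, "ICC"])
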