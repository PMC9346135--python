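"""Independent brute-force oracles used by the test suite.

Each function recomputes a pipeline quantity by the most direct method
available (nested loops, exhaustive scans, dense quadrature, explicit
nested least squares) without touching the implementation under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def windowed_mean_loop(grid: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Shrinking-window 2D moving average by explicit nested loops."""
    grid = np.asarray(grid, dtype=float)
    hb, hl = window[0] // 2, window[1] // 2
    out = np.empty_like(grid)
    nb, nl = grid.shape
    for i in range(nb):
        for j in range(nl):
            block = grid[max(0, i - hb): i + hb + 1, max(0, j - hl): j + hl + 1]
            out[i, j] = block.mean()
    return out


def exhaustive_nulla(values: np.ndarray, tol: float = 1e-9):
    """Deepest point by scanning every grid cell; centroid of exact ties."""
    values = np.asarray(values, dtype=float)
    depth = -np.inf
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            depth = max(depth, values[i, j])
    tied = [
        (i, j)
        for i in range(values.shape[0])
        for j in range(values.shape[1])
        if values[i, j] >= depth - tol
    ]
    bs = sum(t[0] for t in tied) / len(tied)
    lat = sum(t[1] for t in tied) / len(tied)
    return bs, lat, depth, len(tied)


def dense_area(thickness_fn, x1_um: float, x2_um: float, n: int = 1000) -> float:
    """Area by trapezoid quadrature of the thickness on a dense grid."""
    xs = np.linspace(x1_um, x2_um, n + 1)
    ys = np.array([thickness_fn(x) for x in xs])
    return float(np.trapezoid(ys, xs))


def _sse(y: np.ndarray, x: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def anova_type2_nested_ols(
    data: pd.DataFrame, response: str, factors: tuple[str, str]
) -> dict:
    """Type-II two-way ANOVA via explicit nested least-squares fits.

    SS(A|B) = SSE(intercept + B) - SSE(intercept + A + B); F compares the
    factor mean square to the residual mean square of the additive model.
    """
    from scipy import stats as sps

    y = data[response].to_numpy(dtype=float)
    n = len(y)
    ones = np.ones((n, 1))

    def dummies(factor: str) -> np.ndarray:
        return pd.get_dummies(data[factor], drop_first=True).to_numpy(dtype=float)

    xa, xb = dummies(factors[0]), dummies(factors[1])
    full = np.hstack([ones, xa, xb])
    sse_full = _sse(y, full)
    df_res = n - full.shape[1]
    out = {"residual_ss": sse_full, "residual_df": df_res}
    for name, own, other in ((factors[0], xa, xb), (factors[1], xb, xa)):
        sse_reduced = _sse(y, np.hstack([ones, other]))
        ss = sse_reduced - sse_full
        df = own.shape[1]
        f_stat = (ss / df) / (sse_full / df_res)
        p = float(sps.f.sf(f_stat, df, df_res))
        out[name] = (ss, df, f_stat, p)
    return out


def pearson_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from the explicit covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
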