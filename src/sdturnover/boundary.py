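"""Turnover-boundary estimation from sweep outcomes.

The object of interest is the curve in the (s_Y, s_new) plane separating
parameter combinations where the ancestral SD system is maintained
(outcome 0) from those where the novel SD gene takes over (outcome 1),
optionally resolved along the epistasis effect size epsilon.

The binary outcomes are smoothed into a probability-of-turnover surface
with a local-linear kernel smoother (Gaussian product kernel over s_Y,
s_new and, when it varies, epsilon; the local intercept is the estimate,
which removes the first-order edge bias a plain Nadaraya-Watson average
has at the sampled range's borders), and the boundary is the
0.5-probability level set.  Crossings are extracted per s_Y grid column by
linear interpolation, which yields the boundary as polyline vertices and
naturally returns several branches where the boundary is non-monotone (as
happens under coadaptation epistasis).  The smoother is weight-based, so
duplicating every record leaves the estimate unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["turnover_probability", "estimate_boundary"]


def _default_bandwidth(values: np.ndarray) -> float:
    span = float(values.max() - values.min())
    n = len(values)
    return max(span * n ** -0.25, 1e-12)


def _check_records(records: pd.DataFrame):
    needed = {"s_Y", "s_new", "outcome_bit"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns {sorted(missing)}")
    ok = records[records["outcome_bit"].isin([0, 1])]
    if len(ok) < len(records):
        ok = ok.copy()
    classes = set(ok["outcome_bit"].unique())
    if classes != {0, 1}:
        raise ValueError(
            "both outcome classes are required to estimate a boundary; "
            f"got classes {sorted(classes)}"
        )
    return ok


def turnover_probability(
    records: pd.DataFrame,
    s_y_grid: np.ndarray,
    s_new_grid: np.ndarray,
    epsilon: float = None,
    bandwidth: float = None,
    eps_bandwidth: float = None,
) -> np.ndarray:
    """Smoothed P(turnover) on the grid; shape (len(s_y_grid), len(s_new_grid)).

    ``epsilon`` conditions the estimate on one epsilon value via a third
    kernel dimension; omit it (or pass records with constant epsilon) for a
    plain 2-D fit.
    """
    ok = _check_records(records)
    # aggregate exact duplicates into integer weights so that replicating the
    # whole table rescales every sum by the same factor (exact invariance)
    cols = ["s_Y", "s_new", "outcome_bit"]
    if "epsilon" in ok.columns:
        cols.append("epsilon")
    grouped = ok.groupby(cols, sort=True).size().reset_index(name="weight")
    x = grouped["s_Y"].to_numpy(float)
    y = grouped["s_new"].to_numpy(float)
    b = grouped["outcome_bit"].to_numpy(float)
    counts = grouped["weight"].to_numpy(float)
    # bandwidths scale with the number of distinct sampled points, so exact
    # replication of the table leaves the estimate unchanged
    hx = bandwidth if bandwidth is not None else _default_bandwidth(x)
    hy = bandwidth if bandwidth is not None else _default_bandwidth(y)
    shape = (len(s_y_grid), len(s_new_grid))
    # standardized offsets of each record from each grid point
    dx = (s_y_grid[:, None, None] - x[None, None, :]) / hx
    dy = (s_new_grid[None, :, None] - y[None, None, :]) / hy
    dx, dy = np.broadcast_arrays(dx, dy)
    offsets = [dx.reshape(-1, len(x)), dy.reshape(-1, len(x))]
    logw = -0.5 * (offsets[0] ** 2 + offsets[1] ** 2)
    if epsilon is not None and "epsilon" in grouped.columns:
        e = grouped["epsilon"].to_numpy(float)
        if e.max() - e.min() > 0:
            he = eps_bandwidth if eps_bandwidth is not None else _default_bandwidth(e)
            de = np.broadcast_to((epsilon - e[None, :]) / he, logw.shape)
            offsets.append(de)
            logw = logw - 0.5 * de**2
    w = np.exp(logw - logw.max(axis=1, keepdims=True)) * counts[None, :]
    # local-linear fit: weighted LS of b on [1, dx, dy(, de)] at each grid point
    design = np.stack([np.ones_like(w)] + offsets, axis=2)  # (G, n, k)
    wd = w[:, :, None] * design
    XtWX = np.einsum("gnk,gnl->gkl", design, wd)
    XtWb = np.einsum("gnk,n->gk", wd, b)
    k = design.shape[2]
    # tiny ridge on the slope terms guards grid points with one-sided data
    ridge = np.zeros(k)
    ridge[1:] = 1e-8
    XtWX = XtWX + np.diag(ridge)[None, :, :] * XtWX[:, :1, :1]
    beta = np.linalg.solve(XtWX, XtWb[:, :, None])[:, :, 0]
    return beta[:, 0].reshape(shape)


def _column_crossings(s_new_grid: np.ndarray, p_col: np.ndarray):
    """s_new values where the smoothed probability crosses 0.5 (interpolated)."""
    d = p_col - 0.5
    out = []
    for j in range(len(d) - 1):
        a, bb = d[j], d[j + 1]
        if a == 0.0:
            out.append(float(s_new_grid[j]))
        elif a * bb < 0.0:
            t = a / (a - bb)
            out.append(float(s_new_grid[j] + t * (s_new_grid[j + 1] - s_new_grid[j])))
    if d[-1] == 0.0:
        out.append(float(s_new_grid[-1]))
    return out


def estimate_boundary(
    records: pd.DataFrame,
    epsilon_slices=None,
    grid_size: int = 26,
    s_y_grid: np.ndarray = None,
    s_new_grid: np.ndarray = None,
    bandwidth: float = None,
    eps_bandwidth: float = None,
) -> pd.DataFrame:
    """0.5-probability turnover boundary per epsilon slice.

    Returns a table with columns ``epsilon, s_Y, s_new_boundary, branch``;
    ``branch`` numbers the crossings from below within each s_Y column, so a
    monotone boundary has a single branch 0.  Requires both outcome classes.
    """
    ok = _check_records(records)
    if s_y_grid is None:
        s_y_grid = np.linspace(ok["s_Y"].min(), ok["s_Y"].max(), grid_size)
    if s_new_grid is None:
        s_new_grid = np.linspace(ok["s_new"].min(), ok["s_new"].max(), grid_size)
    s_y_grid = np.asarray(s_y_grid, float)
    s_new_grid = np.asarray(s_new_grid, float)
    if epsilon_slices is None:
        slices = [None]
    else:
        slices = list(np.atleast_1d(epsilon_slices).astype(float))
    rows = []
    for eps in slices:
        p = turnover_probability(
            ok, s_y_grid, s_new_grid, epsilon=eps,
            bandwidth=bandwidth, eps_bandwidth=eps_bandwidth,
        )
        for i, sy in enumerate(s_y_grid):
            for branch, crossing in enumerate(_column_crossings(s_new_grid, p[i])):
                rows.append(
                    {
                        "epsilon": np.nan if eps is None else eps,
                        "s_Y": float(sy),
                        "s_new_boundary": crossing,
                        "branch": branch,
                    }
                )
    return pd.DataFrame(rows, columns=["epsilon", "s_Y", "s_new_boundary", "branch"])
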