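"""Two-segment linear (breakpoint) model for the temperature–assimilation
relationship.

The response follows one straight line below a join point γ and another
above it. Two parameterizations are supported:

* ``continuous`` (default): standard segmented regression,
      y = β0 + β1·x               for x ≤ γ
      y = β0 + β1·γ + β2·(x − γ)  for x > γ,
  continuous at γ. With β1 = β2 this family nests the single line, so the
  minimized SSE can never exceed the best single-line SSE.
* ``literal``: the discontinuous indicator form
      y = β0 + β1·x·I(x < γ) + β2·x·I(x > γ),
  kept for fidelity comparisons.

γ is estimated by exhaustive profile search: for every candidate on a
regular grid the conditional least-squares problem in (β0, β1, β2) is
solved in closed form and the γ with the smallest SSE wins (ties toward
the smallest γ). The grid covers the central part of the observed x range
so that at least two points lie on each side of every candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SegmentedError(ValueError):
    pass


@dataclass
class SegmentedFit:
    beta0: float
    beta1: float
    beta2: float
    gamma: float
    sse: float
    mode: str = "continuous"
    grid_step: float = 0.01
    single_line_sse: float = np.nan
    slope2_se: float = np.nan
    flags: list[str] = field(default_factory=list)
    profile: tuple[np.ndarray, np.ndarray] | None = None  # (gamma grid, SSE)


def two_segment_predict(x, fit: SegmentedFit):
    """Evaluate the fitted two-segment model at x."""
    x = np.asarray(x, dtype=float)
    if fit.mode == "continuous":
        return fit.beta0 + fit.beta1 * np.minimum(x, fit.gamma) \
            + fit.beta2 * np.maximum(x - fit.gamma, 0.0)
    if fit.mode == "literal":
        return fit.beta0 + fit.beta1 * x * (x < fit.gamma) \
            + fit.beta2 * x * (x > fit.gamma)
    raise ValueError(f"unknown mode {fit.mode!r}")


def _design(x: np.ndarray, gamma: float, mode: str) -> np.ndarray:
    if mode == "continuous":
        return np.column_stack([
            np.ones_like(x), np.minimum(x, gamma), np.maximum(x - gamma, 0.0),
        ])
    return np.column_stack([
        np.ones_like(x), x * (x < gamma), x * (x > gamma),
    ])


def _profile_sse_continuous(x: np.ndarray, y: np.ndarray,
                            grid: np.ndarray) -> np.ndarray:
    """Vectorized conditional SSE over the γ grid (continuous mode).

    Builds the 3×3 normal equations for every candidate at once; the only
    γ-dependent regressor is the hinge h = max(x − γ, 0); the continuous
    design (1, min(x, γ), h) equals (1, x − h, h), so all moments follow
    from fixed sums and hinge sums.
    """
    n = x.size
    H = np.maximum(x[None, :] - grid[:, None], 0.0)  # (G, n)
    s1 = np.full(grid.size, float(n))
    sx = np.full(grid.size, x.sum())
    sy = np.full(grid.size, y.sum())
    sxx = np.full(grid.size, (x * x).sum())
    sxy = np.full(grid.size, (x * y).sum())
    sh = H.sum(axis=1)
    shh = (H * H).sum(axis=1)
    shx = H @ x
    shy = H @ y
    # regressors: u = x - h, v = h
    su = sx - sh
    suu = sxx - 2 * shx + shh
    suv = shx - shh
    suy = sxy - shy
    G = grid.size
    A = np.empty((G, 3, 3))
    b = np.empty((G, 3))
    A[:, 0, 0] = s1; A[:, 0, 1] = su; A[:, 0, 2] = sh
    A[:, 1, 0] = su; A[:, 1, 1] = suu; A[:, 1, 2] = suv
    A[:, 2, 0] = sh; A[:, 2, 1] = suv; A[:, 2, 2] = shh
    b[:, 0] = sy; b[:, 1] = suy; b[:, 2] = shy
    yy = float(y @ y)
    sse = np.empty(G)
    try:
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        sse = yy - np.einsum("gi,gi->g", beta, b)
    except np.linalg.LinAlgError:
        for g in range(G):
            beta_g, res, *_ = np.linalg.lstsq(_design(x, grid[g], "continuous"),
                                              y, rcond=None)
            r = y - _design(x, grid[g], "continuous") @ beta_g
            sse[g] = float(r @ r)
    return np.maximum(sse, 0.0)


def gamma_grid(x: np.ndarray, step: float, margin: float = 0.05) -> np.ndarray:
    """Candidate join points: a regular grid over the central x range,
    trimmed so ≥ 2 observations lie strictly on each side of any candidate."""
    xs = np.sort(x)
    lo = max(xs[0] + margin * (xs[-1] - xs[0]), xs[1])
    hi = min(xs[-1] - margin * (xs[-1] - xs[0]), xs[-2])
    if hi <= lo:
        raise SegmentedError("x range too narrow for a join-point search")
    start = np.ceil(lo / step) * step
    return np.arange(start, hi + step / 2, step)


def fit_two_segment(x, y, grid_step: float = 0.01, margin: float = 0.05,
                    mode: str = "continuous",
                    flat_tol: float = 1e-10) -> SegmentedFit:
    """Profile-search fit of the two-segment model.

    Returns the γ (and conditional β's) minimizing the SSE over the grid,
    ties broken toward the smallest γ. Truly linear data leave the SSE
    profile flat; the fit is then returned with an
    ``unidentifiable_join_point`` flag rather than an arbitrary winner.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 8:
        raise SegmentedError(f"need at least 8 points, got {x.size}")
    if np.ptp(x) == 0:
        raise SegmentedError("x has zero variance")
    grid = gamma_grid(x, grid_step, margin)

    if mode == "continuous":
        sse = _profile_sse_continuous(x, y, grid)
    else:
        sse = np.empty(grid.size)
        for g, gam in enumerate(grid):
            X = _design(x, gam, mode)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            sse[g] = float(r @ r)

    i = int(np.argmin(sse))  # argmin returns the first (smallest γ) on ties
    gam = float(grid[i])
    X = _design(x, gam, mode)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    best_sse = float(resid @ resid)

    # single straight line for reference (nested in the continuous family)
    Xl = np.column_stack([np.ones_like(x), x])
    bl, *_ = np.linalg.lstsq(Xl, y, rcond=None)
    rl = y - Xl @ bl
    line_sse = float(rl @ rl)

    fit = SegmentedFit(
        beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]),
        gamma=gam, sse=best_sse, mode=mode, grid_step=grid_step,
        single_line_sse=line_sse, profile=(grid, sse),
    )
    # a flat SSE profile (relative to the response's total variation)
    # means the data carry no information about the join point
    tss = float(((y - y.mean()) ** 2).sum())
    if np.ptp(sse) <= flat_tol * max(1.0, tss):
        fit.flags.append("unidentifiable_join_point")

    # conditional-on-γ̂ standard error for the upper slope
    dof = x.size - 3
    if dof > 0 and best_sse > 0:
        sigma2 = best_sse / dof
        try:
            cov = sigma2 * np.linalg.inv(X.T @ X)
            fit.slope2_se = float(np.sqrt(cov[2, 2]))
        except np.linalg.LinAlgError:
            pass
    return fit
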