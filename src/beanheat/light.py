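"""Photosynthetic light-response (A/PAR) curve model and fitting.

The working model is the rectangular hyperbola (Michaelis–Menten form) with
an explicit dark-respiration offset,

    A(Q) = Φ·Q·Amax / (Φ·Q + Amax) − Rd,

where Q is incident PAR (µmol photons m⁻² s⁻¹), Amax the asymptotic gross
light-saturated assimilation, Φ the apparent quantum efficiency (initial
slope) and Rd dark respiration. The light compensation point (LCP) and
light saturation point (LSP) are derived from the fitted parameters in
closed form. A nonrectangular hyperbola with curvature θ is available for
sensitivity checks but is not the default: on ten-point curves θ is weakly
identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """Raised when a curve fit fails or the data cannot identify a model."""


@dataclass
class LightResponseParams:
    """Fitted light-response parameters.

    Respiration is stored positive; the model subtracts it. ``rmse`` is the
    root-mean-square residual of the fit; ``lcp``/``lsp`` are derived, not
    free parameters.
    """

    amax: float
    phi: float
    rd: float
    lcp: float = np.nan
    lsp: float = np.nan
    rmse: float = np.nan
    n_points: int = 0
    genotype_id: str = ""
    flags: list[str] = field(default_factory=list)


def light_response_model(Q, amax: float, phi: float, rd: float):
    """Net assimilation at irradiance Q under the rectangular hyperbola.

    Strictly increasing in Q and bounded above by ``amax - rd``;
    A(0) = -rd.
    """
    Q = np.asarray(Q, dtype=float)
    gross = np.where(Q > 0, phi * Q * amax / (phi * Q + amax), 0.0)
    return gross - rd


def nonrectangular_model(Q, amax: float, phi: float, rd: float, theta: float):
    """Nonrectangular hyperbola with curvature theta in (0, 1)."""
    Q = np.asarray(Q, dtype=float)
    s = phi * Q + amax
    gross = (s - np.sqrt(s * s - 4.0 * theta * phi * Q * amax)) / (2.0 * theta)
    return gross - rd


def derive_lcp(p: LightResponseParams) -> float:
    """Light compensation point: the irradiance where net A crosses zero.

    Closed form LCP = Rd·Amax / (Φ·(Amax − Rd)); requires Rd < Amax,
    otherwise the curve never compensates respiration.
    """
    if p.rd == 0:
        return 0.0
    if p.rd >= p.amax:
        raise FitError(
            f"no light compensation point: Rd={p.rd} >= Amax={p.amax}"
        )
    return p.rd * p.amax / (p.phi * (p.amax - p.rd))


def derive_lsp(p: LightResponseParams, fraction: float = 0.90,
               cap: float = 1e6) -> float:
    """Irradiance at which gross assimilation reaches ``fraction``·Amax.

    LSP = fraction·Amax / ((1 − fraction)·Φ). Monotone increasing in the
    fraction; values above ``cap`` are reported as errors since the
    hyperbola saturates only asymptotically.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"lsp fraction must lie in (0, 1), got {fraction}")
    lsp = fraction * p.amax / ((1.0 - fraction) * p.phi)
    if lsp > cap:
        raise FitError(f"light saturation point {lsp:.3g} exceeds cap {cap:.3g}")
    return lsp


def _initial_guesses(Q: np.ndarray, A: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start grid seeded from slope heuristics."""
    rd0 = max(0.0, -float(A[np.argmin(Q)])) if Q.min() == 0 else max(0.0, -A.min())
    amax0 = float(A.max()) + rd0
    amax0 = max(amax0, 1e-3)
    low = Q[Q > 0]
    if low.size:
        ql = low.min()
        al = float(A[Q == ql][0])
        phi0 = max((al + rd0) / ql, 1e-4)
    else:
        phi0 = 0.05
    starts = []
    for fa in (0.8, 1.2):
        for fp in (0.5, 2.0):
            starts.append(np.array([amax0 * fa, phi0 * fp, rd0 + 0.1]))
    return starts


def fit_light_response(
    Q,
    A,
    lsp_fraction: float = 0.90,
    genotype_id: str = "",
) -> LightResponseParams:
    """Fit (Amax, Φ, Rd) to an A/PAR curve by bounded least squares.

    Uses a deterministic multi-start grid; ties in SSE are broken toward the
    smallest Amax. LCP and LSP are derived from the winning parameters.
    """
    Q = np.asarray(Q, dtype=float)
    A = np.asarray(A, dtype=float)
    if Q.size < 5:
        raise FitError(f"need at least 5 points, got {Q.size}")
    if np.unique(Q).size != Q.size or (Q < 0).any():
        raise FitError("PAR values must be distinct and non-negative")
    if np.ptp(A) < 1e-12:
        raise FitError("constant assimilation: light response unidentifiable")
    if (A <= 0).all():
        raise FitError("no positive assimilation values: curve unidentifiable")

    def resid(p):
        return light_response_model(Q, *p) - A

    bounds = (np.array([1e-6, 1e-8, 0.0]),
              np.array([500.0, 10.0, 50.0]))
    best = None
    for x0 in _initial_guesses(Q, A):
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(resid, x0, bounds=bounds, method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        key = (round(sse, 12), sol.x[0])
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise FitError("light-response fit did not converge from any start")
    sol = best[1]
    amax, phi, rd = map(float, sol.x)
    p = LightResponseParams(
        amax=amax, phi=phi, rd=rd,
        rmse=float(np.sqrt(np.mean(sol.fun**2))),
        n_points=int(Q.size), genotype_id=genotype_id,
    )
    try:
        p.lcp = derive_lcp(p)
    except FitError:
        p.flags.append("no_compensation_point")
    try:
        p.lsp = derive_lsp(p, lsp_fraction)
    except FitError:
        p.flags.append("lsp_above_cap")
    if not np.isnan(p.lcp) and not np.isnan(p.lsp) and p.lcp >= p.lsp:
        p.flags.append("lcp_above_lsp")
    return p
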