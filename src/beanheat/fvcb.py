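"""Farquhar–von Caemmerer–Berry (FvCB) A/Ci model and fitting.

Net assimilation is the minimum of two limitation curves,

    Ac = Vcmax·(Ci − Γ*) / (Ci + Kc·(1 + O/Ko)) − RD   (Rubisco-limited)
    Aj = J·(Ci − Γ*) / (4·Ci + 8·Γ*) − RD              (RuBP-regeneration-limited)
    A  = min(Ac, Aj),

with Γ* the CO2 compensation point without day respiration, Kc/Ko the
Michaelis constants for carboxylation/oxygenation, O the oxygen
concentration and RD day respiration (stored positive, subtracted by the
model). Curves are measured at saturating light, so J = Jmax by default;
an explicit light-modulated J is available via the ``j`` argument of
:func:`fvcb_model`. Triose-phosphate limitation and mesophyll conductance
are out of scope.

Kinetic constants default to the widely used tobacco-derived 25 °C values
(Γ* = 42.75 µmol mol⁻¹, Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹) and
are fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .light import FitError


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics at measurement temperature (default: 25 °C values)."""

    gamma_star: float = 42.75  # µmol mol⁻¹
    kc: float = 404.9          # µmol mol⁻¹
    ko: float = 278.4          # mmol mol⁻¹
    o: float = 210.0           # mmol mol⁻¹ (ambient O2)

    def __post_init__(self):
        for name in ("gamma_star", "kc", "ko", "o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc·(1 + O/Ko)."""
        return self.kc * (1.0 + self.o / self.ko)


@dataclass
class FvCBParams:
    vcmax: float
    jmax: float
    rd: float
    ci_transition: float = np.nan
    rmse: float = np.nan
    n_points: int = 0
    genotype_id: str = ""
    limitation_labels: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def rubisco_limited(Ci, vcmax: float, rd: float, k: KineticConstants):
    Ci = np.asarray(Ci, dtype=float)
    return vcmax * (Ci - k.gamma_star) / (Ci + k.km) - rd


def rubp_limited(Ci, j: float, rd: float, k: KineticConstants):
    Ci = np.asarray(Ci, dtype=float)
    return j * (Ci - k.gamma_star) / (4.0 * Ci + 8.0 * k.gamma_star) - rd


def fvcb_model(Ci, vcmax: float, jmax: float, rd: float,
               k: KineticConstants = KineticConstants(), j: float | None = None):
    """Evaluate the FvCB model: net A and per-point limitation labels.

    Returns ``(A, labels)`` where labels are 'rubisco' or 'rubp' according
    to which curve attains the minimum (ties labelled 'rubisco').
    A(Γ*) = −RD exactly in both branches.
    """
    jeff = jmax if j is None else j
    ac = rubisco_limited(Ci, vcmax, rd, k)
    aj = rubp_limited(Ci, jeff, rd, k)
    a = np.minimum(ac, aj)
    labels = np.where(ac <= aj, "rubisco", "rubp")
    return a, labels


def ci_transition_point(vcmax: float, jmax: float,
                        k: KineticConstants = KineticConstants()) -> float:
    """Ci at which the Rubisco- and RuBP-limited rates are equal.

    Solving Vcmax/(Ci + Km) = Jmax/(4·Ci + 8·Γ*) gives
    Ci* = (Jmax·Km − 8·Γ*·Vcmax) / (4·Vcmax − Jmax); infinite when the
    curves never cross (returned as +inf or −inf by branch dominance).
    """
    denom = 4.0 * vcmax - jmax
    if abs(denom) < 1e-12:
        return np.inf
    ci = (jmax * k.km - 8.0 * k.gamma_star * vcmax) / denom
    return float(ci)


def _aci_starts(Ci: np.ndarray, A: np.ndarray, k: KineticConstants) -> list[np.ndarray]:
    """Deterministic 8-point multi-start grid seeded from slope heuristics."""
    rd0 = max(0.0, -float(A.min()))
    low = Ci < 300
    if low.sum() >= 2:
        slope = np.polyfit(Ci[low], A[low], 1)[0]
        vc0 = max(float(slope) * (Ci[low].mean() + k.km), 5.0)
    else:
        vc0 = 50.0
    amax = float(A.max()) + rd0
    j0 = max(4.0 * amax, 10.0)
    starts = []
    for fv in (0.6, 1.5):
        for fj in (0.6, 1.5):
            starts.append(np.array([vc0 * fv, j0 * fj, rd0 + 0.5]))
    for fv in (1.0, 2.5):
        starts.append(np.array([vc0 * fv, j0, rd0 + 0.5]))
    starts.append(np.array([vc0, j0 * 2.5, rd0 + 0.5]))
    starts.append(np.array([30.0, 60.0, 1.0]))
    return starts


def fit_aci(
    Ci,
    A,
    k: KineticConstants = KineticConstants(),
    genotype_id: str = "",
) -> FvCBParams:
    """Fit (Vcmax, Jmax, RD) to an A/Ci curve by bounded least squares.

    Minimises squared residuals of :func:`fvcb_model` from a deterministic
    multi-start grid (ties broken by SSE then by lower Vcmax). The Ci
    transition point is solved from the fitted parameters; when every
    observation falls on one side of it, the parameter that only the other
    side informs is flagged unidentifiable rather than silently returned.
    """
    Ci = np.asarray(Ci, dtype=float)
    A = np.asarray(A, dtype=float)
    if Ci.size < 6:
        raise FitError(f"need at least 6 points, got {Ci.size}")
    if np.unique(Ci).size != Ci.size:
        raise FitError("Ci values must be distinct")

    def resid(p):
        return fvcb_model(Ci, p[0], p[1], p[2], k)[0] - A

    bounds = (np.array([1e-3, 1e-3, 0.0]), np.array([1000.0, 2000.0, 50.0]))
    best = None
    for x0 in _aci_starts(Ci, A, k):
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
        raise FitError("A/Ci fit did not converge from any start")
    sol = best[1]
    vcmax, jmax, rd = map(float, sol.x)
    trans = ci_transition_point(vcmax, jmax, k)
    _, labels = fvcb_model(Ci, vcmax, jmax, rd, k)
    p = FvCBParams(
        vcmax=vcmax, jmax=jmax, rd=rd, ci_transition=trans,
        rmse=float(np.sqrt(np.mean(sol.fun**2))),
        n_points=int(Ci.size), genotype_id=genotype_id,
        limitation_labels=list(labels),
    )
    if np.isfinite(trans):
        if (Ci <= trans).all():
            p.flags.append("jmax_unidentifiable")
        elif (Ci >= trans).all():
            p.flags.append("vcmax_unidentifiable")
    else:
        p.flags.append("no_transition_in_range")
    return p
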