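"""Two-step passive membrane fit.

Step 1 finds the specific membrane resistance Rm whose model reproduces the
target somatic input resistance (Rin = ΔV/I); step 2, holding that Rm,
finds the specific capacitance Cm reproducing the target membrane time
constant (63%-of-peak criterion on a 200-ms somatic step).  Both maps —
Rm ↦ Rin and Cm ↦ τ63 — are strictly increasing for a passive neuron, so a
bracketed root find (Brent) converges quickly; the morphology is
re-compartmentalized at every candidate Rm so the 0.2λ spacing rule always
holds for the parameters actually used.

Each neuron is fitted to its *group's* mean targets, mirroring the study,
which matched the electrophysiologically determined group means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy.optimize import brentq

from taucable.cable_model import CableModel, MembraneParams, compartmentalize
from taucable.morphology import Morphology
from taucable.solver import MeasurementError, input_resistance, time_constant

RM_BRACKET = (1e3, 1e6)  # Ω·cm²
CM_BRACKET = (0.1, 10.0)  # μF/cm²


def _tau63(cm_model, Cm: float) -> float:
    """τ63 for bracketing: 'not reached within the 200-ms step' maps to a
    large finite surrogate that stays increasing in Cm (Brent needs finite
    values; the root is never in that region)."""
    try:
        return time_constant(cm_model)
    except MeasurementError:
        return 200.0 + 100.0 * Cm


class FitError(RuntimeError):
    """Target unreachable within the (once-widened) parameter bracket."""


@dataclass(frozen=True)
class FitTargets:
    """Group target Rin (MΩ) and τ (ms) with a relative fit tolerance."""

    target_Rin: float
    target_tau: float
    tolerance: float = 1e-3

    def __post_init__(self) -> None:
        if self.target_Rin <= 0 or self.target_tau <= 0 or self.tolerance <= 0:
            raise ValueError("targets and tolerance must be positive")


#: Experimental group means: Rin 197 (WT) / 228 (TG) MΩ; τ 32.5 / 35.2 ms.
WT_TARGETS = FitTargets(197.0, 32.5)
TG_TARGETS = FitTargets(228.0, 35.2)


@dataclass
class FitReport:
    Rm: float
    Cm: float
    achieved_Rin: float
    achieved_tau: float
    iterations_Rm: int
    iterations_Cm: int

    def to_dict(self) -> dict:
        return vars(self).copy()


def _bracketed_root(f, lo, hi, label):
    """Brent root of f on [lo, hi], widening the bracket once if needed."""
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        lo, hi = lo / 10.0, hi * 10.0
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise FitError(f"{label}: target outside bracket [{lo}, {hi}]")
    return brentq(f, lo, hi, rtol=1e-6)


def fit_Rm(
    m: Morphology, t: FitTargets, p0: MembraneParams, max_len: float | None = None
) -> float:
    """Rm (Ω·cm²) whose model matches ``t.target_Rin`` within tolerance."""
    kwargs = {} if max_len is None else {"max_len": max_len}
    evals = [0]

    def resid(Rm: float) -> float:
        evals[0] += 1
        cm = compartmentalize(m, replace(p0, Rm=Rm), **kwargs)
        return input_resistance(cm) - t.target_Rin

    Rm_star = _bracketed_root(resid, *RM_BRACKET, label="fit_Rm")
    achieved = resid(Rm_star) + t.target_Rin
    if abs(achieved - t.target_Rin) / t.target_Rin > t.tolerance:
        raise FitError("fit_Rm: converged point misses tolerance")
    return float(Rm_star)


def fit_Cm(
    m: Morphology,
    t: FitTargets,
    p_with_fitted_Rm: MembraneParams,
    max_len: float | None = None,
) -> float:
    """Cm (μF/cm²) whose model matches ``t.target_tau``, holding the fitted Rm.

    τ63 scales linearly in Cm for the passive system, so Brent's secant
    steps land essentially immediately.
    """
    kwargs = {} if max_len is None else {"max_len": max_len}

    def resid(Cm: float) -> float:
        cm = compartmentalize(m, replace(p_with_fitted_Rm, Cm=Cm), **kwargs)
        return _tau63(cm, Cm) - t.target_tau

    Cm_star = _bracketed_root(resid, *CM_BRACKET, label="fit_Cm")
    achieved = resid(Cm_star) + t.target_tau
    if abs(achieved - t.target_tau) / t.target_tau > t.tolerance:
        raise FitError("fit_Cm: converged point misses tolerance")
    return float(Cm_star)


def fit_membrane(
    m: Morphology, t: FitTargets, p0: MembraneParams, max_len: float | None = None
) -> tuple[MembraneParams, FitReport]:
    """The full two-step fit; returns fitted params and a fit report."""
    counters = {"Rm": 0, "Cm": 0}
    kwargs = {} if max_len is None else {"max_len": max_len}

    def rin_resid(Rm):
        counters["Rm"] += 1
        cm = compartmentalize(m, replace(p0, Rm=Rm), **kwargs)
        return input_resistance(cm) - t.target_Rin

    Rm_star = _bracketed_root(rin_resid, *RM_BRACKET, label="fit_Rm")
    p1 = replace(p0, Rm=Rm_star)

    def tau_resid(Cm):
        counters["Cm"] += 1
        cm = compartmentalize(m, replace(p1, Cm=Cm), **kwargs)
        return _tau63(cm, Cm) - t.target_tau

    Cm_star = _bracketed_root(tau_resid, *CM_BRACKET, label="fit_Cm")
    fitted = replace(p1, Cm=Cm_star)
    model = compartmentalize(m, fitted, **kwargs)
    report = FitReport(
        Rm=float(Rm_star),
        Cm=float(Cm_star),
        achieved_Rin=input_resistance(model),
        achieved_tau=time_constant(model),
        iterations_Rm=counters["Rm"],
        iterations_Cm=counters["Cm"],
    )
    for achieved, target in (
        (report.achieved_Rin, t.target_Rin),
        (report.achieved_tau, t.target_tau),
    ):
        if abs(achieved - target) / target > t.tolerance:
            raise FitError("fit_membrane: achieved values miss tolerance")
    return fitted, report
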