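"""Solvers for the passive compartmental system.

Steady state solves G·V = I, the phasor route solves (G + iωC)·Ṽ = I for
sinusoidal drive, and the time domain uses Crank–Nicolson on

    C dV/dt = −G·V + I(t) − g_syn(t)·(V − E'),

where V is the deviation from rest, G the leak+axial conductance matrix and
E' = E_syn − E_rest the synaptic driving force at rest (the passive system
is affine, so rest enters only here).  Alpha-conductance synapses are
evaluated at half steps, keeping the scheme second-order; the changing
diagonal entries are handled as rank-k Woodbury corrections to one LU
factorization, so a 16 000-step run costs one factorization plus one
triangular solve per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from taucable.cable_model import CableModel, assemble_system

DEFAULT_DT = 0.025  # ms, integration step used throughout the study
DEFAULT_STEP_AMP = 0.01  # nA (+10 pA depolarizing) for Rin / tau protocols
TAU_FRACTION = 1.0 - math.exp(-1.0)  # the "63%" criterion


class MeasurementError(RuntimeError):
    """A required feature (peak, crossing) was not reached in the window."""


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus at one compartment.

    kinds: ``constant_current`` (on from ``onset``), ``current_step``
    (``onset`` to ``onset+duration``), ``sinusoid_current``,
    ``alpha_current`` (amplitude × alpha shape), ``alpha_conductance``
    (amplitude in nS = g_max, with reversal ``e_syn``).
    Currents in nA, conductances in nS, times in ms.
    """

    site: int
    kind: str
    amplitude: float
    onset: float = 0.0
    duration: float = math.inf
    frequency: float = 50.0  # Hz, sinusoid only
    t_peak: float = 0.5  # ms, alpha shapes
    e_syn: float = 0.0  # mV absolute, alpha_conductance only

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.kind == "sinusoid_current" and self.frequency <= 0:
            raise ValueError("sinusoid needs frequency > 0")
        if self.kind not in (
            "constant_current",
            "current_step",
            "sinusoid_current",
            "alpha_current",
            "alpha_conductance",
        ):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")

    def current(self, t: np.ndarray) -> np.ndarray:
        """Injected current (nA) at times t (ms); zero for conductance kinds."""
        rel = t - self.onset
        if self.kind == "constant_current":
            return np.where(rel >= 0, self.amplitude, 0.0)
        if self.kind == "current_step":
            return np.where((rel >= 0) & (rel < self.duration), self.amplitude, 0.0)
        if self.kind == "sinusoid_current":
            w = 2.0 * math.pi * self.frequency * 1e-3  # rad/ms
            return np.where(rel >= 0, self.amplitude * np.sin(w * rel), 0.0)
        if self.kind == "alpha_current":
            return np.where(rel >= 0, self.amplitude * _alpha(rel, self.t_peak), 0.0)
        return np.zeros_like(t)

    def conductance(self, t: np.ndarray) -> np.ndarray:
        """Synaptic conductance (μS) at times t; zero for current kinds."""
        if self.kind != "alpha_conductance":
            return np.zeros_like(t)
        rel = t - self.onset
        # amplitude is in nS -> μS
        return np.where(rel >= 0, self.amplitude * 1e-3 * _alpha(rel, self.t_peak), 0.0)


def _alpha(rel: np.ndarray, t_peak: float) -> np.ndarray:
    rel = np.maximum(rel, 0.0)
    return (rel / t_peak) * np.exp(1.0 - rel / t_peak)


@dataclass
class Traces:
    """Time-domain results: per-compartment voltage deviations from rest."""

    times: np.ndarray  # ms, uniform grid
    voltages: np.ndarray  # (n_comp, n_times) mV, deviation from rest
    injected: np.ndarray  # (n_comp, n_times) nA
    rest: float  # mV, the resting potential the deviations refer to
    dt: float

    def voltage(self, comp: int) -> np.ndarray:
        return self.voltages[comp]

    def absolute_voltage(self, comp: int) -> np.ndarray:
        return self.voltages[comp] + self.rest


# ---------------------------------------------------------------------------
# Steady state and phasor
# ---------------------------------------------------------------------------


def solve_steady(cm: CableModel, site: int, I: float = 1.0) -> np.ndarray:
    """Steady voltage deviation (mV) everywhere for constant current at ``site``."""
    G, _ = assemble_system(cm)
    b = np.zeros(cm.n)
    b[site] = I
    return spla.spsolve(G.tocsc(), b)


def solve_steady_clamped(cm: CableModel, site: int, I: float = 1.0) -> np.ndarray:
    """Steady solve with the soma clamped to rest (Dirichlet at index 0).

    Returns the full voltage vector (soma entry 0); used for charge-transfer
    measures, where the clamp absorbs all current reaching the soma.
    """
    G, _ = assemble_system(cm)
    n = cm.n
    if site == cm.soma_index:
        raise ValueError("site must be dendritic for a soma-clamped solve")
    keep = np.arange(1, n)
    Gdd = G[keep][:, keep]
    b = np.zeros(n - 1)
    b[site - 1] = I
    v = np.zeros(n)
    v[1:] = spla.spsolve(Gdd.tocsc(), b)
    return v


def solve_phasor(cm: CableModel, site: int, f: float, I: float = 1.0) -> np.ndarray:
    """Complex steady-state phasor voltages for sinusoidal current at ``site``.

    Solves (G + iωC)Ṽ = I·e_site with ω = 2πf; |Ṽ_j| is the stationary
    sinusoid amplitude at compartment j.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    G, C = assemble_system(cm)
    omega = 2.0 * math.pi * f * 1e-3  # rad/ms; C in nF, G in μS: μS ≡ nF/ms
    A = (G + 1j * omega * sp.diags(C)).tocsc()
    b = np.zeros(cm.n, dtype=complex)
    b[site] = I
    return spla.spsolve(A, b)


# ---------------------------------------------------------------------------
# Time domain (Crank–Nicolson)
# ---------------------------------------------------------------------------


def simulate(
    cm: CableModel,
    stimuli: list[StimulusSpec],
    t_stop: float,
    dt: float = DEFAULT_DT,
) -> Traces:
    """Crank–Nicolson integration of the passive system from rest.

    Voltages are deviations from ``cm.params.E_leak``; conductance synapses
    see the driving force V − (E_syn − E_rest).
    """
    if dt <= 0 or t_stop <= 0:
        raise ValueError("need positive dt and t_stop")
    for s in stimuli:
        if not 0 <= s.site < cm.n:
            raise ValueError(f"stimulus site {s.site} out of range")
    G, C = assemble_system(cm)
    n = cm.n
    n_steps = int(round(t_stop / dt))
    times = np.arange(n_steps + 1) * dt
    t_half = times[:-1] + dt / 2.0

    A_left = (sp.diags(C / dt) + 0.5 * G).tocsc()
    A_right = (sp.diags(C / dt) - 0.5 * G).tocsr()
    lu = spla.splu(A_left)

    cond_stims = [s for s in stimuli if s.kind == "alpha_conductance"]
    cur_stims = [s for s in stimuli if s.kind != "alpha_conductance"]

    inj = np.zeros((n, n_steps + 1))
    inj_half = np.zeros((n, n_steps))
    for s in cur_stims:
        inj[s.site] += s.current(times)
        inj_half[s.site] += s.current(t_half)

    g_half = np.array([s.conductance(t_half) for s in cond_stims])  # (k, steps)
    sites = np.array([s.site for s in cond_stims], dtype=int)
    e_prime = np.array(
        [s.e_syn - cm.params.E_leak for s in cond_stims]
    )  # driving force at rest, mV
    if cond_stims:
        Z = np.column_stack([lu.solve(_unit_vec(n, s)) for s in sites])  # (n, k)

    V = np.zeros((n, n_steps + 1))
    v = np.zeros(n)
    for step in range(n_steps):
        b = A_right @ v + inj_half[:, step]
        active = g_half[:, step] > 0.0 if cond_stims else np.zeros(0, dtype=bool)
        if active.any():
            g = g_half[active, step]  # μS per active synapse
            s_act = sites[active]
            np.add.at(b, s_act, g * (e_prime[active] - 0.5 * v[s_act]))
            y = lu.solve(b)
            # Woodbury: (A + E diag(g/2) E^T)^{-1} b with E columns e_site
            K = np.diag(2.0 / g) + Z[s_act][:, active]
            alpha = np.linalg.solve(K, y[s_act])
            v = y - Z[:, active] @ alpha
        else:
            v = lu.solve(b)
        if not np.all(np.isfinite(v)):
            raise FloatingPointError("non-finite state in Crank–Nicolson step")
        V[:, step + 1] = v
    return Traces(times=times, voltages=V, injected=inj, rest=cm.params.E_leak, dt=dt)


def _unit_vec(n: int, i: int) -> np.ndarray:
    e = np.zeros(n)
    e[i] = 1.0
    return e


def simulate_epsp_batch(
    cm: CableModel,
    sites: np.ndarray,
    g_max: float = 0.25,
    t_peak: float = 0.5,
    e_syn: float = 0.0,
    t_stop: float = 400.0,
    dt: float = DEFAULT_DT,
    onset: float = 0.0,
    record: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Somatic EPSP traces for one alpha-conductance synapse per site.

    Runs all single-synapse simulations simultaneously (one column per
    site) against a single LU factorization, applying a per-column
    Sherman–Morrison correction for the site's time-varying conductance.
    Returns ``(times, v_rec)`` with ``v_rec`` of shape (n_sites, n_times),
    recorded at ``record`` (default: the soma), in mV deviation from rest.
    """
    sites = np.asarray(sites, dtype=int)
    rec = cm.soma_index if record is None else record
    G, C = assemble_system(cm)
    n, ns = cm.n, len(sites)
    n_steps = int(round(t_stop / dt))
    times = np.arange(n_steps + 1) * dt
    t_half = times[:-1] + dt / 2.0

    A_left = (sp.diags(C / dt) + 0.5 * G).tocsc()
    A_right = (sp.diags(C / dt) - 0.5 * G).tocsr()
    lu = spla.splu(A_left)
    E = np.zeros((n, ns))
    E[sites, np.arange(ns)] = 1.0
    Z = lu.solve(E)  # (n, ns), A_left^{-1} e_site per column
    z_diag = Z[sites, np.arange(ns)]

    rel = t_half - onset
    g_series = np.where(rel >= 0, g_max * 1e-3 * _alpha(rel, t_peak), 0.0)  # μS
    e_prime = e_syn - cm.params.E_leak

    V = np.zeros((n, ns))
    out = np.zeros((ns, n_steps + 1))
    col = np.arange(ns)
    for step in range(n_steps):
        g = g_series[step]
        B = A_right @ V
        if g > 0.0:
            v_site = V[sites, col]
            B[sites, col] += g * (e_prime - 0.5 * v_site)
            Y = lu.solve(B)
            alpha = (0.5 * g * Y[sites, col]) / (1.0 + 0.5 * g * z_diag)
            V = Y - Z * alpha[None, :]
        else:
            V = lu.solve(B)
        out[:, step + 1] = V[rec]
    return times, out


# ---------------------------------------------------------------------------
# Protocol measurements
# ---------------------------------------------------------------------------


def input_resistance(cm: CableModel, I: float = DEFAULT_STEP_AMP) -> float:
    """Somatic input resistance Rin = ΔV/I (MΩ) from a steady somatic solve."""
    v = solve_steady(cm, cm.soma_index, I)
    return float(v[cm.soma_index] / I)


def time_constant(
    cm: CableModel,
    I: float = DEFAULT_STEP_AMP,
    t_step: float = 200.0,
    dt: float = DEFAULT_DT,
) -> float:
    """Effective membrane time constant τ63 (ms) from a somatic current step.

    Simulates a depolarizing ``t_step``-ms step at the soma and locates,
    by linear interpolation between grid points, where the somatic voltage
    crosses 63% (1 − 1/e) of the peak depolarization; the peak is the exact
    steady-state plateau ΔV = Rin·I, which the 200-ms response approaches
    to within a fraction of a percent.
    """
    stim = StimulusSpec(site=cm.soma_index, kind="current_step",
                        amplitude=I, duration=t_step)
    tr = simulate(cm, [stim], t_stop=t_step, dt=dt)
    v = tr.voltages[cm.soma_index]
    plateau = input_resistance(cm, I) * I
    level = TAU_FRACTION * plateau
    above = np.nonzero(v >= level)[0]
    if len(above) == 0:
        raise MeasurementError("63% level not reached within the step window")
    k = above[0]
    if k == 0:
        return 0.0
    t0, t1 = tr.times[k - 1], tr.times[k]
    v0, v1 = v[k - 1], v[k]
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))
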