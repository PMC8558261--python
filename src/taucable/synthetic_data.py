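"""Synthetic pyramidal-like test morphologies.

Two kinds of fixtures:

* analytic ones (:func:`make_cylinder`, :func:`make_rall_tree`) with closed-form
  electrotonic expectations, used as solver oracles; and
* seeded stochastic populations (:func:`sample_population`) emulating the two
  study groups — wild-type-like and tau-transgenic-like layer III pyramidal
  neurons.  The group presets encode the contrasts reported for rTg4510
  neurons qualitatively: reduced apical tuft, mildly thinner dendrites,
  lower spine density (1.00 vs 1.25 /μm) and a larger soma; they make no
  claim to reproduce the NeuroMorpho morphometrics quantitatively.

Branching is a Galton–Watson process truncated at depth 6; all randomness
comes from one ``numpy.random.default_rng(seed)`` (PCG64), so a given seed
yields bit-identical SWC output on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from taucable.morphology import (
    APICAL,
    BASAL,
    SOMA,
    Morphology,
    MorphologyError,
    MorphPoint,
)

MAX_BRANCH_DEPTH = 6
_POINT_STEP = 10.0  # μm between consecutive SWC sample points
_MIN_DIAMETER = 0.3  # μm floor, keeps compartments electrically sane


class GenerationError(RuntimeError):
    """Degenerate parameters produced no usable dendrite."""


@dataclass(frozen=True)
class GroupParams:
    """Generator parameters for one population of pyramidal-like trees."""

    n_basal_stems: int
    branch_probability: float
    segment_length_mean: float  # μm, lognormal mean (linear scale)
    segment_length_sd: float  # μm, lognormal sd (linear scale)
    stem_diameter: float  # μm, basal stem diameter
    taper_ratio: float  # daughter/parent diameter per branch order
    apical_trunk_length: float  # μm
    tuft_size_factor: float  # (0, 1]: scales tuft segment lengths
    spine_density: float  # spines/μm of dendrite
    max_total_extent: float  # μm, cap on path distance from soma
    soma_radius: float  # μm (sphere)
    name: str = ""

    def __post_init__(self) -> None:
        numeric = {
            k: getattr(self, k)
            for k in (
                "n_basal_stems",
                "branch_probability",
                "segment_length_mean",
                "segment_length_sd",
                "stem_diameter",
                "taper_ratio",
                "apical_trunk_length",
                "tuft_size_factor",
                "spine_density",
                "max_total_extent",
                "soma_radius",
            )
        }
        bad = [k for k, v in numeric.items() if v < 0]
        if bad or self.tuft_size_factor > 1 or self.taper_ratio > 1:
            raise ValueError(f"invalid GroupParams: {bad or 'factor > 1'}")


def load_presets() -> dict[str, GroupParams]:
    """The packaged WT-like / TG-like generator presets (data/presets.yaml)."""
    text = resources.files("taucable").joinpath("data/presets.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: GroupParams(name=name, **kv) for name, kv in raw.items()}


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------


def make_cylinder(
    d: float, l: float, n_points: int, soma_radius: float = 5.0
) -> Morphology:
    """Soma plus one straight constant-diameter basal cable of length ``l``.

    The first cable point sits at the soma surface origin so the tip path
    distance equals ``l`` and the lateral area equals π·d·l exactly.
    """
    if n_points < 2:
        raise ValueError("need n_points >= 2")
    pts = [MorphPoint(1, SOMA, 0.0, 0.0, 0.0, soma_radius, -1)]
    xs = np.linspace(0.0, l, n_points)
    for i, x in enumerate(xs):
        pts.append(MorphPoint(i + 2, BASAL, float(x), 0.0, 0.0, d / 2.0, i + 1))
    return Morphology(pts, name=f"cylinder_d{d}_l{l}")


def make_rall_tree(
    parent_d: float,
    depth: int,
    segment_l: float,
    point_step: float = 5.0,
    soma_radius: float = 5.0,
) -> Morphology:
    """Symmetric binary tree obeying the 3/2-power diameter rule.

    Daughter diameters are ``parent_d / 2**(2/3)`` at every bifurcation, so
    the tree is electrotonically equivalent to a single cylinder of diameter
    ``parent_d`` — the classical equivalent-cylinder construction used here
    as a solver oracle.  ``depth`` counts cable levels (1 = unbranched).
    """
    if depth < 1:
        raise ValueError("need depth >= 1")
    pts = [MorphPoint(1, SOMA, 0.0, 0.0, 0.0, soma_radius, -1)]

    def grow(parent_idx, origin, direction, d, level):
        n_seg = max(1, int(math.ceil(segment_l / point_step)))
        step = segment_l / n_seg
        pos = np.asarray(origin, dtype=float)
        idx = parent_idx
        if level > 1:
            # micro-point so the daughter cable carries its own diameter from
            # the bifurcation on (the mean-diameter segment rule would
            # otherwise blend parent and daughter over the first step)
            pos = pos + direction * 1e-6
            pts.append(MorphPoint(len(pts) + 1, BASAL, *map(float, pos), d / 2.0, idx))
            idx = len(pts)
        for _ in range(n_seg):
            pos = pos + direction * step
            pts.append(
                MorphPoint(len(pts) + 1, BASAL, *map(float, pos), d / 2.0, idx)
            )
            idx = len(pts)
        if level < depth:
            d_child = d / 2.0 ** (2.0 / 3.0)
            for sign in (+1.0, -1.0):
                # spread daughters; geometry is irrelevant electrically
                angle = sign * math.pi / 2 ** (level + 2)
                c, s = math.cos(angle), math.sin(angle)
                rot = np.array(
                    [direction[0] * c - direction[1] * s,
                     direction[0] * s + direction[1] * c,
                     0.0]
                )
                grow(idx, pos, rot / np.linalg.norm(rot), d_child, level + 1)

    grow(1, (0.0, 0.0, 0.0), np.array([1.0, 0.0, 0.0]), parent_d, 1)
    return Morphology(pts, name=f"rall_d{parent_d}_depth{depth}")


# ---------------------------------------------------------------------------
# Stochastic populations
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Lognormal draw parameterized by its linear-scale mean and sd."""
    if sd <= 0:
        return mean
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _jitter(rng: np.random.Generator, direction: np.ndarray, sd: float) -> np.ndarray:
    return _unit(direction + rng.normal(0.0, sd, size=3))


def _grow_arbor(
    pts: list[MorphPoint],
    rng: np.random.Generator,
    parent_idx: int,
    origin: np.ndarray,
    direction: np.ndarray,
    diameter: float,
    structure: int,
    gp: GroupParams,
    depth: int,
    path_len: float,
    length_scale: float = 1.0,
    max_depth: int = MAX_BRANCH_DEPTH,
) -> None:
    """Galton–Watson segment growth with lognormal lengths and taper."""
    seg_len = _lognormal(
        rng, gp.segment_length_mean * length_scale, gp.segment_length_sd * length_scale
    )
    seg_len = min(seg_len, gp.max_total_extent - path_len)
    if seg_len < 2.0:
        return
    n_pts = max(1, int(round(seg_len / _POINT_STEP)))
    step = seg_len / n_pts
    pos = origin.copy()
    idx = parent_idx
    for _ in range(n_pts):
        direction = _jitter(rng, direction, 0.15)
        pos = pos + direction * step
        pts.append(
            MorphPoint(len(pts) + 1, structure, *map(float, pos), diameter / 2.0, idx)
        )
        idx = len(pts)
    path_len += seg_len
    if depth < max_depth and path_len < gp.max_total_extent:
        if rng.random() < gp.branch_probability:
            d_child = max(diameter * gp.taper_ratio, _MIN_DIAMETER)
            for sign in (+1.0, -1.0):
                child_dir = _jitter(rng, direction, 0.45 * sign if sign > 0 else 0.45)
                grow_dir = _unit(child_dir + sign * 0.4 * _orthogonal(direction))
                _grow_arbor(
                    pts, rng, idx, pos, grow_dir, d_child, structure, gp,
                    depth + 1, path_len, length_scale, max_depth,
                )


def _orthogonal(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(v, ref))


def generate_neuron(gp: GroupParams, rng: np.random.Generator, name: str = "") -> Morphology:
    """One pyramidal-like tree: basal stems + apical trunk with obliques and tuft."""
    pts = [MorphPoint(1, SOMA, 0.0, 0.0, 0.0, gp.soma_radius, -1)]

    # basal arbor: stems leaving the lower hemisphere
    for _ in range(gp.n_basal_stems):
        phi = rng.uniform(0.0, 2.0 * math.pi)
        cos_t = rng.uniform(-1.0, -0.2)  # downward-ish
        sin_t = math.sqrt(1.0 - cos_t**2)
        direction = np.array(
            [sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t]
        )
        origin = direction * gp.soma_radius
        _grow_arbor(
            pts, rng, 1, origin, direction, gp.stem_diameter, BASAL, gp,
            depth=1, path_len=gp.soma_radius,
        )

    # apical trunk straight up, linearly tapering
    trunk_d0 = 1.6 * gp.stem_diameter
    trunk_d1 = 0.9 * gp.stem_diameter
    n_trunk = max(2, int(round(gp.apical_trunk_length / (2 * _POINT_STEP))))
    step = gp.apical_trunk_length / n_trunk
    pos = np.array([0.0, 0.0, gp.soma_radius])
    direction = np.array([0.0, 0.0, 1.0])
    idx = 1
    trunk_attach: list[tuple[int, np.ndarray, float, float]] = []
    for i in range(n_trunk):
        direction = _jitter(rng, direction, 0.05)
        pos = pos + direction * step
        frac = (i + 1) / n_trunk
        d_here = trunk_d0 + (trunk_d1 - trunk_d0) * frac
        pts.append(MorphPoint(len(pts) + 1, APICAL, *map(float, pos), d_here / 2.0, idx))
        idx = len(pts)
        trunk_attach.append(
            (idx, pos.copy(), d_here, gp.soma_radius + (i + 1) * step)
        )

    # oblique side branches off the trunk
    for attach_idx, attach_pos, d_here, attach_dist in trunk_attach[1:-1]:
        if rng.random() < 0.35:
            side = _orthogonal(direction)
            side = _unit(side + rng.normal(0, 0.3, 3))
            _grow_arbor(
                pts, rng, attach_idx, attach_pos, side,
                max(0.6 * d_here, _MIN_DIAMETER), APICAL, gp,
                depth=3, path_len=attach_dist,
            )

    # terminal tuft, scaled by tuft_size_factor
    tuft_d = max(0.7 * trunk_d1, _MIN_DIAMETER)
    for sign in (+1.0, -1.0):
        tuft_dir = _unit(np.array([0.35 * sign, rng.normal(0, 0.2), 1.0]))
        _grow_arbor(
            pts, rng, idx, pos, tuft_dir, tuft_d, APICAL, gp,
            depth=2, path_len=gp.soma_radius + gp.apical_trunk_length,
            length_scale=gp.tuft_size_factor,
        )

    if len(pts) < 5:
        raise GenerationError(
            f"parameters {gp.name or gp} generated no usable dendrite"
        )
    return Morphology(pts, name=name or f"{gp.name or 'synthetic'}")


def sample_population(
    gp: GroupParams, n_neurons: int, seed: int
) -> list[Morphology]:
    """``n_neurons`` seeded, reproducible trees drawn from one group preset."""
    if n_neurons < 1:
        raise ValueError("need n_neurons >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_neurons):
        out.append(
            generate_neuron(gp, rng, name=f"{gp.name or 'synthetic'}_{seed}_{i:03d}")
        )
    return out
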