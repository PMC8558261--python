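"""Discretization of a morphology into a passive electrical compartment model.

Dendrites become chains of isopotential cylinders (one spherical soma
compartment), spaced so that no compartment is longer than 37 μm or 0.2
space constants, whichever is smaller.  Dendritic spines are not modelled
geometrically: each dendritic compartment's specific capacitance and leak
conductance are scaled by the spine folding factor

    q = (A_spines + A_dendrite) / A_dendrite,

with A_spines = spine_density · length · spine_area, which preserves total
membrane while leaving cable geometry untouched.  The soma keeps q = 1.

Internal units: μm, ms, mV, nA, MΩ, μS, nF (see :mod:`taucable.units`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from taucable import units
from taucable.morphology import SOMA, Morphology, MorphologyError, soma_surface

DEFAULT_MAX_LEN = 37.0  # μm, hard cap on compartment length
LAMBDA_FRACTION = 0.2  # cap as a fraction of the local space constant


@dataclass(frozen=True)
class MembraneParams:
    """Global passive membrane constants plus the spine specification.

    Rm (Ω·cm²) and Cm (μF/cm²) are the specific membrane resistance and
    capacitance of the spiny membrane; Ra (Ω·cm) the cytosol resistivity;
    E_leak the resting potential (−75 mV WT, −65 mV TG).
    """

    Rm: float = 12000.0
    Cm: float = 1.0
    Ra: float = 150.0
    E_leak: float = -75.0
    spine_density: float = 0.0  # spines/μm
    spine_area: float = 1.5  # μm² per spine

    def __post_init__(self) -> None:
        if min(self.Rm, self.Cm, self.Ra) <= 0 or self.spine_density < 0:
            raise ValueError("Rm, Cm, Ra must be > 0 and spine_density >= 0")


def spine_correction_factor(
    diameter: float, density: float, spine_area: float
) -> float:
    """q = (A_s + A_d)/A_d for a cylinder; independent of length.

    A_s = density·l·spine_area and A_d = π·d·l, so q = 1 + density·spine_area/(π·d).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return 1.0 + density * spine_area / (math.pi * diameter)


def space_constant(d: float, Rm_corrected: float, Ra: float) -> float:
    """λ = sqrt(d·Rm/(4·Ra)) in μm; ``Rm_corrected`` is the spine-folded Rm/q."""
    return units.space_constant_um(d, Rm_corrected, Ra)


@dataclass
class Compartment:
    index: int
    kind: str  # "soma" | "dendrite"
    arbor: str  # "apical" | "basal" | "other" | "none"
    length: float  # μm (0 for the soma sphere)
    diameter: float  # μm
    smooth_area: float  # μm², A_d (spineless)
    q: float  # spine folding factor, ≥ 1
    capacitance: float  # nF, Cm·q·A_d
    leak_conductance: float  # μS, q·A_d/Rm
    axial_half_resistance: float  # MΩ, half-cylinder with own diameter (0 for soma)
    parent: int  # parent compartment index (-1 for soma)
    path_distance: float  # μm, midpoint distance from soma


@dataclass
class CableModel:
    """Compartment list plus coupling topology for one neuron."""

    compartments: list[Compartment]
    params: MembraneParams
    #: (i, j, axial conductance μS) for each adjacent pair, i = parent side
    coupling: list[tuple[int, int, float]]
    morphology_name: str = ""

    def __post_init__(self) -> None:
        somata = [c for c in self.compartments if c.kind == "soma"]
        if len(somata) != 1 or somata[0].index != 0:
            raise MorphologyError("model must have exactly one soma at index 0")
        n = len(self.compartments)
        reached = {0}
        for i, j, g in sorted(self.coupling, key=lambda t: t[1]):
            if g <= 0:
                raise MorphologyError("nonpositive axial conductance")
            reached.add(j)
            if i not in reached:
                raise MorphologyError("coupling does not form a soma-rooted tree")
        if reached != set(range(n)):
            raise MorphologyError("model is not connected")

    # -- convenience arrays -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def soma_index(self) -> int:
        return 0

    def dendritic_indices(self) -> np.ndarray:
        return np.array([c.index for c in self.compartments if c.kind == "dendrite"])

    def capacitance_vector(self) -> np.ndarray:
        """Per-compartment membrane capacitance, nF."""
        return np.array([c.capacitance for c in self.compartments])

    def leak_vector(self) -> np.ndarray:
        """Per-compartment leak conductance, μS."""
        return np.array([c.leak_conductance for c in self.compartments])

    def total_capacitance(self) -> float:
        return float(self.capacitance_vector().sum())

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.compartments])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "morphology": self.morphology_name,
            "params": vars(self.params).copy(),
            "compartments": [vars(c) for c in self.compartments],
            "coupling": [[i, j, g] for i, j, g in self.coupling],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def assemble_system(cm: CableModel) -> tuple[sp.csr_matrix, np.ndarray]:
    """The (leak + axial) conductance matrix (μS) and capacitance vector (nF).

    The matrix is symmetric and weakly diagonally dominant; row i sums
    exactly to compartment i's leak conductance (axial terms cancel).
    """
    n = cm.n
    G = sp.lil_matrix((n, n))
    for c in cm.compartments:
        G[c.index, c.index] = c.leak_conductance
    for i, j, g in cm.coupling:
        G[i, j] -= g
        G[j, i] -= g
        G[i, i] += g
        G[j, j] += g
    return G.tocsr(), cm.capacitance_vector()


# ---------------------------------------------------------------------------
# Compartmentalization
# ---------------------------------------------------------------------------


def _sections(m: Morphology) -> list[dict]:
    """Split dendritic segments into unbranched sections, BFS from the soma.

    A section is a maximal chain of morphology segments between branch
    points / soma attachments / tips.  Returns dicts with the proximal
    attachment point id, ordered segment rows, and totals.
    """
    seg = m.segments()
    if seg.empty:
        return []
    children: dict[int, list[int]] = {}
    seg_by_child = {int(r.child_id): r for r in seg.itertuples()}
    for r in seg.itertuples():
        children.setdefault(int(r.parent_id), []).append(int(r.child_id))
    soma_ids = {p.id for p in m.points if p.structure == SOMA}
    # section starts: children of soma points, and children of branch points
    starts: list[tuple[int, int]] = []  # (attach point, first child point)
    for pid in sorted(children):
        kids = children[pid]
        if pid in soma_ids or len(kids) > 1:
            for k in kids:
                starts.append((pid, k))
    sections = []
    for attach, first in starts:
        rows = []
        cur = first
        while True:
            rows.append(seg_by_child[cur])
            kids = children.get(cur, [])
            if len(kids) != 1:
                break
            cur = kids[0]
        sections.append(
            {
                "attach_point": attach,
                "rows": rows,
                "length": float(sum(r.length for r in rows)),
                "arbor": rows[0].arbor,
                "start_distance": float(
                    rows[0].mid_distance - rows[0].length / 2.0
                ),
            }
        )
    return sections


def compartmentalize(
    m: Morphology, p: MembraneParams, max_len: float = DEFAULT_MAX_LEN
) -> CableModel:
    """Build a :class:`CableModel` under the 37 μm / 0.2λ spacing rule.

    Section by section, the compartment length is ``section_length / n``
    with the smallest ``n`` for which every compartment respects
    ``min(max_len, 0.2·λ)``, λ evaluated with the section's narrowest
    diameter and the spine-corrected Rm (conservative, since λ grows with
    d).  Compartment diameters are length-weighted means of the underlying
    morphology segments.  Axial coupling between adjacent compartment
    centers sums the two half-cylinder resistances, each with its own
    diameter; the soma sphere contributes none.
    """
    comps: list[Compartment] = [
        Compartment(
            index=0,
            kind="soma",
            arbor="none",
            length=0.0,
            diameter=2.0 * math.sqrt(soma_surface(m) / (4.0 * math.pi)),
            smooth_area=soma_surface(m),
            q=1.0,
            capacitance=units.membrane_capacitance_nF(p.Cm, soma_surface(m)),
            leak_conductance=units.membrane_conductance_uS(p.Rm, soma_surface(m)),
            axial_half_resistance=0.0,
            parent=-1,
            path_distance=0.0,
        )
    ]
    coupling: list[tuple[int, int, float]] = []
    point_to_comp: dict[int, int] = {
        pt.id: 0 for pt in m.points if pt.structure == SOMA
    }

    for sec in _sections(m):
        rows, L = sec["rows"], sec["length"]
        d_min = min(r.diameter for r in rows)
        q_min = spine_correction_factor(d_min, p.spine_density, p.spine_area)
        lam = space_constant(d_min, p.Rm / q_min, p.Ra)
        allowed = min(max_len, LAMBDA_FRACTION * lam)
        n_comp = max(1, int(math.ceil(L / allowed - 1e-12)))
        clen = L / n_comp

        # length-weighted mean diameter per compartment
        bounds = np.arange(n_comp + 1) * clen
        diam = np.zeros(n_comp)
        pos = 0.0
        for r in rows:
            lo, hi = pos, pos + r.length
            i0 = min(int(lo / clen), n_comp - 1)
            i1 = min(int((hi - 1e-12) / clen), n_comp - 1)
            for i in range(i0, i1 + 1):
                overlap = min(hi, bounds[i + 1]) - max(lo, bounds[i])
                if overlap > 0:
                    diam[i] += overlap * r.diameter
            pos = hi
        diam /= clen

        parent_comp = point_to_comp[sec["attach_point"]]
        first_index = len(comps)
        for i in range(n_comp):
            d_i = float(diam[i])
            A_d = math.pi * d_i * clen
            q = spine_correction_factor(d_i, p.spine_density, p.spine_area)
            comp = Compartment(
                index=len(comps),
                kind="dendrite",
                arbor=sec["arbor"],
                length=clen,
                diameter=d_i,
                smooth_area=A_d,
                q=q,
                capacitance=units.membrane_capacitance_nF(p.Cm, q * A_d),
                leak_conductance=units.membrane_conductance_uS(p.Rm, q * A_d),
                axial_half_resistance=units.axial_resistance_Mohm(
                    p.Ra, clen / 2.0, d_i
                ),
                parent=parent_comp if i == 0 else len(comps) - 1,
                path_distance=sec["start_distance"] + (i + 0.5) * clen,
            )
            r_axial = comp.axial_half_resistance + comps[comp.parent].axial_half_resistance
            coupling.append((comp.parent, comp.index, 1.0 / r_axial))
            comps.append(comp)

        # map this section's morphology points onto its compartments
        pos = 0.0
        for r in rows:
            pos += r.length
            idx = min(int((pos - 1e-12) / clen), n_comp - 1)
            point_to_comp[int(r.child_id)] = first_index + idx

    return CableModel(comps, p, coupling, morphology_name=m.name)
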