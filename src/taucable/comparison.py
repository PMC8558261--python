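"""Group comparison graphs and statistics (WT vs TG).

Two families of comparison graphs are built from per-neuron descriptor
tables:

* ``distance_dependence`` — mean descriptor value per path-distance bin
  (absolute μm bins, or bins of % of each neuron's maximal site distance);
* ``surface_distribution`` — fraction of arbor surface area per descriptor
  bin (absolute descriptor units or % of each neuron's maximum).

Each neuron contributes at most one value per bin, so neurons — not
injection sites — are the independent statistical units.  Graphs are
evaluated by a two-way fixed-effects ANOVA (group × bin, type-II sums of
squares on the unbalanced design) with Bonferroni-corrected per-bin post
hoc tests, run only in bins where both groups have at least three values;
scalar summaries use Mann–Whitney; distribution identity uses a
Kolmogorov–Smirnov statistic on the cumulative binned curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

DEFAULT_ALPHA = 0.05
MIN_BIN_N = 3  # per-group minimum for a bin to enter post hoc testing

#: default bin widths per descriptor (absolute scales); normalized scales
#: use 10% bins.  Chosen to mirror the granularity of the study's graphs.
DEFAULT_BIN_WIDTHS = {
    "path_distance": 50.0,  # μm
    "v_transfer_ss": 0.05,
    "v_transfer_50hz": 0.05,
    "c_transfer": 0.05,
    "delay_local": 2.0,  # ms
    "delay_prop": 2.0,
    "delay_total": 2.0,
    "half_width": 2.0,
    "rise_10_90": 1.0,
    "normalized": 10.0,  # percent
}


class DegenerateDataError(ValueError):
    """All values identical — variance tests are undefined."""


@dataclass
class ComparisonGraph:
    mode: str  # "distance_dependence" | "surface_distribution"
    scale: str  # "absolute" | "normalized"
    descriptor: str
    arbor: str
    edges: np.ndarray
    #: long format: neuron, group, bin (int), value
    data: pd.DataFrame


@dataclass
class StatReport:
    graph: ComparisonGraph
    anova: dict  # p_group, p_bin, p_interaction
    posthoc: pd.DataFrame  # bin, n_wt, n_tg, p_raw, p_adj, significant
    alpha: float = DEFAULT_ALPHA

    @property
    def n_eligible(self) -> int:
        return int(self.posthoc["eligible"].sum())

    @property
    def n_flagged(self) -> int:
        return int(self.posthoc["significant"].sum())


def build_graph(
    tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    mode: str,
    scale: str,
    descriptor: str,
    arbor: str,
    bin_width: float | None = None,
) -> ComparisonGraph:
    """Bin per-neuron descriptor tables into one comparison graph.

    Distance mode bins sites by path distance and averages the descriptor;
    surface mode bins sites by descriptor value and accumulates surface-area
    fractions (which sum to 1 per neuron).  Normalized scales express the
    binning axis as a percentage of each neuron's own maximum.  Neurons
    with an empty arbor are skipped with a warning.
    """
    if mode not in ("distance_dependence", "surface_distribution"):
        raise ValueError(f"unknown mode {mode!r}")
    if scale not in ("absolute", "normalized"):
        raise ValueError(f"unknown scale {scale!r}")
    axis = "path_distance" if mode == "distance_dependence" else descriptor
    if bin_width is None:
        bin_width = (
            DEFAULT_BIN_WIDTHS["normalized"]
            if scale == "normalized"
            else DEFAULT_BIN_WIDTHS.get(axis, 0.05)
        )

    per_neuron: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, tbl in tables.items():
        sub = tbl[tbl["arbor"] == arbor]
        if sub.empty:
            warnings.warn(f"neuron {name}: empty {arbor} arbor, skipped")
            continue
        x = sub[axis].to_numpy(dtype=float)
        if scale == "normalized":
            x = 100.0 * x / x.max()
        y = (
            sub[descriptor].to_numpy(dtype=float)
            if mode == "distance_dependence"
            else sub["area"].to_numpy(dtype=float)
        )
        per_neuron[name] = (x, y)
    if not per_neuron:
        raise ValueError("no neuron has data for this graph")

    if scale == "normalized":
        hi = 100.0
    else:
        hi = max(x.max() for x, _ in per_neuron.values())
    n_bins = max(1, int(np.ceil(hi / bin_width - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width

    rows = []
    for name, (x, y) in per_neuron.items():
        idx = np.minimum((x / bin_width).astype(int), n_bins - 1)
        if mode == "distance_dependence":
            for b in np.unique(idx):
                rows.append(
                    {"neuron": name, "group": groups[name], "bin": int(b),
                     "value": float(y[idx == b].mean())}
                )
        else:
            total = y.sum()
            occupied = np.unique(idx)
            lo_b, hi_b = occupied.min(), occupied.max()
            for b in range(lo_b, hi_b + 1):
                rows.append(
                    {"neuron": name, "group": groups[name], "bin": int(b),
                     "value": float(y[idx == b].sum() / total)}
                )
    data = pd.DataFrame(rows)
    return ComparisonGraph(mode, scale, descriptor, arbor, edges, data)


def two_way_anova(g: ComparisonGraph) -> dict:
    """Fixed-effects two-factor ANOVA (group × bin) on per-neuron bin values."""
    d = g.data
    if d["group"].nunique() < 2 or d.groupby("group")["neuron"].nunique().min() < 2:
        raise ValueError("need at least two neurons in each group")
    if d["bin"].nunique() < 2:
        raise ValueError("need at least two occupied bins")
    if np.allclose(d["value"].var(), 0.0):
        raise DegenerateDataError("all values identical")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.ols("value ~ C(group) * C(bin)", data=d).fit()
        tbl = sm.stats.anova_lm(model, typ=2)
    return {
        "p_group": float(tbl.loc["C(group)", "PR(>F)"]),
        "p_bin": float(tbl.loc["C(bin)", "PR(>F)"]),
        "p_interaction": float(tbl.loc["C(group):C(bin)", "PR(>F)"]),
    }


def bonferroni_posthoc(
    g: ComparisonGraph,
    alpha: float = DEFAULT_ALPHA,
    min_n: int = MIN_BIN_N,
    test: str = "t",
) -> pd.DataFrame:
    """Per-bin two-sample tests, Bonferroni-corrected over eligible bins.

    A bin is eligible only if both groups contribute at least ``min_n``
    values (the study's "at least three data from both populations" rule).
    ``test`` is ``"t"`` (pooled two-sample t, consistent with the ANOVA) or
    ``"mannwhitney"``.
    """
    d = g.data
    groups = sorted(d["group"].unique())
    if len(groups) != 2:
        raise ValueError("post hoc needs exactly two groups")
    rows = []
    for b in sorted(d["bin"].unique()):
        x = d.loc[(d["bin"] == b) & (d["group"] == groups[0]), "value"].to_numpy()
        y = d.loc[(d["bin"] == b) & (d["group"] == groups[1]), "value"].to_numpy()
        rows.append({"bin": b, "n_a": len(x), "n_b": len(y),
                     "eligible": len(x) >= min_n and len(y) >= min_n,
                     "_x": x, "_y": y})
    n_eligible = sum(r["eligible"] for r in rows)
    out = []
    for r in rows:
        if r["eligible"]:
            x, y = r["_x"], r["_y"]
            if np.ptp(np.concatenate([x, y])) == 0:
                p = 1.0
            elif test == "t":
                p = float(st.ttest_ind(x, y).pvalue)
            elif test == "mannwhitney":
                p = float(st.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            p_adj = min(1.0, p * n_eligible)
        else:
            p = p_adj = np.nan
        out.append({"bin": r["bin"], "n_a": r["n_a"], "n_b": r["n_b"],
                    "eligible": r["eligible"], "p_raw": p, "p_adj": p_adj,
                    "significant": bool(r["eligible"] and p_adj < alpha)})
    return pd.DataFrame(out)


def evaluate_graph(
    g: ComparisonGraph, alpha: float = DEFAULT_ALPHA, posthoc_test: str = "t"
) -> StatReport:
    return StatReport(
        graph=g,
        anova=two_way_anova(g),
        posthoc=bonferroni_posthoc(g, alpha=alpha, test=posthoc_test),
        alpha=alpha,
    )


def ks_identity(d1: Sequence[float], d2: Sequence[float]) -> tuple[float, float]:
    """KS statistic and approximate p for two binned fraction distributions.

    ``d1`` and ``d2`` are per-bin fractions over identical bin edges (each
    summing to 1).  D is the maximum absolute difference of the cumulative
    curves; the p value uses the classical two-sample asymptotic formula
    with effective sample size = number of bins — approximate, because the
    weighted fractions are not i.i.d. samples.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("distributions must share bin edges")
    D = float(np.max(np.abs(np.cumsum(a) - np.cumsum(b))))
    nb = len(a)
    en = np.sqrt(nb / 2.0)
    p = float(st.kstwobign.sf((en + 0.12 + 0.11 / en) * D))
    return D, min(1.0, max(0.0, p))


def mann_whitney(x_wt: Sequence[float], x_tg: Sequence[float]) -> float:
    """Two-sided Mann–Whitney U p-value (tie-corrected) for per-neuron scalars."""
    x = np.asarray(x_wt, dtype=float)
    y = np.asarray(x_tg, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(st.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def percent_significant(reports: Sequence[StatReport]) -> float:
    """100 × (flagged bins)/(eligible bins) over a set of stat reports."""
    eligible = sum(r.n_eligible for r in reports)
    if eligible == 0:
        return float("nan")
    return 100.0 * sum(r.n_flagged for r in reports) / eligible
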