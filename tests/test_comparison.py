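import numpy as np
import pandas as pd
import pytest

from taucable import comparison
from taucable.comparison import (
    ComparisonGraph,
    bonferroni_posthoc,
    build_graph,
    ks_identity,
    mann_whitney,
    percent_significant,
    two_way_anova,
)


def _toy_tables(rng, n_per_group=5, shift=0.0, n_sites=40):
    """Synthetic descriptor tables: value drifts with distance + neuron noise."""
    tables, groups = {}, {}
    for g, label in (("WT", "w"), ("TG", "t")):
        for k in range(n_per_group):
            name = f"{label}{k}"
            dist = rng.uniform(5, 480, n_sites)
            offset = shift if g == "TG" else 0.0
            val = 1.0 - dist / 600 + 0.02 * rng.normal(size=n_sites) + offset
            tables[name] = pd.DataFrame(
                {
                    "arbor": "basal",
                    "path_distance": dist,
                    "value": val,
                    "area": rng.uniform(20, 80, n_sites),
                }
            )
            groups[name] = g
    return tables, groups


class TestBuildGraph:
    def test_uniform_descriptor_constant_across_bins(self):
        rng = np.random.default_rng(0)
        tables, groups = _toy_tables(rng, n_per_group=2)
        for t in tables.values():
            t["value"] = 0.7
        g = build_graph(tables, groups, "distance_dependence", "absolute",
                       "value", "basal")
        assert np.allclose(g.data["value"], 0.7)

    def test_surface_fractions_sum_to_one_per_neuron(self):
        rng = np.random.default_rng(1)
        tables, groups = _toy_tables(rng)
        g = build_graph(tables, groups, "surface_distribution", "absolute",
                       "value", "basal", bin_width=0.1)
        sums = g.data.groupby("neuron")["value"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_normalized_scale_max_lands_in_last_bin(self):
        rng = np.random.default_rng(2)
        tables, groups = _toy_tables(rng)
        g = build_graph(tables, groups, "distance_dependence", "normalized",
                       "value", "basal", bin_width=10.0)
        n_bins = len(g.edges) - 1
        for name, t in tables.items():
            assert g.data[(g.data["neuron"] == name)]["bin"].max() == n_bins - 1

    def test_empty_arbor_neuron_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        tables, groups = _toy_tables(rng)
        tables["w0"] = tables["w0"].assign(arbor="apical")
        with pytest.warns(UserWarning, match="w0"):
            g = build_graph(tables, groups, "distance_dependence", "absolute",
                           "value", "basal")
        assert "w0" not in set(g.data["neuron"])


class TestTwoWayAnova:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(4)
        tables, groups = _toy_tables(rng, shift=0.06)  # 3σ of site noise
        g = build_graph(tables, groups, "distance_dependence", "absolute",
                       "value", "basal")
        assert two_way_anova(g)["p_group"] < 0.001

    def test_label_permutation_destroys_signal(self):
        rng = np.random.default_rng(5)
        tables, groups = _toy_tables(rng, n_per_group=6, shift=0.06)
        # balanced relabelling: each pseudo-group gets half of each true group
        mixed = {name: ("WT" if int(name[1:]) % 2 else "TG") for name in groups}
        g = build_graph(tables, mixed, "distance_dependence", "absolute",
                       "value", "basal")
        assert two_way_anova(g)["p_group"] > 0.05

    def test_degenerate_variance_raises(self):
        rng = np.random.default_rng(6)
        tables, groups = _toy_tables(rng)
        for t in tables.values():
            t["value"] = 1.0
        g = build_graph(tables, groups, "distance_dependence", "absolute",
                       "value", "basal")
        with pytest.raises(comparison.DegenerateDataError):
            two_way_anova(g)

    def test_iid_null_rejection_rate_calibrated(self):
        # the cascade's F-test holds its nominal size on exchangeable data
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            rows = [
                {"neuron": f"{g}{k}", "group": g, "bin": b, "value": rng.normal()}
                for g in ("WT", "TG")
                for k in range(6)
                for b in range(8)
            ]
            graph = ComparisonGraph(
                "distance_dependence", "absolute", "x", "basal",
                np.arange(9), pd.DataFrame(rows),
            )
            hits += two_way_anova(graph)["p_group"] < 0.05
        assert 0.02 <= hits / n_rep <= 0.08


class TestBonferroni:
    def test_sparse_bin_excluded(self):
        rng = np.random.default_rng(8)
        tables, groups = _toy_tables(rng, n_per_group=3)
        # push one WT neuron's sites out of the first bin
        tables["w0"] = tables["w0"].assign(
            path_distance=np.clip(tables["w0"]["path_distance"], 120, None)
        )
        g = build_graph(tables, groups, "distance_dependence", "absolute",
                       "value", "basal", bin_width=50.0)
        ph = bonferroni_posthoc(g)
        first = ph[ph["bin"] == 0].iloc[0]
        assert min(first["n_a"], first["n_b"]) == 2 and not first["eligible"]
        assert np.isnan(first["p_adj"])

    def test_identical_groups_rarely_flag(self):
        rng = np.random.default_rng(9)
        flags = 0
        for k in range(20):
            tables, groups = _toy_tables(np.random.default_rng(100 + k))
            g = build_graph(tables, groups, "distance_dependence", "absolute",
                           "value", "basal")
            flags += bonferroni_posthoc(g)["significant"].sum()
        assert flags <= 2  # binomial bound at the corrected level

    def test_strongly_shifted_bin_flagged(self):
        rng = np.random.default_rng(10)
        tables, groups = _toy_tables(rng, n_per_group=6)
        for name, t in tables.items():
            if groups[name] == "TG":
                sel = (t["path_distance"] >= 200) & (t["path_distance"] < 250)
                t.loc[sel, "value"] += 0.5  # ≫ 5σ
        g = build_graph(tables, groups, "distance_dependence", "absolute",
                       "value", "basal", bin_width=50.0)
        ph = bonferroni_posthoc(g)
        assert bool(ph.loc[ph["bin"] == 4, "significant"].iloc[0])


class TestScalarTests:
    def test_ks_identity_of_identical_input(self):
        d = np.array([0.2, 0.3, 0.4, 0.1])
        D, p = ks_identity(d, d)
        assert D == 0.0
        assert p > 0.999

    def test_ks_disjoint_supports(self):
        a = np.array([0.5, 0.5] + [0.0] * 18)
        b = np.array([0.0] * 18 + [0.5, 0.5])
        D, p = ks_identity(a, b)
        assert D == pytest.approx(1.0)
        assert p < 1e-3

    def test_mann_whitney_identical(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert mann_whitney(x, x) == pytest.approx(1.0, abs=0.05)

    def test_mann_whitney_large_shift(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 10)
        assert mann_whitney(x, x + 10.0) < 0.001

    def test_mann_whitney_monotone_transform_invariant(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(1, 2, 8)
        y = rng.uniform(1.5, 2.5, 9)
        assert mann_whitney(x, y) == pytest.approx(
            mann_whitney(np.exp(x), np.exp(y)), rel=1e-12
        )


class TestPercentSignificant:
    def _report(self, flags, eligible):
        ph = pd.DataFrame(
            {
                "bin": range(eligible),
                "eligible": [True] * eligible,
                "significant": [True] * flags + [False] * (eligible - flags),
            }
        )
        g = ComparisonGraph("distance_dependence", "absolute", "x", "basal",
                            np.arange(eligible + 1), pd.DataFrame())
        return comparison.StatReport(g, {}, ph)

    def test_extremes(self):
        assert percent_significant([self._report(0, 10)]) == 0.0
        assert percent_significant([self._report(10, 10)]) == 100.0

    def test_five_of_fifteen(self):
        assert percent_significant(
            [self._report(2, 5), self._report(3, 10)]
        ) == pytest.approx(33.3, abs=0.05)

    def test_order_invariance(self):
        reps = [self._report(1, 4), self._report(2, 6), self._report(0, 5)]
        assert percent_significant(reps) == percent_significant(reps[::-1])
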