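import math

import numpy as np
import pandas as pd
import pytest

from taucable.cable_model import MembraneParams, compartmentalize
from taucable.descriptors import (
    area_weighted_mean,
    current_transfer,
    delays,
    descriptor_table,
    electrotonic_distance,
    electrotonic_summary,
    somatic_epsp_shape,
    voltage_transfer_sin,
    voltage_transfer_ss,
)
from taucable.solver import StimulusSpec, solve_steady
from taucable.synthetic_data import make_cylinder
from taucable import units
from tests.conftest import CANON, make_soma_only

TAU = CANON.Rm * CANON.Cm * 1e-3  # ms


class TestVoltageTransfer:
    def test_soma_site_is_unity(self, cable_model):
        assert voltage_transfer_ss(cable_model, cable_model.soma_index) == 1.0

    def test_monotone_decrease_along_cable(self, cable_model):
        dend = cable_model.dendritic_indices()
        t = [voltage_transfer_ss(cable_model, int(i)) for i in dend]
        assert np.all(np.diff(t) < 0)

    def test_sealed_cable_cosh_oracle(self, cable_model):
        # V(x)/V(l) under tip injection = cosh((l-x)/λ)/cosh(... ) ->
        # transfer from tip to origin of a sealed cable = 1/cosh(L)
        lam = units.space_constant_um(1.0, CANON.Rm, CANON.Ra)
        tip = int(cable_model.dendritic_indices()[-1])
        x_mid = cable_model.compartments[tip].path_distance
        expected = 1.0 / math.cosh(x_mid / lam)
        assert voltage_transfer_ss(cable_model, tip) == pytest.approx(
            expected, rel=0.005
        )

    def test_sinusoid_below_steady_and_dc_limit(self, cable_model):
        site = int(cable_model.dendritic_indices()[30])
        ss = voltage_transfer_ss(cable_model, site)
        assert voltage_transfer_sin(cable_model, site, 50.0) < ss
        assert voltage_transfer_sin(cable_model, site, 1e-4) == pytest.approx(
            ss, rel=1e-6
        )

    def test_lowpass_monotone_in_frequency(self, wt_tree_model):
        site = int(wt_tree_model.dendritic_indices()[40])
        t = [voltage_transfer_sin(wt_tree_model, site, f) for f in (1, 10, 50, 100)]
        assert np.all(np.diff(t) < 0)


class TestCurrentTransfer:
    def test_soma_site_is_unity(self, cable_model):
        assert current_transfer(cable_model, cable_model.soma_index) == 1.0

    def test_reciprocity_identity_all_sites(self, wt_tree_model):
        # somatopetal charge transfer == somatofugal voltage transfer
        v = solve_steady(wt_tree_model, wt_tree_model.soma_index)
        for site in wt_tree_model.dendritic_indices():
            expected = v[site] / v[wt_tree_model.soma_index]
            assert current_transfer(wt_tree_model, int(site)) == pytest.approx(
                expected, rel=1e-8
            )

    def test_distal_below_proximal(self, cable_model):
        dend = cable_model.dendritic_indices()
        assert current_transfer(cable_model, int(dend[-1])) < current_transfer(
            cable_model, int(dend[0])
        )


class TestDelays:
    def test_isopotential_local_delay_is_tau(self, soma_model):
        local, prop, total = delays(soma_model, 0)
        assert prop == pytest.approx(0.0, abs=1e-9)
        assert local == pytest.approx(TAU, abs=0.01)

    def test_input_shape_independence(self, cable_model):
        site = int(cable_model.dendritic_indices()[20])
        alpha = StimulusSpec(site=site, kind="alpha_current", amplitude=0.25)
        pulse = StimulusSpec(site=site, kind="current_step", amplitude=0.1,
                             duration=1.0)
        d1 = delays(cable_model, site, alpha)
        d2 = delays(cable_model, site, pulse)
        # centroid delays of a linear system are input-independent; the
        # residual difference is window truncation + pulse-centroid offset
        assert d1[2] - d1[0] == pytest.approx(d2[2] - d2[0], abs=2e-3)
        assert d1[0] == pytest.approx(d2[0], abs=2e-3)

    def test_moment_route_matches_simulation(self, wt_tree_model):
        tbl = descriptor_table(wt_tree_model, include_epsp_shape=False)
        site = int(tbl["site"].iloc[33])
        loc, prop, tot = delays(wt_tree_model, site, t_stop=800.0)
        row = tbl[tbl["site"] == site].iloc[0]
        assert row["delay_local"] == pytest.approx(loc, abs=0.01)
        assert row["delay_total"] == pytest.approx(tot, abs=0.01)

    def test_total_delay_monotone_with_distance(self, cable_model):
        tbl = descriptor_table(cable_model, include_epsp_shape=False)
        tbl = tbl.sort_values("path_distance")
        assert np.all(np.diff(tbl["delay_total"]) > -1e-9)
        assert (tbl["delay_local"] >= 0).all()
        assert (tbl["delay_prop"] >= 0).all()


class TestEpspShape:
    def test_shape_broadens_with_distance(self, cable_model):
        dend = cable_model.dendritic_indices()
        near, far = int(dend[2]), int(dend[-1])
        r_near, hw_near = somatic_epsp_shape(cable_model, near)
        r_far, hw_far = somatic_epsp_shape(cable_model, far)
        assert r_far > r_near
        assert hw_far > hw_near

    def test_proximal_halfwidth_minimal(self, cable_model):
        tbl = descriptor_table(cable_model, include_epsp_shape=True)
        assert tbl["half_width"].idxmin() == tbl["path_distance"].idxmin()

    def test_quasi_linear_in_gmax(self, cable_model):
        site = int(cable_model.dendritic_indices()[10])
        r1, _ = somatic_epsp_shape(cable_model, site, g_max=0.25)
        r2, _ = somatic_epsp_shape(cable_model, site, g_max=0.5)
        assert abs(r2 - r1) / r1 < 0.01


class TestElectrotonicDistance:
    def test_soma_is_zero(self, cable_model):
        assert electrotonic_distance(cable_model, cable_model.soma_index) == 0.0

    def test_cable_of_one_lambda(self):
        lam = units.space_constant_um(1.0, CANON.Rm, CANON.Ra)
        m = make_cylinder(1.0, lam, 101, soma_radius=0.01)
        cm = compartmentalize(m, CANON, max_len=10.0)
        tip = int(cm.dendritic_indices()[-1])
        assert electrotonic_distance(cm, tip, at="distal") == pytest.approx(
            1.0, rel=1e-6
        )

    def test_spine_density_scaling(self):
        m = make_cylinder(1.0, 400.0, 41)
        bare = compartmentalize(m, MembraneParams(Rm=10000.0))
        spiny = compartmentalize(
            m, MembraneParams(Rm=10000.0, spine_density=1.25, spine_area=1.5)
        )
        q = 1 + 1.25 * 1.5 / math.pi
        tip_b = int(bare.dendritic_indices()[-1])
        tip_s = int(spiny.dendritic_indices()[-1])
        L_b = electrotonic_distance(bare, tip_b, at="distal")
        L_s = electrotonic_distance(spiny, tip_s, at="distal")
        assert L_s == pytest.approx(L_b * math.sqrt(q), rel=1e-6)


class TestTableAndSummaries:
    def test_record_count_and_invariants(self, wt_tree_model):
        tbl = descriptor_table(wt_tree_model, include_epsp_shape=False)
        assert len(tbl) == len(wt_tree_model.dendritic_indices())
        assert ((tbl["v_transfer_ss"] > 0) & (tbl["v_transfer_ss"] <= 1)).all()
        assert (tbl["v_transfer_50hz"] <= tbl["v_transfer_ss"] + 1e-12).all()
        assert ((tbl["c_transfer"] > 0) & (tbl["c_transfer"] <= 1)).all()
        np.testing.assert_allclose(
            tbl["delay_total"], tbl["delay_local"] + tbl["delay_prop"], rtol=1e-12
        )
        assert (tbl["L"] >= 0).all()
        assert np.isfinite(tbl.drop(columns=["neuron", "arbor",
                                             "rise_10_90", "half_width"])
                           .to_numpy(dtype=float)).all()

    def test_table_deterministic(self, wt_tree_model):
        t1 = descriptor_table(wt_tree_model, include_epsp_shape=False)
        t2 = descriptor_table(wt_tree_model, include_epsp_shape=False)
        pd.testing.assert_frame_equal(t1, t2)

    def test_area_weighted_mean_hand_example(self):
        tbl = pd.DataFrame(
            {"area": [1.0, 3.0], "x": [0.0, 1.0], "arbor": ["basal", "basal"]}
        )
        assert area_weighted_mean(tbl, "x") == pytest.approx(0.75)

    def test_area_weighted_mean_uniform_is_identity(self):
        tbl = pd.DataFrame(
            {"area": [2.0, 5.0, 1.0], "x": [3.3, 3.3, 3.3],
             "arbor": ["basal"] * 3}
        )
        assert area_weighted_mean(tbl, "x") == pytest.approx(3.3)

    def test_area_weighted_mean_matches_bruteforce(self, wt_tree_model):
        tbl = descriptor_table(wt_tree_model, include_epsp_shape=False)
        sub = tbl[tbl["arbor"] == "basal"]
        brute = sum(a * d for a, d in zip(sub["area"], sub["v_transfer_ss"])) / sum(
            sub["area"]
        )
        assert area_weighted_mean(tbl, "v_transfer_ss", "basal") == pytest.approx(
            brute, rel=1e-12
        )

    def test_electrotonic_summary_toy_values(self, cable_model):
        es = electrotonic_summary(cable_model)
        row = es[es["arbor"] == "basal"].iloc[0]
        sites = cable_model.dendritic_indices()
        L = np.array([electrotonic_distance(cable_model, int(i)) for i in sites])
        assert row["mean_L"] == pytest.approx(L.mean(), rel=1e-12)
        assert row["var_L"] == pytest.approx(L.var(ddof=1), rel=1e-12)

    def test_symmetric_twins_share_mean(self):
        from taucable.synthetic_data import make_rall_tree

        m1 = make_rall_tree(1.0, depth=1, segment_l=200.0)
        cm1 = compartmentalize(m1, CANON)
        # twin branch tree: two identical stems from the soma
        from taucable.morphology import BASAL, SOMA, Morphology, MorphPoint

        pts = [MorphPoint(1, SOMA, 0, 0, 0, 5.0, -1)]
        for sgn in (1.0, -1.0):
            base = len(pts)
            for k in range(20):
                pts.append(
                    MorphPoint(len(pts) + 1, BASAL, sgn * 10.0 * (k + 1), 0, 0,
                               0.5, 1 if k == 0 else len(pts))
                )
        cm2 = compartmentalize(Morphology(pts), CANON)
        es1 = electrotonic_summary(cm1)
        es2 = electrotonic_summary(cm2)
        m1_mean = es1[es1["arbor"] == "basal"]["mean_L"].iloc[0]
        m2_mean = es2[es2["arbor"] == "basal"]["mean_L"].iloc[0]
        assert m2_mean == pytest.approx(m1_mean, rel=1e-9)
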