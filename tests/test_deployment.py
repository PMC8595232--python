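"""Crimp/release mechanics, pre-dilation, and the A/B/C deployment variants."""

import numpy as np
import pytest

import tevarsim as tv
from tevarsim.deployment import _crimp, _release_curve
from tevarsim.prestress import SolverError


@pytest.fixture(scope="module")
def sg():
    return tv.StentGraft()


@pytest.fixture(scope="module")
def dconfig():
    return tv.DeploymentConfig()


class TestStentRadialPressure:
    def test_virgin_ring_at_nominal_radius_is_stress_free(self, sg, dconfig):
        p, state = tv.stent_radial_pressure(sg.nominal_radius, tv.NitinolState(), sg, dconfig)
        assert p == pytest.approx(0.0, abs=1e-12)
        assert state.stress == 0.0

    def test_crimp_release_hysteresis(self, sg, dconfig):
        """Chronic outward force (release branch) is below the radial
        resistive force (crimping branch) at the same radius."""
        radii_probe = np.linspace(5.0, 12.0, 8)
        state = tv.NitinolState()
        crimping = {}
        for r in np.linspace(sg.nominal_radius, dconfig.crimp_diameter / 2, 600):
            p, state = tv.stent_radial_pressure(r, state, sg, dconfig)
            for rp in radii_probe:
                if abs(r - rp) < 0.01 and rp not in crimping:
                    crimping[rp] = p
        releasing = {}
        for r in np.linspace(dconfig.crimp_diameter / 2, sg.nominal_radius, 600):
            p, state = tv.stent_radial_pressure(r, state, sg, dconfig)
            for rp in radii_probe:
                if abs(r - rp) < 0.01 and rp not in releasing:
                    releasing[rp] = p
        for rp in radii_probe:
            assert releasing[rp] < crimping[rp]

    def test_crimp_strain_in_design_window(self, sg, dconfig):
        # crimping 28 -> 7 mm must land the wire just past the loading plateau
        wire = sg.wire
        state = _crimp(sg, dconfig)
        lo = wire.eps_L
        hi = wire.eps_L + wire.sigma_LE / wire.E_M + 0.01
        assert lo <= state.strain <= hi
        assert state.xi > 0.9

    def test_release_curve_monotone_decreasing(self, sg, dconfig):
        radii, pressures, _ = _release_curve(sg, dconfig)
        assert np.all(np.diff(pressures) <= 1e-9)
        assert pressures[0] > 50.0  # crimped: strongly pushing outward

    def test_recrimp_path_closure(self, sg, dconfig):
        """Re-crimping a released ring and re-releasing returns the same
        pressure at the same radius (closed internal loop)."""
        state = _crimp(sg, dconfig)
        r_eq = 6.0
        for r in np.linspace(dconfig.crimp_diameter / 2, r_eq, 300):
            p1, state = tv.stent_radial_pressure(r, state, sg, dconfig)
        for r in np.linspace(r_eq, dconfig.crimp_diameter / 2, 300):
            _, state = tv.stent_radial_pressure(r, state, sg, dconfig)
        for r in np.linspace(dconfig.crimp_diameter / 2, r_eq, 300):
            p2, state = tv.stent_radial_pressure(r, state, sg, dconfig)
        assert p2 == pytest.approx(p1, abs=1e-6)

    def test_invalid_radius_rejected(self, sg, dconfig):
        with pytest.raises(ValueError):
            tv.stent_radial_pressure(-1.0, tv.NitinolState(), sg, dconfig)


class TestPredilate:
    def test_narrow_station_dilated_to_target(self, default_vessel, dconfig):
        out = tv.predilate(default_vessel, dconfig)
        for st_in, st_out in zip(default_vessel.stations, out.stations):
            if 2 * st_in.ct_radius < 8.0:
                assert st_out.ct_radius == pytest.approx(4.0)
            else:
                assert st_out.ct_radius == st_in.ct_radius

    def test_monotone_no_station_shrinks(self, default_vessel, dconfig):
        out = tv.predilate(default_vessel, dconfig)
        assert np.all(out.radii >= default_vessel.radii - 1e-12)

    def test_narrowest_lumen_reaches_8mm(self, default_vessel, dconfig):
        out = tv.predilate(default_vessel, dconfig)
        assert 2 * out.radii.min() == pytest.approx(8.0)


class TestDeploy:
    def test_free_expansion_to_nominal_radius(self, sg):
        cfg = tv.AnatomyConfig(
            healthy_radius=30.0, entry_radius=32.0, min_lumen_diameter=58.0,
            distal_radius=30.0,
        )
        big = tv.generate_vessel(cfg)
        res = tv.deploy(sg, big, tv.DeploymentConfig(variant="A"))
        assert np.allclose(res.ends["radius_mm"], sg.nominal_radius, atol=0.05)

    def test_eighteen_ends_reported(self, deployments):
        for res in deployments.values():
            assert len(res.ends) == 18
            assert set(res.ends["label"]) == set(tv.StentGraft().end_labels)

    def test_deployed_radius_within_cap(self, deployments, sg):
        for res in deployments.values():
            assert np.all(res.ends["radius_mm"] <= sg.nominal_radius + 0.05)
            assert np.all(res.ends["radius_mm"] > 0)

    def test_variant_a_never_below_predilated_lumen(self, deployments, prestressed_vessel):
        # without pre-stress the wall only resists outward push from its
        # reference radius, so the stent cannot sit below it
        dil = tv.predilate(prestressed_vessel, tv.DeploymentConfig(variant="A"))
        res = deployments["A"]
        for _, row in res.ends.iterrows():
            st = dil.stations[dil.nearest_station(row["s_mm"])]
            assert row["radius_mm"] >= min(st.ct_radius, tv.StentGraft().nominal_radius) - 1e-6

    def test_graft_pressure_is_monotone_outward_load(self, deployments):
        # radius_C >= radius_B at every strut end (equality allowed at bare P1)
        rb = deployments["B"].ends.set_index("label")["radius_mm"]
        rc = deployments["C"].ends.set_index("label")["radius_mm"]
        assert np.all(rc.values >= rb.values - 1e-9)
        assert rc["P1"] == pytest.approx(rb["P1"])  # bare end gets no graft pressure

    def test_removing_prestress_increases_radius(self, deployments):
        ra = deployments["A"].ends.set_index("label")["radius_mm"]
        rb = deployments["B"].ends.set_index("label")["radius_mm"]
        assert np.all(ra.values >= rb.values - 1e-9)

    def test_variant_loa_ordering_in_dissection(self, deployments, dissection_labels):
        """Stress-free wall (A) over-opens, pre-stress without graft pressure
        (B) under-opens, full model (C) lies between: LOA_B <= LOA_C <= LOA_A
        at every dissection-section strut end."""
        loa = {v: deployments[v].ends.set_index("label")["loa_mm2"] for v in "ABC"}
        assert len(dissection_labels) > 0
        for lbl in dissection_labels:
            assert loa["B"][lbl] <= loa["C"][lbl] + 1e-9
            assert loa["C"][lbl] <= loa["A"][lbl] + 1e-9

    def test_entry_tear_largest_dissection_smallest(self, deployments):
        ends = deployments["C"].ends
        by_sec = ends.groupby("section")["loa_mm2"].mean()
        assert by_sec["entry_tear"] > by_sec["healthy"] > by_sec["dissection"]

    def test_device_must_fit_on_centreline(self, prestressed_vessel, sg):
        with pytest.raises(ValueError, match="fit"):
            tv.deploy(sg, prestressed_vessel, tv.DeploymentConfig(landing_offset=100.0))

    def test_loa_consistent_with_radius(self, deployments):
        # spline area through 5 apexes on a circle is slightly below pi r^2
        res = deployments["C"]
        for _, row in res.ends.iterrows():
            circle = np.pi * row["radius_mm"] ** 2
            assert 0.9 * circle < row["loa_mm2"] <= circle


class TestWallStressReport:
    def test_entry_tear_shielded_dissection_loaded(self, deployments, prestressed_vessel):
        rep = tv.wall_stress_report(deployments["C"], prestressed_vessel).set_index("section")
        assert rep.loc["entry_tear", "direction"] == "decrease"
        assert rep.loc["dissection", "direction"] == "increase"

    def test_uncovered_stations_unchanged(self, deployments):
        res = deployments["C"]
        un = ~res.covered
        assert un.any()
        np.testing.assert_allclose(res.wall_post_kpa[un], res.wall_pre_kpa[un])

    def test_variant_a_prestress_reported_as_zero(self, deployments):
        assert np.allclose(deployments["A"].wall_pre_kpa, 0.0)
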