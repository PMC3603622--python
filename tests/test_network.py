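"""Network topology, Murray radii, scenario overlays, serialization."""

import pytest

from coroflow.lumped import CoronaryBed, WindkesselElement
from coroflow.network import (NetworkSpec, apply_scenario, build_network,
                              insert_stenosis, murray_parent_radius)


class TestMurray:
    def test_single_daughter_passthrough(self):
        assert murray_parent_radius([1.3e-3]) == pytest.approx(1.3e-3)

    def test_two_equal_daughters(self):
        assert murray_parent_radius([1e-3, 1e-3]) == pytest.approx(2 ** (1 / 3) * 1e-3)

    def test_cascade(self):
        r = murray_parent_radius([2 ** (1 / 3) * 1e-3, 1e-3])
        assert r == pytest.approx(3 ** (1 / 3) * 1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            murray_parent_radius([])


@pytest.fixture(scope="module")
def net():
    return build_network()


class TestTopology:
    def test_systemic_segment_count(self, net):
        assert sum(1 for s in net.segments.values()
                   if s.name.startswith("sys")) == 22

    def test_fourteen_coronary_terminals(self, net):
        beds = [s for s in net.segments.values()
                if isinstance(s.terminal, CoronaryBed)]
        assert len(beds) == 14
        assert all(s.mean_radius == pytest.approx(1e-3) for s in beds)

    def test_eleven_systemic_terminals(self, net):
        wks = [s for s in net.segments.values()
               if isinstance(s.terminal, WindkesselElement)]
        assert len(wks) == 11

    def test_murray_consistency(self, net):
        """Recomputing every coronary junction from its distal leaves
        reproduces the stored radii exactly."""
        def subtree_radius(name):
            kids = net.children(name)
            if not kids:
                return net.segments[name].mean_radius
            return murray_parent_radius([subtree_radius(k) for k in kids])

        for stem in ("LMCA", "LAD_b", "LAD_c", "LAD_d", "LAD_e", "RCA_b", "LCx_b"):
            assert net.segments[stem].mean_radius == pytest.approx(
                subtree_radius(stem), rel=1e-12)

    def test_expected_murray_values(self, net):
        assert net.segments["LAD_e"].mean_radius * 1e3 == pytest.approx(1.2599, abs=1e-4)
        assert net.segments["LAD_d"].mean_radius * 1e3 == pytest.approx(1.4422, abs=1e-4)
        assert net.segments["LMCA"].mean_radius * 1e3 == pytest.approx(9 ** (1 / 3), abs=1e-4)

    def test_coronary_kappa(self, net):
        for s in net.segments.values():
            if s.wall_kind == "coronary":
                assert s.h / s.mean_radius == pytest.approx(0.1)

    def test_ostia_off_first_aortic_segment(self, net):
        assert net.segments["LMCA"].parent.startswith("sys01")
        assert net.segments["RCA_b"].parent.startswith("sys01")
        assert net.segments["sys01 ascending aorta A"].length == pytest.approx(5e-3)

    def test_table_geometry_spot_checks(self, net):
        asc = net.segments["sys01 ascending aorta A"]
        assert (asc.r_prox, asc.h) == (14.7e-3, 1.63e-3)
        car = net.segments["sys05 left carotid"]
        assert car.terminal.Z == pytest.approx(161e6)
        assert car.terminal.R_w == pytest.approx(1.80e9)
        assert car.terminal.C_w == pytest.approx(0.835e-9)

    def test_validation_catches_orphans(self, net):
        broken = build_network()
        broken.segments["LAD_b"].parent = None
        with pytest.raises(ValueError):
            broken.validate()


class TestScenarios:
    def test_stenosis_overlay_splits_host(self):
        cfg = apply_scenario("stenosis-severe")
        segs = cfg.network.segments
        assert "LAD_c" not in segs
        sten = segs["LAD_c~sten"]
        assert sten.kind == "stenosis"
        assert sten.sten.diameter_reduction == 70.0
        assert sten.sten.length == pytest.approx(7.48e-3)
        assert sten.sten.a0 == pytest.approx(segs["LAD_c~prox"].r_dist)
        # children rewired to the distal stub
        assert segs["LAD_d"].parent == "LAD_c~dist"
        cfg.network.validate()

    def test_stenosis_scenarios_apply_hyperemia(self):
        cfg = apply_scenario("stenosis-mild")
        beds = [s.terminal for s in cfg.network.segments.values()
                if isinstance(s.terminal, CoronaryBed)]
        assert all(b.hyperemia == 5.0 for b in beds)
        assert cfg.network.segments["LAD_c~sten"].sten.diameter_reduction == 50.0

    def test_lvh_overlay(self):
        pre = apply_scenario("lvh-pre")
        assert pre.heart.V_w == pytest.approx(250e-6)
        assert pre.heart.c == pytest.approx(1.4)
        assert pre.valves.R_av_o == pytest.approx(3e7)
        post = apply_scenario("lvh-post")
        assert post.heart.V_w == pytest.approx(200e-6)
        assert post.heart.c == 1.0 and post.valves.R_av_o == 1.0

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            apply_scenario("zebra")

    def test_stenosis_longer_than_host_rejected(self):
        net = build_network()
        with pytest.raises(ValueError):
            insert_stenosis(net, "LAD_c", 50.0, 20e-3)


class TestSerialization:
    def test_round_trip(self):
        cfg = apply_scenario("stenosis-severe")
        data = cfg.network.to_dict()
        back = NetworkSpec.from_dict(data)
        assert set(back.segments) == set(cfg.network.segments)
        for name, seg in cfg.network.segments.items():
            b = back.segments[name]
            assert (b.parent, b.length, b.r_prox, b.r_dist, b.h,
                    b.wall_kind, b.kind) == (
                seg.parent, seg.length, seg.r_prox, seg.r_dist, seg.h,
                seg.wall_kind, seg.kind)
            assert type(b.terminal) is type(seg.terminal)
            if seg.sten is not None:
                assert b.sten.diameter_reduction == seg.sten.diameter_reduction
        back.validate()

    def test_yaml_round_trip(self, tmp_path):
        net = build_network()
        path = tmp_path / "net.yaml"
        net.to_yaml(path)
        back = NetworkSpec.from_yaml(path)
        assert set(back.segments) == set(net.segments)
        back.validate()
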