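"""Body assembly, mass/CoM computation, expansion factors, CoM metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hullmass.body_model import (
    BodyModel,
    BodySegment,
    ExpansionFactorTable,
    Landmarks,
    SegmentValidationError,
    apply_expansion,
    assemble_body,
    body_mass_direct,
    body_volume,
    center_of_mass,
    com_metrics,
    compute_expansion_factors,
    deflate_trunk,
    load_expansion_table,
    load_landmarks_json,
)


def seg(name, volume, x, density=1000.0, ef=1.0):
    return BodySegment(name=name, volume=volume, centroid=np.array([x, 0.0, 0.0]),
                       density=density, expansion_factor=ef)


def two_segment_body(v_trunk=0.003, v_skull=0.002, x_trunk=0.0, x_skull=4.0,
                     landmarks=None):
    return assemble_body(
        [seg("trunk", v_trunk, x_trunk), seg("skull", v_skull, x_skull)],
        landmarks=landmarks, clade="mammal", specimen="toy",
    )


@pytest.fixture
def warnless(recwarn):
    yield  # partial bodies warn; tests that build them accept that


class TestAssembly:
    def test_sixteen_canonical_segments_valid(self, croc_body):
        model, _ = croc_body
        names = {s.name for s in model.segments}
        assert {"skull", "neck", "trunk", "tail"} <= names
        assert len(model.segments) == 16

    def test_sail_is_a_valid_extra_segment(self):
        with pytest.warns(UserWarning):
            model = assemble_body(
                [seg("trunk", 0.01, 0), seg("sail", 0.001, 0.2)], clade="fossil"
            )
        assert model.has_segment("sail")

    def test_duplicate_segment_rejected(self):
        with pytest.raises(SegmentValidationError, match="duplicate"):
            assemble_body([seg("skull", 0.01, 0), seg("skull", 0.01, 1)])

    def test_tail_subdivisions_allowed(self):
        with pytest.warns(UserWarning):
            model = assemble_body(
                [seg("trunk", 0.01, 0)]
                + [seg(f"tail_sub_{k}", 0.001, -k * 0.1) for k in (1, 2, 3)]
            )
        assert model.tail_volume == pytest.approx(0.003)

    def test_unknown_name_rejected(self):
        with pytest.raises(SegmentValidationError, match="unknown segment"):
            BodySegment(name="wing", volume=1.0, centroid=np.zeros(3))


class TestMass:
    def test_body_volume_is_plain_sum(self, warnless):
        model = two_segment_body(0.01, 0.02)
        assert body_volume(model) == pytest.approx(0.03, rel=1e-15)

    def test_volume_ignores_expansion(self, warnless):
        model = two_segment_body()
        expanded = apply_expansion(model, ExpansionFactorTable({"trunk": 2.0}))
        assert body_volume(expanded) == body_volume(model)

    def test_direct_mass_with_defaults(self, warnless):
        model = two_segment_body(0.003, 0.002)
        assert body_mass_direct(model) == pytest.approx(5.0)

    def test_direct_mass_with_trunk_expansion(self, warnless):
        # 0.002*1000 + 0.003*2*1000 = 8 kg
        model = two_segment_body(v_trunk=0.003, v_skull=0.002)
        model = apply_expansion(model, ExpansionFactorTable({"trunk": 2.0}))
        assert body_mass_direct(model) == pytest.approx(8.0)

    def test_sixteen_segment_sum_oracle(self, croc_body):
        model, truth = croc_body
        oracle = sum(v["volume"] for v in truth["segments"].values())
        assert body_volume(model) == pytest.approx(oracle, rel=1e-12)

    def test_single_expansion_changes_mass_by_exact_increment(self, croc_body):
        model, _ = croc_body
        f = 1.37
        trunk = model.segment("trunk")
        expanded = apply_expansion(model, ExpansionFactorTable({"trunk": f}))
        expected = (f - 1) * trunk.volume * trunk.density
        assert body_mass_direct(expanded) - body_mass_direct(model) == pytest.approx(
            expected, rel=1e-12
        )


class TestExpansionFactors:
    def test_mean_of_skin_hull_ratios(self):
        table = compute_expansion_factors(
            {"trunk": [1.0, 2.0]}, {"trunk": [1.2, 2.6]}
        )
        assert table.get("trunk") == pytest.approx(1.25)

    def test_identical_volumes_give_unity(self):
        table = compute_expansion_factors({"skull": [3.0]}, {"skull": [3.0]})
        assert table.get("skull") == 1.0

    def test_unpaired_entries_rejected(self):
        with pytest.raises(SegmentValidationError):
            compute_expansion_factors({"trunk": [1.0, 2.0]}, {"trunk": [1.0]})

    def test_missing_segment_defaults_to_one(self):
        table = ExpansionFactorTable({"trunk": 1.5})
        assert table.get("neck") == 1.0

    def test_all_unity_table_is_identity(self, croc_body):
        model, _ = croc_body
        table = ExpansionFactorTable({s.name: 1.0 for s in model.segments})
        expanded = apply_expansion(model, table)
        assert center_of_mass(expanded) == pytest.approx(center_of_mass(model), abs=0)
        assert body_mass_direct(expanded) == body_mass_direct(model)

    def test_tail_factor_moves_com_toward_tail(self, croc_body):
        model, _ = croc_body
        com0 = center_of_mass(model)
        com1 = center_of_mass(apply_expansion(model, ExpansionFactorTable({"tail": 1.5})))
        tail_x = model.segment("tail").centroid[0]
        assert abs(com1[0] - tail_x) < abs(com0[0] - tail_x)


class TestTrunkDeflation:
    def test_full_fraction_is_identity(self, croc_body):
        model, _ = croc_body
        assert body_mass_direct(deflate_trunk(model, 1.0)) == body_mass_direct(model)

    def test_trunk_only_body_mass_scales(self):
        with pytest.warns(UserWarning):
            model = assemble_body([seg("trunk", 0.01, 0)])
        assert body_mass_direct(deflate_trunk(model, 0.7)) == pytest.approx(7.0)

    def test_com_moves_away_from_trunk_monotonically(self, croc_body):
        model, _ = croc_body
        trunk_c = model.segment("trunk").centroid
        dists = [
            np.linalg.norm(center_of_mass(deflate_trunk(model, f)) - trunk_c)
            for f in (1.0, 0.9, 0.8, 0.7)
        ]
        assert dists == sorted(dists)

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_bad_fraction_rejected(self, croc_body, fraction):
        model, _ = croc_body
        with pytest.raises(SegmentValidationError):
            deflate_trunk(model, fraction)

    def test_no_trunk_rejected(self, warnless):
        with pytest.warns(UserWarning):
            model = assemble_body([seg("skull", 0.01, 0)])
        with pytest.raises(SegmentValidationError, match="trunk"):
            deflate_trunk(model, 0.9)


class TestCenterOfMass:
    def test_equal_masses_average(self, warnless):
        model = two_segment_body(0.01, 0.01, x_trunk=0.0, x_skull=2.0)
        assert center_of_mass(model) == pytest.approx([1.0, 0.0, 0.0])

    def test_weighted_mean(self, warnless):
        model = two_segment_body(v_trunk=0.001, v_skull=0.003, x_trunk=0.0, x_skull=4.0)
        assert center_of_mass(model)[0] == pytest.approx(3.0)

    def test_uniform_density_rescale_leaves_com(self, croc_body):
        model, _ = croc_body
        scaled = BodyModel(
            specimen=model.specimen, clade=model.clade,
            segments=tuple(
                BodySegment(s.name, s.volume, s.centroid, s.density * 1.08,
                            s.expansion_factor)
                for s in model.segments
            ),
            landmarks=model.landmarks,
        )
        assert center_of_mass(scaled) == pytest.approx(center_of_mass(model), abs=1e-15)

    def test_com_inside_centroid_hull(self, croc_body):
        model, _ = croc_body
        com = center_of_mass(model)
        cens = np.array([s.centroid for s in model.segments])
        assert np.all(com >= cens.min(axis=0) - 1e-12)
        assert np.all(com <= cens.max(axis=0) + 1e-12)


class TestCoMMetrics:
    def landmarks(self, ag=2.0, fl=1.0):
        return Landmarks(acetabulum=[0, 0, 0], glenoid=[ag, 0, 0], femur_length=fl)

    def test_com_at_acetabulum_is_zero_pct(self, warnless):
        model = two_segment_body(0.01, 0.01, x_trunk=-1.0, x_skull=1.0,
                                 landmarks=self.landmarks())
        assert com_metrics(model).pct_AG == pytest.approx(0.0, abs=1e-12)

    def test_com_at_glenoid_is_hundred_pct(self, warnless):
        model = two_segment_body(0.01, 0.01, x_trunk=1.0, x_skull=3.0,
                                 landmarks=self.landmarks())
        assert com_metrics(model).pct_AG == pytest.approx(100.0)

    def test_midpoint_with_half_length_femur(self, warnless):
        # CoM at AG midpoint, femur = |AG|/2: pct=50, dca_fl=1
        model = two_segment_body(0.01, 0.01, x_trunk=0.0, x_skull=2.0,
                                 landmarks=self.landmarks(ag=2.0, fl=1.0))
        metrics = com_metrics(model)
        assert metrics.pct_AG == pytest.approx(50.0)
        assert metrics.dca_fl == pytest.approx(1.0)

    def test_pct_and_dca_share_projection(self, croc_body):
        model, _ = croc_body
        m = com_metrics(model)
        ag = np.linalg.norm(model.landmarks.glenoid - model.landmarks.acetabulum)
        assert m.pct_AG == pytest.approx(
            100 * m.dca_fl * model.landmarks.femur_length / ag, rel=1e-12
        )

    def test_rigid_motion_invariance(self, croc_body):
        model, _ = croc_body
        rng = np.random.default_rng(1)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-5, 5, 3)
        moved = BodyModel(
            specimen=model.specimen, clade=model.clade,
            segments=tuple(
                BodySegment(s.name, s.volume, rot @ s.centroid + shift, s.density,
                            s.expansion_factor)
                for s in model.segments
            ),
            landmarks=Landmarks(
                acetabulum=rot @ model.landmarks.acetabulum + shift,
                glenoid=rot @ model.landmarks.glenoid + shift,
                femur_length=model.landmarks.femur_length,
            ),
        )
        m0, m1 = com_metrics(model), com_metrics(moved)
        assert m1.pct_AG == pytest.approx(m0.pct_AG, abs=1e-9)
        assert m1.dca_fl == pytest.approx(m0.dca_fl, abs=1e-9)

    def test_density_range_leaves_metrics_constant(self, croc_body):
        """Uniform whole-body density anywhere in the measured range
        (893-1080 kg/m^3) leaves both positional proxies exactly unchanged."""
        model, _ = croc_body
        base = com_metrics(model)
        for rho in (893.0, 1000.0, 1080.0):
            scaled = BodyModel(
                specimen=model.specimen, clade=model.clade,
                segments=tuple(
                    BodySegment(s.name, s.volume, s.centroid, rho, s.expansion_factor)
                    for s in model.segments
                ),
                landmarks=model.landmarks,
            )
            m = com_metrics(scaled)
            assert m.pct_AG == pytest.approx(base.pct_AG, abs=1e-12)
            assert m.dca_fl == pytest.approx(base.dca_fl, abs=1e-12)

    def test_missing_skull_marks_ratio_unavailable(self, warnless):
        with pytest.warns(UserWarning):
            model = assemble_body(
                [seg("trunk", 0.01, 0), seg("tail", 0.002, -1)],
                landmarks=self.landmarks(),
            )
        assert com_metrics(model).log10_skull_tail is None

    def test_missing_landmarks_disable_metrics_not_mass(self, warnless):
        model = two_segment_body()
        assert body_mass_direct(model) > 0
        with pytest.raises(SegmentValidationError, match="landmarks"):
            com_metrics(model)


class TestSerialization:
    def test_landmarks_json_round_trip(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text(
            '{"acetabulum": [0.1, 0, 0], "glenoid": [0.5, 0, 0.02], "femur_length_m": 0.14}'
        )
        lm = load_landmarks_json(path)
        assert lm.femur_length == 0.14
        assert lm.glenoid == pytest.approx([0.5, 0, 0.02])

    def test_expansion_table_csv_and_json(self, tmp_path):
        csv_path = tmp_path / "sef_table.csv"
        csv_path.write_text("segment,factor\ntrunk,1.21\ntail,1.44\n")
        table = load_expansion_table(csv_path)
        assert table.label == "SEF"
        assert table.get("tail") == 1.44
        json_path = tmp_path / "mef.json"
        json_path.write_text('{"label": "MEF", "factors": {"skull": 1.1}}')
        assert load_expansion_table(json_path).get("skull") == 1.1
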