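import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radrepeat.cohort import generate_lesion_image
from radrepeat.features import (
    BinningConfig,
    FeatureClass,
    FeatureRegistry,
    LesionCandidate,
    MissingFeatureError,
    ReferenceFirstOrderExtractor,
    Transform,
    TransformDomainError,
    apply_transform,
    build_default_registry,
    discretise,
    extract_features,
    first_order_features,
    lesion_eligibility,
)


@pytest.mark.parametrize("adc,rff,vol,change,expected", [
    (1200, 10, 2.0, False, True),    # typical low-ADC, low-fat target
    (1200, 10, 0.8, False, False),   # below the 1 mL volume floor
    (1600, 10, 2.0, True, True),     # high ADC rescued by unequivocal change
    (1600, 10, 2.0, False, False),
    (1200, 25, 2.0, False, False),   # fat signal too high
    (1399.9, 19.9, 1.0, False, True),  # all thresholds boundary-inclusive/exclusive
])
def test_lesion_eligibility_rule(adc, rff, vol, change, expected):
    c = LesionCandidate(mean_adc=adc, mean_rff=rff, volume_ml=vol,
                        unequivocal_change=change)
    assert lesion_eligibility(c) is expected


def test_candidate_requires_positive_volume():
    with pytest.raises(ValueError):
        LesionCandidate(1000, 10, 0.0)


class TestDiscretise:
    def test_formula(self):
        out = discretise([50, 150, 250], BinningConfig(bin_width=100))
        assert out.tolist() == [1, 2, 3]

    def test_adc_full_range_gives_30_levels(self):
        values = np.arange(0, 3000, 0.5)
        levels = discretise(values, BinningConfig.adc())
        assert len(np.unique(levels)) == 30
        assert levels.min() == 1 and levels.max() == 30

    def test_rff_full_range_gives_30_levels(self):
        values = np.linspace(0, 100, 5000, endpoint=False)
        levels = discretise(values, BinningConfig.rff())
        assert len(np.unique(levels)) == 30

    def test_below_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            discretise([-1.0, 5.0], BinningConfig.adc())

    @given(st.floats(1, 500), st.lists(st.floats(0, 3000), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_translation_by_one_bin_increments_levels(self, width, values):
        cfg = BinningConfig(bin_width=width)
        base = discretise(values, cfg)
        shifted = discretise(np.asarray(values) + width, cfg)
        assert np.array_equal(shifted, base + 1)


class TestTransforms:
    @pytest.mark.parametrize("value,rule,expected", [
        (1.0, Transform.LOG, 0.0),
        (0.9, Transform.ONE_MINUS, pytest.approx(0.1)),
        (1 - np.exp(-2.0), Transform.ONE_MINUS_THEN_LOG, pytest.approx(-2.0)),
        (-0.3, Transform.IDENTITY, -0.3),  # skewness keeps its native scale
    ])
    def test_rules(self, value, rule, expected):
        assert apply_transform(value, rule) == expected

    @pytest.mark.parametrize("value,rule", [
        (0.0, Transform.LOG),
        (-1.0, Transform.LOG),
        (1.0, Transform.ONE_MINUS_THEN_LOG),
        (1.5, Transform.ONE_MINUS_THEN_LOG),
    ])
    def test_domain_violations_flagged(self, value, rule):
        with pytest.raises(TransformDomainError):
            apply_transform(value, rule)

    @given(st.floats(-20, 20))
    @settings(max_examples=50, deadline=None)
    def test_log_inverts_exp(self, x):
        assert apply_transform(float(np.exp(x)), Transform.LOG) == pytest.approx(x, abs=1e-9)


class TestRegistry:
    def test_printed_class_counts(self):
        reg = build_default_registry()
        assert len(reg) == 106
        assert reg.class_counts() == {
            "firstorder": 19, "shape": 14, "glcm": 22,
            "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5,
        }

    def test_transform_assignments(self):
        reg = build_default_registry()
        assert reg.transform("firstorder_Skewness") is Transform.IDENTITY
        assert reg.transform("firstorder_Minimum") is Transform.IDENTITY
        assert reg.transform("glcm_Correlation") is Transform.IDENTITY
        assert reg.transform("glcm_ClusterShade") is Transform.IDENTITY
        assert reg.transform("glcm_Idn") is Transform.ONE_MINUS
        assert reg.transform("glcm_Idmn") is Transform.ONE_MINUS
        assert reg.transform("glcm_Imc2") is Transform.ONE_MINUS_THEN_LOG
        assert reg.transform("glcm_Imc1") is Transform.IDENTITY
        assert reg.transform("firstorder_Mean") is Transform.LOG
        assert reg.transform("shape_MeshVolume") is Transform.LOG

    def test_serialisation_roundtrip(self, tmp_path):
        reg = build_default_registry()
        reg.to_yaml(tmp_path / "reg.yaml")
        back = FeatureRegistry.from_yaml(tmp_path / "reg.yaml")
        assert back.class_counts() == reg.class_counts()
        assert back.names() == reg.names()
        assert all(back.transform(n) == reg.transform(n) for n in reg.names())

    def test_duplicate_names_rejected(self):
        from radrepeat.features import RegistryEntry

        e = RegistryEntry("x", FeatureClass.GLCM, Transform.LOG)
        with pytest.raises(ValueError):
            FeatureRegistry([e, e])


class TestFirstOrder:
    def test_constant_sample(self):
        f = first_order_features([1.0, 1.0, 1.0, 1.0])
        assert f["firstorder_Mean"] == 1.0
        assert f["firstorder_Variance"] == 0.0
        assert f["firstorder_Range"] == 0.0
        assert f["firstorder_RootMeanSquared"] == 1.0

    def test_two_point_sample(self):
        f = first_order_features([0.0, 2.0])
        assert f["firstorder_Mean"] == 1.0
        assert f["firstorder_RootMeanSquared"] == pytest.approx(np.sqrt(2), abs=1e-5)

    def test_symmetric_sample_zero_skewness(self):
        assert first_order_features([1.0, 2.0, 3.0])["firstorder_Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_pearson_kurtosis_convention(self):
        # normal sample: Pearson kurtosis ~ 3, never ~ 0
        x = np.random.default_rng(0).standard_normal(20000) + 10
        assert first_order_features(x)["firstorder_Kurtosis"] == pytest.approx(3.0, abs=0.15)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            first_order_features([1.0])


class TestExtractFeatures:
    def _firstorder_registry(self):
        reg = build_default_registry()
        return FeatureRegistry(list(reg.subset(FeatureClass.FIRSTORDER)))

    def test_uniform_image_native_mean(self):
        image, mask = generate_lesion_image(1000, 0, 1.0, (1, 1, 1))
        out = extract_features(image, mask, self._firstorder_registry(),
                               BinningConfig.adc(), transform=False)
        assert out["firstorder_Mean"] == 1000.0

    def test_native_matches_reference_extractor(self):
        """Independent scipy-based extractor agrees with the native
        first-order implementation to 1e-6 relative."""
        image, mask = generate_lesion_image(1000, 200, 1.0, (1, 1, 1), seed=8)
        reg = self._firstorder_registry()
        cfg = BinningConfig.adc()
        native = extract_features(image, mask, reg, cfg, transform=False)
        ref = ReferenceFirstOrderExtractor().extract(image, mask, cfg, reg.names())
        for name, v in ref.items():
            assert native[name] == pytest.approx(v, rel=1e-6, abs=1e-9), name

    def test_transforms_applied_per_registry(self):
        image, mask = generate_lesion_image(1000, 200, 1.0, (1, 1, 1), seed=8)
        reg = self._firstorder_registry()
        cfg = BinningConfig.adc()
        raw = extract_features(image, mask, reg, cfg, transform=False)
        out = extract_features(image, mask, reg, cfg, transform=True)
        assert out["firstorder_Mean"] == pytest.approx(np.log(raw["firstorder_Mean"]))
        assert out["firstorder_Skewness"] == raw["firstorder_Skewness"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_features(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool),
                             self._firstorder_registry(), BinningConfig.adc())

    def test_missing_texture_extractor_raises(self):
        image, mask = generate_lesion_image(1000, 100, 1.0, (1, 1, 1), seed=1)
        with pytest.raises(MissingFeatureError):
            extract_features(image, mask, build_default_registry(),
                             BinningConfig.adc())
        with pytest.raises(MissingFeatureError):
            extract_features(image, mask, build_default_registry(),
                             BinningConfig.adc(),
                             extractor=ReferenceFirstOrderExtractor())

    def test_pluggable_texture_extractor(self):
        """A conforming external extractor supplies texture/shape values,
        which then pass through the registry transforms."""

        class StubExtractor:
            aggregation = "3D"

            def extract(self, image, mask, binning, feature_names):
                values = {}
                for n in feature_names:
                    if n == "glcm_Imc2":
                        values[n] = 1 - np.exp(-1.0)
                    elif n in ("glcm_Idn", "glcm_Idmn"):
                        values[n] = 0.25
                    elif n in ("glcm_Correlation", "glcm_ClusterShade", "glcm_Imc1"):
                        values[n] = -0.5
                    else:
                        values[n] = 2.0
                return values

        image, mask = generate_lesion_image(1000, 100, 1.0, (1, 1, 1), seed=1)
        out = extract_features(image, mask, build_default_registry(),
                               BinningConfig.adc(), extractor=StubExtractor())
        assert len(out) == 106
        assert out["glrlm_RunEntropy"] == pytest.approx(np.log(2.0))
        assert out["glcm_Idn"] == pytest.approx(0.75)
        assert out["glcm_Imc2"] == pytest.approx(-1.0)
        assert out["glcm_Correlation"] == -0.5
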