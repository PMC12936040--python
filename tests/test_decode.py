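"""Decoding: endpoint extraction, mm measurement, thresholds, consensus."""

import numpy as np
import pytest

from alvedef.annotations import DefectClass, LandmarkPair, SliceAnnotation
from alvedef.decode import (
    Detection,
    SliceResult,
    classify_slice,
    decode_slice,
    diagnose_tooth,
    extract_endpoints,
    measure_length,
)
from alvedef.encoder import HeatmapSpec, build_target_stack


def _detection(c, length_mm, score=0.9):
    p2 = np.array([10.0 + length_mm / 0.25, 10.0])
    return Detection(c, np.array([10.0, 10.0]), p2, length_mm, score)


class TestMeasureLength:
    def test_3_4_5(self):
        assert measure_length([0, 0], [3, 4], 0.25) == pytest.approx(1.25)

    def test_pitch_linearity(self):
        assert measure_length([0, 0], [3, 4], 0.5) == pytest.approx(
            2 * measure_length([0, 0], [3, 4], 0.25)
        )


class TestExtractEndpoints:
    def test_roundtrip_on_encoded_target(self, rng):
        from tests.conftest import random_annotation

        for _ in range(25):
            ann = random_annotation(rng)
            stack = build_target_stack(ann, (112, 80))
            for pair in ann.defects:
                g = pair.defect_class.group
                det = extract_endpoints(
                    stack.channels[3 * g : 3 * g + 3],
                    pair.defect_class,
                    ann.pixel_pitch_mm,
                    from_logits=False,
                )
                assert det is not None
                assert np.hypot(*(det.point_for_role(pair.defect_class.roles[0]) - pair.p1)) <= 1.0
                assert np.hypot(*(det.point_for_role(pair.defect_class.roles[1]) - pair.p2)) <= 1.0

    def test_all_background_absent(self):
        channels = np.zeros((3, 64, 64), dtype=np.float32)
        det = extract_endpoints(
            channels, DefectClass.BUCCAL_DEHISCENCE, 0.25, from_logits=False
        )
        assert det is None

    def test_single_pixel_component_absent(self):
        channels = np.zeros((3, 64, 64), dtype=np.float32)
        channels[0, 30, 30] = 1.0
        det = extract_endpoints(
            channels, DefectClass.BUCCAL_DEHISCENCE, 0.25, from_logits=False
        )
        assert det is None

    def test_largest_component_wins(self):
        ann = SliceAnnotation(
            "p", "t", 0, 0.25,
            [LandmarkPair(DefectClass.BUCCAL_DEHISCENCE, [10, 10], [10, 40])],
        )
        stack = build_target_stack(ann, (64, 64))
        channels = stack.channels[0:3].copy()
        channels[0, 2, 50:53] = 1.0  # small spurious blob, zero direction
        det = extract_endpoints(channels, DefectClass.BUCCAL_DEHISCENCE, 0.25, from_logits=False)
        assert det is not None
        assert det.length_mm == pytest.approx(30 * 0.25, abs=0.5)

    def test_heatmap_mode_roundtrip_when_separated(self, rng):
        spec = HeatmapSpec(sigma_px=2.0)
        for _ in range(20):
            p1 = rng.uniform(15, 45, 2)
            off = rng.uniform(10, 16, 2) * rng.choice([-1, 1], 2)
            p2 = np.clip(p1 + off, 5, 58)
            if np.hypot(*(p2 - p1)) < 4 * spec.sigma_px:
                continue
            pair = LandmarkPair(DefectClass.LINGUAL_FENESTRATION, p1, p2)
            ann = SliceAnnotation("p", "t", 0, 0.25, [pair])
            stack = build_target_stack(ann, (64, 64), mode="heatmap", heatmap_spec=spec)
            g = pair.defect_class.group
            det = extract_endpoints(
                stack.channels[3 * g : 3 * g + 3],
                pair.defect_class,
                0.25,
                mode="heatmap",
                heatmap_spec=spec,
            )
            assert det is not None
            # peaks land on the pixel grid: within 1 px of the annotation
            for role, truth in zip(pair.defect_class.roles, (p1, p2)):
                assert np.hypot(*(det.point_for_role(role) - truth)) <= 1.0

    def test_score_in_unit_interval(self, rng):
        from tests.conftest import random_annotation

        ann = random_annotation(rng, classes=[DefectClass.BUCCAL_DEHISCENCE])
        stack = build_target_stack(ann, (112, 80))
        det = extract_endpoints(stack.channels[0:3], DefectClass.BUCCAL_DEHISCENCE,
                                0.25, from_logits=False)
        assert det is not None and 0.0 <= det.score <= 1.0


class TestClassifySlice:
    @pytest.mark.parametrize(
        "defect_class, length, expected",
        [
            (DefectClass.BUCCAL_DEHISCENCE, 2.5, True),
            (DefectClass.BUCCAL_DEHISCENCE, 2.0, False),  # strict inequality
            (DefectClass.LINGUAL_DEHISCENCE, 2.05, True),
            (DefectClass.BUCCAL_FENESTRATION, 2.2, False),  # strict inequality
            (DefectClass.BUCCAL_FENESTRATION, 2.3, True),
            (DefectClass.LINGUAL_FENESTRATION, 1.9, False),
        ],
    )
    def test_threshold_rules(self, defect_class, length, expected):
        labels, scores = classify_slice({defect_class: _detection(defect_class, length)})
        assert labels[defect_class] is expected
        assert scores[defect_class] == pytest.approx(0.9)

    def test_absent_detection_negative_zero_score(self):
        labels, scores = classify_slice({})
        for c in DefectClass:
            assert labels[c] is False and scores[c] == 0.0


def _slice_result(labels: dict, scores: dict) -> SliceResult:
    full_labels = {c: labels.get(c, False) for c in DefectClass}
    full_scores = {c: scores.get(c, 0.0) for c in DefectClass}
    return SliceResult({c: None for c in DefectClass}, full_labels, full_scores)


class TestDiagnoseTooth:
    @pytest.mark.parametrize(
        "labels, expected",
        [((True, True, True), True), ((True, True, False), False),
         ((False, True, True), False), ((False, False, False), False)],
    )
    def test_three_slice_and_rule(self, labels, expected):
        c = DefectClass.BUCCAL_DEHISCENCE
        results = [_slice_result({c: l}, {c: 0.8}) for l in labels]
        diag = diagnose_tooth(results)
        assert diag.tooth_label[c] is expected

    def test_tooth_score_is_min(self):
        c = DefectClass.LINGUAL_FENESTRATION
        results = [_slice_result({c: True}, {c: s}) for s in (0.9, 0.7, 0.8)]
        assert diagnose_tooth(results).tooth_score[c] == pytest.approx(0.7)

    def test_wrong_slice_count_rejected(self):
        r = _slice_result({}, {})
        with pytest.raises(ValueError):
            diagnose_tooth([r, r])

    def test_monotone_in_slice_labels(self, rng):
        """Flipping any slice label positive -> negative never turns the
        tooth positive."""
        c = DefectClass.BUCCAL_FENESTRATION
        for _ in range(50):
            labels = [bool(b) for b in rng.integers(0, 2, 3)]
            base = diagnose_tooth(
                [_slice_result({c: l}, {c: 0.5}) for l in labels]
            ).tooth_label[c]
            for i in range(3):
                if labels[i]:
                    flipped = list(labels)
                    flipped[i] = False
                    after = diagnose_tooth(
                        [_slice_result({c: l}, {c: 0.5}) for l in flipped]
                    ).tooth_label[c]
                    assert not (after and not base)


class TestDecodeSliceRoundTrip:
    def test_full_stack_roundtrip_labels(self, small_dataset):
        mismatches = 0
        for series in small_dataset.series:
            for img, ann in series.slices:
                stack = build_target_stack(ann, img.shape)
                res = decode_slice(stack.channels, ann.pixel_pitch_mm, from_logits=False)
                for c in DefectClass:
                    if res.labels[c] != ann.slice_label(c):
                        mismatches += 1
        assert mismatches == 0
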