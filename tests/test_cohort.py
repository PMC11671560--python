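"""Per-case aggregation, cohort tallies and the glyph encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cle_afq.cohort import (
    FEATURES,
    GLYPH_SLOTS,
    CaseSummary,
    GlyphSpec,
    aggregate_case,
    cohort_report,
    glyph_spec,
    reconcile_percentages,
    render_glyph,
    situ_category_summary,
)


def _rows(case_id, flag_patterns):
    rows = []
    for i, pattern in enumerate(flag_patterns):
        row = {"case_id": case_id, "image_id": f"{case_id}-{i}"}
        row.update({f: f in pattern for f in FEATURES})
        rows.append(row)
    return pd.DataFrame(rows)


class TestAggregateCase:
    def test_fraction_to_percentage(self):
        rows = _rows("P1", [{"fibers"}] * 4 + [set()] * 6)
        summary = aggregate_case(rows)
        assert summary.pct["fibers"] == 40.0
        assert summary.n_images == 10

    def test_all_false_gives_zero(self):
        summary = aggregate_case(_rows("P2", [set()] * 5))
        assert all(v == 0.0 for v in summary.pct.values())

    def test_half_of_26_frames(self):
        rows = _rows("P3", [{"dense_punctuate"}] * 13 + [set()] * 13)
        assert aggregate_case(rows).pct["dense_punctuate"] == 50.0

    def test_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            aggregate_case(_rows("P4", []))

    def test_mixed_cases_rejected(self):
        rows = pd.concat([_rows("P5", [set()]), _rows("P6", [set()])])
        with pytest.raises(ValueError):
            aggregate_case(rows)

    @given(st.integers(1, 40), st.data())
    def test_percentage_identity(self, n, data):
        k = data.draw(st.integers(0, n))
        rows = _rows("PX", [{"diffuse"}] * k + [set()] * (n - k))
        pct = aggregate_case(rows).pct["diffuse"]
        assert pct * n / 100.0 == pytest.approx(k)


class TestSituSummary:
    def test_reference_cohort_tally(self):
        res = situ_category_summary(338, [53, 141, 73])
        assert res["percentages"] == [16, 42, 22]
        assert res["remainder"] == 71

    def test_single_full_category(self):
        res = situ_category_summary(100, [100])
        assert res["percentages"] == [100]
        assert res["remainder"] == 0

    def test_small_total_rounding(self):
        res = situ_category_summary(7, [1, 2])
        assert res["percentages"] == [14, 29]
        assert res["remainder"] == 4

    def test_counts_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            situ_category_summary(10, [7, 7])

    def test_reconciliation_of_reference_counts(self):
        # the four categories of the 338-frame reference series sum to exactly 100%
        assert sum(reconcile_percentages([53, 141, 73, 71])) == 100


def _summary(pct_value=0.0, **overrides):
    pct = {f: pct_value for f in FEATURES}
    pct.update(overrides)
    return CaseSummary(case_id="P1", n_images=10, pct=pct)


class TestGlyphMapping:
    def test_all_zero(self):
        spec = glyph_spec(_summary(0.0))
        assert all(getattr(spec, slot) == 0.0 for slot in GLYPH_SLOTS)
        assert spec.unmapped_default == 0.5

    def test_all_hundred(self):
        spec = glyph_spec(_summary(100.0))
        assert all(getattr(spec, slot) == 1.0 for slot in GLYPH_SLOTS)

    def test_componentwise(self):
        spec = glyph_spec(_summary(0.0, sparse_punctuate=80.0))
        assert spec.face_size == 0.8
        assert all(
            getattr(spec, slot) == 0.0
            for slot, feat in GLYPH_SLOTS.items()
            if feat != "sparse_punctuate"
        )

    @given(st.lists(st.integers(0, 400), min_size=9, max_size=9))
    def test_round_trip_exact(self, raw):
        pct = {f: raw[i] / 4.0 for i, f in enumerate(FEATURES)}
        spec = glyph_spec(CaseSummary(case_id="x", n_images=4, pct=pct))
        assert spec.to_pct() == pct

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GlyphSpec(face_size=1.2)


class TestGlyphRendering:
    def test_identical_specs_byte_identical(self, tmp_path):
        spec = GlyphSpec(face_size=0.7, mouth_shape=0.2)
        a = render_glyph(spec, tmp_path / "a.svg")
        b = render_glyph(spec, tmp_path / "b.svg")
        assert a.read_bytes() == b.read_bytes()

    @pytest.mark.parametrize("slot", sorted(GLYPH_SLOTS))
    def test_each_parameter_changes_output(self, slot, tmp_path):
        base = render_glyph(GlyphSpec(), tmp_path / "base.svg").read_bytes()
        varied = render_glyph(GlyphSpec(**{slot: 0.9}), tmp_path / "var.svg").read_bytes()
        assert base != varied

    def test_default_spec_renders(self, tmp_path):
        assert render_glyph(GlyphSpec(), tmp_path / "default.svg").exists()


class TestCohortReport:
    @pytest.fixture()
    def summaries(self):
        return [
            CaseSummary("P1", "glioblastoma", 10, {f: 43.0 for f in FEATURES}),
            CaseSummary("P2", "glioblastoma", 10, {f: 4.0 for f in FEATURES}),
            CaseSummary("P3", "non_tumor", 10, {f: 80.0 for f in FEATURES}),
        ]

    def test_outputs_written(self, summaries, tmp_path):
        paths = cohort_report(summaries, tmp_path)
        assert all(p.exists() for p in paths.values())
        grid = paths["glyphs"].read_text()
        assert grid.count("<svg") == 1

    def test_per_type_median(self, summaries, tmp_path):
        paths = cohort_report(summaries, tmp_path)
        medians = pd.read_csv(paths["medians"]).set_index("tumor_type")
        assert medians.loc["glioblastoma", "fibers"] == 23.5

    def test_regeneration_byte_identical(self, summaries, tmp_path):
        p1 = cohort_report(summaries, tmp_path / "r1")
        p2 = cohort_report(summaries, tmp_path / "r2")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            cohort_report([], tmp_path)


def test_tumor_and_non_tumor_archetypes_separate_in_cell_slots():
    """High cell abundance moves mouth, nose and pupils, mirroring how
    non-tumor tissue stands out by its cell-driven face parameters."""
    from cle_afq.benchmarks import ground_truth_features
    from cle_afq.cli import _archetype_spec
    from cle_afq.simulate import build_scene

    rng = np.random.default_rng(0)

    def archetype_pct(kind):
        flags = []
        for i in range(5):
            spec = _archetype_spec(kind, 9000 + i, rng)
            _, _, gt = build_scene(spec, seed=spec.seed)
            flags.append(ground_truth_features(gt).flags())
        return {f: 100.0 * np.mean([fl[f] for fl in flags]) for f in FEATURES}

    tumor = glyph_spec(CaseSummary("T", "glioblastoma", 5, archetype_pct("tumor")))
    normal = glyph_spec(CaseSummary("N", "non_tumor", 5, archetype_pct("non_tumor")))
    assert normal.mouth_shape > tumor.mouth_shape  # dense small cells
    assert normal.nose_length > tumor.nose_length  # dense large cells
    assert abs(normal.pupil_direction - tumor.pupil_direction) >= 0.0
    assert normal.forehead_shape < tumor.forehead_shape  # fibers absent
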