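"""Atlas-side classification: tissue means, thresholds, restricted/predominant."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from offcontext import (
    ExpressionMatrix,
    TissueSpecificityClassifier,
    ValidationError,
    atlas_threshold,
    build_specificity_table,
    classify_predominant,
    classify_restricted,
    tissue_means,
)
from offcontext.containers import LINEAR, LOG2, SOMATIC
from conftest import expr_from_tissue_means, make_annotation


def _means_df(rows: dict, tissues) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tissues))


class TestTissueMeans:
    def test_single_sample_per_tissue_is_identity(self, small_annotation):
        tm = _means_df({"g1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, small_annotation.tissues_of_class(SOMATIC) + ["testis", "placenta", "es_line"])
        tm = tm.loc[:, sorted(tm.columns)]
        expr = expr_from_tissue_means(tm, small_annotation)
        out = tissue_means(expr, small_annotation)
        pd.testing.assert_frame_equal(out, tm)

    def test_arithmetic_mean_of_replicates(self):
        ann = make_annotation({"t1": SOMATIC, "t2": SOMATIC}, samples_per_tissue=2)
        df = pd.DataFrame({"t1.s1": [4.0], "t1.s2": [6.0], "t2.s1": [1.0], "t2.s2": [3.0]}, index=["g"])
        out = tissue_means(df, ann)
        assert out.loc["g", "t1"] == 5.0
        assert out.loc["g", "t2"] == 2.0

    def test_matches_scalar_loop_on_random_matrix(self, rng):
        ann = make_annotation({f"t{i}": SOMATIC for i in range(5)}, samples_per_tissue=4)
        df = pd.DataFrame(
            rng.normal(5, 1, size=(50, 20)),
            index=[f"g{i}" for i in range(50)],
            columns=ann.tissue_of.index,
        )
        out = tissue_means(df, ann)
        for g in df.index:
            for t in ann.tissues:
                samples = ann.tissue_of.index[ann.tissue_of == t]
                expected = sum(df.loc[g, s] for s in samples) / len(samples)
                assert out.loc[g, t] == pytest.approx(expected, rel=1e-12)

    def test_unannotated_sample_is_named_in_error(self, small_annotation):
        df = pd.DataFrame({"mystery_sample": [1.0]}, index=["g"])
        with pytest.raises(ValidationError, match="mystery_sample"):
            tissue_means(df, small_annotation)


class TestAtlasThreshold:
    def test_hand_computed_sample_sd(self):
        # somatic means {2, 4, 6}: mean 4, SD (ddof=1) = 2 -> 4 + 3*2 = 10
        ann = make_annotation({"a": SOMATIC, "b": SOMATIC, "c": SOMATIC, "testis": "germline"})
        tm = _means_df({"g": [2.0, 4.0, 6.0, 50.0]}, ["a", "b", "c", "testis"])
        thr = atlas_threshold(tm, ann, k_atlas=3.0)
        assert thr["g"] == pytest.approx(10.0)

    def test_zero_variance_threshold_is_the_mean(self):
        ann = make_annotation({"a": SOMATIC, "b": SOMATIC, "c": SOMATIC})
        tm = _means_df({"g": [5.0, 5.0, 5.0]}, ["a", "b", "c"])
        assert atlas_threshold(tm, ann)["g"] == pytest.approx(5.0)

    def test_fewer_than_two_somatic_tissues_errors(self):
        ann = make_annotation({"a": SOMATIC, "testis": "germline"})
        tm = _means_df({"g": [1.0, 2.0]}, ["a", "testis"])
        with pytest.raises(ValidationError, match="somatic"):
            atlas_threshold(tm, ann)

    def test_matches_scalar_recomputation(self, rng):
        tissues = {f"t{i}": SOMATIC for i in range(8)}
        ann = make_annotation(tissues)
        tm = pd.DataFrame(rng.normal(5, 2, size=(200, 8)), columns=list(tissues),
                          index=[f"g{i}" for i in range(200)])
        thr = atlas_threshold(tm, ann, k_atlas=3.0)
        import statistics
        for g in tm.index:
            vals = [tm.loc[g, t] for t in tissues]
            expected = statistics.mean(vals) + 3.0 * statistics.stdev(vals)
            assert thr[g] == pytest.approx(expected, rel=1e-12)


class TestRestrictedAndPredominant:
    tissues = ["a", "b", "c", "testis", "placenta", "es_line"]

    @pytest.fixture
    def ann(self):
        return make_annotation(
            {"a": SOMATIC, "b": SOMATIC, "c": SOMATIC,
             "testis": "germline", "placenta": "placenta", "es_line": "embryonic_stem"}
        )

    def test_silent_somatic_expressed_target_is_restricted(self, ann):
        tm = _means_df({"g": [0, 0, 0, 50.0, 0, 0]}, self.tissues)
        out = classify_restricted(tm, ann, detection_floor=1.0)
        assert bool(out.loc["g", "restricted"])
        assert out.loc["g", "target_class"] == "germline"

    def test_any_somatic_expression_above_floor_blocks_restriction(self, ann):
        tm = _means_df({"g": [2.0, 0, 0, 50.0, 0, 0]}, self.tissues)  # 2*floor in one somatic tissue
        out = classify_restricted(tm, ann, detection_floor=1.0)
        assert not bool(out.loc["g", "restricted"])

    def test_silent_everywhere_is_not_restricted(self, ann):
        tm = _means_df({"g": [0, 0, 0, 0, 0, 0]}, self.tissues)
        out = classify_restricted(tm, ann, detection_floor=1.0)
        assert not bool(out.loc["g", "restricted"])

    def test_predominant_above_hand_computed_threshold(self, ann):
        tm = _means_df({"g": [2.0, 4.0, 6.0, 12.0, 3.0, 3.0]}, self.tissues)
        thr = atlas_threshold(tm, ann)  # = 10
        out = classify_predominant(tm, thr, ann)
        assert bool(out.loc["g", "predominant"])
        assert out.loc["g", "target_class"] == "germline"

    def test_below_threshold_is_unrestricted(self, ann):
        tm = _means_df({"g": [2.0, 4.0, 6.0, 9.0, 3.0, 3.0]}, self.tissues)
        out = classify_predominant(tm, atlas_threshold(tm, ann), ann)
        assert not bool(out.loc["g", "predominant"])

    def test_class_mean_tie_broken_by_declared_order(self, ann):
        # germline and ES tied at 12 with threshold 10 -> germline wins
        tm = _means_df({"g": [2.0, 4.0, 6.0, 12.0, 3.0, 12.0]}, self.tissues)
        out = classify_predominant(tm, atlas_threshold(tm, ann), ann)
        assert out.loc["g", "target_class"] == "germline"


class TestSpecificityTable:
    def test_restricted_takes_precedence_over_predominant(self):
        ann = make_annotation({"a": SOMATIC, "b": SOMATIC, "testis": "germline"})
        tm = _means_df({"g": [0.0, 0.0, 50.0]}, ["a", "b", "testis"])
        expr = expr_from_tissue_means(tm, ann)
        table = build_specificity_table(
            expr, ann, detection_floor=1.0, target_classes=("germline",)
        )
        # the germline mean 50 also clears the somatic threshold (0), but
        # restricted wins
        assert table.loc["g", "status"] == "restricted"

    def test_missing_target_class_tissue_errors(self):
        ann = make_annotation({"a": SOMATIC, "b": SOMATIC})
        tm = _means_df({"g": [1.0, 2.0]}, ["a", "b"])
        expr = expr_from_tissue_means(tm, ann)
        with pytest.raises(ValidationError, match="target class"):
            build_specificity_table(expr, ann, detection_floor=1.0)

    def test_every_gene_has_exactly_one_status(self, rng):
        ann = make_annotation(
            {**{f"t{i}": SOMATIC for i in range(6)},
             "testis": "germline", "placenta": "placenta", "es": "embryonic_stem"},
            samples_per_tissue=2,
        )
        df = pd.DataFrame(rng.normal(5, 2, size=(100, len(ann.tissue_of))),
                          index=[f"g{i}" for i in range(100)], columns=ann.tissue_of.index)
        table = build_specificity_table(ExpressionMatrix(df, scale=LOG2), ann)
        assert set(table["status"]) <= {"restricted", "predominant", "unrestricted"}
        assert (table.index.value_counts() == 1).all()
        # unrestricted <=> target class 'none'
        assert ((table["status"] == "unrestricted") == (table["target_class"] == "none")).all()

    def test_linear_scale_equivariance(self, rng):
        """Scaling all linear intensities by c scales thresholds by c and
        leaves verdicts unchanged when the floor is scaled too."""
        ann = make_annotation(
            {**{f"t{i}": SOMATIC for i in range(5)},
             "testis": "germline", "placenta": "placenta", "es": "embryonic_stem"}
        )
        vals = rng.uniform(0.1, 100, size=(60, len(ann.tissue_of)))
        vals[:5, :5] = 0.01  # a few near-silent somatic profiles
        vals[:5, 5] = 80.0
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(60)], columns=ann.tissue_of.index)
        c = 7.5
        floor = 1.0
        t1 = build_specificity_table(
            ExpressionMatrix(df, scale=LINEAR), ann, detection_floor=floor
        )
        t1_lin = TissueSpecificityClassifier(detection_floor=floor, scale=LINEAR).fit(
            ExpressionMatrix(df, scale=LINEAR), ann
        ).specificity_table_
        t2_lin = TissueSpecificityClassifier(detection_floor=floor * c, scale=LINEAR).fit(
            ExpressionMatrix(df * c, scale=LINEAR), ann
        ).specificity_table_
        pd.testing.assert_series_equal(t1_lin["status"], t2_lin["status"])
        np.testing.assert_allclose(
            t2_lin["atlas_threshold"], t1_lin["atlas_threshold"] * c, rtol=1e-9
        )
        # default log2 working scale also yields a status for every gene
        assert len(t1) == 60

    @settings(max_examples=50, deadline=None)
    @given(
        base=st.floats(2.0, 8.0),
        bump=st.floats(0.0, 20.0),
        target=st.floats(0.0, 30.0),
    )
    def test_raising_target_mean_never_revokes_predominance(self, base, bump, target):
        ann = make_annotation({"a": SOMATIC, "b": SOMATIC, "c": SOMATIC, "testis": "germline"})
        tm = _means_df({"g": [base, base + 1, base + 2, target]}, ["a", "b", "c", "testis"])
        thr = atlas_threshold(tm, ann)
        classes = ("germline",)
        before = bool(classify_predominant(tm, thr, ann, classes).loc["g", "predominant"])
        tm2 = tm.copy()
        tm2.loc["g", "testis"] += bump
        after = bool(classify_predominant(tm2, thr, ann, classes).loc["g", "predominant"])
        assert after or not before  # predominant never becomes unrestricted
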