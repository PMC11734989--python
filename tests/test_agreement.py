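"""Pielou evenness, observer agreement, aggregate matching, count comparison."""

import math

import numpy as np
import pytest

from _oracles import max_matching_oracle
from conftest import make_annotation
from wildagree import (
    AggregateAnnotation,
    Annotation,
    BoundingBox,
    ClusterParams,
    ImageMeta,
    aggregate_annotation_set,
    agreement_report,
    compute_iou,
    count_comparison,
    default_crowd_profiles,
    generate_crowd,
    generate_scene,
    match_aggregates,
    morphology_scheme,
    observer_agreement,
    pielou_index,
)


class TestPielou:
    @pytest.mark.parametrize(
        "tally,expected",
        [
            ({"duck": 12}, 0.0),
            ({"duck": 5, "goose": 5}, 1.0),
            ({"duck": 8, "goose": 2}, 0.7219),
            ({"a": 1, "b": 1, "c": 1}, 1.0),
        ],
    )
    def test_closed_forms(self, tally, expected):
        assert pielou_index(tally) == pytest.approx(expected, abs=5e-5)

    def test_direct_formula(self):
        # -(0.8 ln 0.8 + 0.2 ln 0.2) / ln 2
        want = -(0.8 * math.log(0.8) + 0.2 * math.log(0.2)) / math.log(2)
        assert pielou_index({"duck": 8, "goose": 2}) == pytest.approx(want)

    def test_scaling_invariance(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 6))
            tally = {f"c{i}": int(v) for i, v in enumerate(rng.integers(1, 30, k))}
            scaled = {c: 7 * v for c, v in tally.items()}
            assert pielou_index(scaled) == pytest.approx(pielou_index(tally))

    def test_decreases_past_uniform(self):
        # fix one class's share growing beyond 1/2 over two classes
        values = [pielou_index({"a": n, "b": 20 - n}) for n in range(10, 20)]
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_zero_iff_single_class(self, rng):
        assert pielou_index({"duck": 3}) == 0.0
        for _ in range(10):
            k = int(rng.integers(2, 5))
            tally = {f"c{i}": int(v) for i, v in enumerate(rng.integers(1, 9, k))}
            if len(set(tally.values())) > 1 or k >= 2:
                assert pielou_index(tally) > 0.0

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            pielou_index({})


def _simple_aggregation(observer_labels, n_observers=6, scheme=None):
    """One cluster per target position; observer o00 labels per the given list."""
    scheme = scheme or morphology_scheme()
    anns = []
    positions = [(100.0 + 200 * t, 100.0) for t in range(len(observer_labels))]
    for t, (cx, cy) in enumerate(positions):
        for i in range(n_observers):
            label = observer_labels[t] if i == 0 else "duck"
            anns.append(make_annotation(cx, cy, observer=f"o{i:02d}", label=label))
    return aggregate_annotation_set(anns, ClusterParams(15, 5), scheme), anns


class TestObserverAgreement:
    def test_perfect_observer(self):
        result, _ = _simple_aggregation(["duck", "duck", "duck"])
        rec = observer_agreement("o00", result, morphology_scheme())
        assert rec.overall == 1.0
        assert rec.per_class == {"duck": 1.0}

    def test_one_wrong_of_four(self):
        result, _ = _simple_aggregation(["goose", "duck", "duck", "duck"])
        rec = observer_agreement("o00", result, morphology_scheme())
        assert rec.overall == pytest.approx(0.75)
        assert rec.per_class["duck"] == pytest.approx(0.75)

    def test_noise_annotation_is_automatic_failure(self):
        anns = [
            make_annotation(100, 100, observer=f"o{i:02d}", label="duck")
            for i in range(6)
        ]
        anns.append(make_annotation(600, 400, observer="o00", label="duck"))
        result = aggregate_annotation_set(anns, ClusterParams(15, 5), morphology_scheme())
        rec = observer_agreement("o00", result, morphology_scheme())
        assert rec.overall == pytest.approx(0.5)

    def test_unknown_observer_rejected(self):
        result, _ = _simple_aggregation(["duck"])
        with pytest.raises(ValueError):
            observer_agreement("ghost", result, morphology_scheme())


class TestAgreementReport:
    def test_unanimous_crowd(self):
        result, anns = _simple_aggregation(["duck", "duck"])
        report = agreement_report(result, morphology_scheme(), raw_annotations=anns)
        assert report.overall["mean_agreement"] == 1.0
        assert report.overall["mean_pielou"] == 0.0
        assert report.overall["mean_iou"] == pytest.approx(1.0)
        assert set(report.per_class.index) == {"duck"}

    def test_empty_class_absent_not_zero(self):
        result, _ = _simple_aggregation(["duck"])
        report = agreement_report(result, morphology_scheme())
        assert "goose" not in report.per_class.index

    def test_overall_is_annotation_weighted_observer_mean(self):
        result, _ = _simple_aggregation(["goose", "duck", "duck"], n_observers=7)
        report = agreement_report(result, morphology_scheme())
        weights = np.array([r.n_scored for r in report.per_observer.values()])
        overall = np.array([r.overall for r in report.per_observer.values()])
        assert report.overall["mean_agreement"] == pytest.approx(
            float((weights * overall).sum() / weights.sum())
        )

    def test_confusion_rate_recovered(self):
        # 20% of duck votes flip to goose; majority stays duck, agreement ~ 0.8
        meta = ImageMeta("img0", 2736, 2084)
        scene = generate_scene(150, {"duck": 1.0}, meta, seed=5)
        profiles = default_crowd_profiles(
            15, ["duck", "goose"], detection_prob=1.0, jitter_sigma=2.0,
            confusion_off_diagonal=0.0, false_positive_rate=0.0,
        )
        for p in profiles:
            p.confusion = {"duck": {"duck": 0.8, "goose": 0.2},
                           "goose": {"duck": 0.0, "goose": 1.0}}
        crowd = generate_crowd(scene, profiles, master_seed=99)
        result = aggregate_annotation_set(crowd, ClusterParams(15, 5), morphology_scheme())
        report = agreement_report(result, morphology_scheme())
        assert report.per_class.loc["duck", "mean_agreement"] == pytest.approx(0.8, abs=0.03)
        # E[pielou(15-X, X) | duck plurality], X ~ Bin(15, 0.2): 0.668 by enumeration
        assert report.per_class.loc["duck", "mean_pielou"] == pytest.approx(0.668, abs=0.05)


def _agg(cx, cy, w=10.0, h=10.0, cls="duck", image="img0"):
    box = BoundingBox(cx - w / 2, cy - h / 2, w, h)
    return AggregateAnnotation(
        image_id=image, box=box, vote_tally={cls: 5}, consensus_class=cls,
        member_ious=[1.0] * 5,
        members=[make_annotation(cx, cy, w, h, observer=f"o{i}", image=image, label=cls)
                 for i in range(5)],
    )


class TestMatchAggregates:
    def test_identity_match(self):
        ref = [_agg(50, 50), _agg(150, 50, cls="goose"), _agg(250, 50, cls="crane")]
        res = match_aggregates(ref, ref, 0.5)
        assert len(res.pairs) == 3
        assert not res.unmatched_reference and not res.unmatched_comparison
        assert (np.diag(res.confusion.to_numpy()) == 1).all()
        assert res.class_match_fraction == 1.0

    def test_half_shift_below_threshold(self):
        ref = [_agg(50, 50)]
        cmp_ = [_agg(55, 50)]
        assert compute_iou(ref[0].box, cmp_[0].box) == pytest.approx(1 / 3)
        res = match_aggregates(ref, cmp_, 0.5)
        assert not res.pairs
        assert len(res.unmatched_reference) == len(res.unmatched_comparison) == 1

    def test_cross_class_confusion_entries(self):
        ref = [_agg(50, 50, cls="duck"), _agg(150, 50, cls="goose")]
        cmp_ = [_agg(50, 50, cls="goose"), _agg(150, 50, cls="goose")]
        res = match_aggregates(ref, cmp_, 0.5)
        assert res.confusion.loc["duck", "goose"] == 1
        assert res.confusion.loc["goose", "goose"] == 1
        assert res.class_match_fraction == pytest.approx(0.5)

    def test_marginals_match_counts(self, rng):
        ref = [_agg(float(x), float(y), cls=rng.choice(["duck", "goose"]))
               for x, y in rng.uniform(20, 400, (12, 2))]
        cmp_ = [_agg(float(x) + rng.normal(0, 2), float(y), cls=rng.choice(["duck", "goose"]))
                for x, y in rng.uniform(20, 400, (10, 2))]
        res = match_aggregates(ref, cmp_, 0.3)
        for c in res.confusion.index:
            assert res.confusion.loc[c].sum() == sum(
                1 for r, _, _ in res.pairs if r.consensus_class == c
            )
        for c in res.confusion.columns:
            assert res.confusion[c].sum() == sum(
                1 for _, k, _ in res.pairs if k.consensus_class == c
            )

    @pytest.mark.parametrize("trial", range(15))
    def test_greedy_at_most_optimal(self, trial):
        rng = np.random.default_rng(3100 + trial)
        n_ref, n_cmp = int(rng.integers(1, 9)), int(rng.integers(1, 9))
        ref = [_agg(float(x), float(y)) for x, y in rng.uniform(10, 60, (n_ref, 2))]
        cmp_ = [_agg(float(x), float(y)) for x, y in rng.uniform(10, 60, (n_cmp, 2))]
        iou = np.array([[compute_iou(r.box, c.box) for c in cmp_] for r in ref])
        res = match_aggregates(ref, cmp_, 0.3)
        optimal = max_matching_oracle(iou, 0.3)
        assert len(res.pairs) <= min(n_ref, n_cmp)
        assert len(res.pairs) <= optimal

    def test_removing_matched_item_never_increases_matches(self, rng):
        ref = [_agg(float(x), float(y)) for x, y in rng.uniform(10, 200, (8, 2))]
        cmp_ = [_agg(float(x + rng.normal(0, 3)), float(y))
                for x, y in rng.uniform(10, 200, (8, 2))]
        res = match_aggregates(ref, cmp_, 0.3)
        if res.pairs:
            dropped = res.pairs[0][1]
            reduced = [c for c in cmp_ if c is not dropped]
            res2 = match_aggregates(ref, reduced, 0.3)
            assert len(res2.pairs) <= len(res.pairs)


class TestCountComparison:
    def test_identical_counts(self):
        ref = [_agg(50 + 100 * i, 50, image=f"t{i % 3}") for i in range(6)]
        res = count_comparison(ref, ref)
        assert res.ratio_overall == 1.0
        assert res.t == pytest.approx(0.0)

    def test_pooled_t_closed_form(self):
        ref = [_agg(50 + 60 * j, 50, image=f"t{i}") for i, n in enumerate([1, 2, 3, 4])
               for j in range(n)]
        cmp_ = [_agg(50 + 60 * j, 50, image=f"t{i}") for i, n in enumerate([2, 3, 4, 5])
                for j in range(n)]
        res = count_comparison(ref, cmp_, ttest="pooled")
        assert res.t == pytest.approx(-1.095, abs=5e-4)
        assert res.df == 6

    def test_uniform_undercount_ratio(self):
        ref = [_agg(30 + 40 * j, 50, image=f"t{i}") for i in range(4) for j in range(10)]
        cmp_ = [_agg(30 + 40 * j, 50, image=f"t{i}") for i in range(4) for j in range(9)]
        res = count_comparison(ref, cmp_)
        assert res.ratio_overall == pytest.approx(0.9)

    def test_zero_reference_class_is_nan(self):
        ref = [_agg(50, 50, cls="duck")]
        cmp_ = [_agg(50, 50, cls="goose")]
        res = count_comparison(ref, cmp_)
        assert res.per_class_ratio["duck"] == 0.0
        assert math.isnan(res.per_class_ratio["goose"])

    def test_welch_variant_runs(self):
        ref = [_agg(50 + 60 * j, 50, image=f"t{i}") for i, n in enumerate([1, 5, 2, 4])
               for j in range(n)]
        cmp_ = [_agg(50 + 60 * j, 50, image=f"t{i}") for i, n in enumerate([2, 2, 2, 2])
                for j in range(n)]
        pooled = count_comparison(ref, cmp_, ttest="pooled")
        welch = count_comparison(ref, cmp_, ttest="welch")
        assert pooled.df == 6
        assert welch.df <= 6
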