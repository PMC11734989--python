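"""Observer-agreement metrics.

Within-group agreement scores each observer's annotations against the
group's consensus: a clustered annotation scores 1 when its label matches
the cluster's consensus class, 0 otherwise, and every discarded (noise)
annotation scores 0 unconditionally.  Vote evenness per aggregate uses an
adapted Pielou index (normalized Shannon entropy of the vote shares,
re-scored to 0 when the vote is unanimous).  Between-group agreement matches
two aggregate sets one-to-one by IOU and tabulates a confusion matrix, and
compares per-tile counts with a two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import AggregateAnnotation, AggregationResult, NO_CONSENSUS, compute_iou
from .annotation_model import Annotation, ClassScheme


def pielou_index(tally: Mapping[str, int]) -> float:
    """Evenness of a class-vote tally: -(sum p_i ln p_i) / ln S.

    S is the number of classes receiving at least one vote and p_i the vote
    share of class i.  A unanimous tally (S = 1) is re-scored to exactly 0;
    a uniform split over S >= 2 classes gives 1.  Higher values mean more
    disagreement.  Invariant to scaling the tally by a constant.
    """
    counts = np.array([c for c in tally.values() if c > 0], dtype=float)
    if counts.size == 0:
        raise ValueError("tally must contain at least one vote")
    if counts.size == 1:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / math.log(counts.size))


@dataclass
class ObserverRecord:
    observer_id: str
    overall: float
    per_class: dict[str, float]
    n_annotations: int
    n_scored: int


@dataclass
class AgreementReport:
    """Per-observer, per-class and overall agreement summaries.

    ``per_class`` and ``overall`` are keyed by consensus class and carry
    annotation-weighted mean/SD agreement, mean/SD Pielou over aggregates,
    and mean member IOU.  ``observer_mean_agreement`` gives the
    observer-weighted alternative (plain mean of per-observer ratios).
    """

    per_observer: dict[str, ObserverRecord]
    per_class: pd.DataFrame
    overall: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = self.per_class.copy()
        rows.loc["__overall__"] = pd.Series(self.overall)
        return rows


def _member_scores(
    aggregation: AggregationResult, scheme: ClassScheme, level: str
) -> list[tuple[Annotation, str, int]]:
    """(annotation, consensus class, 0/1 score) for members of decided clusters."""
    out = []
    for agg in aggregation.aggregates:
        if not agg.has_consensus:
            continue
        for m in agg.members:
            score = int(scheme.at_level(m.label, level) == agg.consensus_class)
            out.append((m, agg.consensus_class, score))
    return out


def observer_agreement(
    observer_id: str,
    aggregation: AggregationResult,
    scheme: ClassScheme,
    level: str = "morphological",
) -> ObserverRecord:
    """One observer's agreement with the group consensus.

    Members of tied (no-consensus) clusters are excluded from scoring;
    discarded annotations count as automatic failures in the overall ratio.
    """
    scored = [(c, s) for m, c, s in _member_scores(aggregation, scheme, level)
              if m.observer_id == observer_id]
    n_noise = sum(1 for a in aggregation.discarded if a.observer_id == observer_id)
    n_skipped = sum(
        1
        for agg in aggregation.aggregates
        if not agg.has_consensus
        for m in agg.members
        if m.observer_id == observer_id
    )
    n_total = len(scored) + n_noise + n_skipped
    if n_total == 0:
        raise ValueError(f"observer {observer_id!r} has no annotations in this aggregation")
    values = [s for _, s in scored] + [0] * n_noise
    overall = float(np.mean(values)) if values else 0.0
    per_class: dict[str, list[int]] = {}
    for c, s in scored:
        per_class.setdefault(c, []).append(s)
    return ObserverRecord(
        observer_id=observer_id,
        overall=overall,
        per_class={c: float(np.mean(v)) for c, v in sorted(per_class.items())},
        n_annotations=n_total,
        n_scored=len(values),
    )


def agreement_report(
    aggregation: AggregationResult,
    scheme: ClassScheme,
    level: str = "morphological",
    raw_annotations: Sequence[Annotation] | None = None,
) -> AgreementReport:
    """Full within-group agreement summary.

    ``raw_annotations``, when given, must be exactly the aggregation input;
    it is used only as a consistency check.
    """
    if raw_annotations is not None and len(raw_annotations) != aggregation.n_input:
        raise ValueError("raw annotations do not match the aggregation input size")

    member_scores = _member_scores(aggregation, scheme, level)
    observers = sorted(
        {m.observer_id for m, _, _ in member_scores}
        | {a.observer_id for a in aggregation.discarded}
    )
    per_observer = {
        o: observer_agreement(o, aggregation, scheme, level) for o in observers
    }

    classes = sorted({c for _, c, _ in member_scores})
    rows = {}
    for c in classes:
        scores = np.array([s for _, cc, s in member_scores if cc == c], dtype=float)
        aggs = [a for a in aggregation.aggregates if a.consensus_class == c]
        pielous = np.array([pielou_index(a.vote_tally) for a in aggs])
        ious = np.concatenate([a.member_ious for a in aggs]) if aggs else np.array([])
        rows[c] = {
            "mean_agreement": scores.mean(),
            "sd_agreement": scores.std(ddof=1) if scores.size > 1 else 0.0,
            "mean_pielou": pielous.mean(),
            "sd_pielou": pielous.std(ddof=1) if pielous.size > 1 else 0.0,
            "mean_iou": ious.mean() if ious.size else float("nan"),
            "n_aggregates": len(aggs),
            "n_annotations": int(scores.size),
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")

    all_scores = np.array(
        [s for _, _, s in member_scores] + [0] * len(aggregation.discarded), dtype=float
    )
    decided = [a for a in aggregation.aggregates if a.has_consensus]
    all_pielou = np.array([pielou_index(a.vote_tally) for a in decided])
    all_iou = (
        np.concatenate([a.member_ious for a in decided]) if decided else np.array([])
    )
    obs_overall = np.array([r.overall for r in per_observer.values()])
    weights = np.array([r.n_scored for r in per_observer.values()], dtype=float)
    overall = {
        "mean_agreement": all_scores.mean() if all_scores.size else float("nan"),
        "sd_agreement": all_scores.std(ddof=1) if all_scores.size > 1 else 0.0,
        "mean_pielou": all_pielou.mean() if all_pielou.size else float("nan"),
        "sd_pielou": all_pielou.std(ddof=1) if all_pielou.size > 1 else 0.0,
        "mean_iou": all_iou.mean() if all_iou.size else float("nan"),
        "observer_mean_agreement": obs_overall.mean() if obs_overall.size else float("nan"),
        "n_aggregates": float(len(decided)),
        "n_annotations": float(all_scores.size),
    }
    return AgreementReport(per_observer=per_observer, per_class=per_class, overall=overall)


@dataclass
class MatchResult:
    """One-to-one IOU matching of a comparison aggregate set to a reference."""

    pairs: list[tuple[AggregateAnnotation, AggregateAnnotation, float]]
    unmatched_reference: list[AggregateAnnotation]
    unmatched_comparison: list[AggregateAnnotation]
    confusion: pd.DataFrame

    @property
    def location_match_fraction(self) -> float:
        """Matched pairs as a fraction of the reference set size."""
        n_ref = len(self.pairs) + len(self.unmatched_reference)
        return len(self.pairs) / n_ref if n_ref else float("nan")

    @property
    def class_match_fraction(self) -> float:
        """Fraction of matched pairs whose classes agree."""
        if not self.pairs:
            return float("nan")
        agree = sum(1 for r, c, _ in self.pairs if r.consensus_class == c.consensus_class)
        return agree / len(self.pairs)


def match_aggregates(
    reference: Sequence[AggregateAnnotation],
    comparison: Sequence[AggregateAnnotation],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of two aggregate sets by descending IOU.

    Only pairs within the same image frame and with IOU >= threshold are
    candidates; ties in IOU are broken by reference order, then comparison
    order.  The confusion matrix counts matched pairs by (reference class,
    comparison class).
    """
    candidates: list[tuple[float, int, int]] = []
    for i, r in enumerate(reference):
        for j, c in enumerate(comparison):
            if r.image_id != c.image_id:
                continue
            iou = compute_iou(r.box, c.box)
            if iou >= iou_threshold:
                candidates.append((iou, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_r: set[int] = set()
    used_c: set[int] = set()
    pairs: list[tuple[AggregateAnnotation, AggregateAnnotation, float]] = []
    for iou, i, j in candidates:
        if i in used_r or j in used_c:
            continue
        used_r.add(i)
        used_c.add(j)
        pairs.append((reference[i], comparison[j], iou))
    classes_r = sorted({r.consensus_class for r, _, _ in pairs})
    classes_c = sorted({c.consensus_class for _, c, _ in pairs})
    confusion = pd.DataFrame(0, index=classes_r, columns=classes_c, dtype=int)
    for r, c, _ in pairs:
        confusion.loc[r.consensus_class, c.consensus_class] += 1
    return MatchResult(
        pairs=pairs,
        unmatched_reference=[r for i, r in enumerate(reference) if i not in used_r],
        unmatched_comparison=[c for j, c in enumerate(comparison) if j not in used_c],
        confusion=confusion,
    )


@dataclass
class CountComparison:
    ratio_overall: float
    per_class_ratio: dict[str, float]
    t: float
    df: float
    p: float


def count_comparison(
    reference: Sequence[AggregateAnnotation],
    comparison: Sequence[AggregateAnnotation],
    ttest: str = "pooled",
) -> CountComparison:
    """Compare detection counts between two aggregate sets tile by tile.

    The overall ratio is total comparison count / total reference count
    (aggregates without a consensus class still count as generic
    detections); per-class ratios use consensus classes only, reported as
    NaN where the reference count is zero.  Per-tile totals are compared
    with a two-sample t-test (reference minus comparison): Student's
    pooled-variance test with df = n1 + n2 - 2 by default, or Welch's with
    ``ttest='welch'``.
    """
    if ttest not in {"pooled", "welch"}:
        raise ValueError("ttest must be 'pooled' or 'welch'")
    tiles = sorted({a.image_id for a in reference} | {a.image_id for a in comparison})
    ref_counts = np.array(
        [sum(1 for a in reference if a.image_id == t) for t in tiles], dtype=float
    )
    cmp_counts = np.array(
        [sum(1 for a in comparison if a.image_id == t) for t in tiles], dtype=float
    )
    n_ref, n_cmp = len(reference), len(comparison)
    ratio = n_cmp / n_ref if n_ref else float("nan")

    classes = sorted(
        {a.consensus_class for a in reference if a.consensus_class != NO_CONSENSUS}
        | {a.consensus_class for a in comparison if a.consensus_class != NO_CONSENSUS}
    )
    per_class = {}
    for c in classes:
        r = sum(1 for a in reference if a.consensus_class == c)
        k = sum(1 for a in comparison if a.consensus_class == c)
        per_class[c] = k / r if r else float("nan")

    if np.ptp(ref_counts) == 0 and np.ptp(cmp_counts) == 0 and (
        ref_counts.mean() == cmp_counts.mean()
    ):
        # degenerate zero-variance case: identical constant counts
        t_stat, p_val = 0.0, 1.0
        df = float(len(ref_counts) + len(cmp_counts) - 2)
        return CountComparison(ratio, per_class, t_stat, df, p_val)
    res = stats.ttest_ind(ref_counts, cmp_counts, equal_var=(ttest == "pooled"))
    if ttest == "pooled":
        df = float(len(ref_counts) + len(cmp_counts) - 2)
    else:
        df = float(res.df)
    return CountComparison(
        ratio_overall=ratio,
        per_class_ratio=per_class,
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
    )
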