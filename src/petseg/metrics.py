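"""Majority-vote reference construction and agreement / feature metrics.

The consensus reference for each lesion and strategy is a majority-vote
(MV) mask: a voxel belongs to the MV iff strictly more than half of the
contributing segmentations include it.  Performed segmentations are
compared pairwise (Jaccard, symmetric percentage MATV difference) and
against the MV (sensitivity, positive predictive value, their mean, and
reference-based percentage feature differences for SUVmax, SUVmean, MATV
and TLG).

Sensitivity and PPV follow the confusion-matrix forms SE = TP/(TP+FN) and
PPV = TP/(TP+FP) with the reference supplying the positives; roles
(segmentation vs reference) are explicit in every signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import numpy as np
import pandas as pd

from .imaging import BinaryMask, SUVImage, mask_volume_ml, require_same_geometry

__all__ = [
    "OverlapCounts",
    "FeatureSet",
    "MVPolicy",
    "overlap_counts",
    "jaccard",
    "sensitivity",
    "ppv",
    "ppv_se",
    "majority_vote",
    "extract_features",
    "percent_diff",
    "pairwise_percent_matv_diff",
    "build_metrics_table",
    "METRICS_COLUMNS",
]

METRICS_COLUMNS = ["lesion", "strategy", "kind", "obs_a", "obs_b", "metric", "value"]


@dataclass(frozen=True)
class OverlapCounts:
    """Voxel tallies for a (segmentation, reference) pair."""

    tp: int
    fp: int
    fn: int

    @property
    def n_seg(self) -> int:
        return self.tp + self.fp

    @property
    def n_ref(self) -> int:
        return self.tp + self.fn


def overlap_counts(seg: BinaryMask, ref: BinaryMask) -> OverlapCounts:
    """True/false positive and false negative voxel counts of seg against ref."""
    require_same_geometry(seg, ref)
    s, r = seg.values, ref.values
    return OverlapCounts(
        tp=int(np.count_nonzero(s & r)),
        fp=int(np.count_nonzero(s & ~r)),
        fn=int(np.count_nonzero(~s & r)),
    )


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """|A ∩ B| / |A ∪ B|; 1 is perfect agreement.  Undefined if both empty."""
    require_same_geometry(a, b)
    inter = int(np.count_nonzero(a.values & b.values))
    union = int(np.count_nonzero(a.values | b.values))
    if union == 0:
        raise ValueError("Jaccard is undefined for two empty masks")
    return inter / union


def sensitivity(seg: BinaryMask, ref: BinaryMask) -> float:
    """SE = TP / (TP + FN): fraction of the reference recovered by seg."""
    c = overlap_counts(seg, ref)
    if c.n_ref == 0:
        raise ValueError("sensitivity is undefined for an empty reference")
    return c.tp / c.n_ref


def ppv(seg: BinaryMask, ref: BinaryMask) -> float:
    """PPV = TP / (TP + FP): fraction of seg that belongs to the reference."""
    c = overlap_counts(seg, ref)
    if c.n_seg == 0:
        raise ValueError("PPV is undefined for an empty segmentation")
    return c.tp / c.n_seg


def ppv_se(seg: BinaryMask, ref: BinaryMask) -> float:
    """Combined agreement score: the arithmetic mean of PPV and SE."""
    return 0.5 * (ppv(seg, ref) + sensitivity(seg, ref))


def majority_vote(masks: list[BinaryMask]) -> BinaryMask:
    """Voxels marked by strictly more than half of the segmentations.

    With an even panel a strict majority is required (n = 6 needs >= 4
    votes); exact ties are excluded.
    """
    if len(masks) < 2:
        raise ValueError("majority vote needs at least 2 masks")
    first = masks[0]
    votes = np.zeros(first.shape, dtype=np.int64)
    for m in masks:
        require_same_geometry(first, m)
        votes += m.values
    return BinaryMask(values=votes > len(masks) / 2.0, spacing=first.spacing)


@dataclass(frozen=True)
class FeatureSet:
    """SUVmax, SUVmean, MATV (mL) and TLG (mL·SUV) of one VOI."""

    suv_max: float
    suv_mean: float
    matv_ml: float
    tlg: float

    def __post_init__(self) -> None:
        if self.suv_mean > self.suv_max + 1e-12:
            raise ValueError("SUVmean cannot exceed SUVmax")
        if abs(self.tlg - self.matv_ml * self.suv_mean) > 1e-9 * max(1.0, abs(self.tlg)):
            raise ValueError("TLG must equal MATV * SUVmean")


def extract_features(image: SUVImage, mask: BinaryMask) -> FeatureSet:
    """Standard uptake features of a VOI, with TLG = MATV × SUVmean."""
    require_same_geometry(image, mask)
    if not mask.values.any():
        raise ValueError("cannot extract features from an empty mask")
    vals = image.values[mask.values]
    matv = mask_volume_ml(mask)
    mean = float(vals.mean())
    return FeatureSet(suv_max=float(vals.max()), suv_mean=mean, matv_ml=matv, tlg=matv * mean)


def percent_diff(observed: float, reference: float) -> float:
    """Reference-based percentage difference, 100 × (reference − observed) / reference.

    The sign convention makes an observed value far above the reference
    strongly negative (observed = 3.925 × reference → −292.5%).
    """
    if reference == 0:
        raise ValueError("percent difference is undefined for a zero reference")
    return 100.0 * (reference - observed) / reference


def pairwise_percent_matv_diff(v1: float, v2: float) -> float:
    """Symmetric percentage volume difference of an observer pair:
    100 × |v1 − v2| / mean(v1, v2)."""
    if v1 <= 0 or v2 <= 0:
        raise ValueError("volumes must be > 0")
    return 100.0 * abs(v1 - v2) / ((v1 + v2) / 2.0)


class MVPolicy(str, Enum):
    """Which observers contribute to the majority-vote reference."""

    EXPERIENCED_ONLY = "experienced"
    ALL = "all"


_VS_MV_FEATURES = (
    ("pct_matv_diff", "matv_ml"),
    ("pct_suv_max_diff", "suv_max"),
    ("pct_suv_mean_diff", "suv_mean"),
    ("pct_tlg_diff", "tlg"),
)


def build_metrics_table(records, cases, observers, mv_policy=MVPolicy.EXPERIENCED_ONLY):
    """Long-format metrics table feeding the statistics stage.

    Per lesion × strategy: all pairwise Jaccard and symmetric %MATV rows
    ("pairwise" kind), plus, against the majority-vote reference built under
    ``mv_policy``, per-observer PPV, SE, PPV/SE and percentage feature
    differences ("vs_mv" kind, obs_b = "MV").

    Parameters
    ----------
    records
        SegmentationRecords covering >= 2 observers per lesion × strategy.
    cases
        PhantomCases (or anything with .lesion_id and .image) for feature
        extraction.
    observers
        ObserverProfiles; used to resolve which observers are experienced.
    """
    mv_policy = MVPolicy(mv_policy)
    case_by_lesion = {c.lesion_id: c for c in cases}
    experienced = {
        o.id
        for o in observers
        if getattr(o.experience, "value", str(o.experience)).lower() == "experienced"
    }

    groups: dict[tuple[str, str], list] = {}
    for rec in records:
        groups.setdefault((rec.lesion_id, str(rec.strategy.value)), []).append(rec)

    rows = []
    for (lesion, strategy), recs in sorted(groups.items()):
        if len(recs) < 2:
            raise ValueError(f"need >= 2 observers for {lesion}/{strategy}")
        recs = sorted(recs, key=lambda r: r.observer_id)
        image = case_by_lesion[lesion].image

        for ra, rb in combinations(recs, 2):
            rows.append((lesion, strategy, "pairwise", ra.observer_id, rb.observer_id,
                         "jaccard", jaccard(ra.mask, rb.mask)))
            va, vb = mask_volume_ml(ra.mask), mask_volume_ml(rb.mask)
            if va > 0 and vb > 0:
                rows.append((lesion, strategy, "pairwise", ra.observer_id, rb.observer_id,
                             "pct_matv_diff", pairwise_percent_matv_diff(va, vb)))

        if mv_policy is MVPolicy.EXPERIENCED_ONLY:
            voters = [r for r in recs if r.observer_id in experienced]
        else:
            voters = recs
        if len(voters) < 2:
            raise ValueError(f"MV policy {mv_policy} leaves < 2 voters for {lesion}/{strategy}")
        mv = majority_vote([r.mask for r in voters])
        if not mv.values.any():
            continue  # no consensus VOI; nothing to compare against
        mv_feat = extract_features(image, mv)

        for rec in recs:
            if not rec.mask.values.any():
                continue
            rows.append((lesion, strategy, "vs_mv", rec.observer_id, "MV",
                         "se", sensitivity(rec.mask, mv)))
            rows.append((lesion, strategy, "vs_mv", rec.observer_id, "MV",
                         "ppv", ppv(rec.mask, mv)))
            rows.append((lesion, strategy, "vs_mv", rec.observer_id, "MV",
                         "ppv_se", ppv_se(rec.mask, mv)))
            feat = extract_features(image, rec.mask)
            for metric, attr in _VS_MV_FEATURES:
                rows.append((lesion, strategy, "vs_mv", rec.observer_id, "MV",
                             metric, percent_diff(getattr(feat, attr), getattr(mv_feat, attr))))

    table = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    dup = table.duplicated(subset=["lesion", "strategy", "kind", "obs_a", "obs_b", "metric"])
    if dup.any():
        raise ValueError("duplicated (key, metric) rows in metrics table")
    return table
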