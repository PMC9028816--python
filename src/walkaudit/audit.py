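"""Coordinate-level presence calls from per-image probabilities.

Each audit coordinate has four directional images (headings 0/90/180/270).
Per-image probabilities become a coordinate-level presence call with the
probability threshold fixed at >= 0.50 (boundary inclusive) and one of
three aggregation rules:

* ``threshold-any`` — present if any directional probability clears the
  threshold (default for all features except sidewalks);
* ``mean-then-threshold`` — the four directional probabilities are
  averaged before thresholding (sidewalks: a sidewalk on one side of the
  block shows in some but not all headings, and averaging keeps one
  strong view from being vetoed by the other directions);
* ``conditional`` — sidewalk buffers are only assessed where a sidewalk
  was detected; without a detected sidewalk the buffer call is absent and
  the buffer classifier is not consulted.

Eligibility restricts crossing furniture (zebra/line crosswalks, walk
signals, curb cuts) to intersection coordinates.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from walkaudit.features import DEFAULT_ELIGIBILITY, PRIMITIVE_FEATURES, StreetFeature
from walkaudit.geosim import HEADINGS

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.50

RULE_ANY = "threshold-any"
RULE_MEAN = "mean-then-threshold"
RULE_CONDITIONAL = "conditional"

#: Per-feature aggregation rule over the four directional probabilities.
DEFAULT_RULES: dict[StreetFeature, str] = {
    **{f: RULE_ANY for f in PRIMITIVE_FEATURES},
    StreetFeature.SIDEWALK: RULE_MEAN,
}

_HCOLS = [f"h{h}" for h in HEADINGS]


@dataclasses.dataclass(frozen=True)
class PresenceCall:
    coordinate_id: str
    feature: StreetFeature
    present: bool
    rule_used: str


def threshold_call(p: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Presence iff probability >= threshold (0.50 itself is present)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability outside [0, 1]: {p}")
    return p >= threshold


def _aggregate(probs: Sequence[float], rule: str, threshold: float) -> bool:
    arr = np.asarray(probs, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no available directional probabilities")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"probabilities outside [0, 1]: {probs}")
    if rule == RULE_MEAN:
        return bool(arr.mean() >= threshold)
    return bool((arr >= threshold).any())


def coordinate_call(
    feature: StreetFeature,
    probs: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
    rule: str | None = None,
    coordinate_id: str = "",
) -> PresenceCall:
    """Aggregate one coordinate's four directional probabilities.

    Sidewalks use the mean-then-threshold rule; all other primitive
    features the any-direction rule (overridable via ``rule``).
    """
    if len(probs) != 4:
        raise ValueError(f"expected 4 directional probabilities, got {len(probs)}")
    used = rule if rule is not None else DEFAULT_RULES[feature]
    present = _aggregate(probs, used, threshold)
    return PresenceCall(coordinate_id=coordinate_id, feature=feature, present=present, rule_used=used)


def buffer_call(
    sidewalk_call: PresenceCall,
    buffer_probs: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> PresenceCall:
    """Sidewalk-buffer call, conditional on the sidewalk call at the same
    coordinate: no detected sidewalk means no buffer, regardless of the
    buffer classifier's output."""
    if sidewalk_call.feature != StreetFeature.SIDEWALK:
        raise ValueError("buffer_call requires the coordinate's sidewalk call")
    if len(buffer_probs) != 4:
        raise ValueError(f"expected 4 directional probabilities, got {len(buffer_probs)}")
    if not sidewalk_call.present:
        present = False
    else:
        present = _aggregate(buffer_probs, RULE_ANY, threshold)
    return PresenceCall(
        coordinate_id=sidewalk_call.coordinate_id,
        feature=StreetFeature.SIDEWALK_BUFFER,
        present=present,
        rule_used=RULE_CONDITIONAL,
    )


def call_coordinates(
    probs: pd.DataFrame,
    coordinate_types: Mapping[str, str] | pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
    rule_map: Mapping[StreetFeature, str] | None = None,
    eligibility: Mapping[StreetFeature, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Turn a directional probability table into a long table of calls.

    ``probs`` columns: coordinate_id, feature, h0, h90, h180, h270 (NaN =
    missing image for that heading; a coordinate with no available
    direction for a feature is skipped and logged, never imputed present).
    Output columns: coordinate_id, feature, present, rule_used.
    Intersection-only features produce no calls at segment coordinates.
    """
    rules = dict(DEFAULT_RULES if rule_map is None else {**DEFAULT_RULES, **rule_map})
    elig = dict(DEFAULT_ELIGIBILITY if eligibility is None else eligibility)
    if isinstance(coordinate_types, pd.Series):
        coordinate_types = coordinate_types.to_dict()

    rows = []
    sidewalk_present: dict[str, bool] = {}
    deferred_buffer: list[tuple[str, np.ndarray]] = []

    for rec in probs.itertuples(index=False):
        feature = StreetFeature(rec.feature)
        ctype = coordinate_types[rec.coordinate_id]
        if ctype not in elig[feature]:
            continue
        vec = np.array([getattr(rec, c) for c in _HCOLS], dtype=float)
        if np.isnan(vec).all():
            logger.warning("coordinate %s feature %s: no available images, skipped", rec.coordinate_id, rec.feature)
            continue
        if feature == StreetFeature.SIDEWALK_BUFFER:
            deferred_buffer.append((rec.coordinate_id, vec))
            continue
        present = _aggregate(vec, rules[feature], threshold)
        if feature == StreetFeature.SIDEWALK:
            sidewalk_present[rec.coordinate_id] = present
        rows.append(
            {"coordinate_id": rec.coordinate_id, "feature": feature.value, "present": present, "rule_used": rules[feature]}
        )

    for cid, vec in deferred_buffer:
        if cid not in sidewalk_present:
            logger.warning("coordinate %s: buffer probabilities without a sidewalk call, skipped", cid)
            continue
        if not sidewalk_present[cid]:
            present = False
        else:
            present = _aggregate(vec, rules[StreetFeature.SIDEWALK_BUFFER], threshold)
        rows.append(
            {
                "coordinate_id": cid,
                "feature": StreetFeature.SIDEWALK_BUFFER.value,
                "present": present,
                "rule_used": RULE_CONDITIONAL,
            }
        )

    return pd.DataFrame(rows, columns=["coordinate_id", "feature", "present", "rule_used"])


def audit_neighborhood(
    classifiers: Mapping[StreetFeature, object],
    coordinates: pd.DataFrame,
    image_provider: Callable[[str, int], np.ndarray | None],
    threshold: float = DEFAULT_THRESHOLD,
    rule_map: Mapping[StreetFeature, str] | None = None,
    eligibility: Mapping[StreetFeature, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Run trained classifiers over every coordinate's directional images
    and aggregate to presence calls.

    ``image_provider(coordinate_id, heading)`` returns the image for that
    heading or None if unavailable (missing directions are excluded from
    the aggregation, not imputed).
    """
    elig = dict(DEFAULT_ELIGIBILITY if eligibility is None else eligibility)
    prob_rows = []
    for rec in coordinates.itertuples(index=False):
        images = {h: image_provider(rec.coordinate_id, h) for h in HEADINGS}
        for feature, clf in classifiers.items():
            if rec.type not in elig[feature]:
                continue
            row = {"coordinate_id": rec.coordinate_id, "feature": feature.value}
            for h in HEADINGS:
                img = images[h]
                row[f"h{h}"] = np.nan if img is None else float(clf.predict_proba(img))
            prob_rows.append(row)
    probs = pd.DataFrame(prob_rows, columns=["coordinate_id", "feature", *_HCOLS])
    ctypes = coordinates.set_index("coordinate_id")["type"]
    return call_coordinates(probs, ctypes, threshold=threshold, rule_map=rule_map, eligibility=elig)
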