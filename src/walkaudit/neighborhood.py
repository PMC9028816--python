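"""Per-participant neighborhood summaries of microscale features.

For each participant, every feature's positive calls within the street-
network buffer are divided by the feature's *eligible* coordinate count
(intersection-only features by the buffer's intersections, all-coordinate
features by all buffer coordinates).  Because those denominators differ by
feature, the fractions are z-scored across the participant sample to give
each feature a ranking relative to the sample mean.  The two crosswalk
types are combined by summing their fractions ("all crosswalks") before
z-scoring, and the total microscale score is the sum of exactly seven
z-terms: sidewalks, sidewalk buffers, curb cuts, all crosswalks, walk
signals, bike symbols, and streetlights.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from walkaudit.features import (
    DEFAULT_ELIGIBILITY,
    PRIMITIVE_FEATURES,
    TOTAL_MICROSCALE_TERMS,
    StreetFeature,
)

logger = logging.getLogger(__name__)


class DegenerateSpreadError(ValueError):
    """Raised when a feature has zero spread across the sample and cannot
    be z-scored."""


def feature_fraction(n_positive: int, n_eligible: int) -> float:
    """Positive coordinates over eligible coordinates; NaN (missing, to be
    excluded from z-scoring) when the buffer holds no eligible coordinate."""
    if n_positive < 0 or n_eligible < 0:
        raise ValueError("counts must be non-negative")
    if n_eligible == 0:
        logger.warning("zero eligible coordinates; fraction reported missing")
        return float("nan")
    if n_positive > n_eligible:
        raise ValueError("positives exceed eligible coordinates")
    return n_positive / n_eligible


def combine_crosswalks(zebra_fraction: float, line_fraction: float) -> float:
    """All-crosswalks value = zebra fraction + line fraction.

    A sum, not a probability: it can exceed 1; it is z-scored downstream.
    Missing inputs propagate to a missing composite.
    """
    return float(zebra_fraction) + float(line_fraction)


def zscore_across_sample(values: pd.Series, name: str = "") -> pd.Series:
    """(x - mean) / SD with the sample SD (n-1 divisor).

    Missing values are excluded from the moments and propagate as missing.
    Zero spread raises, naming the degenerate feature.
    """
    v = pd.Series(values, dtype=float)
    obs = v.dropna()
    if len(obs) < 2:
        raise DegenerateSpreadError(f"need >= 2 non-missing values to z-score {name or 'series'}")
    sd = obs.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSpreadError(f"zero spread: cannot z-score {name or 'series'}")
    return (v - obs.mean()) / sd


def total_microscale(zscores: Mapping[StreetFeature, float]) -> float:
    """Sum of the 7 constituent z-terms (combined crosswalks replaces the
    separate zebra and line z-scores).  Any missing constituent makes the
    total missing."""
    terms = []
    for f in TOTAL_MICROSCALE_TERMS:
        if f not in zscores:
            raise KeyError(f"missing z-term {f.value}")
        terms.append(float(zscores[f]))
    if any(np.isnan(t) for t in terms):
        logger.warning("missing constituent z-term; total microscale reported missing")
        return float("nan")
    return float(sum(terms))


def summarize_neighborhoods(
    calls: pd.DataFrame,
    buffers: Mapping[str, set[str]],
    coordinate_types: pd.Series,
    eligibility: Mapping[StreetFeature, frozenset[str]] | None = None,
    buffer_denominator: str = "all",
    zscore: bool = True,
) -> pd.DataFrame:
    """One summary row per participant: fractions, z-scores, total score.

    ``calls`` is the long call table (coordinate_id, feature, present);
    ``buffers`` maps participant_id to the coordinate ids in their
    network buffer.  ``buffer_denominator`` selects the sidewalk-buffer
    denominator: ``"all"`` (all sidewalk-eligible coordinates; default,
    keeps the fraction monotone in streetscape quality) or
    ``"sidewalk-present"`` (only coordinates with a detected sidewalk).
    ``zscore=False`` returns fractions only (useful for single-buffer
    summaries, where sample z-scores are undefined).
    """
    if buffer_denominator not in ("all", "sidewalk-present"):
        raise ValueError("buffer_denominator must be 'all' or 'sidewalk-present'")
    elig = dict(DEFAULT_ELIGIBILITY if eligibility is None else eligibility)
    ctype = coordinate_types

    present = calls[calls["present"]].groupby("feature")["coordinate_id"].agg(set).to_dict()
    called = calls.groupby("feature")["coordinate_id"].agg(set).to_dict()
    sidewalk_pos = present.get(StreetFeature.SIDEWALK.value, set())

    rows = []
    for pid, members in buffers.items():
        row: dict[str, float | str] = {"participant_id": pid}
        by_type = {
            "intersection": {c for c in members if ctype[c] == "intersection"},
            "segment": {c for c in members if ctype[c] == "segment"},
        }
        for f in PRIMITIVE_FEATURES:
            eligible = set().union(*(by_type[t] for t in elig[f]))
            # restrict to coordinates the auditor actually called (skipped
            # coordinates drop out of both numerator and denominator)
            eligible &= called.get(f.value, set())
            if f == StreetFeature.SIDEWALK_BUFFER and buffer_denominator == "sidewalk-present":
                eligible &= sidewalk_pos
            pos = len(eligible & present.get(f.value, set()))
            row[f"frac_{f.value}"] = feature_fraction(pos, len(eligible))
        row["frac_all_crosswalks"] = combine_crosswalks(
            row[f"frac_{StreetFeature.ZEBRA_CROSSWALK.value}"],
            row[f"frac_{StreetFeature.LINE_CROSSWALK.value}"],
        )
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("participant_id")
    if not zscore:
        return summary.reset_index()

    z_features = [*PRIMITIVE_FEATURES, StreetFeature.ALL_CROSSWALKS]
    for f in z_features:
        summary[f"z_{f.value}"] = zscore_across_sample(summary[f"frac_{f.value}"], name=f.value)
    summary["total_microscale"] = sum(
        summary[f"z_{f.value}"] for f in TOTAL_MICROSCALE_TERMS
    )
    return summary.reset_index()
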