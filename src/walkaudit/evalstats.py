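"""Classifier performance metrics and convergent-validity matrices.

Performance of a per-feature classifier against human labels is summarized
with five confusion-matrix ratios: precision TP/(TP+FP), recall
TP/(TP+FN), negative predictive value TN/(TN+FN), specificity TN/(TN+FP),
and accuracy (TP+TN)/total.  A zero denominator yields an undefined (NaN)
metric, never 0.

Convergent validity of the automated audit is assessed with Spearman rank
correlations (average ranks for ties; two-sided p from the t
approximation) between each microscale measure (per-feature z-scores, the
combined-crosswalks composite, the total microscale score) and each
macroscale component/index and perceived-walkability subscale.  Cells are
pairwise-complete; significance stars follow the {0.10, 0.05, 0.01,
0.001} convention.  No multiple-testing correction is applied by default
(per-cell stars); a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from walkaudit.features import PRIMITIVE_FEATURES, StreetFeature


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclasses.dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    npv: float
    specificity: float
    accuracy: float


def confusion(truth, predicted) -> ConfusionCounts:
    """Tally the confusion counts of binary predictions against truth."""
    t = np.asarray(truth).astype(bool)
    p = np.asarray(predicted).astype(bool)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: truth {t.shape} vs predicted {p.shape}")
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
        tn=int((~t & ~p).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cc: ConfusionCounts) -> MetricSet:
    """The five performance ratios; undefined ratios are NaN."""
    if cc.total < 1:
        raise ValueError("need at least one observation")
    return MetricSet(
        precision=_ratio(cc.tp, cc.tp + cc.fp),
        recall=_ratio(cc.tp, cc.tp + cc.fn),
        npv=_ratio(cc.tn, cc.tn + cc.fn),
        specificity=_ratio(cc.tn, cc.tn + cc.fp),
        accuracy=_ratio(cc.tp + cc.tn, cc.total),
    )


def metrics_table(truth_df: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Per-feature metric rows from a truth table (coordinate x feature
    booleans) and a long call table."""
    rows = []
    for f in PRIMITIVE_FEATURES:
        sub = calls[calls["feature"] == f.value]
        if len(sub) == 0:
            continue
        truth = truth_df.loc[sub["coordinate_id"], f.value].to_numpy()
        cc = confusion(truth, sub["present"].to_numpy())
        m = metrics(cc)
        rows.append({"feature": f.value, **dataclasses.asdict(m), **dataclasses.asdict(cc)})
    return pd.DataFrame(rows)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with pairwise-complete observations.

    Average ranks for ties; two-sided p-value from the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)).  Returns (nan, nan) when fewer
    than 3 complete pairs or when either rank vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return float("nan"), float("nan")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def significance_stars(p: float) -> str:
    """Star convention: dagger p<0.10, then * / ** / *** at 0.05/0.01/0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "†"
    return ""


MICRO_ROWS = [f"z_{f.value}" for f in PRIMITIVE_FEATURES] + [
    f"z_{StreetFeature.ALL_CROSSWALKS.value}",
    "total_microscale",
]

MACRO_COLS = [
    "z_net_residential_density",
    "z_land_use_mix",
    "z_intersection_density",
    "z_transit_access",
    "walkability_index",
]


def validity_matrix(
    summaries: pd.DataFrame,
    macro: pd.DataFrame,
    perceived: pd.DataFrame,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Long-format Spearman validity matrix.

    Rows: the 8 per-feature z-scores, combined crosswalks, and the total
    microscale score.  Columns: the 4 macroscale component z-scores and
    walkability index, then the 7 perceived subscales.  Tables are joined
    on participant_id; each cell uses pairwise-complete observations and
    reports (rho, p, stars, n).  ``bh_correction=True`` replaces raw
    p-values with Benjamini-Hochberg adjusted ones before starring.
    """
    from walkaudit.geosim import PERCEIVED_SUBSCALES

    columns = MACRO_COLS + list(PERCEIVED_SUBSCALES)
    missing_rows = [r for r in MICRO_ROWS if r not in summaries.columns]
    missing_macro = [c for c in MACRO_COLS if c not in macro.columns]
    missing_perc = [c for c in PERCEIVED_SUBSCALES if c not in perceived.columns]
    if missing_rows or missing_macro or missing_perc:
        raise ValueError(f"missing columns: {missing_rows + missing_macro + missing_perc}")
    # restrict each table to its own columns: the raw macro components and
    # the perceived subscales share names (e.g. land_use_mix)
    merged = (
        summaries[["participant_id", *MICRO_ROWS]]
        .merge(macro[["participant_id", *MACRO_COLS]], on="participant_id")
        .merge(perceived[["participant_id", *PERCEIVED_SUBSCALES]], on="participant_id")
    )

    cells = []
    for r in MICRO_ROWS:
        for c in columns:
            ok = merged[[r, c]].dropna()
            rho, p = spearman(merged[r], merged[c])
            cells.append({"row": r, "column": c, "rho": rho, "p": p, "n": len(ok)})
    out = pd.DataFrame(cells)
    if bh_correction:
        mask = out["p"].notna()
        out.loc[mask, "p"] = stats.false_discovery_control(out.loc[mask, "p"], method="bh")
    out["stars"] = [significance_stars(p) for p in out["p"]]
    return out
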