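"""Chromatin-state combination profiling of TE elements.

Each TE copy is classified by the combination of histone-mark peak sets it
overlaps (>=1 bp).  Labels are combination strings over the provided marks
("K27ac+K4me1", "K4me1_only", "none", ...), with H3K27ac+H3K4me1 the
active-enhancer-like signature, H3K4me1 alone the poised-enhancer-like
signature and H3K4me3 the active-promoter signature.  Repressive marks
(H3K9me3, H3K27me3) join combinations without any precedence rule.
Per-family label proportions can use all copies as denominator or only the
copies bearing a chosen mark (e.g. the fraction of H3K27ac-marked elements
also marked by H3K4me1).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import IntervalSet, TEAnnotation

__all__ = [
    "KNOWN_MARKS",
    "classify_elements",
    "family_state_proportions",
    "cross_family_summary",
    "comarking_fraction",
]

# canonical ordering used to build combination labels
KNOWN_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K9me3", "H3K27me3")
_SHORT = {m: m[2:] for m in KNOWN_MARKS}  # H3K27ac -> K27ac


def _label(marks_present: list[str]) -> str:
    if not marks_present:
        return "none"
    shorts = [_SHORT[m] for m in KNOWN_MARKS if m in marks_present]
    if len(shorts) == 1:
        return f"{shorts[0]}_only"
    return "+".join(shorts)


def classify_elements(
    annotation: TEAnnotation, mark_peaks: Mapping[str, IntervalSet]
) -> pd.DataFrame:
    """Per-element mark overlap calls and derived combination label.

    Returns one row per element: ``element_id`` (index into the
    annotation), ``family``, one boolean column per mark, and ``label``.
    The label is a pure function of the set of overlapped marks.
    """
    if not mark_peaks:
        raise ValueError("at least one mark peak set is required")
    unknown = [m for m in mark_peaks if m not in KNOWN_MARKS]
    if unknown:
        raise ValueError(
            f"unknown mark name(s): {', '.join(unknown)}; "
            f"known marks are {', '.join(KNOWN_MARKS)}"
        )
    elements = annotation.all_intervals()
    calls = pd.DataFrame(
        {
            "element_id": np.arange(len(annotation)),
            "family": [el.family for el in annotation.elements],
        }
    )
    marks = [m for m in KNOWN_MARKS if m in mark_peaks]
    for mark in marks:
        calls[mark] = mark_peaks[mark].overlap_flags(elements)
    calls["label"] = [
        _label([m for m in marks if row[m]])
        for _, row in calls.iterrows()
    ]
    return calls


def family_state_proportions(
    calls: pd.DataFrame,
    annotation: TEAnnotation,
    denominator: str = "all",
) -> pd.DataFrame:
    """Per-family proportions of each combination label.

    ``denominator`` is "all" (all family copies) or a mark name (only
    copies bearing that mark, e.g. "H3K27ac" restricts to H3K27ac-marked
    elements).  Rows sum to 1; a family empty under the chosen denominator
    is omitted with a warning.
    """
    if denominator != "all":
        if denominator not in calls.columns:
            raise ValueError(f"denominator mark {denominator!r} not in calls")
        subset = calls[calls[denominator]]
    else:
        subset = calls
    labels = sorted(calls["label"].unique())
    rows = {}
    for family in annotation.families:
        fam_calls = subset[subset["family"] == family]
        if len(fam_calls) == 0:
            warnings.warn(
                f"family {family}: no elements under denominator "
                f"{denominator!r}; omitted"
            )
            continue
        counts = fam_calls["label"].value_counts()
        rows[family] = [counts.get(lbl, 0) / len(fam_calls) for lbl in labels]
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels).sort_index()


def cross_family_summary(proportions: pd.DataFrame, label: str) -> dict[str, float]:
    """Median / min / max of one label's proportion across families."""
    if len(proportions) == 0:
        raise ValueError("need at least one family")
    values = (
        proportions[label].to_numpy(float)
        if label in proportions.columns
        else np.zeros(len(proportions))
    )
    return {
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def comarking_fraction(
    calls: pd.DataFrame, mark: str, given: str
) -> pd.Series:
    """Per-family fraction of ``given``-marked elements also bearing
    ``mark`` (e.g. fraction of H3K27ac-marked copies that are H3K4me1+)."""
    for m in (mark, given):
        if m not in calls.columns:
            raise ValueError(f"mark {m!r} not present in calls")
    base = calls[calls[given]]
    return base.groupby("family")[mark].mean()
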