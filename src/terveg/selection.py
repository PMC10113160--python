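"""Multi-assay candidate-family selection.

Two stages: (1) repeat families with significant H3K27ac peak enrichment in
both of two cell contexts (e.g. primary cytotrophoblast and trophoblast
stem cells); (2) a tissue-specificity filter on DNase hypersensitivity
enrichment — keep a family only if more than 80% of placental datasets show
a fold enrichment above two AND the median placental fold exceeds the
pooled liver/lung/kidney median by more than 2.  All thresholds are strict
inequalities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "concordant_families",
    "dnase_specificity_filter",
    "select_candidate_families",
    "COMPARISON_TISSUES",
]

COMPARISON_TISSUES = ("kidney", "liver", "lung")
PANEL_COLUMNS = ["family", "dataset_id", "tissue", "fold"]


def concordant_families(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> list[str]:
    """Families flagged significant in both enrichment record sets, sorted."""
    sig_a = set(records_a.loc[records_a["significant"].astype(bool), "family"])
    sig_b = set(records_b.loc[records_b["significant"].astype(bool), "family"])
    return sorted(sig_a & sig_b)


def dnase_specificity_filter(
    panel: pd.DataFrame,
    frac_placenta: float = 0.8,
    fold_min: float = 2.0,
    median_diff_min: float = 2.0,
) -> dict:
    """Tissue-specificity decision for one family's DNase enrichment panel.

    ``panel`` has one row per dataset with columns ``dataset_id``,
    ``tissue`` (placenta / kidney / liver / lung) and ``fold``.  Passes iff
    the fraction of placental datasets with fold > ``fold_min`` exceeds
    ``frac_placenta`` and the placental median fold exceeds the pooled
    non-placental median by more than ``median_diff_min``.  Medians of
    even-sized groups are midpoint averages.
    """
    tissues = set(panel["tissue"])
    missing = [t for t in ("placenta", *COMPARISON_TISSUES) if t not in tissues]
    if missing:
        raise ValueError(f"panel is missing tissue group(s): {', '.join(missing)}")
    placenta = panel.loc[panel["tissue"] == "placenta", "fold"].to_numpy(float)
    others = panel.loc[
        panel["tissue"].isin(COMPARISON_TISSUES), "fold"
    ].to_numpy(float)
    pass_fraction = float((placenta > fold_min).mean())
    placenta_median = float(np.median(placenta))
    other_median = float(np.median(others))
    median_diff = placenta_median - other_median
    per_tissue = {
        f"median_{t}": float(
            np.median(panel.loc[panel["tissue"] == t, "fold"])
        )
        for t in COMPARISON_TISSUES
    }
    return {
        "passed": (pass_fraction > frac_placenta) and (median_diff > median_diff_min),
        "placenta_pass_fraction": pass_fraction,
        "placenta_median": placenta_median,
        "other_median": other_median,
        "median_diff": median_diff,
        **per_tissue,
    }


def select_candidate_families(
    h3k27ac_a: pd.DataFrame,
    h3k27ac_b: pd.DataFrame,
    dnase_panels: pd.DataFrame | None = None,
    frac_placenta: float = 0.8,
    fold_min: float = 2.0,
    median_diff_min: float = 2.0,
) -> pd.DataFrame:
    """Compose the two selection rules into the final candidate list.

    Returns one row per concordantly enriched family, sorted by name, with
    the DNase diagnostics and a ``selected`` flag.  With no DNase panels at
    all, every concordant family is returned selected, with a warning and
    ``dnase_evaluated`` False.
    """
    concordant = concordant_families(h3k27ac_a, h3k27ac_b)
    rows = []
    if dnase_panels is None or len(dnase_panels) == 0:
        if concordant:
            warnings.warn(
                "no DNase panels supplied; returning concordant families "
                "without the tissue-specificity filter"
            )
        for fam in concordant:
            rows.append({"family": fam, "dnase_evaluated": False, "selected": True})
        return pd.DataFrame(rows, columns=["family", "dnase_evaluated", "selected"])

    for fam in concordant:
        panel = dnase_panels[dnase_panels["family"] == fam]
        if len(panel) == 0:
            warnings.warn(f"family {fam}: no DNase panel rows; excluded")
            rows.append(
                {"family": fam, "dnase_evaluated": False, "selected": False}
            )
            continue
        diag = dnase_specificity_filter(
            panel, frac_placenta=frac_placenta, fold_min=fold_min,
            median_diff_min=median_diff_min,
        )
        rows.append(
            {
                "family": fam,
                "dnase_evaluated": True,
                "selected": bool(diag.pop("passed")),
                **diag,
            }
        )
    return pd.DataFrame(rows)
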