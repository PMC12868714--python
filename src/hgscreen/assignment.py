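"""Guide detection, capture categorisation and perturbation assignment.

Guides double as perturbation barcodes: a cell is usable only when its
detected Cas9 and Cas12a guides point at a single library hgRNA. Cells
implying two or more hgRNAs are doublets; cells whose two modalities point
at different hgRNAs with no single-hgRNA explanation are decoupled (e.g.
lentiviral template switching) and are dropped because their perturbation
identity is unknowable; cells assigned a non-targeting hgRNA are excluded
from analysis by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .library import GuideLibrary

CAPTURE_CATEGORIES = ("dual", "cas9_only", "cas12a_only", "none")
STATUSES = ("assigned", "doublet", "decoupled", "no_guide",
            "excluded_nontargeting")


@dataclass
class CellAssignment:
    """Per-cell detection sets, capture category, assignment and status."""

    table: pd.DataFrame  # index barcode; columns below

    COLUMNS = ("detected_cas9", "detected_cas12a", "capture_category",
               "assigned_hgrna", "status")

    def assigned_cells(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "assigned"]

    def category_fractions(self) -> tuple[pd.Series, pd.Series]:
        """(fractions over all cells, fractions over cells with >=1 guide)."""
        cat = self.table["capture_category"]
        overall = cat.value_counts(normalize=True).reindex(
            CAPTURE_CATEGORIES, fill_value=0.0)
        with_guide = cat[cat != "none"]
        if len(with_guide):
            detected = with_guide.value_counts(normalize=True).reindex(
                CAPTURE_CATEGORIES, fill_value=0.0)
        else:
            detected = pd.Series(0.0, index=pd.Index(CAPTURE_CATEGORIES))
        return overall, detected


def detect_guides(guide_adata: ad.AnnData, min_umi: int = 5,
                  dominance_ratio: float = 3.0) -> pd.DataFrame:
    """Call detected guides per cell and modality from UMI counts.

    Within a modality, every guide with UMI >= ``min_umi`` is a candidate.
    If two or more candidates exist they are all reported (co-detections
    stay visible so doublets remain detectable). A lone candidate is
    reported only if its UMI count is at least ``dominance_ratio`` times the
    next-highest guide count in that modality, suppressing calls that barely
    exceed ambient background.

    Returns a DataFrame indexed by barcode with ``detected_cas9`` /
    ``detected_cas12a`` columns holding frozensets of hgRNA ids.
    """
    if min_umi < 1:
        raise ValueError("min_umi must be >= 1")
    if dominance_ratio < 1:
        raise ValueError("dominance_ratio must be >= 1")
    if not {"hgrna_id", "modality"} <= set(guide_adata.var.columns):
        raise ValueError("guide matrix features need hgrna_id and modality columns")

    X = guide_adata.X
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    out: dict[str, list[frozenset]] = {"detected_cas9": [], "detected_cas12a": []}
    modal_cols = {
        m: np.flatnonzero((guide_adata.var["modality"] == m).to_numpy())
        for m in ("cas9", "cas12a")
    }
    hgrna = guide_adata.var["hgrna_id"].to_numpy()
    for m, cols in modal_cols.items():
        sub = X[:, cols]
        ids = hgrna[cols]
        key = f"detected_{m}"
        for row in sub:
            cand = np.flatnonzero(row >= min_umi)
            if len(cand) >= 2:
                out[key].append(frozenset(ids[cand]))
            elif len(cand) == 1:
                rest = np.delete(row, cand[0])
                runner_up = rest.max() if len(rest) else 0
                if row[cand[0]] >= dominance_ratio * runner_up:
                    out[key].append(frozenset([ids[cand[0]]]))
                else:
                    out[key].append(frozenset())
            else:
                out[key].append(frozenset())
    return pd.DataFrame(out, index=guide_adata.obs_names.copy())


def categorize_capture(detected: pd.DataFrame) -> pd.Series:
    """Capture category per cell from the two detection sets."""
    has9 = detected["detected_cas9"].map(len) > 0
    has12 = detected["detected_cas12a"].map(len) > 0
    cat = np.where(has9 & has12, "dual",
                   np.where(has9, "cas9_only",
                            np.where(has12, "cas12a_only", "none")))
    return pd.Series(cat, index=detected.index, name="capture_category")


def assign_perturbations(detected: pd.DataFrame, library: GuideLibrary,
                         exclude_nontargeting: bool = True,
                         require_dual: bool = False) -> CellAssignment:
    """Resolve each cell's detection sets to a single hgRNA identity.

    A cell is ``assigned`` iff the union of hgRNAs implied by its detected
    guides is exactly one library hgRNA (single-modality evidence suffices
    unless ``require_dual``). Two or more hgRNAs within one modality mean a
    doublet; one hgRNA per modality but differing means a decoupled cell.
    Non-targeting assignments are excluded when the flag is set.
    """
    known = set(library.hgrna_ids)
    nontargeting = {r.hgrna_id for r in library.records
                    if r.target_class == "non_targeting"}
    categories = categorize_capture(detected)

    statuses, assigned = [], []
    for bc, row in detected.iterrows():
        s9, s12 = row["detected_cas9"], row["detected_cas12a"]
        stray = (s9 | s12) - known
        if stray:
            raise ValueError(f"detected guide(s) not in library: {sorted(stray)}")
        union = s9 | s12
        if not union:
            statuses.append("no_guide")
            assigned.append(None)
        elif len(union) == 1:
            (h,) = union
            if require_dual and not (s9 and s12):
                statuses.append("no_guide")
                assigned.append(None)
            elif exclude_nontargeting and h in nontargeting:
                statuses.append("excluded_nontargeting")
                assigned.append(None)
            else:
                statuses.append("assigned")
                assigned.append(h)
        elif len(s9) <= 1 and len(s12) <= 1:
            statuses.append("decoupled")
            assigned.append(None)
        else:
            statuses.append("doublet")
            assigned.append(None)

    table = pd.DataFrame(
        {"detected_cas9": detected["detected_cas9"],
         "detected_cas12a": detected["detected_cas12a"],
         "capture_category": categories,
         "assigned_hgrna": assigned,
         "status": statuses},
        index=detected.index)
    return CellAssignment(table)


def assignment_summary(assignment: CellAssignment) -> dict:
    """JSON-ready summary of capture-category and status fractions."""
    overall, detected = assignment.category_fractions()
    status = assignment.table["status"].value_counts(normalize=True)
    return {
        "n_cells": int(len(assignment.table)),
        "capture_fraction_all": overall.round(6).to_dict(),
        "capture_fraction_detected": detected.round(6).to_dict(),
        "status_fraction": status.round(6).to_dict(),
    }
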