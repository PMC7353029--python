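"""Truncal/branch/private classification, mutational load, diversity,
panel filtering and driver annotation."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import PanelDefinition, PresenceMatrix, VariantKey

__all__ = [
    "ClonalityLabel",
    "LoadSummary",
    "classify_clonality",
    "clonality_counts",
    "clonality_proportions",
    "cohort_proportions",
    "mutational_load",
    "filter_panel",
    "annotate_drivers",
]


class ClonalityLabel(str, Enum):
    TRUNCAL = "truncal"
    BRANCH = "branch"
    PRIVATE = "private"


@dataclass(frozen=True)
class LoadSummary:
    """Per-biopsy non-synonymous somatic mutational load and its spread."""

    patient_id: str
    biopsy_ids: tuple[str, ...]
    loads: tuple[int, ...]
    mean: float
    sd: float
    diversity_mean: float  # mean pairwise |load_i - load_j|
    diversity_sd: float


def classify_clonality(matrix: PresenceMatrix) -> dict[VariantKey, ClonalityLabel]:
    """Label each variant by the number of analyzed biopsies carrying it.

    truncal = all columns; private = exactly one; branch = in between.
    The denominator is the number of QC-passed biopsies actually in the
    matrix, so a 2-biopsy patient has an empty branch class.
    """
    if matrix.n_biopsies < 2:
        raise ValueError("clonality requires >= 2 biopsy columns")
    b = matrix.n_biopsies
    labels: dict[VariantKey, ClonalityLabel] = {}
    for key, m in zip(matrix.variant_keys, matrix.row_counts()):
        if m == b:
            labels[key] = ClonalityLabel.TRUNCAL
        elif m == 1:
            labels[key] = ClonalityLabel.PRIVATE
        else:
            labels[key] = ClonalityLabel.BRANCH
    return labels


def clonality_counts(labels: Mapping[VariantKey, ClonalityLabel]) -> dict[ClonalityLabel, int]:
    counts = {lab: 0 for lab in ClonalityLabel}
    for lab in labels.values():
        counts[lab] += 1
    return counts


def clonality_proportions(
    labels: Mapping[VariantKey, ClonalityLabel],
) -> dict[ClonalityLabel, float]:
    """Fractions of truncal/branch/private among the labeled variants.

    Zero variants is undefined: returns NaN for all three rather than 0.
    """
    counts = clonality_counts(labels)
    total = sum(counts.values())
    if total == 0:
        return {lab: float("nan") for lab in ClonalityLabel}
    return {lab: counts[lab] / total for lab in ClonalityLabel}


def cohort_proportions(
    per_patient: Mapping[str, Mapping[VariantKey, ClonalityLabel]],
) -> pd.DataFrame:
    """Per-patient proportions plus cohort mean +/- sample sd (ddof=1).

    Patients with zero variants are excluded from the cohort aggregate.
    """
    rows = []
    for patient, labels in sorted(per_patient.items()):
        props = clonality_proportions(labels)
        rows.append(
            {
                "patient_id": patient,
                "n_variants": len(labels),
                "truncal": props[ClonalityLabel.TRUNCAL],
                "branch": props[ClonalityLabel.BRANCH],
                "private": props[ClonalityLabel.PRIVATE],
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        valid = df.dropna(subset=["truncal"])
        summary = {
            "patient_id": "COHORT_MEAN±SD",
            "n_variants": valid["n_variants"].sum(),
        }
        for col in ("truncal", "branch", "private"):
            summary[col] = valid[col].mean()
            summary[col + "_sd"] = valid[col].std(ddof=1) if len(valid) > 1 else float("nan")
        df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    return df


def mutational_load(matrix: PresenceMatrix) -> LoadSummary:
    """Per-biopsy variant counts; diversity = mean +/- sd of all pairwise
    absolute load differences (interpretive definition, see docs)."""
    loads = matrix.column_counts()
    mean = float(np.mean(loads))
    sd = float(np.std(loads, ddof=1)) if len(loads) > 1 else float("nan")
    diffs = [abs(int(a) - int(b)) for a, b in combinations(loads, 2)]
    dmean = float(np.mean(diffs)) if diffs else float("nan")
    dsd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else float("nan")
    return LoadSummary(
        patient_id=matrix.patient_id,
        biopsy_ids=tuple(matrix.biopsy_ids),
        loads=tuple(int(x) for x in loads),
        mean=mean,
        sd=sd,
        diversity_mean=dmean,
        diversity_sd=dsd,
    )


def filter_panel(matrix: PresenceMatrix, panel: PanelDefinition) -> tuple[PresenceMatrix, bool]:
    """Keep only variants whose gene is in the panel.

    Returns ``(filtered_matrix, is_empty)``; an empty result is flagged,
    not fatal (panels can be disjoint from a patient's variants).
    """
    mask = np.array([g in panel for g in matrix.genes], dtype=bool)
    filtered = matrix.select_variants(mask)
    return filtered, filtered.n_variants == 0


def annotate_drivers(
    matrix: PresenceMatrix,
    labels: Mapping[VariantKey, ClonalityLabel],
    driver_genes: set[str] | frozenset[str] | Sequence[str],
) -> tuple[pd.DataFrame, float]:
    """Per-driver-variant clonality report with AF/CCF, plus the fraction
    of driver variants labeled truncal (NaN when no driver variants)."""
    drivers = {g.upper() for g in driver_genes}
    rows = []
    for i, (key, gene) in enumerate(zip(matrix.variant_keys, matrix.genes)):
        if gene not in drivers:
            continue
        present = matrix.presence[i]
        af_vals = matrix.af[i][present]
        af_vals = af_vals[np.isfinite(af_vals)]
        ccf_vals = matrix.ccf[i][present]
        ccf_vals = ccf_vals[np.isfinite(ccf_vals)]
        rows.append(
            {
                "patient_id": matrix.patient_id,
                "gene": gene,
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "clonality": labels[key].value,
                "mean_af": float(af_vals.mean()) if len(af_vals) else float("nan"),
                "mean_ccf": float(ccf_vals.mean()) if len(ccf_vals) else float("nan"),
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "gene",
            "chrom",
            "pos",
            "ref",
            "alt",
            "clonality",
            "mean_af",
            "mean_ccf",
        ],
    )
    if len(report) == 0:
        return report, float("nan")
    frac = float((report["clonality"] == ClonalityLabel.TRUNCAL.value).mean())
    return report, frac
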