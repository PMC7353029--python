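"""Single-biopsy truncal prediction by AF/CCF thresholding.

Ground truth for a variant is its truncal status over all QC-passed
biopsies of the patient. For a candidate threshold t, a variant observed
in one biopsy is called truncal iff its metric value >= t (inclusive
comparison, documented convention). Per-biopsy accuracy is the fraction
of correct calls among the variants present in that biopsy; accuracies
are averaged over biopsies, then over the patients of the grouping
level. The best threshold is the smallest grid value attaining the
maximum average accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clonality import ClonalityLabel, classify_clonality
from .io_model import PresenceMatrix

__all__ = [
    "CCFInput",
    "SweepResult",
    "compute_af",
    "estimate_ccf",
    "classify_by_threshold",
    "biopsy_accuracy",
    "patient_accuracy",
    "sweep_threshold",
    "compare_metrics",
]

Metric = Literal["AF", "CCF"]
Grouping = Literal["cohort", "cancer_type", "patient"]


@dataclass(frozen=True)
class CCFInput:
    af: float
    purity: float
    tumor_cn: float = 2.0
    multiplicity: float = 1.0
    normal_cn: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"af must be in [0, 1], got {self.af}")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.tumor_cn < 0:
            raise ValueError("tumor_cn must be >= 0")


@dataclass
class SweepResult:
    metric: Metric
    grouping: Grouping
    group: str  # "cohort", a cancer type, or a patient id
    panel: str
    grid: np.ndarray
    accuracies: np.ndarray  # mean accuracy per threshold, NaN if unavailable
    patients: list[str]
    skipped_patients: list[str] = field(default_factory=list)
    comparison: str = "ge"  # inclusive threshold, smallest-argmax ties

    @property
    def available(self) -> bool:
        return bool(np.isfinite(self.accuracies).any())

    @property
    def best_threshold(self) -> float:
        if not self.available:
            return float("nan")
        return float(self.grid[int(np.nanargmax(self.accuracies))])

    @property
    def best_accuracy(self) -> float:
        if not self.available:
            return float("nan")
        return float(np.nanmax(self.accuracies))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metric,
                "grouping": self.grouping,
                "group": self.group,
                "panel": self.panel,
                "threshold": self.grid,
                "accuracy": self.accuracies,
            }
        )


def compute_af(alt_count: int, ref_count: int) -> float:
    """Alternative reads over total reads; zero depth is an error."""
    depth = alt_count + ref_count
    if depth <= 0:
        raise ValueError("zero depth: AF undefined")
    return alt_count / depth


def estimate_ccf(inp: CCFInput) -> tuple[float, bool]:
    """Closed-form CCF from AF, purity and copy number.

    CCF = af * (purity*tumor_cn + normal_cn*(1-purity)) / (purity * multiplicity),
    clipped into [0, 1]. Returns ``(ccf, was_clipped)``.
    """
    raw = (
        inp.af
        * (inp.purity * inp.tumor_cn + inp.normal_cn * (1.0 - inp.purity))
        / (inp.purity * inp.multiplicity)
    )
    clipped = raw < 0.0 or raw > 1.0
    return float(min(max(raw, 0.0), 1.0)), clipped


def attach_ccf(
    matrix: PresenceMatrix,
    purity_by_biopsy: Mapping[str, float],
    tumor_cn: float = 2.0,
    multiplicity: float = 1.0,
) -> int:
    """Fill ``matrix.ccf`` in place from per-cell AF and per-biopsy purity.

    Cells without AF stay NaN. Returns the number of clipped estimates.
    """
    clipped = 0
    for j, biopsy in enumerate(matrix.biopsy_ids):
        purity = purity_by_biopsy[biopsy]
        for i in range(matrix.n_variants):
            af = matrix.af[i, j]
            if not np.isfinite(af):
                continue
            ccf, was_clipped = estimate_ccf(
                CCFInput(af=af, purity=purity, tumor_cn=tumor_cn, multiplicity=multiplicity)
            )
            matrix.ccf[i, j] = ccf
            clipped += was_clipped
    return clipped


def classify_by_threshold(values: Sequence[float], threshold: float) -> np.ndarray:
    """Boolean truncal calls: value >= threshold (inclusive)."""
    return np.asarray(values, dtype=float) >= threshold


def _metric_values(matrix: PresenceMatrix, metric: Metric) -> np.ndarray:
    if metric == "AF":
        return matrix.af
    if metric == "CCF":
        return matrix.ccf
    raise ValueError(f"unknown metric {metric!r}")


def biopsy_accuracy(
    values: np.ndarray, truth: np.ndarray, threshold: float
) -> float:
    """Fraction of correct truncal/branch calls among assessed variants."""
    values = np.asarray(values, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if values.size == 0:
        return float("nan")
    calls = values >= threshold
    return float((calls == truth).mean())


def patient_accuracy(
    matrix: PresenceMatrix, metric: Metric, thresholds: np.ndarray
) -> np.ndarray:
    """Mean per-biopsy accuracy for each threshold (the Eq.-3 style
    average with biopsy-i denominators = variants present in biopsy i)."""
    labels = classify_clonality(matrix)
    truth_vec = np.array(
        [labels[k] is ClonalityLabel.TRUNCAL for k in matrix.variant_keys]
    )
    vals = _metric_values(matrix, metric)
    out = np.full(len(thresholds), np.nan)
    per_biopsy: list[np.ndarray] = []
    for j in range(matrix.n_biopsies):
        present = matrix.presence[:, j]
        v = vals[present, j]
        t = truth_vec[present]
        ok = np.isfinite(v)
        v, t = v[ok], t[ok]
        if v.size == 0:
            continue
        acc = (v[None, :] >= np.asarray(thresholds)[:, None]) == t[None, :]
        per_biopsy.append(acc.mean(axis=1))
    if not per_biopsy:
        return out
    return np.mean(per_biopsy, axis=0)


def sweep_threshold(
    matrices: Mapping[str, PresenceMatrix],
    metric: Metric,
    grid: np.ndarray,
    grouping: Grouping = "cohort",
    cancer_types: Mapping[str, str] | None = None,
    panel: str = "WES-NSS",
) -> list[SweepResult]:
    """Grid-search the best threshold per group.

    Patients whose matrix carries no usable metric values (e.g. no
    copy-number information for CCF) are skipped and reported. Groups
    with zero usable patients are emitted as "Not available" results.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if grouping == "cancer_type" and cancer_types is None:
        raise ValueError("cancer_type grouping requires a patient->type mapping")

    per_patient: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for pid, m in sorted(matrices.items()):
        acc = patient_accuracy(m, metric, grid)
        if np.isfinite(acc).any():
            per_patient[pid] = acc
        else:
            skipped.append(pid)

    if grouping == "cohort":
        groups = {"cohort": sorted(per_patient)}
    elif grouping == "patient":
        groups = {pid: [pid] for pid in sorted(per_patient)}
    else:
        groups = {}
        for pid in sorted(matrices):
            groups.setdefault(cancer_types[pid], []).append(pid)
        groups = {
            g: [p for p in pids if p in per_patient] for g, pids in sorted(groups.items())
        }

    results = []
    for group, pids in groups.items():
        if pids:
            acc = np.mean([per_patient[p] for p in pids], axis=0)
        else:
            acc = np.full(grid.shape, np.nan)  # "Not available"
        results.append(
            SweepResult(
                metric=metric,
                grouping=grouping,
                group=group,
                panel=panel,
                grid=grid,
                accuracies=acc,
                patients=list(pids),
                skipped_patients=list(skipped),
            )
        )
    return results


def compare_metrics(
    af_sweeps: Sequence[SweepResult], ccf_sweeps: Sequence[SweepResult]
) -> dict:
    """Paired per-group best-accuracy differences (AF minus CCF) and a
    Wilcoxon signed-rank p-value (NaN for a single pair or all-zero)."""
    af_by_group = {s.group: s for s in af_sweeps}
    ccf_by_group = {s.group: s for s in ccf_sweeps}
    if set(af_by_group) != set(ccf_by_group):
        raise ValueError("AF and CCF sweeps cover different groups")
    groups = sorted(g for g in af_by_group if af_by_group[g].available and ccf_by_group[g].available)
    diffs = np.array(
        [af_by_group[g].best_accuracy - ccf_by_group[g].best_accuracy for g in groups]
    )
    if diffs.size == 0:
        raise ValueError("no paired groups with available sweeps")
    if diffs.size < 2:
        p = float("nan")
    elif np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs, zero_method="wilcox", method="auto").pvalue)
    return {
        "groups": groups,
        "differences": diffs,
        "mean_improvement": float(diffs.mean()),
        "p_value": p,
    }
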