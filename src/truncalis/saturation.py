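"""Combinatorial biopsy-subset analysis.

For each subset size k of a patient's b QC-passed biopsies, three
statistics are averaged over all C(b, k) subsets (deterministic
lexicographic enumeration):

* unique — variants present in at least one biopsy of the subset
* PTV    — putative truncal variants: present in every biopsy of the subset
* PPV    — truncal count (over all b biopsies) divided by the subset's PTV
           count; 0/0 subsets are excluded from the mean and tallied

plus the per-step increment statistics and the Wilcoxon-based
minimum-sample determination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import PresenceMatrix

__all__ = [
    "SaturationProfile",
    "avg_unique",
    "avg_ptv",
    "avg_ppv",
    "saturation_profile",
    "increment_stats",
    "min_samples_required",
    "friedman_load_test",
]


@dataclass
class SaturationProfile:
    patient_id: str
    panel: str
    b: int
    avg_unique: dict[int, float]
    avg_ptv: dict[int, float]
    avg_ppv: dict[int, float]  # NaN when every subset was excluded
    ppv_excluded: dict[int, int]  # subsets with PTV == 0 at each k
    per_subset: pd.DataFrame = field(repr=False)  # long format, one row per subset

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": self.patient_id,
                "panel": self.panel,
                "k": k,
                "avg_unique": self.avg_unique[k],
                "avg_ptv": self.avg_ptv[k],
                "avg_ppv": self.avg_ppv[k],
                "ppv_excluded_subsets": self.ppv_excluded[k],
            }
            for k in sorted(self.avg_unique)
        ]
        return pd.DataFrame(rows)


def _subset_values(matrix: PresenceMatrix, k: int) -> tuple[list[tuple[int, ...]], np.ndarray, np.ndarray]:
    b = matrix.n_biopsies
    if not 1 <= k <= b:
        raise ValueError(f"k={k} out of range 1..{b}")
    subsets = list(combinations(range(b), k))
    uniques = np.empty(len(subsets))
    ptvs = np.empty(len(subsets))
    for i, cols in enumerate(subsets):
        sub = matrix.presence[:, cols]
        uniques[i] = sub.any(axis=1).sum()
        ptvs[i] = sub.all(axis=1).sum()
    return subsets, uniques, ptvs


def avg_unique(matrix: PresenceMatrix, k: int) -> tuple[float, np.ndarray]:
    """Mean union size over all C(b, k) biopsy subsets.

    Returns ``(mean, per_subset_values)`` in lexicographic subset order.
    """
    _, uniques, _ = _subset_values(matrix, k)
    return float(uniques.mean()), uniques


def avg_ptv(matrix: PresenceMatrix, k: int) -> tuple[float, np.ndarray]:
    """Mean intersection size (putative truncal variants) over subsets."""
    _, _, ptvs = _subset_values(matrix, k)
    return float(ptvs.mean()), ptvs


def avg_ppv(matrix: PresenceMatrix, k: int) -> tuple[float, np.ndarray, int]:
    """Mean of C / PTV over subsets, where C = truncal count over all b.

    Subsets with PTV = 0 contribute a 0/0 term; they are excluded from
    the mean and returned as an exclusion count. If every subset is
    excluded the mean is NaN (undefined, reported as missing).
    """
    _, _, ptvs = _subset_values(matrix, k)
    c = int(matrix.presence.all(axis=1).sum())
    valid = ptvs > 0
    terms = np.full(len(ptvs), np.nan)
    terms[valid] = c / ptvs[valid]
    excluded = int((~valid).sum())
    mean = float(terms[valid].mean()) if valid.any() else float("nan")
    return mean, terms, excluded


def saturation_profile(
    matrix: PresenceMatrix, panel: str = "WES-NSS"
) -> SaturationProfile:
    """All three statistics for every k in 1..b, plus per-subset rows."""
    b = matrix.n_biopsies
    c = int(matrix.presence.all(axis=1).sum())
    uq: dict[int, float] = {}
    pt: dict[int, float] = {}
    pv: dict[int, float] = {}
    excl: dict[int, int] = {}
    rows = []
    for k in range(1, b + 1):
        subsets, uniques, ptvs = _subset_values(matrix, k)
        uq[k] = float(uniques.mean())
        pt[k] = float(ptvs.mean())
        valid = ptvs > 0
        pv[k] = float((c / ptvs[valid]).mean()) if valid.any() else float("nan")
        excl[k] = int((~valid).sum())
        for sid, (cols, u, p) in enumerate(zip(subsets, uniques, ptvs)):
            rows.append(
                {
                    "patient_id": matrix.patient_id,
                    "panel": panel,
                    "k": k,
                    "subset_id": sid,
                    "biopsies": ",".join(matrix.biopsy_ids[j] for j in cols),
                    "unique": int(u),
                    "ptv": int(p),
                    "ppv": (c / p) if p > 0 else float("nan"),
                }
            )
    return SaturationProfile(
        patient_id=matrix.patient_id,
        panel=panel,
        b=b,
        avg_unique=uq,
        avg_ptv=pt,
        avg_ppv=pv,
        ppv_excluded=excl,
        per_subset=pd.DataFrame(rows),
    )


def increment_stats(
    profiles: Sequence[SaturationProfile],
) -> dict[str, pd.DataFrame | dict[str, float]]:
    """Per-step deltas of avg_unique / avg_ptv across patients.

    Returns per-patient step deltas, cohort mean +/- sd per step, pooled
    mean +/- sd across all steps, and the k=1->2 PTV drop separately.
    """
    rows = []
    for p in profiles:
        for k in range(1, p.b):
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "panel": p.panel,
                    "step": f"{k}->{k + 1}",
                    "k": k,
                    "delta_unique": p.avg_unique[k + 1] - p.avg_unique[k],
                    "delta_ptv": p.avg_ptv[k + 1] - p.avg_ptv[k],
                }
            )
    per_patient = pd.DataFrame(rows)
    if per_patient.empty:
        raise ValueError("no steps: need profiles with b >= 2")
    per_step = (
        per_patient.groupby("k")[["delta_unique", "delta_ptv"]]
        .agg(["mean", lambda s: s.std(ddof=1)])
        .rename(columns={"<lambda_0>": "sd"}, level=1)
    )
    pooled = {
        "unique_mean": float(per_patient["delta_unique"].mean()),
        "unique_sd": float(per_patient["delta_unique"].std(ddof=1)),
        "ptv_drop_mean": float(-per_patient["delta_ptv"].mean()),
        "ptv_drop_sd": float(per_patient["delta_ptv"].std(ddof=1)),
    }
    first = per_patient[per_patient["k"] == 1]
    first_step_ptv_drop = {
        "mean": float(-first["delta_ptv"].mean()),
        "sd": float(first["delta_ptv"].std(ddof=1)),
    }
    return {
        "per_patient": per_patient,
        "per_step": per_step,
        "pooled": pooled,
        "first_step_ptv_drop": first_step_ptv_drop,
    }


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Exact-when-possible Wilcoxon signed-rank p; all-zero diffs -> p = 1."""
    d = np.asarray(x, float) - np.asarray(y, float)
    if np.allclose(d, 0):
        return 1.0
    res = stats.wilcoxon(x, y, zero_method="wilcox", method="auto")
    return float(res.pvalue)


def min_samples_required(
    profiles: Sequence[SaturationProfile],
    alpha: float = 0.05,
    statistic: Literal["unique", "ptv"] = "ptv",
) -> tuple[int, bool]:
    """Smallest k where adding one more biopsy no longer changes the
    statistic significantly (paired Wilcoxon signed-rank across patients).

    Returns ``(k, saturated_within_b)``; when every step stays significant
    the flag is False and k = b, to be read as ">= b". A degenerate
    ``alpha >= 1`` declares nothing significant and returns 1.
    """
    if len(profiles) < 2:
        raise ValueError("min_samples_required needs >= 2 patients")
    if alpha >= 1:
        return 1, True
    key = {"unique": "avg_unique", "ptv": "avg_ptv"}[statistic]
    b = min(p.b for p in profiles)
    if b < 2:
        raise ValueError("profiles must have b >= 2")
    for k in range(1, b):
        at_k = np.array([getattr(p, key)[k] for p in profiles])
        at_k1 = np.array([getattr(p, key)[k + 1] for p in profiles])
        if _paired_wilcoxon(at_k, at_k1) >= alpha:
            return k, True
    return b, False


def friedman_load_test(loads: pd.DataFrame | np.ndarray) -> float:
    """Friedman chi-square p-value across biopsies (columns) over
    patients (rows); columns must be complete. Constant rows -> p = 1."""
    arr = np.asarray(loads, dtype=float)
    if arr.ndim != 2:
        raise ValueError("loads must be a 2-D patient x biopsy table")
    if arr.shape[0] < 3:
        raise ValueError("Friedman test needs >= 3 patients")
    if arr.shape[1] < 3:
        raise ValueError("Friedman test needs >= 3 biopsies")
    if np.all(arr == arr[:, [0]]):
        return 1.0
    stat, p = stats.friedmanchisquare(*[arr[:, j] for j in range(arr.shape[1])])
    return float(p)
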