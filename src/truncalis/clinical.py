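"""PFS ratios and benefit calls for truncal-directed therapy.

The ratio is therapy PFS over immediately-prior-therapy PFS; a ratio
>= 1.3 (inclusive) defines clinical benefit. Reported ratios are rounded
half-away-from-zero to 3 significant figures; the benefit call and all
medians use the unrounded value. Arithmetic goes through Decimal on the
inputs' decimal representations so that e.g. 6.1/4 rounds to 1.53, not
1.52 via the binary-float artifact 1.5249999….
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import pandas as pd

__all__ = [
    "ClinicalOutcome",
    "pfs_ratio",
    "cohort_summary",
    "round_sig",
    "outcomes_table",
]


def round_sig(value: float, sig: int) -> float:
    """Round half-away-from-zero to ``sig`` significant figures."""
    if value == 0:
        return 0.0
    d = Decimal(str(value))
    exp = d.adjusted()  # floor(log10(|d|))
    quantum = Decimal(1).scaleb(exp - sig + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClinicalOutcome:
    patient_id: str
    pfs_prior: float
    pfs_tdt: float
    ratio: float  # full precision
    ratio_reported: float  # 3 significant figures, half-away-from-zero
    benefit: bool
    truncal_status_of_target: Literal["truncal", "branch", "unknown"] = "unknown"


def pfs_ratio(
    pfs_tdt: float,
    pfs_prior: float,
    patient_id: str = "",
    threshold: float = 1.3,
    truncal_status: Literal["truncal", "branch", "unknown"] = "unknown",
) -> ClinicalOutcome:
    """Ratio of therapy PFS to prior-therapy PFS with a benefit flag."""
    if pfs_tdt <= 0 or pfs_prior <= 0:
        raise ValueError("PFS values must be positive")
    ratio = float(Decimal(str(pfs_tdt)) / Decimal(str(pfs_prior)))
    return ClinicalOutcome(
        patient_id=patient_id,
        pfs_prior=pfs_prior,
        pfs_tdt=pfs_tdt,
        ratio=ratio,
        ratio_reported=round_sig(ratio, 3),
        benefit=ratio >= threshold,
        truncal_status_of_target=truncal_status,
    )


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def cohort_summary(
    outcomes: Sequence[ClinicalOutcome],
    require_truncal_target: bool = False,
) -> dict[str, float]:
    """Median therapy PFS and median (unrounded) PFS ratio, reported at
    2 significant figures. Empty after filtering -> NaN, not zero."""
    selected = [
        o
        for o in outcomes
        if not require_truncal_target or o.truncal_status_of_target == "truncal"
    ]
    if not selected:
        return {
            "n": 0,
            "median_pfs_tdt": float("nan"),
            "median_ratio": float("nan"),
        }
    med_pfs = _median([o.pfs_tdt for o in selected])
    med_ratio = _median([o.ratio for o in selected])
    return {
        "n": len(selected),
        "median_pfs_tdt": round_sig(med_pfs, 2),
        "median_ratio": round_sig(med_ratio, 2),
    }


def outcomes_table(outcomes: Sequence[ClinicalOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "pfs_prior_months": o.pfs_prior,
                "pfs_tdt_months": o.pfs_tdt,
                "pfs_ratio": o.ratio_reported,
                "benefit": o.benefit,
                "truncal_status_of_target": o.truncal_status_of_target,
            }
            for o in outcomes
        ]
    )
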