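"""Synthetic multi-region biopsy cohorts with known clonal structure.

Each patient carries a truncal clone (every biopsy, CCF 1), shared
subclones (random proper subsets of >= 2 biopsies) and private subclones
(single biopsies). Per present variant and biopsy the expected allele
frequency is

    AF = purity * multiplicity * CCF / (purity * tumor_cn + 2 * (1 - purity))

and the alternative read count is binomial at a Poisson-distributed site
depth. A call is emitted iff alt_count >= 1 and it survives the
false-negative knob. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .clonality import ClonalityLabel
from .io_model import BiopsySample, PipelineConfig, VariantCall, VariantKey, qc_filter

__all__ = ["SimConfig", "SimTruth", "generate_cohort", "truth_accuracy", "expected_af"]


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 1
    n_biopsies: int = 4
    n_truncal: int = 10
    n_shared_branch: int = 5
    n_private: int = 10
    purity_range: tuple[float, float] = (0.6, 0.9)
    depth_mean: float = 100.0
    subclonal_ccf_range: tuple[float, float] = (0.1, 0.6)
    tumor_cn: float = 2.0
    multiplicity: float = 1.0
    fn_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_biopsies) < 1:
            raise ValueError("n_patients and n_biopsies must be >= 1")
        if min(self.n_truncal, self.n_shared_branch, self.n_private) < 0:
            raise ValueError("variant counts must be >= 0")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")
        lo, hi = self.subclonal_ccf_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("subclonal_ccf_range must satisfy 0 < lo <= hi <= 1")
        if not 0 <= self.fn_rate <= 1:
            raise ValueError("fn_rate must be in [0, 1]")
        if self.n_shared_branch > 0 and self.n_biopsies < 3:
            raise ValueError("shared-branch variants need >= 3 biopsies")
        if self.n_private > 0 and self.n_biopsies < 1:
            raise ValueError("private variants need >= 1 biopsy")


@dataclass
class SimTruth:
    labels: dict[str, dict[VariantKey, ClonalityLabel]]  # patient -> key -> label
    membership: dict[str, dict[VariantKey, frozenset[str]]]
    ccf: dict[str, dict[VariantKey, float]]  # one CCF per variant (uniform across carriers)
    purity: dict[str, dict[str, float]]  # patient -> biopsy -> purity
    genes: dict[str, dict[VariantKey, str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for patient, labels in sorted(self.labels.items()):
            for key, lab in labels.items():
                rows.append(
                    {
                        "patient_id": patient,
                        "chrom": key[0],
                        "pos": key[1],
                        "ref": key[2],
                        "alt": key[3],
                        "gene": self.genes.get(patient, {}).get(key, ""),
                        "true_clonality": lab.value,
                        "true_ccf": self.ccf[patient][key],
                        "biopsies": ",".join(sorted(self.membership[patient][key])),
                    }
                )
        return pd.DataFrame(rows)


def expected_af(ccf: float, purity: float, tumor_cn: float, multiplicity: float) -> float:
    return purity * multiplicity * ccf / (purity * tumor_cn + 2.0 * (1.0 - purity))


_BASES = ("A", "C", "G", "T")


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a cohort.

    Returns ``(variant_table, sample_table, truth)`` where the two
    tables are exactly the TSV dialects the loaders read (tab-separated
    when written with ``to_csv(sep="\\t")``).
    """
    rng = np.random.default_rng(config.seed)
    variant_rows: list[dict] = []
    sample_rows: list[dict] = []
    labels: dict[str, dict[VariantKey, ClonalityLabel]] = {}
    membership: dict[str, dict[VariantKey, frozenset[str]]] = {}
    ccfs: dict[str, dict[VariantKey, float]] = {}
    purities: dict[str, dict[str, float]] = {}
    genes: dict[str, dict[VariantKey, str]] = {}

    for p in range(config.n_patients):
        patient = f"SP{p + 1:02d}"
        biopsies = [f"B{j + 1}" for j in range(config.n_biopsies)]
        purity = {
            b: float(rng.uniform(*config.purity_range)) for b in biopsies
        }
        for b in biopsies:
            sample_rows.append(
                {"patient_id": patient, "biopsy_id": b, "dna_concentration": 10.0}
            )
        purities[patient] = purity
        labels[patient] = {}
        membership[patient] = {}
        ccfs[patient] = {}
        genes[patient] = {}

        n_total = config.n_truncal + config.n_shared_branch + config.n_private
        positions = rng.choice(np.arange(1, 10_000_000), size=n_total, replace=False)
        for v in range(n_total):
            pos = int(positions[v])
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            key: VariantKey = (f"chr{v % 22 + 1}", pos, str(ref), str(alt))
            gene = f"G{v:04d}"
            if v < config.n_truncal:
                label = ClonalityLabel.TRUNCAL
                carriers = frozenset(biopsies)
                ccf = 1.0
            elif v < config.n_truncal + config.n_shared_branch:
                label = ClonalityLabel.BRANCH
                size = int(rng.integers(2, config.n_biopsies))  # proper subset
                carriers = frozenset(
                    rng.choice(biopsies, size=size, replace=False).tolist()
                )
                ccf = float(rng.uniform(*config.subclonal_ccf_range))
            else:
                label = ClonalityLabel.PRIVATE
                carriers = frozenset([str(rng.choice(biopsies))])
                ccf = float(rng.uniform(*config.subclonal_ccf_range))
            labels[patient][key] = label
            membership[patient][key] = carriers
            ccfs[patient][key] = ccf
            genes[patient][key] = gene

            for b in biopsies:
                if b not in carriers:
                    continue
                af = expected_af(ccf, purity[b], config.tumor_cn, config.multiplicity)
                depth = max(1, int(rng.poisson(config.depth_mean)))
                alt_count = int(rng.binomial(depth, af))
                detected = alt_count >= 1 and (
                    config.fn_rate == 0 or rng.uniform() >= config.fn_rate
                )
                if not detected:
                    continue
                variant_rows.append(
                    {
                        "patient_id": patient,
                        "biopsy_id": b,
                        "gene": gene,
                        "chrom": key[0],
                        "pos": key[1],
                        "ref": key[2],
                        "alt": key[3],
                        "alt_count": alt_count,
                        "ref_count": depth - alt_count,
                        "variant_class": "Missense_Mutation",
                        "is_nss": True,
                    }
                )

    variant_table = pd.DataFrame(
        variant_rows,
        columns=[
            "patient_id",
            "biopsy_id",
            "gene",
            "chrom",
            "pos",
            "ref",
            "alt",
            "alt_count",
            "ref_count",
            "variant_class",
            "is_nss",
        ],
    )
    sample_table = pd.DataFrame(
        sample_rows, columns=["patient_id", "biopsy_id", "dna_concentration"]
    )
    truth = SimTruth(
        labels=labels, membership=membership, ccf=ccfs, purity=purities, genes=genes
    )
    return variant_table, sample_table, truth


def cohort_matrices(
    variant_table: pd.DataFrame,
    sample_table: pd.DataFrame,
    config: PipelineConfig | None = None,
):
    """Convenience: run the simulated tables through the standard QC path."""
    calls = [
        VariantCall(
            patient_id=r.patient_id,
            biopsy_id=r.biopsy_id,
            gene=r.gene,
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            alt_count=int(r.alt_count),
            ref_count=int(r.ref_count),
            variant_class=r.variant_class,
            is_nss=bool(r.is_nss),
        )
        for r in variant_table.itertuples(index=False)
    ]
    samples = [
        BiopsySample(
            patient_id=r.patient_id,
            biopsy_id=r.biopsy_id,
            dna_concentration=float(r.dna_concentration),
        )
        for r in sample_table.itertuples(index=False)
    ]
    return qc_filter(samples, calls, config)


def truth_accuracy(
    predicted: Mapping[VariantKey, ClonalityLabel],
    true_labels: Mapping[VariantKey, ClonalityLabel],
) -> dict[str, float | int]:
    """Truncal-vs-not confusion counts over an identical variant set."""
    if set(predicted) != set(true_labels):
        raise ValueError("predicted and true label sets cover different variants")
    tp = fp = tn = fn = 0
    for key, pred in predicted.items():
        is_pred = pred is ClonalityLabel.TRUNCAL
        is_true = true_labels[key] is ClonalityLabel.TRUNCAL
        if is_pred and is_true:
            tp += 1
        elif is_pred:
            fp += 1
        elif is_true:
            fn += 1
        else:
            tn += 1
    total = tp + fp + tn + fn
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "accuracy": (tp + tn) / total if total else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }
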