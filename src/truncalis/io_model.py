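"""Data model, readers/writers, QC filtering and configuration.

All downstream analyses operate on :class:`PresenceMatrix` objects: one
per patient, rows are variant identity keys ``(chrom, pos, ref, alt)``,
columns are QC-passed biopsies, cells record presence plus (optionally)
per-cell allele frequency and cancer cell fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariantCall",
    "BiopsySample",
    "PresenceMatrix",
    "PanelDefinition",
    "PipelineConfig",
    "QCResult",
    "VariantTableError",
    "load_variant_table",
    "load_samples",
    "load_panel",
    "load_clinical",
    "qc_filter",
    "write_presence_matrix",
    "read_presence_matrix",
]

VariantKey = tuple[str, int, str, str]

#: variant_class values treated as non-synonymous somatic when no explicit
#: is_nss column is supplied.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "MISSENSE",
        "MISSENSE_MUTATION",
        "NONSENSE",
        "NONSENSE_MUTATION",
        "NONSTOP_MUTATION",
        "FRAME_SHIFT_DEL",
        "FRAME_SHIFT_INS",
        "IN_FRAME_DEL",
        "IN_FRAME_INS",
        "SPLICE_SITE",
        "TRANSLATION_START_SITE",
        "START_CODON_SNP",
    }
)

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


class VariantTableError(ValueError):
    """Raised for structurally invalid variant/clinical input tables."""


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant observation in one biopsy."""

    patient_id: str
    biopsy_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    ref_count: int
    variant_class: str = ""
    is_nss: bool = True
    annotations: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def key(self) -> VariantKey:
        """Identity key: gene annotations may disagree between callers,
        so identity is positional only."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count

    @property
    def af(self) -> float:
        if self.depth == 0:
            raise ValueError("zero depth: AF undefined")
        return self.alt_count / self.depth


@dataclass(frozen=True)
class BiopsySample:
    patient_id: str
    biopsy_id: str
    dna_concentration: float | None = None
    germline_source: str | None = None  # metadata only (buccal/blood)

    def qc_pass(self, min_concentration: float = 4.0) -> bool:
        if self.dna_concentration is None:
            return True
        return self.dna_concentration >= min_concentration


@dataclass(frozen=True)
class PanelDefinition:
    """Named gene set; symbols unique and uppercase-normalized."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "PanelDefinition":
        return cls(name=name, genes=frozenset(s.strip().upper() for s in symbols if s.strip()))

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


@dataclass(frozen=True)
class PipelineConfig:
    qc_min_concentration: float = 4.0
    min_alt_reads: int = 0  # 0 = trust the caller's emission
    af_grid_start: float = 0.01
    af_grid_stop: float = 0.55
    af_grid_step: float = 0.01
    ccf_grid_start: float = 0.90
    ccf_grid_stop: float = 1.00
    ccf_grid_step: float = 0.01
    benefit_ratio_threshold: float = 1.3
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        for start, stop, step, label in (
            (self.af_grid_start, self.af_grid_stop, self.af_grid_step, "AF"),
            (self.ccf_grid_start, self.ccf_grid_stop, self.ccf_grid_step, "CCF"),
        ):
            if step <= 0:
                raise ValueError(f"{label} grid step must be > 0")
            if stop < start:
                raise ValueError(f"{label} grid is empty (stop < start)")

    @property
    def af_grid(self) -> np.ndarray:
        return _make_grid(self.af_grid_start, self.af_grid_stop, self.af_grid_step)

    @property
    def ccf_grid(self) -> np.ndarray:
        return _make_grid(self.ccf_grid_start, self.ccf_grid_stop, self.ccf_grid_step)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _make_grid(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


class PresenceMatrix:
    """Per-patient binary variant-by-biopsy matrix.

    Parameters
    ----------
    patient_id : str
    biopsy_ids : ordered biopsy labels (QC-passed only)
    variant_keys : ordered ``(chrom, pos, ref, alt)`` identity keys
    presence : bool array, shape (n_variants, n_biopsies)
    af, ccf : float arrays of the same shape; NaN where absent/undefined
    genes : per-variant gene symbol (uppercased), parallel to variant_keys
    """

    def __init__(
        self,
        patient_id: str,
        biopsy_ids: Sequence[str],
        variant_keys: Sequence[VariantKey],
        presence: np.ndarray,
        af: np.ndarray | None = None,
        ccf: np.ndarray | None = None,
        genes: Sequence[str] | None = None,
    ) -> None:
        presence = np.asarray(presence, dtype=bool)
        if presence.shape != (len(variant_keys), len(biopsy_ids)):
            raise ValueError("presence shape does not match labels")
        if len(set(biopsy_ids)) != len(biopsy_ids):
            raise ValueError("duplicate biopsy ids")
        if len(set(variant_keys)) != len(variant_keys):
            raise ValueError("duplicate variant keys")
        if presence.shape[0] and not presence.any(axis=1).all():
            raise ValueError("all-absent variant row")
        self.patient_id = patient_id
        self.biopsy_ids = list(biopsy_ids)
        self.variant_keys = [tuple(k) for k in variant_keys]
        self.presence = presence
        self.af = np.full(presence.shape, np.nan) if af is None else np.asarray(af, float)
        self.ccf = np.full(presence.shape, np.nan) if ccf is None else np.asarray(ccf, float)
        self.genes = list(genes) if genes is not None else [""] * len(variant_keys)
        if self.af.shape != presence.shape or self.ccf.shape != presence.shape:
            raise ValueError("af/ccf shape does not match presence")
        if len(self.genes) != len(self.variant_keys):
            raise ValueError("genes length does not match variant_keys")

    @property
    def n_biopsies(self) -> int:
        return len(self.biopsy_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def column_counts(self) -> np.ndarray:
        """Per-biopsy variant counts (column sums)."""
        return self.presence.sum(axis=0)

    def row_counts(self) -> np.ndarray:
        """Per-variant number of biopsies carrying the variant."""
        return self.presence.sum(axis=1)

    def select_variants(self, mask: np.ndarray) -> "PresenceMatrix":
        mask = np.asarray(mask, dtype=bool)
        return PresenceMatrix(
            self.patient_id,
            self.biopsy_ids,
            [k for k, m in zip(self.variant_keys, mask) if m],
            self.presence[mask],
            self.af[mask],
            self.ccf[mask],
            [g for g, m in zip(self.genes, mask) if m],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.biopsy_ids == other.biopsy_ids
            and self.variant_keys == other.variant_keys
            and self.genes == other.genes
            and np.array_equal(self.presence, other.presence)
            and np.array_equal(self.af, other.af, equal_nan=True)
            and np.array_equal(self.ccf, other.ccf, equal_nan=True)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PresenceMatrix({self.patient_id!r}, {self.n_variants} variants x "
            f"{self.n_biopsies} biopsies)"
        )


@dataclass
class QCResult:
    """Output of :func:`qc_filter`."""

    matrices: dict[str, PresenceMatrix]
    excluded_patients: dict[str, str]  # patient -> reason
    dropped_biopsies: dict[str, list[str]]  # patient -> failing biopsy ids


MANDATORY_VARIANT_COLUMNS = (
    "patient_id",
    "biopsy_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "alt_count",
    "ref_count",
)


def _parse_bool(raw: str) -> bool:
    low = str(raw).strip().lower()
    if low in _TRUTHY:
        return True
    if low in _FALSY:
        return False
    raise ValueError(f"cannot parse boolean {raw!r}")


def load_variant_table(
    path: str | Path, config: PipelineConfig | None = None
) -> tuple[list[VariantCall], list[str]]:
    """Parse a MAF-like TSV into :class:`VariantCall` records.

    Returns ``(calls, row_errors)``; malformed rows are collected with
    1-based line numbers rather than aborting the whole load. A missing
    mandatory column is a hard :class:`VariantTableError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_VARIANT_COLUMNS:
        if col not in df.columns:
            raise VariantTableError(f"missing column: {col}")
    has_class = "variant_class" in df.columns
    has_nss = "is_nss" in df.columns
    extra_cols = [
        c
        for c in df.columns
        if c not in MANDATORY_VARIANT_COLUMNS and c not in ("variant_class", "is_nss")
    ]
    calls: list[VariantCall] = []
    errors: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        rec = dict(zip(df.columns, row))
        try:
            vclass = rec.get("variant_class", "") if has_class else ""
            if has_nss:
                is_nss = _parse_bool(rec["is_nss"])
            elif has_class:
                is_nss = vclass.strip().upper() in NONSYNONYMOUS_CLASSES
            else:
                is_nss = True
            calls.append(
                VariantCall(
                    patient_id=rec["patient_id"].strip(),
                    biopsy_id=rec["biopsy_id"].strip(),
                    gene=rec["gene"].strip().upper(),
                    chrom=rec["chrom"].strip(),
                    pos=int(rec["pos"]),
                    ref=rec["ref"].strip(),
                    alt=rec["alt"].strip(),
                    alt_count=int(rec["alt_count"]),
                    ref_count=int(rec["ref_count"]),
                    variant_class=vclass.strip(),
                    is_nss=is_nss,
                    annotations={c: rec[c] for c in extra_cols},
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {idx}: {exc}")
    return calls, errors


def load_samples(path: str | Path) -> list[BiopsySample]:
    """Read a biopsy-sample TSV (patient_id, biopsy_id[, dna_concentration])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("patient_id", "biopsy_id"):
        if col not in df.columns:
            raise VariantTableError(f"missing column: {col}")
    samples = []
    for _, row in df.iterrows():
        conc_raw = row.get("dna_concentration", "")
        conc = float(conc_raw) if str(conc_raw).strip() not in ("", "NA") else None
        samples.append(
            BiopsySample(
                patient_id=row["patient_id"].strip(),
                biopsy_id=row["biopsy_id"].strip(),
                dna_concentration=conc,
                germline_source=(row.get("germline_source") or None),
            )
        )
    return samples


def load_panel(path: str | Path, name: str | None = None) -> PanelDefinition:
    """One gene symbol per line; duplicates deduplicated with a warning."""
    path = Path(path)
    symbols = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not symbols:
        raise VariantTableError(f"empty panel file: {path}")
    upper = [s.upper() for s in symbols]
    if len(set(upper)) != len(upper):
        dupes = sorted({s for s in upper if upper.count(s) > 1})
        warnings.warn(f"panel {path.name}: duplicate symbols deduplicated: {dupes}")
    return PanelDefinition.from_symbols(name or path.stem, upper)


def load_clinical(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read clinical outcomes TSV: patient_id, pfs_prior_months, pfs_tdt_months.

    Returns ``(records, row_errors)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("patient_id", "pfs_prior_months", "pfs_tdt_months"):
        if col not in df.columns:
            raise VariantTableError(f"missing column: {col}")
    if df.empty:
        raise VariantTableError(f"empty clinical file: {path}")
    rows, errors = [], []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            rows.append(
                {
                    "patient_id": rec["patient_id"].strip(),
                    "pfs_prior_months": float(rec["pfs_prior_months"]),
                    "pfs_tdt_months": float(rec["pfs_tdt_months"]),
                }
            )
        except ValueError as exc:
            errors.append(f"line {idx}: {exc}")
    return pd.DataFrame(rows), errors


def qc_filter(
    samples: Sequence[BiopsySample],
    calls: Sequence[VariantCall],
    config: PipelineConfig | None = None,
) -> QCResult:
    """Drop failing biopsies, exclude patients with <2 passing biopsies,
    and build one presence matrix per retained patient.

    A cell is present iff a call with ``is_nss`` true and
    ``alt_count >= config.min_alt_reads`` exists for that variant/biopsy.
    """
    config = config or PipelineConfig()
    by_patient_samples: dict[str, list[BiopsySample]] = {}
    for s in samples:
        by_patient_samples.setdefault(s.patient_id, []).append(s)
    known = {(s.patient_id, s.biopsy_id) for s in samples}
    for c in calls:
        if (c.patient_id, c.biopsy_id) not in known:
            raise VariantTableError(
                f"call references unknown biopsy {c.patient_id}/{c.biopsy_id}"
            )

    matrices: dict[str, PresenceMatrix] = {}
    excluded: dict[str, str] = {}
    dropped: dict[str, list[str]] = {}
    calls_by_patient: dict[str, list[VariantCall]] = {}
    for c in calls:
        calls_by_patient.setdefault(c.patient_id, []).append(c)

    for patient_id, psamples in sorted(by_patient_samples.items()):
        passing = [s for s in psamples if s.qc_pass(config.qc_min_concentration)]
        failing = [s.biopsy_id for s in psamples if not s.qc_pass(config.qc_min_concentration)]
        if failing:
            dropped[patient_id] = failing
        if len(passing) < 2:
            excluded[patient_id] = (
                f"{len(passing)} QC-passed biopsies (<2 required for clonality analysis)"
            )
            continue
        biopsy_ids = [s.biopsy_id for s in passing]
        col = {b: j for j, b in enumerate(biopsy_ids)}
        usable = [
            c
            for c in calls_by_patient.get(patient_id, [])
            if c.biopsy_id in col and c.is_nss and c.alt_count >= config.min_alt_reads
        ]
        keys: list[VariantKey] = []
        row = {}
        genes: list[str] = []
        for c in usable:
            if c.key not in row:
                row[c.key] = len(keys)
                keys.append(c.key)
                genes.append(c.gene)
        presence = np.zeros((len(keys), len(biopsy_ids)), dtype=bool)
        af = np.full(presence.shape, np.nan)
        for c in usable:
            i, j = row[c.key], col[c.biopsy_id]
            presence[i, j] = True
            if c.depth > 0:
                af[i, j] = c.af
        matrices[patient_id] = PresenceMatrix(
            patient_id, biopsy_ids, keys, presence, af=af, genes=genes
        )
    return QCResult(matrices=matrices, excluded_patients=excluded, dropped_biopsies=dropped)


# ---------------------------------------------------------------------------
# Presence-matrix TSV round-trip


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    """Long-format TSV: one row per present cell, with AF/CCF columns."""
    rows = []
    for i, key in enumerate(matrix.variant_keys):
        for j, biopsy in enumerate(matrix.biopsy_ids):
            if matrix.presence[i, j]:
                rows.append(
                    {
                        "patient_id": matrix.patient_id,
                        "biopsy_id": biopsy,
                        "gene": matrix.genes[i],
                        "chrom": key[0],
                        "pos": key[1],
                        "ref": key[2],
                        "alt": key[3],
                        "af": repr(float(matrix.af[i, j])),
                        "ccf": repr(float(matrix.ccf[i, j])),
                    }
                )
    header = "# biopsy_ids=" + ",".join(matrix.biopsy_ids) + "\n"
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "biopsy_id",
            "gene",
            "chrom",
            "pos",
            "ref",
            "alt",
            "af",
            "ccf",
        ],
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# biopsy_ids="):
            raise VariantTableError("not a presence-matrix TSV (missing header comment)")
        biopsy_ids = first.strip().split("=", 1)[1].split(",")
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    patient_id = df["patient_id"].iloc[0] if len(df) else ""
    keys: list[VariantKey] = []
    genes: list[str] = []
    row: dict[VariantKey, int] = {}
    for _, r in df.iterrows():
        key = (r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        if key not in row:
            row[key] = len(keys)
            keys.append(key)
            genes.append(r["gene"])
    col = {b: j for j, b in enumerate(biopsy_ids)}
    presence = np.zeros((len(keys), len(biopsy_ids)), dtype=bool)
    af = np.full(presence.shape, np.nan)
    ccf = np.full(presence.shape, np.nan)
    for _, r in df.iterrows():
        key = (r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        i, j = row[key], col[r["biopsy_id"]]
        presence[i, j] = True
        af[i, j] = float(r["af"])
        ccf[i, j] = float(r["ccf"])
    return PresenceMatrix(patient_id, biopsy_ids, keys, presence, af=af, ccf=ccf, genes=genes)
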