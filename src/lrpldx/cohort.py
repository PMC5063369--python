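"""Node-level cohort model: domain types, validation and CSV I/O.

A cohort is a flat table of lymph nodes, one row per node, each carrying
the three MRI diameters (MIAD, MAAD, MACD, in mm), an optional PET SUVmean
channel, and the binary reference-standard label (positive/negative by
follow-up MRI).  Analyses are node-level; the patient identifier is kept
for provenance and for optional cluster resampling, nothing else.

Two "stages" of analysis are distinguished: a three-parameter stage using
only the diameters, and a four-parameter stage that additionally requires
an SUVmean for every node.  Nodes read as "qualitatively negative" on PET
carry no measured SUV; their SUVmean is imputed to exactly 0 for analysis
and the imputation is flagged so it can be audited.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._grid import DIAMETER_RES, SUV_RES, snap

__all__ = [
    "Stage",
    "NodeRecord",
    "Cohort",
    "CohortSummary",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "PARAMETERS",
    "CSV_COLUMNS",
]

#: canonical parameter order used everywhere (tables, grids, rule vectors)
PARAMETERS = ("miad", "maad", "macd", "nsuv")

CSV_COLUMNS = (
    "node_id",
    "patient_id",
    "miad_mm",
    "maad_mm",
    "macd_mm",
    "nsuv_mean",
    "nsuv_qual_neg",
    "label",
    "cohort_tag",
)

_TRUTHY = {"1", "true", "yes", "positive", "pos"}
_FALSY = {"0", "false", "no", "negative", "neg", ""}


class Stage(enum.Enum):
    """Analysis stage: diameters only, or diameters plus SUVmean."""

    STAGE_I = 1
    STAGE_II = 2

    @property
    def parameters(self) -> tuple[str, ...]:
        return PARAMETERS[:3] if self is Stage.STAGE_I else PARAMETERS


@dataclass(frozen=True)
class NodeRecord:
    """One lymph node's measurements plus reference label and provenance.

    ``nsuv`` is ``None`` when no SUV was measured and the node was not
    qualitatively negative (allowed in stage I only).  When
    ``nsuv_qualitative_negative`` is true the SUVmean is 0 by imputation.
    """

    node_id: str
    patient_id: str
    miad: float
    maad: float
    macd: float
    nsuv: float | None = None
    nsuv_qualitative_negative: bool = False
    label: bool = False
    cohort_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "miad", snap(self.miad, DIAMETER_RES))
        object.__setattr__(self, "maad", snap(self.maad, DIAMETER_RES))
        object.__setattr__(self, "macd", snap(self.macd, DIAMETER_RES))
        if self.nsuv is not None:
            object.__setattr__(self, "nsuv", snap(self.nsuv, SUV_RES))


class CohortValidationError(ValueError):
    """Raised when one or more rows violate the cohort invariants.

    ``errors`` is a list of ``(row_number, message)`` pairs; row numbers
    are 1-based over data rows (the header is row 0).
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors[:20])
        more = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


def _validate_record(rec: NodeRecord, stage: Stage) -> list[str]:
    problems = []
    for name in ("miad", "maad", "macd"):
        v = getattr(rec, name)
        if not np.isfinite(v) or v <= 0:
            problems.append(f"{name} must be a positive length, got {v!r}")
    if np.isfinite(rec.miad) and np.isfinite(rec.maad) and rec.miad > rec.maad:
        problems.append(
            f"miad ({rec.miad}) exceeds maad ({rec.maad}); the minimal axial "
            "diameter is measured perpendicular to the maximal one"
        )
    if rec.nsuv is not None and (not np.isfinite(rec.nsuv) or rec.nsuv < 0):
        problems.append(f"nsuv must be >= 0, got {rec.nsuv!r}")
    if rec.nsuv_qualitative_negative and rec.nsuv not in (None, 0.0):
        problems.append(
            "qualitatively negative node carries a nonzero measured SUV"
        )
    if stage is Stage.STAGE_II and rec.nsuv is None and not rec.nsuv_qualitative_negative:
        problems.append(
            "stage II requires an SUVmean (measured, or qualitative-negative flag)"
        )
    return problems


def _impute(rec: NodeRecord) -> NodeRecord:
    if rec.nsuv_qualitative_negative and rec.nsuv is None:
        return replace(rec, nsuv=0.0)
    return rec


@dataclass(frozen=True)
class Cohort:
    """A validated, ordered collection of node records."""

    records: tuple[NodeRecord, ...]
    stage: Stage = Stage.STAGE_I

    def __post_init__(self) -> None:
        errors: list[tuple[int, str]] = []
        imputed = []
        for i, rec in enumerate(self.records, start=1):
            for msg in _validate_record(rec, self.stage):
                errors.append((i, msg))
            imputed.append(_impute(rec))
        if errors:
            raise CohortValidationError(errors)
        object.__setattr__(self, "records", tuple(imputed))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=bool)

    def values(self, parameter: str) -> np.ndarray:
        """Measurement vector for one parameter; NaN where absent."""
        if parameter not in PARAMETERS:
            raise KeyError(f"unknown parameter {parameter!r}")
        out = [getattr(r, parameter) for r in self.records]
        return np.array([np.nan if v is None else v for v in out], dtype=float)

    @property
    def prevalence(self) -> Fraction:
        if not self.records:
            raise ValueError("prevalence of an empty cohort is undefined")
        return Fraction(int(self.labels.sum()), len(self.records))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "node_id": r.node_id,
                    "patient_id": r.patient_id,
                    "miad_mm": r.miad,
                    "maad_mm": r.maad,
                    "macd_mm": r.macd,
                    "nsuv_mean": np.nan if r.nsuv is None else r.nsuv,
                    "nsuv_qual_neg": int(r.nsuv_qualitative_negative),
                    "label": "positive" if r.label else "negative",
                    "cohort_tag": r.cohort_tag,
                }
            )
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    def subset(self, indices: Iterable[int]) -> "Cohort":
        idx = list(indices)
        return Cohort(tuple(self.records[i] for i in idx), stage=self.stage)


def _parse_bool(raw: str, what: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot parse {what} value {raw!r}")


def read_cohort(path: str | Path, stage: Stage = Stage.STAGE_I) -> Cohort:
    """Read and validate a cohort CSV.

    The file must carry a header row with the canonical column names
    (``nsuv_mean``/``nsuv_qual_neg``/``cohort_tag`` may be omitted for a
    stage I file).  Rows violating the invariants are reported together,
    with 1-based data row numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in CSV_COLUMNS[:5] if c not in df.columns] + (
        [] if "label" in df.columns else ["label"]
    )
    if required:
        raise CohortValidationError([(0, f"missing required column(s): {', '.join(required)}")])

    errors: list[tuple[int, str]] = []
    records: list[NodeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            nsuv_raw = str(row_d.get("nsuv_mean", "")).strip()
            rec = NodeRecord(
                node_id=str(row_d["node_id"]),
                patient_id=str(row_d["patient_id"]),
                miad=float(row_d["miad_mm"]),
                maad=float(row_d["maad_mm"]),
                macd=float(row_d["macd_mm"]),
                nsuv=float(nsuv_raw) if nsuv_raw else None,
                nsuv_qualitative_negative=_parse_bool(
                    row_d.get("nsuv_qual_neg", "0"), "nsuv_qual_neg"
                ),
                label=_parse_bool(row_d["label"], "label"),
                cohort_tag=str(row_d.get("cohort_tag", "")),
            )
        except (TypeError, ValueError) as exc:
            errors.append((i, str(exc)))
            continue
        problems = _validate_record(rec, stage)
        if problems:
            errors.extend((i, p) for p in problems)
        else:
            records.append(rec)
    if errors:
        raise CohortValidationError(errors)
    return Cohort(tuple(records), stage=stage)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the analysis-ready cohort (imputation already applied)."""
    cohort.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CohortSummary:
    total: int
    positives: int
    negatives: int
    prevalence: Fraction
    parameter_range: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "total": self.total,
            "positives": self.positives,
            "negatives": self.negatives,
            "prevalence": float(self.prevalence),
        }
        for p, (lo, hi) in self.parameter_range.items():
            d[f"{p}_min"], d[f"{p}_max"] = lo, hi
        return d


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Totals, class counts, prevalence and per-parameter ranges."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    labels = cohort.labels
    pos = int(labels.sum())
    ranges = {}
    for p in cohort.stage.parameters:
        v = cohort.values(p)
        v = v[np.isfinite(v)]
        if v.size:
            ranges[p] = (float(v.min()), float(v.max()))
    return CohortSummary(
        total=len(cohort),
        positives=pos,
        negatives=len(cohort) - pos,
        prevalence=Fraction(pos, len(cohort)),
        parameter_range=ranges,
    )
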