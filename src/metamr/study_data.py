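"""Domain types and I/O for study-level genotype-count tables.

A "study" is one published case-control comparison of a biallelic SNP
(here the MTHFR C677T variant, alleles C and T) against disease status.
Each study contributes six genotype counts -- CC/CT/TT in cases and in
controls -- plus stratum labels (ethnicity, source of controls) used for
subgroup analysis.

The on-disk format is a flat delimited table with one row per study and
the columns listed in :data:`REQUIRED_COLUMNS`; there is no community
standard for genotype-count meta-analysis tables, so the package defines
this minimal one.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger("metamr.study_data")

#: Canonical ethnicity strata (subgroup vocabulary).
ETHNICITIES = ("Asian", "Caucasian", "Mixed")
#: Canonical source-of-controls strata.
CONTROL_SOURCES = ("population", "hospital")

REQUIRED_COLUMNS = (
    "study_id",
    "year",
    "ethnicity",
    "control_source",
    "case_cc",
    "case_ct",
    "case_tt",
    "ctrl_cc",
    "ctrl_ct",
    "ctrl_tt",
)

_COUNT_COLUMNS = REQUIRED_COLUMNS[4:]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm (cases or controls) of one study.

    ``n_cc``/``n_ct``/``n_tt`` are the numbers of CC, CT and TT
    individuals.  Allele counts follow by gene counting: each CC
    individual carries two C alleles, each heterozygote one of each.
    """

    n_cc: int
    n_ct: int
    n_tt: int

    def __post_init__(self) -> None:
        for name in ("n_cc", "n_ct", "n_tt"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"genotype count {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"genotype count {name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.n_cc + self.n_ct + self.n_tt

    @property
    def n_c_alleles(self) -> int:
        return 2 * self.n_cc + self.n_ct

    @property
    def n_t_alleles(self) -> int:
        return 2 * self.n_tt + self.n_ct


@dataclass
class StudyRecord:
    """One case-control study: counts plus the strata used for subgroups."""

    study_id: str
    year: int
    ethnicity: str
    control_source: str
    cases: GenotypeCounts
    controls: GenotypeCounts
    #: Hardy-Weinberg chi-square p-value in controls; None until computed.
    hwe_p: float | None = None

    def __post_init__(self) -> None:
        if self.cases.total < 1 or self.controls.total < 1:
            raise ValidationError(
                f"study {self.study_id!r}: both arms need at least one genotyped individual"
            )
        if self.ethnicity not in ETHNICITIES:
            raise ValidationError(
                f"study {self.study_id!r}: unknown ethnicity {self.ethnicity!r}"
            )
        if self.control_source not in CONTROL_SOURCES:
            raise ValidationError(
                f"study {self.study_id!r}: unknown control_source {self.control_source!r}"
            )


@dataclass(frozen=True)
class EffectEstimate:
    """A per-study (or pooled) log odds ratio with its standard error."""

    study_id: str
    model: str
    log_or: float
    se: float
    #: True when a 0.5 continuity correction was applied to the 2x2 table.
    corrected: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise ValidationError(f"{self.study_id}: log odds ratio must be finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValidationError(f"{self.study_id}: standard error must be positive")


@dataclass(frozen=True)
class GeneExposureEffect:
    """Per-allele effect of the variant on the exposure.

    ``beta`` is in SD units of natural-log plasma total homocysteine per
    T allele; ``se_beta`` its standard error (0 treats the effect as a
    known constant, as when it is taken from a large external GWAS).
    """

    beta: float
    se_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.se_beta < 0:
            raise ValidationError("se_beta must be non-negative")


def _normalize_ethnicity(value: str, study_id: str) -> str:
    v = str(value).strip().lower()
    for canon in ETHNICITIES:
        if v == canon.lower() or v == canon.lower() + "s":
            return canon
    logger.warning("study %s: unrecognized ethnicity %r mapped to 'Mixed'", study_id, value)
    return "Mixed"


def _normalize_control_source(value: str, study_id: str) -> str:
    v = str(value).strip().lower()
    for canon in CONTROL_SOURCES:
        if v.startswith(canon[:3]):
            return canon
    logger.warning(
        "study %s: unrecognized control_source %r mapped to 'hospital'", study_id, value
    )
    return "hospital"


def read_studies(path: str | Path, delimiter: str | None = None) -> list[StudyRecord]:
    """Read a study-level genotype table (TSV/CSV) into records.

    ``delimiter`` is sniffed from the file when not given.  Raises
    :class:`SchemaError` for missing columns and :class:`ValidationError`
    for bad counts or duplicate study ids, naming the offending study.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file {path} does not exist")
    df = pd.read_csv(path, sep=delimiter, engine="python", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[StudyRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        study_id = str(row["study_id"])
        if study_id in seen:
            raise ValidationError(f"duplicate study_id {study_id!r}")
        seen.add(study_id)
        counts = {}
        for col in _COUNT_COLUMNS:
            raw = row[col]
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"study {study_id!r}: count {col} is not numeric ({raw!r})"
                ) from None
            if not float(val).is_integer():
                raise ValidationError(
                    f"study {study_id!r}: count {col} must be an integer, got {raw!r}"
                )
            if val < 0:
                raise ValidationError(
                    f"study {study_id!r}: count {col} must be non-negative, got {raw!r}"
                )
            counts[col] = int(val)
        records.append(
            StudyRecord(
                study_id=study_id,
                year=int(row["year"]),
                ethnicity=_normalize_ethnicity(row["ethnicity"], study_id),
                control_source=_normalize_control_source(row["control_source"], study_id),
                cases=GenotypeCounts(counts["case_cc"], counts["case_ct"], counts["case_tt"]),
                controls=GenotypeCounts(counts["ctrl_cc"], counts["ctrl_ct"], counts["ctrl_tt"]),
            )
        )
    logger.info("read %d studies from %s", len(records), path)
    return records


def studies_to_frame(studies: Sequence[StudyRecord]) -> pd.DataFrame:
    rows = []
    for s in studies:
        rows.append(
            {
                "study_id": s.study_id,
                "year": s.year,
                "ethnicity": s.ethnicity,
                "control_source": s.control_source,
                "case_cc": s.cases.n_cc,
                "case_ct": s.cases.n_ct,
                "case_tt": s.cases.n_tt,
                "ctrl_cc": s.controls.n_cc,
                "ctrl_ct": s.controls.n_ct,
                "ctrl_tt": s.controls.n_tt,
            }
        )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_studies(
    studies: Sequence[StudyRecord], path: str | Path, header_comment: str | None = None
) -> None:
    """Write records as the tab-separated study table read by :func:`read_studies`."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        studies_to_frame(studies).to_csv(fh, sep="\t", index=False)
    logger.info("wrote %d studies to %s", len(studies), path)


def write_report(results: Mapping | object, path: str | Path) -> None:
    """Serialize a full analysis bundle to a JSON document.

    ``results`` is either a plain mapping or an object exposing
    ``to_dict()`` (e.g. the pipeline's report bundle).  Floats keep full
    double precision, so round-tripping preserves at least 6 significant
    digits.
    """
    if hasattr(results, "to_dict"):
        results = results.to_dict()  # type: ignore[union-attr]
    if not isinstance(results, Mapping):
        raise ValidationError("results bundle must be a mapping or expose to_dict()")
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, allow_nan=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    logger.info("wrote analysis report to %s", path)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
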