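"""Study-level data model and delimited-text I/O for case-control genotype counts.

A *study table* holds one row per published case-control study of a biallelic
variant (here written with alleles C and T): genotype counts (CC, CT, TT) for
cases and controls, the reported sample sizes, and a geographical region tag
used for subgroup analysis.  Reported sample sizes and genotype sums are stored
independently — several published tables contain rows whose genotype counts do
not sum to the reported n, and the genotype counts are what every statistic in
this package is computed from.  Discrepancies are surfaced by
:func:`validate_studies`, never silently corrected.

The packaged fixture :func:`load_rs966221_table` is the 14-study case-control
table for the PDE4D rs966221 variant and ischemic stroke in regional Chinese
populations, transcribed row-by-row from the published study table.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from .errors import ParseError, SchemaError

#: Canonical region vocabulary (free text is accepted; these are the tags the
#: packaged fixture uses).  "Multi" marks a study spanning several regions,
#: which subgroup analysis excludes.
CANONICAL_REGIONS = (
    "Northeast",
    "North",
    "East",
    "South",
    "Central",
    "Southwest",
    "Northwest",
    "Multi",
)

REQUIRED_COLUMNS = (
    "study_id",
    "region",
    "n_cases",
    "n_controls",
    "case_CC",
    "case_CT",
    "case_TT",
    "control_CC",
    "control_CT",
    "control_TT",
)

OPTIONAL_COLUMNS = ("hwe_p_reported",)

FIXTURE_NAME = "rs966221_is_studies.csv"


@dataclass(frozen=True)
class StudyRecord:
    """One study's genotype counts plus metadata.

    ``case_genotypes`` and ``control_genotypes`` are (CC, CT, TT) count
    triples.  ``n_cases``/``n_controls`` are the sample sizes as reported,
    which MAY disagree with the genotype sums; both are kept.
    """

    study_id: str
    region: str
    n_cases: int
    n_controls: int
    case_genotypes: tuple[int, int, int]
    control_genotypes: tuple[int, int, int]
    hwe_p_reported: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError(
                f"{self.study_id!r}: sample sizes must be positive "
                f"(got n_cases={self.n_cases}, n_controls={self.n_controls})"
            )
        for arm, counts in (("case", self.case_genotypes), ("control", self.control_genotypes)):
            if len(counts) != 3:
                raise ValueError(f"{self.study_id!r}: {arm} genotypes must be a (CC, CT, TT) triple")
            if any(c < 0 for c in counts):
                raise ValueError(f"{self.study_id!r}: negative {arm} genotype count {counts}")
            if sum(counts) == 0:
                raise ValueError(f"{self.study_id!r}: all {arm} genotype counts are zero")
        if self.hwe_p_reported is not None and not 0.0 <= self.hwe_p_reported <= 1.0:
            raise ValueError(f"{self.study_id!r}: hwe_p_reported outside [0, 1]")

    @property
    def case_genotype_total(self) -> int:
        return sum(self.case_genotypes)

    @property
    def control_genotype_total(self) -> int:
        return sum(self.control_genotypes)


@dataclass(frozen=True)
class ValidationReport:
    """Per-study consistency report: genotype-sum mismatches and a control-HWE flag."""

    study_id: str
    case_sum_mismatch: int
    control_sum_mismatch: int
    hwe_flag: bool
    messages: tuple[str, ...] = ()


@dataclass
class StudyTable:
    """An ordered collection of :class:`StudyRecord` with unique study ids."""

    records: list[StudyRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.study_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate study_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, key: Union[int, str]) -> StudyRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.study_id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    @property
    def study_ids(self) -> list[str]:
        return [r.study_id for r in self.records]

    @property
    def regions(self) -> list[str]:
        """Distinct region tags in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.region, None)
        return list(seen)


def _parse_int(value: str, column: str, row_number: int) -> int:
    text = value.strip()
    try:
        return int(text)
    except ValueError:
        raise ParseError(
            f"row {row_number}: column {column!r} must be an integer count, got {text!r}"
        ) from None


def _sniff_delimiter(sample: str, dialect: Optional[str]) -> str:
    if dialect in ("csv", ","):
        return ","
    if dialect in ("tsv", "\t"):
        return "\t"
    # auto: a tab in the header wins, else comma
    header = sample.splitlines()[0] if sample else ""
    return "\t" if "\t" in header else ","


def load_study_table(
    path: Union[str, Path], dialect: Optional[str] = None, provenance: Optional[str] = None
) -> StudyTable:
    """Read a study table from delimited text (CSV by default, TSV accepted).

    The header must contain every required column (extra columns are ignored);
    counts are parsed as exact integers and a non-integer cell raises
    :class:`ParseError` naming the offending row.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return _parse_study_table(
        text, dialect=dialect, provenance=provenance if provenance is not None else str(path)
    )


def _parse_study_table(text: str, dialect: Optional[str], provenance: str) -> StudyTable:
    delimiter = _sniff_delimiter(text, dialect)
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    if reader.fieldnames is None:
        raise SchemaError("file is empty: a header row is required")
    header = [h.strip() for h in reader.fieldnames]
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    records: list[StudyRecord] = []
    for row_number, row in enumerate(reader, start=2):  # header is row 1
        if all((v is None or not v.strip()) for v in row.values() if v is not None):
            continue  # blank line
        get = lambda col: (row.get(col) or "")
        hwe_raw = get("hwe_p_reported").strip()
        try:
            hwe_p = float(hwe_raw) if hwe_raw else None
        except ValueError:
            raise ParseError(
                f"row {row_number}: column 'hwe_p_reported' must be a probability, got {hwe_raw!r}"
            ) from None
        records.append(
            StudyRecord(
                study_id=get("study_id").strip(),
                region=get("region").strip(),
                n_cases=_parse_int(get("n_cases"), "n_cases", row_number),
                n_controls=_parse_int(get("n_controls"), "n_controls", row_number),
                case_genotypes=tuple(
                    _parse_int(get(c), c, row_number) for c in ("case_CC", "case_CT", "case_TT")
                ),
                control_genotypes=tuple(
                    _parse_int(get(c), c, row_number)
                    for c in ("control_CC", "control_CT", "control_TT")
                ),
                hwe_p_reported=hwe_p,
            )
        )
    return StudyTable(records=records, provenance=provenance)


def write_study_table(
    table: StudyTable, path: Union[str, Path], dialect: Optional[str] = None
) -> None:
    """Write a study table in the package's delimited-text schema (round-trip safe)."""
    delimiter = "\t" if dialect in ("tsv", "\t") else ","
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
        for r in table.records:
            writer.writerow(
                [
                    r.study_id,
                    r.region,
                    r.n_cases,
                    r.n_controls,
                    *r.case_genotypes,
                    *r.control_genotypes,
                    "" if r.hwe_p_reported is None else repr(r.hwe_p_reported),
                ]
            )


def load_rs966221_table() -> StudyTable:
    """The packaged 14-study PDE4D rs966221 / ischemic-stroke fixture."""
    text = resources.files("allelemeta.data").joinpath(FIXTURE_NAME).read_text(encoding="utf-8")
    return _parse_study_table(text, dialect="csv", provenance=f"packaged:{FIXTURE_NAME}")


def validate_studies(table: StudyTable, hwe_threshold: float = 0.001) -> list[ValidationReport]:
    """Consistency report per study: genotype-sum vs reported-n mismatches and
    a Hardy-Weinberg flag on the control genotypes.

    ``hwe_flag`` is True when the control genotypes depart from HWE at
    ``hwe_threshold`` (default p < 0.001, the conventional screening level for
    genotyping artefacts in the control arm).  Reporting only; records are
    never altered.
    """
    from .effect_stats import hwe_chisq  # local import to avoid a cycle
    from .errors import MonomorphicError

    if len(table) == 0:
        raise ValueError("validate_studies requires a non-empty table")

    reports = []
    for r in table:
        messages: list[str] = []
        case_mismatch = r.case_genotype_total - r.n_cases
        control_mismatch = r.control_genotype_total - r.n_controls
        if case_mismatch:
            messages.append(
                f"case genotype counts sum to {r.case_genotype_total}, reported n_cases is {r.n_cases}"
            )
        if control_mismatch:
            messages.append(
                f"control genotype counts sum to {r.control_genotype_total}, "
                f"reported n_controls is {r.n_controls}"
            )
        try:
            hwe = hwe_chisq(r.control_genotypes)
            hwe_flag = hwe.p < hwe_threshold
            if hwe_flag:
                messages.append(
                    f"control genotypes depart from HWE (chi2={hwe.chi2:.3f}, p={hwe.p:.2e} "
                    f"< {hwe_threshold})"
                )
        except MonomorphicError:
            hwe_flag = False
            messages.append("control genotypes are monomorphic; HWE test undefined")
        reports.append(
            ValidationReport(
                study_id=r.study_id,
                case_sum_mismatch=case_mismatch,
                control_sum_mismatch=control_mismatch,
                hwe_flag=hwe_flag,
                messages=tuple(messages),
            )
        )
    return reports


def total_counts(table: StudyTable) -> tuple[int, int]:
    """(total reported cases, total reported controls) over the table."""
    return (sum(r.n_cases for r in table.records), sum(r.n_controls for r in table.records))


def concat_tables(tables: Sequence[StudyTable], provenance: str = "") -> StudyTable:
    """Concatenate study tables, preserving order; study ids must stay unique."""
    records: list[StudyRecord] = []
    for t in tables:
        records.extend(t.records)
    return StudyTable(records=records, provenance=provenance)
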