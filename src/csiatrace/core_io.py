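"""Domain types and plain-text I/O for compound-specific amino-acid isotope data.

Isotope ratios are carried in delta notation (per mil, ‰) against the
conventional reference scales: VPDB for carbon-13 and atmospheric N2 ("AIR")
for nitrogen-15.  The tabular interchange formats are deliberately plain:
comma-separated UTF-8 CSV with a single header row, "." decimal separator,
and delta values stored as bare floats with no unit suffix.
"""

from __future__ import annotations

import csv
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Element",
    "REFERENCE_SCALE",
    "IsotopeValue",
    "AminoAcidDefinition",
    "AminoAcidRegistry",
    "default_registry",
    "PeakMeasurement",
    "SampleRecord",
    "StandardReference",
    "ReplicateSummary",
    "PeakTableError",
    "read_peak_table",
    "write_peak_table",
    "read_standards_table",
    "write_standards_table",
    "read_chemistry_table",
    "write_chemistry_table",
    "read_sample_table",
    "write_sample_table",
    "average_replicates",
    "validate_cohort",
    "CohortReport",
    "TREATMENTS",
    "COMPARTMENTS",
]


class Element(str, Enum):
    """Isotope system of a measurement: 13C/12C or 15N/14N."""

    C13 = "C13"
    N15 = "N15"


#: Fixed pairing of isotope system and international reference scale.
REFERENCE_SCALE: Mapping[Element, str] = {Element.C13: "VPDB", Element.N15: "AIR"}

TREATMENTS = ("autotrophy", "mixotrophy", "heterotrophy", "prey")
COMPARTMENTS = ("host", "symbiont", "prey")


@dataclass(frozen=True)
class IsotopeValue:
    """A delta-notation isotope ratio in per mil against a named scale.

    The scale is determined by the element (C13 -> VPDB, N15 -> AIR) and is
    validated on construction; the value must be finite.
    """

    value: float
    element: Element
    scale: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"delta value must be finite, got {self.value!r}")
        expected = REFERENCE_SCALE[Element(self.element)]
        if self.scale == "":
            object.__setattr__(self, "scale", expected)
        elif self.scale != expected:
            raise ValueError(
                f"element {self.element} pairs with scale {expected}, got {self.scale}"
            )


@dataclass(frozen=True)
class AminoAcidDefinition:
    """An amino acid with the carbon bookkeeping needed for derivatization
    correction.

    ``n_c`` counts the skeletal carbons of the underivatized amino acid and
    ``n_d`` the exogenous carbons added by the chloroformate derivatization;
    ``n_cd = n_c + n_d`` is the carbon count of the measured derivative.
    ``trophic_class`` distinguishes "trophic" amino acids (15N-enriched per
    trophic transfer, e.g. glutamic acid) from "source" ones (near-constant
    15N, e.g. phenylalanine).
    """

    name: str
    code: str
    n_c: int
    n_d: int
    essential: bool
    trophic_class: str  # {"trophic", "source", "other"}

    def __post_init__(self) -> None:
        if self.n_c < 2:
            raise ValueError(f"{self.name}: n_c must be >= 2, got {self.n_c}")
        if self.n_d < 0:
            raise ValueError(f"{self.name}: n_d must be >= 0, got {self.n_d}")
        if self.trophic_class not in ("trophic", "source", "other"):
            raise ValueError(f"{self.name}: bad trophic_class {self.trophic_class}")

    @property
    def n_cd(self) -> int:
        return self.n_c + self.n_d


# Canonical chemistry. Skeletal carbon counts are textbook values; the
# derivatization carbon count defaults to 4 for every amino acid and is
# overridable through a chemistry CSV when the derivative is known exactly.
# Trophic/source classes follow the standard CSIA-AA groupings (glutamic
# acid trophic, phenylalanine source).
_DEFAULT_CHEMISTRY = [
    # name, code, n_c, n_d, essential, trophic_class
    ("alanine", "Ala", 3, 4, False, "trophic"),
    ("glycine", "Gly", 2, 4, False, "source"),
    ("valine", "Val", 5, 4, True, "trophic"),
    ("leucine", "Leu", 6, 4, True, "trophic"),
    ("isoleucine", "Ile", 6, 4, True, "trophic"),
    ("proline", "Pro", 5, 4, False, "trophic"),
    ("aspartic acid", "Asp", 4, 4, False, "trophic"),
    ("methionine", "Met", 5, 4, True, "source"),
    ("glutamic acid", "Glu", 5, 4, False, "trophic"),
    ("phenylalanine", "Phe", 9, 4, True, "source"),
    ("lysine", "Lys", 6, 4, True, "source"),
    ("serine", "Ser", 3, 4, False, "source"),
    ("threonine", "Thr", 4, 4, True, "other"),
    ("tyrosine", "Tyr", 9, 4, False, "source"),
]


class AminoAcidRegistry:
    """Case-insensitive lookup of amino acids by full name or 3-letter code."""

    def __init__(self, definitions: Iterable[AminoAcidDefinition]):
        self._by_key: dict[str, AminoAcidDefinition] = {}
        self._definitions: list[AminoAcidDefinition] = []
        for d in definitions:
            self.add(d)

    def add(self, definition: AminoAcidDefinition) -> None:
        self._definitions.append(definition)
        self._by_key[definition.name.lower()] = definition
        self._by_key[definition.code.lower()] = definition

    def get(self, key: str) -> AminoAcidDefinition:
        try:
            return self._by_key[key.strip().lower()]
        except KeyError:
            raise KeyError(f"unknown amino acid {key!r}") from None

    def __contains__(self, key: str) -> bool:
        return key.strip().lower() in self._by_key

    def __iter__(self):
        return iter(self._definitions)

    def __len__(self) -> int:
        return len(self._definitions)


def default_registry() -> AminoAcidRegistry:
    """Registry with the packaged default chemistry (n_d = 4 for every AA)."""
    return AminoAcidRegistry(
        AminoAcidDefinition(name, code, n_c, n_d, ess, cls)
        for name, code, n_c, n_d, ess, cls in _DEFAULT_CHEMISTRY
    )


@dataclass(frozen=True)
class PeakMeasurement:
    """One integrated chromatographic peak: a single amino acid in a single
    injection, with its raw (uncorrected) delta value."""

    sample_id: str
    aa: AminoAcidDefinition
    element: Element
    replicate_index: int
    injection_index: int
    raw_delta: IsotopeValue
    is_standard: bool = False
    colony: int | None = None
    treatment: str | None = None
    compartment: str | None = None

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        if self.raw_delta.element != self.element:
            raise ValueError("peak element disagrees with its delta value")


@dataclass
class SampleRecord:
    """One biological sample (colony x treatment x compartment) with its
    per-amino-acid delta values keyed by (3-letter code, Element)."""

    sample_id: str
    colony_id: int
    treatment: str
    compartment: str
    delta: dict[tuple[str, Element], IsotopeValue] = field(default_factory=dict)
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if (self.treatment == "prey") != (self.compartment == "prey"):
            raise ValueError("treatment 'prey' pairs exactly with compartment 'prey'")

    def get(self, aa_code: str, element: Element) -> float:
        return self.delta[(aa_code, Element(element))].value


@dataclass(frozen=True)
class StandardReference:
    """A certified reference amino acid: known delta for one isotope system."""

    aa: str  # 3-letter code
    element: Element
    certified_delta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.certified_delta):
            raise ValueError("certified delta must be finite")


class PeakTableError(ValueError):
    """Malformed peak-table CSV (missing columns or unparseable rows)."""


_PEAK_COLUMNS = [
    "sample_id",
    "colony",
    "treatment",
    "compartment",
    "aa",
    "element",
    "replicate",
    "injection",
    "delta",
    "is_standard",
]


def _parse_bool(token: str) -> bool:
    t = token.strip().lower()
    if t in ("1", "true", "yes"):
        return True
    if t in ("0", "false", "no", ""):
        return False
    raise ValueError(f"not a boolean: {token!r}")


def read_peak_table(path: str | Path, aa_registry: AminoAcidRegistry) -> list[PeakMeasurement]:
    """Read a peak-table CSV into :class:`PeakMeasurement` rows.

    Every row is parsed or rejected with a diagnostic naming the line number
    and the offending token; unknown amino-acid names are errors.
    """
    path = Path(path)
    peaks: list[PeakMeasurement] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PeakTableError(f"{path}: empty file")
        missing = [c for c in _PEAK_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise PeakTableError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                aa = aa_registry.get(row["aa"])
            except KeyError as exc:
                raise PeakTableError(f"{path} line {lineno}: {exc.args[0]}") from None
            try:
                element = Element(row["element"].strip())
                delta = float(row["delta"])
                replicate = int(row["replicate"])
                injection = int(row["injection"])
                is_standard = _parse_bool(row["is_standard"])
            except (ValueError, KeyError) as exc:
                raise PeakTableError(f"{path} line {lineno}: {exc}") from None
            colony = int(row["colony"]) if row["colony"].strip() else None
            peaks.append(
                PeakMeasurement(
                    sample_id=row["sample_id"],
                    aa=aa,
                    element=element,
                    replicate_index=replicate,
                    injection_index=injection,
                    raw_delta=IsotopeValue(delta, element),
                    is_standard=is_standard,
                    colony=colony,
                    treatment=row["treatment"].strip() or None,
                    compartment=row["compartment"].strip() or None,
                )
            )
    return peaks


def write_peak_table(peaks: Iterable[PeakMeasurement], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PEAK_COLUMNS)
        for p in peaks:
            writer.writerow(
                [
                    p.sample_id,
                    "" if p.colony is None else p.colony,
                    p.treatment or "",
                    p.compartment or "",
                    p.aa.code,
                    p.element.value,
                    p.replicate_index,
                    p.injection_index,
                    repr(p.raw_delta.value),
                    int(p.is_standard),
                ]
            )


def read_standards_table(path: str | Path, aa_registry: AminoAcidRegistry) -> list[StandardReference]:
    """Standards CSV: columns aa, element, certified_delta."""
    path = Path(path)
    refs = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ("aa", "element", "certified_delta") if c not in (reader.fieldnames or [])]
        if missing:
            raise PeakTableError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            aa = aa_registry.get(row["aa"])  # raises on unknown
            refs.append(
                StandardReference(
                    aa=aa.code,
                    element=Element(row["element"].strip()),
                    certified_delta=float(row["certified_delta"]),
                )
            )
    return refs


def write_standards_table(refs: Iterable[StandardReference], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["aa", "element", "certified_delta"])
        for r in refs:
            writer.writerow([r.aa, r.element.value, repr(r.certified_delta)])


def read_chemistry_table(path: str | Path) -> AminoAcidRegistry:
    """Chemistry CSV: aa, code, n_c, n_d, essential, trophic_class."""
    path = Path(path)
    defs = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            defs.append(
                AminoAcidDefinition(
                    name=row["aa"].strip().lower(),
                    code=row["code"].strip(),
                    n_c=int(row["n_c"]),
                    n_d=int(row["n_d"]),
                    essential=_parse_bool(row["essential"]),
                    trophic_class=row["trophic_class"].strip(),
                )
            )
    return AminoAcidRegistry(defs)


def write_chemistry_table(registry: AminoAcidRegistry, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["aa", "code", "n_c", "n_d", "essential", "trophic_class"])
        for d in registry:
            writer.writerow([d.name, d.code, d.n_c, d.n_d, int(d.essential), d.trophic_class])


_SAMPLE_COLUMNS = ["sample_id", "colony", "treatment", "compartment", "aa", "element", "delta"]


def write_sample_table(records: Iterable[SampleRecord], path: str | Path) -> None:
    """Long-format per-sample delta table (one row per sample x AA x element)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SAMPLE_COLUMNS)
        for rec in records:
            for (code, element), iv in sorted(rec.delta.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
                writer.writerow(
                    [rec.sample_id, rec.colony_id, rec.treatment, rec.compartment, code, element.value, repr(iv.value)]
                )


def read_sample_table(path: str | Path, aa_registry: AminoAcidRegistry, corrected: bool = True) -> list[SampleRecord]:
    path = Path(path)
    by_id: dict[str, SampleRecord] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _SAMPLE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise PeakTableError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            aa = aa_registry.get(row["aa"])
            element = Element(row["element"].strip())
            sid = row["sample_id"]
            if sid not in by_id:
                by_id[sid] = SampleRecord(
                    sample_id=sid,
                    colony_id=int(row["colony"]),
                    treatment=row["treatment"].strip(),
                    compartment=row["compartment"].strip(),
                    corrected=corrected,
                )
            by_id[sid].delta[(aa.code, element)] = IsotopeValue(float(row["delta"]), element)
    return list(by_id.values())


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-(sample, amino acid, element) replicate mean with spread and the
    mean injection position (used downstream by drift correction)."""

    sample_id: str
    aa: AminoAcidDefinition
    element: Element
    mean_delta: float
    sd: float | None  # None flags n = 1 (SD undefined)
    n: int
    mean_injection: float
    is_standard: bool
    colony: int | None = None
    treatment: str | None = None
    compartment: str | None = None


def average_replicates(measurements: Sequence[PeakMeasurement]) -> list[ReplicateSummary]:
    """Arithmetic mean over replicate injections per (sample, AA, element).

    The result is permutation-invariant in replicate order; SD is the sample
    standard deviation (ddof=1) and is flagged ``None`` for n = 1.
    """
    groups: dict[tuple[str, str, Element], list[PeakMeasurement]] = defaultdict(list)
    for m in measurements:
        groups[(m.sample_id, m.aa.code, m.element)].append(m)
    out = []
    for (sid, code, element), peaks in groups.items():
        meta = {(p.is_standard, p.colony, p.treatment, p.compartment) for p in peaks}
        if len(meta) > 1:
            raise ValueError(f"inconsistent metadata within replicate group ({sid}, {code}, {element.value})")
        vals = [p.raw_delta.value for p in peaks]
        n = len(vals)
        mean = sum(vals) / n
        sd = None
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        out.append(
            ReplicateSummary(
                sample_id=sid,
                aa=peaks[0].aa,
                element=element,
                mean_delta=mean,
                sd=sd,
                n=n,
                mean_injection=sum(p.injection_index for p in peaks) / n,
                is_standard=peaks[0].is_standard,
                colony=peaks[0].colony,
                treatment=peaks[0].treatment,
                compartment=peaks[0].compartment,
            )
        )
    return out


@dataclass
class CohortReport:
    """Report-only design check for a cohort of sample records."""

    n_samples: int
    design_counts: dict[tuple[str, str], int]
    balanced: bool
    missing_cells: list[str]
    range_flags: list[str]

    @property
    def ok(self) -> bool:
        return self.balanced and not self.missing_cells and not self.range_flags


def validate_cohort(
    records: Sequence[SampleRecord],
    expected_aas: Sequence[tuple[str, Element]] | None = None,
    delta_limit: float = 100.0,
) -> CohortReport:
    """Check design balance and delta plausibility; never raises.

    Flags (treatment, compartment) groups with unequal sample counts, samples
    missing any of ``expected_aas`` (default: the union of keys seen in the
    cohort), and deltas with absolute value above ``delta_limit`` per mil.
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for rec in records:
        counts[(rec.treatment, rec.compartment)] += 1
    tissue_counts = [v for (t, c), v in counts.items() if t != "prey"]
    balanced = len(set(tissue_counts)) <= 1

    if expected_aas is None:
        seen: set[tuple[str, Element]] = set()
        for rec in records:
            seen.update(rec.delta.keys())
        expected_aas = sorted(seen, key=lambda k: (k[0], k[1].value))

    missing = []
    range_flags = []
    for rec in records:
        for key in expected_aas:
            if key not in rec.delta:
                missing.append(f"{rec.sample_id}: missing {key[0]} {key[1].value}")
        for (code, element), iv in rec.delta.items():
            if abs(iv.value) > delta_limit:
                range_flags.append(
                    f"{rec.sample_id}: {code} {element.value} = {iv.value:+.2f} beyond +/-{delta_limit}"
                )
    return CohortReport(
        n_samples=len(records),
        design_counts=dict(counts),
        balanced=balanced,
        missing_cells=missing,
        range_flags=range_flags,
    )
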