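"""Forward-model generator for amino-acid isotope cohorts and instrument runs.

Two layers are simulated:

* the *tissue* layer — per-sample true delta values drawn independently from
  Normal(mean, SD) cells of a treatment/compartment/AA/element parameter
  table, optionally with a shared per-colony offset;
* the *instrument* layer — gas-chromatography combustion isotope-ratio mass
  spectrometry (GC-C-IRMS) sequences: derivatization adds carbon of known
  isotopic composition (a moles-weighted mixture determines the measured
  carbon delta), the nitrogen channel has an affine instrument response,
  both channels drift linearly over the injection sequence, injections carry
  Gaussian analytical noise, and blocks of certified standards bracket the
  sequence (start, end, and at least every ``standards_interval`` sample
  injections).

Everything is reproducible from a single master seed; per-stage substreams
are spawned deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    AminoAcidDefinition,
    AminoAcidRegistry,
    Element,
    IsotopeValue,
    PeakMeasurement,
    SampleRecord,
    StandardReference,
    default_registry,
)

__all__ = [
    "ParameterTable",
    "InstrumentModel",
    "CohortSpec",
    "SequenceRun",
    "generate_cohort",
    "forward_instrument",
]


class ParameterTable:
    """Map (treatment, compartment, aa code, element) -> (mean, SD) in per mil."""

    def __init__(self, cells: Mapping[tuple[str, str, str, Element], tuple[float, float]]):
        self._cells = dict(cells)
        for key, (mean, sd) in self._cells.items():
            # sd = 0 is allowed as the degenerate (noise-free) limit
            if sd < 0:
                raise ValueError(f"SD must be >= 0 in cell {key}, got {sd}")

    @classmethod
    def from_records(cls, rows: Iterable[Mapping]) -> "ParameterTable":
        cells = {}
        for row in rows:
            key = (row["treatment"], row["compartment"], row["aa"], Element(row["element"]))
            cells[key] = (float(row["mean"]), float(row["sd"]))
        return cls(cells)

    def lookup(self, treatment: str, compartment: str, aa: str, element: Element) -> tuple[float, float]:
        key = (treatment, compartment, aa, Element(element))
        try:
            return self._cells[key]
        except KeyError:
            raise KeyError(
                f"no parameter cell for treatment={treatment!r}, compartment={compartment!r}, "
                f"aa={aa!r}, element={Element(element).value}"
            ) from None

    def cells_for(self, treatment: str, compartment: str) -> list[tuple[str, Element]]:
        keys = [
            (aa, el)
            for (t, c, aa, el) in self._cells
            if t == treatment and c == compartment
        ]
        return sorted(keys, key=lambda k: (k[0], k[1].value))

    def items(self):
        return self._cells.items()

    def __len__(self) -> int:
        return len(self._cells)


@dataclass
class InstrumentModel:
    """Parameters of the GC-C-IRMS measurement layer.

    ``derivatization_delta`` holds the delta13C of the carbon added during
    chloroformate derivatization, per AA code with a ``"default"`` fallback;
    the empirical per-AA correction factor estimated downstream from
    standards recovers exactly this quantity in the noise-free limit.
    ``nitrogen_response`` is the affine instrument response (a, b) such that
    measured = a + b * true for the nitrogen channel.
    """

    derivatization_delta: dict[str, float] = field(default_factory=lambda: {"default": -30.0})
    nitrogen_response: tuple[float, float] = (0.0, 1.0)
    drift_slope: dict[Element, float] = field(
        default_factory=lambda: {Element.C13: 0.0, Element.N15: 0.0}
    )
    noise_sd: dict[Element, float] = field(
        default_factory=lambda: {Element.C13: 0.0, Element.N15: 0.0}
    )
    replicates: dict[Element, int] = field(
        default_factory=lambda: {Element.C13: 2, Element.N15: 3}
    )
    standards_interval: int = 18
    standard_block_size: int = 3

    def __post_init__(self) -> None:
        if self.standards_interval > 18:
            raise ValueError("standards must be re-injected at most every 18 injections")
        if self.standards_interval < 1:
            raise ValueError("standards_interval must be >= 1")
        for el, n in self.replicates.items():
            if n < 1:
                raise ValueError(f"replicates must be >= 1, got {n} for {el}")
        a, b = self.nitrogen_response
        if b <= 0:
            raise ValueError("nitrogen response slope must be positive")

    def deriv_delta(self, aa_code: str) -> float:
        return self.derivatization_delta.get(aa_code, self.derivatization_delta["default"])


@dataclass
class CohortSpec:
    """Design of a simulated cohort: colonies x treatments x compartments,
    plus replicate prey samples."""

    parameter_table: ParameterTable
    n_colonies: int = 6
    treatments: tuple[str, ...] = ("autotrophy", "mixotrophy", "heterotrophy")
    compartments: tuple[str, ...] = ("host", "symbiont")
    n_prey: int = 3
    colony_sd: float = 0.0
    seed: int | None = None  # mandatory at generation time if not passed explicitly

    def __post_init__(self) -> None:
        if self.n_colonies < 2:
            raise ValueError("n_colonies must be >= 2")


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> list[SampleRecord]:
    """Draw tissue-level true values for every sample in the design.

    Each sample's (AA, element) value is drawn independently from the
    Normal(mean, SD) of its parameter cell; when ``colony_sd`` > 0 a shared
    Normal(0, colony_sd) offset per (colony, element) is added to every AA of
    that colony's samples.  Identical seeds yield identical cohorts.
    """
    if seed is None:
        seed = spec.seed
    if seed is None:
        raise ValueError("a seed is mandatory for cohort generation")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    colony_offsets: dict[tuple[int, Element], float] = {}
    if spec.colony_sd > 0:
        for colony in range(1, spec.n_colonies + 1):
            for element in (Element.C13, Element.N15):
                colony_offsets[(colony, element)] = rng.normal(0.0, spec.colony_sd)

    records: list[SampleRecord] = []
    for treatment in spec.treatments:
        for compartment in spec.compartments:
            cells = spec.parameter_table.cells_for(treatment, compartment)
            if not cells:
                raise KeyError(
                    f"no parameter cells for treatment={treatment!r}, compartment={compartment!r}"
                )
            for colony in range(1, spec.n_colonies + 1):
                rec = SampleRecord(
                    sample_id=f"{treatment[:4]}_{compartment[:4]}_c{colony}",
                    colony_id=colony,
                    treatment=treatment,
                    compartment=compartment,
                )
                for aa, element in cells:
                    mean, sd = spec.parameter_table.lookup(treatment, compartment, aa, element)
                    value = rng.normal(mean, sd) + colony_offsets.get((colony, element), 0.0)
                    rec.delta[(aa, element)] = IsotopeValue(value, element)
                records.append(rec)

    prey_cells = spec.parameter_table.cells_for("prey", "prey")
    for i in range(1, spec.n_prey + 1):
        rec = SampleRecord(
            sample_id=f"prey_{i}", colony_id=i, treatment="prey", compartment="prey"
        )
        for aa, element in prey_cells:
            mean, sd = spec.parameter_table.lookup("prey", "prey", aa, element)
            rec.delta[(aa, element)] = IsotopeValue(rng.normal(mean, sd), element)
        records.append(rec)
    return records


@dataclass
class SequenceRun:
    """One ordered GC-C-IRMS injection sequence for a single element, with
    interleaved certified-standard blocks — the unit of drift correction and
    calibration."""

    element: Element
    peaks: list[PeakMeasurement]

    @property
    def n_injections(self) -> int:
        return max((p.injection_index for p in self.peaks), default=0)

    def standards(self) -> list[PeakMeasurement]:
        return [p for p in self.peaks if p.is_standard]

    def samples(self) -> list[PeakMeasurement]:
        return [p for p in self.peaks if not p.is_standard]


def _mix_carbon(aa: AminoAcidDefinition, delta_c: float, delta_d: float) -> float:
    # moles-weighted isotope mass balance of skeleton + derivative carbon
    return (aa.n_c * delta_c + aa.n_d * delta_d) / aa.n_cd


def forward_instrument(
    cohort: Sequence[SampleRecord],
    instrument: InstrumentModel,
    standards: Sequence[StandardReference],
    seed: int,
    registry: AminoAcidRegistry | None = None,
) -> list[SequenceRun]:
    """Emit raw peak tables for one injection sequence per element.

    The sequence layout is: a standard block (``standard_block_size``
    injections of the full certified mix), then sample injections
    (``replicates[element]`` consecutive injections per sample), with a new
    standard block inserted whenever ``standards_interval`` sample
    injections have elapsed since the last one, and a final block at the end.
    """
    registry = registry or default_registry()
    std_by_element: dict[Element, list[StandardReference]] = {Element.C13: [], Element.N15: []}
    for ref in standards:
        std_by_element[ref.element].append(ref)

    ss = np.random.SeedSequence(seed).spawn(2)
    runs = []
    for element, child in zip((Element.C13, Element.N15), ss):
        rng = np.random.default_rng(child)
        refs = std_by_element[element]
        if len(refs) < 2:
            raise ValueError(f"need >= 2 certified standards for {element.value}")
        a, b = instrument.nitrogen_response if element == Element.N15 else (0.0, 1.0)
        drift = instrument.drift_slope.get(element, 0.0)
        noise = instrument.noise_sd.get(element, 0.0)
        peaks: list[PeakMeasurement] = []
        injection = 0
        block_no = 0

        def true_response(aa: AminoAcidDefinition, delta_true: float) -> float:
            if element == Element.C13:
                delta_d = instrument.deriv_delta(aa.code)
                if aa.n_d == 0 and delta_d != 0.0:
                    warnings.warn(
                        f"{aa.code}: n_d = 0, carbon mixing degenerates to identity",
                        stacklevel=2,
                    )
                return _mix_carbon(aa, delta_true, delta_d)
            return a + b * delta_true

        def emit_standard_block() -> None:
            nonlocal injection, block_no
            block_no += 1
            for rep in range(1, instrument.standard_block_size + 1):
                injection += 1
                for ref in refs:
                    aa = registry.get(ref.aa)
                    raw = (
                        true_response(aa, ref.certified_delta)
                        + drift * injection
                        + (rng.normal(0.0, noise) if noise > 0 else 0.0)
                    )
                    peaks.append(
                        PeakMeasurement(
                            sample_id=f"std_b{block_no}",
                            aa=aa,
                            element=element,
                            replicate_index=rep,
                            injection_index=injection,
                            raw_delta=IsotopeValue(raw, element),
                            is_standard=True,
                        )
                    )

        emit_standard_block()
        since_block = 0
        for rec in cohort:
            keys = sorted(
                (k for k in rec.delta if k[1] == element), key=lambda k: k[0]
            )
            if not keys:
                continue
            for rep in range(1, instrument.replicates[element] + 1):
                if since_block >= instrument.standards_interval:
                    emit_standard_block()
                    since_block = 0
                injection += 1
                since_block += 1
                for code, _ in keys:
                    aa = registry.get(code)
                    raw = (
                        true_response(aa, rec.delta[(code, element)].value)
                        + drift * injection
                        + (rng.normal(0.0, noise) if noise > 0 else 0.0)
                    )
                    peaks.append(
                        PeakMeasurement(
                            sample_id=rec.sample_id,
                            aa=aa,
                            element=element,
                            replicate_index=rep,
                            injection_index=injection,
                            raw_delta=IsotopeValue(raw, element),
                            is_standard=False,
                            colony=rec.colony_id,
                            treatment=rec.treatment,
                            compartment=rec.compartment,
                        )
                    )
        emit_standard_block()
        runs.append(SequenceRun(element=element, peaks=peaks))
    return runs
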