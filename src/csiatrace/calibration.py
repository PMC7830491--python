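"""Inversion of the GC-C-IRMS instrument layer.

Order of operations per sequence (one element at a time):

1. replicate averaging (sample peaks to per-sample means, standard blocks to
   per-block means, each keeping its mean injection position);
2. linear drift correction, estimated from the certified-standard injections
   and applied to every peak, referenced to the sequence-mean standard
   position;
3. element-specific calibration:
   - carbon: the per-AA empirical correction factor ``dcorr`` is estimated
     from the bracketing standard blocks through the isotope mass balance
     n_cd * d13C_cd = n_c * d13C_c + n_d * d13C_dcorr, then inverted on each
     sample peak;
   - nitrogen: derivatization adds no nitrogen, so a single per-sequence
     ordinary least-squares fit of certified on measured values across the
     standard amino acids (pooled start and end blocks) calibrates every
     sample peak.

With noise-free inputs the full chain inverts the forward model exactly
(affine responses compose to affine maps; the regression and mass balance
are their exact inverses).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core_io import (
    AminoAcidDefinition,
    AminoAcidRegistry,
    Element,
    IsotopeValue,
    PeakMeasurement,
    ReplicateSummary,
    SampleRecord,
    StandardReference,
    average_replicates,
    default_registry,
)

__all__ = [
    "DriftCorrection",
    "NitrogenCalibration",
    "CorrectionFactors",
    "estimate_drift",
    "apply_drift",
    "estimate_dcorr",
    "correct_carbon",
    "calibrate_nitrogen_fit",
    "calibrate_sequence",
    "calibrate_runs",
]


@dataclass(frozen=True)
class DriftCorrection:
    """Linear drift in per mil per injection, with the reference injection
    position (sequence-mean standard position) peaks are adjusted to."""

    slope: float
    reference_index: float
    n_standard_points: int

    def adjust(self, value: float, injection_index: float) -> float:
        return value - self.slope * (injection_index - self.reference_index)


@dataclass(frozen=True)
class NitrogenCalibration:
    """Per-sequence OLS fit of certified on measured delta15N."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_points: int

    def apply(self, measured: float) -> float:
        return self.intercept + self.slope * measured


@dataclass
class CorrectionFactors:
    """Everything estimated from one sequence's standards."""

    dcorr: dict[str, float] = field(default_factory=dict)
    nitrogen_fit: NitrogenCalibration | None = None
    drift: dict[str, DriftCorrection] = field(default_factory=dict)  # keyed by element value

    def to_dict(self) -> dict:
        out: dict = {"dcorr": dict(self.dcorr), "drift": {}, "nitrogen_fit": None}
        for el, d in self.drift.items():
            out["drift"][el] = {
                "slope": d.slope,
                "reference_index": d.reference_index,
                "n_standard_points": d.n_standard_points,
            }
        if self.nitrogen_fit is not None:
            f = self.nitrogen_fit
            out["nitrogen_fit"] = {
                "slope": f.slope,
                "intercept": f.intercept,
                "r_squared": f.r_squared,
                "residual_sd": f.residual_sd,
                "n_points": f.n_points,
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _standard_blocks(summaries: Sequence[ReplicateSummary]) -> list[list[ReplicateSummary]]:
    """Group standard summaries by block (their sample_id), ordered by
    injection position."""
    blocks: dict[str, list[ReplicateSummary]] = {}
    for s in summaries:
        if s.is_standard:
            blocks.setdefault(s.sample_id, []).append(s)
    return sorted(blocks.values(), key=lambda b: min(x.mean_injection for x in b))


def estimate_drift(summaries: Sequence[ReplicateSummary]) -> DriftCorrection | None:
    """Estimate linear drift from standard injections.

    Pools all standard points after centering within amino acid (each AA has
    a different true level, but shares the sequence-wide drift), and
    regresses the centered reading on the centered injection position.
    Returns ``None`` (drift skipped) when only one standard block is present.
    """
    std = [s for s in summaries if s.is_standard]
    blocks = _standard_blocks(std)
    if len(blocks) < 2:
        warnings.warn("single standard block: drift correction skipped", stacklevel=2)
        return None
    by_aa: dict[str, list[ReplicateSummary]] = {}
    for s in std:
        by_aa.setdefault(s.aa.code, []).append(s)
    xs, ys = [], []
    for group in by_aa.values():
        if len(group) < 2:
            continue
        mean_v = sum(g.mean_delta for g in group) / len(group)
        mean_i = sum(g.mean_injection for g in group) / len(group)
        for g in group:
            xs.append(g.mean_injection - mean_i)
            ys.append(g.mean_delta - mean_v)
    x = np.asarray(xs)
    y = np.asarray(ys)
    denom = float(np.sum(x * x))
    if denom == 0.0:
        warnings.warn("standard injections at a single position: drift skipped", stacklevel=2)
        return None
    slope = float(np.sum(x * y) / denom)
    # Reference at the opening standard block: peaks are restated as if read
    # at the sequence start, where the bracketing standards anchor the scale.
    # Any constant offset this leaves is absorbed by the nitrogen regression
    # or the per-AA carbon correction factor downstream.
    ref = float(min(s.mean_injection for s in std))
    return DriftCorrection(slope=slope, reference_index=ref, n_standard_points=len(xs))


def apply_drift(
    summaries: Sequence[ReplicateSummary], drift: DriftCorrection | None
) -> list[ReplicateSummary]:
    if drift is None:
        return list(summaries)
    out = []
    for s in summaries:
        out.append(
            ReplicateSummary(
                sample_id=s.sample_id,
                aa=s.aa,
                element=s.element,
                mean_delta=drift.adjust(s.mean_delta, s.mean_injection),
                sd=s.sd,
                n=s.n,
                mean_injection=s.mean_injection,
                is_standard=s.is_standard,
                colony=s.colony,
                treatment=s.treatment,
                compartment=s.compartment,
            )
        )
    return out


def _bracketing_means(summaries: Sequence[ReplicateSummary]) -> dict[str, float]:
    """Mean standard reading per AA, averaging the first and the last block
    of the sequence (amino acids combust with different efficiencies, so the
    bracketing blocks are averaged rather than pooled with mid-sequence
    ones)."""
    blocks = _standard_blocks(summaries)
    if not blocks:
        raise ValueError("no standard injections in sequence")
    chosen = [blocks[0]] if len(blocks) == 1 else [blocks[0], blocks[-1]]
    per_aa: dict[str, list[float]] = {}
    for block in chosen:
        for s in block:
            per_aa.setdefault(s.aa.code, []).append(s.mean_delta)
    return {code: sum(v) / len(v) for code, v in per_aa.items()}


def estimate_dcorr(
    summaries: Sequence[ReplicateSummary],
    standards: Sequence[StandardReference],
    registry: AminoAcidRegistry | None = None,
) -> dict[str, float]:
    """Per-AA empirical derivatization-carbon correction factor.

    Inverts the carbon mass balance on the certified standards:
    dcorr = (n_cd * measured_cd - n_c * certified_c) / n_d, using the average
    of the bracketing (start/end) standard blocks.
    """
    registry = registry or default_registry()
    certified = {r.aa: r.certified_delta for r in standards if r.element == Element.C13}
    measured = _bracketing_means([s for s in summaries if s.element == Element.C13])
    dcorr: dict[str, float] = {}
    for code, meas in measured.items():
        if code not in certified:
            continue
        aa = registry.get(code)
        if aa.n_d == 0:
            raise ValueError(f"{code}: n_d = 0, derivatization correction factor undefined")
        dcorr[code] = (aa.n_cd * meas - aa.n_c * certified[code]) / aa.n_d
    if not dcorr:
        raise ValueError("no carbon standards available to estimate dcorr")
    return dcorr


def correct_carbon(measured_cd: float, aa: AminoAcidDefinition, dcorr: float) -> float:
    """Recover the skeletal carbon delta from the derivatized measurement:
    d13C_c = ((n_c + n_d) * d13C_cd - n_d * d13C_dcorr) / n_c."""
    if aa.n_c == 0:
        raise ValueError(f"{aa.code}: n_c = 0")
    return (aa.n_cd * measured_cd - aa.n_d * dcorr) / aa.n_c


def calibrate_nitrogen_fit(
    summaries: Sequence[ReplicateSummary],
    standards: Sequence[StandardReference],
) -> NitrogenCalibration:
    """OLS of certified on measured delta15N across standard amino acids,
    pooling the bracketing standard blocks.  Requires >= 2 distinct standard
    AAs; a non-positive fitted slope indicates an inverted response and is an
    error."""
    certified = {r.aa: r.certified_delta for r in standards if r.element == Element.N15}
    measured = _bracketing_means([s for s in summaries if s.element == Element.N15])
    pairs = [(measured[c], certified[c]) for c in measured if c in certified]
    if len(pairs) < 2:
        raise ValueError("nitrogen calibration needs >= 2 certified standard AAs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in measured standard values")
    res = sps.linregress(x, y)
    if res.slope <= 0:
        raise ValueError(f"nitrogen calibration slope must be > 0, got {res.slope:.4g}")
    fitted = res.intercept + res.slope * x
    resid = y - fitted
    dof = max(len(pairs) - 2, 1)
    return NitrogenCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_sd=float(math.sqrt(np.sum(resid**2) / dof)),
        n_points=len(pairs),
    )


def calibrate_sequence(
    peaks: Sequence[PeakMeasurement],
    standards: Sequence[StandardReference],
    registry: AminoAcidRegistry | None = None,
    drift_correction: bool = True,
) -> tuple[list[ReplicateSummary], CorrectionFactors]:
    """Run the full correction chain on one element's peak list.

    Returns drift-corrected, calibrated per-sample summaries together with
    the estimated correction factors.  Mixed-element input is an error: a
    sequence is the unit of calibration for a single channel.
    """
    registry = registry or default_registry()
    elements = {p.element for p in peaks}
    if len(elements) != 1:
        raise ValueError(f"calibrate_sequence expects a single element, got {sorted(e.value for e in elements)}")
    element = elements.pop()

    summaries = average_replicates(peaks)
    factors = CorrectionFactors()

    drift = estimate_drift(summaries) if drift_correction else None
    if drift is not None:
        factors.drift[element.value] = drift
    summaries = apply_drift(summaries, drift)

    sample_summaries = [s for s in summaries if not s.is_standard]
    corrected: list[ReplicateSummary] = []
    if element == Element.C13:
        dcorr = estimate_dcorr(summaries, standards, registry)
        factors.dcorr = dcorr
        for s in sample_summaries:
            if s.aa.code not in dcorr:
                raise ValueError(
                    f"no carbon standard for {s.aa.code}: cannot set its correction factor"
                )
            value = correct_carbon(s.mean_delta, s.aa, dcorr[s.aa.code])
            corrected.append(_with_value(s, value))
    else:
        fit = calibrate_nitrogen_fit(summaries, standards)
        factors.nitrogen_fit = fit
        for s in sample_summaries:
            corrected.append(_with_value(s, fit.apply(s.mean_delta)))
    return corrected, factors


def _with_value(s: ReplicateSummary, value: float) -> ReplicateSummary:
    return ReplicateSummary(
        sample_id=s.sample_id,
        aa=s.aa,
        element=s.element,
        mean_delta=value,
        sd=s.sd,
        n=s.n,
        mean_injection=s.mean_injection,
        is_standard=s.is_standard,
        colony=s.colony,
        treatment=s.treatment,
        compartment=s.compartment,
    )


def calibrate_runs(
    runs_or_peaks,
    standards: Sequence[StandardReference],
    registry: AminoAcidRegistry | None = None,
    drift_correction: bool = True,
) -> tuple[list[SampleRecord], dict[str, CorrectionFactors]]:
    """Calibrate one or more sequences and assemble corrected sample records.

    Accepts a flat peak list (split internally by element) or a list of
    :class:`~csiatrace.synthetic.SequenceRun`.  Returns records carrying the
    corrected per-AA deltas plus the per-element correction factors.
    """
    registry = registry or default_registry()
    if hasattr(runs_or_peaks[0], "peaks"):
        peak_lists = [(run.element, run.peaks) for run in runs_or_peaks]
    else:
        by_el: dict[Element, list[PeakMeasurement]] = {}
        for p in runs_or_peaks:
            by_el.setdefault(p.element, []).append(p)
        peak_lists = sorted(by_el.items(), key=lambda kv: kv[0].value)

    records: dict[str, SampleRecord] = {}
    reports: dict[str, CorrectionFactors] = {}
    for element, peaks in peak_lists:
        corrected, factors = calibrate_sequence(peaks, standards, registry, drift_correction)
        reports[element.value] = factors
        for s in corrected:
            if s.sample_id not in records:
                records[s.sample_id] = SampleRecord(
                    sample_id=s.sample_id,
                    colony_id=s.colony if s.colony is not None else 0,
                    treatment=s.treatment or "autotrophy",
                    compartment=s.compartment or "host",
                    corrected=True,
                )
            records[s.sample_id].delta[(s.aa.code, element)] = IsotopeValue(s.mean_delta, element)
    return list(records.values()), reports
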