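"""Pipeline configuration: packaged defaults plus YAML/JSON user configs.

``load_config("paper_defaults")`` returns the packaged study conditions
(six-colony, three-treatment, two-compartment coral feeding design with
Artemia prey); ``load_config(path)`` reads the same schema from disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .core_io import Element, StandardReference
from .synthetic import CohortSpec, InstrumentModel, ParameterTable
from .trophic import TPConstants

__all__ = ["PipelineConfig", "load_config", "PACKAGED_CONFIGS"]

PACKAGED_CONFIGS = ("paper_defaults",)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs besides the seed."""

    name: str
    constants: TPConstants
    instrument: InstrumentModel
    cohort: CohortSpec
    standards: list[StandardReference]
    n_perm: int = 999
    alpha: float = 0.05
    permanova_treatments: tuple[str, ...] = ("autotrophy", "heterotrophy")
    seed: int | None = None
    raw: dict = field(default_factory=dict, repr=False)


def _build(doc: dict, name: str) -> PipelineConfig:
    constants = TPConstants(**doc.get("constants", {}))

    inst = doc.get("instrument", {})
    nr = inst.get("nitrogen_response", {"intercept": 0.0, "slope": 1.0})
    instrument = InstrumentModel(
        derivatization_delta=dict(inst.get("derivatization_delta", {"default": -30.0})),
        nitrogen_response=(float(nr["intercept"]), float(nr["slope"])),
        drift_slope={Element(k): float(v) for k, v in inst.get("drift_slope", {}).items()},
        noise_sd={Element(k): float(v) for k, v in inst.get("noise_sd", {}).items()},
        replicates={Element(k): int(v) for k, v in inst.get("replicates", {"C13": 2, "N15": 3}).items()},
        standards_interval=int(inst.get("standards_interval", 18)),
        standard_block_size=int(inst.get("standard_block_size", 3)),
    )

    table = ParameterTable.from_records(doc["parameters"])
    design = doc.get("design", {})
    cohort = CohortSpec(
        parameter_table=table,
        n_colonies=int(design.get("n_colonies", 6)),
        treatments=tuple(design.get("treatments", ("autotrophy", "mixotrophy", "heterotrophy"))),
        compartments=tuple(design.get("compartments", ("host", "symbiont"))),
        n_prey=int(design.get("n_prey", 3)),
        colony_sd=float(design.get("colony_sd", 0.0)),
        seed=doc.get("seed"),
    )

    standards: list[StandardReference] = []
    for row in doc.get("standards", []):
        if "n15" in row:
            standards.append(StandardReference(row["aa"], Element.N15, float(row["n15"])))
        if "c13" in row:
            standards.append(StandardReference(row["aa"], Element.C13, float(row["c13"])))

    st = doc.get("stats", {})
    return PipelineConfig(
        name=doc.get("name", name),
        constants=constants,
        instrument=instrument,
        cohort=cohort,
        standards=standards,
        n_perm=int(st.get("n_perm", 999)),
        alpha=float(st.get("alpha", 0.05)),
        permanova_treatments=tuple(st.get("permanova_treatments", ("autotrophy", "heterotrophy"))),
        seed=doc.get("seed"),
        raw=doc,
    )


def load_config(name_or_path: str | Path = "paper_defaults") -> PipelineConfig:
    """Load a packaged config by name, or a YAML/JSON config file by path."""
    name = str(name_or_path)
    if name in PACKAGED_CONFIGS:
        text = resources.files("csiatrace.data").joinpath(f"{name}.yaml").read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
        return _build(doc, name)
    path = Path(name_or_path)
    if not path.exists():
        raise FileNotFoundError(
            f"config {name!r} is neither a packaged name {PACKAGED_CONFIGS} nor an existing file"
        )
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _build(doc, path.stem)
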