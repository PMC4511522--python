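"""Pipeline configuration: assay scoring specs and run parameters (YAML)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import B_DEFAULT, N_BOOT_SIZE, TIER_CUTPOINTS

ADAPTERS = ("linear", "mann_whitney", "mixed")

#: Default adapter per synthetic assay family.  Real screens override this
#: per assay: the model-per-experiment mapping is configuration, not code.
FAMILY_ADAPTERS = {
    "endpoint_continuous": "linear",
    "timecourse_continuous": "mixed",
    "ordinal_score": "mann_whitney",
    "germination_curve": "linear",
    "burst_total": "linear",
}

__all__ = ["AssaySpec", "PipelineConfig", "ADAPTERS", "FAMILY_ADAPTERS",
           "default_assay_specs"]


@dataclass
class AssaySpec:
    """How one assay is scored: adapter, reference and endpoint timepoints.

    ``endpoints`` lists the timepoints that each contribute one matrix
    column (``assay_id@t<tp>``); empty means a single endpoint column.  The
    ordinal disease-score family always routes to the Mann-Whitney adapter.
    """

    assay_id: str
    adapter: str = "linear"
    reference: str = "Col-0"
    endpoints: tuple[float, ...] = ()
    arm: str | None = None

    def validate(self) -> None:
        if self.adapter not in ADAPTERS:
            raise ValueError(
                f"{self.assay_id!r}: unknown adapter {self.adapter!r}, "
                f"expected one of {ADAPTERS}"
            )

    @property
    def columns(self) -> list[str]:
        if not self.endpoints:
            return [self.assay_id]
        return [f"{self.assay_id}@t{tp:g}" for tp in self.endpoints]


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible simulate->cluster run."""

    input_csv: str | None = None
    simulate: dict = field(default_factory=dict)  # kwargs of study_default_config
    assays: list[AssaySpec] = field(default_factory=list)
    b: int = B_DEFAULT
    n_boot_size: int = N_BOOT_SIZE
    family_scope: str = "per_experiment"
    tier_cutpoints: dict[str, float] = field(default_factory=lambda: dict(TIER_CUTPOINTS))
    clustering: str = "ward_euclidean"
    allele_average: bool = True
    seed: int = 0
    heatmap: bool = False

    def validate(self) -> None:
        if self.b < 1:
            raise ValueError("b (bootstrap replicates) must be >= 1")
        if self.n_boot_size < 2:
            raise ValueError("n_boot_size must be >= 2")
        if self.family_scope not in ("per_experiment", "global"):
            raise ValueError(f"unknown family_scope {self.family_scope!r}")
        if self.clustering not in ("ward_euclidean", "complete_pearson"):
            raise ValueError(f"unknown clustering recipe {self.clustering!r}")
        cp = [self.tier_cutpoints[k] for k in ("fdr10", "fdr5", "fdr1")]
        if not (cp[0] < cp[1] < cp[2]):
            raise ValueError(f"tier cutpoints must be strictly increasing, got {cp}")
        for spec in self.assays:
            spec.validate()

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["assays"] = [asdict(a) for a in self.assays]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        assays = [
            AssaySpec(**{**a, "endpoints": tuple(a.get("endpoints", ()))})
            for a in doc.pop("assays", [])
        ]
        cfg = cls(assays=assays, **doc)
        cfg.validate()
        return cfg


def default_assay_specs(sim_config) -> list[AssaySpec]:
    """Derive scoring specs from a synthetic design: family -> adapter, plus
    one endpoint per time-structured assay (last timepoint for time courses;
    for germination curves the median observation time, where the logistic
    curve is steepest and genotype shifts are most visible)."""
    specs = []
    for design in sim_config.assays:
        adapter = FAMILY_ADAPTERS[design.family]
        endpoints: tuple[float, ...] = ()
        if design.family == "timecourse_continuous":
            endpoints = (design.timepoints[-1],)
        elif design.family == "germination_curve":
            endpoints = (design.timepoints[len(design.timepoints) // 2],)
        specs.append(AssaySpec(assay_id=design.assay_id, adapter=adapter,
                               endpoints=endpoints))
    return specs
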