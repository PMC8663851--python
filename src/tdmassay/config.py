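"""Run configuration: a structured-text (YAML) schema with validated defaults.

A :class:`RunConfig` bundles the three blocks the pipeline needs:

* ``pk`` — dose regimen, population parameter means/SDs, simulation settings;
* ``assay`` — chromatographic geometry, detector response model, calibration
  and QC level lists, replicate/day design;
* ``analysis`` — regression weighting, baseline region, retention-window
  tolerance, acceptance limits and selectivity thresholds.

Unknown keys and invariant violations raise :class:`~tdmassay.errors.ConfigError`
with the offending field path, so CLI users get actionable messages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .errors import ConfigError
from .pk import DoseRegimen, PKParameters
from .synth import (
    DEFAULT_CALIBRATION_LEVELS,
    DEFAULT_QC_LEVELS,
    AssayGeometry,
    ResponseModel,
)
from .validation import AcceptanceLimits

__all__ = ["PKConfig", "AssayConfig", "AnalysisConfig", "RunConfig", "load_config"]

#: documented example population parameter set for a 200 mg q24h oxazolidinone
#: regimen in adults; configuration input, not a claim about any one study
EXAMPLE_PK_PARAMETERS = dict(
    cl_mean=6.9, cl_sd=1.5, v_mean=80.0, v_sd=16.0,
    ka_mean=1.2, ka_sd=0.5, f_mean=0.86, f_sd=0.08,
)


@dataclass(frozen=True)
class PKConfig:
    dose_mg: float = 200.0
    interval_h: float = 24.0
    n_doses: int = 7
    infusion_duration_h: float = 1.0
    routes: tuple[str, ...] = ("iv", "po")
    parameters: Mapping[str, float] = field(default_factory=lambda: dict(EXAMPLE_PK_PARAMETERS))
    n_sim: int = 1000
    percentiles: tuple[float, float] = (0.025, 0.975)
    eval_times_h: tuple[float, ...] = (24.0, 168.0)
    time_step_h: float = 0.1
    log_scale: bool = False

    def pk_parameters(self) -> PKParameters:
        return PKParameters(**self.parameters)

    def regimen(self, route: str) -> DoseRegimen:
        return DoseRegimen(
            dose=self.dose_mg,
            interval=self.interval_h,
            n_doses=self.n_doses,
            route=route,  # type: ignore[arg-type]
            infusion_duration=self.infusion_duration_h if route == "iv" else None,
        )


@dataclass(frozen=True)
class AssayConfig:
    geometry: AssayGeometry = field(default_factory=AssayGeometry)
    response: ResponseModel = field(default_factory=ResponseModel)
    calibration_levels: tuple[float, ...] = DEFAULT_CALIBRATION_LEVELS
    qc_levels: tuple[float, ...] = DEFAULT_QC_LEVELS
    lloq_candidate: float = 0.025
    llod_probe: float | None = 0.01
    top_calibrator: float = 10.0
    days: int = 3
    replicates_per_day: int = 3
    include_recovery: bool = True


@dataclass(frozen=True)
class AnalysisConfig:
    weighting: str = "none"
    baseline_region: tuple[float, float] = (1.0, 5.0)
    rt_tolerance_min: float = 0.2
    smoothing_width: int | None = None
    limits: AcceptanceLimits = field(default_factory=AcceptanceLimits)
    selectivity_analyte_fraction: float = 0.20
    selectivity_is_fraction: float = 0.05
    llod_sn: float = 3.0
    lloq_sn: float = 10.0


@dataclass(frozen=True)
class RunConfig:
    pk: PKConfig = field(default_factory=PKConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 1234
    outdir: str = "tdmassay_out"

    def validate(self) -> "RunConfig":
        if self.assay.lloq_candidate not in self.assay.calibration_levels:
            raise ConfigError(
                "assay.lloq_candidate: must be one of assay.calibration_levels"
            )
        for level in self.assay.qc_levels:
            if not min(self.assay.calibration_levels) <= level <= max(self.assay.calibration_levels):
                raise ConfigError(
                    f"assay.qc_levels: level {level} outside the calibration range"
                )
        for route in self.pk.routes:
            if route not in ("iv", "po"):
                raise ConfigError(f"pk.routes: unknown route {route!r}")
        try:
            self.pk.pk_parameters()
            for route in self.pk.routes:
                self.pk.regimen(route)
        except Exception as exc:  # surfaced with the block path
            raise ConfigError(f"pk: {exc}") from exc
        return self


def _build(cls, data: Mapping[str, Any], path: str):
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}.{sorted(unknown)[0]}: unknown field")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def from_dict(data: Mapping[str, Any]) -> RunConfig:
    """Build and validate a :class:`RunConfig` from nested plain mappings."""
    if not isinstance(data, Mapping):
        raise ConfigError("config root must be a mapping")
    known = {"pk", "assay", "analysis", "seed", "outdir"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{sorted(unknown)[0]}: unknown top-level field")
    pk = _build(PKConfig, data.get("pk", {}), "pk")
    assay_data = dict(data.get("assay", {}))
    geometry = _build(AssayGeometry, assay_data.pop("geometry", {}), "assay.geometry")
    response = _build(ResponseModel, assay_data.pop("response", {}), "assay.response")
    assay = _build(AssayConfig, assay_data, "assay")
    assay = dataclasses.replace(assay, geometry=geometry, response=response)
    analysis_data = dict(data.get("analysis", {}))
    limits = _build(AcceptanceLimits, analysis_data.pop("limits", {}), "analysis.limits")
    analysis = _build(AnalysisConfig, analysis_data, "analysis")
    analysis = dataclasses.replace(analysis, limits=limits)
    cfg = RunConfig(
        pk=pk,
        assay=assay,
        analysis=analysis,
        seed=int(data.get("seed", RunConfig.seed)),
        outdir=str(data.get("outdir", RunConfig.outdir)),
    )
    return cfg.validate()


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; ``None`` yields the validated defaults."""
    if path is None:
        return RunConfig().validate()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig().validate()
    return from_dict(raw)
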