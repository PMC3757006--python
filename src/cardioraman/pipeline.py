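"""End-to-end analysis pipeline: read → baseline → quantify → report.

Driven by a :class:`PipelineConfig` (loadable from YAML), consuming a
manifest CSV (``filename,condition,replicate``) of spectrum files and
producing a tidy per-spectrum indices table (CSV), a JSON run report
with per-condition summaries, group comparisons and percent-of-control
series, and an optional calibration sidecar.  Outputs are deterministic
for identical inputs and configuration (timestamps excluded).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .bands import BandLibrary, default_library
from .baseline import BaselineConfig, subtract_baseline
from .errors import CalibrationError, ValidationError
from .indices import (
    DEFAULT_Q,
    CalibrationConstant,
    calibrate_q,
    compute_indices,
    percent_of_control,
)
from .io import read_spectrum
from .quantify import zero_level_offset
from .stats import group_compare

INDEX_COLUMNS = [
    "filename", "condition", "replicate",
    "norm_604", "norm_750", "norm_1127", "norm_1337", "norm_1358", "norm_1377",
    "ratio_c_b", "f_dmb",
]

#: indices summarized per condition and compared across groups
_SUMMARY_KEYS = ["norm_604", "norm_750", "norm_1127", "norm_1337",
                 "norm_1358", "norm_1377", "ratio_c_b", "f_dmb"]


class PipelineConfig(BaseModel):
    """Configuration of one analysis run."""

    manifest: Path
    band_library: Path | None = None
    dialect: Literal["two_column", "jcamp_dx"] = "two_column"
    baseline: dict = Field(default_factory=dict)
    sum_range: tuple[float, float] = (520.0, 1750.0)
    mode: Literal["height", "fit"] = "fit"
    q_constant: float | None = None
    calibration_oxy: list[Path] | None = None
    calibration_reduced: list[Path] | None = None
    control_condition: str = "control"
    output_dir: Path = Path("cardioraman_out")
    seed: int = 0

    @model_validator(mode="after")
    def _one_calibration_source(self) -> "PipelineConfig":
        has_const = self.q_constant is not None
        has_spectra = self.calibration_oxy is not None or self.calibration_reduced is not None
        if has_const and has_spectra:
            raise ValueError("give either q_constant or calibration spectra, not both")
        if self.calibration_oxy is not None and self.calibration_reduced is None:
            raise ValueError("calibration_reduced required with calibration_oxy")
        if self.calibration_reduced is not None and self.calibration_oxy is None:
            raise ValueError("calibration_oxy required with calibration_reduced")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        # resolve relative paths against the config file location
        base = Path(path).parent
        return cfg.model_copy(update=_resolved_paths(cfg, base))

    def content_hash(self) -> str:
        payload = self.model_dump(mode="json")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _resolved_paths(cfg: PipelineConfig, base: Path) -> dict:
    def res(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    update: dict = {"manifest": res(cfg.manifest), "output_dir": res(cfg.output_dir)}
    if cfg.band_library is not None:
        update["band_library"] = res(cfg.band_library)
    if cfg.calibration_oxy is not None:
        update["calibration_oxy"] = [res(p) for p in cfg.calibration_oxy]
        update["calibration_reduced"] = [res(p) for p in cfg.calibration_reduced]
    return update


class GroupStats(BaseModel):
    n: int
    mean: float | None
    se: float | None


class ComparisonReport(BaseModel):
    omnibus_p: float
    pairwise_p: dict[str, float]


class RunReport(BaseModel):
    """Validated payload of one pipeline run."""

    indices: list[dict]
    condition_summaries: dict[str, dict[str, GroupStats]]
    comparisons: dict[str, ComparisonReport]
    percent_of_control: dict[str, dict[str, float | None]]
    calibration: dict
    provenance: dict

    @classmethod
    def json_schema_text(cls) -> str:
        return json.dumps(cls.model_json_schema(), indent=2)


def _load_calibration(config: PipelineConfig, library: BandLibrary,
                      baseline: BaselineConfig) -> CalibrationConstant:
    if config.calibration_oxy is not None:
        def corrected(path):
            spectrum = read_spectrum(path, config.dialect)
            corr, _ = subtract_baseline(spectrum, baseline)
            return corr

        try:
            oxy = [corrected(p) for p in config.calibration_oxy]
            red = [corrected(p) for p in config.calibration_reduced]
            return calibrate_q(oxy, red, library=library, mode=config.mode)
        except FileNotFoundError as exc:
            raise CalibrationError(f"calibration spectrum missing: {exc}") from exc
    if config.q_constant is not None:
        return CalibrationConstant(q=config.q_constant, provenance="config constant")
    return DEFAULT_Q


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis described by ``config``.

    Fails fast — before any output is written — on missing spectrum
    files, empty manifests or calibration problems.  Writes
    ``indices.csv``, ``report.json`` and ``calibration.json`` into
    ``config.output_dir`` and returns the report.
    """
    manifest = pd.read_csv(config.manifest)
    required = {"filename", "condition"}
    if not required.issubset(manifest.columns):
        raise ValidationError(
            f"manifest must have columns {sorted(required)}, got {list(manifest.columns)}"
        )
    if manifest.empty:
        raise ValidationError("manifest lists no spectra")
    if "replicate" not in manifest.columns:
        manifest["replicate"] = range(len(manifest))

    library = (BandLibrary.from_csv(config.band_library)
               if config.band_library else default_library())
    baseline_cfg = BaselineConfig(**config.baseline)

    base_dir = Path(config.manifest).parent
    paths = []
    for fname in manifest["filename"]:
        path = Path(fname)
        if not path.is_absolute():
            path = base_dir / path
        if not path.exists():
            raise ValidationError(f"spectrum file missing: {path}")
        paths.append(path)

    calibration = _load_calibration(config, library, baseline_cfg)

    rows = []
    for path, record in zip(paths, manifest.to_dict("records")):
        spectrum = read_spectrum(path, config.dialect)
        corrected, _ = subtract_baseline(spectrum, baseline_cfg)
        offset = zero_level_offset(corrected, library)
        corrected = corrected.with_intensities(corrected.intensities - offset)
        idx = compute_indices(
            corrected, library=library, q=calibration,
            mode=config.mode, sum_range=config.sum_range,
        )
        row = {
            "filename": record["filename"],
            "condition": record["condition"],
            "replicate": record["replicate"],
        }
        row.update({k: getattr(idx, k) for k in _SUMMARY_KEYS})
        rows.append(row)
    table = pd.DataFrame(rows, columns=INDEX_COLUMNS)

    summaries: dict[str, dict[str, GroupStats]] = {}
    for condition, sub in table.groupby("condition", sort=False):
        summaries[condition] = {}
        for key in _SUMMARY_KEYS:
            values = sub[key].to_numpy(dtype=float)
            values = values[np.isfinite(values)]
            if values.size == 0:
                summaries[condition][key] = GroupStats(n=0, mean=None, se=None)
                continue
            se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
            summaries[condition][key] = GroupStats(
                n=int(values.size), mean=float(values.mean()), se=se
            )

    comparisons: dict[str, ComparisonReport] = {}
    conditions = list(dict.fromkeys(table["condition"]))
    if len(conditions) >= 2:
        for key in _SUMMARY_KEYS:
            groups = {}
            for condition in conditions:
                vals = table.loc[table["condition"] == condition, key].to_numpy(float)
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    groups[condition] = vals
            if len(groups) < 2:
                continue
            result = group_compare(groups)
            comparisons[key] = ComparisonReport(
                omnibus_p=result.omnibus_p,
                pairwise_p={f"{a}|{b}": p for (a, b), p in result.pairwise_p.items()},
            )

    percent: dict[str, dict[str, float | None]] = {}
    control = table[table["condition"] == config.control_condition]
    if not control.empty:
        for key in _SUMMARY_KEYS:
            ctrl_vals = control[key].to_numpy(float)
            ctrl_vals = ctrl_vals[np.isfinite(ctrl_vals)]
            if ctrl_vals.size == 0 or ctrl_vals.mean() == 0:
                continue
            percent[key] = {}
            for condition in conditions:
                vals = table.loc[table["condition"] == condition, key].to_numpy(float)
                vals = vals[np.isfinite(vals)]
                percent[key][condition] = (
                    float(np.mean(percent_of_control(vals, ctrl_vals)))
                    if vals.size else None
                )

    report = RunReport(
        indices=table.to_dict("records"),
        condition_summaries=summaries,
        comparisons=comparisons,
        percent_of_control=percent,
        calibration=asdict(calibration),
        provenance={
            "package_version": __version__,
            "config_hash": config.content_hash(),
            "control_condition": config.control_condition,
            "mode": config.mode,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "indices.csv", index=False, float_format="%.10g")
    (outdir / "report.json").write_text(
        json.dumps(report.model_dump(mode="json"), indent=2) + "\n"
    )
    calibration.to_json(outdir / "calibration.json")
    return report
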