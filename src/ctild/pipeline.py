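"""Pipeline orchestration: phantom/input -> segmentation -> densitometry
(-> cohort statistics), with a reproducibility manifest.

Configuration lives in YAML; every default matches the reference
parameters (density bands -1024/-700/-200 HU, severe-fibrosis cutoff 7).
The numeric summary JSON contains no timestamps, so a rerun with the same
configuration and seed is byte-identical; volatile metadata (timestamps)
goes to the manifest only.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as ctio
from .cohort import CohortSpec, generate_cohort
from .densitometry import DensityBands, fibrosis_fraction
from .errors import ConfigurationError, CTILDError, PipelineError
from .phantom import PhantomSpec, generate_phantom
from .segmentation import SegmentationParams, segment_lungs
from .stats import criterion_table, icc_two_way, pearson_regression, roc_analysis
from .warrick import DEFAULT_SEVERE_CUTOFF

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    input_series: Path | None = None
    phantom: PhantomSpec | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    bands: DensityBands = field(default_factory=DensityBands)
    warrick_cutoff: float = DEFAULT_SEVERE_CUTOFF
    cohort: CohortSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.output_dir is None:
            raise ConfigurationError("config must name an output directory")
        if self.input_series is None and self.phantom is None and self.cohort is None:
            raise ConfigurationError(
                "config must provide an input series, a phantom spec, or a cohort spec"
            )
        if self.input_series is not None and not Path(self.input_series).exists():
            raise ConfigurationError(f"input series {self.input_series} does not exist")
        if self.warrick_cutoff < 0:
            raise ConfigurationError("warrick cutoff must be >= 0")
        self.bands.validate()
        self.segmentation.validate()

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        if "output_dir" not in raw:
            raise ConfigurationError("config must name an output directory")
        seed = int(raw.get("seed", 0))
        phantom = None
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            ph.setdefault("seed", seed)
            if "grid_shape" in ph:
                ph["grid_shape"] = tuple(ph["grid_shape"])
            if "spacing_mm" in ph:
                ph["spacing_mm"] = tuple(ph["spacing_mm"])
            phantom = PhantomSpec(**ph)
        seg = SegmentationParams(
            **{
                k: tuple(v) if k == "lung_band" else v
                for k, v in raw.get("segmentation", {}).items()
            }
        )
        bands_raw = raw.get("bands")
        if bands_raw is None:
            bands = DensityBands()
        elif isinstance(bands_raw, (list, tuple)) and len(bands_raw) == 3:
            bands = DensityBands(*[int(b) for b in bands_raw])
        else:
            raise ConfigurationError("bands must be a [lower, nonfibrotic, total] triple")
        cohort = None
        if "cohort" in raw:
            co = dict(raw["cohort"])
            co.setdefault("seed", seed)
            cohort = CohortSpec.from_mappings(
                mean_sd=co.pop("mean_sd", None), ranges=co.pop("ranges", None), **co
            )
        return cls(
            output_dir=Path(raw["output_dir"]),
            input_series=Path(raw["input_series"]) if "input_series" in raw else None,
            phantom=phantom,
            segmentation=seg,
            bands=bands,
            warrick_cutoff=float(raw.get("warrick_cutoff", DEFAULT_SEVERE_CUTOFF)),
            cohort=cohort,
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(raw)

    def canonical(self) -> dict[str, Any]:
        def plain(obj: Any) -> Any:
            if hasattr(obj, "__dict__") or hasattr(obj, "__dataclass_fields__"):
                from dataclasses import asdict, is_dataclass

                if is_dataclass(obj):
                    return plain(asdict(obj))
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, (int, float, str, bool)) or obj is None:
                return obj
            return str(obj)

        return {
            "output_dir": str(self.output_dir),
            "input_series": str(self.input_series) if self.input_series else None,
            "phantom": plain(self.phantom),
            "segmentation": plain(self.segmentation),
            "bands": plain(self.bands),
            "warrick_cutoff": self.warrick_cutoff,
            "cohort": plain(self.cohort),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    software_version: str
    outputs: dict[str, str]  # relative path -> sha256
    started_at: float
    finished_at: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "config_hash": self.config_hash,
            "software_version": self.software_version,
            "outputs": self.outputs,
            "started_at": self.started_at,
            "finished_at": self.finished_at,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the configured stages and write reports plus a manifest.

    Any stage failure is re-raised as
    :class:`~ctild.errors.PipelineError` naming the stage.
    """
    started = time.time()
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    outputs: dict[str, str] = {}

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and isinstance(exc, CTILDError):
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    volume = None
    truth = None
    if config.phantom is not None:
        with stage("phantom"):
            ph = generate_phantom(config.phantom)
            volume = ph.volume
            truth = ph.truth_fibrotic_fraction
            summary["phantom"] = {
                "truth_fibrotic_fraction_pct": truth,
                "n_truth_lung_voxels": ph.truth_mask.n_voxels,
            }
    elif config.input_series is not None:
        with stage("read"):
            volume = ctio.read_ct_series(config.input_series)

    if volume is not None:
        with stage("segment"):
            mask = segment_lungs(volume, config.segmentation)
            mask_path = out / "mask.nii.gz"
            ctio.write_mask_nifti(mask, mask_path, spacing_mm=volume.spacing_mm)
        with stage("quantify"):
            result = fibrosis_fraction(volume, mask, config.bands)
            summary["densitometry"] = result.to_dict()

    if config.cohort is not None:
        with stage("cohort"):
            table = generate_cohort(config.cohort)
            cohort_path = out / "cohort.csv"
            ctio.write_cohort_csv(table, cohort_path)
        with stage("stats"):
            summary["statistics"] = cohort_statistics_report(
                table, cutoff=config.warrick_cutoff, out_dir=out
            )

    summary_path = out / "summary.json"
    ctio.write_json_report(summary, summary_path)
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            outputs[str(p.relative_to(out))] = _sha256(p)

    config_hash = hashlib.sha256(
        json.dumps(config.canonical(), sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash,
        software_version=__version__,
        outputs=outputs,
        started_at=started,
        finished_at=time.time(),
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return manifest


def cohort_statistics_report(
    table,
    cutoff: float = DEFAULT_SEVERE_CUTOFF,
    score_column: str = "cam_extent_pct",
    dichotomize_column: str = "warrick_mean",
    out_dir: Path | None = None,
) -> dict[str, Any]:
    """Correlations, reader ICC and ROC/criterion-table analysis of a
    cohort table; optionally writes the criterion table and ROC
    coordinates as CSV."""
    import numpy as np
    import pandas as pd

    cam = table[score_column].to_numpy(dtype=float)
    report: dict[str, Any] = {"n": int(len(table)), "cutoff": cutoff}

    correlations = {}
    for column in ("warrick_mean", "fvc_pct", "fev1_pct", "dlco_pct"):
        if column in table.columns:
            reg = pearson_regression(cam, table[column].to_numpy(dtype=float))
            correlations[column] = {
                "r": reg.r,
                "slope": reg.slope,
                "intercept": reg.intercept,
                "p_value": reg.p_value,
            }
    report["correlations"] = correlations

    if {"warrick_reader1", "warrick_reader2"}.issubset(table.columns):
        ratings = table[["warrick_reader1", "warrick_reader2"]].to_numpy(dtype=float)
        report["reader_icc"] = icc_two_way(ratings)

    labels = table[dichotomize_column].to_numpy(dtype=float) > cutoff
    roc = roc_analysis(cam, labels)
    rows = criterion_table(roc)
    report["roc"] = {
        "auc": roc.auc,
        "auc_se": roc.auc_se,
        "optimal_threshold": roc.optimal_threshold,
        "n_positive": roc.n_positive,
        "n_negative": roc.n_negative,
    }

    if out_dir is not None:
        crit = pd.DataFrame(
            {
                "criterion": [r.criterion for r in rows],
                "sensitivity_pct": [r.sensitivity_pct for r in rows],
                "sensitivity_ci_low": [r.sensitivity_ci[0] for r in rows],
                "sensitivity_ci_high": [r.sensitivity_ci[1] for r in rows],
                "specificity_pct": [r.specificity_pct for r in rows],
                "specificity_ci_low": [r.specificity_ci[0] for r in rows],
                "specificity_ci_high": [r.specificity_ci[1] for r in rows],
                "lr_pos": [r.lr_pos for r in rows],
                "lr_neg": [r.lr_neg for r in rows],
                "ppv_pct": [r.ppv_pct for r in rows],
                "npv_pct": [r.npv_pct for r in rows],
            }
        )
        crit.to_csv(out_dir / "criterion_table.csv", index=False, lineterminator="\n")
        coords = pd.DataFrame(
            {
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivities,
                "specificity": roc.specificities,
                "fpr": 1.0 - np.asarray(roc.specificities),
            }
        )
        coords.to_csv(out_dir / "roc_coordinates.csv", index=False, lineterminator="\n")
    return report
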