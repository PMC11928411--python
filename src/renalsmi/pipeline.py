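"""End-to-end orchestration: simulate -> per-modality analysis -> statistics.

A run is described by a :class:`RunConfig` (usually loaded from YAML): which
stages to execute, their parameters, and one global seed. Stage seeds are
derived from the global seed through ``numpy.random.SeedSequence(seed,
spawn_key=(stage_index,))``, a stable documented derivation, so any stage
can be rerun in isolation and reproduce its output bit-for-bit.

Every run writes a ``manifest.json`` carrying the config hash, the global
seed, the per-stage seeds, the defaults actually used, and a SHA-256 digest
of every output file; identical config + seed therefore yields an identical
manifest. On stage failure the partial outputs are kept and the manifest
records the failing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .ceus import OnsetParams, compute_ttp
from .errors import PipelineError, ValidationError
from .hemodynamics import (
    classify_venous_pattern,
    resistance_index,
    venous_impedance_index,
)
from .histology import edema_fraction, segment_stain_classes
from .simulate import (
    CineSpec,
    CohortSpec,
    TicSpec,
    TraceSpec,
    generate_cine,
    generate_cohort,
    generate_histology,
    generate_tic,
    generate_velocity_trace,
)
from .smi import FlowColorModel, area_ratio_series, compute_irpi
from .stats import summarize_cohort

log = logging.getLogger("renalsmi")

STAGES = ("cine", "tic", "trace", "histology", "cohort")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    irpi_method: str = "per_cycle_median"
    smoothing_window: float = 0.0
    onset_k: float = 3.0
    onset_baseline_window: float = 1.0
    continuous_vii: float = 0.15
    zero_flow_frac: float = 0.05
    cine_path: Path | None = None  # analyze an existing cine instead of simulating
    roi_path: Path | None = None
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"stages: unknown {sorted(unknown)}")
        for name in ("cine_path", "roi_path"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise ValidationError(f"{name}: file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in doc.items() if k in known}
        kwargs["extra"] = {k: v for k, v in doc.items() if k not in known}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "out_dir" not in kwargs:
            raise ValidationError("config: 'out_dir' is required")
        return cls(**kwargs)

    def canonical(self) -> str:
        doc = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in self.__dict__.items()
        }
        doc["stages"] = list(self.stages)
        return json.dumps(doc, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed (< 2**31) derived from the global seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "defaults_used": {
            "irpi_method": config.irpi_method,
            "smoothing_window": config.smoothing_window,
            "onset_k": config.onset_k,
            "onset_baseline_window": config.onset_baseline_window,
            "continuous_vii": config.continuous_vii,
            "zero_flow_frac": config.zero_flow_frac,
        },
        "outputs": {},
        "status": "ok",
    }
    for key, val in manifest["defaults_used"].items():
        log.info("default %s = %s", key, val)

    current = "setup"
    try:
        if "cine" in config.stages:
            current = "cine"
            seed = manifest["stage_seeds"]["cine"]
            if config.cine_path is not None:
                cine = rio.read_cine(config.cine_path)
                if config.roi_path is None:
                    raise ValidationError("roi_path required with cine_path")
                roi = load_roi(config.roi_path, cine.shape)
            else:
                cine, truth = generate_cine(CineSpec(seed=seed))
                roi = truth.roi_set()
                rio.write_cine(out / "cine.tif", cine)
                rio.write_roi_labels(out / "roi_labels.png", roi)
            series = area_ratio_series(
                cine, roi, FlowColorModel(), config.smoothing_window
            )
            import pandas as pd

            rows = []
            for label, s in series.items():
                rio.write_series_csv(out / f"area_ratio_{label}.csv", s)
                res = compute_irpi(s, method=config.irpi_method)
                rows.append(
                    {
                        "roi_label": label,
                        "method": res.method,
                        "irpi": res.irpi,
                        "a_max": res.a_max,
                        "a_min": res.a_min,
                        "n_cycles": res.n_cycles,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "irpi.csv", index=False)

        if "tic" in config.stages:
            current = "tic"
            seed = manifest["stage_seeds"]["tic"]
            import pandas as pd

            rows = []
            for roi_label in ("cortex", "medulla"):
                tic, _ = generate_tic(
                    TicSpec(seed=seed + (roi_label == "medulla"))
                )
                tic.roi_label = roi_label
                rio.write_tic_csv(out / f"tic_{roi_label}.csv", tic)
                params = OnsetParams(
                    baseline_window=config.onset_baseline_window, k=config.onset_k
                )
                res = compute_ttp(tic, params)
                rows.append(
                    {
                        "roi_label": roi_label,
                        "onset_time": res.onset_time,
                        "peak_time": res.peak_time,
                        "ttp": res.ttp,
                        "baseline": res.baseline,
                        "peak_intensity": res.peak_intensity,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "ttp.csv", index=False)

        if "trace" in config.stages:
            current = "trace"
            seed = manifest["stage_seeds"]["trace"]
            import pandas as pd

            rows = []
            cases = [
                ("arterial", 100.0, 39.0),
                ("venous_continuous", 32.0, 28.0),
                ("venous_biphasic", 30.0, 21.0),
                ("venous_monophasic", 30.0, 0.5),
            ]
            for i, (kind, peak, trough) in enumerate(cases):
                trace, truth = generate_velocity_trace(
                    kind, peak, trough, TraceSpec(), seed=seed + i
                )
                rio.write_trace_csv(out / f"trace_{kind}.csv", trace)
                row = {"kind": kind, "ri": None, "vii": None, "pattern": None}
                if trace.vessel_kind == "artery":
                    row["ri"] = resistance_index(trace)
                else:
                    row["vii"] = venous_impedance_index(trace)
                    row["pattern"] = classify_venous_pattern(
                        trace, config.continuous_vii, config.zero_flow_frac
                    )
                rows.append(row)
            pd.DataFrame(rows).to_csv(out / "doppler.csv", index=False)

        if "histology" in config.stages:
            current = "histology"
            seed = manifest["stage_seeds"]["histology"]
            import imageio.v3 as iio
            import pandas as pd

            image, truth = generate_histology(seed=seed)
            iio.imwrite(out / "histology.png", image)
            masks = segment_stain_classes(image)
            res = edema_fraction(masks)
            pd.DataFrame(
                [
                    {
                        "edema_fraction": res.edema_fraction,
                        "n_edema": res.n_edema,
                        "n_parenchyma": res.n_parenchyma,
                        "tissue_area": res.tissue_area,
                        "planted_fraction": truth.realized_fraction,
                    }
                ]
            ).to_csv(out / "edema.csv", index=False)

        if "cohort" in config.stages:
            current = "cohort"
            seed = manifest["stage_seeds"]["cohort"]
            table, _ = generate_cohort(CohortSpec(seed=seed))
            rio.write_cohort_csv(out / "cohort.csv", table)
            report = summarize_cohort(table)
            report.to_csv(out / "comparisons.csv", out / "correlations.csv")
    except Exception as exc:
        manifest["status"] = f"failed:{current}"
        manifest["error"] = str(exc)
        _finish_manifest(out, manifest)
        raise PipelineError(current, str(exc)) from exc

    _finish_manifest(out, manifest)
    return manifest


def _finish_manifest(out: Path, manifest: dict) -> None:
    for p in sorted(out.glob("*")):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )


def load_roi(path, shape: tuple[int, int]):
    """ROI from either a GeoJSON polygon file or a PNG label image."""
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        return rio.rasterize_polygons(rio.read_roi_geojson(path), shape)
    return rio.read_roi_labels(path)
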