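"""One-command orchestration: cohort -> features -> deltas -> statistics.

Every stage writes its table under the output directory so that any
stage can be re-run or audited from the intermediates:

    manifest.csv, doses.csv   cohort design and point doses
    features.csv              one row per capture, 18 feature columns
    delta.csv                 baseline ratios, same shape
    patient_values.csv        point-averaged per-breast deltas
    summary.csv               cross-patient mean +/- SD per cell
    stats_report.json / .csv  ANOVA, paired tests, correlations
    run_log.txt               seed, parameters, row counts

Reruns with the same configuration reproduce identical numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .delta import aggregate_points, build_feature_table, delta_ratios, summarize
from .glcm import GLCMParams
from .stats import run_full_inference
from .synthetic import SyntheticConfig, doses_frame, iter_cohort, load_image

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = logging.getLogger("derma_radiomics")


@dataclass
class RunConfig:
    out_dir: Path
    synthetic: SyntheticConfig | None = None
    manifest: Path | None = None  # CSV with key columns + path, for real captures
    doses_path: Path | None = None
    glcm: GLCMParams = field(default_factory=GLCMParams)
    roi_radius: float = 300.0
    alpha: float = 0.05
    baseline: str = "Before_RT"
    write_images: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.manifest is None):
            raise ValueError("provide exactly one of a synthetic block or an image manifest")
        if 2 * self.roi_radius > min(
            *( (self.synthetic.image_height, self.synthetic.image_width)
               if self.synthetic else (10**9, 10**9) )
        ):
            raise ValueError("image dimensions must be at least twice the ROI radius")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML document."""
    raw = yaml.safe_load(Path(path).read_text())
    syn = raw.get("synthetic")
    glcm = raw.get("glcm", {})
    return RunConfig(
        out_dir=Path(raw["out_dir"]),
        synthetic=SyntheticConfig(**syn) if syn is not None else None,
        manifest=Path(raw["manifest"]) if raw.get("manifest") else None,
        doses_path=Path(raw["doses"]) if raw.get("doses") else None,
        glcm=GLCMParams(**glcm),
        roi_radius=float(raw.get("roi_radius", 300.0)),
        alpha=float(raw.get("alpha", 0.05)),
        baseline=raw.get("baseline", "Before_RT"),
        write_images=bool(raw.get("write_images", False)),
    )


def _iter_manifest_images(manifest: pd.DataFrame):
    for _, row in manifest.iterrows():
        yield load_image(row["path"], row.to_dict())


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write all tables under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.perf_counter()
    try:
        log.info("derma-radiomics %s", __version__)
        if config.synthetic is not None:
            syn = config.synthetic
            log.info("synthetic cohort: %d patients, seed %d", syn.n_patients, syn.seed)
            doses = doses_frame(syn)
            if config.write_images:
                from .synthetic import generate_cohort

                generate_cohort(syn, out_dir=out / "images")
            images = (img for img, _ in iter_cohort(syn))
            config_dump = dataclasses.asdict(syn)
        else:
            manifest = pd.read_csv(config.manifest)
            if config.doses_path is None:
                raise ValueError("an image manifest requires a doses CSV")
            doses = pd.read_csv(config.doses_path)
            images = _iter_manifest_images(manifest)
            config_dump = {"manifest": str(config.manifest)}

        log.info("extracting features (Ng=%d, d=%d, ROI radius %g, dialect %s)",
                 config.glcm.n_levels, config.glcm.displacement,
                 config.roi_radius, config.glcm.dialect)
        features = build_feature_table(
            images, params=config.glcm, roi_radius=config.roi_radius,
            baseline=config.baseline,
        )
        log.info("features: %d rows [%.1f s]", len(features), time.perf_counter() - t0)

        deltas = delta_ratios(features, baseline=config.baseline)
        patient_values = aggregate_points(deltas)
        summary = summarize(patient_values)
        report = run_full_inference(
            patient_values, deltas, doses, alpha=config.alpha, baseline=config.baseline
        )

        if config.synthetic is not None:
            from .synthetic import cohort_manifest

            cohort_manifest(config.synthetic, root=out / "images").to_csv(
                out / "manifest.csv", index=False
            )
        doses.to_csv(out / "doses.csv", index=False)
        features.to_csv(out / "features.csv", index=False)
        deltas.to_csv(out / "delta.csv", index=False)
        patient_values.to_csv(out / "patient_values.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        report.anova.to_csv(out / "stats_anova.csv", index=False)
        report.dose_correlation.to_csv(out / "stats_dose_correlation.csv", index=False)
        (out / "stats_report.json").write_text(
            json.dumps(report.to_json_dict(), indent=1, default=str)
        )
        (out / "run_config.json").write_text(
            json.dumps(
                {
                    "version": __version__,
                    "glcm": dataclasses.asdict(config.glcm),
                    "roi_radius": config.roi_radius,
                    "alpha": config.alpha,
                    "input": config_dump,
                },
                indent=1,
                default=str,
            )
        )
        log.info("pipeline complete [%.1f s]", time.perf_counter() - t0)
        return {
            "doses": doses,
            "features": features,
            "deltas": deltas,
            "patient_values": patient_values,
            "summary": summary,
            "report": report,
        }
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
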