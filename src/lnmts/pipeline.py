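"""End-to-end orchestration: simulate/load -> features -> cutoffs -> classify -> report.

A run is driven by a single :class:`RunConfig` (YAML on disk; CLI flags
override file values).  Every run writes a resolved copy of its
configuration plus a plain-text log recording package/library versions,
the resolved cutoffs and the geometry conventions in force, so outputs are
reproducible and auditable.  All randomness is funneled through the
explicit per-stage seeds in the config; stage failures abort with a
stage-tagged error.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .feature_extraction import LymphNodeFeatureExtractor
from .io_formats import (
    AnnotatedVolume,
    read_annotated_volume,
    read_cohort_table,
    cohort_to_frame,
    write_annotated_volume,
)
from .risk_model import (
    BOUNDARY_NOTE,
    NAMED_CUTOFFS,
    RiskStratifier,
    stratified_report,
)
from .synthetic_data import (
    make_phantom,
    random_phantom_spec,
    survival_from_features,
)

logger = logging.getLogger("lnmts")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage it occurred in."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str
    mode: str = "simulate"                  # simulate | load
    seed: int = 0
    # simulate mode
    n_patients: int = 300
    planted_cutpoints: dict = field(
        default_factory=lambda: {"tlnv": 100.0, "tlnd": 150.0}
    )
    planted_hazard_ratios: dict = field(
        default_factory=lambda: {"tlnv": 0.45, "tlnd": 0.45}
    )
    censoring_rate: float = 0.0
    # load mode
    masks_dir: str | None = None
    cohort_csv: str | None = None
    # analysis
    volume_mode: str = "accumulated"
    cutoff_source: str = "learn"            # learn | paper-2025 | explicit
    explicit_cutoffs: dict | None = None
    endpoint: str = "os"
    min_group_frac: float = 0.10
    covariate_cols: list = field(default_factory=list)
    make_plots: bool = True


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML run config; keyword overrides take precedence."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise PipelineError("config", f"unknown config key(s) {sorted(unknown)}")
    return RunConfig(**data)


def _simulate_inputs(config: RunConfig, outdir: Path) -> list[AnnotatedVolume]:
    """Draw one random phantom per patient and write masks + sidecars."""
    rng = np.random.default_rng(config.seed)
    masks_dir = outdir / "masks"
    masks_dir.mkdir(parents=True, exist_ok=True)
    volumes = []
    for i in range(config.n_patients):
        spec = random_phantom_spec(rng, patient_id=f"sim-{i:05d}")
        volume, _ = make_phantom(spec)
        write_annotated_volume(
            volume,
            masks_dir / f"{volume.patient_id}.nii.gz",
            masks_dir / f"{volume.patient_id}.yaml",
        )
        volumes.append(volume)
    return volumes


def _load_inputs(config: RunConfig) -> tuple[list[AnnotatedVolume], pd.DataFrame]:
    if not config.masks_dir or not Path(config.masks_dir).is_dir():
        raise PipelineError("inputs", f"mask directory not found: {config.masks_dir}")
    if not config.cohort_csv or not Path(config.cohort_csv).is_file():
        raise PipelineError("inputs", f"cohort table not found: {config.cohort_csv}")
    masks_dir = Path(config.masks_dir)
    volumes = []
    for image_path in sorted(masks_dir.glob("*.nii*")):
        sidecar = image_path.with_suffix("").with_suffix(".yaml")
        if not sidecar.exists():
            sidecar = masks_dir / (image_path.name.split(".")[0] + ".yaml")
        volumes.append(
            read_annotated_volume(
                image_path, sidecar if sidecar.exists() else None
            )
        )
    if not volumes:
        raise PipelineError("inputs", f"no NIfTI masks in {masks_dir}")
    cohort = cohort_to_frame(read_cohort_table(config.cohort_csv))
    return volumes, cohort


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    Stage order: inputs -> features -> cutoffs -> classify -> report.
    Deterministic given the config seeds.
    """
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"lnmts {__version__} (numpy {np.__version__}, pandas {pd.__version__})",
        BOUNDARY_NOTE,
        "through-plane rule: delta_S*G + (delta_S-1)*T; same-slice (delta_S=0) term = 0",
        f"volume mode: {config.volume_mode}",
    ]

    # stage: inputs
    if config.mode == "simulate":
        volumes = _simulate_inputs(config, outdir)
        cohort = None  # survival planted after features are extracted
    elif config.mode == "load":
        volumes, cohort = _load_inputs(config)
    else:
        raise PipelineError("inputs", f"unknown mode {config.mode!r}")
    log_lines.append(f"inputs: {len(volumes)} volumes, mode={config.mode}")

    # stage: features
    try:
        extractor = LymphNodeFeatureExtractor(mode=config.volume_mode)
        features = extractor.fit_transform(volumes).reset_index()
    except Exception as exc:
        raise PipelineError("features", str(exc)) from exc
    features.to_csv(outdir / "features.csv", index=False)

    if config.mode == "simulate":
        cohort = survival_from_features(
            features[["patient_id", "tlnv", "tlnd"]],
            cutpoints=config.planted_cutpoints,
            hazard_ratios=config.planted_hazard_ratios,
            seed=config.seed + 1,
            censoring_rate=config.censoring_rate,
        )
        cohort.to_csv(outdir / "cohort.csv", index=False)
    merged = features.merge(
        cohort[[c for c in cohort.columns if c not in ("tlnv", "tlnd")]],
        on="patient_id",
        validate="one_to_one",
    )
    if merged.empty:
        raise PipelineError("features", "no patients shared between masks and cohort")

    # stage: cutoffs
    time_col = f"{config.endpoint}_time"
    event_col = f"{config.endpoint}_event"
    try:
        if config.cutoff_source == "learn":
            model = RiskStratifier(
                min_group_frac=config.min_group_frac, endpoint=config.endpoint
            ).fit(
                merged[["tlnv", "tlnd"]],
                (merged[time_col].to_numpy(), merged[event_col].to_numpy()),
            )
        elif config.cutoff_source in NAMED_CUTOFFS:
            model = RiskStratifier(cutoffs=config.cutoff_source).fit(
                merged[["tlnv", "tlnd"]]
            )
        elif config.cutoff_source == "explicit":
            if not config.explicit_cutoffs:
                raise ValueError("cutoff_source=explicit requires explicit_cutoffs")
            model = RiskStratifier(cutoffs=config.explicit_cutoffs).fit(
                merged[["tlnv", "tlnd"]]
            )
        else:
            raise ValueError(f"unknown cutoff_source {config.cutoff_source!r}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("cutoffs", str(exc)) from exc
    cutoffs = {
        "tlnv": model.cutoff_tlnv_,
        "tlnd": model.cutoff_tlnd_,
        "source": config.cutoff_source,
        "endpoint": config.endpoint,
    }
    (outdir / "cutoffs.yaml").write_text(yaml.safe_dump(cutoffs, sort_keys=True))
    log_lines.append(f"cutoffs: {cutoffs}")

    # stage: classify
    merged["subtype"] = model.predict(merged[["tlnv", "tlnd"]])
    merged[["patient_id", "tlnv", "tlnd", "subtype"]].to_csv(
        outdir / "subtypes.csv", index=False
    )

    # stage: report
    report_dir = outdir / "report"
    try:
        report = stratified_report(
            merged,
            time_col=time_col,
            event_col=event_col,
            endpoint=config.endpoint,
            covariate_cols=config.covariate_cols or None,
        )
        report.write(report_dir)
        if config.make_plots:
            report.plot_km(report_dir / f"{config.endpoint}_km.png")
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc
    if report.absent_subtypes:
        log_lines.append(f"absent subtypes: {report.absent_subtypes}")

    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    )
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
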