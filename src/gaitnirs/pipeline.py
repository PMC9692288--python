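"""End-to-end orchestration: simulate/ingest → optics → preprocess → GLM →
group statistics → outcome regression, with every intermediate persisted.

A single global seed fans out to per-stage seeds through a documented rule
(``stage_seed``: SeedSequence over (seed, stage index)), so each stage is
independently reproducible.  Channel numbering is 1-based everywhere
user-facing; internal arrays are 0-based with the conversion confined to the
I/O boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as gio
from .glm import fit_hemoglobin
from .montage import default_montage, load_brodmann_lookup
from .optics import recording_to_hemoglobin
from .paradigm import Paradigm, default_paradigm
from .preprocess import FilterSpec, WaveletSpec, preprocess
from .regression import assemble_features, loso_gpr
from .stats import channelwise_anova, channelwise_posthoc, significance_map
from .synthetic import CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)

_STAGE_IDS = {"simulate": 1, "preprocess": 2, "glm": 3, "stats": 4, "predict": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Every knob of the synthetic end-to-end run, JSON-round-trippable."""

    out_dir: str = "gaitnirs_out"
    seed: int = 0
    n_subjects: int = 8
    sessions: tuple[str, ...] = ("T0", "T1", "T2")
    fs: float = 10.0
    gmfm_link_slope: float = 60.0
    gmfm_noise_sd: float = 3.0
    filter_order: int = 3
    filter_band: tuple[float, float] = (0.01, 0.4)
    wavelet_family: str = "db5"
    wavelet_alpha: float = 0.1
    drift_order: int = 1
    anova_family: int | None = None
    posthoc_family: int | None = None
    layout: str = "per_timepoint"
    select_per_fold: bool = False
    max_features: int | None = 3
    format: str = "csv"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.format not in ("csv", "snirf"):
            raise ValueError("format must be 'csv' or 'snirf'")
        if self.layout not in ("per_timepoint", "concat_sessions", "delta"):
            raise ValueError(f"unknown layout {self.layout!r}")

    def to_json(self) -> str:
        d = asdict(self)
        d["sessions"] = list(self.sessions)
        d["filter_band"] = list(self.filter_band)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["sessions"] = tuple(d["sessions"])
        d["filter_band"] = tuple(d["filter_band"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study and persist every intermediate.

    Returns a dict with the key artifacts (paths, reports, data frames).
    Any stage failure aborts with the stage name; artifacts persisted so far
    remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = default_montage()
    paradigm = default_paradigm()
    artifacts: dict = {"out_dir": str(out)}

    stage = "simulate"
    try:
        spec = CohortSpec(
            n_subjects=config.n_subjects,
            sessions=config.sessions,
            gmfm_link_slope=config.gmfm_link_slope,
            gmfm_noise_sd=config.gmfm_noise_sd,
            seed=stage_seed(config.seed, "simulate"),
        )
        recordings, clinical, truths = generate_cohort(spec, montage, paradigm, fs=config.fs)
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        ext = "snirf" if config.format == "snirf" else "csv"
        for rec in recordings:
            gio.write_recording(
                rec, rec_dir / f"{rec.subject}_{rec.session}.{ext}", format=config.format
            )
        gio.write_clinical_csv(clinical, out / "clinical.csv")
        gio.write_ground_truth(truths, out / "ground_truth.json")
        artifacts["clinical_csv"] = str(out / "clinical.csv")

        stage = "preprocess+glm"
        fspec = FilterSpec(order=config.filter_order, band=config.filter_band)
        wspec = WaveletSpec(family=config.wavelet_family, alpha=config.wavelet_alpha)
        betamaps = []
        for rec in recordings:
            hemo = recording_to_hemoglobin(rec, age=rec.meta.get("age", 10.0))
            clean = preprocess(hemo, montage=montage, filter_spec=fspec, wavelet_spec=wspec)
            betamaps.append(
                fit_hemoglobin(
                    clean, paradigm, drift_order=config.drift_order, filter_spec=fspec
                )
            )
        beta_path = gio.write_betamaps(betamaps, out / "betamaps.csv")
        artifacts["betamaps_csv"] = str(beta_path)
        beta_df = gio.betamaps_to_frame(betamaps)

        stage = "stats"
        anova = channelwise_anova(beta_df, family_size=config.anova_family)
        posthoc = channelwise_posthoc(beta_df, family_size=config.posthoc_family)
        report = significance_map(anova, posthoc, load_brodmann_lookup())
        report.anova.to_csv(out / "anova.csv", index=False)
        report.posthoc.to_csv(out / "posthoc.csv", index=False)
        (out / "stats_summary.txt").write_text(report.summary() + "\n")
        artifacts["stats_report"] = report
        artifacts["anova_csv"] = str(out / "anova.csv")
        artifacts["posthoc_csv"] = str(out / "posthoc.csv")

        stage = "predict"
        table = assemble_features(
            betamaps,
            clinical,
            layout=config.layout,
            sessions=(config.sessions[0], config.sessions[-1]),
        )
        table.X.to_csv(out / "features.csv", index=False)
        reg = loso_gpr(
            table,
            seed=stage_seed(config.seed, "predict"),
            select_per_fold=config.select_per_fold,
            max_features=config.max_features,
        )
        (out / "regression.json").write_text(json.dumps(reg.to_dict(), indent=1))
        reg.to_frame().to_csv(out / "predictions.csv", index=False)
        artifacts["regression"] = reg
        artifacts["regression_json"] = str(out / "regression.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_IDS},
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest_json"] = str(out / "manifest.json")
    return artifacts


def _versions() -> dict[str, str]:
    import importlib.metadata as im

    out = {}
    for pkg in ("gaitnirs", "numpy", "scipy", "pandas", "scikit-learn", "PyWavelets", "h5py"):
        try:
            out[pkg] = im.version(pkg)
        except im.PackageNotFoundError:  # pragma: no cover
            out[pkg] = "unknown"
    return out
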