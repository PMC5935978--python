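"""End-to-end pipeline: simulate -> segment -> quantify -> thresholds ->
cohort analysis -> observer agreement.

Every stage's parameters and outputs are logged as JSON lines; all randomness
derives from one explicit seed, so a run is a pure function of
(config, seed) and repeated runs write byte-identical CSVs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import io as nio
from .cohortstats import analyze_cohort
from .ctnumber import component_proportions, hu_histogram, mean_ct, segment_nodule
from .phantom import (
    CohortConfig,
    NoduleSpec,
    cohort_to_frame,
    simulate_appearance_cohort,
    simulate_cohort,
    simulate_nodule,
)
from .thresholding import derive_component_thresholds

__all__ = ["PipelineConfig", "run_pipeline", "quantify_phantom"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full synthetic run. ``seed`` must be explicit."""

    seed: int
    n_phantoms: int = 10
    phantom_diameter_cm: float = 1.5
    phantom_blur_sigma_mm: float = 0.5
    cohort_n_invasive: int = 283
    cohort_n_noninvasive: int = 92
    appearance_n: tuple[int, int, int] = (58, 159, 158)
    agreement_n: int = 50
    agreement_edit_sd: float = 0.02
    hu_floor: float = -750.0
    write_volumes: bool = False

    @staticmethod
    def from_mapping(cfg: dict) -> "PipelineConfig":
        if "seed" not in cfg or cfg["seed"] is None:
            raise ValueError(
                "pipeline config must set an explicit integer `seed`"
            )
        known = {f for f in PipelineConfig.__dataclass_fields__}
        extra = set(cfg) - known
        if extra:
            raise ValueError(f"unknown pipeline config keys: {sorted(extra)}")
        if "appearance_n" in cfg:
            cfg = {**cfg, "appearance_n": tuple(cfg["appearance_n"])}
        return PipelineConfig(**cfg)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def quantify_phantom(
    spec: NoduleSpec,
    t_ggo: float = -411.5,
    t_sc: float = -189.5,
    hu_floor: float = -750.0,
) -> dict:
    """Simulate one phantom and run the three-step quantification on it.

    Segmentation is seeded at the volume center (where the phantom nodule
    sits); returns measured mean CT, GGOc/Sc proportions and the ground truth.
    """
    volume, mask, truth = simulate_nodule(spec)
    center = tuple(s // 2 for s in volume.shape)
    seg = segment_nodule(
        volume, center, hu_floor=hu_floor,
        max_radius_mm=spec.diameter_cm * 10 / 2 + 3.0,
    )
    stats_ = mean_ct(volume, seg)
    hist = hu_histogram(volume, seg)
    props = component_proportions(hist, t_ggo=t_ggo, t_sc=t_sc)
    return {
        "mean_hu": stats_.mean,
        "min_hu": stats_.min,
        "max_hu": stats_.max,
        "ggoc_pct": props.ggoc_prop,
        "sc_pct": props.sc_prop,
        "n_voxels": seg.n_voxels,
        "true_solid_fraction": truth.solid_voxel_fraction,
        "true_lepidic_pct": truth.lepidic_pct,
        "appearance": truth.appearance,
        "histologic_group": truth.histologic_group,
    }


def run_pipeline(config: PipelineConfig | dict, outdir: str | Path) -> dict:
    """Run every stage and write its artifacts under ``outdir``.

    Writes: ``phantom_measurements.csv``, ``thresholds.csv``, ``cohort.csv``,
    ``analysis_report.csv``, ``agreement.csv`` and a ``pipeline_log.jsonl``
    with per-stage parameters. Returns the in-memory artifacts. A stage
    failure propagates with the stage name prepended.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_mapping(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **payload) -> None:
        log_fh.write(json.dumps({"stage": stage, **payload}, sort_keys=True) + "\n")

    artifacts: dict = {}
    seeds = _spawn_seeds(config.seed, 4)
    log("config", **{**asdict(config), "appearance_n": list(config.appearance_n)})

    stage = "phantoms"
    try:
        phantom_seeds = _spawn_seeds(seeds[0], config.n_phantoms)
        rng = np.random.default_rng(seeds[0])
        rows = []
        for i, s in enumerate(phantom_seeds):
            spec = NoduleSpec(
                diameter_cm=config.phantom_diameter_cm,
                lepidic_fraction=float(rng.uniform(0.0, 1.0)),
                blur_sigma_mm=config.phantom_blur_sigma_mm,
                seed=s,
            )
            row = quantify_phantom(spec, hu_floor=config.hu_floor)
            row["phantom_id"] = i
            rows.append(row)
            if config.write_volumes:
                vol, msk, _ = simulate_nodule(spec)
                nio.save_volume(vol, outdir / f"phantom_{i:03d}.nii.gz")
                nio.save_mask(msk, outdir / f"phantom_{i:03d}_mask.nii.gz",
                              spacing_mm=vol.spacing_mm)
        phantoms = pd.DataFrame(rows)
        phantoms.to_csv(outdir / "phantom_measurements.csv", index=False)
        artifacts["phantoms"] = phantoms
        log(stage, n=len(phantoms))

        stage = "thresholds"
        app = simulate_appearance_cohort(*config.appearance_n, seed=seeds[1])
        t_ggo, t_sc = derive_component_thresholds(app)
        thr = pd.DataFrame(
            [
                {"component": "ggoc", **t_ggo.__dict__},
                {"component": "sc", **t_sc.__dict__},
            ]
        )
        thr.to_csv(outdir / "thresholds.csv", index=False)
        artifacts["thresholds"] = (t_ggo, t_sc)
        log(stage, t_ggo=t_ggo.cutoff, t_sc=t_sc.cutoff,
            auc_ggo=t_ggo.auc, auc_sc=t_sc.auc)

        stage = "cohort"
        from .phantom import COHORT_MARGIN_DEFAULTS

        groups = {
            "invasive": {**COHORT_MARGIN_DEFAULTS["invasive"], "n": config.cohort_n_invasive},
            "non-invasive": {
                **COHORT_MARGIN_DEFAULTS["non-invasive"], "n": config.cohort_n_noninvasive,
            },
        }
        cohort = cohort_to_frame(
            simulate_cohort(CohortConfig(groups=groups, seed=seeds[2]))
        )
        nio.save_cohort(cohort, outdir / "cohort.csv")
        artifacts["cohort"] = cohort
        log(stage, n=len(cohort))

        stage = "analysis"
        report = analyze_cohort(cohort)
        report.to_frame().to_csv(outdir / "analysis_report.csv", index=False)
        artifacts["report"] = report
        log(stage, **{f"auc_{k}": v for k, v in report.aucs.items()})

        stage = "agreement"
        rater_seeds = tuple(_spawn_seeds(seeds[3], 2))
        pairs = agr.agreement_experiment(
            n_tumors=config.agreement_n,
            seed=seeds[3],
            rater_seeds=rater_seeds,
            edit_sd=config.agreement_edit_sd,
        )
        res = agr.agreement_result(pairs)
        pd.DataFrame([res.__dict__]).to_csv(outdir / "agreement.csv", index=False)
        artifacts["agreement"] = res
        log(stage, icc=res.icc, bias=res.bias)
    except Exception as err:
        log_fh.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    log_fh.close()
    return artifacts
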