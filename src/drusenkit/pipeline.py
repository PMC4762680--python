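"""End-to-end orchestration: per-subject image analysis and the full study.

``analyze_subject`` runs leveling → registration → segmentation →
quantification → remodeling (→ GA overlap when atrophy is annotated) for
one serial image pair, all in the baseline frame. ``run_study`` iterates a
subject manifest, assembles the cohort table, runs the statistical battery
and the GA summary, and writes a reproducible report: fixed configuration
and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dkio
from .core import FundusImage
from .leveling import level
from .longitudinal import GAOverlapResult, RemodelingRecord, cohort_ga_summary, ga_overlap, remodel
from .quantification import SubfieldMetrics, build_template, quantify
from .registration import (
    PlanarTransform,
    RegistrationError,
    estimate_transform,
    manual_fovea_fallback,
    warp,
)
from .segmentation import AnnotationSet, segment_drusen
from .synthetic import Druse, DrusenChanges, GAPatch, SimImageParams, VisitTransform, generate_fundus_pair
from .trial_stats import StatConfig, run_trial_analysis

__all__ = ["RunConfig", "SubjectResult", "StageError", "analyze_subject", "run_study", "simulate_study"]

#: below this cohort size the report notes that inference is unreliable
MIN_STATS_N = 10


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"[{stage}] subject {subject}: {cause}")
        self.stage = stage
        self.subject = subject
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Reproducible configuration of a pipeline run."""

    scale_um_per_px: float = 30.0
    n_zones: int = 3
    blend_frac: float = 0.1
    min_druse_px: int = 4
    registration_family: str = "similarity"
    stats: StatConfig = field(default_factory=StatConfig)
    seed: int = 0
    verbosity: int = 1

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SubjectResult:
    subject_id: str
    baseline_metrics: SubfieldMetrics
    final_metrics: SubfieldMetrics
    remodeling: RemodelingRecord
    transform: PlanarTransform
    ga: GAOverlapResult | None = None


def analyze_subject(
    baseline: FundusImage,
    baseline_ann: AnnotationSet,
    final: FundusImage,
    final_ann: AnnotationSet,
    config: RunConfig | None = None,
    subject_id: str = "?",
) -> SubjectResult:
    """Full image-level analysis of one subject's serial pair.

    Both visits are background-leveled and the final→baseline transform is
    estimated on the leveled images (automatic similarity/affine search,
    falling back to fovea-pair translation when the automatic method cannot
    be trusted). Each visit is then segmented in its own frame — avoiding
    interpolation artifacts in the druse areas — and the registration
    carries the single grading template onto the final visit: its center is
    the baseline fovea mapped through the transform and its µm/px scale
    absorbs the estimated inter-visit magnification. Remodeling is D1−D0
    over the co-localized templates; when GA is annotated at the final
    visit, its mask is warped (nearest-neighbor) into the baseline frame
    and intersected with the baseline drusen.
    """
    config = config or RunConfig()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StageError(name, subject_id, exc) from exc

    lev0, _ = stage("leveling", lambda: level(baseline, n_zones=config.n_zones, blend_frac=config.blend_frac))
    lev1, _ = stage("leveling", lambda: level(final, n_zones=config.n_zones, blend_frac=config.blend_frac))

    def register():
        try:
            return estimate_transform(lev1, lev0, family=config.registration_family)
        except RegistrationError:
            return manual_fovea_fallback(final.fovea_px, baseline.fovea_px)

    tform = stage("registration", register)

    # the magnification factor of final→baseline: µm per final-frame pixel
    scale1 = baseline.scale_um_per_px * tform.scale
    fovea1 = tform.inverse().apply_rc([baseline.fovea_px])[0]
    fovea1 = (
        float(np.clip(fovea1[0], 0, final.shape[0] - 1)),
        float(np.clip(fovea1[1], 0, final.shape[1] - 1)),
    )
    lev1 = FundusImage(lev1.data, scale1, fovea1)

    map0 = stage("segmentation", lambda: segment_drusen(lev0, baseline_ann, config.min_druse_px))
    map1 = stage("segmentation", lambda: segment_drusen(lev1, final_ann, config.min_druse_px))

    t0 = stage(
        "quantification",
        lambda: build_template(baseline.fovea_px, baseline.scale_um_per_px, baseline.shape),
    )
    t1 = stage("quantification", lambda: build_template(fovea1, scale1, final.shape))
    m0 = stage("quantification", lambda: quantify(map0, t0))
    m1 = stage("quantification", lambda: quantify(map1, t1))
    rec = stage(
        "remodeling",
        lambda: remodel(
            m0,
            SubfieldMetrics(table=m1.table, scale_um_per_px=m0.scale_um_per_px),
        ),
    )

    ga = None
    if final_ann.ga is not None and final_ann.ga.any():
        ga_in_base = stage("ga_overlap", lambda: warp(final_ann.ga, tform, baseline.shape))
        ga = stage("ga_overlap", lambda: ga_overlap(map0.foreground(), ga_in_base))
    return SubjectResult(subject_id, m0, m1, rec, tform, ga)


# ---------------------------------------------------------------------------
# Study-level driver
# ---------------------------------------------------------------------------

_COVARIATES = ["arm", "age", "gender", "smoking", "cfh", "arms2"]


def _metrics_row(result: SubjectResult) -> dict[str, float]:
    row: dict[str, float] = {}
    for kind, metrics in (("baseline", result.baseline_metrics), ("final", result.final_metrics)):
        for metric in ("number", "diameter", "area"):
            for sf in ("inner", "middle", "outer", "all"):
                row[f"{kind}_{metric}_{sf}"] = metrics.value(metric, sf)
    row.update(result.remodeling.to_row("delta"))
    return row


def run_study(manifest: pd.DataFrame | str | Path, config: RunConfig, out_dir: str | Path) -> dict:
    """Analyze every manifest subject, then run the cohort statistics.

    The manifest holds one row per subject: image and mask paths, fovea
    coordinates, the µm/px scale and the trial covariates. Subjects whose
    analysis fails at any stage are excluded with the failure recorded —
    never silently dropped. Outputs (per-subject metrics, the four report
    tables, the GA summary and a run log with the configuration hash and
    seed) are written as CSV/JSON under ``out_dir``.
    """
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        manifest = pd.read_csv(manifest)
    else:
        base = Path(".")
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows, ga_results, failures = [], [], []
    for _, m in manifest.iterrows():
        sid = str(m["subject_id"])
        try:
            scale = float(m.get("scale_um_per_px", config.scale_um_per_px))
            img0 = dkio.load_image(base / m["baseline_image"], scale, (m["fovea0_row"], m["fovea0_col"]))
            img1 = dkio.load_image(base / m["final_image"], scale, (m["fovea1_row"], m["fovea1_col"]))
            ann0 = AnnotationSet(
                roi=dkio.load_mask(base / m["baseline_roi"]),
                reticular=_opt_mask(base, m.get("baseline_reticular")),
                ga=_opt_mask(base, m.get("baseline_ga")),
            )
            ann1 = AnnotationSet(
                roi=dkio.load_mask(base / m["final_roi"]),
                reticular=_opt_mask(base, m.get("final_reticular")),
                ga=_opt_mask(base, m.get("final_ga")),
            )
            res = analyze_subject(img0, ann0, img1, ann1, config, subject_id=sid)
        except Exception as exc:  # noqa: BLE001 - accounted, not dropped
            failures.append({"subject_id": sid, "error": str(exc)})
            continue
        row = {"subject_id": sid}
        row.update({c: m[c] for c in _COVARIATES if c in m})
        row.update(_metrics_row(res))
        rows.append(row)
        if res.ga is not None:
            ga_results.append(res.ga)

    cohort = pd.DataFrame(rows)
    cohort.to_csv(out / "subjects.csv", index=False)

    notes = []
    report = None
    if len(cohort) == 0:
        notes.append("no subject analyzed successfully; statistics skipped")
    else:
        if len(cohort) < MIN_STATS_N:
            notes.append(
                f"cohort n={len(cohort)} below {MIN_STATS_N}: statistical inference "
                "requires a larger cohort and is reported for completeness only"
            )
        if all(c in cohort.columns for c in _COVARIATES):
            report = run_trial_analysis(cohort, config.stats)
            for name in ("baseline", "paired", "adjusted", "covariates"):
                tbl = report[name]
                if tbl is not None:
                    tbl.to_csv(out / f"table_{name}.csv", index=False)
            notes.extend(report["errors"])
        else:
            notes.append("manifest lacks trial covariates; statistical tables skipped")

    ga_summary = cohort_ga_summary(ga_results) if ga_results else None
    if ga_summary is not None:
        (out / "ga_summary.json").write_text(json.dumps(ga_summary, indent=2, sort_keys=True))

    log_lines = [
        f"drusenkit run (config {config.digest()}, seed {config.seed})",
        f"subjects in manifest: {len(manifest)}",
        f"subjects analyzed: {len(cohort)}",
        f"subjects excluded: {len(failures)}",
        *(f"  excluded {f['subject_id']}: {f['error']}" for f in failures),
        *(f"note: {n}" for n in notes),
        "config: " + json.dumps(dataclasses.asdict(config), sort_keys=True, default=str),
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "cohort": cohort,
        "report": report,
        "ga_summary": ga_summary,
        "failures": failures,
        "notes": notes,
    }


def _opt_mask(base: Path, value) -> np.ndarray | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return dkio.load_mask(base / str(value))


# ---------------------------------------------------------------------------
# Synthetic study materialization (images + manifest on disk)
# ---------------------------------------------------------------------------


def simulate_study(
    out_dir: str | Path,
    n_subjects: int = 4,
    seed: int = 0,
    shape: tuple[int, int] = (192, 192),
    scale_um_per_px: float = 32.0,
    ga_fraction: float = 0.25,
) -> Path:
    """Write a small ground-truthed image study to disk; returns the manifest path.

    Each subject gets a serial image pair with randomized drusen, a modest
    inter-visit similarity transform, remodeling changes, and (for a
    fraction of subjects) a final-visit GA patch; plus ROI/GA masks and
    trial covariates in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    margin = 12
    for i in range(n_subjects):
        n_drusen = int(rng.integers(8, 16))
        drusen = []
        for _ in range(n_drusen):
            r = rng.uniform(margin + 8, shape[0] - margin - 8)
            c = rng.uniform(margin + 8, shape[1] - margin - 8)
            a = rng.uniform(70, 220)
            drusen.append(
                Druse((r, c), (a, a * rng.uniform(0.75, 1.25)), rng.uniform(25, 50))
            )
        changes = DrusenChanges(
            removed=(0,) if n_drusen > 2 and rng.random() < 0.7 else (),
            grown={1: float(rng.uniform(1.1, 1.4))} if n_drusen > 2 else {},
            added=(
                Druse(
                    (rng.uniform(40, shape[0] - 40), rng.uniform(40, shape[1] - 40)),
                    (rng.uniform(80, 160),) * 2,
                    rng.uniform(25, 45),
                ),
            ),
        )
        ga = None
        if rng.random() < ga_fraction:
            ga = GAPatch(
                center_px=(drusen[-1].center_px if drusen else (shape[0] / 2, shape[1] / 2)),
                radius_um=rng.uniform(400, 800),
                contrast=45.0,
            )
        params = SimImageParams(
            shape=shape,
            scale_um_per_px=scale_um_per_px,
            noise_sd=2.0,
            drusen=tuple(drusen),
            ga_patch=ga,
            transform=VisitTransform(
                rotation_deg=float(rng.uniform(-3, 3)),
                translation_px=tuple(rng.uniform(-8, 8, 2)),
                scale=float(rng.uniform(0.98, 1.02)),
            ),
            changes=changes,
        )
        img0, img1, truth = generate_fundus_pair(params, seed=int(rng.integers(0, 2**31 - 1)))
        sid = f"S{i:03d}"
        dkio.save_image(out / f"{sid}_v0.png", img0)
        dkio.save_image(out / f"{sid}_v1.png", img1)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        roi = (
            (rr > margin) & (rr < shape[0] - margin) & (cc > margin) & (cc < shape[1] - margin)
        )
        dkio.save_mask(out / f"{sid}_roi.png", roi)
        ga_path = ""
        if truth.ga_mask_final.any():
            ga_path = f"{sid}_ga.png"
            dkio.save_mask(out / ga_path, truth.ga_mask_final)
        rows.append(
            {
                "subject_id": sid,
                "baseline_image": f"{sid}_v0.png",
                "final_image": f"{sid}_v1.png",
                "baseline_roi": f"{sid}_roi.png",
                "final_roi": f"{sid}_roi.png",
                "final_ga": ga_path,
                "fovea0_row": img0.fovea_px[0],
                "fovea0_col": img0.fovea_px[1],
                "fovea1_row": img1.fovea_px[0],
                "fovea1_col": img1.fovea_px[1],
                "scale_um_per_px": scale_um_per_px,
                "arm": "treated" if rng.random() < 0.5 else "placebo",
                "age": round(float(rng.normal(73.6, 6.8)), 1),
                "gender": "female" if rng.random() < 0.617 else "male",
                "smoking": "ever" if rng.random() < 0.431 else "never",
                "cfh": str(rng.choice(["CC", "CT", "TT"], p=[0.29, 0.47, 0.24])),
                "arms2": str(rng.choice(["CC", "CT", "TT"], p=[0.31, 0.46, 0.23])),
            }
        )
    manifest_path = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
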