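"""Reproducible pipeline plumbing: configuration, stages, provenance.

Stages mirror the study workflow: ``simulate`` writes a cohort table and one
glabella PNG per subject; ``extract`` selects the most uniform region of each
image, applies quality control and writes per-channel intensity summaries;
``screen`` joins intensities with the subject table and runs the statistical
analysis (correlations, threshold scan, discrimination-limit screening,
stepwise regression). Every stage writes a provenance manifest (seed,
canonical config hash, package version, output checksums) sufficient to
verify byte-identical reproduction.

All randomness flows from a single root seed; per-cohort and per-subject
streams are derived by counter through ``numpy.random.SeedSequence`` so
partial re-runs reproduce exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cohort as coh
from . import images as img
from . import stats as st

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "QcFailureError",
    "derive_seed",
    "config_hash",
    "write_manifest",
    "run_simulate",
    "run_extract",
    "run_screen",
    "run_report",
    "cohort_channel_means",
    "replicate_correlations",
    "COHORT_COLUMNS",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "subject_id",
    "tsb_umol_l",
    "tcb_umol_l",
    "ga_weeks",
    "age_days",
    "weight_g",
    "hb_mmol_l",
    "sex",
]


class PipelineError(RuntimeError):
    pass


class QcFailureError(PipelineError):
    """More than the tolerated share of images failed quality control."""


@dataclass
class PipelineConfig:
    """Run configuration; CLI flags override these, which override defaults."""

    out_dir: Path = Path("results")
    image_dir: Optional[Path] = None
    subject_table: Optional[Path] = None
    n_subjects: int = 51
    seed: int = 0
    image_side: int = 64
    window_side: int = 16
    block_side: Optional[int] = None
    outlier_k: float = 3.0
    limit_green: float = 212.0
    limit_blue: float = 190.0
    clinical_threshold: float = st.DEFAULT_CLINICAL_THRESHOLD
    qc_max_saturated: float = 0.05
    qc_max_artifact: float = 0.10
    qc_min_region_pixels: int = 16
    max_qc_failure_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.clinical_threshold <= 0:
            raise PipelineError("clinical_threshold must be positive")
        for name in ("limit_green", "limit_blue"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise PipelineError(f"{name} {v} outside [0, 255]")
        self.out_dir = Path(self.out_dir)
        if self.image_dir is not None:
            self.image_dir = Path(self.image_dir)
        if self.subject_table is not None:
            self.subject_table = Path(self.subject_table)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d

    def provenance_dict(self) -> dict:
        """Config without filesystem locations: two runs of the same
        analysis in different directories must hash identically."""
        d = self.to_dict()
        for k in ("out_dir", "image_dir", "subject_table"):
            d.pop(k, None)
        return d

    def qc_thresholds(self) -> img.QcThresholds:
        return img.QcThresholds(
            max_saturated_fraction=self.qc_max_saturated,
            max_artifact_fraction=self.qc_max_artifact,
            min_region_pixels=self.qc_min_region_pixels,
        )


def derive_seed(root: int, *counters: int) -> int:
    """A child seed below 2**31, derived deterministically by counter."""
    ss = np.random.SeedSequence([int(root), *map(int, counters)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def config_hash(obj: dict) -> str:
    """SHA-256 of the canonicalised (sorted, compact) JSON form."""
    return hashlib.sha256(_canonical(obj).encode()).hexdigest()


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, seed: int, config: dict, files: list[Path]) -> Path:
    try:
        from importlib.metadata import version

        pkg_version = version("biliscreen")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = {
        "seed": int(seed),
        "config": config,
        "config_sha256": config_hash(config),
        "package_version": pkg_version,
        "files": {p.name: _sha256_file(p) for p in sorted(files)},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(_canonical(manifest) + "\n")
    return path


def subjects_to_frame(subjects: list[coh.Subject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "tsb_umol_l": s.tsb,
                "tcb_umol_l": s.tcb if s.tcb is not None else np.nan,
                "ga_weeks": s.gestational_age,
                "age_days": s.postnatal_age,
                "weight_g": s.birth_weight,
                "hb_mmol_l": s.haemoglobin,
                "sex": s.sex,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


# --- stages -------------------------------------------------------------------


def run_simulate(
    config: PipelineConfig,
    effects: coh.ChannelEffectModel | None = None,
    artifacts: coh.ArtifactSpec | None = None,
) -> dict:
    """Generate a cohort table and one rendered PNG per subject."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)

    cohort_cfg = coh.CohortConfig(n_subjects=config.n_subjects, seed=config.seed)
    effects = effects or coh.default_effect_model(cohort_cfg.tsb_distribution)
    subjects = coh.sample_cohort(cohort_cfg)

    files = []
    for i, s in enumerate(subjects):
        image = coh.render_image(
            s,
            effects,
            height=config.image_side,
            width=config.image_side,
            seed=derive_seed(config.seed, 1, i),
        )
        if artifacts is not None and (
            artifacts.hair_streak_count or artifacts.specular_spot_count
        ):
            image = coh.inject_artifacts(
                image,
                dataclasses.replace(
                    artifacts, artifact_seed=derive_seed(config.seed, 2, i)
                ),
            )
        path = img_dir / f"{s.subject_id}.png"
        img.write_image(image, path)
        files.append(path)

    table = subjects_to_frame(subjects)
    cohort_path = out / "cohort.csv"
    table.to_csv(cohort_path, index=False)
    files.append(cohort_path)

    profile = {
        "cohort": dataclasses.asdict(cohort_cfg),
        "effects": dataclasses.asdict(effects),
        "artifacts": dataclasses.asdict(artifacts) if artifacts else None,
        "image_side": config.image_side,
    }
    manifest = write_manifest(out, config.seed, profile, files)
    return {"cohort_csv": cohort_path, "image_dir": img_dir, "manifest": manifest}


def run_extract(config: PipelineConfig) -> dict:
    """Select uniform regions, apply QC, and write intensity summaries.

    Every excluded image is logged with its QC reasons; the stage fails if
    more than ``max_qc_failure_fraction`` of the images are inadmissible.
    """
    image_dir = Path(config.image_dir or Path(config.out_dir) / "images")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = sorted(
        p
        for p in image_dir.iterdir()
        if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    )
    if not paths:
        raise PipelineError(f"no images found in {image_dir}")

    rows, qc_rows = [], []
    n_failed = 0
    thresholds = config.qc_thresholds()
    for path in paths:
        image = img.read_image(path)
        mask = img.select_uniform_region(image, config.window_side)
        report = img.qc_image(image, mask, thresholds)
        qc_rows.append(
            {
                "subject_id": image.subject_id,
                "passed": report.passed,
                "reasons": ";".join(report.reasons),
                "saturated_fraction": report.saturated_fraction,
                "artifact_fraction": report.artifact_fraction,
            }
        )
        if not report.passed:
            n_failed += 1
            logger.warning(
                "excluding image %s: %s", image.subject_id, report.reasons
            )
            continue
        summary = img.extract_intensity(image, mask)
        rows.extend(img.summary_row(image.subject_id, image.method, summary))
        if config.block_side:
            block = img.block_summaries(image, mask, config.block_side)
            rows.extend(img.summary_row(image.subject_id, image.method, block))

    qc_path = out / "qc_log.csv"
    pd.DataFrame(qc_rows).to_csv(qc_path, index=False)
    if n_failed > config.max_qc_failure_fraction * len(paths):
        raise QcFailureError(
            f"{n_failed}/{len(paths)} images failed quality control"
        )
    intensities_path = out / "intensities.csv"
    pd.DataFrame(rows).to_csv(intensities_path, index=False)
    return {"intensities_csv": intensities_path, "qc_log": qc_path, "n_excluded": n_failed}


def _pivot_intensities(df: pd.DataFrame) -> pd.DataFrame:
    raw = df[df["aggregation_block"] == 1]
    wide = raw.pivot_table(index="subject_id", columns="channel", values="mean")
    wide.columns = [f"{c}_mean" for c in wide.columns]
    return wide.reset_index()


def run_screen(config: PipelineConfig) -> dict:
    """Join intensities with subjects and run the screening analysis."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    intensities = pd.read_csv(out / "intensities.csv")
    subjects = pd.read_csv(config.subject_table or out / "cohort.csv")

    wide = _pivot_intensities(intensities)
    unmatched = set(wide["subject_id"]) - set(subjects["subject_id"])
    if unmatched:
        raise PipelineError(
            f"subject table is missing ids: {sorted(unmatched)}"
        )
    data = wide.merge(subjects, on="subject_id", how="inner")

    # subjects without a laboratory TsB cannot enter the analysis
    missing = data[data["tsb_umol_l"].isna()]["subject_id"].tolist()
    for sid in missing:
        logger.warning("excluding subject %s: no TsB available", sid)
    data = data.dropna(subset=["tsb_umol_l"]).reset_index(drop=True)
    if len(data) < 3:
        raise PipelineError("fewer than 3 analysable subjects after exclusions")

    tsb = data["tsb_umol_l"].to_numpy()
    files = []

    corr_rows = [
        dataclasses.asdict(st.pearson(data[f"{ch}_mean"], tsb, channel=ch))
        for ch in img.CHANNELS
    ]
    corr_path = out / "correlations.csv"
    pd.DataFrame(corr_rows).to_csv(corr_path, index=False)
    files.append(corr_path)

    screening = {}
    for ch, limit in (("green", config.limit_green), ("blue", config.limit_blue)):
        res = st.classify_and_score(
            data[f"{ch}_mean"], tsb, limit, config.clinical_threshold
        )
        scan = st.threshold_scan(
            data[f"{ch}_mean"], tsb, config.clinical_threshold
        )
        scan_path = out / f"threshold_scan_{ch}.csv"
        scan.table.to_csv(scan_path, index=False)
        files.append(scan_path)
        screening[ch] = {
            "limit": limit,
            "confusion": dataclasses.asdict(res.confusion),
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
            "best_limit_full_sensitivity": scan.best_limit_full_sensitivity,
        }
    screen_path = out / "screening.json"
    screen_path.write_text(_canonical(screening) + "\n")
    files.append(screen_path)

    candidates = data[
        ["green_mean", "blue_mean", "red_mean", "ga_weeks", "age_days", "weight_g", "hb_mmol_l"]
    ].copy()
    candidates["sex_female"] = (data["sex"] == "female").astype(float)
    candidates = candidates.loc[:, candidates.nunique() > 1]
    # stepwise needs n > k + 2; keep the leading (channel-first) candidates
    max_k = len(data) - 3
    if candidates.shape[1] > max_k:
        candidates = candidates.iloc[:, :max_k]
    model = st.stepwise_forward(tsb, candidates)
    retained = st.exclude_outliers(data["green_mean"], config.outlier_k)
    report = {
        "n_analysed": int(len(data)),
        "excluded_missing_tsb": missing,
        "stepwise": {
            "selected_terms": model.selected_terms,
            "coefficients": model.coefficients,
            "intercept": model.intercept,
            "entry_p_values": model.entry_p_values,
        },
        "outlier_rule": {
            "k": config.outlier_k,
            "n_retained_green": int(retained.size),
        },
    }
    reg_path = out / "regression.json"
    reg_path.write_text(_canonical(report) + "\n")
    files.append(reg_path)

    write_manifest(out, config.seed, config.provenance_dict(), files)
    return {
        "correlations_csv": corr_path,
        "screening_json": screen_path,
        "regression_json": reg_path,
        "excluded_missing_tsb": missing,
    }


def run_report(config: PipelineConfig) -> Path:
    """Collate the screen outputs into one human-readable summary."""
    out = Path(config.out_dir)
    corr = pd.read_csv(out / "correlations.csv")
    screening = json.loads((out / "screening.json").read_text())
    regression = json.loads((out / "regression.json").read_text())
    lines = ["# Screening report", "", "## Channel correlations with TsB", ""]
    for _, row in corr.iterrows():
        lines.append(
            f"- {row['channel']}: r = {row['r']:.3f} (p = {row['p_value']:.3g}, n = {int(row['n'])})"
        )
    lines += ["", "## Discrimination limits", ""]
    for ch, s in screening.items():
        sens = "undefined" if s["sensitivity"] is None else f"{s['sensitivity']:.1f}%"
        spec = "undefined" if s["specificity"] is None else f"{s['specificity']:.1f}%"
        lines.append(
            f"- {ch} limit {s['limit']}: sensitivity {sens}, specificity {spec} "
            f"(largest 100%-sensitivity limit in scan: {s['best_limit_full_sensitivity']})"
        )
    lines += [
        "",
        "## Stepwise regression",
        "",
        f"- selected terms: {regression['stepwise']['selected_terms']}",
        f"- n analysed: {regression['n_analysed']}",
        "",
    ]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path


# --- in-memory study helpers --------------------------------------------------


def cohort_channel_means(
    n: int = 51,
    seed: int = 0,
    effects: coh.ChannelEffectModel | None = None,
    image_side: int = 64,
    window_side: int = 16,
) -> pd.DataFrame:
    """Simulate one cohort and run the full extraction pipeline in memory.

    Returns one row per subject with covariates and the per-channel mean
    intensity of the selected uniform region — the analysis table the
    screening statistics operate on.
    """
    cfg = coh.CohortConfig(n_subjects=n, seed=seed)
    effects = effects or coh.default_effect_model(cfg.tsb_distribution)
    subjects = coh.sample_cohort(cfg)
    rows = []
    for i, s in enumerate(subjects):
        image = coh.render_image(
            s, effects, image_side, image_side, seed=derive_seed(seed, 1, i)
        )
        mask = img.select_uniform_region(image, window_side)
        summary = img.extract_intensity(image, mask)
        rows.append(
            {
                "subject_id": s.subject_id,
                "tsb": s.tsb,
                "ga_weeks": s.gestational_age,
                "age_days": s.postnatal_age,
                "weight_g": s.birth_weight,
                "hb_mmol_l": s.haemoglobin,
                "sex": s.sex,
                "red_mean": float(summary.mean[0]),
                "green_mean": float(summary.mean[1]),
                "blue_mean": float(summary.mean[2]),
            }
        )
    return pd.DataFrame(rows)


def replicate_correlations(
    n_cohorts: int = 200,
    n: int = 51,
    root_seed: int = 1,
    effects: coh.ChannelEffectModel | None = None,
) -> pd.DataFrame:
    """Channel-TsB Pearson r (and p) for each of many replicate cohorts."""
    rows = []
    for k in range(n_cohorts):
        df = cohort_channel_means(n=n, seed=derive_seed(root_seed, k), effects=effects)
        row = {"cohort": k}
        for ch in img.CHANNELS:
            res = st.pearson(df[f"{ch}_mean"], df["tsb"], channel=ch)
            row[f"r_{ch}"] = res.r
            row[f"p_{ch}"] = res.p_value
        rows.append(row)
    return pd.DataFrame(rows)
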