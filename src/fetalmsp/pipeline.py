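"""End-to-end orchestration: preprocessing, cross-validation, evaluation.

The processing order mirrors the study protocol: left/right flip alignment
(heads on the right are mirrored to the left), exclusion of cases whose
ground-truth obliquity exceeds the +/-30 degree baseline, cube cropping
around the seed point, stage-1 (seed cascade) and stage-2 (adversarial mask
generator) training, inference, plane fitting and the four-metric
evaluation. Plane metrics are computed on seed-centred coefficients (the
labelling convention places the origin at the seed point, which makes the
coefficient 4-vector comparison meaningful).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import gan, metrics, seed as seed_mod
from .geometry import Plane, fit_plane_from_mask, normalize_plane
from .phantom import PhantomSample
from .seed import SeedPoint

FLIP_AXIS = 2  # the horizontal in-plane axis of the sagittal view


@dataclass
class CaseRecord:
    """Bookkeeping for one case through the pipeline."""

    case_id: str
    sample: PhantomSample
    status: str = "included"  # or "excluded:<reason>"
    fold: int = -1
    detected_seed: SeedPoint | None = None
    predicted_plane: Plane | None = None

    @property
    def included(self) -> bool:
        return self.status == "included"


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; the defaults mirror the study protocol
    (crop half-width 40 -> 80-cube, +/-30 degree baseline, five folds)."""

    crop_half_width: int = 40
    angle_baseline: float = 30.0
    folds: int = 5
    rng_seed: int = 0
    gan_epochs: int = 30
    gan_batch: int = 8
    gan_lr: float = 1e-4
    loss_weights: gan.LossWeights = field(default_factory=gan.LossWeights)
    gen_config: gan.GeneratorConfig = field(default_factory=gan.scaled_generator_config)
    critic_config: gan.CriticConfig = field(default_factory=gan.scaled_critic_config)
    seed_config: seed_mod.SeedCascadeConfig = field(default_factory=seed_mod.SeedCascadeConfig)
    fit_thresholds: tuple[float, ...] = (0.5, 0.25, 0.1)


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

def flip_plane(plane: Plane, n: int, axis: int = FLIP_AXIS) -> Plane:
    """Plane coefficients after mirroring an n-voxel axis (x -> n-1-x)."""
    v = list(plane.vector)
    v[3] += v[axis] * (n - 1)
    v[axis] = -v[axis]
    return normalize_plane(v)


def align_flip(sample: PhantomSample) -> PhantomSample:
    """Mirror right-sided heads to the left along the horizontal axis.

    Left-sided samples pass through unchanged; the ground-truth plane, seed
    and label volumes are transformed consistently. An unknown side passes
    through with a warning.
    """
    if sample.head_side == "left":
        return sample
    if sample.head_side != "right":
        warnings.warn(f"unknown head side {sample.head_side!r}; volume not aligned")
        return sample
    n = sample.volume.shape[FLIP_AXIS]
    seed = sample.gt_seed.copy()
    seed[FLIP_AXIS] = (n - 1) - seed[FLIP_AXIS]
    return PhantomSample(
        volume=np.flip(sample.volume, axis=FLIP_AXIS).copy(),
        gt_plane=flip_plane(sample.gt_plane, n),
        gt_seed=seed,
        gt_mask=np.flip(sample.gt_mask, axis=FLIP_AXIS).copy(),
        theta_axi=sample.theta_axi,
        theta_cor=sample.theta_cor,
        head_side="left",
        head_label=np.flip(sample.head_label, axis=FLIP_AXIS).copy(),
    )


def filter_by_angle(record: CaseRecord, baseline: float = 30.0) -> CaseRecord:
    """Exclude cases whose obliquity exceeds the baseline (inclusive bound)."""
    if abs(record.sample.theta_axi) > baseline or abs(record.sample.theta_cor) > baseline:
        record.status = "excluded:angle-out-of-range"
    return record


def crop_cube(volume: np.ndarray, seed, half_width: int) -> np.ndarray:
    """Cube of side 2*half_width centred at the rounded seed, zero-padded.

    The extraction window is [c - hw, c + hw) per axis so the output extent
    is always exactly 2*half_width regardless of the seed position.
    """
    if isinstance(seed, SeedPoint):
        center = seed.rounded()
    else:
        center = tuple(int(np.floor(float(v) + 0.5)) for v in np.asarray(seed).reshape(3))
    for c, n in zip(center, volume.shape):
        if not 0 <= c < n:
            raise ValueError(f"seed {center} outside volume {volume.shape}")
    hw = int(half_width)
    out = np.zeros((2 * hw,) * 3, dtype=volume.dtype)
    src, dst = [], []
    for c, n in zip(center, volume.shape):
        lo, hi = c - hw, c + hw
        src.append(slice(max(lo, 0), min(hi, n)))
        dst.append(slice(max(lo, 0) - lo, 2 * hw - (hi - min(hi, n))))
    out[tuple(dst)] = volume[tuple(src)]
    return out


def translate_plane(plane: Plane, offset) -> Plane:
    """The plane expressed in coordinates x' = x - offset."""
    off = np.asarray(offset, dtype=float).reshape(3)
    n = plane.normal
    return normalize_plane([n[0], n[1], n[2], plane.offset + float(n @ off)])


def _crop_corner(seed, half_width: int) -> np.ndarray:
    if isinstance(seed, SeedPoint):
        center = seed.rounded()
    else:
        center = tuple(int(np.floor(float(v) + 0.5)) for v in np.asarray(seed).reshape(3))
    return np.array([c - half_width for c in center], dtype=float)


# ----------------------------------------------------------------------
# inference on one case
# ----------------------------------------------------------------------

def _fit_with_fallback(mask: np.ndarray, thresholds) -> Plane:
    for thr in thresholds:
        try:
            return fit_plane_from_mask(mask, thr)
        except ValueError:  # insufficient support at this threshold
            continue
    # adaptive fallback for timid soft masks: keep the side^2 strongest
    # voxels (the expected size of a one-voxel-thick plane) as support
    k = max(mask.shape[0] ** 2, 4)
    thr = float(np.partition(mask.ravel(), -k)[-k])
    return fit_plane_from_mask(mask, np.nextafter(thr, -np.inf))


def infer_case(
    sample: PhantomSample,
    generator: gan.Generator,
    config: RunConfig,
    seed_models: seed_mod.SeedModels | None = None,
    seed_point=None,
) -> tuple[Plane, Plane, SeedPoint]:
    """Detect/crop/predict/fit for one aligned case.

    Returns (predicted plane, ground-truth plane, seed used), both planes in
    seed-centred crop coordinates. ``seed_point`` overrides detection (the
    semi-automatic arm); otherwise ``seed_models`` drives stage 1.
    """
    if seed_point is None:
        if seed_models is None:
            raise ValueError("need either seed_models or an explicit seed_point")
        sp = seed_mod.detect_seed(sample.volume, seed_models)
    elif isinstance(seed_point, SeedPoint):
        sp = seed_point
    else:
        arr = np.asarray(seed_point, dtype=float).reshape(3)
        sp = SeedPoint(*arr)
    hw = config.crop_half_width
    cube = crop_cube(sample.volume, sp, hw)
    soft = gan.predict_mask(generator, cube)
    pred = _fit_with_fallback(soft, config.fit_thresholds)
    corner = _crop_corner(sp, hw)
    gt = translate_plane(sample.gt_plane, corner)
    # centre both on the crop midpoint (the seed) for coefficient metrics
    mid = np.full(3, hw - 0.5)
    return translate_plane(pred, mid), translate_plane(gt, mid), sp


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------

def assign_folds(records: list[CaseRecord], folds: int, rng_seed: int) -> None:
    """Seeded striped partition into near-equal folds (in place)."""
    included = [r for r in records if r.included]
    if len(included) < folds:
        raise ValueError(f"need at least {folds} included cases, got {len(included)}")
    order = np.random.default_rng(rng_seed).permutation(len(included))
    for pos, idx in enumerate(order):
        included[idx].fold = pos % folds


@dataclass
class CrossValReport:
    per_case: pd.DataFrame
    per_fold: pd.DataFrame
    overall: dict
    anova_p: dict
    agreement: dict | None = None

    def to_json(self) -> str:
        payload = {
            "overall": self.overall,
            "anova_p": self.anova_p,
            "per_fold": self.per_fold.to_dict(orient="records"),
        }
        if self.agreement is not None:
            payload["agreement"] = self.agreement
        return json.dumps(payload, indent=2, default=float)


def run_cross_validation(
    samples: list[PhantomSample],
    config: RunConfig | None = None,
    semi_automatic_arm: bool = False,
    out_dir=None,
) -> CrossValReport:
    """Five-fold (configurable) cross-validation of the full two-stage system.

    Per fold: stage 1 and stage 2 are trained on the training split, then
    each test case runs seed detection, cropping, mask prediction, plane
    fitting and the four metrics. With ``semi_automatic_arm`` the oracle
    seed is used alongside the detected seed and the two arms' agreement is
    summarized. Fold means are compared by one-way analysis of variance.
    """
    config = config or RunConfig()
    records = [
        filter_by_angle(CaseRecord(case_id=f"case{i:04d}", sample=align_flip(s)),
                        config.angle_baseline)
        for i, s in enumerate(samples)
    ]
    assign_folds(records, config.folds, config.rng_seed)

    rows = []
    for fold in range(config.folds):
        train = [r.sample for r in records if r.included and r.fold != fold]
        test = [r for r in records if r.included and r.fold == fold]
        if not test:
            raise ValueError(f"fold {fold} has no test cases")
        seed_models, _ = seed_mod.train_seed_networks(
            train, config.seed_config, seed=config.rng_seed + 1000 + fold
        )
        hw = config.crop_half_width
        vols, msks = [], []
        for s in train:
            vols.append(crop_cube(s.volume, s.gt_seed, hw))
            msks.append(crop_cube(s.gt_mask, s.gt_seed, hw))
        generator, _, _ = gan.train_gan(
            vols, msks, config.gen_config, config.critic_config, config.loss_weights,
            epochs=config.gan_epochs, batch_size=config.gan_batch, lr=config.gan_lr,
            seed=config.rng_seed + 2000 + fold,
        )
        for rec in test:
            row = {"case_id": rec.case_id, "fold": fold}
            try:
                pred, gt, sp = infer_case(rec.sample, generator, config,
                                          seed_models=seed_models)
                pm = metrics.plane_pair_metrics(pred, gt)
                row.update(theta=pm.theta, dist=pm.dist, dyaw=pm.dyaw, droll=pm.droll)
                row["seed_error"] = float(
                    np.linalg.norm(sp.as_array() - rec.sample.gt_seed)
                )
                rec.detected_seed, rec.predicted_plane = sp, pred
            except (seed_mod.DetectionFailureError, ValueError) as exc:
                row["error"] = str(exc)
            if semi_automatic_arm:
                try:
                    pred_s, gt_s, _ = infer_case(
                        rec.sample, generator, config, seed_point=rec.sample.gt_seed
                    )
                    pm = metrics.plane_pair_metrics(pred_s, gt_s)
                    row.update(theta_semi=pm.theta, dist_semi=pm.dist,
                               dyaw_semi=pm.dyaw, droll_semi=pm.droll)
                except ValueError as exc:
                    row["error_semi"] = str(exc)
            rows.append(row)

    per_case = pd.DataFrame(rows)
    metric_cols = [c for c in ("theta", "dist", "dyaw", "droll") if c in per_case]
    per_fold = per_case.groupby("fold")[metric_cols].mean().reset_index()
    overall = {
        "n_total": len(records),
        "n_included": int(sum(r.included for r in records)),
        "n_excluded": int(sum(not r.included for r in records)),
    }
    for c in metric_cols:
        overall[f"mean_{c}"] = float(per_case[c].mean())
        overall[f"median_{c}"] = float(per_case[c].median())
    anova_p = {}
    for c in metric_cols:
        groups = [g.dropna().values for _, g in per_case.groupby("fold")[c]]
        groups = [g for g in groups if len(g) > 1]
        if len(groups) >= 2 and any(np.ptp(g) > 0 for g in groups):
            anova_p[c] = float(stats.f_oneway(*groups).pvalue)
        else:
            anova_p[c] = float("nan")
    agreement_summary = None
    if (semi_automatic_arm and "theta" in per_case and "theta_semi" in per_case):
        both = per_case.dropna(subset=["theta", "theta_semi"])
        if len(both) >= 3:
            agreement_summary = {}
            for c in metric_cols:
                st = metrics.agreement(both[f"{c}_semi"].values, both[c].values)
                agreement_summary[c] = dataclasses.asdict(st)
    report = CrossValReport(per_case, per_fold, overall, anova_p, agreement_summary)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_case.to_csv(out / "per_case_metrics.csv", index=False)
        per_fold.to_csv(out / "per_fold_metrics.csv", index=False)
        (out / "report.json").write_text(report.to_json())
        if agreement_summary is not None:
            both = per_case.dropna(subset=["theta", "theta_semi"])
            metrics.bland_altman_plot(both["theta_semi"], both["theta"],
                                      out / "bland_altman_theta.png", "included angle")
    return report
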