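"""End-to-end orchestration: simulate -> train -> predict -> score -> evaluate.

A single master seed fans out deterministically to every stage (phantom
sampling, network initialization, patch sampling, augmentation), so a run
is reproducible from one integer.  The reference study is the scaled-down
experiment the package's tests and acceptance script both run: a few
dozen phantoms, a tiny U-Net trained for minutes on one CPU, and the full
agreement-statistics suite on the held-out scans.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import agatston, evalstats, heartnet, io_volumes, labelgen, phantom

log = logging.getLogger("heartcac")

#: categories a vessel-specific report is summarised with in CSV form
CSV_COLUMNS = ["scan_id", "total", "lm", "lad", "lcx", "rca", "category"]


class StudyConfig(BaseModel):
    """Validated configuration of the reference experiment.

    Unknown keys are rejected so config-file typos fail loudly.
    """

    model_config = ConfigDict(extra="forbid")

    n_train: int = 24
    n_test: int = 25
    seed: int = 0
    lesion_free_rate: float = 1.0 / 3.0
    distractor_rate: float = 0.4
    dense_label_fraction: float = 1.0 / 3.0
    dense_tube_radius_mm: float = 5.0
    other_label_iterations: int = 2
    epochs: int = 55
    steps_per_epoch: int = 10
    batch_size: int = 4
    learning_rate: float = 3e-3
    depth: int = 2
    base_channels: int = 8
    patch_size: tuple[int, int, int] = (16, 24, 24)
    working_downsample: tuple[int, int, int] = (1, 4, 4)
    hu_window: tuple[float, float] = (-100.0, 300.0)

    def net_config(self, seed: int) -> heartnet.NetConfig:
        return heartnet.NetConfig(
            depth=self.depth,
            base_channels=self.base_channels,
            patch_size=self.patch_size,
            working_downsample=self.working_downsample,
            hu_window=self.hu_window,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            steps_per_epoch=self.steps_per_epoch,
            batch_size=self.batch_size,
            seed=seed,
        )


def _stage_seed(master: int, stage: int) -> int:
    """Deterministic per-stage seed below 2^31."""
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2 ** 31))


def build_supervision(scan: phantom.PhantomScan, dense: bool,
                      config: StudyConfig) -> labelgen.SupervisionVolume:
    """Assemble the training labels one scan contributes.

    Every scan contributes expert-style sparse calcium labels, the
    automatically generated non-coronary labels, and dense outside-heart
    labels; scans flagged `dense` additionally contribute whole-course
    coronary labels (the fully annotated subset of the training data).
    """
    ann = phantom.sparse_annotations(scan)
    sparse = labelgen.sparse_from_annotations(ann, scan.spec.shape, scan.spec.spacing)
    other = labelgen.generate_other_labels(scan.ct, scan.heart,
                                           n_iter=config.other_label_iterations)
    dense_lab = (phantom.coronary_tube_labels(scan.spec, config.dense_tube_radius_mm)
                 if dense else None)
    return labelgen.compose_supervision(sparse, other, scan.heart, dense_coronary=dense_lab)


def dice_per_class(pred: np.ndarray, truth: np.ndarray,
                   mask: np.ndarray | None = None) -> dict[int, float]:
    """Dice per class of `truth` (optionally restricted to `mask`)."""
    if mask is None:
        mask = np.ones_like(truth, dtype=bool)
    out = {}
    for c in np.unique(truth[mask]):
        a = (pred == c) & mask
        b = (truth == c) & mask
        denom = int(a.sum()) + int(b.sum())
        out[int(c)] = 2.0 * float((a & b).sum()) / denom if denom else float("nan")
    return out


def report_to_row(scan_id: str, rep: agatston.CacReport) -> dict:
    return {
        "scan_id": scan_id,
        "total": rep.total,
        "lm": rep.per_vessel["LM"],
        "lad": rep.per_vessel["LAD"],
        "lcx": rep.per_vessel["LCX"],
        "rca": rep.per_vessel["RCA"],
        "category": rep.risk_category,
    }


def reference_study(seed: int = 0, config: StudyConfig | None = None) -> dict:
    """Run the scaled-down end-to-end experiment and return its metrics.

    Returns a dict with the held-out risk-category agreement, Cohen's
    kappa with a 95% bootstrap-free binomial CI on the agreement rate,
    per-class Dice over the held-out scans' labelled voxels and over the
    full ground-truth territory maps, the score-agreement statistics
    (Bland-Altman, Pearson, K-S), and the truth/predicted score tables.
    """
    config = config or StudyConfig()
    t0 = time.time()
    train_scans = phantom.simulate_dataset(
        config.n_train, seed=_stage_seed(seed, 1),
        lesion_free_rate=config.lesion_free_rate,
        distractor_rate=config.distractor_rate)
    test_scans = phantom.simulate_dataset(
        config.n_test, seed=_stage_seed(seed, 2),
        lesion_free_rate=config.lesion_free_rate,
        distractor_rate=config.distractor_rate)
    log.info("simulated %d train / %d test phantoms in %.1fs",
             len(train_scans), len(test_scans), time.time() - t0)

    dense_every = max(1, round(1.0 / max(config.dense_label_fraction, 1e-9)))
    dataset = [
        (s.ct, s.heart, build_supervision(s, dense=(i % dense_every == 0), config=config))
        for i, s in enumerate(train_scans)
    ]

    t0 = time.time()
    net_cfg = config.net_config(seed=_stage_seed(seed, 3))
    net, train_log = heartnet.train(dataset, net_cfg)
    log.info("trained %d epochs in %.1fs (final loss %.3f)",
             net_cfg.epochs, time.time() - t0, train_log[-1]["loss"])

    rows_truth, rows_pred = [], []
    dice_sup: dict[int, list[float]] = {}
    dice_full: dict[int, list[float]] = {}
    for i, scan in enumerate(test_scans):
        pred_labels, _ = heartnet.predict(scan.ct, scan.heart, net)
        rep = agatston.score_scan(scan.ct, pred_labels)
        rows_truth.append(report_to_row(f"scan{i:03d}", scan.truth_report))
        rows_pred.append(report_to_row(f"scan{i:03d}", rep))
        sup = build_supervision(scan, dense=False, config=config)
        for c, d in dice_per_class(pred_labels.voxels, sup.labels, sup.supervise).items():
            dice_sup.setdefault(c, []).append(d)
        for c, d in dice_per_class(pred_labels.voxels, scan.territories.voxels).items():
            dice_full.setdefault(c, []).append(d)

    truth_df = pd.DataFrame(rows_truth)
    pred_df = pd.DataFrame(rows_pred)
    report, cm = evalstats.agreement_report(
        truth_df["total"], pred_df["total"],
        truth_df["category"], pred_df["category"], k=5)

    n = len(test_scans)
    n_agree = int((truth_df["category"] == pred_df["category"]).sum())
    ci_lo, ci_hi = _binomial_ci(n_agree, n)
    mean_sup = float(np.mean([np.mean(v) for v in dice_sup.values()]))
    mean_full = float(np.mean([np.mean(v) for v in dice_full.values()]))
    return {
        "config": config.model_dump(),
        "seed": seed,
        "n_test": n,
        "category_agreement": n_agree / n,
        "category_agreement_ci": (ci_lo, ci_hi),
        "kappa": report.kappa,
        "confusion": cm.counts.tolist(),
        "agreement_report": report.to_dict(),
        "dice_supervised": {c: float(np.mean(v)) for c, v in sorted(dice_sup.items())},
        "dice_full_map": {c: float(np.mean(v)) for c, v in sorted(dice_full.items())},
        "mean_dice_supervised": mean_sup,
        "mean_dice_full_map": mean_full,
        "train_loss_first": train_log[0]["loss"],
        "train_loss_last": train_log[-1]["loss"],
        "truth_table": truth_df,
        "pred_table": pred_df,
        "net": net,
    }


def _binomial_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return float("nan"), float("nan")
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return float(max(0.0, centre - half)), float(min(1.0, centre + half))


# ---------------------------------------------------------------------------
# full pipeline with artifacts on disk
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(out_dir: str | Path, seed: int = 0,
                 config: StudyConfig | None = None) -> Path:
    """Run the reference study and materialize every artifact under a
    run directory: phantom volumes, trained weights, per-scan reports,
    truth/prediction CSVs, the evaluation JSON, and a manifest with the
    config, seeds and content hashes of every output file."""
    config = config or StudyConfig()
    out = Path(out_dir)
    for sub in ("phantoms", "weights", "predictions", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    result = reference_study(seed=seed, config=config)
    net = result.pop("net")
    heartnet.save_weights(net, out / "weights" / "heartnet.npz")
    truth_df: pd.DataFrame = result.pop("truth_table")
    pred_df: pd.DataFrame = result.pop("pred_table")
    truth_df.to_csv(out / "reports" / "truth.csv", index=False)
    pred_df.to_csv(out / "reports" / "pred.csv", index=False)
    (out / "reports" / "evaluation.json").write_text(
        json.dumps(result, indent=2, default=_json_default))

    # a small illustrative sample of phantoms for inspection
    sample = phantom.simulate_dataset(2, seed=_stage_seed(seed, 2),
                                      lesion_free_rate=config.lesion_free_rate,
                                      distractor_rate=config.distractor_rate)
    for i, scan in enumerate(sample):
        io_volumes.write_volume(scan.ct, out / "phantoms" / f"scan{i:03d}_ct.nii.gz")
        io_volumes.write_volume(scan.heart, out / "phantoms" / f"scan{i:03d}_heart.nii.gz")
        io_volumes.write_volume(scan.territories, out / "phantoms" / f"scan{i:03d}_labels.nii.gz")

    manifest = {
        "seed": seed,
        "config": config.model_dump(),
        "files": {},
    }
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path: str | Path | None) -> StudyConfig:
    if path is None:
        return StudyConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return StudyConfig(**data)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def report_render(report: evalstats.AgreementReport,
                  cm: evalstats.ConfusionMatrix) -> str:
    """Human-readable markdown summary of a category agreement analysis."""
    k = cm.counts.shape[0]
    lines = ["| truth \\ pred | " + " | ".join(f"[{j}]" for j in range(k)) + " | n |",
             "|---" * (k + 2) + "|"]
    for i in range(k):
        lines.append(f"| [{i}] | " + " | ".join(str(int(v)) for v in cm.counts[i])
                     + f" | {int(cm.counts[i].sum())} |")
    lines += [
        "",
        f"- n = {cm.n}",
        f"- accuracy: {report.accuracy:.3f}",
        f"- Cohen's kappa: {report.kappa:.2f}",
        f"- sensitivity: {_pct(report.sensitivity)}, specificity: {_pct(report.specificity)}, "
        f"PPV: {_pct(report.ppv)}, NPV: {_pct(report.npv)}",
        f"- Bland-Altman: mean diff {report.ba_mean_diff:.1f}, "
        f"LoA [{report.ba_loa_low:.1f}, {report.ba_loa_high:.1f}]",
        f"- Pearson r: {report.pearson_r:.3f}" if np.isfinite(report.pearson_r) else "- Pearson r: undefined",
        f"- K-S: D = {report.ks_d:.3f}, p = {report.ks_p:.3f}",
    ]
    return "\n".join(lines)


def _pct(x: float) -> str:
    return "undefined" if not np.isfinite(x) else f"{100 * x:.1f}%"
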