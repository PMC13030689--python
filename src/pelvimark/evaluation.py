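"""Evaluation metrics: segmentation quality, localization-error summaries,
within-visit repeatability (STD, CV, ICC) and the hyperparameter grid.

Repeatability follows the measurement-reliability conventions for repeated
scans of the same quantity: the STD is the pooled within-visit standard
deviation, the CV expresses it as a percentage of the grand mean, and the
ICC is the two-way random-effects, absolute-agreement, single-measure form
(ICC(2,1); ICC(3,1) available by flag) with an F-based 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import LANDMARK_NAMES, LandmarkSet

__all__ = [
    "EvaluationReport",
    "RepeatabilityReport",
    "iou_recall",
    "localization_errors",
    "summarize_errors",
    "paired_distance_series",
    "repeatability",
    "sensitivity_grid",
    "LANDMARK_PAIRS",
]

#: paired measurement regions used for repeatability
LANDMARK_PAIRS = {
    "PSIS_L-PSIS_R": ("PSIS_L", "PSIS_R"),
    "IC_L-IC_R": ("IC_L", "IC_R"),
    "L1-L4": ("L1", "L4"),
}


@dataclass
class EvaluationReport:
    median_mm: float
    per_landmark_median_mm: dict[str, float]
    subject_mean_mm: float
    subject_ci95_mm: tuple[float, float]
    n_subjects: int
    n_instances: int
    n_missing: int
    cdf: pd.DataFrame  # columns: threshold_mm, cumulative_fraction

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (metric, group, value) for CSV export."""
        rows = [("median_mm", "overall", self.median_mm)]
        rows += [("median_mm", k, v) for k, v in self.per_landmark_median_mm.items()]
        rows += [
            ("subject_mean_mm", "overall", self.subject_mean_mm),
            ("subject_ci95_lo_mm", "overall", self.subject_ci95_mm[0]),
            ("subject_ci95_hi_mm", "overall", self.subject_ci95_mm[1]),
        ]
        return pd.DataFrame(rows, columns=["metric", "group", "value"])

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "median_mm": self.median_mm,
                "per_landmark_median_mm": self.per_landmark_median_mm,
                "subject_mean_mm": self.subject_mean_mm,
                "subject_ci95_mm": list(self.subject_ci95_mm),
                "n_subjects": self.n_subjects,
                "n_instances": self.n_instances,
                "n_missing": self.n_missing,
            }
        )


@dataclass
class RepeatabilityReport:
    regions: pd.DataFrame  # region, std_mm, cv_percent, icc, icc_ci_lo, icc_ci_hi


def iou_recall(pred, gt, classes=(0, 1)) -> dict[int, dict[str, float]]:
    """Class-specific IoU = TP/(TP+FP+FN) and recall = TP/(TP+FN).

    A class absent from both prediction and truth has undefined metrics and
    is reported as NaN.
    """
    p = np.asarray(getattr(pred, "labels", pred)).ravel()
    g = np.asarray(getattr(gt, "labels", gt)).ravel()
    if p.shape != g.shape:
        raise ValueError("prediction and ground truth must be aligned")
    out = {}
    for c in classes:
        tp = int(((p == c) & (g == c)).sum())
        fp = int(((p == c) & (g != c)).sum())
        fn = int(((p != c) & (g == c)).sum())
        if tp + fp + fn == 0:
            out[c] = {"iou": np.nan, "recall": np.nan}
        else:
            out[c] = {
                "iou": tp / (tp + fp + fn),
                "recall": tp / (tp + fn) if tp + fn else np.nan,
            }
    return out


def localization_errors(pred: LandmarkSet, gt: LandmarkSet) -> dict[str, float]:
    """Per-landmark Euclidean distance (mm); missing predictions are NaN."""
    out = {}
    for name in LANDMARK_NAMES:
        if name not in gt:
            continue
        out[name] = (
            float(np.linalg.norm(pred[name] - gt[name])) if name in pred else np.nan
        )
    return out


def summarize_errors(errors: pd.DataFrame, subject_col: str = "subject_id") -> EvaluationReport:
    """Summarize a long error table (columns: subject_id, landmark, error_mm).

    Medians are over non-missing instances; the subject-level mean is the
    unweighted mean of per-subject means with a Student-t 95% CI over
    subjects; the CDF is tabulated at 1 mm steps.
    """
    df = errors.copy()
    n_missing = int(df["error_mm"].isna().sum())
    valid = df.dropna(subset=["error_mm"])
    if valid.empty:
        raise ValueError("no valid errors to summarize")
    med = float(valid["error_mm"].median())
    per_lm = {
        k: float(v) for k, v in valid.groupby("landmark")["error_mm"].median().items()
    }
    subj_means = valid.groupby(subject_col)["error_mm"].mean()
    mean = float(subj_means.mean())
    n_subj = len(subj_means)
    if n_subj > 1:
        sem = subj_means.std(ddof=1) / np.sqrt(n_subj)
        tcrit = stats.t.ppf(0.975, df=n_subj - 1)
        ci = (float(mean - tcrit * sem), float(mean + tcrit * sem))
    else:
        ci = (mean, mean)
    thresholds = np.arange(0.0, np.ceil(valid["error_mm"].max()) + 1.0, 1.0)
    frac = [(valid["error_mm"] <= t).sum() / len(df) for t in thresholds]
    cdf = pd.DataFrame({"threshold_mm": thresholds, "cumulative_fraction": frac})
    return EvaluationReport(
        median_mm=med,
        per_landmark_median_mm=per_lm,
        subject_mean_mm=mean,
        subject_ci95_mm=ci,
        n_subjects=n_subj,
        n_instances=len(df),
        n_missing=n_missing,
        cdf=cdf,
    )


def paired_distance_series(records) -> pd.DataFrame:
    """Inter-landmark distances per repeat for the three paired regions.

    ``records`` is an iterable of objects with ``subject_id``, ``visit``,
    ``repeat`` and ``landmarks`` attributes (e.g. ScanRecord or predictions
    wrapped in the same structure).  A region whose landmark is missing in a
    repeat yields NaN for that repeat.
    """
    rows = []
    for rec in records:
        lms = rec.landmarks
        for region, (a, b) in LANDMARK_PAIRS.items():
            d = (
                float(np.linalg.norm(lms[a] - lms[b]))
                if (a in lms and b in lms)
                else np.nan
            )
            rows.append((rec.subject_id, rec.visit, rec.repeat, region, d))
    return pd.DataFrame(
        rows, columns=["subject_id", "visit", "repeat", "region", "distance_mm"]
    )


def _pooled_within_std(df: pd.DataFrame) -> tuple[float, float]:
    """Pooled within-visit STD and the grand mean of a region's distances."""
    stds, dfs = [], []
    for _, grp in df.groupby(["subject_id", "visit"]):
        vals = grp["distance_mm"].dropna().to_numpy()
        if len(vals) >= 2:
            stds.append(np.var(vals, ddof=1))
            dfs.append(len(vals) - 1)
    if not dfs:
        return np.nan, np.nan
    pooled = float(np.sqrt(np.average(stds, weights=dfs)))
    return pooled, float(df["distance_mm"].dropna().mean())


def repeatability(series: pd.DataFrame, icc_form: str = "ICC2") -> RepeatabilityReport:
    """Within-visit repeatability per measurement region.

    STD is the pooled within-visit standard deviation; CV is that STD as a
    percentage of the grand mean; the ICC treats each (subject, visit) as a
    target and the repeat index as the rater (visits with fewer repeats than
    the common count are truncated/dropped to keep the design balanced).
    Degenerate data with zero total variance yields a missing ICC.
    """
    import pingouin as pg

    rows = []
    for region, df in series.groupby("region"):
        std, grand = _pooled_within_std(df)
        cv = 100.0 * std / grand if grand and np.isfinite(std) and grand > 0 else np.nan
        # balanced long table for the ICC
        icc = ci_lo = ci_hi = np.nan
        sub = df.dropna(subset=["distance_mm"]).copy()
        sub["target"] = sub["subject_id"].astype(str) + "/" + sub["visit"].astype(str)
        counts = sub.groupby("target").size()
        # visits with a single usable repeat cannot inform the ICC; drop them
        # before balancing instead of letting them collapse the design
        usable = counts[counts >= 2]
        sub = sub[sub["target"].isin(usable.index)]
        counts = usable
        k = int(counts.min()) if len(counts) else 0
        if k >= 2 and len(counts) >= 2:
            trimmed = (
                sub.sort_values(["target", "repeat"])
                .groupby("target")
                .head(k)
                .copy()
            )
            trimmed["rater"] = trimmed.groupby("target").cumcount()
            if float(np.var(trimmed["distance_mm"])) <= 1e-24 or len(trimmed) < 5:
                rows.append((region, std, cv, np.nan, np.nan, np.nan))
                continue
            res = pg.intraclass_corr(
                data=trimmed,
                targets="target",
                raters="rater",
                ratings="distance_mm",
            ).set_index("Type")
            # two-way random, absolute agreement, single measure (and the
            # consistency form for the ICC3 flag); row/column labels differ
            # across pingouin versions
            aliases = {
                "ICC2": ("ICC2", "ICC(A,1)"),
                "ICC3": ("ICC3", "ICC(C,1)"),
            }[icc_form]
            key = next(k for k in aliases if k in res.index)
            row = res.loc[key]
            ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
            icc = float(row["ICC"])
            ci_lo, ci_hi = (float(v) for v in row[ci_col])
        rows.append((region, std, cv, icc, ci_lo, ci_hi))
    return RepeatabilityReport(
        regions=pd.DataFrame(
            rows,
            columns=["region", "std_mm", "cv_percent", "icc", "icc_ci_lo", "icc_ci_hi"],
        )
    )


def sensitivity_grid(
    train_records,
    test_records,
    cfg,
    lambda_dist_values=(5.0, 10.0, 15.0),
    radius_values=(10.0, 15.0, 20.0),
) -> pd.DataFrame:
    """Landmark-stage sensitivity grid: sweep lambda_dist at the 10 mm radius,
    then the labeling radius at lambda_dist = 10; the shared center setting
    trains once.  Returns rows (parameter, value, mean_error_mm).
    """
    from .losses import LossWeights
    from .training import (
        evaluate_landmarks,
        prepare_landmark_samples,
        train_landmarknet,
    )

    cache: dict[tuple[float, float], float] = {}

    def run(lmbd: float, radius: float) -> float:
        key = (float(lmbd), float(radius))
        if key not in cache:
            tr = prepare_landmark_samples(train_records, cfg, radius_mm=radius)
            te = prepare_landmark_samples(test_records, cfg, radius_mm=radius)
            model, _ = train_landmarknet(tr, cfg, w=LossWeights(lambda_dist=lmbd))
            errs, _ = evaluate_landmarks(model, te, cfg)
            cache[key] = float(errs["error_mm"].dropna().mean())
        return cache[key]

    rows = []
    for lmbd in lambda_dist_values:
        rows.append(("lambda_dist", lmbd, run(lmbd, 10.0)))
    for radius in radius_values:
        rows.append(("label_radius_mm", radius, run(10.0, radius)))
    return pd.DataFrame(rows, columns=["parameter", "value", "mean_error_mm"])
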