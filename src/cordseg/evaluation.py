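"""Per-ROI segmentation metrics and the DTI-specific Mean FA Error.

All metrics operate on hardened (argmax) label masks.  For each class i:

    TP(i) = |pred = i  and  label = i|        precision = TP / (TP + FP)
    FN(i) = |pred != i and  label = i|        recall    = TP / (TP + FN)
    FP(i) = |pred = i  and  label != i|       Dice      = 2TP / (2TP + FN + FP)

The confusion matrix counts pixels by (true class, predicted class); the
row-normalised form divides each row by its true-class pixel count.

The Mean FA Error of class i compares the mean FA computed over the
predicted mask with the mean FA over the reference mask of the same ROI:

    error(i) = |FA_measured(i) - FA_label(i)| / FA_label(i)

reported per slice, then aggregated as mean +/- std across slices.  A
class absent from a slice's reference (or with an empty prediction, for
FA_measured) is flagged as missing for that slice and excluded from the
aggregation rather than contributing zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import N_CLASSES, ROI_NAMES

FOREGROUND = tuple(range(1, N_CLASSES))


@dataclass
class MetricsReport:
    """Aggregated per-class precision/recall/Dice plus confusion matrix."""
    per_slice: pd.DataFrame          # columns: slice, class, tp, fn, fp, ...
    summary: pd.DataFrame            # per-class + "mean" row, mean & std
    confusion: np.ndarray            # 9x9 row-normalised ratios

    def mean_foreground_dice(self) -> float:
        return float(self.summary.loc["mean", "dice_mean"])

    def to_csv(self, metrics_path, confusion_path) -> None:
        self.summary.to_csv(metrics_path)
        pd.DataFrame(self.confusion,
                     index=[ROI_NAMES[i] for i in range(N_CLASSES)],
                     columns=[ROI_NAMES[i] for i in range(N_CLASSES)]
                     ).to_csv(confusion_path)


@dataclass
class FAReport:
    """Per-class labeled/measured mean FA and Mean FA Error."""
    per_slice: pd.DataFrame
    summary: pd.DataFrame            # label_fa/measured_fa/error mean & std

    def mean_roi_error(self) -> float:
        """Mean FA Error averaged over the 8 cord ROIs (fraction, not %)."""
        return float(self.summary.loc["mean", "error_mean"])

    def to_csv(self, path) -> None:
        self.summary.to_csv(path)


def confusion_counts(pred_mask: np.ndarray, label_mask: np.ndarray
                     ) -> dict[str, np.ndarray]:
    """Hard pixel counts: per-class TP/FN/FP and the 9x9 count matrix."""
    pred_mask = np.asarray(pred_mask)
    label_mask = np.asarray(label_mask)
    if pred_mask.shape != label_mask.shape:
        raise ValueError("pred/label shape mismatch")
    for m in (pred_mask, label_mask):
        if m.min() < 0 or m.max() >= N_CLASSES:
            raise ValueError("mask values outside 0..8")
    conf = np.bincount(
        (label_mask.astype(np.int64) * N_CLASSES + pred_mask).ravel(),
        minlength=N_CLASSES * N_CLASSES).reshape(N_CLASSES, N_CLASSES)
    tp = np.diag(conf).astype(np.int64)
    fn = conf.sum(axis=1) - tp          # row = true class
    fp = conf.sum(axis=0) - tp          # column = predicted class
    return {"tp": tp, "fn": fn, "fp": fp, "confusion": conf}


def precision_recall_dice(counts: dict[str, np.ndarray]) -> pd.DataFrame:
    """Eqs. precision/recall/Dice per class; absent classes yield NaN."""
    tp, fn, fp = (counts[k].astype(np.float64) for k in ("tp", "fn", "fp"))
    if (tp < 0).any() or (fn < 0).any() or (fp < 0).any():
        raise ValueError("counts must be nonnegative")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        dice = 2 * tp / (2 * tp + fn + fp)
    absent = (tp + fn + fp) == 0        # class in neither pred nor label
    for arr in (precision, recall, dice):
        arr[absent] = np.nan
    # a class that exists but is entirely missed scores 0, not NaN
    present = ~absent
    for arr in (precision, recall, dice):
        arr[present & np.isnan(arr)] = 0.0
    return pd.DataFrame({"tp": counts["tp"], "fn": counts["fn"],
                         "fp": counts["fp"], "precision": precision,
                         "recall": recall, "dice": dice},
                        index=range(N_CLASSES))


def row_normalize(conf: np.ndarray) -> np.ndarray:
    """Confusion ratios per true class; empty rows become NaN."""
    rows = conf.sum(axis=1, keepdims=True).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return conf / rows


def mean_fa_error_slice(pred_mask: np.ndarray, label_mask: np.ndarray,
                        fa_map: np.ndarray) -> pd.DataFrame:
    """Per-class FA_label, FA_measured and relative error for one slice."""
    fa_map = np.asarray(fa_map, dtype=np.float64)
    if fa_map.shape != label_mask.shape or pred_mask.shape != label_mask.shape:
        raise ValueError("fa map and masks must share one shape")
    rows = []
    for i in range(N_CLASSES):
        lab_sel = label_mask == i
        pred_sel = pred_mask == i
        label_fa = fa_map[lab_sel].mean() if lab_sel.any() else np.nan
        measured_fa = fa_map[pred_sel].mean() if pred_sel.any() else np.nan
        if np.isnan(label_fa) or np.isnan(measured_fa) or label_fa == 0:
            error = np.nan
        else:
            error = abs(measured_fa - label_fa) / label_fa
        rows.append({"class": i, "pixel_count": int(lab_sel.sum()),
                     "label_fa": label_fa, "measured_fa": measured_fa,
                     "error": error})
    return pd.DataFrame(rows)


def _aggregate(per_slice: pd.DataFrame, value_cols: list[str]
               ) -> pd.DataFrame:
    """Across-slice mean/std per class plus an 8-ROI 'mean' row."""
    out = {}
    grouped = per_slice.groupby("class")
    for col in value_cols:
        out[f"{col}_mean"] = grouped[col].mean()
        out[f"{col}_std"] = grouped[col].std(ddof=0)
    summary = pd.DataFrame(out)
    summary.index = [ROI_NAMES[i] for i in summary.index]
    fg = per_slice[per_slice["class"].isin(FOREGROUND)]
    per_slice_fg = fg.groupby("slice")[value_cols].mean()
    mean_row = {}
    for col in value_cols:
        mean_row[f"{col}_mean"] = per_slice_fg[col].mean()
        mean_row[f"{col}_std"] = per_slice_fg[col].std(ddof=0)
    summary.loc["mean"] = pd.Series(mean_row)
    return summary


def evaluate_masks(pred_masks, label_masks, fa_maps=None
                   ) -> tuple[MetricsReport, "FAReport | None"]:
    """Reports for parallel lists of predicted and reference masks."""
    metric_rows, fa_rows = [], []
    conf_total = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for k, (pred, lab) in enumerate(zip(pred_masks, label_masks)):
        counts = confusion_counts(pred, lab)
        conf_total += counts["confusion"]
        df = precision_recall_dice(counts)
        df = df.reset_index(names="class")
        df.insert(0, "slice", k)
        metric_rows.append(df)
        if fa_maps is not None:
            fdf = mean_fa_error_slice(pred, lab, fa_maps[k])
            fdf.insert(0, "slice", k)
            fa_rows.append(fdf)
    per_slice = pd.concat(metric_rows, ignore_index=True)
    # drop classes absent from both masks of a slice before aggregation
    valid = per_slice.dropna(subset=["dice"])
    metrics = MetricsReport(per_slice=per_slice,
                            summary=_aggregate(valid,
                                               ["precision", "recall", "dice"]),
                            confusion=row_normalize(conf_total))
    fa_report = None
    if fa_maps is not None:
        fa_all = pd.concat(fa_rows, ignore_index=True)
        fa_valid = fa_all.dropna(subset=["error"])
        fa_report = FAReport(per_slice=fa_all,
                             summary=_aggregate(
                                 fa_valid,
                                 ["label_fa", "measured_fa", "error"]))
    return metrics, fa_report


def evaluate_model(model, samples) -> tuple[MetricsReport, FAReport]:
    """Run inference on phantom samples and compute both reports.

    Argmax ties break toward the lowest class index (background favored).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("dataset is empty")
    preds = [model.predict_mask(s.b0) for s in samples]
    labels = [s.mask for s in samples]
    fas = [s.fa for s in samples]
    metrics, fa_report = evaluate_masks(preds, labels, fas)
    assert fa_report is not None
    return metrics, fa_report
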