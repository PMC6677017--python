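"""Assessment metrics for heavily imbalanced solvent classification.

With ~96% of peaks being water, raw accuracy is nearly meaningless (an
all-water predictor scores 98% on a 50:1 table), so the headline metric is
the F1 score with the smallest population assigned to the positive
condition, macro-averaged over classes for multi-class tables.  Additional
per-feature diagnostics: a signal-to-noise separation statistic, a
one-dimensional logistic-regression classifier per feature, and the
feature-swap impact dF1 (how much the final F1 drops when a feature's
values are exchanged between the sulfate and water populations).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import CC_FEATURES, ED_FEATURES

#: Default resolution bin edges (Å) for binned F1 reporting.
DEFAULT_RESOLUTION_BINS = (0.70, 1.31, 1.50, 1.72, 1.97, 2.25, 2.58, 2.95, 3.37, 4.50)


def accuracy_f1(labels, predictions, positive):
    """Accuracy and binary F1 treating ``positive`` as the positive condition."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.size == 0 or y.size != p.size:
        raise ValueError("labels and predictions must be equal-length and non-empty")
    acc = float(np.mean(y == p))
    tp = int(np.sum((y == positive) & (p == positive)))
    fp = int(np.sum((y != positive) & (p == positive)))
    fn = int(np.sum((y == positive) & (p != positive)))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, f1


def _class_vs_other_f1(labels, predictions, cls):
    """Binary class-vs-rest F1 with the smaller population as positive."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    in_cls = y == cls
    # smallest-population-positive convention
    if in_cls.sum() <= (~in_cls).sum():
        yb, pb = in_cls, p == cls
    else:
        yb, pb = ~in_cls, p != cls
    _, f1 = accuracy_f1(yb, pb, positive=True)
    return f1


def macro_f1(labels, predictions, classes=None) -> float:
    """Mean over classes of the class-vs-other F1 (smallest population positive)."""
    y = np.asarray(labels)
    if classes is None:
        classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("macro F1 needs at least two classes")
    return float(np.mean([_class_vs_other_f1(y, predictions, c) for c in classes]))


def confusion_matrix(labels, predictions, classes) -> pd.DataFrame:
    y = np.asarray(labels)
    p = np.asarray(predictions)
    mat = np.array([[np.sum((y == a) & (p == b)) for b in classes] for a in classes])
    return pd.DataFrame(mat, index=classes, columns=classes)


def snr(values, binary_labels) -> float:
    """Class separation: squared mean difference over summed variances."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(binary_labels)
    groups = sorted(set(y.tolist()))
    if len(groups) != 2:
        raise ValueError("snr needs exactly two classes")
    a, b = (x[y == g] for g in groups)
    denom = a.var() + b.var()
    if denom <= 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) ** 2 / denom)


def single_feature_lr(values, binary_labels, positive=None,
                      max_iter: int = 100, tol: float = 1e-8, cap: float = 15.0):
    """One-dimensional logistic regression by IRLS; returns (accuracy, f1).

    Coefficients are capped at ``cap`` (with a warning) under perfect
    separation, where the MLE diverges.  ``positive`` defaults to the
    minority class.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(binary_labels)
    groups = sorted(set(y.tolist()))
    if len(groups) != 2:
        raise ValueError("need exactly two classes")
    if positive is None:
        positive = min(groups, key=lambda g: np.sum(y == g))
    t = (y == positive).astype(float)
    xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    X = np.column_stack([np.ones_like(xs), xs])
    beta = np.zeros(2)
    capped = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        WX = X * w[:, None]
        try:
            delta = np.linalg.solve(X.T @ WX, X.T @ (t - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.max(np.abs(beta)) > cap:
            beta = np.clip(beta, -cap, cap)
            capped = True
            break
        if np.max(np.abs(delta)) < tol:
            break
    if capped:
        warnings.warn("perfect separation: logistic coefficients capped")
    pred_pos = (X @ beta) > 0
    acc, f1 = accuracy_f1(t.astype(bool), pred_pos, positive=True)
    return acc, f1


def _rank_matched_swap(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Exchange a feature between two populations by matched order statistics.

    The k-th ranked member of one class receives the matching quantile of the
    other class's values, so both marginal shapes are preserved even when
    the populations differ in size.
    """
    out = values.copy()
    va, vb = values[mask_a], values[mask_b]
    for mask, donor in ((mask_a, vb), (mask_b, va)):
        v = values[mask]
        ranks = np.argsort(np.argsort(v, kind="mergesort"), kind="mergesort")
        q = ranks / max(len(v) - 1, 1)
        out[mask] = np.quantile(donor, q)
    return out


def two_class_f1(labels, predictions, positive="sulfate", negative="water") -> float:
    """F1 on the rows labeled positive/negative; any other prediction counts
    against the true class."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    m = (y == positive) | (y == negative)
    _, f1 = accuracy_f1(y[m], p[m], positive=positive)
    return f1


def delta_f1(feature: str, trained, df: pd.DataFrame) -> float:
    """F1 change when a feature is swapped between sulfate and water rows.

    Negative values measure how much unique, non-redundant signal the feature
    carries; a feature whose information is shared with others loses little.
    """
    if feature not in ED_FEATURES + CC_FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    labels = df["label"].to_numpy()
    scores = trained.score_frame(df)
    pred0 = trained.predict_table(scores["ed"].to_numpy(), scores["cc"].to_numpy())
    f1_orig = two_class_f1(labels, pred0)
    swapped = df.copy()
    swapped[feature] = _rank_matched_swap(
        df[feature].to_numpy(dtype=float), labels == "sulfate", labels == "water")
    s1 = trained.score_frame(swapped)
    pred1 = trained.predict_table(s1["ed"].to_numpy(), s1["cc"].to_numpy())
    return two_class_f1(labels, pred1) - f1_orig


def binned_f1(labels, predictions, resolutions,
              bin_edges=DEFAULT_RESOLUTION_BINS, classes=None) -> pd.DataFrame:
    """Macro and per-class F1 within resolution bins."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    d = np.asarray(resolutions, dtype=float)
    if not (len(y) == len(p) == len(d)):
        raise ValueError("inconsistent lengths")
    if classes is None:
        classes = sorted(set(y))
    rows = []
    edges = list(bin_edges)
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (d >= lo) & (d < hi)
        row = {"d_min": lo, "d_max": hi, "count": int(m.sum())}
        if m.sum() == 0:
            row.update({"macro_f1": np.nan, **{f"f1_{c}": np.nan for c in classes}})
        else:
            present = [c for c in classes if np.any(y[m] == c)]
            row["macro_f1"] = (macro_f1(y[m], p[m], classes=present)
                               if len(present) >= 2 else np.nan)
            for c in classes:
                row[f"f1_{c}"] = (_class_vs_other_f1(y[m], p[m], c)
                                  if np.any(y[m] == c) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_features(df: pd.DataFrame, trained=None) -> pd.DataFrame:
    """Per-feature diagnostic table over the sulfate/water rows.

    Columns: correlation with resolution, S/N separation, single-feature LR
    accuracy and F1, and (when a trained classifier is given) dF1.
    """
    sub = df[df["label"].isin(["water", "sulfate"])]
    rows = []
    for f in ED_FEATURES + CC_FEATURES:
        x = sub[f].to_numpy(dtype=float)
        y = sub["label"].to_numpy()
        cc_r = float(np.corrcoef(x, sub["resolution"])[0, 1])
        acc, f1 = single_feature_lr(x, y, positive="sulfate")
        row = {"feature": f, "cc_r": cc_r, "snr": snr(x, y),
               "lr_accuracy": acc, "lr_f1": f1}
        if trained is not None:
            row["delta_f1"] = delta_f1(f, trained, df)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["rank"] = out["snr"].rank(ascending=False).astype(int)
    return out
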