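"""Euler-ratio quality control with per-site ROC thresholds.

The per-subject quality score is the ratio between the Euler characteristic
of each hemisphere's surface before topology correction and that surface's
vertex count; more negative means more reconstruction defects.  Against a
(partial) set of manual pass/fail labels, an ROC curve over candidate
thresholds yields a per-site cutoff (default criterion: Youden's J), and
subjects scoring below their site's threshold — or flagged during visual
inspection — are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, EstimationError

QC_COLUMNS = [
    "subject_id", "site_id", "euler_lh", "euler_rh",
    "nvert_lh", "nvert_rh", "manual_label",
]


def euler_ratio(
    euler_lh: float, euler_rh: float, nvert_lh: float, nvert_rh: float,
    combine: str = "min",
) -> float:
    """chi/nvert per hemisphere, combined as the worst (min) or the mean."""
    if nvert_lh <= 0 or nvert_rh <= 0:
        raise DataError("vertex counts must be positive")
    r_lh = euler_lh / nvert_lh
    r_rh = euler_rh / nvert_rh
    if combine == "min":
        return min(r_lh, r_rh)
    if combine == "mean":
        return (r_lh + r_rh) / 2.0
    raise ConfigurationError(f"unknown combine rule {combine!r}")


def euler_ratios(records: pd.DataFrame, combine: str = "min") -> pd.Series:
    """Vectorized `euler_ratio` over a QC table."""
    if (records["nvert_lh"] <= 0).any() or (records["nvert_rh"] <= 0).any():
        raise DataError("vertex counts must be positive")
    r_lh = records["euler_lh"] / records["nvert_lh"]
    r_rh = records["euler_rh"] / records["nvert_rh"]
    if combine == "min":
        out = np.minimum(r_lh, r_rh)
    elif combine == "mean":
        out = (r_lh + r_rh) / 2.0
    else:
        raise ConfigurationError(f"unknown combine rule {combine!r}")
    return pd.Series(out, index=records.index, name="euler_ratio")


@dataclass
class ROCResult:
    """ROC curve over score thresholds with a chosen operating point.

    "fail" is the positive class and lower scores indicate failure, so at
    threshold t the decision "score < t" has TPR = P(score < t | fail) and
    FPR = P(score < t | pass); both rise monotonically with t.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    chosen_threshold: float
    criterion: str = "youden"

    def sensitivity_specificity(self) -> tuple[float, float]:
        i = int(np.where(self.thresholds == self.chosen_threshold)[0][0])
        return float(self.tpr[i]), float(1.0 - self.fpr[i])


def roc_threshold(
    scores: Sequence[float],
    labels: Sequence[str],
    criterion: str = "youden",
) -> ROCResult:
    """Sweep all thresholds (midpoints between distinct scores, plus +/-inf).

    The trapezoid AUC over this sweep equals the Mann-Whitney U statistic
    divided by n_pass*n_fail.  The chosen threshold maximizes Youden's
    J = TPR - FPR; ties break toward the lower (less exclusionary) threshold.
    """
    if criterion != "youden":
        raise ConfigurationError(f"unknown selection criterion {criterion!r}")
    scores = np.asarray(scores, dtype=float)
    fail = np.asarray([str(l).lower() == "fail" for l in labels])
    n_fail = int(fail.sum())
    n_pass = int(len(fail) - n_fail)
    if n_fail == 0 or n_pass == 0:
        raise EstimationError(
            "ROC threshold undefined: need at least one pass and one fail label"
        )
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    below = scores[None, :] < thresholds[:, None]
    tpr = below[:, fail].mean(axis=1)
    fpr = below[:, ~fail].mean(axis=1)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax returns the first (lowest threshold) tie
    return ROCResult(thresholds, tpr, fpr, auc, float(thresholds[best]), criterion)


def fit_site_thresholds(
    records: pd.DataFrame,
    combine: str = "min",
    criterion: str = "youden",
) -> tuple[dict[str, float], dict[str, str], dict[str, ROCResult]]:
    """Per-site ROC thresholds with a pooled fallback for unlabeled sites.

    Returns (thresholds, provenance, rocs): provenance marks each site as
    "site" (own labels) or "pooled" (inherited all-site threshold).
    """
    ratios = euler_ratios(records, combine)
    labeled = records["manual_label"].isin(["pass", "fail"])
    if labeled.sum() == 0:
        raise EstimationError("no manual labels available in the QC table")
    pooled = roc_threshold(
        ratios[labeled], records.loc[labeled, "manual_label"], criterion
    )
    thresholds: dict[str, float] = {}
    provenance: dict[str, str] = {}
    rocs: dict[str, ROCResult] = {"__pooled__": pooled}
    for site, sub in records.groupby("site_id"):
        mask = sub["manual_label"].isin(["pass", "fail"])
        sub_labels = sub.loc[mask, "manual_label"]
        if (sub_labels == "fail").sum() >= 1 and (sub_labels == "pass").sum() >= 1:
            roc = roc_threshold(ratios[sub.index][mask], sub_labels, criterion)
            thresholds[site] = roc.chosen_threshold
            provenance[site] = "site"
            rocs[site] = roc
        else:
            thresholds[site] = pooled.chosen_threshold
            provenance[site] = "pooled"
    return thresholds, provenance, rocs


def apply_qc(
    records: pd.DataFrame,
    site_thresholds: Mapping[str, float],
    gross_exclusions: Iterable[str] = (),
    combine: str = "min",
    default_threshold: float | None = None,
) -> pd.DataFrame:
    """Inclusion manifest: excluded = visual flags UNION {ratio < threshold}.

    Exclusion by ratio uses strict inequality, so a subject exactly at the
    threshold is kept.  Visually flagged subjects are excluded regardless of
    their ratio (reason "visual").
    """
    gross = set(gross_exclusions)
    ratios = euler_ratios(records, combine)
    rows = []
    for idx, rec in records.iterrows():
        site = rec["site_id"]
        if site in site_thresholds:
            thr = site_thresholds[site]
        elif default_threshold is not None:
            thr = default_threshold
        else:
            raise ConfigurationError(f"no threshold for site {site!r} and no fallback")
        ratio = ratios[idx]
        visual = rec["subject_id"] in gross
        below = ratio < thr
        decision = "exclude" if (visual or below) else "include"
        reason = "visual" if visual else ("euler_ratio" if below else "")
        rows.append({
            "subject_id": rec["subject_id"], "site_id": site,
            "ratio": ratio, "threshold": thr,
            "decision": decision, "reason": reason,
        })
    return pd.DataFrame(rows)


def _tukey_hinges(x: np.ndarray) -> tuple[float, float, float]:
    """Median and Tukey hinges (medians of the halves, sharing the middle
    value when n is odd)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    med = float(np.median(x))
    half = (n + 1) // 2
    lower = x[:half]
    upper = x[n - half:]
    return float(np.median(lower)), med, float(np.median(upper))


def iqm_summary(
    metrics: pd.DataFrame,
    metric_columns: Sequence[str] | None = None,
    by: str = "site_id",
) -> pd.DataFrame:
    """Per-site five-number summaries plus 1.5*IQR outlier flags.

    Returns one row per (site, metric) with min, q1, median, q3, max
    (Tukey hinges) and a semicolon-joined list of outlying subject ids.
    """
    import warnings

    if metric_columns is None:
        metric_columns = [
            c for c in metrics.columns
            if c not in ("subject_id", by, "manual_label")
            and pd.api.types.is_numeric_dtype(metrics[c])
        ]
    rows = []
    for site, sub in metrics.groupby(by):
        for col in metric_columns:
            vals = sub[col].dropna()
            if len(vals) == 0:
                warnings.warn(f"site {site!r}: no data for metric {col!r}; skipped")
                continue
            q1, med, q3 = _tukey_hinges(vals.to_numpy())
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            out_mask = (vals < lo) | (vals > hi)
            if "subject_id" in sub.columns:
                outliers = sub.loc[vals.index[out_mask], "subject_id"].tolist()
            else:
                outliers = [str(i) for i in vals.index[out_mask]]
            rows.append({
                by: site, "metric": col,
                "min": float(vals.min()), "q1": q1, "median": med,
                "q3": q3, "max": float(vals.max()),
                "n": int(len(vals)), "outliers": ";".join(map(str, outliers)),
            })
    return pd.DataFrame(rows)
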