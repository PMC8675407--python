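"""Per-site effect breakdown (forest tables), combined estimates, and export.

A mega-analysis can be broken down into one OLS fit per site to show how the
effect of interest varies across sites; when the mega-model contains no fixed
slopes or fixed intercept (everything per-site), those separate fits
reproduce the mega-model's per-site columns exactly.  The combined row is the
inverse-variance-weighted mean with a normal-approximation 95% interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EstimationError
from .glm import DesignSpec, _encode

_Z95 = 1.959963984540054


def _site_fit(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """OLS estimate and classical SE of the last column's coefficient."""
    n, k = X.shape
    if n <= k or np.linalg.matrix_rank(X) < k:
        raise EstimationError("contrast inestimable within this site")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    s2 = float(resid @ resid) / (n - k)
    xtx_inv = np.linalg.inv(X.T @ X)
    return float(coef[-1]), float(np.sqrt(s2 * xtx_inv[-1, -1]))


def per_site_effects(y, subjects: pd.DataFrame, spec: DesignSpec,
                     weighting: str = "inverse_variance") -> pd.DataFrame:
    """Forest table: per-site OLS interest-effect estimates plus combined row.

    Each site is fitted separately with an intercept, the interest variable,
    and the nuisance terms (within a single site "random" and "fixed" slopes
    coincide).  Sites where the contrast is inestimable (e.g. a single group
    present) get an NA row and are excluded from the combined estimate.
    """
    if weighting not in ("inverse_variance", "sample_size"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ConfigurationError("per_site_effects expects a single element (1-D y)")
    interest = [t for t in spec.terms if t.role == "interest"]
    if len(interest) != 1:
        raise ConfigurationError("exactly one interest term is required")
    nuisance = [t for t in spec.terms if t.role != "interest"]

    rows = []
    sites = subjects[spec.site_column].to_numpy()
    for site in pd.unique(sites):
        mask = sites == site
        sub = subjects[mask]
        cols = [np.ones(mask.sum())]
        for t in nuisance:
            v = _encode(sub[t.variable])
            v = v - v.mean()
            cols.append(v)
            if t.transform == "quadratic":
                q = v**2
                cols.append(q - q.mean())
        v = _encode(sub[interest[0].variable])
        cols.append(v - v.mean())
        X = np.column_stack(cols)
        try:
            est, se = _site_fit(y[mask], X)
            rows.append({"site": site, "estimate": est, "se": se,
                         "ci_low": est - _Z95 * se, "ci_high": est + _Z95 * se,
                         "n": int(mask.sum()), "weighting": ""})
        except EstimationError:
            rows.append({"site": site, "estimate": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "n": int(mask.sum()), "weighting": "inestimable"})

    table = pd.DataFrame(rows)
    ok = table["se"].notna() & (table["se"] > 0)
    if not ok.any():
        raise EstimationError("no site has an estimable contrast")
    est = table.loc[ok, "estimate"].to_numpy()
    se = table.loc[ok, "se"].to_numpy()
    n = table.loc[ok, "n"].to_numpy()
    w = 1.0 / se**2 if weighting == "inverse_variance" else n.astype(float)
    combined = float((w * est).sum() / w.sum())
    if weighting == "inverse_variance":
        comb_se = float(np.sqrt(1.0 / w.sum()))
    else:
        comb_se = float(np.sqrt((w**2 * se**2).sum() / w.sum() ** 2))
    table.loc[len(table)] = {
        "site": "combined", "estimate": combined, "se": comb_se,
        "ci_low": combined - _Z95 * comb_se,
        "ci_high": combined + _Z95 * comb_se,
        "n": int(n.sum()), "weighting": weighting,
    }
    return table


def export(results: pd.DataFrame | None, forest: pd.DataFrame | None,
           out_dir, vertexwise: bool = False) -> list[str]:
    """Write result tables as TSV; adds -log10 p columns to the results.

    With ``vertexwise=True`` each p-value column is additionally written as a
    two-column per-vertex data file aligned to the analysis mesh.  Returns
    the written paths.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    if results is not None:
        res = results.copy()
        for col in ("p_unc", "p_fwer", "p_fdr"):
            if col in res.columns:
                res[f"neg_log10_{col}"] = -np.log10(res[col])
        path = out_dir / "results.tsv"
        res.to_csv(path, sep="\t", index=False)
        written.append(str(path))
        if vertexwise:
            for col in ("p_unc", "p_fwer", "p_fdr"):
                if col not in res.columns:
                    continue
                for fam, sub in res.groupby("family"):
                    path = out_dir / f"map_{fam}_{col}.tsv"
                    sub[["element_id", col]].to_csv(path, sep="\t", index=False)
                    written.append(str(path))
    if forest is not None:
        path = out_dir / "forest.tsv"
        forest.to_csv(path, sep="\t", index=False)
        written.append(str(path))
    return written


def forest_plot(forest: pd.DataFrame, path) -> None:
    """Simple forest plot (per-site estimates with CIs plus combined)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.5 * len(forest) + 1))
    ypos = np.arange(len(forest))[::-1]
    for y, (_, row) in zip(ypos, forest.iterrows()):
        color = "tab:red" if row["site"] == "combined" else "tab:blue"
        if np.isfinite(row["estimate"]):
            ax.errorbar(row["estimate"], y,
                        xerr=[[row["estimate"] - row["ci_low"]],
                              [row["ci_high"] - row["estimate"]]],
                        fmt="o", color=color, capsize=3)
    ax.axvline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(forest["site"])
    ax.set_xlabel("effect estimate (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
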