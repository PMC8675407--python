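"""Design matrices for multi-site GLMs: fixed/random intercepts and slopes,
global-covariate strategies, and contrasts of interest.

"Random" here is the design-matrix sense used in permutation-based multi-site
analyses: a random intercept expands to one indicator column per site and a
random slope to one (within-site centered) covariate column per site, so a
per-site interaction is explicit in the model rather than integrated out.
The contrast for a random-slope effect of interest spans its per-site columns
with site-size (default) or equal weights.

Global covariates (total surface area, mean thickness, intracranial volume)
can be handled by one of three strategies: divide each element by the global
(proportion), residualize the data on it, or include it as a model column —
the latter generally preferred.  ``dual_model_run`` fits the model with and
without the global and corrects across both families jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .errors import ConfigurationError, DataError


@dataclass
class Term:
    """One model variable: its role, slope type, and transform."""

    variable: str
    role: str = "nuisance"      # "interest" | "nuisance"
    slope: str = "fixed"        # "fixed" | "random" (per-site columns)
    transform: str = "none"     # "none" | "center" | "quadratic"

    def __post_init__(self) -> None:
        if self.role not in ("interest", "nuisance"):
            raise ConfigurationError(f"bad role {self.role!r} for {self.variable!r}")
        if self.slope not in ("fixed", "random"):
            raise ConfigurationError(f"bad slope {self.slope!r} for {self.variable!r}")
        if self.transform not in ("none", "center", "quadratic"):
            raise ConfigurationError(
                f"bad transform {self.transform!r} for {self.variable!r}"
            )


@dataclass
class DesignSpec:
    terms: Sequence[Term]
    intercept: str = "random"           # "fixed" | "random"
    global_strategy: str = "none"       # "none"|"proportion"|"residualize"|"include"
    global_variable: str | None = None
    site_column: str = "site_id"
    scanner_column: str = "scanner_id"
    interest_weights: str = "size"      # "size" | "equal"

    def __post_init__(self) -> None:
        if self.intercept not in ("fixed", "random"):
            raise ConfigurationError(f"bad intercept kind {self.intercept!r}")
        if self.global_strategy not in ("none", "proportion", "residualize", "include"):
            raise ConfigurationError(f"bad global strategy {self.global_strategy!r}")
        if self.global_strategy != "none" and not self.global_variable:
            raise ConfigurationError("global_strategy set but no global_variable")


@dataclass
class DesignMatrix:
    """Numeric design aligned to the subject table, with contrast and groups."""

    matrix: np.ndarray
    columns: list[str]
    contrast: np.ndarray
    variance_groups: np.ndarray
    exchangeability_blocks: np.ndarray
    subject_ids: list = field(default_factory=list)
    site_of_column: list = field(default_factory=list)  # site label or None per column

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def _encode(values: pd.Series) -> np.ndarray:
    """Numeric covariates pass through; two-level categoricals become
    centered +/-1/2 indicators."""
    if pd.api.types.is_numeric_dtype(values):
        v = values.to_numpy(dtype=float)
        if set(np.unique(v)) <= {0.0, 1.0}:
            return v - 0.5
        return v
    levels = sorted(values.dropna().unique())
    if len(levels) != 2:
        raise ConfigurationError(
            f"categorical variable {values.name!r} must have exactly 2 levels "
            f"(got {levels}); recode multi-level factors as indicators first"
        )
    return np.where(values == levels[1], 0.5, -0.5)


def _aliased_columns(M: np.ndarray, names: list[str]) -> list[str]:
    _, _, piv = sla.qr(M, pivoting=True, mode="economic")
    rank = np.linalg.matrix_rank(M)
    return [names[i] for i in sorted(piv[rank:])]


def build_design(subjects: pd.DataFrame, spec: DesignSpec) -> DesignMatrix:
    """Expand a DesignSpec against a subject table.

    Random intercept: one indicator per site (no global intercept column).
    Random slope for v: site_i * (v centered within site), one column per
    site; sites where v is constant lose their column with a warning.
    Quadratic adds the square of the (centered) variable under the same rule.
    """
    n = len(subjects)
    sites = subjects[spec.site_column].to_numpy()
    site_levels = list(pd.unique(sites))
    for s in site_levels:
        if (sites == s).sum() < 1:
            raise ConfigurationError(f"empty site {s!r}")

    cols: list[np.ndarray] = []
    names: list[str] = []
    col_site: list = []
    interest_cols: list[int] = []
    interest_weight: list[float] = []

    if spec.intercept == "random":
        for s in site_levels:
            cols.append((sites == s).astype(float))
            names.append(f"intercept[{s}]")
            col_site.append(s)
    else:
        cols.append(np.ones(n))
        names.append("intercept")
        col_site.append(None)

    for term in spec.terms:
        if term.variable not in subjects.columns:
            raise ConfigurationError(f"variable {term.variable!r} not in the table")
        raw = _encode(subjects[term.variable])
        if np.isnan(raw).any():
            keep = ~np.isnan(raw)
            raise DataError(
                f"variable {term.variable!r} has {int((~keep).sum())} missing "
                "values; apply listwise deletion before building the design"
            )
        powers = [1] if term.transform != "quadratic" else [1, 2]
        for p in powers:
            suffix = "" if p == 1 else "^2"
            if term.slope == "fixed":
                v = raw - raw.mean() if term.transform in ("center", "quadratic") else raw
                col = v**p
                if p == 2:
                    col = col - col.mean()
                cols.append(col)
                names.append(f"{term.variable}{suffix}")
                col_site.append(None)
                if term.role == "interest" and p == 1:
                    interest_cols.append(len(cols) - 1)
                    interest_weight.append(1.0)
            else:
                for s in site_levels:
                    mask = sites == s
                    v = raw[mask] - raw[mask].mean()  # within-site centering
                    if np.allclose(v, 0.0):
                        warnings.warn(
                            f"variable {term.variable!r} constant within site "
                            f"{s!r}; dropping its random-slope column"
                        )
                        continue
                    col = np.zeros(n)
                    col[mask] = v**p
                    if p == 2:
                        col[mask] -= col[mask].mean()
                    cols.append(col)
                    names.append(f"{term.variable}{suffix}[{s}]")
                    col_site.append(s)
                    if term.role == "interest" and p == 1:
                        interest_cols.append(len(cols) - 1)
                        w = mask.mean() if spec.interest_weights == "size" else 1.0
                        interest_weight.append(w)

    M = np.column_stack(cols)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        raise ConfigurationError(
            f"design is rank deficient; aliased columns: {_aliased_columns(M, names)}"
        )
    if not interest_cols:
        raise ConfigurationError("no interest term in the design specification")
    C = np.zeros(M.shape[1])
    w = np.asarray(interest_weight)
    C[interest_cols] = w / w.sum()  # weighted mean of per-site slopes

    if spec.scanner_column in subjects.columns:
        blocks = subjects[spec.scanner_column].to_numpy()
    else:
        blocks = sites
    return DesignMatrix(
        matrix=M, columns=names, contrast=C,
        variance_groups=sites, exchangeability_blocks=blocks,
        subject_ids=list(subjects.get("subject_id", pd.RangeIndex(n))),
        site_of_column=col_site,
    )


def apply_global_strategy(Y: np.ndarray, g: np.ndarray, strategy: str):
    """Adjust data and/or return an extra design column for a global covariate.

    Returns (Y_adjusted, extra_column_or_None, provenance_string).
    """
    Y = np.asarray(Y, dtype=float)
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise DataError("global covariate contains non-finite values")
    if strategy == "none":
        return Y, None, "global:none"
    if strategy == "proportion":
        if np.any(g == 0):
            raise DataError("global covariate has zeros; proportion undefined")
        return Y / g[:, None], None, "global:proportion"
    if strategy == "residualize":
        D = np.column_stack([np.ones_like(g), g])
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        return Y - D @ coef, None, "global:residualize"
    if strategy == "include":
        return Y, g - g.mean(), "global:include"
    raise ConfigurationError(f"unknown global strategy {strategy!r}")


def add_global_column(design: DesignMatrix, g_centered: np.ndarray,
                      name: str = "global") -> DesignMatrix:
    """Append the (centered) global covariate as a nuisance column."""
    r = np.corrcoef(g_centered, design.matrix @ design.contrast)[0, 1]
    if np.isfinite(r) and abs(r) > 0.99:
        warnings.warn(
            "global covariate is nearly collinear (|r| > 0.99) with the "
            "interest contrast; results are produced but may be unstable"
        )
    M = np.column_stack([design.matrix, g_centered])
    return DesignMatrix(
        matrix=M, columns=design.columns + [name],
        contrast=np.append(design.contrast, 0.0),
        variance_groups=design.variance_groups,
        exchangeability_blocks=design.exchangeability_blocks,
        subject_ids=design.subject_ids,
        site_of_column=design.site_of_column + [None],
    )


def dual_model_run(Y, subjects: pd.DataFrame, spec: DesignSpec, scheme,
                   element_ids: Sequence | None = None) -> pd.DataFrame:
    """Run inference with and without the global covariate, jointly corrected.

    Both model families share the same permutation schedule, and the
    max-statistic FWER correction pools the two families, since presenting
    results from two models doubles the opportunities for false positives.
    """
    from .inference import fdr_bh, fwer_maxstat, permutation_test

    if not spec.global_variable:
        raise ConfigurationError("dual_model_run requires a global_variable")
    if spec.global_variable not in subjects.columns:
        raise ConfigurationError(
            f"global variable {spec.global_variable!r} not in the table"
        )
    Y = np.asarray(Y, dtype=float)
    g = subjects[spec.global_variable].to_numpy(dtype=float)

    base = build_design(subjects, replace(spec, global_strategy="none"))
    strategy = spec.global_strategy if spec.global_strategy != "none" else "include"
    Y_adj, extra, provenance = apply_global_strategy(Y, g, strategy)
    withg = add_global_column(base, extra, spec.global_variable) \
        if extra is not None else base

    if scheme.blocks is None:
        from dataclasses import replace as _dc_replace

        scheme = _dc_replace(scheme, blocks=base.exchangeability_blocks)
    res_without = permutation_test(Y, base.matrix, base.contrast, scheme,
                                   variance_groups=base.variance_groups)
    res_with = permutation_test(Y_adj, withg.matrix, withg.contrast, scheme,
                                variance_groups=withg.variance_groups)
    p_fwer = fwer_maxstat([res_without, res_with])

    ids = list(element_ids) if element_ids is not None else list(range(Y.shape[1]))
    frames = []
    for fam, res, pf in (
        ("without_global", res_without, p_fwer[0]),
        (provenance, res_with, p_fwer[1]),
    ):
        frames.append(pd.DataFrame({
            "element_id": ids, "family": fam, "stat": res.stat,
            "p_unc": res.p_unc, "p_fwer": pf, "p_fdr": fdr_bh(res.p_unc),
        }))
    return pd.concat(frames, ignore_index=True)
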