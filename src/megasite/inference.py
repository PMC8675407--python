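"""Permutation inference for the GLM with exchangeability blocks, variance
groups, a heteroscedasticity-robust statistic, and max-statistic FWER.

The test statistic is the Aspin-Welch v for rank-1 contrasts and its F-type
generalization (the G statistic) for multi-column contrasts: residual
variances are estimated separately within each variance group (by default one
group per site), observations are weighted by group df / group residual sum
of squares, and the contrast variance is assembled from those weights.  With
a single variance group both reduce exactly to the classical t and F.

Permutation follows the Freedman-Lane scheme: the nuisance-only fit is
removed, residuals are permuted within exchangeability blocks (site or
scanner), the nuisance fit is re-added, and the statistic recomputed on the
full model.  Under exchangeability within blocks the test is exact: the
probability of p < alpha is alpha under the null.  Familywise error across
elements — and across measure/model families sharing the same permutation
schedule — is controlled by referring each observed statistic to the
permutation distribution of the maximum statistic over all pooled tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, EstimationError

_TIE_TOL = 1e-12


@dataclass
class PermutationScheme:
    """How to permute: count, blocks, variance groups, seed, exhaustiveness."""

    n_perm: int
    blocks: Sequence | None = None
    variance_groups: Sequence | None = None
    seed: int = 0
    exhaustive: bool = False
    exhaustive_cap: int = 50_000

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be at least 1")

    def key(self, n: int) -> tuple:
        blocks = tuple(np.asarray(self.blocks)) if self.blocks is not None else None
        return (n, self.n_perm, blocks, int(self.seed), bool(self.exhaustive))


@dataclass
class PermutationResult:
    """Observed statistics, uncorrected p-values, and the full null stream.

    ``null`` holds magnitude-scale statistics with one row per permutation;
    the first row is the identity permutation (the observed data).
    """

    stat: np.ndarray        # (V,) observed, signed for t-type
    p_unc: np.ndarray       # (V,)
    null: np.ndarray        # (P, V) magnitude scale, row 0 = identity
    exhaustive: bool
    scheme_key: tuple

    @property
    def n_perm(self) -> int:
        return self.null.shape[0] - 1


def _group_onehot(groups, n: int) -> tuple[np.ndarray, np.ndarray]:
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups)
    if len(groups) != n:
        raise DataError("variance-group labels do not match the data rows")
    _, inverse = np.unique(groups, return_inverse=True)
    B = inverse.max() + 1
    onehot = np.zeros((n, B))
    onehot[np.arange(n), inverse] = 1.0
    return onehot, inverse


def _stat_batch(
    Y: np.ndarray, M: np.ndarray, C: np.ndarray,
    onehot: np.ndarray, R: np.ndarray, dfres_b: np.ndarray,
) -> np.ndarray:
    """Aspin-Welch v (s=1, signed) or G (s>1) for each column of Y."""
    E = R @ Y                                   # (N, V) residuals of full model
    sse = onehot.T @ (E * E)                    # (B, V)
    if np.any(sse <= 0):
        sse = np.maximum(sse, 1e-300)
    Wb = dfres_b[:, None] / sse                 # (B, V)
    w = onehot @ Wb                             # (N, V) per-observation weights
    A = np.einsum("nk,nv,nl->vkl", M, w, M)     # (V, k, k)
    rhs = np.einsum("nk,nv->vk", M, w * Y)      # (V, k)
    psi = np.linalg.solve(A, rhs[..., None])[..., 0]  # (V, k) weighted estimates
    C = np.atleast_2d(C.T).T if C.ndim == 1 else C
    s = C.shape[1]
    Ainv_C = np.linalg.solve(A, np.broadcast_to(C, (A.shape[0],) + C.shape))
    S = np.einsum("ks,vkt->vst", C, Ainv_C)     # (V, s, s) = C' A^{-1} C
    cpsi = psi @ C                              # (V, s)
    if s == 1:
        return (cpsi[:, 0] / np.sqrt(S[:, 0, 0]))
    quad = np.einsum("vs,vst,vt->v", cpsi, np.linalg.inv(S), cpsi)
    n_b = onehot.sum(axis=0)
    sw = (n_b[:, None] * Wb).sum(axis=0)        # (V,) total weight
    h = (n_b[:, None] * Wb) / sw[None, :]       # (B, V)
    lam = 1.0 + (2.0 * (s - 1) / (s * (s + 2.0))) * (
        ((1.0 - h) ** 2) / dfres_b[:, None]
    ).sum(axis=0)
    return quad / (s * lam)


def _prepare(M: np.ndarray, variance_groups) -> tuple:
    M = np.asarray(M, dtype=float)
    N, k = M.shape
    if np.linalg.matrix_rank(M) < k:
        raise ConfigurationError("design matrix is rank deficient")
    pinv = np.linalg.pinv(M)
    R = np.eye(N) - M @ pinv
    onehot, inverse = _group_onehot(variance_groups, N)
    dfres_b = onehot.T @ np.diag(R)
    if np.any(dfres_b <= 1e-8):
        raise EstimationError(
            "a variance group has zero residual degrees of freedom"
        )
    return M, R, onehot, dfres_b


def robust_statistic(Y, M, C, variance_groups=None) -> np.ndarray | float:
    """Heteroscedasticity-robust contrast statistic (v for rank-1, else G).

    ``variance_groups=None`` puts all observations in one group, reducing to
    the classical t (signed) or F.  Returns a scalar for 1-D ``Y``.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    M, R, onehot, dfres_b = _prepare(M, variance_groups)
    C = np.asarray(C, dtype=float)
    stat = _stat_batch(Y, M, C, onehot, R, dfres_b)
    return float(stat[0]) if squeeze else stat


def _block_indices(blocks, n: int) -> list[np.ndarray]:
    if blocks is None:
        return [np.arange(n)]
    blocks = np.asarray(blocks)
    if len(blocks) != n:
        raise DataError("exchangeability-block labels do not match the data rows")
    # order blocks by first occurrence so results are invariant to relabeling
    _, first = np.unique(blocks, return_index=True)
    ordered = blocks[np.sort(first)]
    return [np.nonzero(blocks == b)[0] for b in ordered]


def count_rearrangements(blocks, n: int) -> int:
    """Number of distinct within-block row rearrangements (product of n_b!)."""
    total = 1
    for idx in _block_indices(blocks, n):
        total *= math.factorial(len(idx))
    return total


def _enumerate_perms(block_idx: list[np.ndarray], n: int) -> np.ndarray:
    per_block = [list(itertools.permutations(idx)) for idx in block_idx]
    perms = []
    for combo in itertools.product(*per_block):
        perm = np.arange(n)
        for idx, arrangement in zip(block_idx, combo):
            perm[idx] = arrangement
        perms.append(perm)
    return np.asarray(perms)


def _sample_perms(block_idx: list[np.ndarray], n: int, n_perm: int,
                  seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perms = np.tile(np.arange(n), (n_perm, 1))
    for p in range(n_perm):
        for idx in block_idx:
            perms[p, idx] = idx[rng.permutation(len(idx))]
    return perms


def permutation_test(Y, M, C, scheme: PermutationScheme,
                     variance_groups=None) -> PermutationResult:
    """Freedman-Lane permutation test of contrast C in the model Y = M psi + e.

    Nuisance columns (zero contrast weight) are fitted and their residuals
    permuted within blocks; p_unc = (1 + #{perm stat >= observed}) /
    (1 + n_perm), which includes the identity and is therefore never below
    1/(n_perm+1).  In exhaustive mode all within-block rearrangements are
    enumerated (when their count fits the cap) and the p-value is the exact
    enumeration probability.  t-type contrasts are two-sided via |v|.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    N, V = Y.shape
    if variance_groups is None:
        variance_groups = scheme.variance_groups
    M, R, onehot, dfres_b = _prepare(M, variance_groups)
    C = np.asarray(C, dtype=float)
    Cmat = C[:, None] if C.ndim == 1 else C
    two_sided = Cmat.shape[1] == 1

    # nuisance partition for Freedman-Lane
    nuisance = np.all(Cmat == 0.0, axis=1)
    if nuisance.any():
        Z = M[:, nuisance]
        Hz = Z @ np.linalg.pinv(Z)
        Rz_Y = Y - Hz @ Y
        base = Y - Rz_Y
    else:
        Rz_Y = Y
        base = np.zeros_like(Y)

    block_idx = _block_indices(scheme.blocks, N)
    total = count_rearrangements(scheme.blocks, N)
    exhaustive = scheme.exhaustive and total <= scheme.exhaustive_cap
    if scheme.exhaustive and not exhaustive:
        import warnings

        warnings.warn(
            f"{total} rearrangements exceed the exhaustive cap "
            f"({scheme.exhaustive_cap}); falling back to sampling"
        )
    if exhaustive:
        perms = _enumerate_perms(block_idx, N)  # identity comes first
    else:
        sampled = _sample_perms(block_idx, N, scheme.n_perm, scheme.seed)
        perms = np.vstack([np.arange(N)[None, :], sampled])
    P = len(perms)

    Ystack = Rz_Y[perms] + base[None, :, :]          # (P, N, V)
    flat = np.moveaxis(Ystack, 1, 0).reshape(N, P * V)
    stats = _stat_batch(flat, M, C, onehot, R, dfres_b).reshape(P, V)

    obs = stats[0]
    null = np.abs(stats) if two_sided else stats
    obs_mag = null[0]
    tol = _TIE_TOL * np.maximum(1.0, np.abs(obs_mag))
    exceed = (null >= (obs_mag - tol)[None, :]).sum(axis=0)
    p_unc = exceed / P
    return PermutationResult(
        stat=obs, p_unc=p_unc, null=null,
        exhaustive=exhaustive, scheme_key=scheme.key(N),
    )


def fwer_maxstat(results: Sequence[PermutationResult],
                 pool: str = "joint") -> list[np.ndarray]:
    """FWER-adjusted p-values from the permutation distribution of the max.

    With ``pool="joint"`` the maximum is taken per permutation over every
    element of every family (requiring all families to share one permutation
    schedule); ``pool="separate"`` corrects each family over its own elements
    only.  Returns one adjusted-p array per input family.
    """
    if pool not in ("joint", "separate"):
        raise ConfigurationError(f"unknown pooling mode {pool!r}")
    if not results:
        raise ConfigurationError("no permutation results to correct")
    if pool == "joint":
        key = results[0].scheme_key
        for r in results[1:]:
            if r.scheme_key != key:
                raise ConfigurationError(
                    "families have mismatched permutation schedules; "
                    "joint max-statistic correction requires a shared schedule"
                )
        max_row = np.max(
            np.column_stack([r.null for r in results]), axis=1
        )
        out = []
        for r in results:
            obs = r.null[0]
            tol = _TIE_TOL * np.maximum(1.0, obs)
            p = (max_row[:, None] >= (obs - tol)[None, :]).sum(axis=0) / len(max_row)
            out.append(p)
        return out
    out = []
    for r in results:
        max_row = r.null.max(axis=1)
        obs = r.null[0]
        tol = _TIE_TOL * np.maximum(1.0, obs)
        p = (max_row[:, None] >= (obs - tol)[None, :]).sum(axis=0) / len(max_row)
        out.append(p)
    return out


def fdr_bh(p_unc) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_unc, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_glm(Y, design, scheme: PermutationScheme,
            element_ids: Sequence | None = None,
            family: str = "model") -> tuple[pd.DataFrame, PermutationResult]:
    """One-family analysis: permutation p, max-stat FWER, and BH FDR.

    ``design`` is a glm.DesignMatrix; blocks/variance groups default to the
    design's unless the scheme overrides them.
    """
    scheme_blocks = scheme.blocks if scheme.blocks is not None \
        else design.exchangeability_blocks
    eff = PermutationScheme(
        n_perm=scheme.n_perm, blocks=scheme_blocks,
        variance_groups=scheme.variance_groups
        if scheme.variance_groups is not None else design.variance_groups,
        seed=scheme.seed, exhaustive=scheme.exhaustive,
        exhaustive_cap=scheme.exhaustive_cap,
    )
    res = permutation_test(np.asarray(Y, dtype=float), design.matrix,
                           design.contrast, eff,
                           variance_groups=eff.variance_groups)
    p_fwer = fwer_maxstat([res])[0]
    ids = list(element_ids) if element_ids is not None \
        else list(range(len(res.stat)))
    table = pd.DataFrame({
        "element_id": ids, "family": family, "stat": res.stat,
        "p_unc": res.p_unc, "p_fwer": p_fwer, "p_fdr": fdr_bh(res.p_unc),
    })
    return table, res
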