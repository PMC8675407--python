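"""Seeded synthetic multi-site cohorts, measurement matrices, and QC metrics.

The generative model for a measurement of subject *j* at element *v* is

    Y_jv = alpha + sum_c X_jc * beta_cv + gamma_i + delta_i * eps_jv,

with ``gamma_i`` an additive and ``delta_i`` a multiplicative site (batch)
effect, and ``eps_jv ~ Normal(0, sigma^2)`` — the location/scale batch model
that ComBat-style harmonization assumes.  Covariates are drawn per site
(truncated-normal age, Bernoulli sex/group), so covariate distributions can
differ across sites, e.g. some sites enrolling only young and others only
elderly participants.

Randomness is organised as one master seed spawning named substreams
(cohort / measures / qc), and within each stream one substream per subject,
keyed on a stable per-subject index.  Shuffling the row order of a cohort
therefore never changes the values any given subject receives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

# stream tags for SeedSequence spawn keys
_STREAM_COHORT = 1
_STREAM_MEASURES = 2
_STREAM_QC = 3


def _subject_rng(seed: int, stream: int, subject_idx: int) -> np.random.Generator:
    """Independent generator for one subject within one named stream."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(stream, int(subject_idx)))
    )


@dataclass
class CovariateSpec:
    """Per-site generative description of one covariate.

    kind="truncated_normal" takes per-site params (mean, sd, low, high);
    kind="bernoulli" takes per-site params (p,).  ``params`` holds one mapping
    per site; a single mapping is broadcast to all sites.
    """

    name: str
    kind: str  # "truncated_normal" | "bernoulli"
    params: Sequence[Mapping[str, float]] | Mapping[str, float]

    def site_params(self, i: int, n_sites: int) -> Mapping[str, float]:
        if isinstance(self.params, Mapping):
            return self.params
        if len(self.params) != n_sites:
            raise ConfigurationError(
                f"covariate {self.name!r}: {len(self.params)} parameter sets "
                f"for {n_sites} sites"
            )
        return self.params[i]

    def draw(self, rng: np.random.Generator, params: Mapping[str, float]) -> float:
        if self.kind == "truncated_normal":
            mu, sd = params["mean"], params["sd"]
            lo = params.get("low", -np.inf)
            hi = params.get("high", np.inf)
            a, b = (lo - mu) / sd, (hi - mu) / sd
            return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
        if self.kind == "bernoulli":
            return float(rng.random() < params["p"])
        raise ConfigurationError(f"unknown covariate kind {self.kind!r}")


@dataclass
class SimulationSpec:
    """Full description of a synthetic multi-site study.

    ``site_location_effects`` (gamma) are additive per-site shifts in measure
    units; ``site_scale_effects`` (delta) multiply the residual noise and must
    be positive.  ``effect_sizes`` maps covariate/group names to a scalar or a
    length-``n_elements`` vector of regression effects (beta).
    """

    n_sites: int
    subjects_per_site: int | Sequence[int]
    site_location_effects: Sequence[float] | None = None
    site_scale_effects: Sequence[float] | None = None
    covariate_specs: Sequence[CovariateSpec] = field(default_factory=list)
    effect_sizes: Mapping[str, float | Sequence[float]] = field(default_factory=dict)
    n_elements: int = 1
    alpha: float = 0.0
    noise_sd: float = 1.0
    group_probability: float | Sequence[float] = 0.5
    bad_scan_fraction: float = 0.0
    missing_rate: float = 0.0
    measure_name: str = "thickness"
    units: str = "mm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be a positive integer")
        sizes = self.site_sizes()
        if any(s < 1 for s in sizes):
            raise ConfigurationError("subjects_per_site entries must be positive")
        if self.site_location_effects is None:
            self.site_location_effects = [0.0] * self.n_sites
        if self.site_scale_effects is None:
            self.site_scale_effects = [1.0] * self.n_sites
        if len(self.site_location_effects) != self.n_sites:
            raise ConfigurationError("site_location_effects length != n_sites")
        if len(self.site_scale_effects) != self.n_sites:
            raise ConfigurationError("site_scale_effects length != n_sites")
        if any(d <= 0 for d in self.site_scale_effects):
            raise ConfigurationError("site_scale_effects (delta) must all be > 0")
        if not 0.0 <= self.bad_scan_fraction <= 1.0:
            raise ConfigurationError("bad_scan_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_elements < 1:
            raise ConfigurationError("n_elements must be positive")

    def site_sizes(self) -> list[int]:
        if isinstance(self.subjects_per_site, (int, np.integer)):
            return [int(self.subjects_per_site)] * self.n_sites
        if len(self.subjects_per_site) != self.n_sites:
            raise ConfigurationError("subjects_per_site list length != n_sites")
        return [int(s) for s in self.subjects_per_site]

    def group_p(self, i: int) -> float:
        if isinstance(self.group_probability, (int, float)):
            return float(self.group_probability)
        return float(self.group_probability[i])

    def beta_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Effect sizes as a (n_covariates, n_elements) array in `names` order."""
        for key in self.effect_sizes:
            if key not in names:
                raise ConfigurationError(
                    f"effect size given for unknown covariate {key!r}"
                )
        B = np.zeros((len(names), self.n_elements))
        for c, name in enumerate(names):
            b = np.asarray(self.effect_sizes.get(name, 0.0), dtype=float)
            B[c] = np.broadcast_to(b, (self.n_elements,))
        return B


@dataclass
class MeasureMatrix:
    """Subjects x elements measurement matrix for one measure."""

    values: pd.DataFrame  # index: subject_id, columns: element ids
    measure_name: str = "measure"
    element_kind: str = "roi"  # "roi" | "vertex"
    units: str = ""

    @property
    def element_ids(self) -> list:
        return list(self.values.columns)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def generate_cohort(spec: SimulationSpec) -> pd.DataFrame:
    """Generate the subject covariate table.

    Returns a DataFrame with columns subject_id, subject_idx (stable per-subject
    stream key), site_id, scanner_id, group, qc_truth, and one column per
    covariate in ``spec.covariate_specs``.  Deterministic for a fixed seed.
    """
    sizes = spec.site_sizes()
    rows = []
    idx = 0
    for i in range(spec.n_sites):
        site = f"site{i + 1:02d}"
        scanner = f"scanner{i + 1:02d}"
        for _ in range(sizes[i]):
            rng = _subject_rng(spec.seed, _STREAM_COHORT, idx)
            row = {
                "subject_id": f"sub-{idx + 1:05d}",
                "subject_idx": idx,
                "site_id": site,
                "scanner_id": scanner,
            }
            for cov in spec.covariate_specs:
                row[cov.name] = cov.draw(rng, cov.site_params(i, spec.n_sites))
            row["group"] = int(rng.random() < spec.group_p(i))
            row["qc_truth"] = "fail" if rng.random() < spec.bad_scan_fraction else "pass"
            rows.append(row)
            idx += 1
    table = pd.DataFrame(rows)
    if table["subject_id"].duplicated().any():  # pragma: no cover - by construction
        raise ConfigurationError("duplicate subject ids generated")
    return table


def generate_measures(subjects: pd.DataFrame, spec: SimulationSpec) -> MeasureMatrix:
    """Generate Y = alpha + X beta + gamma_site + delta_site * eps per element.

    Covariate columns named in ``spec.effect_sizes`` (plus ``group``) form X.
    Each subject's noise comes from its own substream keyed on ``subject_idx``,
    so row order does not affect values.
    """
    names = [c for c in subjects.columns
             if c not in ("subject_id", "subject_idx", "site_id", "scanner_id",
                          "qc_truth")]
    for key in spec.effect_sizes:
        if key not in names:
            raise ConfigurationError(
                f"effect size refers to covariate {key!r} absent from the table"
            )
    B = spec.beta_matrix(names)
    X = subjects[names].to_numpy(dtype=float)
    site_index = {f"site{i + 1:02d}": i for i in range(spec.n_sites)}
    gamma = np.asarray(spec.site_location_effects, dtype=float)
    delta = np.asarray(spec.site_scale_effects, dtype=float)

    n = len(subjects)
    Y = np.empty((n, spec.n_elements))
    fixed = spec.alpha + X @ B  # (n, V)
    for r, (sidx, site) in enumerate(zip(subjects["subject_idx"], subjects["site_id"])):
        i = site_index.get(site)
        if i is None:
            raise ConfigurationError(f"site {site!r} not covered by the spec")
        rng = _subject_rng(spec.seed, _STREAM_MEASURES, sidx)
        eps = rng.normal(0.0, spec.noise_sd, size=spec.n_elements)
        Y[r] = fixed[r] + gamma[i] + delta[i] * eps
        if spec.missing_rate > 0.0:
            Y[r, rng.random(spec.n_elements) < spec.missing_rate] = np.nan
    values = pd.DataFrame(
        Y,
        index=pd.Index(subjects["subject_id"], name="subject_id"),
        columns=[f"elem{v + 1:04d}" for v in range(spec.n_elements)],
    )
    return MeasureMatrix(values, spec.measure_name, "roi", spec.units)


@dataclass
class QCDistribution:
    """Gaussian parameters for per-hemisphere Euler number and vertex count."""

    euler_mean: float
    euler_sd: float
    nvert_mean: float = 130_000.0
    nvert_sd: float = 8_000.0


GOOD_QC = QCDistribution(euler_mean=-40.0, euler_sd=30.0)
BAD_QC = QCDistribution(euler_mean=-400.0, euler_sd=150.0)


def _even_euler(x: np.ndarray | float) -> np.ndarray | int:
    """Round to the nearest even integer, capped at 2 (closed surfaces have
    even Euler number; defects only lower it below the sphere's 2)."""
    e = 2 * np.round(np.asarray(x) / 2.0)
    return np.minimum(e, 2).astype(int)


def generate_qc_metrics(
    subjects: pd.DataFrame,
    good_params: QCDistribution = GOOD_QC,
    bad_params: QCDistribution = BAD_QC,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject QC table correlated with the planted qc_truth labels.

    Subjects whose ``qc_truth`` is "fail" draw per-hemisphere Euler numbers
    from ``bad_params`` (more negative); all others from ``good_params``.
    Euler numbers are rounded to the nearest even integer <= 2.
    """
    rows = []
    for sidx, sid, site, truth in zip(
        subjects["subject_idx"], subjects["subject_id"],
        subjects["site_id"], subjects["qc_truth"],
    ):
        rng = _subject_rng(seed, _STREAM_QC, sidx)
        p = bad_params if truth == "fail" else good_params
        chi = _even_euler(rng.normal(p.euler_mean, p.euler_sd, size=2))
        nv = np.maximum(rng.normal(p.nvert_mean, p.nvert_sd, size=2), 1000.0)
        rows.append({
            "subject_id": sid,
            "site_id": site,
            "euler_lh": int(chi[0]),
            "euler_rh": int(chi[1]),
            "nvert_lh": int(round(nv[0])),
            "nvert_rh": int(round(nv[1])),
            "manual_label": truth,
        })
    return pd.DataFrame(rows)
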