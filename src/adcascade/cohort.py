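"""Synthetic longitudinal ADNI-like cohorts.

Generates the data the staging pipeline assumes: per-visit cortical
geometry features for T visits, MMSE responses linearly coupled to a
group-sparse, temporally smooth weight matrix, and a baseline clinical
table with four diagnosis classes (NC / EMCI / LMCI / AD) whose
class-conditional distributions follow published ADNI cohort summaries.
Ground-truth weights are returned for recovery experiments.

Model:

* feature columns are iid standard normal at every visit (neutral choice;
  keeps the regression well-conditioned),
* true weights: ``s`` active feature rows, base amplitude
  ±Uniform(0.5, 1.5)/sqrt(s) (so the imaging signal in MMSE has unit-order
  SD regardless of s), random-walk steps bounded by ``drift`` across visits,
* MMSE at visit j: X_j w_j + class offset + N(0, noise_sd^2), clipped to
  the instrument's [0, 30] range; class offsets are the class mean MMSE of
  the clinical profile, so mean MMSE is ordered NC > EMCI > LMCI > AD,
* clinical covariates: class-conditional normals (age, education, CDR,
  FAQ, MMSE) and Bernoulli indicators (male sex, married, APOE e4 carrier).

Diagnoses are stable over time by construction, matching the inclusion
criterion of the cohorts being emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CLINICAL_COLUMNS, feature_names
from .tglasso import LongitudinalDesign

__all__ = [
    "LABELS",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_dev_and_validation",
    "inject_missingness",
    "adni_like_profile",
    "ADNI_LIKE_COUNTS",
    "ADNI_LIKE_DEV_COUNTS",
]

LABELS = ("NC", "EMCI", "LMCI", "AD")

#: Class sizes of the emulated temporal-validation cohort (n = 685).
ADNI_LIKE_COUNTS = (417, 110, 83, 75)
#: Class sizes of the emulated model-development cohort (n = 985).
ADNI_LIKE_DEV_COUNTS = (314, 208, 258, 205)

# Class-conditional clinical summaries (mean, SD) and proportions from the
# published ADNI development / temporal-validation cohorts.
_PROFILE_DEV = {
    "NC": {"age": (74.22, 5.73), "education_years": (16.23, 2.69), "cdr": (0.04, 0.14),
           "faq": (0.17, 0.69), "mmse": (29.19, 1.04),
           "sex": 0.5096, "married": 0.6815, "apoe4": 0.2357},
    "EMCI": {"age": (71.34, 7.58), "education_years": (16.11, 2.75), "cdr": (1.21, 0.69),
             "faq": (1.88, 3.02), "mmse": (28.28, 1.57),
             "sex": 0.4231, "married": 0.7740, "apoe4": 0.3173},
    "LMCI": {"age": (73.49, 7.36), "education_years": (15.98, 2.82), "cdr": (1.45, 0.85),
             "faq": (2.76, 3.75), "mmse": (27.68, 1.69),
             "sex": 0.4070, "married": 0.7519, "apoe4": 0.3488},
    "AD": {"age": (74.62, 7.88), "education_years": (15.24, 2.88), "cdr": (4.26, 1.53),
           "faq": (12.92, 6.51), "mmse": (23.24, 2.30),
           "sex": 0.4585, "married": 0.8390, "apoe4": 0.4780},
}
_PROFILE_VAL = {
    "NC": {"age": (70.94, 6.22), "education_years": (16.85, 2.33), "cdr": (0.07, 0.25),
           "faq": (0.24, 0.89), "mmse": (29.10, 1.15),
           "sex": 0.5803, "married": 0.7362, "apoe4": 0.3165},
    "EMCI": {"age": (71.16, 6.66), "education_years": (16.18, 2.76), "cdr": (1.22, 1.02),
             "faq": (2.41, 4.09), "mmse": (28.26, 1.77),
             "sex": 0.4273, "married": 0.8000, "apoe4": 0.3364},
    "LMCI": {"age": (71.70, 8.20), "education_years": (16.08, 2.66), "cdr": (1.54, 1.02),
             "faq": (3.46, 3.84), "mmse": (27.48, 2.18),
             "sex": 0.4096, "married": 0.7349, "apoe4": 0.4217},
    "AD": {"age": (73.90, 8.00), "education_years": (15.75, 2.48), "cdr": (5.61, 2.79),
           "faq": (15.55, 8.04), "mmse": (21.87, 4.49),
           "sex": 0.4133, "married": 0.7867, "apoe4": 0.6000},
}

_CONTINUOUS_VARS = ("age", "education_years", "cdr", "faq", "mmse")
_BINARY_VARS = ("sex", "married", "apoe4")


def adni_like_profile(which: str = "validation") -> dict:
    """Clinical profile preset mirroring the published ADNI cohort summaries.

    ``which`` is ``"validation"`` (the post-2017 temporal-validation cohort)
    or ``"development"``.
    """
    if which in ("validation", "val"):
        return {k: dict(v) for k, v in _PROFILE_VAL.items()}
    if which in ("development", "dev"):
        return {k: dict(v) for k, v in _PROFILE_DEV.items()}
    raise ValueError(f"unknown profile preset {which!r}; use 'development' or 'validation'")


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``mmse_offsets`` overrides the per-class MMSE intercepts (defaults to
    the class mean MMSE of ``clinical_profile``).
    """

    n_per_class: tuple[int, int, int, int] = ADNI_LIKE_COUNTS
    d: int = 592
    T: int = 4
    s: int = 40
    drift: float = 0.05
    noise_sd: float = 1.5
    clinical_profile: dict = field(default_factory=adni_like_profile)
    missing_rate: float = 0.0
    seed: int = 0
    mmse_offsets: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 4 or any(int(n) <= 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be four positive integers (NC, EMCI, LMCI, AD)")
        self.n_per_class = tuple(int(n) for n in self.n_per_class)
        if self.d <= 0:
            raise ValueError("d must be a positive feature count")
        if self.T <= 0:
            raise ValueError("T must be a positive number of time points")
        if not 0 < self.s <= self.d:
            raise ValueError("s must satisfy 0 < s <= d")
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for lab in LABELS:
            if lab not in self.clinical_profile:
                raise ValueError(f"clinical_profile is missing class {lab!r}")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_class)


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    design: LongitudinalDesign
    true_weights: np.ndarray  # (d, T)
    clinical_table: pd.DataFrame
    subject_ids: list[str]
    labels: np.ndarray  # str per subject, aligned with design rows
    feature_ids: list[str]
    y_linear: list[np.ndarray]  # pre-clipping MMSE responses, per visit
    spec: CohortSpec

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def modelling_table(self, imaging_feature_ids: list[str] | None = None) -> pd.DataFrame:
        """Baseline classification table: clinical covariates + visit-1 values
        of the given imaging features (all features if None)."""
        fids = imaging_feature_ids if imaging_feature_ids is not None else self.feature_ids
        idx = [self.feature_ids.index(f) for f in fids]
        imaging = pd.DataFrame(self.design.X[0][:, idx], columns=fids)
        imaging.insert(0, "subject_id", self.subject_ids)
        return self.clinical_table.merge(imaging, on="subject_id")

    def mmse_long(self) -> pd.DataFrame:
        """Long-format per-visit MMSE table (subject_id, visit, mmse)."""
        frames = [
            pd.DataFrame(
                {"subject_id": self.subject_ids, "visit": j + 1, "mmse": self.design.y[j]}
            )
            for j in range(self.design.T)
        ]
        return pd.concat(frames, ignore_index=True)


def _draw_true_weights(rng: np.random.Generator, d: int, T: int, s: int, drift: float) -> np.ndarray:
    W = np.zeros((d, T))
    support = np.sort(rng.choice(d, size=s, replace=False))
    base = rng.uniform(0.5, 1.5, size=s) * rng.choice([-1.0, 1.0], size=s) / np.sqrt(s)
    steps = rng.uniform(-drift, drift, size=(s, max(T - 1, 0)))
    W[support, 0] = base
    for j in range(1, T):
        W[support, j] = W[support, j - 1] + steps[:, j - 1]
    # guard against a random walk landing a whole row at exactly zero
    return W


def generate_cohort(
    spec: CohortSpec,
    *,
    true_weights: np.ndarray | None = None,
    subject_prefix: str = "S",
) -> SyntheticCohort:
    """Generate one cohort; deterministic given ``spec.seed``.

    ``true_weights`` injects an externally drawn weight matrix (used to make
    a development and a validation cohort share one generative law).
    """
    rng = np.random.default_rng(spec.seed)
    d, T = spec.d, spec.T
    if true_weights is None:
        W = _draw_true_weights(rng, d, T, spec.s, spec.drift)
    else:
        W = np.asarray(true_weights, dtype=float)
        if W.shape != (d, T):
            raise ValueError(f"true_weights must have shape ({d}, {T})")

    n = spec.n_total
    labels = np.repeat(LABELS, spec.n_per_class)
    subject_ids = [f"{subject_prefix}{i:05d}" for i in range(n)]
    fids = feature_names(d)

    if spec.mmse_offsets is None:
        offsets = {lab: spec.clinical_profile[lab]["mmse"][0] for lab in LABELS}
    else:
        offsets = dict(zip(LABELS, spec.mmse_offsets))
    offset_vec = np.array([offsets[lab] for lab in labels])

    X, y, y_linear = [], [], []
    for j in range(T):
        Xj = rng.standard_normal((n, d))
        lin = Xj @ W[:, j] + offset_vec
        yj = lin + rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else lin.copy()
        X.append(Xj)
        y_linear.append(yj.copy())
        y.append(np.clip(yj, 0.0, 30.0))

    rows = {"subject_id": subject_ids}
    prof = spec.clinical_profile
    for var in _CONTINUOUS_VARS:
        mu = np.array([prof[lab][var][0] for lab in labels])
        sd = np.array([prof[lab][var][1] for lab in labels])
        vals = rng.normal(mu, sd)
        if var in ("cdr", "faq"):
            vals = np.clip(vals, 0.0, None)
        elif var == "mmse":
            vals = np.clip(vals, 0.0, 30.0)
        rows[var] = vals
    for var in _BINARY_VARS:
        p = np.array([prof[lab][var] for lab in labels])
        rows[var] = (rng.random(n) < p).astype(float)
    rows["label"] = labels
    clinical = pd.DataFrame(rows)[["subject_id", *CLINICAL_COLUMNS, "label"]]

    if spec.missing_rate > 0:
        clinical = inject_missingness(
            clinical, spec.missing_rate, seed=int(rng.integers(0, 2**31 - 1))
        )

    return SyntheticCohort(
        design=LongitudinalDesign(X, y),
        true_weights=W,
        clinical_table=clinical,
        subject_ids=subject_ids,
        labels=labels,
        feature_ids=fids,
        y_linear=y_linear,
        spec=spec,
    )


def generate_dev_and_validation(
    spec_dev: CohortSpec, spec_val: CohortSpec
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Two disjoint cohorts drawn from one generative law.

    The true weight matrix is shared; subjects, features and noise are
    drawn independently per cohort.  Subject identifiers are disjoint by
    construction (``dev``/``val`` prefixes).
    """
    if spec_dev.d != spec_val.d or spec_dev.T != spec_val.T:
        raise ValueError(
            "development and validation specs must agree on d and T "
            f"(got d={spec_dev.d}/{spec_val.d}, T={spec_dev.T}/{spec_val.T})"
        )
    rng_w = np.random.default_rng([spec_dev.seed, 0x5EED])
    W = _draw_true_weights(rng_w, spec_dev.d, spec_dev.T, spec_dev.s, spec_dev.drift)
    dev = generate_cohort(spec_dev, true_weights=W, subject_prefix="dev")
    val = generate_cohort(
        replace(spec_val, seed=spec_val.seed + 1 if spec_val.seed == spec_dev.seed else spec_val.seed),
        true_weights=W,
        subject_prefix="val",
    )
    return dev, val


def inject_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mask clinical cells missing-completely-at-random at expectation ``rate``.

    ``subject_id`` and ``label`` are never masked.  Returns a copy; masked
    columns become float with NaN holes.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    maskable = [c for c in out.columns if c not in ("subject_id", "label")]
    mask = rng.random((len(out), len(maskable))) < rate
    for k, col in enumerate(maskable):
        if mask[:, k].any():
            out[col] = out[col].astype(float)
            out.loc[mask[:, k], col] = np.nan
    return out
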