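"""Synthetic per-eye embedding cohorts.

Real pipelines extract a 1024-dimensional feature vector per fundus image with a
frozen vision-transformer encoder and regress chronological age on it. This
module fabricates cohorts with the same statistical skeleton so that every
downstream stage (client networks, distributed training, age-gap statistics)
can be exercised without any imaging data:

* ages follow a truncated normal matched to a target mean/sd/range;
* each subject contributes exactly two records (left and right eye) sharing a
  latent age signal ``s = signal_strength * (z + nonlinearity_coef*z**2 + eta)``
  with ``z`` the standardized age and ``eta ~ N(0, latent_sd^2)`` the subject's
  biological deviation from the age norm (the scatter that retinal-age-gap
  analysis lives on — both eyes share it);
* the signal lives on a single fixed unit direction ``u`` in feature space,
  on top of per-center offsets, per-eye-side offsets and isotropic noise;
* an optional disease subgroup has its signal computed at ``age +
  disease_offset`` — an "older-looking retina" — which is what the retinal age
  gap (RAG) statistics downstream are meant to recover.

Noise defaults are calibrated once so that a closed-form ridge readout of age
reaches a held-out MAE in the 3-4 year range typical of fundus-based age
prediction (see :func:`ridge_oracle_mae` and docs/methods.md).
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CohortSpec",
    "FeatureRecord",
    "Cohort",
    "UKB_LIKE",
    "BRSET_LIKE",
    "PRESETS",
    "sample_ages",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "ridge_oracle_mae",
]


class ParameterError(ValueError):
    """A cohort / spec parameter violates its documented bound."""


class FormatError(ValueError):
    """A cohort file does not conform to the documented CSV schema."""


class IntegrityError(ValueError):
    """Cohort content violates a structural invariant (e.g. eye pairing)."""


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    Age parameters describe the *observed* (truncated) distribution: the
    sampler solves for the parent normal whose truncation to
    ``[age_min, age_max]`` has exactly ``(age_mean, age_sd)``.
    """

    n_subjects: int
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float
    feature_dim: int = 1024
    n_centers: int = 8
    signal_strength: float = 2.0
    nonlinearity_coef: float = 0.15
    latent_sd: float = 0.58
    site_sd: float = 0.05
    eye_sd: float = 0.10
    noise_sd: float = 0.10
    disease_fraction: float = 0.0
    disease_offset: float = 3.5
    seed: int = 0
    # The feature map emulates one frozen encoder shared by every cohort:
    # the signal direction, eye offsets and the age standardization are tied
    # to (feature_seed, ref_age_mean, ref_age_sd), not to the cohort draw, so
    # heads trained on one cohort transfer to another (external validation).
    ref_age_mean: float = 52.32
    ref_age_sd: float = 7.98
    feature_seed: int = 777

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.feature_dim < 1:
            raise ParameterError("feature_dim must be >= 1")
        if self.n_centers < 1:
            raise ParameterError("n_centers must be >= 1")
        if not self.age_min < self.age_max:
            raise ParameterError(
                f"age_min must be < age_max (got {self.age_min} >= {self.age_max})"
            )
        for name in ("age_sd", "latent_sd", "site_sd", "eye_sd", "noise_sd", "ref_age_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0 (got {getattr(self, name)})")
        if not 0.0 <= self.disease_fraction <= 1.0:
            raise ParameterError(
                f"disease_fraction must be in [0, 1] (got {self.disease_fraction})"
            )

    def with_(self, **kwargs) -> "CohortSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: UK-Biobank-like preset: 8315 healthy subjects (observed age 52.32 +/- 7.98,
#: range 40-74) plus 119 type-1-diabetes-like subjects with a +3.5 y offset.
UKB_LIKE = CohortSpec(
    n_subjects=8434,
    age_mean=52.32,
    age_sd=7.98,
    age_min=40.0,
    age_max=74.0,
    disease_fraction=119 / 8434,
)

#: BRSET-like preset: 479 healthy subjects (observed age 46.97 +/- 17.46,
#: range 6-91) plus 214 disease subjects.
BRSET_LIKE = CohortSpec(
    n_subjects=693,
    age_mean=46.97,
    age_sd=17.46,
    age_min=6.0,
    age_max=91.0,
    disease_fraction=214 / 693,
)

PRESETS = {"ukb_like": UKB_LIKE, "brset_like": BRSET_LIKE}


@dataclass(frozen=True)
class FeatureRecord:
    """One eye's embedding plus subject metadata."""

    subject_id: str
    eye: str  # "L" or "R"
    age: float
    center_id: int
    group: str  # "healthy" or "disease"
    features: np.ndarray

    def __eq__(self, other: object) -> bool:  # numpy-aware equality
        if not isinstance(other, FeatureRecord):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.eye == other.eye
            and self.age == other.age
            and self.center_id == other.center_id
            and self.group == other.group
            and np.array_equal(self.features, other.features)
        )


class Cohort:
    """Row-aligned metadata table plus feature matrix (one row per eye)."""

    META_COLUMNS = ["subject_id", "eye", "center", "group", "age"]

    def __init__(self, meta: pd.DataFrame, features: np.ndarray):
        if list(meta.columns) != self.META_COLUMNS:
            raise FormatError(f"meta columns must be {self.META_COLUMNS}, got {list(meta.columns)}")
        if len(meta) != features.shape[0]:
            raise IntegrityError("meta rows and feature rows differ")
        self.meta = meta.reset_index(drop=True)
        self.features = np.asarray(features, dtype=float)
        self._validate()

    # -- structural invariants -------------------------------------------------
    def _validate(self) -> None:
        meta = self.meta
        bad_eye = set(meta["eye"]) - {"L", "R"}
        if bad_eye:
            raise FormatError(f"eye values must be L or R, got {sorted(bad_eye)}")
        bad_group = set(meta["group"]) - {"healthy", "disease"}
        if bad_group:
            raise FormatError(f"group values must be healthy or disease, got {sorted(bad_group)}")
        counts = meta.groupby("subject_id", sort=False).size()
        wrong = counts[counts != 2]
        if len(wrong):
            raise IntegrityError(
                f"every subject needs exactly 2 records (L and R); offenders: "
                f"{list(wrong.index[:5])}"
            )
        by_subj = meta.groupby("subject_id", sort=False)
        if not (by_subj["eye"].nunique() == 2).all():
            bad = by_subj["eye"].nunique()
            raise IntegrityError(
                f"subject(s) missing an eye side: {list(bad[bad != 2].index[:5])}"
            )
        for col in ("age", "center", "group"):
            if not (by_subj[col].nunique() == 1).all():
                raise IntegrityError(f"records of one subject must share {col}")

    # -- accessors -------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.meta["subject_id"].nunique()

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(self.meta.loc[mask].reset_index(drop=True), self.features[mask])

    def healthy(self) -> "Cohort":
        return self.subset((self.meta["group"] == "healthy").to_numpy())

    def disease(self) -> "Cohort":
        return self.subset((self.meta["group"] == "disease").to_numpy())

    def quantized(self, bits: int = 8) -> "Cohort":
        """Cohort with every feature vector passed through 8-bit (or ``bits``)
        affine quantize-dequantize, emulating a quantized encoder output."""
        from .accounting import quantize_dequantize

        return Cohort(self.meta.copy(), quantize_dequantize(self.features, bits))

    def to_records(self) -> list[FeatureRecord]:
        return [
            FeatureRecord(
                subject_id=row.subject_id,
                eye=row.eye,
                age=float(row.age),
                center_id=int(row.center),
                group=row.group,
                features=self.features[i].copy(),
            )
            for i, row in enumerate(self.meta.itertuples(index=False))
        ]

    @classmethod
    def from_records(cls, records: Sequence[FeatureRecord]) -> "Cohort":
        if not len(records):
            raise IntegrityError("cannot build a cohort from zero records")
        meta = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in records],
                "eye": [r.eye for r in records],
                "center": [int(r.center_id) for r in records],
                "group": [r.group for r in records],
                "age": [float(r.age) for r in records],
            }
        )
        return cls(meta, np.stack([np.asarray(r.features, dtype=float) for r in records]))

    def content_hash(self) -> str:
        """SHA-256 over the canonical CSV serialization (determinism checks)."""
        buf = io.StringIO()
        write_cohort(self, buf)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.meta.equals(other.meta) and np.array_equal(self.features, other.features)


# ---------------------------------------------------------------------------
# age sampling
# ---------------------------------------------------------------------------

def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose truncation to [lo, hi] has the given moments."""

    def residual(p):
        mu, log_sigma = p
        sigma = float(np.exp(log_sigma))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - well-posed for sane presets
        raise ParameterError(
            f"could not match truncated-normal moments mean={mean}, sd={sd} on [{lo}, {hi}]"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def sample_ages(spec: CohortSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``spec.n_subjects`` ages by rejection sampling a normal into
    ``[age_min, age_max]``, with the parent moments solved so the *observed*
    distribution matches ``(age_mean, age_sd)``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.age_sd == 0:
        if not spec.age_min <= spec.age_mean <= spec.age_max:
            raise ParameterError("age_mean outside [age_min, age_max] with age_sd=0")
        return np.full(spec.n_subjects, float(spec.age_mean))
    mu, sigma = _truncnorm_parent(spec.age_mean, spec.age_sd, spec.age_min, spec.age_max)
    out = np.empty(0)
    while out.size < spec.n_subjects:
        draw = rng.normal(mu, sigma, size=2 * spec.n_subjects)
        out = np.concatenate([out, draw[(draw >= spec.age_min) & (draw <= spec.age_max)]])
    return out[: spec.n_subjects]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full two-eyes-per-subject cohort.

    Feature model per record of subject ``i`` (direction ``u`` fixed by seed)::

        x = s_i * u + c_center(i) + e_eye + eps
        s_i = signal_strength * (z_i + nonlinearity_coef * z_i**2 + eta_i)
        z_i = (age_i + offset_i - ref_age_mean) / ref_age_sd   # offset_i = disease shift

    ``eta_i ~ N(0, latent_sd^2)`` is the subject's biological deviation from
    the age norm, shared by both eyes (it bounds any readout's accuracy and is
    the scatter the retinal-age-gap statistics analyse). ``c`` is one offset
    vector per center ~ N(0, site_sd^2 I), ``e`` one vector per eye side (L/R,
    shared across subjects) ~ N(0, eye_sd^2 I), and ``eps`` ~ N(0, noise_sd^2 I)
    is independent per record.
    """
    rng = np.random.default_rng(spec.seed)
    d, n = spec.feature_dim, spec.n_subjects

    # encoder-level structure: shared by every cohort with the same feature_seed
    enc_rng = np.random.default_rng(spec.feature_seed)
    u = enc_rng.normal(size=d)
    u /= np.linalg.norm(u)
    eye_off = enc_rng.normal(0.0, spec.eye_sd, size=(2, d)) if spec.eye_sd else np.zeros((2, d))

    # cohort-level structure: centers, ages, subjects, per-record noise
    center_off = rng.normal(0.0, spec.site_sd, size=(spec.n_centers, d)) if spec.site_sd else np.zeros((spec.n_centers, d))
    ages = sample_ages(spec, rng)
    centers = rng.integers(0, spec.n_centers, size=n)
    n_disease = int(round(spec.disease_fraction * n))
    disease_idx = rng.choice(n, size=n_disease, replace=False)
    is_disease = np.zeros(n, dtype=bool)
    is_disease[disease_idx] = True

    effective_age = ages + np.where(is_disease, spec.disease_offset, 0.0)
    z = (
        (effective_age - spec.ref_age_mean) / spec.ref_age_sd
        if spec.ref_age_sd
        else np.zeros(n)
    )
    eta = rng.normal(0.0, spec.latent_sd, size=n) if spec.latent_sd else np.zeros(n)
    s = spec.signal_strength * (z + spec.nonlinearity_coef * z**2 + eta)

    # record order: subject 0 L, subject 0 R, subject 1 L, ...
    signal = np.repeat(s, 2)[:, None] * u[None, :]
    features = signal + center_off[np.repeat(centers, 2)]
    features += np.tile(eye_off, (n, 1))
    if spec.noise_sd:
        features += rng.normal(0.0, spec.noise_sd, size=(2 * n, d))

    width = max(6, len(str(n - 1)))
    subj = [f"S{i:0{width}d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "subject_id": np.repeat(subj, 2),
            "eye": ["L", "R"] * n,
            "center": np.repeat(centers, 2),
            "group": np.repeat(np.where(is_disease, "disease", "healthy"), 2),
            "age": np.repeat(ages, 2),
        }
    )
    return Cohort(meta, features)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def _feature_columns(d: int) -> list[str]:
    width = max(4, len(str(d - 1)))
    return [f"f{i:0{width}d}" for i in range(d)]


def write_cohort(cohort: "Cohort | Sequence[FeatureRecord]", path) -> None:
    """Write the documented CSV schema (full-precision decimal features)."""
    if not isinstance(cohort, Cohort):
        cohort = Cohort.from_records(cohort)
    d = cohort.feature_dim
    df = cohort.meta.copy()
    feat = pd.DataFrame(cohort.features, columns=_feature_columns(d))
    pd.concat([df, feat], axis=1).to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> Cohort:
    """Read a cohort CSV, validating schema and eye pairing."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV (ragged rows, ...)
        raise FormatError(f"unreadable cohort file: {exc}") from exc
    expected_meta = Cohort.META_COLUMNS
    if list(df.columns[: len(expected_meta)]) != expected_meta:
        raise FormatError(
            f"header must start with {','.join(expected_meta)}; got {list(df.columns[:5])}"
        )
    feat_cols = list(df.columns[len(expected_meta) :])
    if not feat_cols or feat_cols != _feature_columns(len(feat_cols)):
        raise FormatError(f"feature columns malformed (got {feat_cols[:3]}...)")
    try:
        feats = df[feat_cols].to_numpy(dtype=float)
    except (TypeError, ValueError):
        numeric = df[feat_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
        row = int(np.argwhere(np.isnan(numeric))[0, 0])
        raise FormatError(f"non-numeric feature at data row {row}") from None
    bad = ~np.isfinite(feats)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise FormatError(f"non-finite feature at data row {row}")
    return Cohort(df[expected_meta].copy(), feats)


# ---------------------------------------------------------------------------
# closed-form learnability oracle
# ---------------------------------------------------------------------------

def ridge_oracle_mae(
    cohort: Cohort,
    n_train: int,
    seed: int = 0,
    alpha: float = 10.0,
) -> float:
    """Held-out MAE of a closed-form ridge regression of age on features.

    Independent of the iterative training engines: splits healthy subjects into
    ``n_train`` train and the rest held out, solves the centered normal
    equations directly, and returns the held-out mean absolute error in years.
    """
    healthy = cohort.healthy()
    subjects = healthy.meta["subject_id"].unique()
    if n_train >= len(subjects):
        raise ParameterError(f"n_train={n_train} needs < {len(subjects)} healthy subjects")
    rng = np.random.default_rng(seed)
    train_subj = set(rng.choice(subjects, size=n_train, replace=False))
    is_train = healthy.meta["subject_id"].isin(train_subj).to_numpy()

    X_tr, y_tr = healthy.features[is_train], healthy.meta["age"].to_numpy()[is_train]
    X_te, y_te = healthy.features[~is_train], healthy.meta["age"].to_numpy()[~is_train]
    x_mean, y_mean = X_tr.mean(axis=0), y_tr.mean()
    Xc, yc = X_tr - x_mean, y_tr - y_mean
    d = Xc.shape[1]
    w = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(d), Xc.T @ yc)
    pred = (X_te - x_mean) @ w + y_mean
    return float(np.mean(np.abs(pred - y_te)))
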