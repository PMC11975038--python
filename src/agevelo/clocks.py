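"""Linear biological-age clocks.

A clock is a named linear predictor over a feature space (CpG beta values or
gene expression): ``transformed_age = intercept + sum_f weight_f * x_f``.
DNA-methylation clocks in the Horvath tradition calibrate the linear part on a
piecewise log-linear transform of age that is logarithmic through development
and linear in adulthood:

    F(age) = log(age + 1) - log(adult_age + 1)     for age <= adult_age
    F(age) = (age - adult_age) / (adult_age + 1)   for age >  adult_age

F is continuous, strictly increasing, and zero at ``adult_age``; predicted
ages are obtained by inverting F.  Transcriptomic clocks typically use the
identity transform on log-stabilized expression (log2(FPKM+1)).

Missing clock features are imputed from clock-supplied reference means up to
``max_missing_frac``; beyond that the prediction errs loudly, because linear
clocks are sensitive to silent probe dropout.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError
from .io import ExpressionMatrix

TRANSFORMS = ("identity", "log_linear_adult")
INPUT_TRANSFORMS = ("none", "log2_plus1")
FEATURE_SPACES = ("cpg", "gene")

DEFAULT_ADULT_AGE = 20.0


def age_transform(age, adult_age: float = DEFAULT_ADULT_AGE):
    """Horvath-style piecewise log-linear age calibration F(age)."""
    if adult_age <= 0:
        raise DomainError(f"adult_age must be > 0, got {adult_age}")
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr <= -1):
        raise DomainError("age_transform requires age > -1")
    out = np.where(
        age_arr <= adult_age,
        np.log(age_arr + 1.0) - np.log(adult_age + 1.0),
        (age_arr - adult_age) / (adult_age + 1.0),
    )
    return out.item() if np.isscalar(age) or out.ndim == 0 else out


def inverse_age_transform(value, adult_age: float = DEFAULT_ADULT_AGE):
    """Inverse of :func:`age_transform`."""
    if adult_age <= 0:
        raise DomainError(f"adult_age must be > 0, got {adult_age}")
    v = np.asarray(value, dtype=float)
    out = np.where(
        v <= 0,
        np.exp(v) * (adult_age + 1.0) - 1.0,
        v * (adult_age + 1.0) + adult_age,
    )
    return out.item() if np.isscalar(value) or out.ndim == 0 else out


@dataclass
class ClockModel:
    """A named linear age predictor."""

    name: str
    feature_space: str                 # "cpg" | "gene"
    intercept: float                   # in transformed-age units
    weights: pd.Series                 # feature -> coefficient
    transform: str = "identity"        # "identity" | "log_linear_adult"
    adult_age: float = DEFAULT_ADULT_AGE
    input_transform: str = "none"      # "none" | "log2_plus1"
    reference_means: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    max_missing_frac: float = 0.2

    def __post_init__(self):
        self.intercept = float(self.intercept)
        self.adult_age = float(self.adult_age)
        self.max_missing_frac = float(self.max_missing_frac)
        self.weights = pd.Series(self.weights, dtype=float)
        self.reference_means = pd.Series(self.reference_means, dtype=float)
        if len(self.weights) == 0:
            raise FormatError(f"clock {self.name!r}: empty weight vector")
        if self.weights.index.has_duplicates:
            dup = self.weights.index[self.weights.index.duplicated()][0]
            raise FormatError(f"clock {self.name!r}: duplicate feature {dup!r}")
        if self.feature_space not in FEATURE_SPACES:
            raise FormatError(f"clock {self.name!r}: unknown feature space "
                              f"{self.feature_space!r}")
        if self.transform not in TRANSFORMS:
            raise FormatError(f"clock {self.name!r}: unknown transform "
                              f"{self.transform!r}")
        if self.input_transform not in INPUT_TRANSFORMS:
            raise FormatError(f"clock {self.name!r}: unknown input transform "
                              f"{self.input_transform!r}")
        if self.transform == "log_linear_adult" and not self.adult_age > 0:
            raise FormatError(f"clock {self.name!r}: adult_age must be > 0")
        if not (0 <= self.max_missing_frac < 1):
            raise FormatError(f"clock {self.name!r}: max_missing_frac must be in [0,1)")

    # -- transforms ----------------------------------------------------------
    def _inverse(self, value):
        if self.transform == "identity":
            return value
        return inverse_age_transform(value, self.adult_age)

    def transform_age(self, age):
        if self.transform == "identity":
            return age
        return age_transform(age, self.adult_age)


def predict_clock_age(matrix, clock: ClockModel) -> pd.DataFrame:
    """Apply a clock to a feature x sample matrix.

    Parameters
    ----------
    matrix
        A beta-value DataFrame (feature_space ``cpg``) or an
        :class:`~agevelo.io.ExpressionMatrix` (feature_space ``gene``).
    clock
        The :class:`ClockModel` to apply.

    Returns
    -------
    DataFrame indexed by sample with columns ``predicted_age``,
    ``n_features_used`` and ``n_imputed``.
    """
    if clock.feature_space == "gene":
        if not isinstance(matrix, ExpressionMatrix):
            raise FormatError(
                f"clock {clock.name!r} expects gene expression input "
                f"(ExpressionMatrix), got {type(matrix).__name__}"
            )
        values = (matrix.log2_plus1() if clock.input_transform == "log2_plus1"
                  else matrix.values.astype(float))
    else:
        if isinstance(matrix, ExpressionMatrix):
            raise FormatError(
                f"clock {clock.name!r} expects CpG beta input, got expression matrix"
            )
        values = matrix.astype(float)

    features = clock.weights.index
    present = features.intersection(values.index)
    x = values.reindex(features)  # missing features become NaN rows

    n_feat = len(features)
    missing_mask = x.isna()
    n_missing = missing_mask.sum(axis=0)
    frac_missing = n_missing / n_feat
    over = frac_missing[frac_missing > clock.max_missing_frac]
    if len(over):
        sample = over.index[0]
        absent = x.index[missing_mask[sample]].tolist()
        raise FormatError(
            f"clock {clock.name!r}: sample {sample!r} is missing "
            f"{over.iloc[0]:.0%} of clock features (limit "
            f"{clock.max_missing_frac:.0%}); absent features (first 10): "
            f"{absent[:10]}"
        )
    if n_missing.any():
        ref = clock.reference_means.reindex(features)
        unimputable = x.index[missing_mask.any(axis=1) & ref.isna()]
        if len(unimputable):
            raise FormatError(
                f"clock {clock.name!r}: no reference mean to impute features "
                f"{unimputable.tolist()[:10]}"
            )
        x = x.apply(lambda col: col.fillna(ref))

    linear = x.mul(clock.weights, axis=0).sum(axis=0) + clock.intercept
    predicted = clock._inverse(linear.to_numpy())
    out = pd.DataFrame({
        "predicted_age": predicted,
        "n_features_used": n_feat - n_missing,
        "n_imputed": n_missing,
    }, index=values.columns)
    out.index.name = "sample_id"
    assert len(present) <= n_feat
    return out


# ---------------------------------------------------------------------------
# on-disk format: CSV body (feature, weight, reference_mean) preceded by a
# '# key: value' metadata block carrying intercept/transform settings.
# ---------------------------------------------------------------------------

_META_KEYS = ("name", "feature_space", "intercept", "transform", "adult_age",
              "input_transform", "max_missing_frac")


def save_clock(clock: ClockModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {clock.name}\n")
        fh.write(f"# feature_space: {clock.feature_space}\n")
        fh.write(f"# intercept: {clock.intercept!r}\n")
        fh.write(f"# transform: {clock.transform}\n")
        fh.write(f"# adult_age: {clock.adult_age!r}\n")
        fh.write(f"# input_transform: {clock.input_transform}\n")
        fh.write(f"# max_missing_frac: {clock.max_missing_frac!r}\n")
        fh.write("feature,weight,reference_mean\n")
        ref = clock.reference_means.reindex(clock.weights.index)
        for feat, w in clock.weights.items():
            r = ref.get(feat)
            r_str = "" if pd.isna(r) else repr(float(r))
            fh.write(f"{feat},{float(w)!r},{r_str}\n")


def load_clock(path) -> ClockModel:
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    for required in ("name", "feature_space", "intercept", "transform"):
        if required not in meta:
            raise FormatError(f"{path}: clock file missing metadata key {required!r}")
    if not body_lines:
        raise FormatError(f"{path}: clock file has no coefficient rows")
    body = pd.read_csv(_io.StringIO("".join(body_lines)))
    if not {"feature", "weight"} <= set(body.columns):
        raise FormatError(f"{path}: clock body needs 'feature' and 'weight' columns")
    if body["feature"].duplicated().any():
        dup = body.loc[body["feature"].duplicated(), "feature"].iloc[0]
        raise FormatError(f"{path}: duplicate feature row {dup!r}")
    weights = pd.Series(body["weight"].to_numpy(), index=body["feature"])
    ref = (pd.Series(body["reference_mean"].to_numpy(), index=body["feature"]).dropna()
           if "reference_mean" in body.columns else pd.Series(dtype=float))
    return ClockModel(
        name=meta["name"],
        feature_space=meta["feature_space"],
        intercept=float(meta["intercept"]),
        weights=weights,
        transform=meta["transform"],
        adult_age=float(meta.get("adult_age", DEFAULT_ADULT_AGE)),
        input_transform=meta.get("input_transform", "none"),
        reference_means=ref,
        max_missing_frac=float(meta.get("max_missing_frac", 0.2)),
    )
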