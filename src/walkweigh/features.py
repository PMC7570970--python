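"""Signal features of a valid segment and their min-max normalisation.

Five features summarise a valid weight segment f(1..N):

* range ``R = fmax - fmin`` (kg),
* population standard deviation ``sigma`` (kg),
* peak factor ``PAR = R / RMS`` (a crest-factor variant, dimensionless),
* form factor ``FF = RMS / mean`` (>= 1, = 1 iff constant),
* crossing speed ``v = platform_length / t`` (m/s) with ``t`` the segment
  duration.

Feature tables are min-max normalised with statistics fitted on the
training split only and reused unchanged for test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ValidSegment

__all__ = ["FeatureVector", "NormStats", "FEATURE_NAMES",
           "compute_features", "fit_minmax", "apply_minmax", "feature_frame"]

FEATURE_NAMES = ("R", "sigma", "PAR", "FF", "v")


@dataclass(frozen=True)
class FeatureVector:
    range_kg: float        # R
    std_kg: float          # sigma (population form, divisor N)
    peak_factor: float     # PAR = R / RMS
    form_factor: float     # FF = RMS / mean
    speed_m_s: float       # v = platform length / duration
    f_max: float
    f_min: float
    f_mean: float

    def as_array(self) -> np.ndarray:
        return np.array([self.range_kg, self.std_kg, self.peak_factor,
                         self.form_factor, self.speed_m_s])


def compute_features(segment: ValidSegment, platform_length_m: float = 2.5) -> FeatureVector:
    """Compute the five features of a valid segment."""
    f = segment.values
    if f.size == 0 or segment.duration_s <= 0:
        raise ValueError("segment must be nonempty with positive duration")
    f_mean = float(np.mean(f))
    if f_mean == 0.0:
        raise ValueError("zero-mean segment: form factor undefined")
    f_max, f_min = float(np.max(f)), float(np.min(f))
    r = f_max - f_min
    sigma = float(np.sqrt(np.mean((f - f_mean) ** 2)))  # divisor N
    rms = float(np.sqrt(np.mean(f**2)))
    return FeatureVector(
        range_kg=r,
        std_kg=sigma,
        peak_factor=r / rms,
        form_factor=rms / f_mean,
        speed_m_s=platform_length_m / segment.duration_s,
        f_max=f_max,
        f_min=f_min,
        f_mean=f_mean,
    )


def feature_frame(vectors, labels=None, animal_ids=None) -> pd.DataFrame:
    """Stack FeatureVectors into a tidy table (columns R, sigma, PAR, FF, v)."""
    arr = np.vstack([v.as_array() for v in vectors])
    df = pd.DataFrame(arr, columns=list(FEATURE_NAMES))
    if animal_ids is not None:
        df.insert(0, "animal_id", list(animal_ids))
    if labels is not None:
        df["label"] = list(labels)
    return df


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    if len(table) and isinstance(table[0], FeatureVector):
        return np.vstack([v.as_array() for v in table])
    return np.asarray(table, dtype=float)


@dataclass(frozen=True)
class NormStats:
    """Per-feature minima and maxima fitted on one reference table."""

    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self):
        if np.any(self.x_max < self.x_min):
            raise ValueError("x_max must be >= x_min for every feature")


def fit_minmax(table) -> NormStats:
    """Record per-feature min and max of ``table`` (rows x 5 features)."""
    x = _as_matrix(table)
    if x.size == 0:
        raise ValueError("cannot fit normalisation on an empty table")
    return NormStats(x_min=x.min(axis=0), x_max=x.max(axis=0))


def apply_minmax(table, stats: NormStats):
    """Map each value to ``(x - xmin) / (xmax - xmin)``.

    Values outside the fitted range are not clipped.  A feature with
    ``xmax == xmin`` maps to 0 (with a warning).
    """
    x = _as_matrix(table)
    span = stats.x_max - stats.x_min
    degenerate = span == 0
    if np.any(degenerate):
        warnings.warn("constant feature(s) in normalisation stats map to 0",
                      stacklevel=2)
    safe = np.where(degenerate, 1.0, span)
    out = (x - stats.x_min) / safe
    out[:, degenerate] = 0.0
    if isinstance(table, pd.DataFrame):
        res = table.copy()
        res.loc[:, list(FEATURE_NAMES)] = out
        return res
    return out
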