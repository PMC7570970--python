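"""Grade-specific dynamic-weight estimators.

The dynamic weight ``mc`` of a valid segment is computed with an
estimator matched to the activity grade:

* **low (0)** — trimmed mean: drop one occurrence each of the segment's
  maximum and minimum, average the rest.  The low-grade waveform is
  nearly stationary, so this is both accurate and cheap.
* **medium (1)** — EWT: decompose the segment with the empirical wavelet
  transform and average the approximation/trend component ``f0``, which
  carries the weight while the detail bands absorb the gait oscillation.
* **high (2)** — periodic-continuation EWT: the segment is short and
  strongly oscillatory, so its head is wrapped onto its tail before the
  transform to suppress edge artefacts; ``f0`` is truncated back to the
  original support before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ewt import build_filter_bank, compute_spectrum, detect_boundaries, \
    ewt_decompose, periodic_extend
from .preprocess import ValidSegment

__all__ = ["EstimatorConfig", "WeightEstimate", "estimate_trimmed_mean",
           "estimate_ewt", "estimate_ewt_periodic", "estimate_weight"]


@dataclass(frozen=True)
class EstimatorConfig:
    """EWT settings shared by the medium- and high-grade estimators.

    ``filter_length`` is the periodic-continuation length M; ``None``
    wraps half the segment (M = N // 2 + 1).
    """

    n_modes: int = 3
    gamma: float | None = None
    filter_length: int | None = None


@dataclass(frozen=True)
class WeightEstimate:
    mc_kg: float
    method: str          # trimmed_mean | ewt | ewt_periodic
    grade: int | None
    n_used: int
    segment: ValidSegment


def estimate_trimmed_mean(segment: ValidSegment, grade: int | None = 0) -> WeightEstimate:
    """Mean of the segment after removing one max and one min occurrence."""
    f = segment.values
    if f.size < 3:
        raise ValueError("trimmed mean needs at least 3 samples")
    trimmed = np.sort(f)[1:-1]
    return WeightEstimate(mc_kg=float(np.mean(trimmed)), method="trimmed_mean",
                          grade=grade, n_used=trimmed.size, segment=segment)


def _decompose(values: np.ndarray, config: EstimatorConfig):
    spectrum = compute_spectrum(values)
    partition = detect_boundaries(spectrum, n_modes=config.n_modes)
    bank = build_filter_bank(partition, gamma=config.gamma)
    return ewt_decompose(values, bank)


def estimate_ewt(segment: ValidSegment, config: EstimatorConfig | None = None,
                 grade: int | None = 1) -> WeightEstimate:
    """Mean of the EWT trend component f0 of the segment."""
    if segment.n < 8:
        raise ValueError("EWT estimation needs at least 8 samples")
    config = config or EstimatorConfig()
    f0 = _decompose(segment.values, config).f0
    return WeightEstimate(mc_kg=float(np.mean(f0)), method="ewt", grade=grade,
                          n_used=f0.size, segment=segment)


def estimate_ewt_periodic(segment: ValidSegment, config: EstimatorConfig | None = None,
                          grade: int | None = 2) -> WeightEstimate:
    """Periodic continuation, EWT, then mean of f0 truncated to the segment.

    The continuation only stabilises the transform near the edges; it
    adds no data, so f0 is cut back to the original N samples before
    averaging.
    """
    if segment.n < 4:
        raise ValueError("periodic-continuation EWT needs at least 4 samples")
    config = config or EstimatorConfig()
    m = config.filter_length if config.filter_length is not None else segment.n // 2 + 1
    extended = periodic_extend(segment.values, m)
    f0 = _decompose(extended, config).f0[: segment.n]
    return WeightEstimate(mc_kg=float(np.mean(f0)), method="ewt_periodic",
                          grade=grade, n_used=f0.size, segment=segment)


def estimate_weight(segment: ValidSegment, grade: int,
                    config: EstimatorConfig | None = None) -> WeightEstimate:
    """Dispatch to the estimator for ``grade`` (0, 1 or 2)."""
    if grade == 0:
        return estimate_trimmed_mean(segment, grade=0)
    if grade == 1:
        return estimate_ewt(segment, config, grade=1)
    if grade == 2:
        return estimate_ewt_periodic(segment, config, grade=2)
    raise ValueError(f"unknown activity grade {grade!r}")
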