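"""Valid-segment extraction from a raw walk-over weight trace.

A passage has three stages: the animal steps on (rising load), stands
fully on the platform (plateau), and steps off (falling load).  Only the
all-hooves-on plateau is valid for weighing.  It is located by
thresholding the trace at ``K1 = eta * Wmax``, differentiating the
thresholded series, and taking the samples between the start of the
rising edge (A) and the start of the falling edge (B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WeightTrace", "ValidSegment", "EmptySegmentError", "extract_valid_segment"]


class EmptySegmentError(ValueError):
    """No sample of the trace reaches the detection threshold."""


@dataclass(frozen=True)
class WeightTrace:
    """A raw sampled weight curve for one animal passage.

    Times must be strictly increasing with constant spacing (to within
    one part in 1e6 of the interval); weights are in kilograms.
    """

    times: np.ndarray
    weights: np.ndarray
    sampling_interval_s: float
    animal_id: str | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if t.size != w.size:
            raise ValueError("times and weights must have equal length")
        if t.size < 3:
            raise ValueError("a trace needs at least 3 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.abs(dt - self.sampling_interval_s) > 1e-6 * self.sampling_interval_s):
            raise ValueError("times must be uniformly spaced at the sampling interval")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "weights", w)

    @property
    def w_max(self) -> float:
        return float(np.max(self.weights))

    @property
    def n(self) -> int:
        return self.weights.size

    @property
    def duration_s(self) -> float:
        return self.n * self.sampling_interval_s


@dataclass(frozen=True)
class ValidSegment:
    """The all-hooves-on sub-series f(t) of a trace.

    ``start_index``/``end_index`` (A/B, inclusive) locate the segment in
    the parent trace; all values are >= ``threshold_kg`` (K1).
    """

    values: np.ndarray
    start_index: int
    end_index: int
    sampling_interval_s: float
    threshold_kg: float
    eta: float
    animal_id: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise EmptySegmentError("valid segment is empty")
        if self.start_index > self.end_index:
            raise ValueError("start_index must not exceed end_index")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n * self.sampling_interval_s


def _runs(mask: np.ndarray):
    """(start, stop_inclusive) pairs of contiguous True runs."""
    edges = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask) - 1)
    return list(zip(starts, stops))


def extract_valid_segment(trace: WeightTrace, eta: float = 0.8) -> ValidSegment:
    """Extract the valid plateau of ``trace``.

    The threshold is ``K1 = eta * Wmax``; samples below K1 are zeroed and
    the first differences of the zeroed series locate the rising and
    falling edges.  The returned values are the original (unthresholded)
    samples between the edges, all >= K1 (closed comparison, so boundary
    samples are kept).  If the animal hesitates and produces several
    disjoint above-threshold runs, the longest run is kept with a
    warning.
    """
    if not 0.0 < eta < 1.0:
        raise ValueError("eta must lie strictly between 0 and 1")
    w = trace.weights
    if trace.w_max <= 0.0:
        raise EmptySegmentError("no positive sample in trace; nothing exceeds the threshold")
    k1 = eta * trace.w_max

    thresholded = np.where(w >= k1, w, 0.0)
    mask = thresholded > 0.0
    if not mask.any():
        raise EmptySegmentError(f"no sample reaches K1 = {k1:.6g} kg")

    runs = _runs(mask)
    if len(runs) > 1:
        warnings.warn(
            f"{len(runs)} disjoint above-threshold runs (animal hesitating?); "
            "keeping the longest",
            stacklevel=2,
        )
    a, b = max(runs, key=lambda r: r[1] - r[0])
    return ValidSegment(
        values=w[a : b + 1],
        start_index=int(a),
        end_index=int(b),
        sampling_interval_s=trace.sampling_interval_s,
        threshold_kg=float(k1),
        eta=float(eta),
        animal_id=trace.animal_id,
    )
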