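"""Core in-memory containers for luminescence recordings.

A :class:`LuminescenceTrace` is one well's time series: a strictly increasing
time axis in hours and a luminescence signal in arbitrary counts, together
with the ordered list of preprocessing steps already applied to it.  A
:class:`PlateRecording` bundles the traces of one plate run — all sharing a
single time axis, as produced by a plate luminometer that reads every well on
a common schedule — with the well → condition and well → replicate metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConditionNotFoundError, ParameterError

#: Two successive sampling intervals differing by less than this (hours) are
#: considered equal; a trace whose intervals all agree to this tolerance is
#: declared regularly sampled.
REGULAR_SAMPLING_TOL_H = 1e-6


@dataclass(frozen=True)
class LuminescenceTrace:
    """One well's bioluminescence time series.

    Parameters
    ----------
    well_id
        Short well label, e.g. ``"A1"``.
    time_h
        Strictly increasing time axis in hours.  A 12-minute cadence is
        represented as 0.2 h steps.
    signal
        Luminescence counts, same length as ``time_h``.  Missing values are
        not permitted.
    steps_applied
        Ordered labels of the preprocessing steps already applied; empty for
        raw data.
    """

    well_id: str
    time_h: np.ndarray
    signal: np.ndarray
    steps_applied: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "signal", y)
        object.__setattr__(self, "steps_applied", tuple(self.steps_applied))
        if t.ndim != 1 or y.ndim != 1:
            raise ParameterError("time_h and signal must be one-dimensional")
        if t.size != y.size:
            raise ParameterError(
                f"time_h and signal lengths differ ({t.size} != {y.size}) "
                f"for well {self.well_id!r}"
            )
        if t.size < 2:
            raise ParameterError(
                f"trace {self.well_id!r} needs at least 2 samples, got {t.size}"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise ParameterError(
                f"trace {self.well_id!r} contains non-finite values"
            )
        if np.any(np.diff(t) <= 0):
            idx = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ParameterError(
                f"time_h must be strictly increasing; violation at index {idx} "
                f"(t={t[idx]}) in well {self.well_id!r}"
            )

    @property
    def n(self) -> int:
        return int(self.time_h.size)

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])

    @property
    def dt_h(self) -> float:
        """Median sampling interval in hours."""
        return float(np.median(np.diff(self.time_h)))

    @property
    def is_regular(self) -> bool:
        """True when successive time differences agree within 1e-6 h."""
        d = np.diff(self.time_h)
        return bool(d.max() - d.min() < REGULAR_SAMPLING_TOL_H)

    def with_values(
        self,
        time_h: np.ndarray,
        signal: np.ndarray,
        step: str | None = None,
    ) -> "LuminescenceTrace":
        """Return a copy carrying new values, appending ``step`` to the
        provenance list when given."""
        steps = self.steps_applied + ((step,) if step else ())
        return LuminescenceTrace(self.well_id, time_h, signal, steps)


@dataclass(frozen=True)
class PlateRecording:
    """A set of traces sharing one time axis, plus well metadata.

    ``condition_of`` maps every well to its condition label (cell line or
    treatment); ``replicate_of`` maps wells to technical-replicate indices
    and defaults to enumeration order within each condition.
    """

    traces: tuple[LuminescenceTrace, ...]
    condition_of: dict[str, str]
    replicate_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        traces = tuple(self.traces)
        object.__setattr__(self, "traces", traces)
        if not traces:
            raise ParameterError("plate has no traces")
        wells = [tr.well_id for tr in traces]
        if len(set(wells)) != len(wells):
            dup = next(w for w in wells if wells.count(w) > 1)
            raise ParameterError(f"duplicate well id {dup!r} on plate")
        t0 = traces[0].time_h
        for tr in traces[1:]:
            if tr.time_h.size != t0.size or not np.array_equal(tr.time_h, t0):
                raise ParameterError(
                    f"well {tr.well_id!r} does not share the plate time axis"
                )
        for w in wells:
            if w not in self.condition_of:
                raise ParameterError(f"well {w!r} missing from condition map")
        for w in self.condition_of:
            if w not in wells:
                raise ParameterError(
                    f"condition map names unknown well {w!r}"
                )
        if not self.replicate_of:
            reps: dict[str, int] = {}
            counter: dict[str, int] = {}
            for w in wells:
                c = self.condition_of[w]
                counter[c] = counter.get(c, 0) + 1
                reps[w] = counter[c]
            object.__setattr__(self, "replicate_of", reps)

    @property
    def time_h(self) -> np.ndarray:
        return self.traces[0].time_h

    @property
    def wells(self) -> list[str]:
        return [tr.well_id for tr in self.traces]

    def get(self, well_id: str) -> LuminescenceTrace:
        for tr in self.traces:
            if tr.well_id == well_id:
                return tr
        raise KeyError(well_id)

    def conditions(self) -> list[str]:
        """Distinct condition labels in plate order."""
        seen: list[str] = []
        for w in self.wells:
            c = self.condition_of[w]
            if c not in seen:
                seen.append(c)
        return seen

    def wells_for(self, condition: str) -> list[str]:
        found = [w for w in self.wells if self.condition_of[w] == condition]
        if not found:
            raise ConditionNotFoundError(
                f"condition {condition!r} not on plate; available: "
                f"{', '.join(self.conditions())}"
            )
        return found

    def map_traces(self, fn) -> "PlateRecording":
        """Apply ``fn`` to every trace, keeping metadata."""
        return replace(self, traces=tuple(fn(tr) for tr in self.traces))
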