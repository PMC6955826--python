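"""Container for per-subject resting-state network time-courses.

A :class:`TimeCourseSet` holds the representative time-course of every
labelled component (one column per network, one row per retained volume),
the sampling interval, and a per-component neuronal/artifactual flag.  It
is the unit on which functional network connectivity is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

#: Canonical names of the 10 large-scale resting-state networks analysed.
RSN_LABELS: tuple[str, ...] = (
    "auditory",
    "cerebellum",
    "DMN",
    "ECN-left",
    "ECN-right",
    "saliency",
    "sensorimotor",
    "visual-lateral",
    "visual-medial",
    "visual-occipital",
)

MIN_TIMEPOINTS = 32


@dataclass
class TimeCourseSet:
    """Named multivariate time-courses for one subject.

    Parameters
    ----------
    data:
        Array of shape ``(n_timepoints, n_components)``.
    labels:
        Component names, one per column.
    sampling_interval:
        Time between consecutive rows, in seconds (fMRI repetition time).
    neuronal:
        Boolean flag per component; non-neuronal components are excluded
        from connectivity (their matrix rows/columns are zeroed).
    meta:
        Free-form provenance (group, subject id, generator seed, ...).
    """

    data: np.ndarray
    labels: list[str]
    sampling_interval: float = 2.0
    neuronal: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be 2-D (timepoints x components)")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[1]:
            raise InvalidArgumentError(
                f"{len(self.labels)} labels for {self.data.shape[1]} columns"
            )
        if len(set(self.labels)) != len(self.labels):
            raise InvalidArgumentError("duplicate component labels")
        if self.sampling_interval <= 0:
            raise InvalidArgumentError("sampling_interval must be positive")
        if self.neuronal is None:
            self.neuronal = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.neuronal = np.asarray(self.neuronal, dtype=bool)
            if self.neuronal.shape != (self.data.shape[1],):
                raise InvalidArgumentError("neuronal flags must match column count")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def column(self, label: str) -> np.ndarray:
        """Return the time-course for one labelled component."""
        try:
            idx = self.labels.index(label)
        except ValueError as exc:
            raise InvalidArgumentError(f"unknown label {label!r}") from exc
        return self.data[:, idx]
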