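"""Per-learner event trajectories.

A learner's behaviour is represented as the vector of completion times
(days since course start) ordered by curriculum task index.  Tasks that
were never completed are absent from the vector, so different learners
generally have vectors of different length; the elastic DTW comparison
handles the length mismatch natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventSeries"]


@dataclass(frozen=True)
class EventSeries:
    """One learner's completion-time trajectory.

    Parameters
    ----------
    learner_id : str
        Unique learner identifier.
    times : ndarray of shape (n_completed,)
        Completion times in days since course start, ordered by the
        curriculum index of the completed task.
    n_total_tasks : int
        Number of tasks in the curriculum (denominator of the
        completion fraction).
    """

    learner_id: str
    times: np.ndarray = field(repr=False)
    n_total_tasks: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError(f"non-finite completion time for {self.learner_id!r}")
        total = int(self.n_total_tasks) if self.n_total_tasks else t.size
        if t.size > total:
            raise ValueError(
                f"{self.learner_id!r}: {t.size} completions exceed "
                f"n_total_tasks={total}"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_total_tasks", total)

    def __len__(self) -> int:
        return self.times.size

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (days, cumulative task count) sorted by completion day.

        This is the representation used for Gaussian-process trajectory
        averaging: the running number of tasks finished by each day.
        """
        days = np.sort(self.times)
        return days, np.arange(1, days.size + 1, dtype=float)
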