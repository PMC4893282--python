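"""Follow-up time discretization and person-interval expansion.

The sequential threshold model treats a censored time-to-event outcome as a
sequence of conditional binary trials: a patient reaches interval k only by
surviving intervals 1..k-1 event-free, and the probability of surviving
interval k given it was reached is Phi(gamma_k - eta), where eta is the
patient's liability-scale linear predictor, gamma_k the interval's cutoff
and the residual standard deviation is fixed at 1 for identifiability.

A patient with the event in interval k* contributes records for intervals
1..k* with outcomes 0,...,0,1.  A censored patient contributes one 0-outcome
record per *fully survived* interval: the interval in which censoring occurs
is dropped, since the patient's exposure there is incomplete (a time equal
to an interval's upper boundary counts that interval as fully survived).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalGrid:
    """Cut-points partitioning follow-up time into K intervals.

    ``boundaries`` is a strictly increasing array of K+1 time points,
    starting at 0 and ending at +inf; interval k (1-based) is
    [boundaries[k-1], boundaries[k]).
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if len(b) < 2:
            raise ValueError("grid needs at least 2 boundaries (K >= 1)")
        if b[0] != 0:
            raise ValueError("first boundary must be 0")
        if not np.isinf(b[-1]):
            raise ValueError("last boundary must be +inf")
        if not (np.diff(b) > 0).all():
            raise ValueError("boundaries must be strictly increasing")

    @property
    def K(self) -> int:
        return len(self.boundaries) - 1

    def interval_of(self, time: np.ndarray | float) -> np.ndarray | int:
        """1-based interval index containing each time point."""
        idx = np.searchsorted(self.boundaries, time, side="right")
        return np.minimum(idx, self.K)

    def n_fully_survived(self, time: np.ndarray) -> np.ndarray:
        """Number of intervals whose (finite) upper boundary is <= time."""
        finite_ub = self.boundaries[1:-1]
        return np.searchsorted(finite_ub, np.asarray(time), side="right")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"boundaries": [
                "inf" if np.isinf(b) else float(b) for b in self.boundaries
            ]}, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "IntervalGrid":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(np.array([float(b) for b in obj["boundaries"]]))


@dataclass
class ExpandedData:
    """Person-interval binary records of the sequential model."""

    record_patient: np.ndarray       # (R,) int index into the cohort
    record_interval: np.ndarray      # (R,) int, 1-based interval index
    record_outcome: np.ndarray       # (R,) int, 1 = event in this interval

    def __post_init__(self) -> None:
        self.record_patient = np.asarray(self.record_patient, dtype=int)
        self.record_interval = np.asarray(self.record_interval, dtype=int)
        self.record_outcome = np.asarray(self.record_outcome, dtype=int)

    @property
    def n_records(self) -> int:
        return len(self.record_patient)

    def to_frame(self, patient_ids: np.ndarray | None = None) -> pd.DataFrame:
        pid = (self.record_patient if patient_ids is None
               else np.asarray(patient_ids)[self.record_patient])
        return pd.DataFrame({
            "patient_id": pid,
            "interval": self.record_interval,
            "outcome": self.record_outcome,
        })


def build_grid_from_survival(time: np.ndarray, event: np.ndarray,
                             K: int) -> IntervalGrid:
    """Place K-1 interior cut-points at event-time quantiles.

    The cut-points split the observed event times into K groups as evenly
    as possible, so every interval contains at least one event.  This is an
    automatic analogue of choosing cut-points by inspecting the
    Kaplan-Meier curve; an explicit boundary list can be used instead via
    :class:`IntervalGrid`.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    et = np.sort(time[event == 1])
    if len(et) < K:
        raise ValueError(
            f"only {len(et)} events observed but K={K}; use a smaller K"
        )
    if K == 1:
        return IntervalGrid(np.array([0.0, np.inf]))
    cuts = np.quantile(et, np.arange(1, K) / K)
    if not (np.diff(cuts) > 0).all() or cuts[0] <= 0:
        raise ValueError(
            "event-time quantiles are tied; cannot place strictly increasing "
            f"boundaries for K={K}; use a smaller K"
        )
    grid = IntervalGrid(np.concatenate(([0.0], cuts, [np.inf])))
    counts = np.bincount(grid.interval_of(et), minlength=K + 1)[1:]
    if (counts == 0).any():
        raise ValueError(f"interval without events for K={K}; use a smaller K")
    return grid


def expand(cohort, grid: IntervalGrid) -> ExpandedData:
    """Expand (time, event) outcomes into person-interval records."""
    return expand_survival(cohort.time, cohort.event, grid)


def expand_survival(time: np.ndarray, event: np.ndarray,
                    grid: IntervalGrid) -> ExpandedData:
    """Vectorised person-interval expansion (see module docstring)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n_full = grid.n_fully_survived(time)
    # event patients add one record for the event interval itself
    counts = np.where(event == 1, n_full + 1, n_full)
    n_zero = int(((counts == 0) & (event == 0)).sum())
    if n_zero:
        log.info("%d censored patient(s) with no fully survived interval "
                 "contribute no records", n_zero)
    total = int(counts.sum())
    record_patient = np.repeat(np.arange(len(time)), counts)
    stops = np.cumsum(counts)
    starts = stops - counts
    record_interval = np.arange(total) - np.repeat(starts, counts) + 1
    record_outcome = np.zeros(total, dtype=int)
    last = stops - 1
    ev_mask = (event == 1) & (counts > 0)
    record_outcome[last[ev_mask]] = 1
    return ExpandedData(record_patient, record_interval, record_outcome)


def sequential_probability(gamma_k: float | np.ndarray,
                           eta: float | np.ndarray) -> float | np.ndarray:
    """Probability of surviving interval k event-free given it was reached.

    Phi(gamma_k - eta) with residual standard deviation 1; larger eta means
    higher event risk.
    """
    return ndtr(np.asarray(gamma_k) - np.asarray(eta))


def sequence_likelihood(gamma: np.ndarray, eta: float,
                        k_event: int | None = None,
                        n_survived: int | None = None) -> float:
    """Likelihood of one patient's full interval sequence.

    Exactly one of ``k_event`` (event in interval k, after surviving
    1..k-1) and ``n_survived`` (censored after fully surviving m intervals)
    must be given.  Equals the product of per-record Bernoulli likelihoods
    of the patient's expanded records.
    """
    gamma = np.asarray(gamma, dtype=float)
    K = len(gamma)
    if (k_event is None) == (n_survived is None):
        raise ValueError("give exactly one of k_event and n_survived")
    surv = ndtr(gamma - eta)
    if k_event is not None:
        if not 1 <= k_event <= K:
            raise IndexError(f"k_event={k_event} outside 1..{K}")
        return float(np.prod(surv[:k_event - 1]) * (1.0 - surv[k_event - 1]))
    if not 0 <= n_survived <= K:
        raise IndexError(f"n_survived={n_survived} outside 0..{K}")
    return float(np.prod(surv[:n_survived]))
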