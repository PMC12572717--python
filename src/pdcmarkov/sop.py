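"""State occupancy probabilities (SOPs) and mean time in state.

Transition probabilities conditioned on the previous state are
unconditioned by recursive matrix multiplication: given a subject's
state at window 4 and baseline covariates, the probability of occupying
each adherence state at windows 5..20 is

    pi_5 = P_5[initial, :],   pi_t = pi_{t-1} @ P_t,

where P_t is the one-step transition matrix at window t built from the
fitted proportional-odds model.  Mean time in a state (in 90-day units)
is the sum of that state's occupancy probabilities across the
prediction horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import POFit, probs_from_design

__all__ = [
    "SOPMatrix",
    "transition_matrix",
    "compute_sops",
    "compute_sops_cohort",
    "mean_time_in_state",
    "collapse_states",
    "FOUR_STATE",
    "THREE_STATE",
]

# built-in sensitivity groupings of the ten PDC states
FOUR_STATE = [(1, 1), (2, 7), (8, 9), (10, 10)]   # 0-9, 10-69, 70-89, 90-100 %
THREE_STATE = [(1, 1), (2, 9), (10, 10)]          # 0-9, 10-89, 90-100 %


@dataclass
class SOPMatrix:
    """Per-subject occupancy probabilities: windows x states."""

    patient_id: object
    windows: np.ndarray          # window indices, default 5..20
    probs: np.ndarray            # (T, n_states), rows sum to 1

    def __post_init__(self):
        self.windows = np.asarray(self.windows)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != len(self.windows):
            raise ValueError("probs rows must match windows")

    @property
    def n_states(self) -> int:
        return self.probs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        T, K = self.probs.shape
        return pd.DataFrame({
            "patient_id": np.repeat(self.patient_id, T * K),
            "window_index": np.repeat(self.windows, K),
            "state": np.tile(np.arange(1, K + 1), T),
            "probability": self.probs.ravel(),
        })


def transition_matrix(fit_: POFit, covariates: dict, time: float) -> np.ndarray:
    """K x K one-step matrix at a window; row s = P(next | prev = s)."""
    K = fit_.spec.n_states
    rows = []
    for s in range(1, K + 1):
        r = dict(covariates)
        r["y_prev"] = s
        r["time"] = time
        rows.append(r)
    X = fit_.builder.transform(pd.DataFrame(rows))
    return probs_from_design(fit_.alpha, fit_.beta, X, K)


def compute_sops(
    fit_: POFit,
    covariates: dict,
    initial_state: int,
    patient_id=None,
    windows=None,
) -> SOPMatrix:
    """Occupancy probabilities from the observed window-4 state onward.

    The first prediction row conditions on ``initial_state``; each later
    row marginalizes over the previous window's occupancy distribution.
    """
    K = fit_.spec.n_states
    if not 1 <= initial_state <= K:
        raise ValueError(f"initial_state {initial_state} outside 1..{K}")
    if windows is None:
        windows = np.arange(5, 21)
    windows = np.asarray(windows)
    # one design transform for all (window, previous-state) pairs
    T = len(windows)
    rows = pd.DataFrame({
        **{k: np.repeat(v, T * K) for k, v in covariates.items()},
        "time": np.repeat(windows.astype(float), K),
        "y_prev": np.tile(np.arange(1, K + 1), T),
    })
    X = fit_.builder.transform(rows)
    P_all = probs_from_design(fit_.alpha, fit_.beta, X, K).reshape(T, K, K)
    pi = np.zeros(K)
    pi[initial_state - 1] = 1.0
    out = np.empty((T, K))
    for i in range(T):
        pi = pi @ P_all[i]
        out[i] = pi
    return SOPMatrix(patient_id=patient_id, windows=windows, probs=out)


def compute_sops_cohort(
    fit_: POFit,
    transitions: pd.DataFrame,
    windows=None,
) -> list[SOPMatrix]:
    """SOPs for every patient in a transition table.

    Covariates are held at each subject's own values; the initial state
    is the observed state at the window before the first prediction
    window (``y_prev`` of the subject's first transition row).
    """
    cov_vars = [v for v, _ in fit_.spec.terms]
    out = []
    for pid, g in transitions.groupby("patient_id", sort=True):
        g = g.sort_values("time")
        covs = {v: g[v].iloc[0] for v in cov_vars}
        init = int(g["y_prev"].iloc[0])
        w = windows if windows is not None else g["time"].to_numpy()
        out.append(compute_sops(fit_, covs, init, patient_id=pid, windows=w))
    return out


def mean_time_in_state(sops: SOPMatrix, state: int) -> float:
    """Expected number of 90-day windows spent in ``state``."""
    if not 1 <= state <= sops.n_states:
        raise ValueError(f"state {state} outside 1..{sops.n_states}")
    return float(sops.probs[:, state - 1].sum())


def _check_partition(mapping, n_states: int) -> list[tuple[int, int]]:
    groups = [tuple(g) for g in mapping]
    expected_start = 1
    for lo, hi in groups:
        if lo != expected_start or hi < lo:
            raise ValueError(
                f"mapping {mapping} is not an ordered contiguous partition "
                f"of 1..{n_states}"
            )
        expected_start = hi + 1
    if expected_start != n_states + 1:
        raise ValueError(f"mapping {mapping} does not cover 1..{n_states}")
    return groups


def collapse_states(obj, mapping):
    """Collapse states into ordered contiguous groups.

    ``mapping`` is a list of (low, high) state ranges partitioning
    1..n_states, e.g. :data:`FOUR_STATE`.  For an :class:`SOPMatrix`,
    group probabilities are sums over member states; for an integer
    state array, states are relabelled by group index (1-based).
    """
    if isinstance(obj, SOPMatrix):
        groups = _check_partition(mapping, obj.n_states)
        cols = [obj.probs[:, lo - 1 : hi].sum(axis=1) for lo, hi in groups]
        return SOPMatrix(
            patient_id=obj.patient_id,
            windows=obj.windows,
            probs=np.column_stack(cols),
        )
    states = np.asarray(obj)
    n_states = max(int(states.max()), mapping[-1][-1])
    groups = _check_partition(mapping, n_states)
    out = np.zeros_like(states)
    for gi, (lo, hi) in enumerate(groups, start=1):
        out[(states >= lo) & (states <= hi)] = gi
    return out
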