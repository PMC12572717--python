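"""Restricted cubic spline bases and the transition-model design matrix.

Continuous predictors (age, CHA2DS2-VASc score, first-year covered days)
enter the model through restricted (natural) cubic splines with four
knots: a linear term plus two truncated-cubic terms constrained so the
fitted function is linear beyond the boundary knots.  The design matrix
additionally carries the previous-state encoding, a (centered) time
term, and optional spline-by-time interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["rcs_basis", "default_knots", "ModelSpec", "DesignBuilder"]

DEFAULT_KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's truncated-power form).

    For k knots ``t1 < ... < tk`` the basis has ``k-1`` columns: the
    identity ``x`` followed by ``k-2`` nonlinear terms

        B_j(x) = [ (x-t_j)+^3
                   - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                   + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

    for j = 1..k-2.  Any linear combination is linear for x outside
    [t1, tk]; below t1 the nonlinear columns are exactly zero.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"knots must be strictly increasing, got {knots}")
    k = len(knots)
    tk, tk1, t1 = knots[-1], knots[-2], knots[0]
    scale = (tk - t1) ** 2
    cols = [x]
    pos3 = lambda v: np.clip(v, 0.0, None) ** 3
    for j in range(k - 2):
        tj = knots[j]
        term = (
            pos3(x - tj)
            - pos3(x - tk1) * (tk - tj) / (tk - tk1)
            + pos3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


def default_knots(x, quantiles=DEFAULT_KNOT_QUANTILES) -> np.ndarray:
    """Knots at the conventional outer/inner quantiles for 4 knots."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 20:
        raise ValueError("need >= 20 distinct values for quantile knots")
    knots = np.quantile(x, quantiles)
    if len(np.unique(knots)) < len(quantiles):
        raise ValueError(
            f"quantile knots are not distinct ({knots}); supply explicit knots"
        )
    return knots


# transforms recognised in ModelSpec.terms
_TRANSFORMS = ("rcs4", "linear", "categorical")


@dataclass
class ModelSpec:
    """Declarative description of the transition-model design.

    Parameters
    ----------
    terms : list of (variable, transform)
        transform in {'rcs4', 'linear', 'categorical'}.
    interactions : list of (variable, 'time')
        Each basis column of ``variable`` is multiplied by the centered
        time column (main effects are always retained).
    prev_state_encoding : 'categorical' (reference = highest state) or
        'linear'.
    time_encoding : 'linear' or 'rcs4'.
    knots : dict variable -> 4 knots; computed from the data when absent.
    centers : dict variable -> centering constant; training means when
        absent.  Time is always centered.
    n_states : number of ordinal outcome levels.
    """

    terms: list = field(default_factory=list)
    interactions: list = field(default_factory=list)
    prev_state_encoding: str = "categorical"
    time_encoding: str = "linear"
    knots: dict = field(default_factory=dict)
    centers: dict = field(default_factory=dict)
    n_states: int = 10

    def __post_init__(self):
        seen = set()
        for var, tr in self.terms:
            if tr not in _TRANSFORMS:
                raise ValueError(f"unknown transform {tr!r} for {var!r}")
            if (var, tr) in seen:
                raise ValueError(f"duplicate term {var!r}")
            seen.add((var, tr))
        if self.prev_state_encoding not in ("categorical", "linear"):
            raise ValueError("prev_state_encoding must be categorical|linear")
        if self.time_encoding not in ("linear", "rcs4"):
            raise ValueError("time_encoding must be linear|rcs4")
        for var, _ in self.interactions:
            if var not in [v for v, _ in self.terms]:
                raise ValueError(f"interaction references unknown term {var!r}")

    def to_dict(self) -> dict:
        return {
            "terms": [list(t) for t in self.terms],
            "interactions": [list(t) for t in self.interactions],
            "prev_state_encoding": self.prev_state_encoding,
            "time_encoding": self.time_encoding,
            "knots": {k: list(map(float, v)) for k, v in self.knots.items()},
            "centers": {k: float(v) for k, v in self.centers.items()},
            "n_states": self.n_states,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            terms=[tuple(t) for t in d["terms"]],
            interactions=[tuple(t) for t in d["interactions"]],
            prev_state_encoding=d["prev_state_encoding"],
            time_encoding=d["time_encoding"],
            knots={k: np.asarray(v, float) for k, v in d["knots"].items()},
            centers=dict(d["centers"]),
            n_states=int(d["n_states"]),
        )

    @classmethod
    def from_strings(cls, term_strings, **kwargs) -> "ModelSpec":
        """Parse config-style term strings.

        e.g. ``["rcs4:age", "rcs4:days_w3 * time", "prev:categorical"]``.
        """
        terms, interactions = [], []
        prev_enc = kwargs.pop("prev_state_encoding", "categorical")
        for s in term_strings:
            s = s.strip()
            if s.startswith("prev:"):
                prev_enc = s.split(":", 1)[1]
                continue
            inter = False
            if "*" in s:
                s, rhs = (p.strip() for p in s.split("*", 1))
                if rhs != "time":
                    raise ValueError(f"only interactions with time supported: {s!r}")
                inter = True
            tr, var = s.split(":", 1)
            terms.append((var, tr))
            if inter:
                interactions.append((var, "time"))
        return cls(terms=terms, interactions=interactions,
                   prev_state_encoding=prev_enc, **kwargs)


class DesignBuilder:
    """Builds (and re-applies) the design matrix for a ModelSpec.

    ``fit(table)`` resolves knots, centering constants and the observed
    previous-state levels from a training transition table; ``transform``
    then maps any table with the same columns onto the fitted basis, so
    predictions use exactly the training-time design.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.knots_: dict = {}
        self.centers_: dict = {}
        self.prev_levels_: np.ndarray | None = None
        self.column_names_: list[str] | None = None

    # -- fitting ---------------------------------------------------------
    def fit(self, table: pd.DataFrame) -> "DesignBuilder":
        self._check_columns(table)
        for var, tr in self.spec.terms:
            if tr == "rcs4":
                if var in self.spec.knots:
                    self.knots_[var] = np.asarray(self.spec.knots[var], float)
                else:
                    self.knots_[var] = default_knots(table[var].to_numpy())
            self.centers_[var] = float(
                self.spec.centers.get(var, table[var].mean())
            )
        self.centers_["time"] = float(
            self.spec.centers.get("time", table["time"].mean())
        )
        if self.spec.time_encoding == "rcs4":
            self.knots_["time"] = np.asarray(
                self.spec.knots.get("time", default_knots(table["time"].to_numpy())),
                float,
            )
        if self.spec.prev_state_encoding == "categorical":
            self.prev_levels_ = np.unique(table["y_prev"].to_numpy())
        self.column_names_ = self._column_names()
        return self

    def fit_transform(self, table: pd.DataFrame) -> np.ndarray:
        return self.fit(table).transform(table)

    # -- application -----------------------------------------------------
    def transform(self, table: pd.DataFrame) -> np.ndarray:
        if self.column_names_ is None:
            raise RuntimeError("DesignBuilder not fitted")
        self._check_columns(table)
        blocks = []
        time_c = table["time"].to_numpy(float) - self.centers_["time"]
        for var, tr in self.spec.terms:
            blocks.append(self._term_block(table, var, tr))
        for var, _ in self.spec.interactions:
            tr = dict(self.spec.terms)[var]
            blocks.append(self._term_block(table, var, tr) * time_c[:, None])
        blocks.append(self._prev_block(table))
        blocks.append(self._time_block(time_c))
        X = np.hstack(blocks)
        if np.isnan(X).any():
            raise ValueError("design matrix contains missing values")
        return X

    # -- pieces ----------------------------------------------------------
    def _term_block(self, table, var, tr) -> np.ndarray:
        x = table[var].to_numpy(float)
        if tr == "linear":
            return (x - self.centers_[var])[:, None]
        if tr == "rcs4":
            b = rcs_basis(x, self.knots_[var])
            bc = rcs_basis(np.array([self.centers_[var]]), self.knots_[var])
            return b - bc  # centered so reference row is all-zero
        # categorical: indicators for all but the first observed level
        levels = np.unique(table[var].to_numpy())
        return np.column_stack([(table[var].to_numpy() == l).astype(float)
                                for l in levels[1:]])

    def _prev_block(self, table) -> np.ndarray:
        y_prev = table["y_prev"].to_numpy()
        if self.spec.prev_state_encoding == "linear":
            return (y_prev.astype(float) - self.spec.n_states)[:, None]
        levels = self.prev_levels_
        y_prev = self._merge_unseen(y_prev, levels)
        ref = self.spec.n_states if self.spec.n_states in levels else levels[-1]
        return np.column_stack([(y_prev == l).astype(float)
                                for l in levels if l != ref])

    def _merge_unseen(self, y_prev, levels) -> np.ndarray:
        unseen = np.setdiff1d(np.unique(y_prev), levels)
        if unseen.size:
            logger.warning(
                "previous-state levels %s unseen in training; merged with "
                "nearest observed level", unseen.tolist(),
            )
            y_prev = y_prev.copy()
            for u in unseen:
                nearest = levels[np.argmin(np.abs(levels - u))]
                y_prev[y_prev == u] = nearest
        return y_prev

    def _time_block(self, time_c) -> np.ndarray:
        if self.spec.time_encoding == "linear":
            return time_c[:, None]
        return rcs_basis(time_c + self.centers_["time"], self.knots_["time"])

    # -- naming / bookkeeping -------------------------------------------
    def _column_names(self) -> list[str]:
        names = []
        for var, tr in self.spec.terms:
            names.extend(self._term_names(var, tr))
        for var, _ in self.spec.interactions:
            tr = dict(self.spec.terms)[var]
            names.extend([f"{n}:time" for n in self._term_names(var, tr)])
        if self.spec.prev_state_encoding == "linear":
            names.append("y_prev")
        else:
            ref = (self.spec.n_states if self.spec.n_states in self.prev_levels_
                   else self.prev_levels_[-1])
            names.extend([f"y_prev[{l}]" for l in self.prev_levels_ if l != ref])
        if self.spec.time_encoding == "linear":
            names.append("time")
        else:
            names.extend(["time", "time'", "time''"])
        return names

    @staticmethod
    def _term_names(var, tr) -> list[str]:
        if tr == "linear":
            return [var]
        if tr == "rcs4":
            return [var, f"{var}'", f"{var}''"]
        return [f"{var}[cat]"]

    def _check_columns(self, table) -> None:
        need = {v for v, _ in self.spec.terms} | {"y_prev", "time"}
        missing = sorted(need - set(table.columns))
        if missing:
            raise ValueError(f"transition table missing columns {missing}")
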