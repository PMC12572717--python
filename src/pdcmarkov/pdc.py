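"""Gap-adjusted proportion-of-days-covered (PDC) over 90-day windows.

Pharmacy dispensing records are turned into day-level coverage intervals
with carry-over: an early refill is shifted forward so that no day of
supply is lost and no day is double counted.  All direct oral
anticoagulant (DOAC) agents are pooled into a single supply stream, so
switching between agents preserves carry-over.  Hospitalized days are
credited to the numerator (inpatients receive their medication from the
hospital), and each window's PDC is

    PDC = min(covered days + in-hospital days, 90) / 90

which is then binned into one of ten ordinal adherence states
(state 1 = PDC 0-9%, ..., state 10 = PDC 90-100%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_DAYS = 90
N_STATES = 10

__all__ = [
    "CoverageInterval",
    "gap_adjust",
    "window_coverage",
    "compute_pdc",
    "map_pdc_to_state",
    "build_cohort_windows",
    "load_dispensing",
    "load_hospital",
    "load_baseline",
]


@dataclass(frozen=True)
class CoverageInterval:
    """Half-open day range ``[start_day, end_day)`` of drug coverage.

    Day offsets are 0-based relative to the patient's index date.
    """

    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ValueError(
                f"empty interval [{self.start_day}, {self.end_day})"
            )


def gap_adjust(fill_days, days_supplied) -> list[CoverageInterval]:
    """Convert fills into maximal non-overlapping coverage intervals.

    Carry-over is unlimited: each fill's effective start is the later of
    its dispense day and the previous fill's effective end, so supply
    stockpiles indefinitely and total covered days equal the total days
    supplied.

    Parameters
    ----------
    fill_days : sequence of int
        Dispense day offsets (0-based from the index date), sorted
        ascending.  All agents are pooled before calling this.
    days_supplied : sequence of int
        Positive days of supply per fill, aligned with ``fill_days``.

    Returns
    -------
    list of CoverageInterval, sorted and non-overlapping.
    """
    fill_days = np.asarray(fill_days, dtype=np.int64)
    supply = np.asarray(days_supplied, dtype=np.int64)
    if fill_days.size == 0:
        raise ValueError("no fills")
    if fill_days.shape != supply.shape:
        raise ValueError("fill_days and days_supplied differ in length")
    if np.any(np.diff(fill_days) < 0):
        raise ValueError("fills must be sorted ascending by dispense day")
    if np.any(supply <= 0):
        raise ValueError("days_supplied must be >= 1")

    intervals: list[CoverageInterval] = []
    cursor = -1  # effective end of supply so far
    cur_start = None
    for day, ds in zip(fill_days.tolist(), supply.tolist()):
        start = max(day, cursor if cursor >= 0 else day)
        if cur_start is None:  # first fill
            cur_start, cursor = start, start + ds
        elif start > cursor:
            intervals.append(CoverageInterval(cur_start, cursor))
            cur_start, cursor = start, start + ds
        else:  # abuts or overlaps: extend (start == cursor after shifting)
            cursor = start + ds
    intervals.append(CoverageInterval(cur_start, cursor))
    return intervals


def _days_in_window(starts, ends, lo: int, hi: int) -> np.ndarray:
    """Boolean day mask of length hi-lo covered by any [start, end)."""
    mask = np.zeros(hi - lo, dtype=bool)
    for s, e in zip(starts, ends):
        a, b = max(s, lo), min(e, hi)
        if b > a:
            mask[a - lo : b - lo] = True
    return mask


def window_coverage(
    intervals: list[CoverageInterval],
    stays,
    k: int,
    hospital_credit: str = "union",
) -> tuple[int, int]:
    """Covered and credited hospital days inside window ``k``.

    Window ``k`` (1-based) spans days ``[90(k-1), 90k)`` from the index
    date.  With ``hospital_credit='union'`` (default) hospital days that
    overlap drug-covered days are not double counted; ``'sum'`` adds raw
    hospital days (the final PDC is capped at 1 either way).

    ``stays`` is a sequence of ``(admit_day, discharge_day)`` offsets;
    the discharge day itself counts as in hospital.  Days before the
    index date are clipped, not rejected.
    """
    if k < 1:
        raise ValueError("window index k must be >= 1")
    if hospital_credit not in ("union", "sum"):
        raise ValueError(f"unknown hospital_credit mode {hospital_credit!r}")
    lo, hi = WINDOW_DAYS * (k - 1), WINDOW_DAYS * k
    cov = _days_in_window(
        [iv.start_day for iv in intervals], [iv.end_day for iv in intervals], lo, hi
    )
    hosp = _days_in_window(
        [max(a, 0) for a, _ in stays], [d + 1 for _, d in stays], lo, hi
    )
    covered_days = int(cov.sum())
    if hospital_credit == "union":
        hospital_days = int((hosp & ~cov).sum())
    else:
        hospital_days = int(hosp.sum())
    return covered_days, hospital_days


def compute_pdc(covered_days: int, hospital_days: int) -> float:
    """PDC = min(covered + hospital, 90) / 90."""
    if covered_days < 0 or hospital_days < 0:
        raise ValueError("day counts must be non-negative")
    return min(covered_days + hospital_days, WINDOW_DAYS) / WINDOW_DAYS


def map_pdc_to_state(pdc: float) -> int:
    """Ordinal adherence state 1-10 for a PDC value.

    Percentage bins are left-closed, right-open ([0,10), [10,20), ...)
    with the top bin [90,100] closed, matching the labels 0%-9%, ...,
    90%-100% while covering every real-valued pct = 100*n/90.
    """
    if not 0.0 <= pdc <= 1.0:
        raise ValueError(f"pdc {pdc} outside [0, 1]")
    pct = 100.0 * pdc
    return 10 if pct >= 90.0 else int(pct // 10) + 1


def _patient_windows(
    fill_days,
    supplies,
    stays,
    n_windows: int,
    hospital_credit: str,
) -> list[tuple[int, int, int, float, int]]:
    intervals = gap_adjust(fill_days, supplies)
    rows = []
    for k in range(1, n_windows + 1):
        c, h = window_coverage(intervals, stays, k, hospital_credit)
        pdc = compute_pdc(c, h)
        rows.append((k, c, h, pdc, map_pdc_to_state(pdc)))
    return rows


def build_cohort_windows(
    dispensing: pd.DataFrame,
    hospital: pd.DataFrame,
    baseline: pd.DataFrame,
    n_windows: int = 20,
    hospital_credit: str = "union",
    min_fills: int = 2,
    min_days_supplied: int = 60,
) -> pd.DataFrame:
    """Per-patient windowed adherence table.

    Eligibility follows the "on therapy for at least two months" rule:
    at least ``min_fills`` dispensing records totalling at least
    ``min_days_supplied`` days of supply.  Patients without a baseline
    row (and hence no index date) are logged and dropped.  The index
    date defaults to each patient's first dispense date when the
    baseline ``index_date`` column is missing.

    Returns a DataFrame with columns patient_id, window_index,
    covered_days, hospital_days, pdc, state — exactly ``n_windows``
    rows per eligible patient.
    """
    disp = dispensing.copy()
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])
    base = baseline.set_index("patient_id")
    if "index_date" in base.columns:
        index_dates = pd.to_datetime(base["index_date"])
    else:
        index_dates = disp.groupby("patient_id")["dispense_date"].min()

    hosp_by_pid: dict = {}
    if len(hospital):
        h = hospital.copy()
        h["admit_date"] = pd.to_datetime(h["admit_date"])
        h["discharge_date"] = pd.to_datetime(h["discharge_date"])
        if (h["discharge_date"] < h["admit_date"]).any():
            raise ValueError("hospital stay with discharge before admission")
        for pid, g in h.groupby("patient_id"):
            hosp_by_pid[pid] = g

    out = []
    n_dropped = n_inelig = 0
    for pid, g in disp.sort_values("dispense_date").groupby("patient_id"):
        if pid not in base.index:
            logger.warning("patient %s has no baseline row; dropped", pid)
            n_dropped += 1
            continue
        if len(g) < min_fills or g["days_supplied"].sum() < min_days_supplied:
            n_inelig += 1
            continue
        idx = index_dates.loc[pid]
        fill_days = (g["dispense_date"] - idx).dt.days.to_numpy()
        keep = fill_days >= 0
        if not keep.all():
            logger.warning(
                "patient %s: %d fills before index date ignored", pid, (~keep).sum()
            )
        if not keep.any():
            n_inelig += 1
            continue
        stays = []
        if pid in hosp_by_pid:
            hg = hosp_by_pid[pid]
            stays = list(
                zip(
                    (hg["admit_date"] - idx).dt.days,
                    (hg["discharge_date"] - idx).dt.days,
                )
            )
            stays = [(a, d) for a, d in stays if d >= 0]
        for k, c, h_, pdc, state in _patient_windows(
            fill_days[keep], g["days_supplied"].to_numpy()[keep], stays,
            n_windows, hospital_credit,
        ):
            out.append((pid, k, c, h_, pdc, state))

    if n_dropped or n_inelig:
        logger.info(
            "build_cohort_windows: %d patients without baseline dropped, "
            "%d ineligible (<%d fills or <%d days supplied)",
            n_dropped, n_inelig, min_fills, min_days_supplied,
        )
    return pd.DataFrame(
        out,
        columns=[
            "patient_id", "window_index", "covered_days",
            "hospital_days", "pdc", "state",
        ],
    )


def load_dispensing(path) -> pd.DataFrame:
    """Read a dispensing CSV (patient_id,dispense_date,drug_code,days_supplied)."""
    df = pd.read_csv(path)
    _require(df, ["patient_id", "dispense_date", "drug_code", "days_supplied"], path)
    if (df["days_supplied"] < 1).any():
        raise ValueError(f"{path}: days_supplied must be >= 1")
    return df


def load_hospital(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["patient_id", "admit_date", "discharge_date"], path)
    return df


def load_baseline(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["patient_id", "index_date", "age", "chads_vasc"], path)
    return df


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
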