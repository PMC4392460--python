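"""Containers for serial glycerol-test audiometry.

A *case* is one tested ear of one patient: a pre-test audiogram (hour 0)
and hourly post-glycerol audiograms up to hour 4, each a set of hearing
thresholds (dB HL, 5 dB steps) by frequency.  A :class:`CaseSet` holds a
whole cohort in a long-format table plus, for synthetically generated
cohorts, a hidden-truth table (latent group and true MTR per case) that
parameter-recovery tests can check against without re-inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .quantize import AUDIOMETER_MAX_DB, AUDIOMETER_MIN_DB

__all__ = ["Audiogram", "Case", "CaseSet", "CASE_COLUMNS", "TRUTH_COLUMNS", "CaseDataError"]

CASE_COLUMNS = ["case_id", "ear", "hour", "freq_hz", "threshold_db"]
TRUTH_COLUMNS = ["case_id", "ear", "true_mtr", "group"]
VALID_EARS = ("L", "R")
VALID_HOURS = (0, 1, 2, 3, 4)


class CaseDataError(ValueError):
    """Malformed case table (bad threshold, duplicate key, missing column...)."""


@dataclass(frozen=True)
class Audiogram:
    """Thresholds (dB HL) by frequency (Hz) for one case/ear/timepoint.

    ``label`` is free-form context ("C0012/L hour 0") used only to make
    error messages actionable.
    """

    thresholds: Mapping[int, float]
    label: str | None = None

    def threshold_at(self, freq_hz: int) -> float:
        try:
            return float(self.thresholds[freq_hz])
        except KeyError:
            where = f" in audiogram {self.label}" if self.label else ""
            raise KeyError(f"no threshold at {freq_hz} Hz{where}") from None

    def mean_over(self, freqs) -> float:
        return float(np.mean([self.threshold_at(f) for f in freqs]))

    @property
    def freqs(self) -> tuple[int, ...]:
        return tuple(sorted(int(f) for f in self.thresholds))


@dataclass(frozen=True)
class Case:
    """One case: audiograms keyed by hour, plus optional hidden truth."""

    case_id: str
    ear: str
    audiograms: Mapping[int, Audiogram]
    group: str | None = None
    true_mtr: int | None = None


def _validate_case_frame(df: pd.DataFrame, where: str = "case table") -> pd.DataFrame:
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise CaseDataError(f"{where}: missing column(s) {missing}")
    df = df[CASE_COLUMNS].copy()
    if len(df) == 0:
        return df
    bad_ear = ~df["ear"].isin(VALID_EARS)
    if bad_ear.any():
        row = int(np.flatnonzero(bad_ear.to_numpy())[0])
        raise CaseDataError(f"{where}, row {row}: ear must be one of {VALID_EARS}, got {df['ear'].iloc[row]!r}")
    for col in ("hour", "freq_hz", "threshold_db"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise CaseDataError(f"{where}, row {row}: non-numeric {col}: {df[col].iloc[row]!r}")
        df[col] = vals
    bad_hour = ~df["hour"].isin(VALID_HOURS)
    if bad_hour.any():
        row = int(np.flatnonzero(bad_hour.to_numpy())[0])
        raise CaseDataError(f"{where}, row {row}: hour must be in {VALID_HOURS}, got {df['hour'].iloc[row]}")
    thr = df["threshold_db"].to_numpy(dtype=float)
    bad_thr = (np.mod(thr, 5) != 0) | (thr < AUDIOMETER_MIN_DB) | (thr > AUDIOMETER_MAX_DB)
    if bad_thr.any():
        row = int(np.flatnonzero(bad_thr)[0])
        raise CaseDataError(
            f"{where}, row {row}: threshold must be a multiple of 5 dB in "
            f"[{AUDIOMETER_MIN_DB:.0f}, {AUDIOMETER_MAX_DB:.0f}], got {thr[row]}"
        )
    dup = df.duplicated(subset=["case_id", "ear", "hour", "freq_hz"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = df.loc[df.index[row], ["case_id", "ear", "hour", "freq_hz"]].tolist()
        raise CaseDataError(f"{where}, row {row}: duplicate (case_id, ear, hour, freq_hz) key {key}")
    df["hour"] = df["hour"].astype(np.int8)
    df["freq_hz"] = df["freq_hz"].astype(np.int32)
    df["threshold_db"] = df["threshold_db"].astype(np.int16)
    return df


@dataclass
class CaseSet:
    """A cohort of glycerol-test cases.

    ``data`` is long format with columns ``case_id, ear, hour, freq_hz,
    threshold_db``; ``truth`` (synthetic cohorts only) has columns
    ``case_id, ear, true_mtr, group``.
    """

    data: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = _validate_case_frame(pd.DataFrame(self.data))
        if self.truth is not None:
            truth = pd.DataFrame(self.truth)
            missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
            if missing:
                raise CaseDataError(f"truth table: missing column(s) {missing}")
            self.truth = truth

    @property
    def n_cases(self) -> int:
        if len(self.data) == 0:
            return 0
        return len(self.data[["case_id", "ear"]].drop_duplicates())

    def hours(self) -> tuple[int, ...]:
        return tuple(sorted(self.data["hour"].unique().tolist()))

    def freqs(self) -> tuple[int, ...]:
        return tuple(sorted(self.data["freq_hz"].unique().tolist()))

    def threshold_pivot(self, hour: int, freqs=None) -> pd.DataFrame:
        """Wide table: rows (case_id, ear), columns freq_hz, at one hour.

        Only cases with *all* requested frequencies present are returned.
        """
        sub = self.data[self.data["hour"] == hour]
        if freqs is not None:
            sub = sub[sub["freq_hz"].isin(list(freqs))]
        wide = sub.pivot_table(
            index=["case_id", "ear"], columns="freq_hz", values="threshold_db", aggfunc="first"
        )
        if freqs is not None:
            present = [f for f in freqs if f in wide.columns]
            wide = wide[present] if present else wide.iloc[:, :0]
            if len(present) < len(list(freqs)):
                return wide.dropna().iloc[0:0]
        return wide.dropna()

    def audiogram(self, case_id: str, ear: str, hour: int) -> Audiogram:
        sub = self.data[
            (self.data["case_id"] == case_id) & (self.data["ear"] == ear) & (self.data["hour"] == hour)
        ]
        if len(sub) == 0:
            raise KeyError(f"no audiogram for case {case_id}/{ear} at hour {hour}")
        thresholds = dict(zip(sub["freq_hz"].astype(int), sub["threshold_db"].astype(float)))
        return Audiogram(thresholds, label=f"{case_id}/{ear} hour {hour}")

    def iter_cases(self) -> Iterator[Case]:
        truth_idx = None
        if self.truth is not None:
            truth_idx = self.truth.set_index(["case_id", "ear"])
        for (case_id, ear), sub in self.data.groupby(["case_id", "ear"], sort=True, observed=True):
            audiograms = {}
            for hour, hsub in sub.groupby("hour"):
                thresholds = dict(zip(hsub["freq_hz"].astype(int), hsub["threshold_db"].astype(float)))
                audiograms[int(hour)] = Audiogram(thresholds, label=f"{case_id}/{ear} hour {hour}")
            group = true_mtr = None
            if truth_idx is not None and (case_id, ear) in truth_idx.index:
                row = truth_idx.loc[(case_id, ear)]
                group = None if pd.isna(row["group"]) else str(row["group"])
                true_mtr = None if pd.isna(row["true_mtr"]) else int(row["true_mtr"])
            yield Case(str(case_id), str(ear), audiograms, group, true_mtr)

    def equals(self, other: "CaseSet") -> bool:
        a = self.data.sort_values(CASE_COLUMNS, ignore_index=True).astype({"case_id": str})
        b = other.data.sort_values(CASE_COLUMNS, ignore_index=True).astype({"case_id": str})
        return a.equals(b)
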