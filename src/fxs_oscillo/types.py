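"""Domain containers shared by all pipeline stages.

All voltages are microvolts (µV), all times seconds unless a name says
otherwise (``*_ms``).  Stimulus event times are seconds from recording
onset; sample indexing is 0-based and epoch windows are half-open
``[t0, t1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "KO")
SEXES = ("F", "M")
#: Baclofen dose levels (mg/kg); "vehicle" is the saline control session.
DOSES = ("vehicle", "1.0", "2.5", "5.0")


class ValidationError(ValueError):
    """Input violates a container invariant."""


class FormatError(ValueError):
    """A file could not be parsed; the message names the offending field."""


class ConfigurationError(ValueError):
    """Inconsistent or out-of-range configuration."""


class EmptyInputError(ValueError):
    """An operation received no usable data (e.g. zero kept sweeps)."""


class PairingError(ValueError):
    """A within-subject pairing (vehicle vs dose session) is missing."""


class UndefinedValueError(ValueError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""


def normalize_dose(dose) -> str:
    """Canonicalize a dose label to one of :data:`DOSES`.

    Accepts the canonical strings, the numeric doses (1, 2.5, 5) as
    numbers or strings, and 0 / "0" for vehicle.
    """
    if isinstance(dose, str):
        d = dose.strip().lower()
        if d in ("vehicle", "veh"):
            return "vehicle"
        try:
            val = float(d)
        except ValueError as err:
            raise ValidationError(f"unknown dose label {dose!r}") from err
    else:
        val = float(dose)
    if val == 0:
        return "vehicle"
    for lab in DOSES[1:]:
        if val == float(lab):
            return lab
    raise ValidationError(f"dose {dose!r} not one of {DOSES}")


@dataclass(frozen=True)
class SubjectMeta:
    """Identity and design cell of one mouse."""

    subject_id: str
    genotype: str  # "WT" | "KO"
    sex: str  # "F" | "M"

    def __post_init__(self):
        if not self.subject_id:
            raise ValidationError("subject_id must be a non-empty string")
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"genotype {self.genotype!r} not in {GENOTYPES}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex {self.sex!r} not in {SEXES}")


@dataclass(frozen=True)
class Session:
    """One test day: a dose condition plus its ordinal position."""

    dose: str
    session_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "dose", normalize_dose(self.dose))
        if int(self.session_index) != self.session_index or self.session_index < 0:
            raise ValidationError("session_index must be a non-negative integer")


@dataclass
class Recording:
    """Continuous single-channel EEG with stimulus onset times.

    ``samples`` is µV at constant rate ``fs``; ``events`` are stimulus
    onsets in seconds, strictly increasing and inside the recording.
    """

    samples: np.ndarray
    fs: float
    events: np.ndarray
    meta: SubjectMeta
    session: Session

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be a 1-D voltage trace")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        self.events = np.asarray(self.events, dtype=float).ravel()
        if self.events.size and np.any(np.diff(self.events) <= 0):
            raise ValidationError("events must be strictly increasing")
        if self.events.size:
            if self.events[0] < 0 or self.events[-1] > self.duration:
                bad = self.events[(self.events < 0) | (self.events > self.duration)]
                raise ValidationError(
                    f"events outside recording [0, {self.duration:.6g}] s: {bad[:5]}"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs


@dataclass
class EpochSet:
    """Stimulus-locked sweeps: ``data`` is sweeps × samples, t=0 at onset.

    ``kept`` marks sweeps that survived artifact rejection; rejected
    sweeps keep their data so the rejection is reviewable.
    """

    data: np.ndarray
    t: np.ndarray
    fs: float
    kept: np.ndarray
    meta: SubjectMeta
    session: Session

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("epoch data must be 2-D (sweeps × samples)")
        if self.t.ndim != 1 or self.t.size != self.data.shape[1]:
            raise ValidationError("time axis length must match epoch samples")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValidationError("time axis must be uniform")
        self.kept = np.asarray(self.kept, dtype=bool).ravel()
        if self.kept.size != self.data.shape[0]:
            raise ValidationError("kept mask must have one entry per sweep")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept]

    def with_mask(self, kept: np.ndarray) -> "EpochSet":
        return EpochSet(self.data, self.t, self.fs, kept, self.meta, self.session)


_META_COLS = ("subject_id", "genotype", "sex", "dose")


class CohortTable:
    """Per-subject, per-dose measures in a wide table keyed by (subject_id, dose).

    The on-disk interchange format is long CSV with columns
    ``subject_id, genotype, sex, dose, measure, value``; in memory the
    table is wide (one column per measure) for convenient joins.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns {missing}")
        df["dose"] = [normalize_dose(d) for d in df["dose"]]
        if df.duplicated(subset=["subject_id", "dose"]).any():
            dups = df[df.duplicated(subset=["subject_id", "dose"], keep=False)]
            raise ValidationError(
                "duplicate (subject_id, dose) keys: "
                f"{sorted(set(map(tuple, dups[['subject_id', 'dose']].values)))[:5]}"
            )
        for g in df["genotype"]:
            if g not in GENOTYPES:
                raise ValidationError(f"genotype {g!r} not in {GENOTYPES}")
        for s in df["sex"]:
            if s not in SEXES:
                raise ValidationError(f"sex {s!r} not in {SEXES}")
        # genotype/sex must be constant per subject
        per_subj = df.groupby("subject_id")[["genotype", "sex"]].nunique()
        bad = per_subj[(per_subj > 1).any(axis=1)].index.tolist()
        if bad:
            raise ValidationError(f"inconsistent genotype/sex for subjects {bad}")
        for col in df.columns:
            if col.endswith("_pct"):
                vals = pd.to_numeric(df[col], errors="coerce").dropna()
                if ((vals < 0) | (vals > 100)).any():
                    raise ValidationError(f"percentage measure {col!r} outside [0, 100]")
        self.df = df.reset_index(drop=True)

    @property
    def measures(self) -> list[str]:
        return [c for c in self.df.columns if c not in _META_COLS]

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        a = self.df.sort_values(["subject_id", "dose"]).reset_index(drop=True)
        b = other.df.sort_values(["subject_id", "dose"]).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b[a.columns], check_like=True)
            return True
        except AssertionError:
            return False

    def to_long(self) -> pd.DataFrame:
        long = self.df.melt(
            id_vars=list(_META_COLS), var_name="measure", value_name="value"
        )
        return long.dropna(subset=["value"]).reset_index(drop=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "CohortTable":
        need = set(_META_COLS) | {"measure", "value"}
        missing = sorted(need - set(long.columns))
        if missing:
            raise FormatError(f"long cohort table missing columns {missing}")
        wide = long.pivot_table(
            index=list(_META_COLS), columns="measure", values="value", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        return cls(wide)

    def merge(self, other: "CohortTable") -> "CohortTable":
        """Outer-join measures of two tables on the (subject, dose) key."""
        merged = self.df.merge(
            other.df, on=list(_META_COLS), how="outer", validate="one_to_one"
        )
        return CohortTable(merged)
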