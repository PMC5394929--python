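"""Filtering, epoch extraction and per-animal artifact rejection.

Filtering is zero-phase (forward-backward Butterworth) so ERP peak
latencies are not shifted.  Sweeps are rejected when their RMS exceeds
``reject_mult`` (default 2) times the RMS of the animal's whole
filtered recording — a per-mouse criterion, so a noisy animal is not
judged against a quiet one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import EpochSpec, FilterSpec
from .types import EmptyInputError, EpochSet, Recording, ValidationError

log = logging.getLogger(__name__)


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase band-pass; removes DC, passband gain within ±5%."""
    spec = (spec or FilterSpec()).validate(rec.fs)
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                     fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    return Recording(filtered, rec.fs, rec.events, rec.meta, rec.session)


def recording_rms(rec: Recording) -> float:
    """Root-mean-square amplitude of the whole (filtered) trace, µV."""
    return float(np.sqrt(np.mean(rec.samples ** 2)))


def extract_epochs(rec: Recording, window: tuple[float, float] = (-0.25, 0.5)) -> EpochSet:
    """Slice stimulus-locked sweeps over the half-open window [pre, post).

    Events whose window falls outside the recording are skipped with a
    logged count; no usable events raises :class:`EmptyInputError`.
    """
    pre_s, post_s = window
    if pre_s >= post_s:
        raise ValidationError("epoch window must satisfy pre < post")
    fs = rec.fs
    n_samp = int(round((post_s - pre_s) * fs))
    rows, used = [], []
    skipped = 0
    for onset in rec.events:
        start = int(round((onset + pre_s) * fs))
        if start < 0 or start + n_samp > rec.n_samples:
            skipped += 1
            continue
        rows.append(rec.samples[start : start + n_samp])
        used.append(onset)
    if skipped:
        log.info("extract_epochs: skipped %d/%d events with incomplete windows",
                 skipped, rec.events.size)
    if not rows:
        raise EmptyInputError("no events with a complete epoch window")
    t = pre_s + np.arange(n_samp) / fs
    return EpochSet(np.vstack(rows), t, fs, np.ones(len(rows), bool),
                    rec.meta, rec.session)


@dataclass
class RejectionReport:
    """Per-sweep artifact-rejection bookkeeping."""

    sweep_rms: np.ndarray
    threshold: float  # µV: reject_mult × recording RMS
    kept: np.ndarray

    @property
    def n_rejected(self) -> int:
        return int((~self.kept).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sweep": np.arange(self.kept.size),
            "sweep_rms": self.sweep_rms,
            "threshold": self.threshold,
            "kept": self.kept,
        })


def reject_artifacts(ep: EpochSet, rec_rms: float,
                     reject_mult: float = 2.0) -> tuple[EpochSet, RejectionReport]:
    """Reject sweeps whose RMS exceeds ``reject_mult × rec_rms``.

    ``rec_rms`` must be the RMS of the same animal's full filtered
    recording.  Sweep data are preserved; only the kept mask changes.
    The criterion is scale invariant: scaling recording and epochs by
    the same constant leaves the mask unchanged.
    """
    if ep.n_sweeps == 0:
        raise EmptyInputError("cannot reject artifacts in an empty epoch set")
    if rec_rms <= 0:
        raise ValidationError("rec_rms must be positive")
    sweep_rms = np.sqrt(np.mean(ep.data ** 2, axis=1))
    threshold = reject_mult * rec_rms
    kept = ep.kept & (sweep_rms <= threshold)
    if not kept.any():
        raise EmptyInputError(
            f"all {ep.n_sweeps} sweeps exceed the rejection threshold "
            f"{threshold:.3g} µV; review the 2×RMS criterion for this animal"
        )
    report = RejectionReport(sweep_rms=sweep_rms, threshold=threshold, kept=kept)
    return ep.with_mask(kept), report


def preprocess_recording(rec: Recording, filt: FilterSpec | None = None,
                         epoch: EpochSpec | None = None
                         ) -> tuple[EpochSet, RejectionReport, Recording]:
    """Filter → epoch → reject, returning the filtered recording too."""
    epoch = epoch or EpochSpec()
    filtered = bandpass(rec, filt)
    ep = extract_epochs(filtered, (epoch.pre_s, epoch.post_s))
    ep, report = reject_artifacts(ep, recording_rms(filtered), epoch.reject_mult)
    return ep, report, filtered
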