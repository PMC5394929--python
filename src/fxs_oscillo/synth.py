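"""Synthetic auditory-EEG cohorts with retained ground truth.

Each recording is a sum of independent components, emulating a mouse
skull-screw EEG session: a 1/f^alpha broadband background, ongoing
band-limited 30-80 Hz activity whose power carries the genotype × sex
baseline-gamma effect, a stimulus-locked ERP kernel (positive Gabor
near 20 ms, negative Gabor near 40 ms), a phase-locked gamma burst
(identical phase every sweep → evoked power) and a phase-random gamma
burst (uniform phase per sweep → induced power), plus sporadic
high-amplitude movement-artifact transients.  The protocol is a silent
baseline followed by ``n_stim`` white-noise stimuli at a fixed ISI.

Effect multipliers act on *power*; amplitudes are scaled by their
square root.  Ground truth (true component energies, ERP amplitudes,
artifact sweep indices, pre-noise behavior) is retained per
subject-session so recovery tests can compare measured against
generated quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import EffectConfig
from .types import (
    CohortTable,
    ConfigurationError,
    DOSES,
    GENOTYPES,
    PairingError,
    Recording,
    SEXES,
    Session,
    SubjectMeta,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# primitives

def gabor(t: np.ndarray, center: float, sigma: float, freq: float,
          amp: float, phase: float = 0.0) -> np.ndarray:
    """Gaussian-windowed cosine atom; ``freq=0`` gives a plain Gaussian bump."""
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return amp * env * np.cos(2 * np.pi * freq * (t - center) + phase)


def pink_noise(n: int, rng: np.random.Generator, sd: float, alpha: float = 1.0) -> np.ndarray:
    """1/f^alpha noise normalized to the requested standard deviation."""
    if n == 0 or sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0  # avoid DC blow-up; DC removed below anyway
    spec = spec / f ** (alpha / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def band_noise(n: int, fs: float, band: tuple, rng: np.random.Generator, sd: float) -> np.ndarray:
    """Gaussian noise band-passed to ``band``, normalized to ``sd``."""
    if n == 0 or sd == 0:
        return np.zeros(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x * (sd / s) if s > 0 else x


def coupling_for_rho(rho: float, behavior_noise_sd: float) -> float:
    """Coupling slope giving population correlation ``rho`` between the
    Δ evoked-energy z-score and Δ %alternation.

    Δ %alternation = coupling·(−z) + (noise_dose − noise_vehicle), so
    ρ = −c / sqrt(c² + 2σ²); this inverts that relation.
    """
    if not -1 < rho < 1:
        raise ConfigurationError("rho must be in (-1, 1)")
    return abs(rho) * np.sqrt(2.0) * behavior_noise_sd / np.sqrt(1.0 - rho ** 2)


# ---------------------------------------------------------------------------
# ground truth

@dataclass(frozen=True)
class SubjectEffects:
    """Subject-level lognormal power multipliers, constant across sessions."""

    baseline: float = 1.0
    evoked: float = 1.0
    induced: float = 1.0
    erp: float = 1.0


@dataclass
class GroundTruth:
    """Per subject-session generative truth.

    ``table`` has one row per (subject_id, dose); ``artifacts`` maps
    (subject_id, dose) to the sweep indices that received a transient.
    """

    table: pd.DataFrame
    artifacts: dict

    @classmethod
    def concat(cls, parts: list["GroundTruth"]) -> "GroundTruth":
        table = pd.concat([p.table for p in parts], ignore_index=True)
        artifacts: dict = {}
        for p in parts:
            artifacts.update(p.artifacts)
        return cls(table, artifacts)


def draw_subject_effects(cfg: EffectConfig, rng: np.random.Generator) -> SubjectEffects:
    sd = cfg.subject_jitter_sd
    draw = lambda: float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0
    return SubjectEffects(baseline=draw(), evoked=draw(), induced=draw(), erp=draw())


def _session_truth(meta: SubjectMeta, session: Session, cfg: EffectConfig,
                   rng: np.random.Generator, effects: SubjectEffects):
    """Draw the generative truth for one session from ``rng``."""
    sd = cfg.session_jitter_sd
    jit = lambda: float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0
    cell = f"{meta.genotype},{meta.sex}"
    if cell not in cfg.baseline_gamma_gain:
        raise ConfigurationError(f"baseline_gamma_gain missing cell {cell!r}")
    dose = session.dose
    base_gain = cfg.baseline_gamma_gain[cell] * effects.baseline * jit()
    evoked_gain = cfg.evoked_gain[dose] * effects.evoked * jit()
    induced_gain = cfg.induced_gain[dose] * effects.induced * jit()
    erp_mult = cfg.erp_gain[dose] * effects.erp
    artifacts = np.flatnonzero(rng.random(cfg.n_stim) < cfg.artifact_rate)
    row = {
        "subject_id": meta.subject_id,
        "genotype": meta.genotype,
        "sex": meta.sex,
        "dose": dose,
        "session_index": session.session_index,
        "baseline_gamma_power": cfg.ongoing_gamma_sd ** 2 * base_gain,
        "evoked_energy": cfg.evoked_burst_amp ** 2 * evoked_gain,
        "induced_energy": cfg.induced_burst_amp ** 2 * induced_gain,
        "p20_amp": cfg.p20_amp * erp_mult,
        "p20_lat_ms": cfg.p20_center_ms,
        "n40_amp": cfg.n40_amp * erp_mult,
        "n40_lat_ms": cfg.n40_center_ms,
        "n_artifact_sweeps": artifacts.size,
    }
    return row, artifacts, {"base_gain": base_gain, "evoked_gain": evoked_gain,
                            "induced_gain": induced_gain, "erp_mult": erp_mult}


def draw_session_truth(meta: SubjectMeta, session: Session, cfg: EffectConfig,
                       seed: int, effects: SubjectEffects | None = None) -> GroundTruth:
    """Ground truth only, without synthesizing the voltage trace.

    Used for cheap Monte-Carlo studies of the behavior coupling, where
    only the true component energies matter.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    row, artifacts, _ = _session_truth(meta, session, cfg, rng, effects or SubjectEffects())
    return GroundTruth(pd.DataFrame([row]), {(meta.subject_id, session.dose): artifacts})


# ---------------------------------------------------------------------------
# signal synthesis

def generate_recording(meta: SubjectMeta, session: Session, cfg: EffectConfig,
                       seed: int, effects: SubjectEffects | None = None
                       ) -> tuple[Recording, GroundTruth]:
    """Synthesize one session: baseline segment then ``n_stim`` stimuli.

    Deterministic given ``seed`` (and the subject-level ``effects``).
    """
    cfg.validate()
    effects = effects or SubjectEffects()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    row, artifact_idx, gains = _session_truth(meta, session, cfg, rng, effects)

    fs = cfg.fs
    n_base = int(round(cfg.baseline_s * fs))
    isi_n = int(round(cfg.isi_s * fs))
    n = n_base + cfg.n_stim * isi_n
    events = cfg.baseline_s + np.arange(cfg.n_stim) * cfg.isi_s

    x = pink_noise(n, rng, cfg.pink_sd, cfg.pink_alpha)
    x += band_noise(n, fs, cfg.gamma_band, rng,
                    cfg.ongoing_gamma_sd * np.sqrt(gains["base_gain"]))

    amp_ev = cfg.evoked_burst_amp * np.sqrt(gains["evoked_gain"])
    amp_in = cfg.induced_burst_amp * np.sqrt(gains["induced_gain"])
    bg_rms = np.sqrt(cfg.pink_sd ** 2
                     + cfg.ongoing_gamma_sd ** 2 * gains["base_gain"])
    art_amp = cfg.artifact_amp_mult * bg_rms
    art_set = set(int(i) for i in artifact_idx)

    # per-sweep local time axis covering the full ISI after each stimulus
    t_loc = np.arange(isi_n) / fs
    kernel = (
        gabor(t_loc, cfg.p20_center_ms / 1e3, cfg.p20_sigma_ms / 1e3, 0.0,
              row["p20_amp"])
        + gabor(t_loc, cfg.n40_center_ms / 1e3, cfg.n40_sigma_ms / 1e3, 0.0,
                row["n40_amp"])
        + gabor(t_loc, cfg.burst_center_ms / 1e3, cfg.burst_sigma_ms / 1e3,
                cfg.burst_freq, amp_ev, phase=0.0)
    )
    for k in range(cfg.n_stim):
        start = n_base + k * isi_n
        sweep = kernel.copy()
        if amp_in != 0:
            sweep += gabor(t_loc, cfg.burst_center_ms / 1e3,
                           cfg.burst_sigma_ms / 1e3, cfg.burst_freq, amp_in,
                           phase=float(rng.uniform(0, 2 * np.pi)))
        if k in art_set:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            sweep += gabor(t_loc, cfg.artifact_center_ms / 1e3,
                           cfg.artifact_sigma_s, 10.0, sign * art_amp)
        x[start : start + isi_n] += sweep

    rec = Recording(x, fs, events, meta, session)
    truth = GroundTruth(pd.DataFrame([row]),
                        {(meta.subject_id, session.dose): artifact_idx})
    return rec, truth


# ---------------------------------------------------------------------------
# behavior

def generate_behavior(truth: GroundTruth, cfg: EffectConfig, seed: int) -> tuple[CohortTable, pd.DataFrame]:
    """Behavioral scores per subject-session, coupled to Δ evoked energy.

    %alternation = base + genotype/dose offsets
                   + coupling · (−standardized Δ true evoked energy)
                   + Gaussian noise, clipped to [0, 100].
    Δ is relative to the subject's own vehicle session and standardized
    across the cohort within each dose.  Also emits %center-time,
    %social and water-maze latency with configurable genotype offsets.

    Returns the (noisy, clipped) behavior table and a pre-noise truth
    frame with the deterministic part of each score.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tab = truth.table.sort_values(["subject_id", "dose"]).reset_index(drop=True)
    piv = tab.pivot(index="subject_id", columns="dose", values="evoked_energy")
    if "vehicle" not in piv.columns or piv["vehicle"].isna().any():
        missing = (piv.index[piv["vehicle"].isna()].tolist()
                   if "vehicle" in piv.columns else piv.index.tolist())
        raise PairingError(f"subjects missing a vehicle session: {missing}")

    zscores = pd.DataFrame(0.0, index=piv.index, columns=piv.columns)
    for dose in piv.columns:
        if dose == "vehicle":
            continue
        delta = (piv[dose] - piv["vehicle"]).dropna()
        sdev = delta.std(ddof=0)
        z = (delta - delta.mean()) / sdev if sdev > 0 else delta * 0.0
        zscores.loc[z.index, dose] = z

    meta_cols = tab.groupby("subject_id")[["genotype", "sex"]].first()
    rows, truth_rows = [], []
    for sid in sorted(piv.index):
        geno = meta_cols.loc[sid, "genotype"]
        ko = 1.0 if geno == "KO" else 0.0
        for dose in [d for d in DOSES if d in piv.columns]:
            if pd.isna(piv.loc[sid, dose]):
                continue
            z = float(zscores.loc[sid, dose])
            alt_true = (cfg.alt_base_pct + ko * cfg.alt_ko_offset
                        + cfg.alt_dose_offset[dose] + cfg.behavior_coupling * (-z))
            ct_true = (cfg.center_base_pct + ko * cfg.center_ko_offset
                       + cfg.center_dose_offset[dose])
            so_true = (cfg.social_base_pct + ko * cfg.social_ko_offset
                       + cfg.social_dose_offset[dose])
            lat_log_true = cfg.latency_log_base + ko * cfg.latency_ko_log_offset
            alt = alt_true + rng.normal(0.0, cfg.behavior_noise_sd) if cfg.behavior_noise_sd > 0 else alt_true
            ct = ct_true + rng.normal(0.0, cfg.center_noise_sd) if cfg.center_noise_sd > 0 else ct_true
            so = so_true + rng.normal(0.0, cfg.social_noise_sd) if cfg.social_noise_sd > 0 else so_true
            lat = np.exp(lat_log_true + (rng.normal(0.0, cfg.latency_log_sd)
                                         if cfg.latency_log_sd > 0 else 0.0))
            rows.append({
                "subject_id": sid, "genotype": geno,
                "sex": meta_cols.loc[sid, "sex"], "dose": dose,
                "tmaze_pct": float(np.clip(alt, 0.0, 100.0)),
                "center_time_pct": float(np.clip(ct, 0.1, 100.0)),
                "social_pct": float(np.clip(so, 0.0, 100.0)),
                "wm_latency_s": float(lat),
            })
            truth_rows.append({"subject_id": sid, "dose": dose,
                               "tmaze_true_pct": alt_true,
                               "delta_evoked_z": z})
    return CohortTable(pd.DataFrame(rows)), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# cohort assembly

def _derive_seed(*key) -> int:
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2 ** 31))


def cohort_subjects(cfg: EffectConfig) -> list[SubjectMeta]:
    return [
        SubjectMeta(f"{geno}-{sex}-{i:03d}", geno, sex)
        for geno in GENOTYPES for sex in SEXES for i in range(cfg.n_per_cell)
    ]


def generate_cohort(cfg: EffectConfig
                    ) -> tuple[list[Recording], CohortTable, GroundTruth]:
    """Full crossed design: genotype × sex × 4 doses for every subject.

    All randomness derives deterministically from ``cfg.rng_seed``,
    subject index and session index, so identical configs give
    byte-identical cohorts.
    """
    cfg.validate()
    subjects = cohort_subjects(cfg)
    recordings: list[Recording] = []
    truths: list[GroundTruth] = []
    for si, meta in enumerate(subjects):
        eff_rng = np.random.default_rng(
            np.random.SeedSequence((cfg.rng_seed, 99_000_000, si)))
        effects = draw_subject_effects(cfg, eff_rng)
        for di, dose in enumerate(DOSES):
            session = Session(dose=dose, session_index=di)
            seed = _derive_seed((cfg.rng_seed, si, di))
            rec, tr = generate_recording(meta, session, cfg, seed, effects)
            recordings.append(rec)
            truths.append(tr)
    truth = GroundTruth.concat(truths)
    behavior, behav_truth = generate_behavior(
        truth, cfg, _derive_seed((cfg.rng_seed, 77_000_000)))
    truth.table = truth.table.merge(behav_truth, on=["subject_id", "dose"], how="left")
    return recordings, behavior, truth


def generate_truth_cohort(cfg: EffectConfig) -> GroundTruth:
    """Ground truth for a whole cohort without synthesizing any signal."""
    cfg.validate()
    parts = []
    for si, meta in enumerate(cohort_subjects(cfg)):
        eff_rng = np.random.default_rng(
            np.random.SeedSequence((cfg.rng_seed, 99_000_000, si)))
        effects = draw_subject_effects(cfg, eff_rng)
        for di, dose in enumerate(DOSES):
            session = Session(dose=dose, session_index=di)
            seed = _derive_seed((cfg.rng_seed, si, di))
            parts.append(draw_session_truth(meta, session, cfg, seed, effects))
    return GroundTruth.concat(parts)
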