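"""End-to-end orchestration: simulate → preprocess → erp → spectra →
stats → responders, with plain-file intermediates and a run manifest.

Every stage reads its inputs from, and writes its outputs to, an output
directory, so any stage can be re-run individually and every
intermediate is inspectable (CSV / NPZ / JSON).  The run is
deterministic given the config: re-running changes no CSV or JSON
output contents.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, dump_config, load_config
from .erp import erp_features
from .io import read_cohort_table, read_recording, write_cohort_table, write_recording
from .preprocess import preprocess_recording
from .responders import compute_deltas, responder_contrast
from .spectral import spectral_summary
from .stats import lsd_posthoc, maybe_log_transform, rm_anova, factorial_anova
from .synth import generate_cohort
from .types import CohortTable, EpochSet, Session, SubjectMeta

log = logging.getLogger(__name__)

_REC_DIR = "recordings"
_EPOCH_DIR = "epochs"


def _session_tag(sid: str, dose: str) -> str:
    return f"{sid}_{dose.replace('.', 'p')}"


def _json_dump(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    recs, behavior, truth = generate_cohort(cfg.synth)
    rec_dir = out / _REC_DIR
    paths = []
    for rec in recs:
        tag = _session_tag(rec.meta.subject_id, rec.session.dose)
        path = rec_dir / (tag + (".edf" if cfg.recording_format == "edf" else ""))
        write_recording(rec, path, cfg.recording_format)
        paths.append(str(path.relative_to(out)))
    write_cohort_table(behavior, out / "behavior.csv")
    tt = truth.table.copy()
    tt.to_csv(out / "ground_truth.csv", index=False)
    return {"n_recordings": len(recs),
            "n_subjects": len({r.meta.subject_id for r in recs}),
            "recordings": paths,
            "outputs": ["behavior.csv", "ground_truth.csv"]}


def _iter_recordings(cfg: PipelineConfig, out: Path):
    rec_dir = out / _REC_DIR
    entries = sorted(rec_dir.glob("*.edf")) if cfg.recording_format == "edf" else \
        sorted(p for p in rec_dir.iterdir() if p.is_dir())
    if not entries:
        raise FileNotFoundError(f"no recordings under {rec_dir}; run simulate first")
    for path in entries:
        yield read_recording(path, cfg.recording_format)


def stage_preprocess(cfg: PipelineConfig, out: Path) -> dict:
    ep_dir = out / _EPOCH_DIR
    ep_dir.mkdir(parents=True, exist_ok=True)
    reports = []
    kept = rejected = 0
    for rec in _iter_recordings(cfg, out):
        ep, report, _ = preprocess_recording(rec, cfg.filter, cfg.epoch)
        tag = _session_tag(rec.meta.subject_id, rec.session.dose)
        np.savez(ep_dir / f"{tag}.npz", data=ep.data, t=ep.t, fs=ep.fs,
                 kept=ep.kept, subject_id=rec.meta.subject_id,
                 genotype=rec.meta.genotype, sex=rec.meta.sex,
                 dose=rec.session.dose, session_index=rec.session.session_index)
        frame = report.to_frame()
        frame.insert(0, "subject_id", rec.meta.subject_id)
        frame.insert(1, "dose", rec.session.dose)
        reports.append(frame)
        kept += ep.n_kept
        rejected += report.n_rejected
    rej = pd.concat(reports, ignore_index=True)
    rej.to_csv(out / "rejection.csv", index=False)
    return {"n_sessions": len(reports), "sweeps_kept": int(kept),
            "sweeps_rejected": int(rejected),
            "outputs": ["rejection.csv", _EPOCH_DIR]}


def load_epochs(path: Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        meta = SubjectMeta(str(z["subject_id"]), str(z["genotype"]), str(z["sex"]))
        session = Session(str(z["dose"]), int(z["session_index"]))
        return EpochSet(z["data"], z["t"], float(z["fs"]), z["kept"], meta, session)


def _iter_epochs(out: Path):
    ep_dir = out / _EPOCH_DIR
    files = sorted(ep_dir.glob("*.npz"))
    if not files:
        raise FileNotFoundError(f"no epochs under {ep_dir}; run preprocess first")
    for f in files:
        yield load_epochs(f)


def stage_erp(cfg: PipelineConfig, out: Path) -> dict:
    rows = []
    for ep in _iter_epochs(out):
        feats = erp_features(ep)
        rows.append({"subject_id": ep.meta.subject_id, "genotype": ep.meta.genotype,
                     "sex": ep.meta.sex, "dose": ep.session.dose,
                     "p20_amp": feats.p20_amp, "p20_lat_ms": feats.p20_lat_ms,
                     "n40_amp": feats.n40_amp, "n40_lat_ms": feats.n40_lat_ms,
                     "n_sweeps_used": feats.n_sweeps_used})
    table = CohortTable(pd.DataFrame(rows))
    write_cohort_table(table, out / "erp.csv")
    return {"n_sessions": len(rows), "outputs": ["erp.csv"]}


def stage_spectra(cfg: PipelineConfig, out: Path) -> dict:
    from .preprocess import bandpass
    epochs = {( ep.meta.subject_id, ep.session.dose): ep for ep in _iter_epochs(out)}
    rows = []
    for rec in _iter_recordings(cfg, out):
        key = (rec.meta.subject_id, rec.session.dose)
        ep = epochs.get(key)
        if ep is None:
            raise FileNotFoundError(f"no epochs for session {key}")
        summ = spectral_summary(bandpass(rec, cfg.filter), ep, cfg.bands)
        rows.append({"subject_id": rec.meta.subject_id, "genotype": rec.meta.genotype,
                     "sex": rec.meta.sex, "dose": rec.session.dose,
                     **dataclasses.asdict(summ)})
    table = CohortTable(pd.DataFrame(rows))
    write_cohort_table(table, out / "spectral.csv")
    return {"n_sessions": len(rows), "outputs": ["spectral.csv"]}


def build_cohort_table(out: Path) -> CohortTable:
    """Join ERP, spectral and behavioral measures on (subject, dose)."""
    table = None
    for name in ("erp.csv", "spectral.csv", "behavior.csv"):
        path = out / name
        if not path.exists():
            continue
        part = read_cohort_table(path)
        table = part if table is None else table.merge(part)
    if table is None:
        raise FileNotFoundError(f"no stage outputs under {out}")
    return table


def stage_stats(cfg: PipelineConfig, out: Path) -> dict:
    table = build_cohort_table(out)
    write_cohort_table(table, out / "cohort.csv")
    results = {}
    for measure in cfg.stats.measures:
        if measure not in table.measures:
            log.warning("stats: measure %r absent from cohort table; skipped", measure)
            continue
        df = table.df.dropna(subset=[measure]).copy()
        transformed, applied = maybe_log_transform(
            df[measure].to_numpy(), measure, log_measures=cfg.stats.log_measures)
        df[measure] = transformed
        entry = {"log_transformed": bool(applied)}
        try:
            veh = factorial_anova(df, measure, dose="vehicle")
            entry["vehicle_factorial"] = veh.to_dict()
        except ValueError as err:
            entry["vehicle_factorial"] = {"error": str(err)}
        try:
            mixed = rm_anova(df, measure)
            entry["mixed_rm"] = mixed.to_dict()
            dose_eff = mixed.effects.get("dose")
            if dose_eff is not None and dose_eff.p < 0.05:
                ph = lsd_posthoc(mixed, "dose", reference="vehicle")
                entry["lsd_dose_vs_vehicle"] = ph.pairs.to_dict(orient="records")
        except ValueError as err:
            entry["mixed_rm"] = {"error": str(err)}
        results[measure] = entry
    _json_dump(results, out / "anova.json")
    return {"n_measures": len(results), "outputs": ["cohort.csv", "anova.json"]}


def stage_responders(cfg: PipelineConfig, out: Path) -> dict:
    table = read_cohort_table(out / "cohort.csv") if (out / "cohort.csv").exists() \
        else build_cohort_table(out)
    deltas = compute_deltas(table, dose=cfg.responders.dose)
    report = {}
    for measure in cfg.responders.measures:
        if f"delta_{measure}" not in deltas.columns:
            log.warning("responders: measure %r unavailable; skipped", measure)
            continue
        contrasts = responder_contrast(deltas, measure, cfg.responders.outcome)
        report[measure] = {k: v.to_dict() for k, v in contrasts.items()}
    deltas.to_csv(out / "deltas.csv", index=False)
    _json_dump(report, out / "responders.json")
    return {"n_subjects": len(deltas), "outputs": ["deltas.csv", "responders.json"]}


_STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "erp": stage_erp,
    "spectra": stage_spectra,
    "stats": stage_stats,
    "responders": stage_responders,
}


def run_stage(name: str, cfg: PipelineConfig, out_dir) -> dict:
    out = Path(out_dir)
    try:
        return _STAGES[name](cfg, out)
    except Exception as err:
        raise RuntimeError(f"stage {name!r} failed: {err}") from err


def run_all(config, out_dir) -> dict:
    """Run every stage and write ``manifest.json``; returns the manifest."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canonical = dump_config(cfg)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "rng_seed": cfg.synth.rng_seed,
        "stages": {},
    }
    for name in _STAGES:
        log.info("running stage %s", name)
        manifest["stages"][name] = run_stage(name, cfg, out)
    (out / "config.yaml").write_text(canonical)
    _json_dump(manifest, out / "manifest.json")
    return manifest
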