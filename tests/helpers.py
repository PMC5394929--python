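"""Shared test utilities and independent oracles.

The mixed-ANOVA oracle computes the classical balanced-design sums of
squares directly from marginal means — no least squares, no shared code
with the implementation under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fxs_oscillo import Recording, Session, SubjectMeta
from fxs_oscillo.types import EpochSet

META = SubjectMeta("m-000", "WT", "M")
VEH = Session("vehicle", 0)


def make_recording(samples, fs=1000.0, events=(), meta=META, session=VEH) -> Recording:
    return Recording(np.asarray(samples, float), fs, np.asarray(events, float),
                     meta, session)


def sine_recording(freq=40.0, amp=10.0, fs=2000.0, dur=10.0) -> Recording:
    t = np.arange(int(dur * fs)) / fs
    return make_recording(amp * np.sin(2 * np.pi * freq * t), fs)


def make_epochs(data, fs=1000.0, pre_s=-0.25, kept=None,
                meta=META, session=VEH) -> EpochSet:
    data = np.atleast_2d(np.asarray(data, float))
    t = pre_s + np.arange(data.shape[1]) / fs
    if kept is None:
        kept = np.ones(data.shape[0], bool)
    return EpochSet(data, t, fs, kept, meta, session)


def random_mixed_table(rng, n_per_cell=2, k=4, effects=None) -> pd.DataFrame:
    """Balanced genotype × sex × dose long table with random normal data."""
    effects = effects or {}
    doses = ["vehicle", "1.0", "2.5", "5.0"][:k]
    rows = []
    for g in ("WT", "KO"):
        for s in ("F", "M"):
            for i in range(n_per_cell):
                sid = f"{g}-{s}-{i}"
                u = rng.normal(0, effects.get("subject_sd", 1.0))
                for di, d in enumerate(doses):
                    y = (u + rng.normal()
                         + effects.get("genotype", 0.0) * (g == "KO")
                         + effects.get("sex", 0.0) * (s == "M")
                         + effects.get("dose", 0.0) * di
                         + effects.get("dose_genotype", 0.0) * di * (g == "KO"))
                    rows.append({"subject_id": sid, "genotype": g, "sex": s,
                                 "dose": d, "y": y})
    return pd.DataFrame(rows)


def brute_mixed_anova(df: pd.DataFrame, value: str = "y") -> dict:
    """Classical balanced mixed-design SS partition from marginal means.

    Requires a fully balanced design (equal subjects per genotype × sex
    cell, every subject at every dose).  Returns F statistics per
    effect, keyed like the implementation's AnovaResult.
    """
    k = df["dose"].nunique()
    subj = (df.groupby(["subject_id", "genotype", "sex"])[value]
            .mean().reset_index().rename(columns={value: "m"}))
    N = len(subj)
    gm = df[value].mean()
    mg = subj.groupby("genotype")["m"].mean()
    ms = subj.groupby("sex")["m"].mean()
    mcell = subj.groupby(["genotype", "sex"])["m"].mean()

    sm = subj["m"].to_numpy()
    g_of = subj["genotype"].to_numpy()
    s_of = subj["sex"].to_numpy()
    cell_of = list(zip(g_of, s_of))
    ss_geno = k * float(np.sum((mg[g_of].to_numpy() - gm) ** 2))
    ss_sex = k * float(np.sum((ms[s_of].to_numpy() - gm) ** 2))
    mcell_i = np.array([mcell[c] for c in cell_of])
    ss_gs = k * float(np.sum((mcell_i - mg[g_of].to_numpy()
                              - ms[s_of].to_numpy() + gm) ** 2))
    ss_err_b = k * float(np.sum((sm - mcell_i) ** 2))
    df_err_b = N - 4

    yd = df.groupby("dose")[value].mean()
    ydg = df.groupby(["dose", "genotype"])[value].mean()
    yds = df.groupby(["dose", "sex"])[value].mean()
    ydgs = df.groupby(["dose", "genotype", "sex"])[value].mean()
    ss_dose = N * float(((yd - gm) ** 2).sum())
    n_g = N / 2  # balanced 2 x 2
    n_cell = N / 4
    ss_dg = ss_ds = ss_dgs = 0.0
    for d in yd.index:
        for g in mg.index:
            ss_dg += n_g * (ydg[(d, g)] - yd[d] - mg[g] + gm) ** 2
        for s in ms.index:
            ss_ds += n_g * (yds[(d, s)] - yd[d] - ms[s] + gm) ** 2
        for g in mg.index:
            for s in ms.index:
                ss_dgs += n_cell * (ydgs[(d, g, s)] - ydg[(d, g)] - yds[(d, s)]
                                    - mcell[(g, s)] + yd[d] + mg[g] + ms[s] - gm) ** 2
    # dose × subject(group) residual
    merged = df.merge(subj[["subject_id", "m"]], on="subject_id")
    cell_dose = (df.groupby(["genotype", "sex", "dose"])[value].mean()
                 .rename("cd").reset_index())
    merged = merged.merge(cell_dose, on=["genotype", "sex", "dose"])
    mcell_col = merged.apply(lambda r: mcell[(r["genotype"], r["sex"])], axis=1)
    resid = merged[value] - merged["m"] - merged["cd"] + mcell_col
    ss_err_w = float((resid ** 2).sum())
    df_err_w = (N - 4) * (k - 1)

    ms_b = ss_err_b / df_err_b
    ms_w = ss_err_w / df_err_w
    out = {
        "genotype": ss_geno / 1 / ms_b,
        "sex": ss_sex / 1 / ms_b,
        "genotype:sex": ss_gs / 1 / ms_b,
    }
    if k > 1:
        out.update({
            "dose": (ss_dose / (k - 1)) / ms_w,
            "dose:genotype": (ss_dg / (k - 1)) / ms_w,
            "dose:sex": (ss_ds / (k - 1)) / ms_w,
            "dose:genotype:sex": (ss_dgs / (k - 1)) / ms_w,
        })
    return out
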