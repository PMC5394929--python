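"""Within-subject drug-response analysis.

For each subject with both a vehicle and a target-dose (default
2.5 mg/kg) session, Δ measures are dose − vehicle.  A subject is a
*responder* for a measure when that Δ is strictly negative (the
measure decreased with the drug); Δ = 0 counts as nonresponder.  The
responder/nonresponder contrast on a behavioral outcome uses a
pooled-variance t-test plus the Pearson correlation between the Δ
measure and the outcome, overall and within genotype strata.  The same
machinery applies to any (Δ measure, outcome) pair, so null checks on
other measures are one-liners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import pearson, two_sample_t
from .types import CohortTable, PairingError, UndefinedValueError, ValidationError

log = logging.getLogger(__name__)


def compute_deltas(table: CohortTable, dose: str = "2.5",
                   measures: list[str] | None = None) -> pd.DataFrame:
    """Per-subject ``delta_<measure>`` = value(dose) − value(vehicle).

    Subjects missing either session are excluded with a logged count.
    Returns a frame indexed by subject with genotype/sex columns.
    """
    df = table.df
    measures = measures or [m for m in table.measures]
    have = df.groupby("subject_id")["dose"].agg(set)
    keep = have[have.apply(lambda s: {"vehicle", dose} <= s)].index
    excluded = sorted(set(df["subject_id"]) - set(keep))
    if excluded:
        log.info("compute_deltas: excluded %d subjects missing vehicle or %s: %s",
                 len(excluded), dose, excluded[:10])
    if not len(keep):
        raise PairingError(f"no subject has both vehicle and {dose} sessions")
    sub = df[df["subject_id"].isin(keep)]
    meta = sub.groupby("subject_id")[["genotype", "sex"]].first()
    out = meta.copy()
    for m in measures:
        piv = sub.pivot(index="subject_id", columns="dose", values=m)
        out[f"delta_{m}"] = piv[dose] - piv["vehicle"]
    return out.reset_index()


def classify_responders(deltas: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Flag responders: Δ strictly < 0; Δ = 0 → nonresponder.

    Adds a boolean ``responder_<measure>`` column; rows with undefined
    Δ get NA.
    """
    col = f"delta_{measure}"
    if col not in deltas.columns:
        raise ValidationError(f"deltas frame has no column {col!r}")
    out = deltas.copy()
    flag = out[col] < 0
    flag = flag.mask(out[col].isna())
    out[f"responder_{measure}"] = flag
    return out


@dataclass(frozen=True)
class StratumContrast:
    estimable: bool
    n_responders: int = 0
    n_nonresponders: int = 0
    mean_responders: float = np.nan
    mean_nonresponders: float = np.nan
    t: float = np.nan
    df: int = 0
    p: float = np.nan
    r: float = np.nan
    r_p: float = np.nan
    note: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def responder_contrast(deltas: pd.DataFrame, measure: str,
                       outcome: str = "tmaze_pct",
                       strata: tuple[str, ...] = ("all", "WT", "KO")
                       ) -> dict[str, StratumContrast]:
    """Responder vs nonresponder contrast on a Δ outcome, per stratum.

    Each stratum reports the pooled two-sample t (responders first) on
    ``delta_<outcome>`` and the Pearson correlation between
    ``delta_<measure>`` and ``delta_<outcome>``.  A stratum with an
    empty or degenerate group is reported as not estimable rather than
    raising, so other strata still run.
    """
    flagged = classify_responders(deltas, measure)
    out_col, d_col, flag_col = f"delta_{outcome}", f"delta_{measure}", f"responder_{measure}"
    if out_col not in flagged.columns:
        raise ValidationError(f"deltas frame has no outcome column {out_col!r}")
    results = {}
    for stratum in strata:
        sub = flagged if stratum == "all" else flagged[flagged["genotype"] == stratum]
        sub = sub.dropna(subset=[out_col, d_col, flag_col])
        resp = sub.loc[sub[flag_col].astype(bool), out_col].to_numpy(float)
        non = sub.loc[~sub[flag_col].astype(bool), out_col].to_numpy(float)
        if resp.size < 2 or non.size < 2:
            results[stratum] = StratumContrast(
                estimable=False, n_responders=resp.size, n_nonresponders=non.size,
                note="fewer than 2 records in a responder group")
            continue
        tt = two_sample_t(resp, non, pooled=True)
        try:
            pr = pearson(sub[d_col], sub[out_col])
            r, r_p = pr.r, pr.p
        except UndefinedValueError:
            r, r_p = np.nan, np.nan
        results[stratum] = StratumContrast(
            estimable=True, n_responders=resp.size, n_nonresponders=non.size,
            mean_responders=float(resp.mean()), mean_nonresponders=float(non.mean()),
            t=tt.t, df=tt.df, p=tt.p, r=r, r_p=r_p)
    return results
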