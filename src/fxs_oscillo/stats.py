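"""Cohort statistics: transforms, factorial and mixed repeated-measures
ANOVA, LSD post hocs, Pearson correlations and pooled t-tests.

The ANOVA is the classical univariate mixed-design decomposition:
between-subject effects (genotype, sex and their interaction) are
tested against the subject-within-group mean square, within-subject
effects (dose and its interactions) against the dose × subject
residual.  No sphericity correction is applied and LSD post hocs are
unadjusted — matching the reporting conventions this pipeline targets;
sums of squares are Type II, computed by least-squares model
comparisons so mildly unbalanced cells are handled.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .types import (
    CohortTable,
    DOSES,
    UndefinedValueError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: measures that are always log10-transformed (markedly skewed scores)
PREREGISTERED_LOG = ("center_time_pct", "wm_latency_s")

_EPS = 1e-12


# ---------------------------------------------------------------------------
# transform

def maybe_log_transform(values, measure: str | None = None,
                        skew_bounds: tuple[float, float] = (-1.0, 1.0),
                        log_measures=PREREGISTERED_LOG) -> tuple[np.ndarray, bool]:
    """log10-transform a measure when its sample skewness leaves ``skew_bounds``
    or the measure is pre-registered as transformed.

    Skewness is the adjusted Fisher-Pearson coefficient.  Returns the
    (possibly transformed) values and whether the transform was applied.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    apply = measure is not None and measure in log_measures
    if not apply and x.size >= 3:
        skew = float(sstats.skew(x, bias=False))
        apply = not (skew_bounds[0] <= skew <= skew_bounds[1])
    if not apply:
        return x, False
    if np.any(x <= 0):
        raise ValidationError(
            f"cannot log-transform {measure or 'measure'}: non-positive values present"
        )
    return np.log10(x), True


# ---------------------------------------------------------------------------
# least-squares machinery (Type II sums of squares)

def _levels(df: pd.DataFrame, factor: str) -> list:
    vals = df[factor].unique().tolist()
    if factor == "dose":
        return [d for d in DOSES if d in vals]
    return sorted(vals)


def _dummies(df: pd.DataFrame, factor: str) -> np.ndarray:
    levels = _levels(df, factor)
    cols = [(df[factor] == lev).to_numpy(float) for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def _term_matrix(df: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    mats = [_dummies(df, f) for f in term]
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ni,nj->nij", out, m).reshape(len(df), -1)
    return out


def _design(df: pd.DataFrame, terms) -> np.ndarray:
    blocks = [np.ones((len(df), 1))]
    blocks += [_term_matrix(df, t) for t in terms]
    return np.hstack(blocks)


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _type2_ss(df: pd.DataFrame, y: np.ndarray, terms: list[tuple],
              target_terms: list[tuple]) -> dict[tuple, float]:
    """Type II SS per target term: drop the term and all its relatives."""
    out = {}
    for term in target_terms:
        relatives = [t for t in terms if set(term) < set(t)]
        base = [t for t in terms if t != term and t not in relatives]
        out[term] = _sse(_design(df, base), y) - _sse(_design(df, base + [term]), y)
    return out


def _df_num(df: pd.DataFrame, term: tuple[str, ...]) -> int:
    n = 1
    for f in term:
        n *= len(_levels(df, f)) - 1
    return n


# ---------------------------------------------------------------------------
# results containers

@dataclass(frozen=True)
class EffectStat:
    name: str
    ss: float
    df_num: int
    df_den: int
    F: float
    p: float
    stratum: str  # "between" | "within"


@dataclass
class AnovaResult:
    """Per-effect F tests plus the error strata needed for LSD post hocs."""

    effects: dict = field(default_factory=dict)
    strata: dict = field(default_factory=dict)  # name -> {"ss","df","ms"}
    design: dict = field(default_factory=dict)
    frame: pd.DataFrame | None = None  # long data actually analyzed
    subject_means: pd.DataFrame | None = None

    def __getitem__(self, name: str) -> EffectStat:
        return self.effects[name]

    def to_dict(self) -> dict:
        return {
            "effects": {
                k: {"ss": e.ss, "df_num": e.df_num, "df_den": e.df_den,
                    "F": e.F, "p": e.p, "stratum": e.stratum}
                for k, e in self.effects.items()
            },
            "strata": self.strata,
            "design": {k: v for k, v in self.design.items()
                       if isinstance(v, (int, float, str, list, tuple))},
        }


def _effect(name, ss, df_num, err_ss, err_df, stratum) -> EffectStat:
    ms_err = err_ss / err_df if err_df > 0 else np.nan
    scale = max(abs(ss), abs(err_ss), 1.0)
    if ss <= _EPS * scale and err_ss <= _EPS * scale:
        F, p = 0.0, 1.0  # degenerate: no variation at all
    elif err_ss <= _EPS * scale:
        F, p = np.inf, 0.0
    else:
        F = (ss / df_num) / ms_err
        F = max(F, 0.0)
        p = float(sstats.f.sf(F, df_num, err_df))
    return EffectStat(name, float(ss), int(df_num), int(err_df), float(F), p, stratum)


def _term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


# ---------------------------------------------------------------------------
# factorial (between-subjects) ANOVA

def factorial_anova(table: CohortTable | pd.DataFrame, measure: str,
                    dose: str | None = "vehicle",
                    factors: tuple[str, ...] = ("genotype", "sex")) -> AnovaResult:
    """Two-way (or n-way) between-subjects ANOVA at a single dose.

    One observation per subject; Type II sums of squares; error df is
    N minus the number of cells.
    """
    df = table.df if isinstance(table, CohortTable) else table
    if dose is not None:
        df = df[df["dose"] == dose]
    df = df.dropna(subset=[measure]).reset_index(drop=True)
    if not len(df):
        raise ValidationError(f"no observations for measure {measure!r}")
    level_sets = [_levels(df, f) for f in factors]
    n_cells = int(np.prod([len(ls) for ls in level_sets]))
    counts = df.groupby(list(factors), observed=True).size()
    if len(counts) < n_cells or (counts < 1).any():
        raise ValidationError("factorial ANOVA requires >= 1 observation per cell")

    y = df[measure].to_numpy(float)
    terms = [t for r in range(1, len(factors) + 1)
             for t in itertools.combinations(factors, r)]
    ss = _type2_ss(df, y, terms, terms)
    err_ss = _sse(_design(df, terms), y)
    err_df = len(df) - n_cells

    res = AnovaResult(frame=df)
    res.strata["between"] = {"ss": err_ss, "df": err_df,
                             "ms": err_ss / err_df if err_df else np.nan}
    for term in terms:
        res.effects[_term_name(term)] = _effect(
            _term_name(term), ss[term], _df_num(df, term), err_ss, err_df, "between")
    res.design = {"kind": "factorial", "factors": list(factors), "n": len(df),
                  "within": None, "k": 1, "measure": measure}
    return res


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA

def rm_anova(table: CohortTable | pd.DataFrame, measure: str,
             between: tuple[str, ...] = ("genotype", "sex"),
             within: str = "dose") -> AnovaResult:
    """Mixed-design univariate ANOVA: between factors × a within factor.

    Subjects missing any within level are listed and dropped
    (complete-case).  Between effects are tested against the
    subject-within-group stratum (df = N − cells); within effects
    against the dose × subject residual (df = (N − cells)(k − 1)).
    No sphericity correction.
    """
    df = table.df if isinstance(table, CohortTable) else table
    df = df.dropna(subset=[measure])
    levels_w = _levels(df, within)
    k = len(levels_w)
    per_subj = df.groupby("subject_id")[within].nunique()
    complete = per_subj[per_subj == k].index
    dropped = sorted(set(df["subject_id"]) - set(complete))
    if dropped:
        log.warning("rm_anova: dropping %d incomplete subjects: %s",
                    len(dropped), dropped[:10])
    df = df[df["subject_id"].isin(complete)].reset_index(drop=True)
    if not len(df):
        raise ValidationError("no subject has all within-factor levels")

    subj = (df.groupby(["subject_id", *between], observed=True)[measure]
            .mean().reset_index().rename(columns={measure: "subj_mean"}))
    n_subj = len(subj)
    cell_counts = subj.groupby(list(between), observed=True).size()
    level_sets = [_levels(subj, f) for f in between]
    n_cells = int(np.prod([len(ls) for ls in level_sets]))
    if len(cell_counts) < n_cells or (cell_counts < 2).any():
        raise ValidationError("need >= 2 complete subjects per between-group cell")

    # --- between-subject stratum (on subject means; SS reported × k) ---
    terms_b = [t for r in range(1, len(between) + 1)
               for t in itertools.combinations(between, r)]
    y_means = subj["subj_mean"].to_numpy(float)
    ss_b = _type2_ss(subj, y_means, terms_b, terms_b)
    err_b_means = _sse(_design(subj, terms_b), y_means)
    err_b_df = n_subj - n_cells

    res = AnovaResult()
    res.strata["between"] = {"ss": err_b_means * k, "df": err_b_df,
                             "ms": err_b_means * k / err_b_df if err_b_df else np.nan,
                             "ms_means": err_b_means / err_b_df if err_b_df else np.nan}
    for term in terms_b:
        res.effects[_term_name(term)] = _effect(
            _term_name(term), ss_b[term] * k, _df_num(subj, term),
            err_b_means * k, err_b_df, "between")
        # F computed from scaled SS and scaled error: identical to means-scale F

    # --- within-subject stratum (on deviations from subject means) ---
    if k > 1:
        dev = df.merge(subj[["subject_id", "subj_mean"]], on="subject_id")
        dev["_dev"] = dev[measure] - dev["subj_mean"]
        terms_w = [(within,)] + [
            (within, *t) for t in terms_b
        ]
        all_terms = terms_b + terms_w
        y_dev = dev["_dev"].to_numpy(float)
        ss_w = _type2_ss(dev, y_dev, all_terms, terms_w)
        err_w = _sse(_design(dev, all_terms), y_dev)
        err_w_df = (n_subj - n_cells) * (k - 1)
        res.strata["within"] = {"ss": err_w, "df": err_w_df,
                                "ms": err_w / err_w_df if err_w_df else np.nan}
        for term in terms_w:
            res.effects[_term_name(term)] = _effect(
                _term_name(term), ss_w[term], _df_num(dev, term), err_w, err_w_df,
                "within")

    res.design = {"kind": "mixed", "factors": list(between), "within": within,
                  "k": k, "n": n_subj, "measure": measure,
                  "dropped_subjects": dropped}
    res.frame = df
    res.subject_means = subj
    return res


# ---------------------------------------------------------------------------
# LSD post hocs

@dataclass
class PosthocResult:
    factor: str
    pairs: pd.DataFrame  # level_a, level_b, mean_a, mean_b, diff, t, df, p

    def __len__(self) -> int:
        return len(self.pairs)


def lsd_posthoc(anova: AnovaResult, factor: str,
                reference: str | None = None) -> PosthocResult:
    """Fisher LSD pairwise comparisons using the ANOVA error stratum.

    For the within factor the comparison uses the dose × subject
    residual MS; for between factors the subject stratum.  p values
    are unadjusted, per the LSD convention.
    """
    if anova.frame is None:
        raise ValidationError("ANOVA result carries no data frame")
    measure = anova.design["measure"]
    if factor == anova.design.get("within"):
        data = anova.frame
        ycol = measure
        ms = anova.strata["within"]["ms"]
        dferr = anova.strata["within"]["df"]
    elif anova.design["kind"] == "mixed":
        data = anova.subject_means
        ycol = "subj_mean"
        ms = anova.strata["between"]["ms_means"]
        dferr = anova.strata["between"]["df"]
    else:
        data = anova.frame
        ycol = measure
        ms = anova.strata["between"]["ms"]
        dferr = anova.strata["between"]["df"]
    if factor not in data.columns:
        raise ValidationError(f"factor {factor!r} not in the analyzed design")

    levels = _levels(data, factor)
    stats = data.groupby(factor, observed=True)[ycol].agg(["mean", "count"])
    if reference is not None:
        if reference not in levels:
            raise ValidationError(f"reference level {reference!r} absent")
        pair_list = [(reference, l) for l in levels if l != reference]
    else:
        pair_list = list(itertools.combinations(levels, 2))

    rows = []
    for a, b in pair_list:
        ma, mb = stats.loc[a, "mean"], stats.loc[b, "mean"]
        na, nb = stats.loc[a, "count"], stats.loc[b, "count"]
        se = np.sqrt(ms * (1.0 / na + 1.0 / nb))
        diff = ma - mb
        if se > 0:
            t = diff / se
            p = float(2 * sstats.t.sf(abs(t), dferr))
        else:
            t, p = (0.0, 1.0) if abs(diff) <= _EPS else (np.inf, 0.0)
        rows.append({"level_a": a, "level_b": b, "mean_a": ma, "mean_b": mb,
                     "diff": diff, "t": float(t), "df": int(dferr), "p": p})
    return PosthocResult(factor, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# correlations and t-tests

@dataclass(frozen=True)
class PearsonResult:
    r: float
    t: float
    df: int
    p: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Pearson correlation with the exact t-based two-tailed p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise UndefinedValueError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedValueError("Pearson correlation undefined for zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) >= 1.0:
        return PearsonResult(r, np.inf if r > 0 else -np.inf, df, 0.0, n)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = float(2 * sstats.t.sf(abs(t), df))
    return PearsonResult(r, float(t), df, p, n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def two_sample_t(a, b, pooled: bool = True) -> TTestResult:
    """Two-sample t-test; pooled variance gives df = n_a + n_b − 2."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    if pooled:
        df = na + nb - 2
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
        se = np.sqrt(va + vb)
        df = int(np.floor((va + vb) ** 2 /
                          (va ** 2 / (na - 1) + vb ** 2 / (nb - 1)))) if va + vb > 0 else na + nb - 2
    if se == 0:
        t, p = (0.0, 1.0) if abs(diff) <= _EPS else (np.inf * np.sign(diff), 0.0)
    else:
        t = diff / se
        p = float(2 * sstats.t.sf(abs(t), df))
    return TTestResult(float(t), int(df), p, float(a.mean()), float(b.mean()), na, nb)
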