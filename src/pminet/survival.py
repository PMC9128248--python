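"""Survival-factor discovery and patient scoring from CoCNV/CoDM gene pairs.

For every gene pair recalled from the PMI network, patients are grouped by
the pair's joint copy-number status (GG/LL/GL/LG/NC) or split at the median
of one of its CoDM values (HH/LL/LH/HL).  Group pairs large enough
(strictly more than ``min_n`` samples each for CoCNV) are compared with the
log-rank test; significant comparisons become *survival factors*, written
"GG > NC" or "HH-low > HH-high" with the better-surviving side first
(better = larger area under the Kaplan–Meier curve).

Each factor-bearing pair then contributes a per-patient term I_gp in
{-1, 0, +1}: +1 when the patient's status sits only on the better side of
the pair's factors, -1 only on the worse side, 0 for NC or unmentioned
statuses.  The patient Score is the sum of I_gp over pairs; patients are
stratified into three groups by Score, and Cox proportional-hazards models
with clinical covariates (plus 80%-subsample refits) check that the Score
adds information beyond the clinic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalFactor", "FactorConflictError",
    "cocnv_patient_groups", "single_cnv_status_table", "logrank",
    "find_cocnv_factors", "find_codm_factors", "codm_patient_status",
    "i_gp", "score_patients", "divide_by_score",
    "cox_multivariate", "subsample_stability",
]

COCNV_GROUPS = ("GG", "LL", "GL", "LG", "NC")
CODM_VALUES = ("LL", "HH", "LH", "HL")


class FactorConflictError(ValueError):
    """A status appears on both the better and the worse side of one pair's
    factors, so its contribution is ill-defined."""


@dataclass
class SurvivalFactor:
    """A pair-level comparison "better_type > worse_type" that passed the
    log-rank test, e.g. ``GG > NC`` (CoCNV) or ``HH-low > HH-high`` (CoDM)."""

    pair: tuple
    modality: str               # "CoCNV" or "CoDM"
    better_type: str
    worse_type: str
    n_better: int
    n_worse: int
    statistic: float
    pvalue: float

    @property
    def label(self) -> str:
        return f"{self.pair[0]}-{self.pair[1]} {self.better_type} > {self.worse_type}"


def _check_clinical(clinical: pd.DataFrame) -> None:
    if "time" not in clinical.columns or "event" not in clinical.columns:
        raise ValueError("clinical table needs 'time' and 'event' columns")
    if (clinical["time"] < 0).any():
        raise ValueError("negative survival times")
    if not clinical["event"].isin([0, 1]).all():
        raise ValueError("events must be 0/1")


def cocnv_patient_groups(status: pd.Series) -> dict:
    """Partition samples into the 5 CoCNV groups GG/LL/GL/LG/NC.

    ``status`` maps sample -> status string (one pair's per-sample CoCNV
    statuses).  Every group key is present; empty groups map to empty lists.
    """
    groups = {g: [] for g in COCNV_GROUPS}
    for sample, s in status.items():
        if s not in groups:
            raise ValueError(f"unknown CoCNV status {s!r}")
        groups[s].append(sample)
    return groups


def single_cnv_status_table(cnv: pd.DataFrame, genes) -> dict:
    """Single-gene analogue of the CoCNV status table: per gene and sample,
    G (gain), L (loss) or NC, with |level| as the level product.  Lets the
    pair-factor machinery run on single genes for comparison."""
    out = {}
    for g in genes:
        calls = cnv.loc[g].astype(int)
        status = calls.map(lambda c: "NC" if c == 0 else ("G" if c > 0 else "L"))
        out[g] = pd.DataFrame({"status": status, "level_product": calls.abs()})
    return out


def logrank(group_a, group_b) -> tuple:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Each group is ``(times, events)``.  Requires at least one event across
    the two groups.
    """
    ta, ea = np.asarray(group_a[0], dtype=float), np.asarray(group_a[1], dtype=int)
    tb, eb = np.asarray(group_b[0], dtype=float), np.asarray(group_b[1], dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _km_area(times, events) -> float:
    """Area under the Kaplan-Meier curve up to the last observed time
    (restricted mean survival time); larger = better survival."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tau = float(np.max(times))
    if tau == 0:
        return 0.0
    return float(restricted_mean_survival_time(kmf, t=tau))


def _orient(pair, modality, name_a, name_b, samples_a, samples_b,
            clinical, statistic, pvalue) -> SurvivalFactor:
    ta, ea = clinical.loc[samples_a, "time"], clinical.loc[samples_a, "event"]
    tb, eb = clinical.loc[samples_b, "time"], clinical.loc[samples_b, "event"]
    if _km_area(ta, ea) >= _km_area(tb, eb):
        better, worse = (name_a, len(samples_a)), (name_b, len(samples_b))
    else:
        better, worse = (name_b, len(samples_b)), (name_a, len(samples_a))
    return SurvivalFactor(pair=pair, modality=modality,
                          better_type=better[0], worse_type=worse[0],
                          n_better=better[1], n_worse=worse[1],
                          statistic=statistic, pvalue=pvalue)


def find_cocnv_factors(pairs, cocnv_statuses: dict, clinical: pd.DataFrame,
                       min_n: int = 20, alpha: float = 0.05) -> list:
    """Discover CoCNV survival factors over the given pairs.

    For each pair, patients are partitioned into the 5 status groups; every
    unordered group pair with both sizes strictly greater than ``min_n`` is
    log-rank tested, and comparisons with p < ``alpha`` are returned as
    factors oriented better > worse by Kaplan–Meier area.
    """
    _check_clinical(clinical)
    factors = []
    for pair in pairs:
        status = cocnv_statuses[pair]["status"]
        status = status.loc[status.index.intersection(clinical.index)]
        groups = cocnv_patient_groups(status)
        names = [g for g in COCNV_GROUPS if len(groups[g]) > min_n]
        for a, b in combinations(names, 2):
            sa, sb = groups[a], groups[b]
            stat, p = logrank((clinical.loc[sa, "time"], clinical.loc[sa, "event"]),
                              (clinical.loc[sb, "time"], clinical.loc[sb, "event"]))
            if p < alpha:
                factors.append(_orient(pair, "CoCNV", a, b, sa, sb, clinical, stat, p))
    return factors


def nmad(values) -> float:
    """Normalized mean absolute deviation: mean(|v - mean(v)|) / mean(v)."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ZeroDivisionError("mean is zero")
    return float(np.mean(np.abs(v - m)) / m)


def codm_patient_status(profile: pd.DataFrame, value: str) -> pd.Series:
    """Median-split assignment for one CoDM value of one pair: samples with
    the value strictly above the cohort median are "high", others "low"."""
    v = profile[value]
    med = float(v.median())
    return pd.Series(np.where(v > med, "high", "low"), index=profile.index)


def find_codm_factors(pairs, codm_profiles: dict, clinical: pd.DataFrame,
                      nmad_thr: float = 0.25, alpha: float = 0.05) -> list:
    """Discover CoDM survival factors over the given pairs.

    Per pair and CoDM value (HH/LL/LH/HL): values whose normalized mean
    absolute deviation across samples exceeds ``nmad_thr`` are median-split
    into high/low patient groups and log-rank tested; significant ones are
    returned as factors such as "HH-low > HH-high".  Values with zero mean
    are skipped with a warning.
    """
    _check_clinical(clinical)
    factors = []
    for pair in pairs:
        profile = codm_profiles[pair]
        profile = profile.loc[profile.index.intersection(clinical.index)]
        for value in CODM_VALUES:
            v = profile[value]
            if float(v.mean()) == 0:
                logger.warning("CoDM value %s of pair %s has zero mean; skipped", value, pair)
                continue
            if nmad(v) <= nmad_thr:
                continue
            sides = codm_patient_status(profile, value)
            hi = list(sides.index[sides == "high"])
            lo = list(sides.index[sides == "low"])
            if not hi or not lo:
                continue
            stat, p = logrank((clinical.loc[hi, "time"], clinical.loc[hi, "event"]),
                              (clinical.loc[lo, "time"], clinical.loc[lo, "event"]))
            if p < alpha:
                factors.append(_orient(pair, "CoDM", f"{value}-high", f"{value}-low",
                                       hi, lo, clinical, stat, p))
    return factors


def i_gp(pair_factors, patient_status) -> int:
    """Per-pair score contribution I_gp in {-1, 0, +1} for one patient.

    CoCNV: ``patient_status`` is the pair's status string.  Statuses
    appearing only on the better side of the pair's factors give +1, only on
    the worse side -1; NC and statuses absent from every factor give 0.  A
    non-NC status on both sides raises :class:`FactorConflictError`.

    CoDM: ``patient_status`` maps CoDM value names to the patient's
    median-group side ("high"/"low"); each factor contributes +1 or -1 by
    which side the patient falls on, and the pair contribution is the sign
    of the sum.
    """
    factors = list(pair_factors)
    if not factors:
        return 0
    modalities = {f.modality for f in factors}
    if len(modalities) != 1:
        raise ValueError("i_gp expects factors of a single modality for one pair")
    modality = modalities.pop()

    if modality == "CoCNV":
        better = {f.better_type for f in factors} - {"NC"}
        worse = {f.worse_type for f in factors} - {"NC"}
        conflicted = better & worse
        if conflicted:
            raise FactorConflictError(
                f"status(es) {sorted(conflicted)} on both sides of factors for "
                f"pair {factors[0].pair}")
        if patient_status == "NC":
            return 0
        if patient_status in better:
            return 1
        if patient_status in worse:
            return -1
        return 0

    if modality == "CoDM":
        total = 0
        for f in factors:
            value, good_side = f.better_type.rsplit("-", 1)
            side = patient_status[value]
            total += 1 if side == good_side else -1
        return int(np.sign(total))

    raise ValueError(f"unknown modality {modality!r}")


def score_patients(factors, cocnv_statuses: dict | None = None,
                   codm_profiles: dict | None = None) -> pd.DataFrame:
    """Sum I_gp over factor-bearing pairs and stratify by the score.

    ``factors`` is a flat list; CoCNV factors need ``cocnv_statuses``
    (pair -> per-sample status frame) and CoDM factors need
    ``codm_profiles`` (pair -> per-sample value frame).  Returns a frame
    indexed by sample with integer ``score`` and tertile ``group``.
    """
    by_pair: dict = {}
    for f in factors:
        by_pair.setdefault((f.pair, f.modality), []).append(f)

    samples = None
    for (pair, modality) in by_pair:
        src = cocnv_statuses if modality == "CoCNV" else codm_profiles
        if src is None or pair not in src:
            raise ValueError(f"missing status data for {modality} pair {pair}")
        idx = src[pair].index
        samples = idx if samples is None else samples.intersection(idx)
    if samples is None:
        logger.warning("no survival factors; all scores 0")
        raise ValueError("cannot score patients without factors")

    scores = pd.Series(0, index=samples, dtype=int)
    for (pair, modality), fs in by_pair.items():
        if modality == "CoCNV":
            status = cocnv_statuses[pair]["status"]
            for s in samples:
                scores[s] += i_gp(fs, status[s])
        else:
            profile = codm_profiles[pair].loc[samples]
            sides = {v: codm_patient_status(profile, v) for v in CODM_VALUES}
            for s in samples:
                scores[s] += i_gp(fs, {v: sides[v][s] for v in CODM_VALUES})
    out = pd.DataFrame({"score": scores})
    out["group"] = divide_by_score(scores)
    return out


def divide_by_score(scores: pd.Series) -> pd.Series:
    """Tertile split of scores into low/mid/high; ties go to the lower group."""
    q1, q2 = scores.quantile([1 / 3, 2 / 3])
    if scores.nunique() == 1:
        logger.warning("all scores identical; degenerate single-group division")
        return pd.Series("low", index=scores.index)
    labels = np.where(scores <= q1, "low", np.where(scores <= q2, "mid", "high"))
    return pd.Series(labels, index=scores.index)


def cox_multivariate(clinical: pd.DataFrame, scores=None, covariates=()) -> pd.DataFrame:
    """Cox proportional-hazards fit of survival on score(s) plus covariates.

    ``scores`` may be a Series, a DataFrame of several score columns (CoCNV
    and CoDM scores can enter one model together), or None.  Returns one row
    per regressor with coefficient, hazard ratio and p-value.
    """
    _check_clinical(clinical)
    df = clinical[["time", "event"] + list(covariates)].copy()
    if scores is not None:
        sc = scores.to_frame("score") if isinstance(scores, pd.Series) else scores
        df = df.join(sc, how="inner")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    return pd.DataFrame({
        "coef": summary["coef"],
        "hazard_ratio": summary["exp(coef)"],
        "p": summary["p"],
    })


def subsample_stability(clinical: pd.DataFrame, scores=None, covariates=(),
                        frac: float = 0.8, reps: int = 100,
                        seed: int | None = None) -> pd.DataFrame:
    """Stability of Cox p-values under repeated subsampling.

    Refits the model of :func:`cox_multivariate` on ``reps`` random
    ``frac``-fraction subsets and reports the per-regressor mean and
    standard deviation of the p-values (sd is NaN for reps = 1).
    """
    _check_clinical(clinical)
    rng = np.random.default_rng(seed)
    if scores is not None and isinstance(scores, pd.Series):
        scores = scores.to_frame("score")
    pvals: dict = {}
    n = len(clinical)
    k = int(round(frac * n))
    for _ in range(reps):
        idx = clinical.index[rng.choice(n, size=k, replace=False)]
        sub_scores = scores.loc[scores.index.intersection(idx)] if scores is not None else None
        res = cox_multivariate(clinical.loc[idx], sub_scores, covariates)
        for name, p in res["p"].items():
            pvals.setdefault(name, []).append(p)
    rows = {}
    for name, ps in pvals.items():
        arr = np.asarray(ps)
        rows[name] = {"p_mean": float(arr.mean()),
                      "p_sd": float(arr.std(ddof=1)) if reps > 1 else float("nan")}
    return pd.DataFrame(rows).T
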