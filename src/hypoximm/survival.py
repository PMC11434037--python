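"""Association screens, group contrasts, and survival machinery.

Includes the Spearman + FDR feature screen, Wilcoxon group comparisons
(rank-sum unpaired / signed-rank paired, exact at small n), the
checkpoint-blockade response contrast with its two pooling conventions
(PD vs CR/PR, or PD vs CR/PR/SD), maximally selected log-rank cutpoint
stratification, and Kaplan-Meier / log-rank estimation.

The Kaplan-Meier product-limit estimator and the two-group log-rank test
(hypergeometric variance) are implemented natively because the cutpoint
scan evaluates the standardized log-rank statistic at every admissible
split; the scan reports the uncorrected maximally selected statistic and
the log-rank p of the chosen split.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .pseudotime import bh_qvalues
from .types import ScoreVector, SurvivalCohort

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- screens

def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Spearman p by full permutation enumeration (n <= 9)."""
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan, np.nan
    obs = float(rx @ ry / denom)
    n = len(rx)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = float(rx[list(perm)] @ ry / denom)
        total += 1
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
    return obs, count / total


def spearman_screen(
    scores: ScoreVector, features: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Spearman correlation of the score with each feature column, BH
    q-values across features, and a significance flag at q < ``fdr``.

    Exact permutation p-values are used when n <= 9; the t-approximation
    otherwise.  Constant features are reported with missing Rs.
    """
    sc = scores.to_series()
    common = [s for s in sc.index if s in features.index]
    if len(common) < 4:
        raise ValueError("need >= 4 paired observations")
    sc = sc.loc[common]
    feats = features.loc[common]
    rows = []
    for col in feats.columns:
        y = feats[col].to_numpy(float)
        mask = np.isfinite(y) & np.isfinite(sc.to_numpy())
        if mask.sum() < 4 or np.all(y[mask] == y[mask][0]):
            rows.append((col, np.nan, np.nan))
            continue
        x, yv = sc.to_numpy()[mask], y[mask]
        if mask.sum() <= 9:
            rs, p = _exact_spearman_p(x, yv)
        else:
            rs, p = scipy.stats.spearmanr(x, yv)
        rows.append((col, float(rs), float(p)))
    df = pd.DataFrame(rows, columns=["feature", "rs", "p_value"]).set_index("feature")
    valid = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_qvalues(df.loc[valid, "p_value"].to_numpy())
    df["q_value"] = q
    df["significant"] = df["q_value"] < fdr
    return df


# ------------------------------------------------------- group comparisons

def group_compare(
    scores: np.ndarray,
    group_labels: np.ndarray,
    paired: bool = False,
    exact_n: int = 25,
) -> dict:
    """Two-sided Wilcoxon comparison of scores between two groups.

    Unpaired data use the rank-sum (Mann-Whitney) test, paired data the
    signed-rank test; p-values are exact for total n <= ``exact_n`` without
    ties, else the normal approximation with tie correction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels, dtype=object)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a = scores[labels == groups[0]]
    b = scores[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal group sizes")
        diffs = a - b
        if np.all(diffs == 0):
            return {"statistic": 0.0, "p_value": 1.0, "test": "signed_rank",
                    "groups": groups, "n": (len(a), len(b))}
        method = "exact" if (len(a) <= exact_n and len(np.unique(np.abs(diffs)))
                             == len(diffs) and not np.any(diffs == 0)) else "approx"
        res = scipy.stats.wilcoxon(a, b, alternative="two-sided", method=method)
        test = "signed_rank"
    else:
        no_ties = len(np.unique(scores[np.isin(labels, groups)])) == len(a) + len(b)
        method = "exact" if (len(a) + len(b) <= exact_n and no_ties) else "asymptotic"
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "rank_sum"
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "test": test,
        "groups": groups,
        "n": (len(a), len(b)),
        "median": (float(np.median(a)), float(np.median(b))),
    }


RESPONSE_POOLINGS = {
    "pd-vs-prcr": {"responder": ("CR", "PR"), "non_responder": ("PD",)},
    "imvigor": {"responder": ("CR", "PR", "SD"), "non_responder": ("PD",)},
}


def response_contrast(cohort: SurvivalCohort, pooling: str = "pd-vs-prcr") -> dict:
    """Hypoxia-score contrast between ICB responders and non-responders.

    Default pooling compares PD against CR/PR (SD excluded); the IMvigor
    convention pools SD with the responders.  Where paired pre/on samples
    exist, the per-patient on-minus-pre score delta is additionally
    contrasted between response groups.
    """
    if cohort.response is None:
        raise ValueError("cohort has no response labels")
    if pooling not in RESPONSE_POOLINGS:
        raise ValueError(f"unknown pooling {pooling!r}")
    spec = RESPONSE_POOLINGS[pooling]

    df = cohort.to_frame()
    base = df[df["timepoint"] == "pre"] if cohort.timepoint is not None else df
    is_resp = base["response"].isin(spec["responder"])
    is_non = base["response"].isin(spec["non_responder"])
    kept = base[is_resp | is_non]
    groups = np.where(kept["response"].isin(spec["responder"]),
                      "responder", "non_responder")
    if len(set(groups)) < 2:
        raise ValueError("pooling leaves a response group empty")
    result = {
        "pooling": pooling,
        "score_contrast": group_compare(kept["score"].to_numpy(), groups),
    }

    if cohort.timepoint is not None and cohort.patient_id is not None:
        pre = df[df["timepoint"] == "pre"].set_index("patient_id")
        on = df[df["timepoint"] == "on"].set_index("patient_id")
        shared = pre.index.intersection(on.index)
        if len(shared) >= 4:
            delta = (on.loc[shared, "score"] - pre.loc[shared, "score"]).to_numpy()
            resp = pre.loc[shared, "response"].isin(spec["responder"]).to_numpy()
            non = pre.loc[shared, "response"].isin(spec["non_responder"]).to_numpy()
            keep = resp | non
            if resp[keep].any() and (~resp[keep]).any():
                dgroups = np.where(resp[keep], "responder", "non_responder")
                result["delta_contrast"] = group_compare(delta[keep], dgroups)
                result["n_pairs"] = int(keep.sum())
    return result


# --------------------------------------------------- Kaplan-Meier/log-rank

def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns event-time rows with numbers at risk, events, and the survival
    estimate after each time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    rows = []
    surv = 1.0
    n = len(time)
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def km_median(curve: pd.DataFrame) -> float:
    """Earliest event time at which the KM estimate drops to <= 0.5 (NaN if
    it never does)."""
    below = curve[curve["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("nan")


def logrank_two_group(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float, float]:
    """Two-group log-rank test with hypergeometric variance.

    Returns (z, chi_square, p) where z is the standardized observed-minus-
    expected statistic of the first (sorted-label) group.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = sorted(set(group.tolist()))
    if len(labels) != 2:
        raise ValueError("log-rank requires exactly 2 groups")
    g1 = group == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_t = int(at_risk.sum())
        n1_t = int((at_risk & g1).sum())
        d_t = int(((time == t) & (event == 1)).sum())
        d1_t = int(((time == t) & (event == 1) & g1).sum())
        e1 = d_t * n1_t / n_t
        o_minus_e += d1_t - e1
        if n_t > 1:
            var += (
                d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
            )
    if var <= 0:
        return 0.0, 0.0, 1.0
    z = o_minus_e / np.sqrt(var)
    chi2 = z * z
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return float(z), float(chi2), p


def km_logrank(cohort: SurvivalCohort, group_labels: np.ndarray) -> dict:
    """KM curves, per-group median survival, and the two-group log-rank test."""
    labels = np.asarray(group_labels, dtype=object)
    names = sorted(set(labels.tolist()))
    if len(names) != 2:
        raise ValueError("need exactly 2 groups")
    curves, medians = {}, {}
    for name in names:
        mask = labels == name
        if not mask.any():
            raise ValueError(f"group {name!r} is empty")
        curve = km_curve(cohort.time[mask], cohort.event[mask])
        curves[name] = curve
        medians[name] = km_median(curve)
    z, chi2, p = logrank_two_group(cohort.time, cohort.event, labels)
    return {
        "curves": curves,
        "median_survival": medians,
        "z": z,
        "chi_square": chi2,
        "p_value": p,
    }


# ------------------------------------------------------- optimal cutpoint

@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float  # maximally selected |standardized log-rank|
    groups: np.ndarray  # high / low per sample
    logrank_chi2: float
    logrank_p: float

    def __post_init__(self) -> None:
        names = set(np.asarray(self.groups).tolist())
        if names != {"high", "low"}:
            raise ValueError("cutpoint must split into non-empty high/low groups")


def optimal_cutpoint(
    cohort: SurvivalCohort, min_group_frac: float = 0.10
) -> CutpointResult:
    """Maximally selected log-rank cutpoint.

    Candidate cutpoints are midpoints between consecutive distinct scores
    whose split leaves each group at least ``min_group_frac`` of the
    samples; the cutpoint maximizing the absolute standardized log-rank
    statistic is returned (ties broken toward the smaller cutpoint).
    """
    n = len(cohort.sample_ids)
    if n < 10:
        raise ValueError("cutpoint search needs >= 10 samples")
    if cohort.event.sum() < 3:
        raise ValueError("cutpoint search needs >= 3 events")
    distinct = np.unique(cohort.score)
    if len(distinct) < 2:
        raise ValueError("all scores identical; no cutpoint exists")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    min_n = int(np.ceil(min_group_frac * n))

    best = None
    for c in candidates:
        low = cohort.score <= c
        if low.sum() < min_n or (~low).sum() < min_n:
            continue
        groups = np.where(low, "low", "high")
        z, chi2, p = logrank_two_group(cohort.time, cohort.event, groups)
        stat = abs(z)
        # strict > keeps the smallest cutpoint on ties
        if best is None or stat > best[0] + 1e-12:
            best = (stat, float(c), chi2, p, groups)
    if best is None:
        raise ValueError(
            f"no candidate cutpoint leaves both groups >= {min_group_frac:.0%} "
            "of samples"
        )
    stat, cut, chi2, p, groups = best
    return CutpointResult(cut, stat, groups.astype(object), chi2, p)
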