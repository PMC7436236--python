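"""Intra-participant and inter-participant (LOSO) evaluation protocols.

The intra-participant protocol trains one model per subject on the first
half of every speed trial (no shuffling; windows are assigned by their
centre sample) and tests on the second halves.  The inter-participant
protocol holds each subject out in turn, training on the remaining
subjects' full trials.  Accuracy is summarized per subject by the Pearson
correlation R, the RMSE in body weights, and the NRMSE (RMSE divided by the
reference range, in percent), pooled over all of the subject's test samples
across speeds ("whole course") and additionally recomputed per speed.
Stance-phase passive/active peak magnitude errors and timing delays
(reference minus estimate) complete the report.

Location and speed effects on any per-subject metric are tested with a
fixed-effects two-way ANOVA (subjects as replicates) followed by Tukey HSD
pairwise comparisons on a factor's marginal means using the ANOVA error
term, at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import pearsonr, studentized_range

from . import events, features, forest
from .synthetic import Trial

__all__ = ["ProtocolConfig", "MetricsReport", "AnovaResult", "intra_split",
           "loso_split", "score", "run_protocol", "two_way_anova", "tukey_hsd"]

log = logging.getLogger("gaitforce")

_METRICS = ["r", "rmse", "nrmse", "pp_error", "pp_abs_error", "pp_delay",
            "ap_error", "ap_abs_error", "ap_delay"]


@dataclass(frozen=True)
class ProtocolConfig:
    """Model hyperparameters and bookkeeping for one protocol run."""

    n_trees: int = 50
    min_leaf: int = 5
    seed: int = 0
    engine: str = "sklearn"


@dataclass
class MetricsReport:
    """Per-subject, per-(subject, speed) and aggregated accuracy tables."""

    mode: str
    location: str
    per_subject: pd.DataFrame          # one row per subject, pooled metrics
    per_subject_speed: pd.DataFrame    # one row per (subject, speed)
    stances: pd.DataFrame              # per-stance peak comparison
    dropped: List[str] = field(default_factory=list)  # flagged undefined cells

    @property
    def aggregate(self) -> pd.DataFrame:
        """Mean and SD across subjects of every pooled metric."""
        vals = self.per_subject[_METRICS]
        return pd.DataFrame({"mean": vals.mean(), "sd": vals.std(ddof=0 if len(vals) == 1 else 1)})

    def aggregate_by_speed(self) -> pd.DataFrame:
        g = self.per_subject_speed.groupby("speed")[_METRICS]
        out = g.agg(["mean", "std"])
        return out


def intra_split(n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Row indices (train, test) of the in-order half split; floor to train."""
    if n < 2:
        raise ValueError("need at least two rows to split")
    half = n // 2
    return np.arange(half), np.arange(half, n)


def loso_split(cohort: Sequence[Trial], held_out: str
               ) -> Tuple[List[Trial], List[Trial]]:
    """Partition a cohort by subject id for one leave-one-subject-out fold."""
    subjects = {t.subject_id for t in cohort}
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    if held_out not in subjects:
        raise KeyError(f"unknown subject {held_out!r}")
    train = [t for t in cohort if t.subject_id != held_out]
    test = [t for t in cohort if t.subject_id == held_out]
    return train, test


def score(yhat: np.ndarray, yref: np.ndarray) -> Tuple[float, float, float]:
    """(R, RMSE in BW, NRMSE in % of reference range).

    Returns NaNs when the reference range or either variance is zero; the
    caller excludes such cells from aggregates.
    """
    yhat = np.asarray(yhat, dtype=float)
    yref = np.asarray(yref, dtype=float)
    if yhat.shape != yref.shape or yhat.size < 2:
        raise ValueError("score needs two equal-length vectors of >= 2 samples")
    rng = yref.max() - yref.min()
    rmse = float(np.sqrt(np.mean((yhat - yref) ** 2)))
    if rng == 0 or np.std(yhat) == 0 or np.std(yref) == 0:
        return float("nan"), rmse, float("nan")
    r = float(pearsonr(yhat, yref)[0])
    return r, rmse, 100.0 * rmse / rng


def _peak_metrics(ref_signal: np.ndarray, est_lp: np.ndarray,
                  mass: float, fs: float) -> pd.DataFrame:
    """Per-stance comparison table; empty if no complete stance exists."""
    stances = events.segment_stances(ref_signal, mass, fs)
    stances = [events.find_stance_peaks(ref_signal, s) for s in stances]
    return events.compare_peaks(stances, est_lp)


def _summarize(subject: str, pairs, peak_tables) -> dict:
    """Pool (yhat, yref) segment pairs and per-stance tables for one subject."""
    yhat = np.concatenate([p[0] for p in pairs])
    yref = np.concatenate([p[1] for p in pairs])
    r, rmse, nrmse = score(yhat, yref)
    row = {"subject": subject, "r": r, "rmse": rmse, "nrmse": nrmse,
           "n_samples": yref.size}
    pk = pd.concat(peak_tables, ignore_index=True) if peak_tables else pd.DataFrame()
    if len(pk):
        row.update({
            "pp_error": pk["pp_error_bw"].mean(),
            "pp_abs_error": pk["pp_error_bw"].abs().mean(),
            "pp_delay": pk["pp_delay_pct"].mean(),
            "ap_error": pk["ap_error_bw"].mean(),
            "ap_abs_error": pk["ap_error_bw"].abs().mean(),
            "ap_delay": pk["ap_delay_pct"].mean(),
            "n_stances": len(pk),
        })
    else:
        row.update({k: float("nan") for k in
                    ["pp_error", "pp_abs_error", "pp_delay",
                     "ap_error", "ap_abs_error", "ap_delay"]})
        row["n_stances"] = 0
    return row


def _feature_cache(cohort: Sequence[Trial], location: str
                   ) -> Dict[Tuple[str, float], features.FeatureMatrix]:
    cache = {}
    for t in cohort:
        log.debug("features: subject=%s speed=%.1f loc=%s", t.subject_id,
                  t.speed, location)
        cache[(t.subject_id, t.speed)] = features.build_feature_matrix(t, location)
    return cache


def run_protocol(cohort: Sequence[Trial], location: str = "shank",
                 mode: str = "intra",
                 config: ProtocolConfig | None = None) -> MetricsReport:
    """Run the full pipeline under one protocol and report accuracies.

    Orchestrates feature extraction -> train-fit normalization -> forest
    training -> prediction -> 10 Hz low-pass -> stance segmentation -> peak
    comparison -> scoring, per the chosen protocol.
    """
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    config = config or ProtocolConfig()
    subjects = sorted({t.subject_id for t in cohort})
    by_subject: Dict[str, List[Trial]] = {
        s: sorted([t for t in cohort if t.subject_id == s], key=lambda t: t.speed)
        for s in subjects}
    fmx = _feature_cache(cohort, location)

    subj_rows, speed_rows, stance_tables, dropped = [], [], [], []
    for subject in subjects:
        trials = by_subject[subject]
        if mode == "intra":
            train_blocks, test_specs = [], []
            for t in trials:
                fm = fmx[(t.subject_id, t.speed)]
                tr_idx, te_idx = intra_split(fm.n_samples)
                train_blocks.append((fm.values[tr_idx], fm.target[tr_idx]))
                test_specs.append((t, fm, te_idx))
        else:
            train_trials, _ = loso_split(cohort, subject)
            train_blocks = [(fmx[(t.subject_id, t.speed)].values,
                             fmx[(t.subject_id, t.speed)].target)
                            for t in train_trials]
            test_specs = [(t, fmx[(t.subject_id, t.speed)],
                           np.arange(fmx[(t.subject_id, t.speed)].n_samples))
                          for t in trials]

        X_train = np.vstack([b[0] for b in train_blocks])
        y_train = np.concatenate([b[1] for b in train_blocks])
        lo, hi = features.fit_normalizer(X_train)
        model = forest.fit_forest(
            features.scale_values(X_train, lo, hi), y_train,
            n_trees=config.n_trees, min_leaf=config.min_leaf,
            seed=config.seed, engine=config.engine,
            feature_names=fmx[(subject, trials[0].speed)].feature_names)
        log.info("%s/%s subject=%s: trained on %d rows", mode, location,
                 subject, X_train.shape[0])

        pairs, peak_tables = [], []
        for t, fm, te_idx in test_specs:
            Xte = features.scale_values(fm.values[te_idx], lo, hi)
            yhat = forest.predict(model, Xte)
            yhat_lp = events.lowpass_10(yhat, t.fs)
            yref = fm.target[te_idx]
            pairs.append((yhat_lp, yref))
            r_s, rmse_s, nrmse_s = score(yhat_lp, yref)
            if np.isnan(nrmse_s):
                dropped.append(f"{subject}@{t.speed}: zero range/variance")
            pk = _peak_metrics(yref, yhat_lp, t.mass, t.fs)
            pk.insert(0, "subject", subject)
            pk.insert(1, "speed", t.speed)
            peak_tables.append(pk)
            speed_rows.append({
                "subject": subject, "speed": t.speed, "r": r_s,
                "rmse": rmse_s, "nrmse": nrmse_s,
                "pp_error": pk["pp_error_bw"].mean() if len(pk) else float("nan"),
                "pp_abs_error": pk["pp_error_bw"].abs().mean() if len(pk) else float("nan"),
                "pp_delay": pk["pp_delay_pct"].mean() if len(pk) else float("nan"),
                "ap_error": pk["ap_error_bw"].mean() if len(pk) else float("nan"),
                "ap_abs_error": pk["ap_error_bw"].abs().mean() if len(pk) else float("nan"),
                "ap_delay": pk["ap_delay_pct"].mean() if len(pk) else float("nan"),
            })
        subj_rows.append(_summarize(subject, pairs, peak_tables))
        stance_tables.extend(peak_tables)

    return MetricsReport(
        mode=mode, location=location,
        per_subject=pd.DataFrame(subj_rows),
        per_subject_speed=pd.DataFrame(speed_rows),
        stances=pd.concat(stance_tables, ignore_index=True)
        if stance_tables else pd.DataFrame(),
        dropped=dropped,
    )


@dataclass
class AnovaResult:
    """Two-way fixed-effects ANOVA with interaction on a balanced design."""

    table: pd.DataFrame                # statsmodels anova_lm table (Type I)
    f_location: float
    p_location: float
    f_speed: float
    p_speed: float
    f_interaction: float
    p_interaction: float
    mse_error: float
    df_error: int
    alpha: float = 0.05


def two_way_anova(df: pd.DataFrame, value: str = "value",
                  location: str = "location", speed: str = "speed"
                  ) -> AnovaResult:
    """location x speed ANOVA with subjects as replicates.

    Requires a balanced complete design (every cell equally populated);
    Type-I sums of squares then coincide with the textbook decomposition.
    """
    counts = df.groupby([location, speed]).size()
    if counts.nunique() != 1 or counts.min() == 0:
        raise ValueError("design must be balanced and complete")
    data = df.rename(columns={value: "_y", location: "_loc", speed: "_sp"})
    model = smf.ols("_y ~ C(_loc) * C(_sp)", data=data).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    resid = tab.loc["Residual"]
    return AnovaResult(
        table=tab,
        f_location=float(tab.loc["C(_loc)", "F"]),
        p_location=float(tab.loc["C(_loc)", "PR(>F)"]),
        f_speed=float(tab.loc["C(_sp)", "F"]),
        p_speed=float(tab.loc["C(_sp)", "PR(>F)"]),
        f_interaction=float(tab.loc["C(_loc):C(_sp)", "F"]),
        p_interaction=float(tab.loc["C(_loc):C(_sp)", "PR(>F)"]),
        mse_error=float(resid["sum_sq"] / resid["df"]),
        df_error=int(resid["df"]),
    )


def tukey_hsd(df: pd.DataFrame, factor: str, anova: AnovaResult,
              value: str = "value") -> pd.DataFrame:
    """Tukey HSD on a factor's marginal means using the ANOVA error term.

    The studentized-range statistic q = |m_i - m_j| / sqrt(MSE / n) is
    referred to its distribution with k groups and the ANOVA's residual
    degrees of freedom.
    """
    means = df.groupby(factor)[value].mean()
    n_per = df.groupby(factor)[value].count()
    if n_per.nunique() != 1:
        raise ValueError("marginal groups must be equally sized")
    n = int(n_per.iloc[0])
    k = len(means)
    se = np.sqrt(anova.mse_error / n)
    rows = []
    for a, b in combinations(means.index, 2):
        diff = means[a] - means[b]
        q = abs(diff) / se
        p = float(studentized_range.sf(q, k, anova.df_error))
        rows.append({"group1": a, "group2": b, "diff": diff, "q": q,
                     "p": p, "significant": p < anova.alpha})
    return pd.DataFrame(rows)
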