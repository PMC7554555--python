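"""Waveform variability: Winter's coefficient of variation and group tests.

Winter's waveform CV for a set of equal-length trials x_i(t):

    CV% = 100 * sqrt( (1/T) * sum_t s_t^2 ) / ( (1/T) * sum_t |xbar_t| )

with s_t^2 the between-trial (sample, n-1 denominator) variance and xbar_t
the mean waveform at grid point t.  Per 27-variable kick data the CV is
computed per variable and aggregated as the unweighted mean over variables.

Group comparisons follow a normality-gated repeated-measures design: if no
level rejects Shapiro-Wilk, a one-way repeated-measures ANOVA (with
Greenhouse-Geisser correction when Mauchly's test rejects sphericity) and
paired t post-hocs with Cohen's d; otherwise a Friedman test with Wilcoxon
signed-rank post-hocs and r effect sizes.  All post-hoc p-values are
Holm-Bonferroni adjusted and post-hocs run only when the omnibus test
rejects at alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError, SchemaError
from .preprocess import FeatureMatrix

logger = logging.getLogger("kinemid.variability")

GROUPINGS = ("inter_individual", "block", "set", "block_within_set")


# ---------------------------------------------------------------------------
# Winter CV
# ---------------------------------------------------------------------------

def winter_cv(waveforms: np.ndarray) -> float:
    """Winter waveform CV (%) of an (n_trials, T) stack of one variable.

    Returns NaN (and logs) when the mean waveform is identically zero,
    leaving the ratio undefined.
    """
    w = np.asarray(waveforms, dtype=float)
    if w.ndim != 2:
        raise SchemaError(f"expected (n_trials, T) waveforms, got shape {w.shape}")
    if w.shape[0] < 2:
        raise SchemaError(f"need >= 2 waveforms for a CV, got {w.shape[0]}")
    var_t = w.var(axis=0, ddof=1)
    denom = np.mean(np.abs(w.mean(axis=0)))
    if denom == 0.0:
        logger.warning("undefined Winter CV: mean waveform identically zero")
        return float("nan")
    return 100.0 * float(np.sqrt(var_t.mean()) / denom)


def winter_cv_features(values: np.ndarray, n_grid: int) -> float:
    """Winter CV of multi-variable kick rows: per variable, then mean.

    ``values`` is (n_kicks, n_variables * n_grid) in variable-major column
    order.  Variables with an undefined CV are excluded from the mean.
    """
    x = np.asarray(values, dtype=float)
    n_vars = x.shape[1] // n_grid
    if x.shape[1] != n_vars * n_grid:
        raise SchemaError("feature width is not a multiple of the grid size")
    per_var = np.array([winter_cv(x[:, v * n_grid:(v + 1) * n_grid]) for v in range(n_vars)])
    if np.all(np.isnan(per_var)):
        return float("nan")
    return float(np.nanmean(per_var))


# ---------------------------------------------------------------------------
# CV by grouping
# ---------------------------------------------------------------------------

def cv_by_grouping(features: FeatureMatrix, grouping: str) -> pd.DataFrame:
    """Winter CVs under the grouping of each classification design.

    * inter_individual: one CV per (leg, intensity) over all kicks pooled
      across subjects;
    * block: one CV per (subject, leg, chronological block) over its K-80
      kicks (27 groups per subject per leg with the full protocol);
    * set: one CV per (subject, leg, set) over its K-80 kicks;
    * block_within_set: one CV per (subject, leg, within-set block index),
      pooling that block index across all sets (3 groups per subject per
      leg), matching the three-class design.

    Computed on the same preprocessed (time-normalized) data as the
    classification tasks; groups with < 2 kicks are skipped with a log
    entry.
    """
    if grouping not in GROUPINGS:
        raise ParameterError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    lab = features.labels
    rows: list[dict] = []

    def _cv(mask: np.ndarray) -> float | None:
        if mask.sum() < 2:
            logger.warning("grouping %s: group with %d kicks skipped", grouping, int(mask.sum()))
            return None
        return winter_cv_features(features.values[mask], features.n_grid)

    if grouping == "inter_individual":
        for (leg, intensity), g in lab.groupby(["leg", "intensity"], sort=True):
            cv = _cv(((lab["leg"] == leg) & (lab["intensity"] == intensity)).to_numpy())
            if cv is not None:
                rows.append({"grouping": grouping, "subject": -1, "leg": leg,
                             "intensity": intensity, "group": 0, "cv_percent": cv,
                             "n_kicks": int(len(g))})
        return pd.DataFrame(rows)

    k80 = lab["intensity"] == "K80"
    blocks_per_set = int(lab.loc[k80, "block"].max()) if k80.any() else 0
    for (subject, leg), g in lab[k80].groupby(["subject", "leg"], sort=True):
        base = ((lab["subject"] == subject) & (lab["leg"] == leg) & k80).to_numpy()
        if grouping == "block":
            for set_i in sorted(g["set"].unique()):
                for block_i in sorted(g["block"].unique()):
                    gid = blocks_per_set * (set_i - 1) + block_i
                    mask = base & (lab["set"] == set_i).to_numpy() & (lab["block"] == block_i).to_numpy()
                    cv = _cv(mask)
                    if cv is not None:
                        rows.append({"grouping": grouping, "subject": subject, "leg": leg,
                                     "intensity": "K80", "group": int(gid), "cv_percent": cv,
                                     "n_kicks": int(mask.sum())})
        elif grouping == "set":
            for set_i in sorted(g["set"].unique()):
                mask = base & (lab["set"] == set_i).to_numpy()
                cv = _cv(mask)
                if cv is not None:
                    rows.append({"grouping": grouping, "subject": subject, "leg": leg,
                                 "intensity": "K80", "group": int(set_i), "cv_percent": cv,
                                 "n_kicks": int(mask.sum())})
        else:  # block_within_set
            for block_i in sorted(g["block"].unique()):
                mask = base & (lab["block"] == block_i).to_numpy()
                cv = _cv(mask)
                if cv is not None:
                    rows.append({"grouping": grouping, "subject": subject, "leg": leg,
                                 "intensity": "K80", "group": int(block_i), "cv_percent": cv,
                                 "n_kicks": int(mask.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Holm-Bonferroni step-down
# ---------------------------------------------------------------------------

def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in input order.

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the
    ascending order statistics p_(1) <= ... <= p_(m).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adjusted_sorted = np.maximum.accumulate(adjusted_sorted)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


# ---------------------------------------------------------------------------
# Repeated-measures group comparison
# ---------------------------------------------------------------------------

@dataclass
class StatsReport:
    """Normality gate, omnibus test, and Holm-adjusted post-hoc table."""

    design: str
    n_subjects: int
    n_levels: int
    alpha: float
    normality: pd.DataFrame        # per level: W statistic, p, normal flag
    route: str                     # "parametric" | "nonparametric"
    omnibus: dict                  # test, statistic, df, p, effect size, sphericity info
    posthoc: pd.DataFrame | None   # pair, raw p, holm p, effect size; None if omnibus n.s.


def paired_cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    sd = diff.std(ddof=1)
    return float(diff.mean() / sd) if sd > 0 else float("inf") if diff.mean() != 0 else 0.0


def compare_cv_groups(cv_table: pd.DataFrame, design: str, alpha: float = 0.05) -> StatsReport:
    """Compare CV levels in a repeated-measures layout (subjects x levels).

    ``cv_table`` needs columns (subject, group, cv_percent) for a single
    leg; ``design`` in {"block", "set", "block_within_set"} (27 / 9 / 3
    levels with the full protocol).
    """
    if design not in ("block", "set", "block_within_set"):
        raise ParameterError(f"unknown design {design!r}")
    wide = cv_table.pivot_table(index="subject", columns="group", values="cv_percent")
    if wide.isna().any().any():
        raise SchemaError("repeated-measures layout has missing cells")
    n_subjects, n_levels = wide.shape
    if n_subjects < 3:
        raise InsufficientDataError(f"need >= 3 subjects for a group comparison, got {n_subjects}")
    if n_levels < 2:
        raise InsufficientDataError(f"need >= 2 levels, got {n_levels}")

    # normality gate: the family routes parametric only if no level rejects
    norm_rows = []
    for level in wide.columns:
        x = wide[level].to_numpy()
        if np.allclose(x, x[0]):
            w, p = np.nan, 1.0  # constant sample: Shapiro undefined, treat as non-rejecting
        else:
            w, p = sps.shapiro(x)
        norm_rows.append({"level": level, "W": w, "p": p, "normal": p >= alpha})
    normality = pd.DataFrame(norm_rows)
    parametric = bool(normality["normal"].all())

    long = wide.reset_index().melt(id_vars="subject", var_name="level", value_name="cv")
    pairs = [(a, b) for i, a in enumerate(wide.columns) for b in list(wide.columns)[i + 1:]]

    if parametric:
        route = "parametric"
        aov = pg.rm_anova(data=long, dv="cv", within="level", subject="subject",
                          correction=True, detailed=False, effsize="np2")
        row = aov.iloc[0].to_dict()
        spher_ok = bool(row.get("sphericity", True))
        eps = float(row.get("eps", 1.0))
        dfn, dfd = float(row["ddof1"]), float(row["ddof2"])
        if "F" not in row:
            # zero within-subject variance: the F ratio is undefined and the
            # degenerate table omits it; there is no evidence of a level effect
            f_stat, p_val, np2 = float("nan"), 1.0, float("nan")
        elif not spher_ok:
            f_stat, p_val = float(row["F"]), float(row["p_GG_corr"])
            dfn, dfd = dfn * eps, dfd * eps
            np2 = float(row["np2"])
        else:
            f_stat, p_val, np2 = float(row["F"]), float(row["p_unc"]), float(row["np2"])
        omnibus = {
            "test": "rm_anova", "statistic": f_stat,
            "df": (dfn, dfd), "p": p_val, "effect_size": np2,
            "effect_size_name": "partial_eta_squared",
            "sphericity": spher_ok, "gg_epsilon": eps,
        }
    else:
        route = "nonparametric"
        cols = [wide[c].to_numpy() for c in wide.columns]
        stat, p_val = sps.friedmanchisquare(*cols)
        kendall_w = float(stat / (n_subjects * (n_levels - 1)))
        omnibus = {
            "test": "friedman", "statistic": float(stat),
            "df": (n_levels - 1,), "p": float(p_val), "effect_size": kendall_w,
            "effect_size_name": "kendall_w",
        }

    if not np.isfinite(omnibus["p"]):
        # zero within-subject variance leaves the test statistic undefined;
        # there is no evidence of a level effect
        omnibus["p"] = 1.0

    posthoc = None
    if omnibus["p"] < alpha and pairs:
        ph_rows = []
        for a, b in pairs:
            xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
            if parametric:
                t, p_raw = sps.ttest_rel(xa, xb)
                eff, eff_name, stat_name, stat_val = paired_cohens_d(xa, xb), "cohens_d", "t", float(t)
            else:
                diff = xa - xb
                if np.allclose(diff, 0.0):
                    stat_val, p_raw, z = 0.0, 1.0, 0.0
                else:
                    res = sps.wilcoxon(xa, xb, method="approx")
                    stat_val, p_raw, z = float(res.statistic), float(res.pvalue), float(res.zstatistic)
                eff, eff_name, stat_name = float(abs(z) / np.sqrt(n_subjects)), "r", "W"
            ph_rows.append({"level_a": a, "level_b": b, stat_name: stat_val,
                            "p_raw": float(p_raw), "effect_size": eff, "effect_size_name": eff_name})
        posthoc = pd.DataFrame(ph_rows)
        posthoc["p_holm"] = holm_bonferroni(posthoc["p_raw"].to_numpy())
        posthoc["significant"] = posthoc["p_holm"] < alpha

    return StatsReport(design=design, n_subjects=n_subjects, n_levels=n_levels,
                       alpha=alpha, normality=normality, route=route,
                       omnibus=omnibus, posthoc=posthoc)
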