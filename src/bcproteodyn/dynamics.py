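"""Drug-perturbation time-course analysis.

From a replicate-level perturbation proteome (lines x drugs x time points x
replicates) this module derives:

* replicate-averaged expression profiles per (protein, line, drug);
* an IC50 screen — per-time-point Pearson correlation of expression with
  log10 IC50 across cell lines, classifying proteins whose mean correlation
  exceeds a threshold as resistance- (positive) or sensitivity- (negative)
  associated;
* per-(protein, line, drug) trend statistics: one-way ANOVA across time
  points, last-vs-first fold change, and a monotone-consistency direction
  call (Spearman |rho| of the mean profile against time);
* opposite-dynamics selection — proteins consistently up-regulated over time
  in one subtype group and down-regulated in the other, under B-H-adjusted
  ANOVA p < 0.05 and |fold change| > 2 in the supporting lines;
* a pathway-consistency filter over the selected proteins;
* persistently dysregulated proteins (PDPs) — 0 h vs 72 h differential
  proteins shared by more than a given fraction of TNBC lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust, differential_expression
from .io import (DrugResponseTable, OmicsMatrix, PathwayAnnotation,
                 TimeCourseExperiment, logger)

IC50_CLASSES = ("resistance_associated", "sensitivity_associated", "none")


@dataclass
class ProfileMatrix:
    """Replicate-averaged profiles: features x (cell_line, drug, time_h)."""

    values: pd.DataFrame
    counts: pd.DataFrame

    @property
    def time_points_h(self) -> list[float]:
        return sorted(set(self.values.columns.get_level_values("time_h")))


@dataclass
class DynamicsSelection:
    """Outcome of the opposite-dynamics screen."""

    selected: list[str]
    per_drug: dict[str, pd.DataFrame]       # feature, tnbc_dir, non_tnbc_dir
    calls: pd.DataFrame                      # qualified per (feature,line,drug)
    intersect_drugs: bool = False


def summarize_timecourse(tc: TimeCourseExperiment) -> ProfileMatrix:
    """Mean over non-missing replicates per (protein, line, drug, time);
    missing only where every replicate is missing."""
    grouped = tc.values.T.groupby(level=["cell_line", "drug", "time_h"])
    values = grouped.mean().T
    counts = grouped.count().T
    return ProfileMatrix(values, counts)


# ---------------------------------------------------------------------------
# IC50 screen
# ---------------------------------------------------------------------------

def _masked_pearson(X: np.ndarray, y: np.ndarray):
    """Row-wise Pearson r of X (features x lines, NaN allowed) against y."""
    mask = ~np.isnan(X)
    n = mask.sum(axis=1)
    Xz = np.where(mask, X, 0.0)
    sx = Xz.sum(axis=1)
    sxx = (Xz ** 2).sum(axis=1)
    sy = mask @ y
    syy = mask @ (y ** 2)
    sxy = Xz @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt((n * sxx - sx ** 2) * (n * syy - sy ** 2))
        r = num / den
    r[(n < 3) | ~np.isfinite(r)] = np.nan
    return r


def ic50_screen(profiles: ProfileMatrix, response: DrugResponseTable,
                tau: float = 0.7, max_missing_timepoints: int = 1
                ) -> pd.DataFrame:
    """Per (drug, protein): per-time-point Pearson r of expression with log10
    IC50 across cell lines, mean r over computable time points, and a class
    call (resistance if mean r > tau, sensitivity if mean r < -tau).

    A protein is eligible only if fewer than two time points lack a
    computable correlation (pairwise-complete, >= 3 lines, non-degenerate).
    """
    times = profiles.time_points_h
    all_lines = sorted(set(profiles.values.columns.get_level_values("cell_line")))
    drugs = sorted(set(profiles.values.columns.get_level_values("drug")))
    features = profiles.values.index
    frames = []
    for drug in drugs:
        lines = [l for l in all_lines
                 if l in response.values.index
                 and not np.isnan(response.values.at[l, drug])]
        if len(lines) < 3:
            raise ValueError(f"drug {drug!r}: need >= 3 lines with response")
        y = response.values.loc[lines, drug].to_numpy(dtype=float)
        rs = {}
        for t in times:
            cols = [(l, drug, t) for l in lines]
            X = profiles.values.loc[:, cols].to_numpy(dtype=float)
            rs[f"r_{t:g}h"] = _masked_pearson(X, y)
        df = pd.DataFrame(rs, index=features)
        n_missing = df.isna().sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_r = df.mean(axis=1)
        eligible = n_missing <= max_missing_timepoints
        cls = np.where(
            eligible & (mean_r > tau), "resistance_associated",
            np.where(eligible & (mean_r < -tau), "sensitivity_associated",
                     "none"),
        )
        df["mean_r"] = mean_r.where(eligible)
        df["eligible"] = eligible
        df["ic50_class"] = cls
        df["drug"] = drug
        frames.append(df.reset_index(names="feature"))
    out = pd.concat(frames, ignore_index=True)
    return out.set_index(["drug", "feature"])


# ---------------------------------------------------------------------------
# trend statistics
# ---------------------------------------------------------------------------

def _anova_across_times(data: np.ndarray, n_times: int, n_reps: int):
    """Vectorised one-way ANOVA per row; groups are the time points.

    ``data`` is features x (time * replicate), replicate fastest.  Returns
    (p, per-time means, tested flag).
    """
    cube = data.reshape(data.shape[0], n_times, n_reps)
    obs = ~np.isnan(cube)
    n_t = obs.sum(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_t = np.nanmean(cube, axis=2)
        var_t = np.nanvar(cube, axis=2, ddof=1)
    groups = n_t >= 1
    k = groups.sum(axis=1)
    N = n_t.sum(axis=1)
    nz_mean = np.where(groups, mean_t, 0.0)
    grand = np.where(N > 0, (n_t * nz_mean).sum(axis=1) / np.maximum(N, 1),
                     np.nan)
    ssb = (n_t * (nz_mean - grand[:, None]) ** 2 * groups).sum(axis=1)
    ssw = (np.maximum(n_t - 1, 0) * np.where(n_t >= 2, var_t, 0.0)).sum(axis=1)
    df1 = k - 1
    df2 = N - k
    tested = (df1 >= 1) & (df2 >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ssb / df1) / (ssw / df2)
        p = stats.f.sf(F, df1, df2)
    # degenerate within-group variance: flat -> no evidence, shifted -> certain
    degen = tested & (ssw <= 1e-300)
    p = np.where(degen & (ssb <= 1e-300), 1.0, p)
    p = np.where(degen & (ssb > 1e-300), 0.0, p)
    p = np.where(tested, p, np.nan)
    return p, mean_t, tested


def _monotone_direction(mean_t: np.ndarray, times: np.ndarray,
                        rho_threshold: float) -> np.ndarray:
    """Direction call per row: sign(last - first) where the mean profile is
    monotone-consistent (Spearman |rho| vs time >= threshold), else 0."""
    n_rows, n_times = mean_t.shape
    direction = np.zeros(n_rows, dtype=int)
    first, last = mean_t[:, 0], mean_t[:, -1]
    complete = ~np.isnan(mean_t).any(axis=1)
    if complete.any():
        ranks = stats.rankdata(mean_t[complete], axis=1)
        tr = stats.rankdata(times)
        rc = ranks - ranks.mean(axis=1, keepdims=True)
        tc_ = tr - tr.mean()
        denom = np.sqrt((rc ** 2).sum(axis=1) * (tc_ ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rc @ tc_) / denom
        ok = np.isfinite(rho) & (np.abs(rho) >= rho_threshold)
        idx = np.where(complete)[0]
        sign = np.sign(last[idx] - first[idx]).astype(int)
        direction[idx[ok]] = sign[ok]
    # rows with missing time-point means: small fallback loop
    for i in np.where(~complete)[0]:
        prof = mean_t[i]
        ok_m = ~np.isnan(prof)
        if np.isnan(first[i]) or np.isnan(last[i]) or ok_m.sum() < 3:
            continue
        if np.std(prof[ok_m]) == 0:
            continue
        rho = stats.spearmanr(times[ok_m], prof[ok_m]).statistic
        if np.isfinite(rho) and abs(rho) >= rho_threshold:
            direction[i] = int(np.sign(last[i] - first[i]))
    return direction


def trend_table(tc: TimeCourseExperiment, monotone_rho: float = 0.8
                ) -> pd.DataFrame:
    """Trend statistics for every (feature, cell line, drug).

    Columns: ``anova_p`` (one-way ANOVA of log2 replicate values across time
    points), ``adj_p`` (B-H within each line x drug family), ``log2_fc`` and
    ``last_first_fc`` (72 h vs 0 h replicate means), ``direction``
    (+1 / -1 / 0 per the monotone-consistency gate) and ``tested``.
    """
    times = np.array(tc.time_points_h, dtype=float)
    features = tc.feature_ids
    frames = []
    for line in tc.cell_lines:
        for drug in tc.drugs:
            sub = tc.values.loc[:, (line, drug)]
            sub = sub.sort_index(axis=1, level=["time_h", "replicate"])
            n_reps = sub.shape[1] // len(times)
            data = sub.to_numpy(dtype=float)
            p, mean_t, tested = _anova_across_times(data, len(times), n_reps)
            adj = np.full(len(p), np.nan)
            if tested.any():
                adj[tested] = bh_adjust(p[tested])
            log2_fc = mean_t[:, -1] - mean_t[:, 0]
            direction = _monotone_direction(mean_t, times, monotone_rho)
            frames.append(pd.DataFrame({
                "feature": features,
                "cell_line": line,
                "drug": drug,
                "anova_p": p,
                "adj_p": adj,
                "log2_fc": log2_fc,
                "last_first_fc": np.power(2.0, log2_fc),
                "direction": direction,
                "tested": tested,
            }))
    return pd.concat(frames, ignore_index=True)


def trend_stats(tc: TimeCourseExperiment, protein: str, line: str, drug: str,
                monotone_rho: float = 0.8):
    """ANOVA p, last-vs-first fold change and direction for one triple
    (raw p; see :func:`trend_table` for the B-H-adjusted family)."""
    table = trend_table(tc, monotone_rho)
    row = table[(table["feature"] == protein)
                & (table["cell_line"] == line) & (table["drug"] == drug)]
    if row.empty:
        raise KeyError((protein, line, drug))
    r = row.iloc[0]
    return float(r["anova_p"]), float(r["last_first_fc"]), int(r["direction"])


# ---------------------------------------------------------------------------
# opposite dynamics
# ---------------------------------------------------------------------------

def _group_direction(calls: pd.DataFrame, group_lines: list[str]) -> pd.Series:
    """Per feature: +1/-1 if that direction is qualified in a strict majority
    of the group's lines, else 0."""
    need = len(group_lines) / 2.0
    sub = calls[calls["cell_line"].isin(group_lines) & calls["qualified"]]
    counts = sub.groupby(["feature", "direction"])["cell_line"].nunique()
    out = {}
    for (feature, direction), n in counts.items():
        if n > need:
            out[feature] = direction
    return pd.Series(out, dtype=float)


def opposite_dynamics_select(tc: TimeCourseExperiment,
                             p_threshold: float = 0.05,
                             fc_threshold: float = 2.0,
                             monotone_rho: float = 0.8,
                             intersect_drugs: bool = False
                             ) -> DynamicsSelection:
    """Proteins whose time-course direction is consistent within TNBC lines
    and reversed in non-TNBC lines.

    A (protein, line, drug) call is *qualified* when the B-H-adjusted ANOVA p
    (within the line x drug family) is below ``p_threshold``, the last-vs-
    first fold change exceeds ``fc_threshold`` in magnitude, and the profile
    passes the monotone-consistency gate.  Per drug, a protein is selected
    when a strict majority of TNBC lines share a qualified direction and a
    strict majority of non-TNBC lines share the opposite one.  The final set
    is the union over drugs (intersection with ``intersect_drugs``).
    """
    tnbc_lines = tc.tnbc_lines()
    non_lines = tc.non_tnbc_lines()
    if not tnbc_lines or not non_lines:
        raise ValueError("need both TNBC and non-TNBC lines")
    table = trend_table(tc, monotone_rho)
    log2_thr = math.log2(fc_threshold)
    table["qualified"] = (
        table["tested"]
        & (table["adj_p"] < p_threshold)
        & (table["log2_fc"].abs() > log2_thr)
        & (table["direction"] != 0)
    )
    per_drug: dict[str, pd.DataFrame] = {}
    sets = []
    for drug in tc.drugs:
        calls = table[table["drug"] == drug]
        d_t = _group_direction(calls, tnbc_lines)
        d_n = _group_direction(calls, non_lines)
        common = d_t.index.intersection(d_n.index)
        opposite = [f for f in common if d_t[f] == -d_n[f]]
        per_drug[drug] = pd.DataFrame({
            "tnbc_dir": d_t.reindex(opposite).astype(int),
            "non_tnbc_dir": d_n.reindex(opposite).astype(int),
        })
        sets.append(set(opposite))
    if intersect_drugs:
        selected = set.intersection(*sets) if sets else set()
    else:
        selected = set.union(*sets) if sets else set()
    return DynamicsSelection(
        selected=sorted(selected), per_drug=per_drug,
        calls=table[table["qualified"]].copy(),
        intersect_drugs=intersect_drugs,
    )


def pathway_consistency(selection: DynamicsSelection,
                        pathways: PathwayAnnotation,
                        tc: TimeCourseExperiment,
                        tnbc_min: float = 3 / 5,
                        non_tnbc_min: float = 2 / 4) -> pd.DataFrame:
    """Pathway pass table: a pathway passes when at least
    ``ceil(tnbc_min * n_tnbc)`` TNBC lines and ``ceil(non_tnbc_min * n_non)``
    non-TNBC lines each carry a qualified call on >= 1 selected protein of
    the pathway (thresholds inclusive)."""
    tnbc_lines = set(tc.tnbc_lines())
    non_lines = set(tc.non_tnbc_lines())
    need_t = math.ceil(tnbc_min * len(tnbc_lines) - 1e-9)
    need_n = math.ceil(non_tnbc_min * len(non_lines) - 1e-9)
    selected = set(selection.selected)
    calls = selection.calls[selection.calls["feature"].isin(selected)]
    rows = []
    for pid in sorted(pathways):
        members = pathways[pid] & selected
        hit_lines = set(calls.loc[calls["feature"].isin(members), "cell_line"])
        n_t = len(hit_lines & tnbc_lines)
        n_n = len(hit_lines & non_lines)
        rows.append((pid, len(members), n_t, n_n,
                     n_t >= need_t and n_n >= need_n))
    return pd.DataFrame(
        rows, columns=["pathway_id", "n_selected_members",
                       "n_tnbc_lines_hit", "n_non_tnbc_lines_hit", "passes"]
    ).set_index("pathway_id")


# ---------------------------------------------------------------------------
# persistently dysregulated proteins
# ---------------------------------------------------------------------------

def pdp_detect(tc: TimeCourseExperiment, drug: str,
               frac_threshold: float = 0.6, p_threshold: float = 0.05,
               fc_up: float = 1.5, fc_down: float = 0.67) -> list[str]:
    """Proteins differentially expressed between 0 h and 72 h (t-test, B-H
    within each line, joint fold-change thresholds) in strictly more than
    ``frac_threshold`` of the TNBC lines treated with ``drug``."""
    times = tc.time_points_h
    t_last = times[-1]
    dep_flags = {}
    for line in tc.tnbc_lines():
        cols0 = tc.condition(line, drug, 0.0)
        cols1 = tc.condition(line, drug, t_last)
        if cols1.notna().sum().sum() == 0:
            logger.warning("line %s lacks %gh data for %s; excluded",
                           line, t_last, drug)
            continue
        both = pd.concat([cols0, cols1], axis=1)
        both.columns = ([f"t0_r{i}" for i in range(cols0.shape[1])]
                        + [f"t1_r{i}" for i in range(cols1.shape[1])])
        keep = both.notna().any(axis=1)
        m = OmicsMatrix("protein", both.loc[keep])
        labels = np.array([c.startswith("t1") for c in both.columns])
        dep = differential_expression(m, labels, p_threshold, fc_up, fc_down)
        dep_flags[line] = dep["is_dep"].reindex(tc.feature_ids,
                                                fill_value=False)
    if not dep_flags:
        return []
    flags = pd.DataFrame(dep_flags)
    frac = flags.mean(axis=1)
    return sorted(flags.index[frac > frac_threshold])
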