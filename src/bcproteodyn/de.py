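"""TNBC vs non-TNBC differential expression on log2 abundance matrices.

Per feature: a two-tailed unpaired Student's t test on log2 values (equal
variance by default, Welch behind a flag), a fold change from the difference
of log2 group means (i.e. a geometric-mean ratio on the linear scale),
Benjamini-Hochberg adjustment across all *tested* features, and a joint
adjusted-p / fold-change call:

    DEP  <=>  adjusted p < 0.05  and  (FC > 1.5 or FC < 0.67)

Features with fewer than two observed values in either group are reported as
untested and excluded from the B-H family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix, logger


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( p_(j) * n / j ), capped at 1, for the ascending
    order statistics p_(1) <= ... <= p_(n).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(values: np.ndarray, cols: np.ndarray):
    sub = values[:, cols]
    n = np.sum(~np.isnan(sub), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(sub, axis=1)
        var = np.nanvar(sub, axis=1, ddof=1)
    return n, mean, var


def differential_expression(m: OmicsMatrix, group_labels,
                            p_threshold: float = 0.05,
                            fc_up: float = 1.5, fc_down: float = 0.67,
                            equal_var: bool = True) -> pd.DataFrame:
    """Feature-wise differential-expression table between two groups.

    Parameters
    ----------
    group_labels
        Boolean array over ``m.sample_ids``: True = group 1 (e.g. TNBC),
        False = group 2.  Fold change is group1 over group2.

    Returns a frame indexed by feature with columns ``mean_log2_g1``,
    ``mean_log2_g2``, ``log2_fold_change``, ``fold_change``, ``p_value``,
    ``adjusted_p``, ``tested`` and ``is_dep``.
    """
    labels = np.asarray(group_labels, dtype=bool)
    if labels.shape[0] != m.shape[1]:
        raise ValueError("group_labels length must match the sample count")
    if labels.all() or not labels.any():
        raise ValueError("both groups must be non-empty")
    values = m.values.to_numpy(dtype=float)
    n1, m1, v1 = _group_stats(values, np.where(labels)[0])
    n2, m2, v2 = _group_stats(values, np.where(~labels)[0])
    tested = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        if equal_var:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = (m1 - m2) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero pooled variance: identical groups -> no evidence; unequal means
    # with zero variance -> certain difference
    degenerate = tested & ~np.isfinite(t)
    p = np.where(degenerate & (m1 == m2), 1.0, p)
    p = np.where(degenerate & (m1 != m2), 0.0, p)

    log2_fc = m1 - m2
    fc = np.power(2.0, log2_fc)
    adjusted = np.full(len(p), np.nan)
    if tested.any():
        adjusted[tested] = bh_adjust(p[tested])
    is_dep = tested & (adjusted < p_threshold) & ((fc > fc_up) | (fc < fc_down))
    return pd.DataFrame(
        {
            "mean_log2_g1": m1, "mean_log2_g2": m2,
            "log2_fold_change": log2_fc, "fold_change": fc,
            "p_value": np.where(tested, p, np.nan),
            "adjusted_p": adjusted,
            "tested": tested, "is_dep": is_dep,
        },
        index=m.values.index,
    )


def select_signature(dep: pd.DataFrame, n: int = 38) -> list[str]:
    """The ``n`` most significant DEPs: smallest adjusted p, ties broken by
    larger absolute log2 fold change, then feature id.  If fewer DEPs exist,
    all of them are returned with a warning."""
    deps = dep[dep["is_dep"]].copy()
    if len(deps) < n:
        logger.warning("only %d DEPs available for a signature of %d",
                       len(deps), n)
    deps["_neg_abs_lfc"] = -deps["log2_fold_change"].abs()
    deps["_feature"] = deps.index
    deps = deps.sort_values(by=["adjusted_p", "_neg_abs_lfc", "_feature"],
                            kind="mergesort")
    return list(deps.index[:n])


def signature_separation(m: OmicsMatrix, group_labels, signature) -> float:
    """Mean silhouette of the two group labels in the signature subspace
    (correlation distance over complete-case signature features) — a
    label-agnostic score of how well the signature separates the groups."""
    signature = list(signature)
    if len(signature) < 2:
        raise ValueError("signature must contain at least 2 features")
    absent = [f for f in signature if f not in m.values.index]
    if absent:
        raise ValueError(f"signature feature(s) absent from matrix: {absent}")
    sub = m.values.loc[signature].dropna(axis=0, how="any")
    if len(sub) < 2:
        raise ValueError("fewer than 2 complete-case signature features")
    labels = np.asarray(group_labels, dtype=bool)
    X = sub.to_numpy(dtype=float).T   # samples x features
    return float(silhouette_score(X, labels, metric="correlation"))
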