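"""Within-complex subunit co-expression at the protein and transcript levels.

Curated protein complexes are mapped onto a cell-line-averaged expression
matrix; every unordered pair of co-quantified subunits contributes one
Pearson correlation across cell lines.  Comparing the distributions of pair
correlations between the protein and transcript layers quantifies how much
more tightly complex subunits co-express as proteins than as mRNAs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .io import ComplexCatalog, OmicsMatrix


def enumerate_pairs(cat: ComplexCatalog, m: OmicsMatrix) -> pd.DataFrame:
    """All unordered member pairs of each complex with both members in ``m``.

    A complex is *matched* if it contributes at least one pair; singleton
    complexes (or those with fewer than two quantified members) contribute
    none.  Members are ordered lexicographically within a pair.
    """
    present = set(m.feature_ids)
    rows = []
    for cid in sorted(cat):
        members = sorted(mem for mem in cat[cid] if mem in present)
        rows.extend(
            (cid, a, b) for a, b in itertools.combinations(members, 2)
        )
    return pd.DataFrame(rows, columns=["complex_id", "feature_a", "feature_b"])


def matched_complexes(pairs: pd.DataFrame) -> list[str]:
    return sorted(pairs["complex_id"].unique())


def pair_correlations(pairs: pd.DataFrame, m: OmicsMatrix, level: str,
                      min_co_observed: int = 3) -> pd.DataFrame:
    """Pearson r per subunit pair on pairwise-complete cell-line values.

    Pairs with fewer than ``min_co_observed`` co-observed lines, or with a
    zero-variance member over the co-observed lines, are dropped; the returned
    frame carries a ``dropped_reason`` column ("" for retained rows) so the
    attrition is auditable.
    """
    values = m.values
    out = []
    for cid, fa, fb in pairs.itertuples(index=False):
        xa = values.loc[fa].to_numpy(dtype=float)
        xb = values.loc[fb].to_numpy(dtype=float)
        ok = ~(np.isnan(xa) | np.isnan(xb))
        n = int(ok.sum())
        if n < min_co_observed:
            out.append((cid, fa, fb, level, np.nan, n, "too_few_co_observed"))
            continue
        sa, sb = xa[ok], xb[ok]
        if sa.std() == 0 or sb.std() == 0:
            out.append((cid, fa, fb, level, np.nan, n, "zero_variance"))
            continue
        r = float(np.corrcoef(sa, sb)[0, 1])
        out.append((cid, fa, fb, level, r, n, ""))
    return pd.DataFrame(
        out,
        columns=["complex_id", "feature_a", "feature_b", "level",
                 "pearson_r", "n_samples_used", "dropped_reason"],
    )


def compare_levels(protein_rs, transcript_rs):
    """Two-tailed unpaired equal-variance t-test between the two lists of
    pair correlations (protein vs transcript), as in the published figure
    legend — run on the raw r values, not Fisher-z transforms.

    Returns ``(t_statistic, p_value, median_protein_r, median_transcript_r)``.
    """
    a = np.asarray(protein_rs, dtype=float)
    b = np.asarray(transcript_rs, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 correlations per level for the t-test")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), float(np.median(a)), float(np.median(b))


def top_pairs(table: pd.DataFrame, n: int = 10,
              level: str | None = None) -> pd.DataFrame:
    """The ``n`` pairs with the largest correlation (at one level if given);
    ties broken by (complex_id, feature_a, feature_b) lexicographic order."""
    if table.empty:
        raise ValueError("empty pair-correlation table")
    t = table[table["pearson_r"].notna()]
    if level is not None:
        t = t[t["level"] == level]
    t = t.sort_values(
        by=["pearson_r", "complex_id", "feature_a", "feature_b"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    return t.head(n).reset_index(drop=True)
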