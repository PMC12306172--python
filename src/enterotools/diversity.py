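"""Rarefaction, alpha-diversity estimation and group comparison.

Counts are rarefied once (single draw, seed recorded by the caller) to a
common depth by exact without-replacement subsampling, then per-sample
Shannon, Gini-Simpson, Chao1 (bias-corrected), ACE and observed richness
are computed. Two groups are compared per index with the Wilcoxon rank-sum
test; all indices jointly non-significant at 0.05 flags the groups as
having comparable alpha diversity.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import alpha as _alpha

from .io import AbundanceTable

INDICES = ("shannon", "simpson", "chao1", "ace", "observed")
ALPHA_LEVEL = 0.05


def rarefy(table: AbundanceTable, depth: int | None = None, seed: int = 0) -> AbundanceTable:
    """Subsample every sample column without replacement to ``depth``.

    ``depth`` defaults to the minimum sample total. Sampling treats each
    column as a multiset of individual observations (multivariate
    hypergeometric draw), so totals are conserved exactly and no count
    increases.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    shallow = [table.sample_ids[i] for i in np.flatnonzero(totals < depth)]
    if shallow:
        raise ValueError(
            f"depth {depth} exceeds total count of sample(s): {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return AbundanceTable(
        list(table.taxon_ids), list(table.sample_ids), out, table.lineages
    )


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.sum() <= 0:
        raise ValueError("count vector has zero total")
    return c


def shannon(counts, base: float = math.e) -> float:
    """Shannon entropy H = -sum p_i log p_i (natural log by default)."""
    return float(_alpha.shannon(_check_counts(counts), base=base))


def simpson(counts, gini: bool = True) -> float:
    """Gini-Simpson 1 - sum p_i^2 (or the raw dominance sum p_i^2)."""
    c = _check_counts(counts)
    d = float(_alpha.dominance(c))
    return 1.0 - d if gini else d


def observed(counts) -> int:
    return int(np.count_nonzero(_check_counts(counts)))


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    return float(_alpha.chao1(_check_counts(counts), bias_corrected=True))


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator with rare/abundant cutoff.

    Falls back to Chao1 when the sample coverage of the rare fraction is
    zero (every rare taxon a singleton), where the ACE formula is undefined.
    """
    c = _check_counts(counts)
    c = c[c > 0]
    f1 = int(np.sum(c == 1))
    n_rare = int(c[c <= rare_cutoff].sum())
    if n_rare == 0:  # no rare taxa: estimator reduces to observed richness
        return float(len(c))
    if f1 == n_rare:  # C_ACE = 0
        return chao1(counts)
    return float(_alpha.ace(c, rare_threshold=rare_cutoff))


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample diversity table with columns from :data:`INDICES`."""
    rows = {}
    for j, sid in enumerate(table.sample_ids):
        c = table.counts[:, j]
        rows[sid] = {
            "shannon": shannon(c),
            "simpson": simpson(c),
            "chao1": chao1(c),
            "ace": ace(c),
            "observed": observed(c),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df[list(INDICES)]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when n1 + n2 <= 20 without ties; otherwise the normal
    approximation with tie and continuity corrections. Returns the
    Mann-Whitney U statistic for ``x`` and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_alpha(diversity: pd.DataFrame, labels: pd.Series | dict) -> pd.DataFrame:
    """Wilcoxon test per diversity index between exactly two label groups.

    Returns a table with columns ``index, statistic, p_value`` plus a
    ``comparable`` attribute-style column: True on every row when no index
    differs at the 0.05 level, mirroring the call of "comparable alpha
    diversity" between enterotype clusters.
    """
    labels = pd.Series(labels)
    labels = labels.loc[diversity.index]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    a = diversity.loc[labels == groups[0]]
    b = diversity.loc[labels == groups[1]]
    rows = []
    for idx in INDICES:
        stat, p = wilcoxon_rank_sum(a[idx].to_numpy(), b[idx].to_numpy())
        rows.append({"index": idx, "statistic": stat, "p_value": p})
    out = pd.DataFrame(rows)
    out["comparable"] = bool((out["p_value"] >= ALPHA_LEVEL).all())
    return out
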