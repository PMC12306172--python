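"""Differential testing of functional-pathway abundances between clusters.

Consumes a predicted pathway-abundance table (e.g. PICRUSt2/KEGG output,
any hierarchy level) and tests each pathway between the two enterotype
clusters with the Wilcoxon rank-sum test, reporting the direction of the
median shift and the count and percentage of significant pathways. No
multiple-testing adjustment is applied by default; Benjamini-Hochberg is
available via ``adjust='bh'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import wilcoxon_rank_sum


@dataclass
class PathwayTable:
    """Pathways x samples non-negative real abundances with level tags."""

    pathway_ids: list[str]
    levels: list[int]
    sample_ids: list[str]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.pathway_ids), len(self.sample_ids)):
            raise ValueError("abundance shape mismatch")
        if np.any(self.abundances < 0):
            raise ValueError("pathway abundances must be non-negative")
        seen = set()
        for pid, lev in zip(self.pathway_ids, self.levels):
            if (pid, lev) in seen:
                raise ValueError(f"duplicate pathway id {pid!r} at level {lev}")
            seen.add((pid, lev))


def read_pathway_table(path: str | Path) -> PathwayTable:
    """TSV with columns ``#Pathway``, ``level``, then one per sample."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "#Pathway" or df.columns[1] != "level":
        raise ValueError("pathway table must start with '#Pathway' and 'level' columns")
    return PathwayTable(
        pathway_ids=df["#Pathway"].astype(str).tolist(),
        levels=df["level"].astype(int).tolist(),
        sample_ids=list(df.columns[2:]),
        abundances=df.iloc[:, 2:].to_numpy(float),
    )


def write_pathway_table(table: PathwayTable, path: str | Path) -> None:
    df = pd.DataFrame(table.abundances, columns=table.sample_ids)
    df.insert(0, "level", table.levels)
    df.insert(0, "#Pathway", table.pathway_ids)
    df.to_csv(path, sep="\t", index=False)


def significant_fraction(n_significant: int, n_total: int) -> float:
    """Percentage of significant pathways, rounded to 2 decimals."""
    if n_total <= 0 or not 0 <= n_significant <= n_total:
        raise ValueError("need 0 <= n_significant <= n_total with n_total > 0")
    return round(100.0 * n_significant / n_total, 2)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def compare_pathways(table: PathwayTable, labels, alpha: float = 0.05,
                     adjust: str = "none", level: int | None = None
                     ) -> tuple[pd.DataFrame, int, float]:
    """Wilcoxon rank-sum per pathway between two clusters.

    Returns ``(per-pathway table, n_significant, percent_significant)``;
    the percentage is rounded to 2 decimals. ``direction`` is the sign of
    the median difference (group1 minus group0).
    """
    labels = pd.Series(labels)
    labels = labels.loc[table.sample_ids]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    mask0 = (labels == groups[0]).to_numpy()
    mask1 = (labels == groups[1]).to_numpy()
    if mask0.sum() < 2 or mask1.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    keep = range(len(table.pathway_ids)) if level is None else [
        i for i, lev in enumerate(table.levels) if lev == level
    ]
    rows = []
    for i in keep:
        a = table.abundances[i, mask0]
        b = table.abundances[i, mask1]
        stat, p = wilcoxon_rank_sum(a, b)
        rows.append({
            "pathway": table.pathway_ids[i],
            "level": table.levels[i],
            "statistic": stat,
            "p_value": p,
            "direction": int(np.sign(np.median(b) - np.median(a))),
        })
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
        sig = out["p_adjusted"] < alpha
    elif adjust == "none":
        out["p_adjusted"] = out["p_value"]
        sig = out["p_value"] < alpha
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["significant"] = sig
    n_sig = int(sig.sum())
    percent = significant_fraction(n_sig, len(out))
    return out, n_sig, percent
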