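"""mRNA count normalization and bound/unbound group comparison.

Size factors follow the median-of-ratios construction (per-sample median of
count/geometric-mean over genes with all-positive counts).  Per-gene log2
fold changes are computed on size-factor-normalized means with a small
pseudo-expression, after excluding genes with any raw count below 1.  The
group comparison reports median log2 fold changes, the median fold change
with its orientation, and a two-tailed equal-variance t-test between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONTROL, DEPLETED = "control", "depleted"


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column)."""
    if (matrix < 0).any().any():
        raise ValueError("counts must be non-negative")
    positive = matrix[(matrix > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has positive counts in every sample")
    logs = np.log(positive.to_numpy(dtype=float))
    log_gmean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_gmean, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    factors = size_factors(matrix) if factors is None else factors
    return matrix / factors


def gene_log2fc(matrix: pd.DataFrame, condition_map: dict[str, str],
                min_raw: float = 1.0, eps: float = 0.5,
                exclude_rule: str = "any") -> pd.Series:
    """Per-gene log2(depleted / control) on normalized mean counts.

    Genes with any sample's raw count < ``min_raw`` are excluded
    (``exclude_rule='sum'`` switches to excluding on the summed raw count).
    ``eps`` is a pseudo-expression keeping low-count genes finite.
    """
    ctrl = [s for s, c in condition_map.items() if c == CONTROL]
    depl = [s for s, c in condition_map.items() if c == DEPLETED]
    if not ctrl or not depl:
        raise ValueError("both 'control' and 'depleted' conditions are required")
    if exclude_rule == "any":
        keep = (matrix >= min_raw).all(axis=1)
    elif exclude_rule == "sum":
        keep = matrix.sum(axis=1) >= min_raw
    else:
        raise ValueError("exclude_rule must be 'any' or 'sum'")
    norm = normalize(matrix)[keep]
    mean_c = norm[ctrl].mean(axis=1)
    mean_d = norm[depl].mean(axis=1)
    return pd.Series(
        np.log2((mean_d + eps) / (mean_c + eps)), index=norm.index, name="log2fc"
    )


@dataclass
class GroupComparison:
    median_log2fc: dict[str, float]
    median_fold_change: dict[str, float]   # 2**|median|, orientation labeled
    orientation: dict[str, str]            # "reduced" or "increased"
    p_value: float                         # two-tailed t-test, bound vs unbound
    n: dict[str, int]


def group_compare(log2fc: pd.Series, groups: pd.DataFrame) -> GroupComparison:
    """Compare bound vs unbound per-gene log2 fold changes.

    ``groups`` has columns [gene, group] with group in {bound, unbound} and
    an optional boolean ``germline`` column; the germline subset (when
    present) is summarized alongside the two groups.
    """
    g = groups.set_index("gene")
    if not set(g["group"]).issubset({"bound", "unbound"}):
        raise ValueError("groups must be 'bound' or 'unbound'")
    med, fc, orient, n = {}, {}, {}, {}
    subsets = {
        "bound": log2fc[log2fc.index.isin(g.index[g["group"] == "bound"])],
        "unbound": log2fc[log2fc.index.isin(g.index[g["group"] == "unbound"])],
    }
    if "germline" in g.columns:
        subsets["germline"] = log2fc[log2fc.index.isin(g.index[g["germline"].astype(bool)])]
    for name, vals in subsets.items():
        m = float(vals.median()) if len(vals) else float("nan")
        med[name] = m
        fc[name] = float(2.0 ** abs(m)) if np.isfinite(m) else float("nan")
        orient[name] = "reduced" if m < 0 else "increased"
        n[name] = int(len(vals))
    t, p = stats.ttest_ind(subsets["bound"], subsets["unbound"], equal_var=True)
    return GroupComparison(med, fc, orient, float(p), n)
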