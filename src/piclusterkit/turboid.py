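"""Proximity-labeling (TurboID) spectral-count enrichment.

Raw spectral counts are scaled to a common library size (total-count
normalization to the mean sample total), fold changes use a pseudocount of
0.1 in both numerator and denominator, and significance comes from a
one-tailed (tagged > control) equal-variance two-sample t-test.  The
published filter keeps proteins with tagged mean normalized counts >= 2,
fold change >= 8 and P <= .05 (all inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

TAGGED, CONTROL = "tagged", "control"


def _split_samples(condition_map: dict[str, str]) -> tuple[list[str], list[str]]:
    tagged = [s for s, c in condition_map.items() if c == TAGGED]
    control = [s for s, c in condition_map.items() if c == CONTROL]
    if not tagged or not control:
        raise ValueError("both 'tagged' and 'control' conditions are required")
    return tagged, control


def normalize_counts(table: pd.DataFrame, enabled: bool = True) -> pd.DataFrame:
    """Scale each sample by (mean total across samples) / (sample total).

    Column totals are equal afterwards.  ``enabled=False`` returns the raw
    table unchanged (the no-normalization alternative).
    """
    if (table < 0).any().any():
        raise ValueError("spectral counts must be non-negative")
    if not enabled:
        return table.copy()
    totals = table.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("a sample has zero total counts")
    return table * (totals.mean() / totals)


def enrichment_stats(norm_table: pd.DataFrame, condition_map: dict[str, str],
                     pseudocount: float = 0.1,
                     pseudocount_denominator_only: bool = False) -> pd.DataFrame:
    """Per-protein fold change and one-tailed t-test p-value.

    Fold change = (mean_tagged + pc) / (mean_control + pc); the
    denominator-only pseudocount variant is available behind a flag.  For
    degenerate zero-variance rows the one-tailed convention is p = 0.5 when
    the group means are equal, 0 when tagged > control, 1 otherwise.
    """
    tagged, control = _split_samples(condition_map)
    if len(tagged) < 2 or len(control) < 2:
        raise ValueError("the t-test needs >= 2 replicates per condition")
    t_vals = norm_table[tagged].to_numpy(dtype=float)
    c_vals = norm_table[control].to_numpy(dtype=float)
    mean_t, mean_c = t_vals.mean(axis=1), c_vals.mean(axis=1)
    num = mean_t + (0.0 if pseudocount_denominator_only else pseudocount)
    fc = num / (mean_c + pseudocount)

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance rows raise a precision warning; they are resolved
        # explicitly below under the one-tailed convention
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(t_vals, c_vals, axis=1, equal_var=True,
                                    alternative="greater")
    diff = mean_t - mean_c
    degenerate = np.isnan(p)
    p = np.where(degenerate & (diff == 0), 0.5, p)
    p = np.where(degenerate & (diff > 0), 0.0, p)
    p = np.where(degenerate & (diff < 0), 1.0, p)

    with np.errstate(divide="ignore"):
        log2fc = np.log2(fc)
    return pd.DataFrame(
        {
            "mean_tagged": mean_t,
            "mean_control": mean_c,
            "fold_change": fc,
            "log2_fold_change": log2fc,
            "p_value": p,
        },
        index=norm_table.index,
    )


def filter_enriched(rows: pd.DataFrame, min_norm_count: float = 2.0,
                    min_fc: float = 8.0, max_p: float = 0.05) -> pd.DataFrame:
    """Enriched set: tagged mean >= min_norm_count AND fc >= min_fc AND
    p <= max_p, every bound inclusive."""
    mask = (
        (rows["mean_tagged"] >= min_norm_count)
        & (rows["fold_change"] >= min_fc)
        & (rows["p_value"] <= max_p)
    )
    return rows[mask]


def volcano_coords(rows: pd.DataFrame, fc_line: float = 8.0,
                   alpha: float = 0.05) -> pd.DataFrame:
    """(log2 fold change, -log10 p) coordinates with the threshold lines.

    log2(fc_line) = 3 for the published 8-fold line, so the volcano cut and
    the fold-change filter select the same proteins.
    """
    p = rows["p_value"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "x_log2fc": rows["log2_fold_change"],
            "y_neglog10p": -np.log10(np.clip(p, 1e-300, None)),
        },
        index=rows.index,
    )
    out.attrs["x_line"] = float(np.log2(fc_line))
    out.attrs["y_line"] = float(-np.log10(alpha))
    return out
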