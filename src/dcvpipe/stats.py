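"""Nested replicate ("SuperPlot") statistics, comparative-Ct qPCR fold
changes, and electron-microscopy morphometry derivations.

The SuperPlot convention treats the biological replicate (culture
preparation), not the cell or vesicle profile, as the experimental unit:
per-unit values are averaged within each replicate and the group comparison
is a two-sample t-test on replicate means.  qPCR fold changes use the
comparative-Ct (2^-ddCt) estimator with a housekeeping reference gene, and
inference runs on log2 fold changes, whose geometric mean summarizes the
effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SuperplotResult",
    "DdctResult",
    "superplot_compare",
    "ddct_fold_change",
    "morphometry_derive",
]


@dataclass
class SuperplotResult:
    replicate_means: pd.DataFrame  # columns: group, replicate, mean, n_units
    grand_means: dict[str, float]
    t: float
    df: int
    p: float


@dataclass
class DdctResult:
    per_pair: pd.DataFrame  # columns: pair, ddct, log2_fc, fold_change
    geometric_mean_fc: float
    geometric_sd_fc: float
    t: float | None
    df: int | None
    p: float | None


def superplot_compare(
    data: pd.DataFrame,
    group_a: str,
    group_b: str,
    *,
    group_col: str = "group",
    replicate_col: str = "replicate",
    value_col: str = "value",
    equal_var: bool = True,
) -> SuperplotResult:
    """Two-group comparison on biological-replicate means.

    Each replicate's units are averaged first; the two groups are then
    compared with a two-tailed unpaired Student t-test on those replicate
    means (``equal_var=False`` switches to Welch).  Replicates with zero
    units are excluded with a warning.
    """
    sub = data[data[group_col].isin([group_a, group_b])]
    reps = (
        sub.groupby([group_col, replicate_col], sort=True)[value_col]
        .agg(mean="mean", n_units="count")
        .reset_index()
    )
    empty = reps[reps["n_units"] == 0]
    if len(empty):
        warnings.warn(f"excluding {len(empty)} replicate(s) with zero units", stacklevel=2)
        reps = reps[reps["n_units"] > 0]

    a = reps.loc[reps[group_col] == group_a, "mean"].to_numpy()
    b = reps.loc[reps[group_col] == group_b, "mean"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group for a t-test on replicate means")

    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else None
    if np.isnan(t):  # identical constant groups: no variance, no difference
        t, p = 0.0, 1.0
    return SuperplotResult(
        replicate_means=reps.rename(columns={group_col: "group", replicate_col: "replicate"}),
        grand_means={group_a: float(a.mean()), group_b: float(b.mean())},
        t=float(t),
        df=df,
        p=float(p),
    )


def ddct_fold_change(
    table: pd.DataFrame,
    target_gene: str,
    control_condition: str,
    *,
    reference_gene: str = "Gapdh",
    condition_col: str = "condition",
    gene_col: str = "gene",
    ct_col: str = "ct",
    pair_col: str = "pair",
) -> DdctResult:
    """Comparative-Ct (2^-ddCt) fold change of a target gene.

    Per sample, dCt = Ct(target) - Ct(reference).  Per pair of samples
    (matched by ``pair_col`` across the two conditions), ddCt =
    dCt(condition) - dCt(control) and FC = 2^-ddCt.  The summary is the
    geometric mean (and geometric SD) of FC, and a two-tailed one-sample
    t-test of log2 FC against 0.  Pairs missing a reference or target Ct in
    either condition are dropped with a warning.
    """
    conditions = set(table[condition_col].unique())
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} not in table")
    test_conditions = conditions - {control_condition}
    if len(test_conditions) != 1:
        raise ValueError("table must contain the control plus exactly one test condition")
    test_condition = test_conditions.pop()

    def dct(pair: object, condition: str) -> float | None:
        sub = table[(table[pair_col] == pair) & (table[condition_col] == condition)]
        tgt = sub.loc[sub[gene_col] == target_gene, ct_col]
        ref = sub.loc[sub[gene_col] == reference_gene, ct_col]
        if len(tgt) != 1 or len(ref) != 1:
            return None
        return float(tgt.iloc[0]) - float(ref.iloc[0])

    rows = []
    for pair in pd.unique(table[pair_col]):
        d_test = dct(pair, test_condition)
        d_ctrl = dct(pair, control_condition)
        if d_test is None or d_ctrl is None:
            warnings.warn(f"pair {pair!r} lacks a target or reference Ct; dropped", stacklevel=2)
            continue
        ddct = d_test - d_ctrl
        rows.append(
            {"pair": pair, "ddct": ddct, "log2_fc": -ddct, "fold_change": 2.0 ** (-ddct)}
        )
    if not rows:
        raise ValueError("no complete sample pairs in the Ct table")
    per_pair = pd.DataFrame(rows)

    log2fc = per_pair["log2_fc"].to_numpy()
    geo_mean = float(2.0 ** log2fc.mean())
    geo_sd = float(2.0 ** log2fc.std(ddof=1)) if len(log2fc) > 1 else float("nan")
    if len(log2fc) > 1 and log2fc.std(ddof=1) > 0:
        t, p = sps.ttest_1samp(log2fc, 0.0)
        t, p, df = float(t), float(p), len(log2fc) - 1
    else:
        # zero variance (e.g. identical conditions): t-test undefined
        t = p = df = None
    return DdctResult(
        per_pair=per_pair,
        geometric_mean_fc=geo_mean,
        geometric_sd_fc=geo_sd,
        t=t,
        df=df,
        p=p,
    )


def morphometry_derive(
    d_control: float | None = None,
    d_test: float | None = None,
    p_control: float | None = None,
    p_test: float | None = None,
    diameters: np.ndarray | list[float] | None = None,
    bin_edges: np.ndarray | list[float] | None = None,
) -> dict:
    """Morphometry arithmetic on vesicle diameters and prevalence percentages.

    * ``volume_change_pct`` = 100 * (1 - (d_test / d_control)^3): the volume
      decrease implied by a mean-diameter decrease, assuming spherical
      vesicles.
    * ``relative_change_pct`` = 100 * (1 - p_test / p_control): the relative
      decrease of a prevalence percentage.
    * ``binned_fractions``: fraction of ``diameters`` in each half-open bin
      ``[lo, hi)`` of ``bin_edges``.
    """
    out: dict = {}
    if d_control is not None and d_test is not None:
        if d_control <= 0 or d_test <= 0:
            raise ValueError("diameters must be positive")
        out["volume_change_pct"] = 100.0 * (1.0 - (d_test / d_control) ** 3)
    if p_control is not None and p_test is not None:
        if not (0 <= p_test <= 100 and 0 < p_control <= 100):
            raise ValueError("percentages must lie in [0, 100] with p_control > 0")
        out["relative_change_pct"] = 100.0 * (1.0 - p_test / p_control)
    if diameters is not None and bin_edges is not None:
        diameters = np.asarray(diameters, dtype=float)
        if np.any(diameters <= 0):
            raise ValueError("diameters must be positive")
        edges = np.asarray(bin_edges, dtype=float)
        counts = np.array(
            [np.sum((diameters >= lo) & (diameters < hi)) for lo, hi in zip(edges[:-1], edges[1:])]
        )
        out["binned_fractions"] = counts / len(diameters)
        out["bin_edges"] = edges
    if not out:
        raise ValueError("no inputs given")
    return out
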