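"""Functional inference linking predicted gene families to dyeing intensity.

Three analyses share this module:

* subpathway percentage profiles and day-pair ratio selection — which
  functional subpathways are relatively enriched on strongly dyeing days
  versus weak ones (selection at ratio >= 1.05, highlight at mean ratio
  > 1.4 by default);
* taxon-stratified contribution decomposition — what share of a
  function's (or subpathway's) predicted abundance each taxon
  contributes, compared with that taxon's relative abundance;
* the CLR correlation screen — per gene family, the correlation of its
  centered log-ratio transformed abundance with the dyeing-intensity
  trajectory, selected at a caller threshold (0.9 for the fast-ORP-drop
  batch, 0.77 for the slow one).

Compositional predicted-abundance tables are CLR transformed before
correlation; zeros are multiplicatively replaced with half the smallest
nonzero proportion of their sample (the strategy is pluggable).
No multiple-testing correction is applied by default, matching the
original screen; Benjamini-Hochberg q-values are available on request.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

UNCLASSIFIED = "Unclassified"


# ---------------------------------------------------------------------------
# subpathway profiles and day-pair ratios


def subpathway_percentages(functions: pd.DataFrame,
                           hierarchy: pd.DataFrame) -> pd.DataFrame:
    """Per-sample percentage of total function abundance per subpathway.

    Functions absent from the hierarchy are binned as ``Unclassified``.
    Returns a subpathway x sample table whose columns sum to 100.
    """
    totals = functions.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise InputError(f"sample {zero[0]!r} has zero total function abundance")
    sub = hierarchy["subpathway"].reindex(functions.index).fillna(UNCLASSIFIED)
    grouped = functions.groupby(sub.values).sum()
    pct = grouped.div(totals, axis=1) * 100.0
    pct.index.name = "subpathway"
    return pct


def ratio_select(profiles: pd.DataFrame, sample_days: pd.Series,
                 pairs: list[tuple[int, int]],
                 select_threshold: float = 1.05,
                 highlight_threshold: float = 1.4) -> pd.DataFrame:
    """Day-pair subpathway percentage ratios with threshold selection.

    Replicate samples of a day are averaged before forming ratios. A
    subpathway is *selected* when any pair's ratio is >= the selection
    threshold and *highlighted* when the mean ratio over the pairs
    exceeds the highlight threshold. Subpathways whose denominator-day
    percentage is zero in some pair get that ratio as NaN, are excluded
    from selection, and are logged.
    """
    if select_threshold <= 0 or highlight_threshold <= 0:
        raise InputError("ratio thresholds must be positive")
    days = pd.Series(sample_days).reindex(profiles.columns)
    if days.isna().any():
        missing = days.index[days.isna()][0]
        raise InputError(f"no day recorded for sample {missing!r}")
    by_day = profiles.T.groupby(days.values).mean().T  # subpathway x day

    result = pd.DataFrame(index=profiles.index)
    for num_day, den_day in pairs:
        for d in (num_day, den_day):
            if d not in by_day.columns:
                raise InputError(f"day {d} not present in the profiles")
        num = by_day[num_day]
        den = by_day[den_day]
        ratio = num / den.replace(0.0, np.nan)
        result[f"D{num_day}/D{den_day}"] = ratio

    undefined = result.isna().any(axis=1)
    if undefined.any():
        logger.warning(
            "%d subpathways with an undefined (zero-denominator) ratio "
            "excluded from selection: %s",
            int(undefined.sum()),
            ", ".join(map(str, result.index[undefined][:5])),
        )
    ratios = result.copy()
    result["selected"] = (ratios >= select_threshold).any(axis=1) & ~undefined
    result["highlighted"] = (ratios.mean(axis=1) > highlight_threshold) & ~undefined
    return result


# ---------------------------------------------------------------------------
# taxon-stratified contribution decomposition


def taxon_contribution(strat: pd.DataFrame, function_ids, sample_id,
                       rel_abundance: pd.Series | None = None) -> pd.DataFrame:
    """Per-taxon percentage of the summed contribution to a function set.

    For one sample, sums ``CountContributedByOTU`` over each taxon's
    OTUs and the requested functions, and normalizes over taxa to
    percentages. When per-taxon relative abundances are supplied they
    are attached for the over/under-representation comparison.
    """
    function_ids = list(function_ids)
    if not function_ids:
        raise InputError("empty function set")
    group_col = "taxon" if "taxon" in strat.columns else "OTU"
    rows = strat[(strat["Sample"] == sample_id) & strat["Gene"].isin(function_ids)]
    if rows.empty:
        raise InputError(
            f"no stratified rows for sample {sample_id!r} and the given functions"
        )
    contrib = rows.groupby(group_col)["CountContributedByOTU"].sum()
    total = contrib.sum()
    if total == 0:
        raise InputError(f"zero total contribution in sample {sample_id!r}")
    out = (contrib / total * 100.0).rename("contribution_pct").to_frame()
    out = out.sort_values("contribution_pct", ascending=False)
    if rel_abundance is not None:
        out["relative_abundance_pct"] = rel_abundance.reindex(out.index) * 100.0
    out.index.name = "taxon"
    return out


def otu_contribution_for_function(strat: pd.DataFrame, function_id,
                                  sample_id) -> pd.DataFrame:
    """Same decomposition restricted to one function.

    Returns an empty frame (with a warning) when no rows exist for the
    (function, sample) pair.
    """
    rows = strat[(strat["Sample"] == sample_id) & (strat["Gene"] == function_id)]
    if rows.empty:
        logger.warning("no stratified rows for function %r in sample %r",
                       function_id, sample_id)
        return pd.DataFrame(columns=["contribution_pct"])
    return taxon_contribution(strat, [function_id], sample_id)


# ---------------------------------------------------------------------------
# CLR transform and phenotype correlation


def _replace_zeros_multiplicative(props: np.ndarray) -> np.ndarray:
    """Replace zeros with 0.5 x the smallest nonzero proportion, then
    shrink nonzero parts multiplicatively so the column still sums to 1."""
    out = props.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        zeros = col == 0
        if not zeros.any():
            continue
        delta = 0.5 * col[col > 0].min()
        fill = delta * zeros.sum()
        col[zeros] = delta
        col[~zeros] *= 1.0 - fill
        out[:, j] = col
    return out


ZERO_STRATEGIES = {"multiplicative": _replace_zeros_multiplicative}


def clr_transform(functions: pd.DataFrame,
                  zero_replacement: str = "multiplicative") -> pd.DataFrame:
    """Centered log-ratio transform of a function x sample table.

    Per sample: close to proportions, replace zeros, take natural logs
    and subtract the sample's mean log. Each transformed column sums to
    zero.
    """
    if functions.shape[0] < 2:
        raise InputError("CLR needs at least 2 functions")
    if (functions.values < 0).any():
        raise InputError("negative abundances are not compositional")
    totals = functions.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise InputError(f"sample {zero[0]!r} has zero total abundance")
    try:
        replace = ZERO_STRATEGIES[zero_replacement]
    except KeyError:
        raise InputError(
            f"unknown zero-replacement strategy {zero_replacement!r}; "
            f"known: {sorted(ZERO_STRATEGIES)}"
        ) from None
    props = functions.div(totals, axis=1).to_numpy(dtype=float)
    if (props == 0).any():
        logger.info("zero replacement (%s) applied before CLR", zero_replacement)
    props = replace(props)
    logs = np.log(props)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=functions.index, columns=functions.columns)


def correlate_with_phenotype(clr_table: pd.DataFrame, phenotype: pd.Series,
                             method: str = "pearson",
                             threshold: float = 0.9,
                             bh_correction: bool = False,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Per-function correlation of CLR values with the phenotype.

    Functions with zero variance across samples have an undefined
    correlation (NaN) and are never selected. Selection is one-sided:
    ``r >= threshold``, matching a screen for functions that *increase*
    with dyeing intensity. With ``bh_correction`` a Benjamini-Hochberg
    q-value column is added and selection additionally requires
    ``q < alpha``.
    """
    if method not in ("pearson", "spearman"):
        raise InputError(f"unknown correlation method {method!r}")
    pheno = phenotype.reindex(clr_table.columns)
    if pheno.isna().any():
        missing = pheno.index[pheno.isna()][0]
        raise InputError(f"no phenotype value for sample {missing!r}")
    n = clr_table.shape[1]
    if n < 3:
        raise InputError("need at least 3 samples to correlate")

    y = pheno.to_numpy(dtype=float)
    x = clr_table.to_numpy(dtype=float)
    if method == "spearman":
        y = stats.rankdata(y)
        x = np.apply_along_axis(stats.rankdata, 1, x)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((sx > 0) & (sy > 0), (xc @ yc) / (sx * sy), np.nan)
    r = np.clip(r, -1.0, 1.0)

    out = pd.DataFrame({"r": r}, index=clr_table.index)
    out.index.name = "function_id"
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
    out["p"] = np.where(np.isnan(r), np.nan, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    out["selected"] = (out["r"] >= threshold).fillna(False)
    if bh_correction:
        valid = out["p"].notna()
        q = np.full(len(out), np.nan)
        if valid.any():
            q[valid.to_numpy()] = stats.false_discovery_control(
                out.loc[valid, "p"].to_numpy(), method="bh")
        out["q"] = q
        out["selected"] &= pd.Series(q, index=out.index) < alpha
    return out
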