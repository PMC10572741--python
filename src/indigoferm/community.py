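"""Relative abundance, prevalence filtering, rarefaction, alpha diversity."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError


def to_relative(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize a count table to per-sample proportions."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise InputError(f"sample {zero[0]!r} has zero total count")
    return counts.astype(float).div(totals, axis=1)


def filter_prevalent(rel: pd.DataFrame, threshold: float = 0.02,
                     other_label: str = "Other") -> pd.DataFrame:
    """Keep taxa reaching ``threshold`` proportion in at least one sample.

    The boundary is inclusive (a taxon at exactly the threshold is
    kept). Filtered taxa are aggregated into a single ``other_label``
    row so columns still sum to 1; the row is omitted when nothing was
    filtered.
    """
    if not (0 < threshold <= 1):
        raise InputError("prevalence threshold must lie in (0, 1]")
    keep = (rel >= threshold).any(axis=1)
    kept = rel.loc[keep]
    if keep.all():
        return kept.copy()
    other = rel.loc[~keep].sum(axis=0)
    other.name = other_label
    return pd.concat([kept, other.to_frame().T])


def rarefy(counts: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample each sample to ``depth`` reads without replacement.

    A single seeded multivariate-hypergeometric draw per sample, the way
    a fixed-depth diversity analysis subsamples once. Deterministic for
    a given seed.
    """
    if depth <= 0:
        raise InputError("rarefaction depth must be positive")
    totals = counts.sum(axis=0)
    short = totals.index[totals < depth]
    if len(short):
        raise InputError(
            f"sample {short[0]!r} has only {int(totals[short[0]])} reads, "
            f"fewer than depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(0, index=counts.index, columns=counts.columns, dtype=np.int64)
    for sample in counts.columns:
        colors = counts[sample].to_numpy()
        out[sample] = rng.multivariate_hypergeometric(colors, depth)
    return out


def rarefy_mean(counts: pd.DataFrame, depth: int, seed: int,
                repeats: int = 10) -> pd.DataFrame:
    """Average of repeated rarefactions (stability variant)."""
    if repeats < 1:
        raise InputError("repeats must be >= 1")
    acc = sum(
        rarefy(counts, depth, s).astype(float)
        for s in np.random.SeedSequence(seed).generate_state(repeats)
    )
    return acc / repeats


def observed_features(counts: pd.DataFrame) -> pd.Series:
    """Number of taxa with nonzero count, per sample."""
    return (counts > 0).sum(axis=0).rename("observed_features")


def shannon(counts: pd.DataFrame, base: float = 2.0) -> pd.Series:
    """Shannon diversity H = -sum p_i log p_i per sample.

    Log base 2 by default (bits), the QIIME 2 convention.
    """
    if base <= 0 or base == 1:
        raise InputError("log base must be positive and != 1")
    rel = to_relative(counts)
    values = {}
    for sample in rel.columns:
        p = rel[sample].to_numpy()
        p = p[p > 0]
        values[sample] = float(-(p * (np.log(p) / np.log(base))).sum())
    return pd.Series(values, name="shannon").reindex(counts.columns)
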