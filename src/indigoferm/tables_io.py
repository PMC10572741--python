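"""Readers and writers for every file dialect the pipeline touches.

All tabular formats are tab-delimited text; the stratified contribution
dialect follows the PICRUSt2 ``pred_metagenome_contrib.legacy`` column
names. Writers emit sorted, deterministic row/column order so outputs
are diffable; readers validate and name the first offending row or
column. Genome annotations are GFF3 (1-based, inclusive coordinates),
parsed through :mod:`gffutils`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

STRATIFIED_COLUMNS = (
    "Sample",
    "Gene",
    "OTU",
    "GeneCountPerGenome",
    "OTUAbundanceInSample",
    "CountContributedByOTU",
)

METADATA_COLUMNS = (
    "sample_id",
    "day",
    "batch",
    "replicate",
    "pH",
    "orp_mV",
    "dyeing_intensity",
)

#: Relative tolerance for the CountContributedByOTU product invariant.
PRODUCT_RTOL = 1e-6


def _check_unique(values, kind: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()][0]
        raise FormatError(f"duplicate {kind} identifier: {dup!r}")


def _check_header_unique(path, kind: str) -> None:
    # pandas mangles duplicate header fields, so inspect the raw header line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], kind)


# ---------------------------------------------------------------------------
# count / function tables


def read_count_table(path) -> pd.DataFrame:
    """Read a taxon x sample table of nonnegative integer counts."""
    _check_header_unique(path, "column")
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    _check_unique(raw.index, "row")
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from exc
    if (values.values < 0).any():
        row, col = np.argwhere(values.values < 0)[0]
        raise FormatError(
            f"negative count at row {values.index[row]!r}, "
            f"column {values.columns[col]!r}"
        )
    frac = values.values - np.floor(values.values)
    if (frac != 0).any():
        row, col = np.argwhere(frac != 0)[0]
        raise FormatError(
            f"non-integer count at row {values.index[row]!r}, "
            f"column {values.columns[col]!r}"
        )
    table = values.astype(np.int64)
    empty = table.columns[table.sum(axis=0) == 0]
    if len(empty):
        raise FormatError(f"sample {empty[0]!r} has no nonzero counts")
    table.index.name = raw.index.name or "taxon_id"
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    out = table.sort_index(axis=0).sort_index(axis=1)
    out.index.name = out.index.name or "taxon_id"
    out.to_csv(path, sep="\t")


def read_function_table(path) -> pd.DataFrame:
    """Read a function x sample table of nonnegative abundances."""
    _check_header_unique(path, "sample")
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0)
    _check_unique(raw.index, "function")
    values = raw.astype(float)
    if (values.values < 0).any():
        row, col = np.argwhere(values.values < 0)[0]
        raise FormatError(
            f"negative abundance at row {values.index[row]!r}, "
            f"column {values.columns[col]!r}"
        )
    values.index.name = raw.index.name or "function_id"
    return values


def write_function_table(table: pd.DataFrame, path) -> None:
    out = table.sort_index(axis=0).sort_index(axis=1)
    out.index.name = out.index.name or "function_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata file missing column {missing[0]!r}")
    _check_unique(meta["sample_id"], "sample_id")
    if (meta["day"] < 1).any():
        bad = meta.loc[meta["day"] < 1, "sample_id"].iloc[0]
        raise FormatError(f"day < 1 for sample {bad!r}")
    if (meta["dyeing_intensity"] < 0).any():
        bad = meta.loc[meta["dyeing_intensity"] < 0, "sample_id"].iloc[0]
        raise FormatError(f"negative dyeing_intensity for sample {bad!r}")
    return meta.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.reset_index(drop=True).sort_values("sample_id")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stratified contributions (PICRUSt2 legacy dialect)


def read_stratified(path, taxonomy: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a stratified contribution table.

    Rows whose ``CountContributedByOTU`` is not the product of the two
    factor columns (beyond relative tolerance 1e-6) are kept but logged:
    externally produced files need not satisfy the invariant.
    """
    rows = pd.read_csv(path, sep="\t")
    for col in STRATIFIED_COLUMNS:
        if col not in rows.columns:
            raise FormatError(f"stratified table missing column {col!r}")
    keys = rows[["Sample", "Gene", "OTU"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        raise FormatError(
            f"duplicate (Sample, Gene, OTU) key: {keys[keys.duplicated()].iloc[0]}"
        )
    for col in ("GeneCountPerGenome", "OTUAbundanceInSample", "CountContributedByOTU"):
        if (rows[col] < 0).any():
            raise FormatError(f"negative value in column {col!r}")
    product = rows["GeneCountPerGenome"] * rows["OTUAbundanceInSample"]
    off = ~np.isclose(rows["CountContributedByOTU"], product, rtol=PRODUCT_RTOL)
    if off.any():
        logger.warning(
            "%d stratified rows where CountContributedByOTU != "
            "GeneCountPerGenome * OTUAbundanceInSample (first at line %d); kept",
            int(off.sum()),
            int(np.flatnonzero(off)[0]) + 2,
        )
    if taxonomy is not None and "taxon" not in rows.columns:
        rows["taxon"] = [genus_of(taxonomy.get(o, o)) for o in rows["OTU"]]
    return rows


def write_stratified(rows: pd.DataFrame, path) -> None:
    cols = [c for c in STRATIFIED_COLUMNS if c in rows.columns]
    cols += [c for c in rows.columns if c not in cols]
    out = rows[cols].sort_values(["Sample", "Gene", "OTU"])
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# taxonomy and function hierarchy maps


def read_taxonomy(path) -> dict[str, str]:
    """Read a 2-column (otu_id, semicolon-delimited lineage) map."""
    tax = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"],
                      dtype=str, comment="#")
    _check_unique(tax["otu_id"], "otu_id")
    return dict(zip(tax["otu_id"], tax["lineage"]))


def write_taxonomy(taxonomy: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for otu in sorted(taxonomy):
            fh.write(f"{otu}\t{taxonomy[otu]}\n")


_GENUS_RE = re.compile(r"g__([^;]+)")


def genus_of(lineage: str) -> str:
    """Genus from a Silva-style lineage: last ``g__`` rank, else final token."""
    hits = _GENUS_RE.findall(lineage)
    if hits:
        return hits[-1].strip()
    return lineage.rsplit(";", 1)[-1].strip()


def read_hierarchy(path) -> pd.DataFrame:
    """Read a function -> (subpathway, superpathway, category) map."""
    hier = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("function_id", "subpathway", "superpathway", "category"):
        if col not in hier.columns:
            raise FormatError(f"hierarchy file missing column {col!r}")
    _check_unique(hier["function_id"], "function_id")
    return hier.set_index("function_id")


def write_hierarchy(hier: pd.DataFrame, path) -> None:
    out = hier.reset_index().sort_values("function_id")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# colorimetry


def read_pixels(path) -> pd.DataFrame:
    """Read per-pixel CIE L*a*b* measurements (CSV, columns L,a,b)."""
    pix = pd.read_csv(path)
    for col in ("L", "a", "b"):
        if col not in pix.columns:
            raise FormatError(f"pixel file missing column {col!r}")
    if (pix["L"] < 0).any():
        raise FormatError(f"negative L* at line {int(np.flatnonzero(pix['L'] < 0)[0]) + 2}")
    if not np.isfinite(pix[["L", "a", "b"]].values).all():
        raise FormatError("non-finite L*a*b* value")
    return pix[["L", "a", "b"]]


# ---------------------------------------------------------------------------
# genome annotation (GFF3)


@dataclass(frozen=True)
class Feature:
    """One annotated CDS with GFF3 (1-based, inclusive) coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    gene: str | None
    product: str | None
    ordinal: int  # position among CDS of the same contig, coordinate order


@dataclass
class GenomeFeatureSet:
    """Ordered CDS records of one annotated genome."""

    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def by_contig(self) -> dict[str, list[Feature]]:
        out: dict[str, list[Feature]] = {}
        for feat in self.features:
            out.setdefault(feat.contig, []).append(feat)
        return out


def read_gff3(path) -> GenomeFeatureSet:
    """Read CDS features from a GFF3 file, ordered per contig."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # malformed GFF3
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    per_contig: dict[str, list] = {}
    for rec in db.features_of_type("CDS"):
        if rec.end < rec.start:
            raise FormatError(
                f"malformed coordinates (end < start) for feature on "
                f"{rec.seqid} at {rec.start}..{rec.end}"
            )
        per_contig.setdefault(rec.seqid, []).append(rec)

    features: list[Feature] = []
    for contig in sorted(per_contig):
        recs = sorted(per_contig[contig], key=lambda r: (r.start, r.end))
        for ordinal, rec in enumerate(recs):
            gene = rec.attributes.get("gene", [None])[0]
            product = rec.attributes.get("product", [None])[0]
            features.append(
                Feature(
                    contig=contig,
                    start=int(rec.start),
                    end=int(rec.end),
                    strand=rec.strand or ".",
                    gene=gene,
                    product=product,
                    ordinal=ordinal,
                )
            )
    return GenomeFeatureSet(features)


# ---------------------------------------------------------------------------
# configuration


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise InputError(f"config {path} must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
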