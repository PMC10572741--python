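"""Scan annotated genomes for the flavin-based EET gene catalog.

The flavin-based extracellular electron transfer (EET) system described
in *Listeria monocytogenes* comprises three functional groups: FAD
transport and flavinylation (ecfA, ecfA', fmnA, apbE/fmnB), electron
transfer from NADH to the extracellular flavoprotein (eetA, eetB,
ndh-2-like, pplA, frdA-like), and demethylmenaquinone synthesis (dmkA,
dmkB). This module matches annotated CDS features against an editable
pattern catalog and classifies each group's locus architecture:
co-located in one cluster, split across clusters, or dispersed.

"Similar locations" are defined by gene-ordinal gaps (number of
intervening CDS) rather than base-pair distance, which is robust to
intergenic length variation; the default maximum gap inside a cluster
is 10 genes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import FormatError, InputError
from .tables_io import Feature, GenomeFeatureSet

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP_GENES = 10

ARCH_CLUSTERED = "clustered"
ARCH_SPLIT = "split"
ARCH_DISPERSED = "dispersed"
ARCH_ABSENT = "absent"


@dataclass(frozen=True)
class CatalogEntry:
    """One canonical EET gene label with its matching patterns."""

    label: str
    role: str
    name_patterns: tuple[str, ...]
    product_patterns: tuple[str, ...]


@dataclass
class EETCatalog:
    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise InputError("duplicate catalog labels")
        for e in self.entries:
            if not (e.name_patterns or e.product_patterns):
                raise InputError(f"catalog label {e.label!r} has no patterns")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    @property
    def roles(self) -> list[str]:
        seen = []
        for e in self.entries:
            if e.role not in seen:
                seen.append(e.role)
        return seen


def load_catalog(path=None) -> EETCatalog:
    """Load the pattern catalog (the packaged default when no path given)."""
    if path is None:
        source = resources.files("indigoferm.data") / "eet_catalog.tsv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    else:
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("label", "role", "name_patterns", "product_patterns"):
        if col not in table.columns:
            raise FormatError(f"catalog file missing column {col!r}")
    entries = []
    for _, row in table.iterrows():
        def split(cell):
            if pd.isna(cell) or not str(cell).strip():
                return ()
            return tuple(s for s in str(cell).split(";;") if s)

        entries.append(CatalogEntry(row["label"], row["role"],
                                    split(row["name_patterns"]),
                                    split(row["product_patterns"])))
    return EETCatalog(entries)


def _best_match(feature: Feature, catalog: EETCatalog):
    """(label, specificity) of the best-matching catalog entry, or None.

    A name match always beats a product match; among equal kinds the
    longer pattern wins. Ties are logged and broken by catalog order.
    """
    best = None  # (kind_rank, pattern_len, label); kind_rank: 1 name, 0 product
    tied = []
    for entry in catalog:
        if feature.gene:
            for pat in entry.name_patterns:
                if re.search(pat, feature.gene, re.IGNORECASE):
                    cand = (1, len(pat), entry.label)
                    if best is None or cand[:2] > best[:2]:
                        best, tied = cand, []
                    elif cand[:2] == best[:2] and cand[2] != best[2]:
                        tied.append(cand[2])
        if feature.product:
            for pat in entry.product_patterns:
                if re.search(pat, feature.product, re.IGNORECASE):
                    cand = (0, len(pat), entry.label)
                    if best is None or cand[:2] > best[:2]:
                        best, tied = cand, []
                    elif cand[:2] == best[:2] and cand[2] != best[2]:
                        tied.append(cand[2])
    if best is None:
        return None
    if tied:
        logger.warning(
            "feature %s:%d..%d matches labels %s equally well; assigned %r",
            feature.contig, feature.start, feature.end,
            [best[2], *tied], best[2],
        )
    return best[2]


def match_catalog(features: GenomeFeatureSet,
                  catalog: EETCatalog) -> dict[str, list[Feature]]:
    """Map each catalog label to its matched features (possibly none).

    Each feature is assigned to at most one label (the most specific
    match). Absence is a result, not an error.
    """
    if len(features) == 0:
        raise InputError("empty feature set")
    matches: dict[str, list[Feature]] = {label: [] for label in catalog.labels}
    for feature in features:
        label = _best_match(feature, catalog)
        if label is not None:
            matches[label].append(feature)
    return matches


def _single_linkage_clusters(feats: list[Feature],
                             max_gap_genes: int) -> list[list[Feature]]:
    """Group same-contig features whose ordinal gap is <= max_gap_genes."""
    by_contig: dict[str, list[Feature]] = {}
    for f in feats:
        by_contig.setdefault(f.contig, []).append(f)
    clusters = []
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda f: f.ordinal)
        current = [ordered[0]]
        for f in ordered[1:]:
            if f.ordinal - current[-1].ordinal <= max_gap_genes:
                current.append(f)
            else:
                clusters.append(current)
                current = [f]
        clusters.append(current)
    return clusters


def cluster_matches(matches: dict[str, list[Feature]],
                    catalog: EETCatalog,
                    max_gap_genes: int = DEFAULT_MAX_GAP_GENES):
    """Cluster matched features and classify each role group's architecture.

    Returns ``(clusters, architecture)`` where clusters is a list of
    feature groups (single-linkage over gene ordinals, per contig,
    across all labels) and architecture maps each role group to one of
    clustered / split / dispersed / absent.
    """
    if max_gap_genes < 0:
        raise InputError("max_gap_genes must be >= 0")
    all_feats = [f for feats in matches.values() for f in feats]
    clusters = _single_linkage_clusters(all_feats, max_gap_genes) if all_feats else []
    cluster_of: dict[Feature, int] = {}
    for k, cl in enumerate(clusters):
        for f in cl:
            cluster_of[f] = k

    architecture: dict[str, str] = {}
    for role in catalog.roles:
        feats = [f for e in catalog if e.role == role for f in matches.get(e.label, [])]
        if not feats:
            architecture[role] = ARCH_ABSENT
            continue
        ids = {cluster_of[f] for f in feats}
        if len(ids) == 1:
            architecture[role] = ARCH_CLUSTERED
            continue
        far_apart = all(
            a.contig != b.contig or abs(a.ordinal - b.ordinal) > max_gap_genes
            for i, a in enumerate(feats) for b in feats[i + 1:]
        )
        architecture[role] = ARCH_DISPERSED if far_apart else ARCH_SPLIT
    return clusters, architecture


def completeness(matches: dict[str, list[Feature]],
                 catalog: EETCatalog) -> tuple[float, dict[str, bool]]:
    """Fraction of catalog labels present, and per-role completeness."""
    present = {label: bool(matches.get(label)) for label in catalog.labels}
    frac = sum(present.values()) / len(catalog)
    role_complete = {
        role: all(present[e.label] for e in catalog if e.role == role)
        for role in catalog.roles
    }
    return frac, role_complete


def scan_genome(features: GenomeFeatureSet,
                catalog: EETCatalog | None = None,
                max_gap_genes: int = DEFAULT_MAX_GAP_GENES) -> pd.DataFrame:
    """Full scan: match, cluster, classify; returns a per-label report.

    Columns: label, role, present, n_matches, contig, ordinal_span,
    cluster_ids, architecture (of the label's role group).
    """
    if catalog is None:
        catalog = load_catalog()
    matches = match_catalog(features, catalog)
    clusters, architecture = cluster_matches(matches, catalog, max_gap_genes)
    cluster_of = {f: k for k, cl in enumerate(clusters) for f in cl}
    rows = []
    for entry in catalog:
        feats = matches[entry.label]
        rows.append(
            {
                "label": entry.label,
                "role": entry.role,
                "present": bool(feats),
                "n_matches": len(feats),
                "contig": ";".join(sorted({f.contig for f in feats})) or "-",
                "ordinal_span": (
                    f"{min(f.ordinal for f in feats)}-{max(f.ordinal for f in feats)}"
                    if feats else "-"
                ),
                "cluster_ids": ";".join(str(cluster_of[f]) for f in feats) or "-",
                "architecture": architecture[entry.role],
            }
        )
    return pd.DataFrame(rows)
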