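"""OTU tables and genus-level relative-abundance profiles.

Covers the count-table processing that precedes correlation analysis:
singleton filtering, rarefaction (without-replacement subsampling to a common
depth), genus-level aggregation of lineage-annotated OTUs, and abundance
filtering against per-day thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "GenusProfile",
    "read_otu_table",
    "read_sample_metadata",
    "filter_singletons",
    "rarefy",
    "aggregate_to_genus",
    "abundance_filter",
    "parse_genus_label",
]

_RANK_NAMES = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
_GENUS_RANK = 5  # 0-based position of genus in a QIIME-style lineage


@dataclass
class OtuTable:
    """Sample x OTU integer counts plus lineages and sample metadata.

    ``counts``: samples x OTUs (rows are samples).  ``lineages``: OTU id ->
    semicolon-delimited lineage string.  ``metadata``: indexed by sample id
    with columns such as ``day``, ``treatment``, ``dose_uM``, ``inoculated``.
    """

    counts: pd.DataFrame
    lineages: pd.Series
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in OTU table")
        if (self.counts.values < 0).any():
            raise ValueError("negative OTU counts")
        self.counts = self.counts.astype(np.int64)
        self.lineages = self.lineages.reindex(self.counts.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otus(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class GenusProfile:
    """Genus-level counts and relative abundances per sample.

    ``relative_abundance`` rows sum to 1 for samples with nonzero totals;
    samples with all-zero counts are listed in ``undefined_samples`` and
    dropped from the abundance table.
    """

    counts: pd.DataFrame
    relative_abundance: pd.DataFrame
    metadata: pd.DataFrame | None = None
    undefined_samples: list[str] = field(default_factory=list)

    @property
    def genera(self) -> list[str]:
        return list(self.relative_abundance.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.relative_abundance.index)


def read_otu_table(path: str, metadata_path: str | None = None) -> OtuTable:
    """Read a tab-separated OTU matrix (first column OTU id, last column
    lineage, middle columns per-sample counts) plus optional metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    otu_col, lineage_col = df.columns[0], df.columns[-1]
    sample_cols = list(df.columns[1:-1])
    lineages = pd.Series(df[lineage_col].values, index=df[otu_col].values)
    counts = df[sample_cols].astype(np.int64)
    counts.index = df[otu_col].values
    metadata = read_sample_metadata(metadata_path) if metadata_path else None
    return OtuTable(counts=counts.T, lineages=lineages, metadata=metadata)


def read_sample_metadata(path: str) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    if "day" in md.columns:
        md["day"] = pd.to_numeric(md["day"])
    if "dose_uM" in md.columns:
        md["dose_uM"] = pd.to_numeric(md["dose_uM"])
    if "inoculated" in md.columns:
        md["inoculated"] = md["inoculated"].str.lower().isin(("1", "true", "yes"))
    return md


def filter_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs observed exactly once across all samples (total count == 1)."""
    totals = table.counts.sum(axis=0)
    keep = totals != 1
    return OtuTable(
        counts=table.counts.loc[:, keep],
        lineages=table.lineages[keep],
        metadata=table.metadata,
    )


def rarefy(table: OtuTable, depth: int | str = "min", seed: int | None = None) -> OtuTable:
    """Subsample every sample's counts without replacement to a common depth.

    ``depth="min"`` uses the smallest sample total.  The draw per sample is a
    single multivariate hypergeometric sample; the result is reproducible for
    a fixed ``seed``.
    """
    totals = table.sample_totals()
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    short = totals.index[totals < depth]
    if len(short):
        raise ValueError(
            f"sample(s) {list(short)} have totals below the rarefaction depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.values)
    for i, row in enumerate(table.counts.values):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(counts=counts, lineages=table.lineages, metadata=table.metadata)


def parse_genus_label(lineage: str) -> str:
    """Extract a genus label from a semicolon-delimited lineage string.

    Understands QIIME-style rank prefixes (``g__Lactobacillus``) and plain
    rank lists.  OTUs unclassified at the genus level receive the stable
    synthesized label ``unclassified_<parent-rank>_<parent-name>`` built from
    the deepest classified rank, so that they aggregate as their own group
    rather than vanishing or colliding across parents.
    """
    ranks = [r.strip() for r in str(lineage).split(";")]

    def strip_prefix(token: str) -> str:
        if len(token) >= 3 and token[1:3] == "__":
            return token[3:].strip()
        return token

    names = [strip_prefix(r) for r in ranks]
    if len(names) > _GENUS_RANK and names[_GENUS_RANK]:
        return names[_GENUS_RANK].strip()
    # fall back to the deepest non-empty parent rank
    for depth in range(min(len(names), _GENUS_RANK) - 1, -1, -1):
        if names[depth]:
            rank_name = _RANK_NAMES[depth] if depth < len(_RANK_NAMES) else f"rank{depth}"
            return f"unclassified_{rank_name}_{names[depth]}"
    return "unclassified_root_unknown"


def aggregate_to_genus(table: OtuTable) -> GenusProfile:
    """Sum OTU counts per genus, then convert to per-sample relative abundance.

    Count conservation holds: per sample, the genus-level counts sum to the
    OTU-level total.  Samples with zero total are excluded from the abundance
    table and flagged.
    """
    genus_labels = table.lineages.map(parse_genus_label)
    counts = table.counts.T.groupby(genus_labels.values).sum().T
    counts = counts[sorted(counts.columns)]
    totals = counts.sum(axis=1)
    undefined = totals.index[totals == 0].tolist()
    nonzero = counts.loc[totals > 0]
    rel = nonzero.div(nonzero.sum(axis=1), axis=0)
    return GenusProfile(
        counts=counts,
        relative_abundance=rel,
        metadata=table.metadata,
        undefined_samples=undefined,
    )


def abundance_filter(
    profile: GenusProfile,
    threshold: float,
    require_days: Iterable[int] = (1, 7),
) -> GenusProfile:
    """Keep genera whose mean relative abundance exceeds ``threshold`` within
    every required day group ("detected on both days" semantics).

    ``threshold`` is a fraction in (0, 1): 0.0005 (0.05 %) is the default
    eligibility cutoff for correlation analysis, 0.0001 (0.01 %) the cutoff
    for inclusion in the capability model.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly between 0 and 1")
    if profile.metadata is None:
        raise ValueError("abundance_filter requires sample metadata with a 'day' column")
    require_days = set(require_days)
    observed_days = set(profile.metadata["day"].dropna().unique())
    missing = require_days - observed_days
    if missing:
        raise ValueError(f"required day group(s) {sorted(missing)} not present in metadata")

    rel = profile.relative_abundance
    md = profile.metadata.reindex(rel.index)
    keep = pd.Series(True, index=rel.columns)
    for day in sorted(require_days):
        day_samples = md.index[md["day"] == day]
        day_rel = rel.loc[rel.index.intersection(day_samples)]
        if day_rel.empty:
            raise ValueError(f"no profiled samples on day {day}")
        keep &= day_rel.mean(axis=0) > threshold
    kept = rel.columns[keep]
    return GenusProfile(
        counts=profile.counts[kept] if profile.counts is not None else None,
        relative_abundance=rel[kept],
        metadata=profile.metadata,
        undefined_samples=list(profile.undefined_samples),
    )
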