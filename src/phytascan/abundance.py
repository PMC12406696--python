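"""Marker-gene-normalized gene abundances and class-level taxonomic profiles.

Per-sample gene counts are expressed relative to the mean abundance of ten
universal single-copy bacterial marker genes in the same sample, yielding a
per-genome-equivalent relative abundance that is invariant to sequencing
depth. Taxonomy is consumed from precomputed best-hit tables (this package
never queries external databases): per query the top-bitscore subject wins,
its lineage is reduced to (class, kingdom), and class frequencies are
normalized to 1 within each sample type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MARKER_GENES",
    "AbundanceTable",
    "TaxProfile",
    "normalize_to_markers",
    "assign_best_hit_taxon",
    "class_frequency_profile",
    "shared_class_counts",
    "top_n_share",
]

#: Ten universal single-copy marker COGs used for normalization (configurable).
DEFAULT_MARKER_GENES = (
    "COG0012", "COG0016", "COG0018", "COG0172", "COG0215",
    "COG0495", "COG0525", "COG0533", "COG0541", "COG0552",
)


@dataclass
class AbundanceTable:
    """Marker-normalized relative abundances (samples × genes)."""

    values: pd.DataFrame
    normalizer: pd.Series
    dropped_samples: tuple[str, ...] = ()

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TaxProfile:
    """Class-level frequency profile of one sample type (frequencies sum to 1)."""

    sample_type: str
    class_frequencies: dict[str, float]
    kingdom_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.class_frequencies.values())
        if self.class_frequencies and abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.sample_type}: frequencies sum to {total}, not 1")
        # keep classes sorted by descending frequency (name breaks ties)
        self.class_frequencies = dict(
            sorted(self.class_frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        )

    @property
    def classes(self) -> set[str]:
        return set(self.class_frequencies)


def normalize_to_markers(
    gene_counts: pd.DataFrame,
    marker_counts: pd.DataFrame,
    n_markers: int = 10,
) -> AbundanceTable:
    """Normalize per-sample gene counts by the mean marker-gene abundance.

    Both frames are samples × genes (counts may be fractional, e.g.
    coverage-based). Samples whose marker mean is zero are dropped with a
    warning. Multiplying every count in a sample by a constant leaves its
    normalized abundances unchanged.
    """
    if (gene_counts.values < 0).any() or (marker_counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    if marker_counts.shape[1] != n_markers:
        raise ValueError(
            f"expected {n_markers} marker genes, got {marker_counts.shape[1]}"
        )
    gene_counts = gene_counts.loc[marker_counts.index]
    normalizer = marker_counts.mean(axis=1)
    zero = normalizer[normalizer <= 0].index
    if len(zero):
        logger.warning("dropping samples with zero marker abundance: %s", list(zero))
    keep = normalizer.index.difference(zero, sort=False)
    values = gene_counts.loc[keep].div(normalizer.loc[keep], axis=0)
    return AbundanceTable(
        values=values, normalizer=normalizer.loc[keep], dropped_samples=tuple(zero)
    )


def assign_best_hit_taxon(
    homolog_hits: pd.DataFrame,
    lineage_map: Mapping[str, tuple[str, str]],
) -> dict[str, tuple[str, str]]:
    """Best-hit taxonomy per query: max bitscore, then min e-value, then subject id.

    ``homolog_hits`` needs columns query, subject, bitscore, e_value,
    subject_taxon; ``lineage_map`` resolves a taxon string to
    (class, kingdom). Unresolvable lineages become ("unclassified",
    "unclassified") rather than being dropped.
    """
    required = {"query", "subject", "bitscore", "e_value", "subject_taxon"}
    missing = required - set(homolog_hits.columns)
    if missing:
        raise KeyError(f"hit table missing columns: {sorted(missing)}")
    if homolog_hits.empty:
        raise ValueError("hit table is empty")
    ordered = homolog_hits.sort_values(
        ["query", "bitscore", "e_value", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ordered.groupby("query", sort=False).first()
    out: dict[str, tuple[str, str]] = {}
    for query, row in best.iterrows():
        out[str(query)] = lineage_map.get(
            str(row["subject_taxon"]), ("unclassified", "unclassified")
        )
    return out


def class_frequency_profile(
    assignments: Mapping[str, tuple[str, str] | str],
    sample_type_of: Mapping[str, str],
) -> list[TaxProfile]:
    """Per-sample-type class frequencies, normalized to 1 and sorted descending."""
    unmapped = [q for q in assignments if q not in sample_type_of]
    if unmapped:
        raise KeyError(f"queries without a sample type: {unmapped[:5]}")
    buckets: dict[str, dict[str, int]] = {}
    kingdoms: dict[str, dict[str, str]] = {}
    for query, assign in assignments.items():
        cls, kingdom = (assign, "") if isinstance(assign, str) else assign
        stype = sample_type_of[query]
        buckets.setdefault(stype, {}).setdefault(cls, 0)
        buckets[stype][cls] += 1
        kingdoms.setdefault(stype, {})[cls] = kingdom
    profiles = []
    for stype in sorted(buckets):
        counts = buckets[stype]
        total = sum(counts.values())
        if total == 0:
            logger.warning("sample type %s has no assignments; omitted", stype)
            continue
        freqs = {cls: n / total for cls, n in counts.items()}
        profiles.append(TaxProfile(stype, freqs, kingdoms[stype]))
    return profiles


def shared_class_counts(profiles: Sequence[TaxProfile]) -> dict[frozenset, int]:
    """Exclusive-region Venn counts of classes across sample types.

    For every non-empty subset S of sample types, counts classes present in
    all members of S and absent from all other profiles.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    labels = [p.sample_type for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample-type labels")
    sets = {p.sample_type: p.classes for p in profiles}
    out: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for subset in combinations(labels, r):
            inside = set.intersection(*(sets[t] for t in subset))
            for other in set(labels) - set(subset):
                inside -= sets[other]
            out[frozenset(subset)] = len(inside)
    return out


def top_n_share(profile: TaxProfile, n: int = 10) -> float:
    """Summed frequency of the ``n`` most abundant classes (1.0 if n ≥ classes)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    freqs = sorted(profile.class_frequencies.values(), reverse=True)
    if n >= len(freqs):
        logger.info("top_n_share: n=%d >= %d classes; returning full share", n, len(freqs))
    return float(np.sum(freqs[:n]))
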