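"""Partition two treatments' compounds into shared and exclusive sets.

Matching is by normalized annotation identity only: the two treatments are
annotated against the same spectral libraries, so the annotation string is
the shared key.  No m/z–retention-time tolerance matching is attempted and
distinct keys are never merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .feature_io import CompoundRecord, FeatureTable


@dataclass(frozen=True)
class MatchedCompendium:
    """Shared / filter-only / autoclave-only partition with paired records.

    filter_only holds compounds lost to autoclaving (heat-degraded);
    autoclave_only holds compounds that appear only after autoclaving
    (heat-degradation products).
    """

    shared: dict[str, tuple[CompoundRecord, CompoundRecord]]
    filter_only: frozenset[str]
    autoclave_only: frozenset[str]
    match_policy: str = "normalized_identity"


class PartitionCounts(NamedTuple):
    n_shared: int
    n_filter_only: int
    n_autoclave_only: int
    n_filter_total: int
    n_autoclave_total: int


def match_compounds(ft_filter: FeatureTable, ft_autoclave: FeatureTable) -> MatchedCompendium:
    """Exact-key intersection of the two tables.

    Both tables must already be validated and deduplicated with the same
    key normalization (guaranteed when both came through
    :func:`~thermoscreen.feature_io.read_feature_table`).
    """
    keys_f = ft_filter.keys()
    keys_a = ft_autoclave.keys()
    rec_f = {r.compound_key: r for r in ft_filter.records}
    rec_a = {r.compound_key: r for r in ft_autoclave.records}
    shared = {k: (rec_f[k], rec_a[k]) for k in sorted(keys_f & keys_a)}
    return MatchedCompendium(
        shared=shared,
        filter_only=frozenset(keys_f - keys_a),
        autoclave_only=frozenset(keys_a - keys_f),
    )


def partition_counts(m: MatchedCompendium) -> PartitionCounts:
    """Counts of the partition; totals obey the conservation identities
    ``n_filter_total = n_shared + n_filter_only`` and
    ``n_autoclave_total = n_shared + n_autoclave_only``."""
    n_shared = len(m.shared)
    return PartitionCounts(
        n_shared=n_shared,
        n_filter_only=len(m.filter_only),
        n_autoclave_only=len(m.autoclave_only),
        n_filter_total=n_shared + len(m.filter_only),
        n_autoclave_total=n_shared + len(m.autoclave_only),
    )
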