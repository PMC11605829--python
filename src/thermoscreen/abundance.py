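"""Relative-abundance normalization.

The screen's abundance statistic for compound *i* in a treatment table of
*N* compounds with peak areas ``a_1..a_N`` is

    RA_i = a_i / (a_1 + ... + a_N) * N

i.e. the peak area divided by the mean area of the table.  By construction
the values sum to N, average 1, and are invariant to rescaling all areas by
a common positive factor — so the statistic is comparable between two
tables with different compound counts and different total ion signal.
Positive- and negative-mode compounds are pooled into a single table before
normalization, giving one RA value per compound per treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .feature_io import FeatureTable


@dataclass(frozen=True)
class AbundanceTable:
    """Per-compound relative abundances for one treatment."""

    treatment_label: str
    entries: dict[str, float]
    n_compounds: int
    total_area: float

    def __getitem__(self, key: str) -> float:
        return self.entries[key]


def relative_abundance(table: FeatureTable) -> AbundanceTable:
    """Compute the relative abundance of every compound in *table*.

    Requires a validated, deduplicated table (all areas positive); the
    :class:`~thermoscreen.feature_io.FeatureTable` invariants guarantee
    both, including that the table is non-empty.
    """
    areas = table.areas()
    n = len(areas)
    total = sum(areas.values())
    entries = {k: a / total * n for k, a in areas.items()}
    return AbundanceTable(
        treatment_label=table.treatment_label,
        entries=entries,
        n_compounds=n,
        total_area=total,
    )
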