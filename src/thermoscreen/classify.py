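"""Stability-ratio classification of shared compounds and the full screen.

For every compound detected in both treatments the statistic is
``ratio = Rf / Ra``, the relative abundance in the filter-sterilized
medium over that in the autoclaved medium.  Two open windows define the
candidate calls:

* ``low < ratio < high`` (default 0.75–1.5): the compound survived
  autoclaving with near-unchanged relative abundance — heat-stable,
  an anti-aging candidate;
* ``ratio > inhibitor`` (default 9): strong depletion after autoclaving —
  heat-sensitive, a growth-inhibiting candidate.

Everything else is unclassified.  Boundaries are strict: a ratio exactly
at a threshold receives no call.  The inhibitor cutoff of 9 is the
operational rendering of "more than 90% reduction of relative abundance";
taken literally a 90% reduction corresponds to a ratio of 10, but 9 is
the cutoff as used, and it is configurable.

Compounds absent from one treatment never receive a ratio: disappearance
is reported through the partition (filter-only / autoclave-only), not as
an infinite ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import enum
import math

from .abundance import relative_abundance
from .feature_io import UNCLASSIFIED_SUPERCLASS, FeatureTable
from .matching import PartitionCounts, match_compounds, partition_counts


class StabilityLabel(str, enum.Enum):
    ANTI_AGING = "anti_aging_candidate"
    INHIBITOR = "growth_inhibiting_candidate"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Thresholds:
    """Ratio windows for the two candidate calls; must satisfy
    ``0 < low < high <= inhibitor``."""

    low: float = 0.75
    high: float = 1.5
    inhibitor: float = 9.0

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high <= self.inhibitor):
            raise ValueError(
                "thresholds must satisfy 0 < low < high <= inhibitor, got "
                f"low={self.low}, high={self.high}, inhibitor={self.inhibitor}"
            )


@dataclass(frozen=True)
class StabilityRecord:
    compound_key: str
    Rf: float
    Ra: float
    ratio: float
    label: StabilityLabel
    superclass: str | None = None


@dataclass(frozen=True)
class StabilityResult:
    """Per-shared-compound ratios and labels plus run-level summaries."""

    records: tuple[StabilityRecord, ...]
    counts: PartitionCounts
    n_anti_aging: int
    n_inhibitor: int
    superclass_summary: dict[str, int]
    thresholds: Thresholds


def stability_ratio(Rf: float, Ra: float) -> float:
    """Rf / Ra.  Both must be strictly positive; a non-positive value here
    means a compound absent from one treatment leaked past matching."""
    if not (Rf > 0 and math.isfinite(Rf)) or not (Ra > 0 and math.isfinite(Ra)):
        raise ValueError(f"Rf and Ra must be positive finite, got Rf={Rf}, Ra={Ra}")
    return Rf / Ra


def classify_compound(ratio: float, thresholds: Thresholds = Thresholds()) -> StabilityLabel:
    """Apply the two open ratio windows; boundary values are unclassified."""
    if thresholds.low < ratio < thresholds.high:
        return StabilityLabel.ANTI_AGING
    if ratio > thresholds.inhibitor:
        return StabilityLabel.INHIBITOR
    return StabilityLabel.UNCLASSIFIED


def superclass_summary(records: list[StabilityRecord] | tuple[StabilityRecord, ...]) -> dict[str, int]:
    """Counts of shared compounds per chemical-superclass label.

    The superclass is an opaque taxonomy string from the annotation;
    records lacking one are pooled under ``unclassified_superclass``.
    """
    out: dict[str, int] = {}
    for r in records:
        label = r.superclass or UNCLASSIFIED_SUPERCLASS
        out[label] = out.get(label, 0) + 1
    return out


def screen(
    ft_filter: FeatureTable,
    ft_autoclave: FeatureTable,
    thresholds: Thresholds = Thresholds(),
) -> StabilityResult:
    """Run the end-to-end screen on two validated feature tables.

    Composes per-treatment relative abundance, identity matching, the
    stability ratio and window classification for every shared compound,
    and the superclass summary.  Deterministic for fixed inputs and
    thresholds; records are ordered by compound key.
    """
    ra_filter = relative_abundance(ft_filter)
    ra_autoclave = relative_abundance(ft_autoclave)
    compendium = match_compounds(ft_filter, ft_autoclave)
    counts = partition_counts(compendium)

    records: list[StabilityRecord] = []
    for key, (rec_f, rec_a) in compendium.shared.items():
        rf = ra_filter[key]
        ra = ra_autoclave[key]
        ratio = stability_ratio(rf, ra)
        # superclass may be annotated in only one treatment's export
        superclass = rec_f.superclass or rec_a.superclass
        records.append(
            StabilityRecord(
                compound_key=key,
                Rf=rf,
                Ra=ra,
                ratio=ratio,
                label=classify_compound(ratio, thresholds),
                superclass=superclass,
            )
        )

    return StabilityResult(
        records=tuple(records),
        counts=counts,
        n_anti_aging=sum(r.label is StabilityLabel.ANTI_AGING for r in records),
        n_inhibitor=sum(r.label is StabilityLabel.INHIBITOR for r in records),
        superclass_summary=superclass_summary(records),
        thresholds=thresholds,
    )
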