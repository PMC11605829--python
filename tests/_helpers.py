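"""Shared test helpers: table construction and the independent brute-force
oracle against which the pipeline is checked.

The oracle is deliberately straight-line code that shares nothing with the
package's implementation beyond plain arithmetic.
"""

from __future__ import annotations

from hypothesis import strategies as st

from thermoscreen import CompoundRecord, FeatureTable, IonMode


def make_table(
    areas: dict[str, float],
    label: str = "treatment",
    superclasses: dict[str, str] | None = None,
) -> FeatureTable:
    superclasses = superclasses or {}
    records = tuple(
        CompoundRecord(
            compound_key=k,
            raw_name=k,
            ion_mode=IonMode.UNSPECIFIED,
            area=a,
            superclass=superclasses.get(k),
        )
        for k, a in areas.items()
    )
    return FeatureTable(treatment_label=label, records=records)


def brute_force_screen(
    filter_areas: dict[str, float],
    autoclave_areas: dict[str, float],
    low: float = 0.75,
    high: float = 1.5,
    inhibitor: float = 9.0,
) -> dict[str, tuple[float, str]]:
    """Independent recomputation of ratio and label for every shared compound."""
    n_f = len(filter_areas)
    n_a = len(autoclave_areas)
    total_f = 0.0
    for a in filter_areas.values():
        total_f += a
    total_a = 0.0
    for a in autoclave_areas.values():
        total_a += a
    out: dict[str, tuple[float, str]] = {}
    for key in filter_areas:
        if key not in autoclave_areas:
            continue
        rf = filter_areas[key] / total_f * n_f
        ra = autoclave_areas[key] / total_a * n_a
        ratio = rf / ra
        if low < ratio < high:
            label = "anti_aging_candidate"
        elif ratio > inhibitor:
            label = "growth_inhibiting_candidate"
        else:
            label = "unclassified"
        out[key] = (ratio, label)
    return out


_KEY_POOL = [f"cmpd{i:02d}" for i in range(16)]

areas_strategy = st.dictionaries(
    keys=st.sampled_from(_KEY_POOL),
    values=st.floats(min_value=1e-3, max_value=1e9, allow_nan=False, allow_infinity=False),
    min_size=1,
    max_size=10,
)
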