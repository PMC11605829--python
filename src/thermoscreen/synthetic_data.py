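"""Synthetic paired feature tables with planted ground truth.

The generator emulates the structure of a filter-sterilized vs autoclaved
metabolome comparison:

* ``stable`` compounds are present in both treatments with unchanged
  underlying area (heat-stable);
* ``sensitive`` compounds survive autoclaving at a small retention
  fraction of their original area (heat-sensitive, strongly depleted);
* ``degraded`` compounds are present only before autoclaving;
* ``product`` compounds (heat-degradation products) appear only after.

Base peak areas are log-normal (LC-MS areas span orders of magnitude),
each observed area carries independent multiplicative log-normal
measurement noise per table, and areas under a detection threshold are
dropped from that table.  All randomness flows from one root seed through
named sub-streams, so e.g. changing the number of product compounds does
not perturb the stable compounds' areas or noise.

Note the composition effect is real and intended: relative abundance
re-normalizes within each table, so removing degraded mass and adding
product mass shifts every ratio.  "Stable" means stable in *area*; whether
stable compounds land inside the anti-aging ratio window under a given
parameter set is a property of the whole composition, checked in tests by
an independent brute-force oracle rather than assumed.
"""

from __future__ import annotations

import enum
import json
import math
import os
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .classify import StabilityLabel, StabilityResult
from .feature_io import CompoundRecord, FeatureTable, IonMode

FILTER_LABEL = "filter_sterilized"
AUTOCLAVE_LABEL = "autoclaved"

#: Ten coarse chemical-taxonomy labels of the kind compound annotation
#: pipelines attach (ClassyFire-style superclasses).
DEFAULT_SUPERCLASS_POOL = (
    "Lipids and lipid-like molecules",
    "Organic acids and derivatives",
    "Organoheterocyclic compounds",
    "Benzenoids",
    "Organic oxygen compounds",
    "Phenylpropanoids and polyketides",
    "Alkaloids and derivatives",
    "Nucleosides, nucleotides, and analogues",
    "Organic nitrogen compounds",
    "Organosulfur compounds",
)


class TrueClass(str, enum.Enum):
    STABLE = "stable"
    SENSITIVE = "sensitive"
    DEGRADED = "degraded"
    PRODUCT = "product"


# named sub-stream indices under the root seed
_STREAMS = {
    "stable_area": 0,
    "sensitive_area": 1,
    "retention": 2,
    "degraded_area": 3,
    "product_area": 4,
    "superclass": 5,
    "mz": 6,
    "rt": 7,
    "ion_mode": 8,
    "noise_filter_stable": 10,
    "noise_filter_sensitive": 11,
    "noise_filter_degraded": 12,
    "noise_autoclave_stable": 13,
    "noise_autoclave_sensitive": 14,
    "noise_autoclave_product": 15,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SimulationParams:
    """Generator parameters.

    Defaults are the reference screen preset: 89 stable + 13 sensitive shared compounds,
    368 degraded and 1141 products, mirroring the magnitudes of a real
    fermented-medium screen (470 compounds before autoclaving, 1243 after,
    102 shared).  ``area_log_mean``/``area_log_sd`` are the natural-log
    mean and SD of base peak areas (defaults give a median area of ~1e6
    detector units with a moderate, ~10-fold 95% range; a moderate spread
    keeps the total-area normalization stable at these compound counts so
    that the between-table composition shift stays small — see the package
    methods documentation);
    ``noise_log_sd`` is the SD of multiplicative measurement noise on the
    log scale (default 0.05, i.e. ~5% CV); sensitive compounds retain a
    uniform fraction in [retention_min, retention_max] of their area after
    autoclaving (default 2–5%, i.e. 95–98% destroyed).
    """

    n_stable: int = 89
    n_sensitive: int = 13
    n_degraded: int = 368
    n_products: int = 1141
    area_log_mean: float = math.log(1e6)
    area_log_sd: float = 0.6
    noise_log_sd: float = 0.05
    retention_min: float = 0.02
    retention_max: float = 0.05
    detection_threshold: float = 0.0
    seed: int = 0
    superclass_pool: tuple[str, ...] = DEFAULT_SUPERCLASS_POOL

    def __post_init__(self) -> None:
        if min(self.n_stable, self.n_sensitive, self.n_degraded, self.n_products) < 0:
            raise ValueError("compound counts must be non-negative")
        if self.n_stable + self.n_sensitive + self.n_degraded + self.n_products == 0:
            raise ValueError("at least one compound class must be non-empty")
        if not (0 < self.retention_min <= self.retention_max < 1):
            raise ValueError(
                "retention fractions must satisfy 0 < retention_min <= retention_max < 1"
            )
        if self.area_log_sd < 0 or self.noise_log_sd < 0:
            raise ValueError("log-scale standard deviations must be non-negative")
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_stable + self.n_sensitive + self.n_degraded + self.n_products


def reference_params(seed: int = 0, **overrides) -> SimulationParams:
    """The default preset with a chosen seed (and optional overrides)."""
    return replace(SimulationParams(seed=seed), **overrides)


@dataclass(frozen=True)
class TruthCompound:
    true_class: TrueClass
    base_area: float
    retention: Optional[float]  # set for sensitive compounds only
    superclass: str
    ion_mode: IonMode
    mz: float
    rt: float


@dataclass(frozen=True)
class SyntheticTruth:
    params: SimulationParams
    compounds: dict[str, TruthCompound]

    def keys_of(self, cls: TrueClass) -> list[str]:
        return [k for k, c in self.compounds.items() if c.true_class is cls]


def generate_truth(params: SimulationParams) -> SyntheticTruth:
    """Draw the planted compounds; deterministic for a fixed seed."""
    n_by_class = {
        TrueClass.STABLE: params.n_stable,
        TrueClass.SENSITIVE: params.n_sensitive,
        TrueClass.DEGRADED: params.n_degraded,
        TrueClass.PRODUCT: params.n_products,
    }
    area_stream = {
        TrueClass.STABLE: "stable_area",
        TrueClass.SENSITIVE: "sensitive_area",
        TrueClass.DEGRADED: "degraded_area",
        TrueClass.PRODUCT: "product_area",
    }
    retentions = _rng(params.seed, "retention").uniform(
        params.retention_min, params.retention_max, params.n_sensitive
    )
    sc_rng = _rng(params.seed, "superclass")
    mz_rng = _rng(params.seed, "mz")
    rt_rng = _rng(params.seed, "rt")
    mode_rng = _rng(params.seed, "ion_mode")

    compounds: dict[str, TruthCompound] = {}
    for cls, n in n_by_class.items():
        areas = _rng(params.seed, area_stream[cls]).lognormal(
            params.area_log_mean, params.area_log_sd, n
        )
        superclasses = sc_rng.choice(len(params.superclass_pool), size=n)
        mzs = mz_rng.uniform(50.0, 1100.0, n)
        rts = rt_rng.uniform(0.2, 18.0, n)
        modes = mode_rng.random(n) < 0.5
        for i in range(n):
            key = f"{cls.value}-{i + 1:04d}"
            compounds[key] = TruthCompound(
                true_class=cls,
                base_area=float(areas[i]),
                retention=float(retentions[i]) if cls is TrueClass.SENSITIVE else None,
                superclass=params.superclass_pool[int(superclasses[i])],
                ion_mode=IonMode.POSITIVE if modes[i] else IonMode.NEGATIVE,
                mz=float(mzs[i]),
                rt=float(rts[i]),
            )
    return SyntheticTruth(params=params, compounds=compounds)


def _noisy(base: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    if sd == 0:
        return base.copy()
    return base * np.exp(rng.normal(0.0, sd, base.shape))


def render_tables(truth: SyntheticTruth) -> tuple[FeatureTable, FeatureTable]:
    """Render the observed filter-sterilized and autoclaved tables.

    Each table gets an independent multiplicative noise draw per compound;
    observed areas below the detection threshold are dropped from that
    table only (which can move a compound between partition classes — the
    truth keeps the intended class).
    """
    p = truth.params

    def observed(keys: list[str], stream: str, scale: dict[str, float] | None = None) -> dict[str, float]:
        base = np.array(
            [truth.compounds[k].base_area * (scale[k] if scale else 1.0) for k in keys]
        )
        noisy = _noisy(base, _rng(p.seed, stream), p.noise_log_sd)
        return {
            k: float(a) for k, a in zip(keys, noisy) if a >= p.detection_threshold and a > 0
        }

    stable = truth.keys_of(TrueClass.STABLE)
    sensitive = truth.keys_of(TrueClass.SENSITIVE)
    degraded = truth.keys_of(TrueClass.DEGRADED)
    products = truth.keys_of(TrueClass.PRODUCT)
    retention = {k: truth.compounds[k].retention for k in sensitive}

    filter_areas: dict[str, float] = {}
    filter_areas.update(observed(stable, "noise_filter_stable"))
    filter_areas.update(observed(sensitive, "noise_filter_sensitive"))
    filter_areas.update(observed(degraded, "noise_filter_degraded"))

    autoclave_areas: dict[str, float] = {}
    autoclave_areas.update(observed(stable, "noise_autoclave_stable"))
    autoclave_areas.update(observed(sensitive, "noise_autoclave_sensitive", retention))
    autoclave_areas.update(observed(products, "noise_autoclave_product"))

    def table(label: str, areas: dict[str, float]) -> FeatureTable:
        records = tuple(
            CompoundRecord(
                compound_key=k,
                raw_name=k,
                ion_mode=truth.compounds[k].ion_mode,
                area=a,
                mz=truth.compounds[k].mz,
                rt=truth.compounds[k].rt,
                superclass=truth.compounds[k].superclass,
            )
            for k, a in sorted(areas.items())
        )
        return FeatureTable(treatment_label=label, records=records, dialect_name="synthetic")

    return table(FILTER_LABEL, filter_areas), table(AUTOCLAVE_LABEL, autoclave_areas)


@dataclass(frozen=True)
class ConfusionSummary:
    """Per-true-class tally of pipeline calls and the derived rates.

    ``per_class[true_class][outcome]`` counts compounds; outcomes are the
    three shared-compound labels plus ``not_shared`` (the compound fell in
    an exclusive partition set — for degraded/product compounds that is
    the correct recovery).  Sensitivities condition on the compound being
    shared (detected in both tables); specificities are over shared
    compounds of every other true class.  Rates are NaN when undefined.
    """

    per_class: dict[str, dict[str, int]]
    anti_aging_sensitivity: float
    inhibitor_sensitivity: float
    anti_aging_specificity: float
    inhibitor_specificity: float

    def count(self, true_class: TrueClass, outcome: str) -> int:
        return self.per_class.get(true_class.value, {}).get(outcome, 0)


NOT_SHARED = "not_shared"


def evaluate_recovery(result: StabilityResult, truth: SyntheticTruth) -> ConfusionSummary:
    """Score the pipeline's calls against the planted classes.

    Raises ``ValueError`` if the result contains a compound the truth does
    not know — the result must come from tables rendered from this truth.
    """
    predicted = {r.compound_key: r.label for r in result.records}
    unknown = set(predicted) - set(truth.compounds)
    if unknown:
        raise ValueError(
            f"result contains {len(unknown)} compound(s) absent from the truth, "
            f"e.g. {sorted(unknown)[:3]}"
        )

    per_class: dict[str, dict[str, int]] = {c.value: {} for c in TrueClass}
    for key, compound in truth.compounds.items():
        label = predicted.get(key)
        outcome = label.value if label is not None else NOT_SHARED
        bucket = per_class[compound.true_class.value]
        bucket[outcome] = bucket.get(outcome, 0) + 1

    def shared_of(cls: TrueClass) -> int:
        return sum(
            n for outcome, n in per_class[cls.value].items() if outcome != NOT_SHARED
        )

    def rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    n_stable_shared = shared_of(TrueClass.STABLE)
    n_sensitive_shared = shared_of(TrueClass.SENSITIVE)
    anti_tp = per_class[TrueClass.STABLE.value].get(StabilityLabel.ANTI_AGING.value, 0)
    inh_tp = per_class[TrueClass.SENSITIVE.value].get(StabilityLabel.INHIBITOR.value, 0)

    other_shared_anti = sum(shared_of(c) for c in TrueClass if c is not TrueClass.STABLE)
    other_anti_calls = sum(
        per_class[c.value].get(StabilityLabel.ANTI_AGING.value, 0)
        for c in TrueClass
        if c is not TrueClass.STABLE
    )
    other_shared_inh = sum(shared_of(c) for c in TrueClass if c is not TrueClass.SENSITIVE)
    other_inh_calls = sum(
        per_class[c.value].get(StabilityLabel.INHIBITOR.value, 0)
        for c in TrueClass
        if c is not TrueClass.SENSITIVE
    )

    return ConfusionSummary(
        per_class=per_class,
        anti_aging_sensitivity=rate(anti_tp, n_stable_shared),
        inhibitor_sensitivity=rate(inh_tp, n_sensitive_shared),
        anti_aging_specificity=rate(other_shared_anti - other_anti_calls, other_shared_anti),
        inhibitor_specificity=rate(other_shared_inh - other_inh_calls, other_shared_inh),
    )


# ---------------------------------------------------------------------------
# truth sidecar serialization (TSV + JSON params), used by the CLI

_TRUTH_TABLE = "truth.tsv"
_TRUTH_PARAMS = "truth_params.json"


def write_truth(truth: SyntheticTruth, out_dir: str | os.PathLike) -> dict[str, str]:
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    table_path = os.path.join(out_dir, _TRUTH_TABLE)
    params_path = os.path.join(out_dir, _TRUTH_PARAMS)
    rows = [
        {
            "compound_key": k,
            "true_class": c.true_class.value,
            "base_area": repr(c.base_area),
            "retention": repr(c.retention) if c.retention is not None else "",
            "superclass": c.superclass,
            "ion_mode": c.ion_mode.value,
            "mz": repr(c.mz),
            "rt": repr(c.rt),
        }
        for k, c in sorted(truth.compounds.items())
    ]
    pd.DataFrame(
        rows,
        columns=["compound_key", "true_class", "base_area", "retention",
                 "superclass", "ion_mode", "mz", "rt"],
    ).to_csv(table_path, sep="\t", index=False, encoding="utf-8")
    p = truth.params
    with open(params_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "n_stable": p.n_stable,
                "n_sensitive": p.n_sensitive,
                "n_degraded": p.n_degraded,
                "n_products": p.n_products,
                "area_log_mean": p.area_log_mean,
                "area_log_sd": p.area_log_sd,
                "noise_log_sd": p.noise_log_sd,
                "retention_min": p.retention_min,
                "retention_max": p.retention_max,
                "detection_threshold": p.detection_threshold,
                "seed": p.seed,
                "superclass_pool": list(p.superclass_pool),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return {"table": table_path, "params": params_path}


def read_truth(out_dir: str | os.PathLike) -> SyntheticTruth:
    out_dir = os.fspath(out_dir)
    with open(os.path.join(out_dir, _TRUTH_PARAMS), encoding="utf-8") as fh:
        raw = json.load(fh)
    raw["superclass_pool"] = tuple(raw["superclass_pool"])
    params = SimulationParams(**raw)
    frame = pd.read_csv(
        os.path.join(out_dir, _TRUTH_TABLE),
        sep="\t", dtype=str, keep_default_na=False, encoding="utf-8",
    )
    compounds = {
        row["compound_key"]: TruthCompound(
            true_class=TrueClass(row["true_class"]),
            base_area=float(row["base_area"]),
            retention=float(row["retention"]) if row["retention"] else None,
            superclass=row["superclass"],
            ion_mode=IonMode(row["ion_mode"]),
            mz=float(row["mz"]),
            rt=float(row["rt"]),
        )
        for _, row in frame.iterrows()
    }
    return SyntheticTruth(params=params, compounds=compounds)
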