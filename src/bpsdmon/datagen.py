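"""Synthetic labeled datasets drawn uniformly from the regularity tables.

Each sample is one person-moment: a vector of discrete factor levels drawn
independently and uniformly from the admissible range of its
(BPSD type, severity) cell.  Severity "none" yields label 3 (no BPSD)
regardless of the generating type, so the no-BPSD class is a mixture of the
three types' "none" columns.  The default composition is the published one:
per BPSD type 40 samples = 20 high + 10 mild + 10 none, 120 in total,
giving 30 samples per label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .regularities import (
    BPSD_TYPES,
    NO_BPSD,
    FactorSpec,
    RegularityTable,
    load_table,
    validate_sample,
)

__all__ = [
    "Sample",
    "Dataset",
    "DEFAULT_COMPOSITION",
    "default_composition",
    "generate_sample",
    "generate_dataset",
    "variant_feature_set",
    "variant_table",
    "VARIANTS",
]

#: The four classifier variants and their feature-set sizes.
VARIANTS = ("psyco", "psyco_hrv", "bephyen", "bephyen_nohrv")

#: Published per-(type, severity) composition: 20 high / 10 mild / 10 none
#: for each of agitation, apathy, depression.
DEFAULT_COMPOSITION: dict[tuple[int, str], int] = {
    (bpsd, sev): n
    for bpsd in BPSD_TYPES
    for sev, n in (("high", 20), ("mild", 10), ("none", 10))
}


def default_composition(total: int = 120) -> dict[tuple[int, str], int]:
    """The default composition scaled proportionally to ``total`` samples.

    ``total`` must be a multiple of 12 so the 20/10/10-per-type pattern
    scales to integers (60, 120, 240, 480, ...).
    """
    if total % 12 != 0:
        raise ValueError(f"total must be a multiple of 12, got {total}")
    return {key: n * total // 120 for key, n in DEFAULT_COMPOSITION.items()}


@dataclass(frozen=True)
class Sample:
    """One labeled vector of factor levels plus generation provenance."""

    values: dict[str, int]
    label: int
    bpsd_type: int
    severity: str

    def feature_vector(self, order: Iterable[str]) -> list[int]:
        return [self.values[name] for name in order]


@dataclass
class Dataset:
    """An ordered collection of samples from one model variant."""

    samples: list[Sample]
    model_kind: str
    seed: int | None = None
    composition: dict[tuple[int, str], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return variant_feature_set(self.model_kind)

    def label_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for s in self.samples:
            counts[s.label] = counts.get(s.label, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one column per feature plus label/bpsd_type/severity."""
        rows = [
            {**{n: s.values[n] for n in self.feature_names},
             "label": s.label, "bpsd_type": s.bpsd_type, "severity": s.severity}
            for s in self.samples
        ]
        return pd.DataFrame(rows, columns=[*self.feature_names, "label", "bpsd_type", "severity"])

    def X_y(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.array([s.feature_vector(self.feature_names) for s in self.samples])
        y = np.array([s.label for s in self.samples])
        return X, y

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_kind: str) -> "Dataset":
        df = pd.read_csv(path)
        feats = variant_feature_set(model_kind)
        samples = [
            Sample(
                values={n: int(row[n]) for n in feats},
                label=int(row["label"]),
                bpsd_type=int(row["bpsd_type"]),
                severity=str(row["severity"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(samples=samples, model_kind=model_kind)


def variant_feature_set(kind: str) -> tuple[str, ...]:
    """Ordered feature list for one of the four classifier variants."""
    psyco = (
        "impaired_communication",
        "somatic_diseases",
        "mmse",
        "weight_loss",
        "loss_of_insight",
        "stressful_events",
        "self_esteem",
        "anxiety",
    )
    bephyen = (
        "time",
        "environmental_change",
        "walking_speed",
        "hrv",
        "daytime_activity",
        "wandering",
    )
    if kind == "psyco":
        return psyco
    if kind == "psyco_hrv":
        return psyco + ("hrv",)
    if kind == "bephyen":
        return bephyen
    if kind == "bephyen_nohrv":
        return tuple(f for f in bephyen if f != "hrv")
    raise ValueError(f"unknown variant {kind!r}")


def variant_table(kind: str) -> RegularityTable:
    """Regularity table backing a variant's generator.

    ``psyco_hrv`` extends the PsyCo table with the HRV row of the BePhyEn
    table (no separate published table exists for this variant);
    ``bephyen_nohrv`` drops the HRV row.
    """
    if kind in ("psyco", "bephyen"):
        return load_table(kind)
    if kind == "psyco_hrv":
        psyco, bephyen = load_table("psyco"), load_table("bephyen")
        hrv_spec = bephyen.factor("hrv")
        factors = list(psyco.factors) + [
            FactorSpec("hrv", "psyco_hrv", hrv_spec.domain, hrv_spec.related_bpsd)
        ]
        entries = psyco.cells()
        for (name, bpsd, sev), rng in bephyen.cells().items():
            if name == "hrv":
                entries[(name, bpsd, sev)] = rng
        return RegularityTable("psyco_hrv", factors, entries)
    if kind == "bephyen_nohrv":
        bephyen = load_table("bephyen")
        factors = [
            FactorSpec(f.name, "bephyen_nohrv", f.domain, f.related_bpsd)
            for f in bephyen.factors
            if f.name != "hrv"
        ]
        entries = {k: v for k, v in bephyen.cells().items() if k[0] != "hrv"}
        return RegularityTable("bephyen_nohrv", factors, entries)
    raise ValueError(f"unknown variant {kind!r}")


def generate_sample(
    table: RegularityTable,
    bpsd: int,
    severity: str,
    rng: np.random.Generator,
) -> Sample:
    """Draw one sample for a (BPSD type, severity) stratum.

    Every factor level is drawn uniformly over the integers of its
    admissible range, inclusive of both ends.  Severity "none" labels the
    sample 3 (no BPSD); high/mild label it with the generating type.
    """
    if bpsd not in BPSD_TYPES:
        raise ValueError(f"generating bpsd type must be in {BPSD_TYPES}, got {bpsd}")
    values = {}
    for spec in table.factors:
        r = table.lookup(spec.name, bpsd, severity)
        values[spec.name] = int(rng.integers(r.lo, r.hi + 1))
    label = bpsd if severity in ("high", "mild") else NO_BPSD
    sample = Sample(values=values, label=label, bpsd_type=bpsd, severity=severity)
    assert validate_sample(values, table, bpsd, severity)
    return sample


def generate_dataset(
    table: RegularityTable,
    composition: Mapping[tuple[int, str], int] | None = None,
    seed: int = 0,
) -> Dataset:
    """Generate a shuffled labeled dataset; a pure function of its arguments.

    ``composition`` maps (bpsd_type, severity) to a sample count; the
    default is the published 120-sample composition.
    """
    comp = dict(DEFAULT_COMPOSITION if composition is None else composition)
    if any(n < 0 for n in comp.values()):
        raise ValueError("composition counts must be non-negative")
    rng = np.random.default_rng(seed)
    samples: list[Sample] = []
    for (bpsd, sev) in sorted(comp):
        for _ in range(comp[(bpsd, sev)]):
            samples.append(generate_sample(table, bpsd, sev, rng))
    order = rng.permutation(len(samples))
    samples = [samples[i] for i in order]
    return Dataset(samples=samples, model_kind=table.model_kind, seed=seed, composition=comp)
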