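"""Factor definitions, discretization rules, and regularity tables.

The two classifier families rest on "regularity tables": for every
(factor, BPSD type, severity) cell, a literature-derived admissible range of
discrete factor levels.  The PsyCo table covers eight psycho-cognitive
factors observable by caregivers; the BePhyEn table covers six
behavior/physiology/environment manifestations observable by sensors.
These tables are the generative model for every dataset in the package.

BPSD label coding used throughout: 0 = agitation, 1 = apathy,
2 = depression, 3 = no BPSD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "AGITATION",
    "APATHY",
    "DEPRESSION",
    "NO_BPSD",
    "BPSD_LABELS",
    "SEVERITIES",
    "LABEL_NAMES",
    "FactorSpec",
    "LevelRange",
    "RegularityTable",
    "load_table",
    "lookup_range",
    "discretize_time",
    "discretize_speed",
    "validate_sample",
]

AGITATION, APATHY, DEPRESSION, NO_BPSD = 0, 1, 2, 3
BPSD_LABELS = (AGITATION, APATHY, DEPRESSION, NO_BPSD)
#: The three symptomatic types a regularity table is indexed by.
BPSD_TYPES = (AGITATION, APATHY, DEPRESSION)
SEVERITIES = ("high", "mild", "none")
LABEL_NAMES = {0: "agitation", 1: "apathy", 2: "depression", 3: "no_bpsd"}

#: Inclusive integer level bounds for each factor domain.
DOMAIN_BOUNDS = {
    "ordinal4": (0, 3),
    "mmse": (0, 30),
    "time6": (0, 5),
    "binary": (0, 1),
}


@dataclass(frozen=True)
class LevelRange:
    """Inclusive integer range of admissible factor levels."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"empty level range ({self.lo}, {self.hi})")

    def __contains__(self, value: int) -> bool:
        return self.lo <= value <= self.hi

    def levels(self) -> range:
        """All admissible integer levels, inclusive of both ends."""
        return range(self.lo, self.hi + 1)


@dataclass(frozen=True)
class FactorSpec:
    """One model input: its discrete domain and the BPSD types it relates to."""

    name: str
    model_kind: str
    domain: str
    related_bpsd: frozenset[int]

    @property
    def bounds(self) -> tuple[int, int]:
        return DOMAIN_BOUNDS[self.domain]


class LookupError_(KeyError):
    """Unknown (factor, bpsd, severity) key in a regularity table."""


class RegularityTable:
    """(factor, BPSD type, severity) -> admissible level range.

    Complete over factors x {agitation, apathy, depression} x
    {high, mild, none}; the entries are a cell-for-cell transcription of the
    published range tables, shipped as versioned JSON fixtures.
    """

    def __init__(
        self,
        model_kind: str,
        factors: Iterable[FactorSpec],
        entries: Mapping[tuple[str, int, str], LevelRange],
    ) -> None:
        self.model_kind = model_kind
        self.factors = tuple(factors)
        self._entries = dict(entries)
        self._validate_complete()

    def _validate_complete(self) -> None:
        for spec in self.factors:
            lo_d, hi_d = spec.bounds
            for bpsd in BPSD_TYPES:
                for sev in SEVERITIES:
                    key = (spec.name, bpsd, sev)
                    if key not in self._entries:
                        raise ValueError(f"incomplete regularity table: missing {key}")
                    rng = self._entries[key]
                    if rng.lo < lo_d or rng.hi > hi_d:
                        raise ValueError(
                            f"range {rng} for {key} outside domain {spec.bounds}"
                        )

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.factors)

    def factor(self, name: str) -> FactorSpec:
        for spec in self.factors:
            if spec.name == name:
                return spec
        raise LookupError_(f"unknown factor {name!r} for model {self.model_kind!r}")

    def lookup(self, factor: str, bpsd: int, severity: str) -> LevelRange:
        self.factor(factor)  # raises for unknown factor
        if bpsd not in BPSD_TYPES:
            raise LookupError_(
                f"bpsd must be one of {BPSD_TYPES} for a range lookup, got {bpsd!r}"
            )
        if severity not in SEVERITIES:
            raise LookupError_(f"unknown severity {severity!r}")
        return self._entries[(factor, bpsd, severity)]

    def cells(self) -> dict[tuple[str, int, str], LevelRange]:
        """A copy of all table cells (54 per published table)."""
        return dict(self._entries)


def _table_from_dict(payload: dict) -> RegularityTable:
    kind = payload["model_kind"]
    factors = [
        FactorSpec(
            name=f["name"],
            model_kind=kind,
            domain=f["domain"],
            related_bpsd=frozenset(f["related_bpsd"]),
        )
        for f in payload["factors"]
    ]
    entries: dict[tuple[str, int, str], LevelRange] = {}
    for fname, per_bpsd in payload["entries"].items():
        for bpsd_str, per_sev in per_bpsd.items():
            for sev, (lo, hi) in per_sev.items():
                entries[(fname, int(bpsd_str), sev)] = LevelRange(lo, hi)
    return RegularityTable(kind, factors, entries)


def load_table(model_kind: str) -> RegularityTable:
    """Load a packaged regularity table: ``"psyco"`` or ``"bephyen"``.

    The composite feature sets (PsyCo+HRV, BePhyEn without HRV) are derived
    from these two tables by :func:`bpsdmon.datagen.variant_tables`.
    """
    if model_kind not in ("psyco", "bephyen"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    ref = resources.files("bpsdmon.data") / f"regularities_{model_kind}.json"
    payload = json.loads(ref.read_text())
    table = _table_from_dict(payload)
    n_expected = 8 if model_kind == "psyco" else 6
    if len(table.factors) != n_expected:
        raise ValueError(
            f"{model_kind} table must define {n_expected} factors, "
            f"got {len(table.factors)}"
        )
    return table


def lookup_range(
    table: RegularityTable, factor: str, bpsd: int, severity: str
) -> LevelRange:
    """Admissible level range for a factor under one (BPSD type, severity)."""
    return table.lookup(factor, bpsd, severity)


def discretize_time(hour: float) -> int:
    """Map a 0-24 clock hour to the six-valued time-of-day level.

    Morning (9-12) is level 0; afternoon through evening bins follow at
    12-15, 15-17 (the peak-agitation window), 17-19 (the classic wandering
    window), 19-21 (sundowning); every other hour is level 5.  Bins are
    left-closed, right-open.
    """
    if not 0.0 <= hour < 24.0:
        raise ValueError(f"hour must lie in [0, 24), got {hour}")
    for level, (lo, hi) in enumerate([(9, 12), (12, 15), (15, 17), (17, 19), (19, 21)]):
        if lo <= hour < hi:
            return level
    return 5


def discretize_speed(v: float) -> int:
    """Map a walking speed in m/s to the four-valued speed level.

    Levels: very low [0, 0.7), low [0.7, 0.9), normal [0.9, 1.2),
    high [1.2, inf).  Slow gait is the strongest single behavioral marker of
    dementia, hence the asymmetric cut points.
    """
    if v < 0:
        raise ValueError(f"speed must be non-negative, got {v}")
    if v < 0.7:
        return 0
    if v < 0.9:
        return 1
    if v < 1.2:
        return 2
    return 3


def validate_sample(
    values: Mapping[str, int],
    table: RegularityTable,
    bpsd: int,
    severity: str,
) -> bool:
    """True iff every factor value lies inside its (bpsd, severity) range.

    A missing factor makes the sample invalid rather than raising, so the
    check can be used as a bulk filter over generated data.
    """
    for spec in table.factors:
        if spec.name not in values:
            return False
        if values[spec.name] not in table.lookup(spec.name, bpsd, severity):
            return False
    return True
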