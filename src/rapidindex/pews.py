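"""Configurable aggregated Paediatric Early Warning (PEW) score.

Seven bedside parameters — respiratory rate, respiratory distress,
pulse-oximetry, inspired oxygen, heart rate, systolic blood pressure and
capillary refill time — each map through age-banded bands to a small
integer subscore; the total runs 0-26 and a score of >= 9 triggers a
request for intensive-care review.

The exact band cut-offs of the originating hospital chart are not
published; the default table shipped here is a structurally faithful
reconstruction (seven parameters, maximum total 26, alert threshold 9,
age-banded vital-sign bands) intended for simulation and pipeline work,
not for clinical use.  Any table obeying the same schema can be loaded
from YAML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

PARAMETERS = (
    "respiratory_rate",
    "respiratory_distress",
    "spo2",
    "inspired_oxygen",
    "heart_rate",
    "systolic_bp",
    "capillary_refill_seconds",
)

MAX_TOTAL = 26
ALERT_THRESHOLD = 9


@dataclass(frozen=True)
class PewsObservation:
    """One nurse observation set; ``None`` marks an unrecorded parameter."""

    timestamp: int
    respiratory_rate: float | None = None
    respiratory_distress: int | None = None
    spo2: float | None = None
    inspired_oxygen: float | None = None
    heart_rate: float | None = None
    systolic_bp: float | None = None
    capillary_refill_seconds: float | None = None

    def __post_init__(self) -> None:
        for p in PARAMETERS:
            v = getattr(self, p)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{p} must be finite")
        if self.respiratory_distress is not None and not 0 <= self.respiratory_distress <= 3:
            raise ValueError("respiratory_distress must be an ordinal 0..3")


#: a band is (lower, upper, subscore); lower inclusive, upper exclusive,
#: bands must partition (-inf, inf)
Band = tuple[float, float, int]


def _sym_bands(lo: float, hi: float, step: float, scores=(0, 1, 2, 3, 4)) -> list[Band]:
    """Normal range [lo, hi) scores 0; each ``step`` outside adds a point."""
    inf = float("inf")
    s1, s2, s3, s4 = scores[1:]
    return [
        (-inf, lo - 3 * step, s4),
        (lo - 3 * step, lo - 2 * step, s3),
        (lo - 2 * step, lo - step, s2),
        (lo - step, lo, s1),
        (lo, hi, scores[0]),
        (hi, hi + step, s1),
        (hi + step, hi + 2 * step, s2),
        (hi + 2 * step, hi + 3 * step, s3),
        (hi + 3 * step, inf, s4),
    ]


def _default_table_dict() -> dict:
    inf = float("inf")
    age_bands = [(0, 12), (12, 60), (60, 144), (144, 10**9)]
    rr_normal = {0: (25, 50, 10), 12: (20, 40, 8), 60: (16, 30, 7), 144: (12, 25, 6)}
    hr_normal = {0: (100, 160, 20), 12: (90, 140, 18), 60: (70, 120, 15), 144: (60, 100, 13)}
    bp_normal = {0: (65, 110, 12), 12: (70, 115, 12), 60: (80, 125, 13), 144: (90, 135, 14)}

    def banded(spec):
        return [
            {"age_lo": lo, "age_hi": hi, "bands": _sym_bands(*spec[lo])}
            for lo, hi in age_bands
        ]

    return {
        "alert_threshold": ALERT_THRESHOLD,
        "parameters": {
            "respiratory_rate": {"age_banded": True, "tables": banded(rr_normal)},
            "heart_rate": {"age_banded": True, "tables": banded(hr_normal)},
            "systolic_bp": {"age_banded": True, "tables": banded(bp_normal)},
            "respiratory_distress": {
                "age_banded": False,
                "bands": [(-inf, 1, 0), (1, 2, 1), (2, 3, 2), (3, inf, 3)],
            },
            "spo2": {
                "age_banded": False,
                "bands": [
                    (-inf, 80, 4),
                    (80, 85, 3),
                    (85, 90, 2),
                    (90, 95, 1),
                    (95, inf, 0),
                ],
            },
            "inspired_oxygen": {
                # fraction of inspired oxygen; room air is 0.21
                "age_banded": False,
                "bands": [
                    (-inf, 0.22, 0),
                    (0.22, 0.30, 1),
                    (0.30, 0.40, 2),
                    (0.40, 0.60, 3),
                    (0.60, inf, 4),
                ],
            },
            "capillary_refill_seconds": {
                "age_banded": False,
                "bands": [(-inf, 2, 0), (2, 3, 1), (3, 5, 2), (5, inf, 3)],
            },
        },
    }


@dataclass
class PewsScoringTable:
    """Age-banded value -> subscore bands for the seven parameters."""

    spec: dict = field(default_factory=_default_table_dict)

    def __post_init__(self) -> None:
        params = self.spec["parameters"]
        missing = set(PARAMETERS) - set(params)
        if missing:
            raise ValueError(f"table missing parameters: {sorted(missing)}")
        if self.max_total() != MAX_TOTAL:
            raise ValueError(f"max subscores must sum to {MAX_TOTAL}, got {self.max_total()}")
        for name in PARAMETERS:
            for bands in self._all_band_lists(name):
                self._check_partition(name, bands)

    def _all_band_lists(self, name: str) -> list[list[Band]]:
        p = self.spec["parameters"][name]
        if p.get("age_banded"):
            return [[tuple(b) for b in t["bands"]] for t in p["tables"]]
        return [[tuple(b) for b in p["bands"]]]

    @staticmethod
    def _check_partition(name: str, bands: list[Band]) -> None:
        bands = sorted(bands, key=lambda b: b[0])
        if bands[0][0] != -float("inf") or bands[-1][1] != float("inf"):
            raise ValueError(f"{name}: bands must cover the whole real line")
        for (_, hi, sc), (lo2, _, _) in zip(bands, bands[1:]):
            if hi != lo2:
                raise ValueError(f"{name}: bands must partition (gap/overlap at {hi})")
        for _, _, sc in bands:
            if sc < 0 or int(sc) != sc:
                raise ValueError(f"{name}: subscores must be non-negative integers")

    def max_total(self) -> int:
        total = 0
        for name in PARAMETERS:
            total += max(
                max(b[2] for b in bands) for bands in self._all_band_lists(name)
            )
        return total

    @property
    def alert_threshold(self) -> int:
        return int(self.spec.get("alert_threshold", ALERT_THRESHOLD))

    def bands_for(self, name: str, age_months: float) -> list[Band]:
        p = self.spec["parameters"][name]
        if not p.get("age_banded"):
            return [tuple(b) for b in p["bands"]]
        for t in p["tables"]:
            if t["age_lo"] <= age_months < t["age_hi"]:
                return [tuple(b) for b in t["bands"]]
        raise ValueError(f"no {name} bands for age {age_months} months")

    def subscore(self, name: str, value: float, age_months: float) -> int:
        for lo, hi, sc in self.bands_for(name, age_months):
            if lo <= value < hi:
                return int(sc)
        raise ValueError(f"{name}={value} outside all scoring bands")

    # -- YAML ----------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(listify(self.spec), default_flow_style=None))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PewsScoringTable":
        return cls(spec=yaml.safe_load(Path(path).read_text()))


def compute_pews(
    obs: PewsObservation, table: PewsScoringTable | None = None, age_months: float = 27.0
) -> int:
    """Aggregate PEW score 0..26; missing parameters score 0 with a warning."""
    table = table or PewsScoringTable()
    total = 0
    missing = []
    for name in PARAMETERS:
        v = getattr(obs, name)
        if v is None:
            missing.append(name)
            continue
        total += table.subscore(name, float(v), age_months)
    if missing:
        warnings.warn(f"observation incomplete ({', '.join(missing)} scored 0)", stacklevel=2)
    return total


def pews_alert_series(
    observations: list[PewsObservation],
    table: PewsScoringTable | None = None,
    age_months: float = 27.0,
    threshold: int = ALERT_THRESHOLD,
) -> list[int]:
    """Timestamps of observations whose score meets the alert threshold."""
    table = table or PewsScoringTable()
    out = []
    last_t = None
    for obs in observations:
        if last_t is not None and obs.timestamp < last_t:
            raise ValueError("observations must be sorted by timestamp")
        last_t = obs.timestamp
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if compute_pews(obs, table, age_months) >= threshold:
                out.append(obs.timestamp)
    return out
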