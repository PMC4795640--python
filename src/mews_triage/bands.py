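"""Scoring bands for the Modified Early Warning Score (MEWS).

The MEWS maps five bedside observations — systolic blood pressure, pulse
rate, respiratory rate, axillary temperature and AVPU consciousness level —
to integer subscores whose sum (0–14) grades haemodynamic instability.
This module holds the banded scoring rule as data, so that alternative
boundary conventions can be loaded from a config file without touching code.

The default rule uses half-open intervals ``[lo, hi)`` cut at the published
lower bound of each band (the top band of each parameter is closed at the
admissible-range ceiling).  This closes the boundary gaps of the printed
rule deterministically: every admissible value maps to exactly one subscore.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

__all__ = ["Band", "ScoreBands", "default_bands", "SCORED_PARAMETERS", "AVPU_LEVELS"]

#: The five scored parameters, in canonical order.
SCORED_PARAMETERS = ("sbp", "pulse", "rr", "temp", "avpu")

#: AVPU consciousness levels, most to least alert.
AVPU_LEVELS = ("A", "V", "P", "U")

#: Admissible measurement ranges; values outside are rejected, and unbounded
#: printed bands are truncated here.  Units: mmHg, bpm, breaths/min, degC.
ADMISSIBLE_RANGES = {
    "sbp": (1.0, 300.0),
    "pulse": (1.0, 250.0),
    "rr": (1.0, 80.0),
    "temp": (25.0, 45.0),
}


@dataclass(frozen=True)
class Band:
    """One scoring interval ``[lo, hi)`` mapping to an integer subscore."""

    lo: float
    hi: float
    score: int

    def __contains__(self, value: float) -> bool:
        return self.lo <= value < self.hi


class BandCoverageError(ValueError):
    """The band set does not partition the admissible range."""


@dataclass
class ScoreBands:
    """A complete MEWS scoring rule: interval bands per vital plus the AVPU map.

    Invariants (checked by :meth:`validate`): for each parameter the bands are
    disjoint and cover the admissible range exactly; subscores are integers in
    0–3; the maximum attainable total is 14.
    """

    sbp: list[Band]
    pulse: list[Band]
    rr: list[Band]
    temp: list[Band]
    avpu_map: dict[str, int] = field(
        default_factory=lambda: {"A": 0, "V": 1, "P": 2, "U": 3}
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- scoring ----------------------------------------------------------

    def bands_for(self, parameter: str) -> list[Band]:
        if parameter not in ("sbp", "pulse", "rr", "temp"):
            raise KeyError(f"no interval bands for parameter {parameter!r}")
        return getattr(self, parameter)

    def score(self, parameter: str, value) -> int:
        """Subscore for one measurement; raises for invalid input.

        AVPU takes a single-letter code; the other four take a number inside
        the parameter's admissible range.
        """
        if parameter == "avpu":
            try:
                return self.avpu_map[str(value)]
            except KeyError:
                raise ValueError(
                    f"avpu level must be one of {sorted(self.avpu_map)}, got {value!r}"
                ) from None
        if parameter not in ADMISSIBLE_RANGES:
            raise KeyError(f"unknown parameter {parameter!r}")
        value = float(value)
        lo, hi = ADMISSIBLE_RANGES[parameter]
        if not (lo <= value <= hi) or value != value:
            raise ValueError(
                f"{parameter} = {value!r} outside admissible range [{lo}, {hi}]"
            )
        bands = self.bands_for(parameter)
        # top band is closed at the ceiling
        if value == bands[-1].hi:
            return bands[-1].score
        for band in bands:
            if value in band:
                return band.score
        raise BandCoverageError(f"{parameter} = {value} matched no band")  # pragma: no cover

    def max_total(self) -> int:
        return sum(
            max(b.score for b in self.bands_for(p)) for p in ("sbp", "pulse", "rr", "temp")
        ) + max(self.avpu_map.values())

    def achievable_subscores(self, parameter: str) -> tuple[int, ...]:
        """Sorted distinct subscores reachable for one parameter."""
        if parameter == "avpu":
            return tuple(sorted(set(self.avpu_map.values())))
        return tuple(sorted({b.score for b in self.bands_for(parameter)}))

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for parameter in ("sbp", "pulse", "rr", "temp"):
            bands = self.bands_for(parameter)
            if not bands:
                raise BandCoverageError(f"{parameter}: empty band list")
            lo, hi = ADMISSIBLE_RANGES[parameter]
            ordered = sorted(bands, key=lambda b: b.lo)
            if ordered[0].lo > lo or ordered[-1].hi < hi:
                raise BandCoverageError(
                    f"{parameter}: bands do not span admissible range [{lo}, {hi}]"
                )
            for left, right in zip(ordered, ordered[1:]):
                if left.hi != right.lo:
                    raise BandCoverageError(
                        f"{parameter}: gap or overlap between {left} and {right}"
                    )
            for band in bands:
                if band.lo >= band.hi:
                    raise BandCoverageError(f"{parameter}: empty interval {band}")
                if not (0 <= band.score <= 3 and int(band.score) == band.score):
                    raise BandCoverageError(f"{parameter}: subscore out of 0-3 in {band}")
        if set(self.avpu_map) != set(AVPU_LEVELS):
            raise BandCoverageError(f"avpu_map must cover exactly {AVPU_LEVELS}")
        if self.max_total() != 14:
            raise BandCoverageError(
                f"maximum attainable total is {self.max_total()}, expected 14"
            )

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {"avpu_map": dict(self.avpu_map)}
        for parameter in ("sbp", "pulse", "rr", "temp"):
            out[parameter] = [
                {"lo": b.lo, "hi": b.hi, "score": int(b.score)}
                for b in self.bands_for(parameter)
            ]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ScoreBands":
        kwargs = {
            parameter: [Band(float(d["lo"]), float(d["hi"]), int(d["score"]))
                        for d in data[parameter]]
            for parameter in ("sbp", "pulse", "rr", "temp")
        }
        return cls(avpu_map={k: int(v) for k, v in data["avpu_map"].items()}, **kwargs)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "ScoreBands":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def default_bands() -> ScoreBands:
    """The standard MEWS rule (classic five-parameter bands, gap-closed).

    Cut points sit at the published lower bound of each band; each interval is
    ``[lo, hi)`` with the parameter's top band closed at the admissible
    ceiling.  Low SBP <= 70 scores 3 and SBP >= 200 scores 2; pulse <= 40
    scores 2 and >= 130 scores 3; respiratory rate <= 8 scores 2 and >= 30
    scores 3; temperature below 35 or at/above 38.5 scores 2 (the temperature
    row has no 1-band).
    """
    s = ADMISSIBLE_RANGES
    return ScoreBands(
        sbp=[
            Band(s["sbp"][0], 71, 3),
            Band(71, 81, 2),
            Band(81, 101, 1),
            Band(101, 200, 0),
            Band(200, s["sbp"][1], 2),
        ],
        pulse=[
            Band(s["pulse"][0], 41, 2),
            Band(41, 51, 1),
            Band(51, 101, 0),
            Band(101, 111, 1),
            Band(111, 130, 2),
            Band(130, s["pulse"][1], 3),
        ],
        rr=[
            Band(s["rr"][0], 9, 2),
            Band(9, 15, 0),
            Band(15, 21, 1),
            Band(21, 30, 2),
            Band(30, s["rr"][1], 3),
        ],
        temp=[
            Band(s["temp"][0], 35, 2),
            Band(35, 38.5, 0),
            Band(38.5, s["temp"][1], 2),
        ],
    )
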