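"""Experimental design model for multi-fraction IP proteomics.

A study is a collection of *sample sets* — one bait strain harvested under
one condition (and, optionally, one stress time point) — each separated
into an ordered series of fractions (by default IP, P, S, T, U: elution,
20,000 g pellet, supernatant, total lysate and IP-unbound) and measured in
replicate. Conditions are grouped into analysis *splits* (e.g. untreated
vs. glucose-depleted), each of which yields one concatenated profile
vector per protein downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import yaml

DEFAULT_FRACTIONS: tuple[str, ...] = ("IP", "P", "S", "T", "U")


@dataclass(frozen=True)
class SampleSet:
    """One bait x condition (x time) combination fractionated together."""

    bait: str
    condition: str
    tagged: bool
    time: str = ""

    @property
    def label(self) -> str:
        return f"{self.bait}|{self.condition}"


@dataclass(frozen=True)
class SampleKey:
    """Unique address of one intensity column."""

    bait: str
    condition: str
    fraction: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


@dataclass
class StudyDesign:
    """Sample sets, fraction order, replication and condition grouping.

    ``groups`` maps each condition label to the analysis split it belongs
    to; conditions absent from the mapping form their own split.
    """

    sample_sets: list[SampleSet]
    fractions: tuple[str, ...] = DEFAULT_FRACTIONS
    n_replicates: int = 3
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fractions = tuple(self.fractions)
        if len(set(self.fractions)) != len(self.fractions):
            raise ValueError("fraction labels must be unique")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        labels = [s.label for s in self.sample_sets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate sample-set labels: {labels}")
        for split in self.splits():
            sets = self.sample_sets_for(split)
            if not any(s.tagged for s in sets):
                raise ValueError(f"split {split!r} has no tagged sample set")
            if not any(not s.tagged for s in sets):
                raise ValueError(f"split {split!r} has no untagged control")

    def split_of(self, condition: str) -> str:
        return self.groups.get(condition, condition)

    def splits(self) -> list[str]:
        out: list[str] = []
        for s in self.sample_sets:
            g = self.split_of(s.condition)
            if g not in out:
                out.append(g)
        return out

    def sample_sets_for(self, split: str) -> list[SampleSet]:
        return [s for s in self.sample_sets if self.split_of(s.condition) == split]

    def sample_keys(self) -> list[SampleKey]:
        """All intensity-column keys in canonical order.

        Sample sets in declared order, fractions in design order,
        replicates innermost.
        """
        return [
            SampleKey(s.bait, s.condition, f, r)
            for s in self.sample_sets
            for f in self.fractions
            for r in range(1, self.n_replicates + 1)
        ]

    def tagged_ip_columns(self) -> list[SampleKey]:
        return [
            k
            for k, s in zip(self.sample_keys(), self._key_sets())
            if s.tagged and k.fraction == self.fractions[0]
        ]

    def _key_sets(self) -> list[SampleSet]:
        return [
            s
            for s in self.sample_sets
            for _ in self.fractions
            for _ in range(self.n_replicates)
        ]

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        sets = [
            SampleSet(
                bait=s["bait"],
                condition=s["condition"],
                tagged=bool(s["tagged"]),
                time=str(s.get("time", "")),
            )
            for s in d["sample_sets"]
        ]
        return cls(
            sample_sets=sets,
            fractions=tuple(d.get("fractions", DEFAULT_FRACTIONS)),
            n_replicates=int(d.get("n_replicates", 3)),
            groups=dict(d.get("groups", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "sample_sets": [
                {
                    "bait": s.bait,
                    "condition": s.condition,
                    "tagged": s.tagged,
                    "time": s.time,
                }
                for s in self.sample_sets
            ],
            "fractions": list(self.fractions),
            "n_replicates": self.n_replicates,
            "groups": dict(self.groups),
        }


def granule_ip_design(n_replicates: int = 3) -> StudyDesign:
    """The two-marker granule IP design.

    Untreated: Dcp1-myc (P-body marker bait), Pbp1-myc (stress-granule
    marker bait) and an untagged control — three sample sets, giving
    3 x 5 = 15 profile values. Glucose-depleted: Dcp1-myc at 10 min,
    Pbp1-myc at 60 min (the respective condensate-induction times) plus
    time-matched untagged controls — four sample sets, 4 x 5 = 20 values.
    """
    sets = [
        SampleSet("dcp1_myc", "untreated", True),
        SampleSet("pbp1_myc", "untreated", True),
        SampleSet("untagged", "untreated", False),
        SampleSet("dcp1_myc", "glucose_10min", True, time="10"),
        SampleSet("pbp1_myc", "glucose_60min", True, time="60"),
        SampleSet("untagged", "glucose_10min", False, time="10"),
        SampleSet("untagged", "glucose_60min", False, time="60"),
    ]
    groups = {
        "untreated": "untreated",
        "glucose_10min": "glucose_depleted",
        "glucose_60min": "glucose_depleted",
    }
    return StudyDesign(sample_sets=sets, n_replicates=n_replicates, groups=groups)


def parse_generic_column(name: str) -> SampleKey:
    """Parse a generic-dialect column header ``bait|condition|fraction|repK``."""
    parts = name.split("|")
    if len(parts) != 4 or not parts[3].startswith("rep"):
        raise ValueError(f"cannot parse column header {name!r}")
    try:
        rep = int(parts[3][3:])
    except ValueError as exc:
        raise ValueError(f"cannot parse replicate in {name!r}") from exc
    return SampleKey(parts[0], parts[1], parts[2], rep)


def format_generic_column(key: SampleKey) -> str:
    return f"{key.bait}|{key.condition}|{key.fraction}|rep{key.replicate}"


def expect_columns(design: StudyDesign, names: Iterable[str]) -> None:
    wanted = {format_generic_column(k) for k in design.sample_keys()}
    got = set(names)
    missing = wanted - got
    if missing:
        raise ValueError(f"design columns missing from table: {sorted(missing)[:5]} ...")
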