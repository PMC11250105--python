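"""Stimulus protocols for islet perifusion experiments.

A protocol is an ordered list of non-overlapping time segments, each tagged with
the stimulus applied during that window (basal glucose, 15 or 6 mM glucose,
5 mM leucine, a 1.5 mM oleate/palmitate mixture, combinations with 6 mM
glucose, or 30 mM KCl).  Exactly one segment is the designated pre-stimulus
baseline used for baseline subtraction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = [
    "Segment",
    "StimulusProtocol",
    "canonical_protocols",
    "read_protocol_yaml",
    "write_protocol_yaml",
    "STIMULUS_LABELS",
]

#: recognised stimulus labels
STIMULUS_LABELS = (
    "basal",
    "glucose15",
    "glucose6",
    "leucine",
    "leu_plus_g6",
    "fat",
    "fat_plus_g6",
    "kcl",
    "washout",
)


@dataclass(frozen=True)
class Segment:
    """One contiguous stimulus window of a perifusion protocol."""

    name: str
    stimulus: str
    start_min: float
    end_min: float
    notes: str = ""

    def __post_init__(self) -> None:
        if self.stimulus not in STIMULUS_LABELS:
            raise ValueError(f"unknown stimulus label {self.stimulus!r}")
        if not self.end_min > self.start_min:
            raise ValueError(
                f"segment {self.name!r}: end_min must exceed start_min"
            )

    @property
    def duration(self) -> float:
        return self.end_min - self.start_min


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping segments with one designated baseline."""

    arm: str
    segments: tuple[Segment, ...]
    baseline_segment: str = "baseline"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        prev_end = None
        for seg in self.segments:
            if prev_end is not None and seg.start_min < prev_end:
                raise ValueError(
                    f"segments overlap or are out of order at {seg.name!r}"
                )
            prev_end = seg.end_min
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        if self.baseline_segment not in names:
            raise ValueError(
                f"baseline segment {self.baseline_segment!r} not in protocol"
            )

    def __getitem__(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    @property
    def baseline(self) -> Segment:
        return self[self.baseline_segment]

    @property
    def stimulus_segments(self) -> tuple[Segment, ...]:
        """Segments carrying a nutrient/depolarization stimulus (not basal or washout)."""
        return tuple(
            s for s in self.segments if s.stimulus not in ("basal", "washout")
        )

    @property
    def end_min(self) -> float:
        return self.segments[-1].end_min


def canonical_protocols() -> dict[str, StimulusProtocol]:
    """The canonical three-arm perifusion protocol set.

    Each arm starts with a 24-min recording at 3 mM basal glucose (after an
    unrecorded equilibration), followed by stimulus windows separated by
    15-min washouts back to basal glucose.  The glucose arm carries the
    40-min 15 mM glucose challenge (15 min first phase + 25 min second
    phase), the moderate 6 mM glucose challenge, and the 30 mM KCl
    depolarization.  The leucine and fat arms test the nutrient alone at
    basal glucose and then combined with 6 mM glucose.
    """
    arm_g = StimulusProtocol(
        arm="G",
        segments=(
            Segment("baseline", "basal", 0.0, 24.0, "3 mM glucose"),
            Segment("glucose15", "glucose15", 24.0, 64.0, "15 mM glucose"),
            Segment("washout1", "washout", 64.0, 79.0, "3 mM glucose"),
            Segment("glucose6", "glucose6", 79.0, 104.0, "6 mM glucose"),
            Segment("washout2", "washout", 104.0, 119.0, "3 mM glucose"),
            Segment("kcl", "kcl", 119.0, 134.0, "30 mM KCl"),
        ),
    )
    arm_l = StimulusProtocol(
        arm="L",
        segments=(
            Segment("baseline", "basal", 0.0, 24.0, "3 mM glucose"),
            Segment("leucine", "leucine", 24.0, 64.0, "5 mM leucine, 3 mM glucose"),
            Segment("washout1", "washout", 64.0, 79.0, "3 mM glucose"),
            Segment(
                "leu_plus_g6", "leu_plus_g6", 79.0, 104.0, "5 mM leucine + 6 mM glucose"
            ),
            Segment("washout2", "washout", 104.0, 119.0, "3 mM glucose"),
        ),
    )
    arm_f = StimulusProtocol(
        arm="F",
        segments=(
            Segment("baseline", "basal", 0.0, 24.0, "3 mM glucose"),
            Segment(
                "fat", "fat", 24.0, 64.0, "1.5 mM oleate/palmitate 1:1, 3 mM glucose"
            ),
            Segment("washout1", "washout", 64.0, 79.0, "3 mM glucose"),
            Segment(
                "fat_plus_g6",
                "fat_plus_g6",
                79.0,
                104.0,
                "1.5 mM oleate/palmitate + 6 mM glucose",
            ),
            Segment("washout2", "washout", 104.0, 119.0, "3 mM glucose"),
        ),
    )
    return {"G": arm_g, "L": arm_l, "F": arm_f}


def write_protocol_yaml(protocols: dict[str, StimulusProtocol], path) -> None:
    doc = {
        arm: {
            "baseline_segment": p.baseline_segment,
            "segments": [
                {
                    "name": s.name,
                    "stimulus": s.stimulus,
                    "start_min": s.start_min,
                    "end_min": s.end_min,
                    "notes": s.notes,
                }
                for s in p.segments
            ],
        }
        for arm, p in protocols.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_protocol_yaml(path) -> dict[str, StimulusProtocol]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for arm, block in doc.items():
        segs = tuple(
            Segment(
                d["name"], d["stimulus"], float(d["start_min"]), float(d["end_min"]),
                d.get("notes", ""),
            )
            for d in block["segments"]
        )
        out[arm] = StimulusProtocol(
            arm=arm, segments=segs, baseline_segment=block["baseline_segment"]
        )
    return out
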