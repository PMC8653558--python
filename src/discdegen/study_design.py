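"""Experimental layout of the rabbit lumbar disc degeneration study.

A single lumbar spine carries five motion segments, each receiving a
different treatment: a contrast-agent-only injection control (CA), three
monosodium-iodoacetate doses (MIA 0.01 / 0.1 / 1.0 mg in 10 µl CA), and a
non-injected control level (NI) that serves as the normalisation reference
for every height index. Cohorts of six animals are sacrificed at 2, 4, 8
and 12 weeks; within each cohort three animals go to micro-CT and three to
MRI, and all discs proceed to histology afterwards. Radiographs are taken
at baseline (week 0) and every two weeks.

Every downstream module keys its inputs on this design, so it is encoded
once here and serialised losslessly through YAML/JSON config blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = [
    "Treatment",
    "StudyDesign",
    "default_design",
    "DISC_LEVELS",
    "TREATMENT_LABELS",
]

#: Lumbar disc levels in cranio-caudal order (L6-L7 excluded: too close to
#: the lumbosacral junction).
DISC_LEVELS = ("L1-L2", "L2-L3", "L3-L4", "L4-L5", "L5-L6")

TREATMENT_LABELS = ("CA", "MIA_0.01", "MIA_0.1", "MIA_1.0", "NI")

_ALLOWED_DOSES = (0.0, 0.01, 0.1, 1.0)


@dataclass(frozen=True)
class Treatment:
    """One injection condition applied to a disc level.

    ``dose_mg`` is the MIA dose; CA and NI carry 0.  All injected levels
    (CA and the three MIA doses) receive a 10 µl vehicle volume; NI is
    untouched.
    """

    label: str
    dose_mg: float
    vehicle_volume_ul: float

    def __post_init__(self) -> None:
        if self.label not in TREATMENT_LABELS:
            raise ValueError(f"unknown treatment label {self.label!r}")
        if self.dose_mg < 0 or self.dose_mg not in _ALLOWED_DOSES:
            raise ValueError(f"dose_mg must be one of {_ALLOWED_DOSES}, got {self.dose_mg}")
        if self.label == "NI" and self.vehicle_volume_ul != 0:
            raise ValueError("NI control receives no vehicle")
        if self.label != "NI" and self.vehicle_volume_ul != 10:
            raise ValueError("injected treatments receive 10 ul of vehicle")


@dataclass
class StudyDesign:
    """The full experimental layout.

    The NI reference level is a field (``reference_level``) rather than a
    hard-coded constant so alternative layouts remain configurable; exactly
    one level must map to the NI treatment and it must be the reference.
    """

    level_map: dict[str, Treatment]
    timepoints_weeks: tuple[int, ...] = (2, 4, 8, 12)
    radiograph_interval_weeks: int = 2
    n_per_timepoint: int = 6
    n_imaging_arm: int = 3
    reference_level: str = "L5-L6"
    ca_level: str = field(default="L1-L2")

    def __post_init__(self) -> None:
        self.timepoints_weeks = tuple(int(w) for w in self.timepoints_weeks)
        if len(self.level_map) != 5:
            raise ValueError("design requires exactly five disc levels")
        ni_levels = [lv for lv, t in self.level_map.items() if t.label == "NI"]
        if len(ni_levels) != 1:
            raise ValueError("design requires exactly one NI (reference) level")
        if ni_levels[0] != self.reference_level:
            raise ValueError("reference_level must be the NI level")
        if any(b <= a for a, b in zip(self.timepoints_weeks, self.timepoints_weeks[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_imaging_arm * 2 != self.n_per_timepoint:
            raise ValueError("imaging arms must split the cohort evenly")

    # -- replicate bookkeeping -------------------------------------------
    # Animals are indexed 1..n_total with a deterministic mapping: animals
    # 1..6 -> first sacrifice week, 7..12 -> second, etc.; within a cohort
    # the first n_imaging_arm animals form the micro-CT arm, the rest the
    # MRI arm.  Animals carry no natural identity in this design; a fixed
    # convention keeps synthetic fixtures reproducible.

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.level_map)

    @property
    def mia_levels(self) -> tuple[str, ...]:
        return tuple(lv for lv, t in self.level_map.items() if t.label.startswith("MIA"))

    @property
    def n_animals(self) -> int:
        return self.n_per_timepoint * len(self.timepoints_weeks)

    @property
    def radiograph_weeks(self) -> tuple[int, ...]:
        """Biweekly radiograph schedule from baseline to the last sacrifice."""
        last = self.timepoints_weeks[-1]
        step = self.radiograph_interval_weeks
        return tuple(range(0, last + 1, step))

    def animals(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_animals + 1))

    def week_of_animal(self, animal: int) -> int:
        if not 1 <= animal <= self.n_animals:
            raise ValueError(f"animal index {animal} out of range 1..{self.n_animals}")
        return self.timepoints_weeks[(animal - 1) // self.n_per_timepoint]

    def arm_of_animal(self, animal: int) -> str:
        """'microct' or 'mri' arm of an animal (first half of each cohort
        goes to micro-CT)."""
        within = (animal - 1) % self.n_per_timepoint
        return "microct" if within < self.n_imaging_arm else "mri"

    def level_for_treatment(self, label: str) -> str:
        for lv, t in self.level_map.items():
            if t.label == label:
                return lv
        raise KeyError(label)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["level_map"] = {lv: asdict(t) for lv, t in self.level_map.items()}
        d["timepoints_weeks"] = list(self.timepoints_weeks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        d["level_map"] = {lv: Treatment(**t) for lv, t in d["level_map"].items()}
        d["timepoints_weeks"] = tuple(d["timepoints_weeks"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump({"design": self.to_dict()}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyDesign":
        payload = yaml.safe_load(text)
        return cls.from_dict(payload["design"] if "design" in payload else payload)


def default_design() -> StudyDesign:
    """The study layout: five levels L1-L2 .. L5-L6 mapped to CA, three
    ascending MIA doses and the NI reference; sacrifices at 2/4/8/12 weeks,
    six animals per timepoint split 3 micro-CT / 3 MRI."""
    level_map = {
        "L1-L2": Treatment("CA", 0.0, 10.0),
        "L2-L3": Treatment("MIA_0.01", 0.01, 10.0),
        "L3-L4": Treatment("MIA_0.1", 0.1, 10.0),
        "L4-L5": Treatment("MIA_1.0", 1.0, 10.0),
        "L5-L6": Treatment("NI", 0.0, 0.0),
    }
    return StudyDesign(level_map=level_map)
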