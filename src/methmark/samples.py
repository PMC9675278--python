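"""Subject metadata: sample sheets and the reference study cohorts.

Two deterministic cohort builders are provided. ``table1_cohort``
reproduces the enrollment table of the urine study exactly (group
sizes, sex, stage and grade marginals). ``validation_cohort`` encodes
the 169-sample clinical validation set (55 bladder cancer, 25 benign
urologic disease, 81 healthy, 8 other urologic cancers) together with a
per-sample methylation call assignment whose margins reproduce every
printed clinical statistic: per-stratum positivity, the overall 42/55
sensitivity, the 32/37 headline stratum and the 98/106 specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import pandas as pd

from .errors import SchemaError

COHORTS = ("healthy", "BUD", "BCa", "other")
STAGES = ("Ta", "T1", "T2", "T3", "T4")
GRADES = ("low", "high", "unknown")

SHEET_COLUMNS = ["sample_id", "group", "stage", "grade", "sex", "age"]


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: str                      # healthy | BUD | BCa | other
    stage: Optional[str] = None     # Ta..T4, BCa only
    grade: Optional[str] = None     # low | high | unknown, BCa only
    sex: str = "M"
    age: int = 60

    def validate(self) -> None:
        if self.group not in COHORTS:
            raise SchemaError(f"unknown group {self.group!r}")
        if self.group == "BCa":
            if self.stage not in STAGES:
                raise SchemaError(f"BCa sample {self.sample_id} needs a stage Ta-T4")
            if self.grade not in GRADES:
                raise SchemaError(f"BCa sample {self.sample_id} needs a grade")
        elif self.stage is not None or self.grade is not None:
            raise SchemaError(
                f"stage/grade only apply to BCa samples ({self.sample_id})"
            )
        if self.sex not in ("M", "F"):
            raise SchemaError(f"sex must be M or F ({self.sample_id})")
        if not self.age > 0:
            raise SchemaError(f"age must be positive ({self.sample_id})")


def write_sample_sheet(records: list[SampleRecord], path) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=SHEET_COLUMNS)
    df.to_csv(path, index=False)


def read_sample_sheet(path) -> list[SampleRecord]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample sheet missing column(s): {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            rec = SampleRecord(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                stage=None if pd.isna(row["stage"]) else str(row["stage"]),
                grade=None if pd.isna(row["grade"]) else str(row["grade"]),
                sex=str(row["sex"]),
                age=int(row["age"]),
            )
            rec.validate()
        except (SchemaError, ValueError) as exc:
            raise SchemaError(f"malformed sample sheet row at line {line}: {exc}") from exc
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# deterministic study cohorts
# ---------------------------------------------------------------------------

def _ages(n: int, young: int, young_age: int = 58, old_age: int = 71) -> list[int]:
    """First ``young`` subjects below 65, the rest at/above."""
    return [young_age] * young + [old_age] * (n - young)


def _sexes(n: int, male: int) -> list[str]:
    return ["M"] * male + ["F"] * (n - male)


def table1_cohort() -> list[SampleRecord]:
    """The full urine enrollment: 93 healthy, 48 BUD, 71 BCa.

    Sex counts per group and the BCa stage (Ta 28, T1 35, T2 4, T3 2,
    T4 2) and grade (low 35, high 33, unknown 3) marginals match the
    enrollment table exactly; ages are representative values.
    """
    records: list[SampleRecord] = []
    for i, sex in enumerate(_sexes(93, 60)):
        records.append(SampleRecord(f"H{i:03d}", "healthy", sex=sex, age=54))
    for i, sex in enumerate(_sexes(48, 29)):
        records.append(SampleRecord(f"B{i:03d}", "BUD", sex=sex, age=53))
    stages = ["Ta"] * 28 + ["T1"] * 35 + ["T2"] * 4 + ["T3"] * 2 + ["T4"] * 2
    grades = ["low"] * 35 + ["high"] * 33 + ["unknown"] * 3
    sexes = _sexes(71, 55)
    for i in range(71):
        records.append(
            SampleRecord(f"C{i:03d}", "BCa", stage=stages[i], grade=grades[i],
                         sex=sexes[i], age=69)
        )
    return records


# (stage, grade, call, count) blocks for the 55 validation BCa samples.
# Joint assignment consistent with every printed margin: TaLG 10/18,
# T1 high-grade 17/19, T2-T4 5/5, grade low 16/26, grade high 26/28,
# stage Ta/T1 37/50, one unknown-grade negative; 42/55 overall.
_VALIDATION_BCA_BLOCKS = [
    ("Ta", "low", True, 10), ("Ta", "low", False, 8),
    ("Ta", "high", True, 4),
    ("T1", "low", True, 6), ("T1", "low", False, 2),
    ("T1", "high", True, 17), ("T1", "high", False, 2),
    ("T2", "high", True, 3), ("T3", "high", True, 1), ("T4", "high", True, 1),
    ("Ta", "unknown", False, 1),
]

# control positives: 8 of 106 controls (specificity 92.5%), split 3 BUD
# + 5 healthy; the 8 other-cancer samples are all negative.
_N_BUD, _BUD_POS = 25, 3
_N_HEALTHY, _HEALTHY_POS = 81, 5
_N_OTHER = 8


def validation_cohort() -> tuple[list[SampleRecord], dict[str, bool]]:
    """The 169-sample validation set with its fixture methylation calls.

    Within the cancer group, sex (32/43 male, 10/12 female positive) and
    age (<65: 12/19, >=65: 30/36) are assigned independently over the
    positive and negative sample lists, which reproduces the printed
    2x2 margins without constraining their joint distribution.
    """
    blocks = []
    for stage, grade, call, count in _VALIDATION_BCA_BLOCKS:
        blocks += [(stage, grade, call)] * count
    positives = [b for b in blocks if b[2]]
    negatives = [b for b in blocks if not b[2]]
    assert len(positives) == 42 and len(negatives) == 13

    records: list[SampleRecord] = []
    calls: dict[str, bool] = {}
    pos_sex, pos_age = _sexes(42, 32), _ages(42, 12)
    neg_sex, neg_age = _sexes(13, 11), _ages(13, 7)
    i = 0
    for (stage, grade, call), sex, age in (
        list(zip(positives, pos_sex, pos_age)) + list(zip(negatives, neg_sex, neg_age))
    ):
        sid = f"VC{i:03d}"
        records.append(SampleRecord(sid, "BCa", stage=stage, grade=grade, sex=sex, age=age))
        calls[sid] = call
        i += 1
    for j, sex in enumerate(_sexes(_N_BUD, 15)):
        sid = f"VB{j:03d}"
        records.append(SampleRecord(sid, "BUD", sex=sex, age=52))
        calls[sid] = j < _BUD_POS
    for j, sex in enumerate(_sexes(_N_HEALTHY, 52)):
        sid = f"VH{j:03d}"
        records.append(SampleRecord(sid, "healthy", sex=sex, age=54))
        calls[sid] = j < _HEALTHY_POS
    for j in range(_N_OTHER):
        sid = f"VO{j:03d}"
        records.append(SampleRecord(sid, "other", sex="M", age=66))
        calls[sid] = False
    return records, calls


def is_headline_case(rec: SampleRecord) -> bool:
    """Member of the headline sensitivity stratum: any BCa except Ta low-grade."""
    return rec.group == "BCa" and not (rec.stage == "Ta" and rec.grade == "low")


def is_control(rec: SampleRecord) -> bool:
    """Specificity denominator: BUD + healthy (other cancers excluded)."""
    return rec.group in ("BUD", "healthy")
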