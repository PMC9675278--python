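"""qMSP 40-dCT scoring and cutoff classification for the urine assay.

Each specimen yields a CT pair: the methylation-specific target
amplicon (PENK) and the CpG-free reference amplicon (COL2A1) that
confirms amplifiable bisulfite-converted DNA. The per-sample score is

    40-dCT = 40 - (CT_target - CT_reference)

so higher scores mean more methylated target. An undetected target CT
in a sample with a valid reference is imputed to a floor score of 25
(just below the lowest observed score); an undetected or too-late
reference CT invalidates the sample (insufficient converted DNA).
Samples classify positive when the score strictly exceeds the cutoff
(default 31.35).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import QCError, SchemaError

DEFAULT_CUTOFF = 31.35
IMPUTED_SCORE = 25.0
REFERENCE_CT_MAX = 38.0

#: Assay constants carried verbatim into run reports; not used in computation.
ASSAY_METADATA = {
    "target_gene": "PENK",
    "reference_gene": "COL2A1",
    "amplicon": "+524 to +595 bp (72 bp)",
    "annealing_c": 60,
    "cycles": 40,
}

QMSP_COLUMNS = [
    "sample_id", "ct_target", "ct_reference",
    "target_detected", "reference_detected",
]


@dataclass(frozen=True)
class QmspRawRecord:
    """One well's CT export; ``None`` CT means undetected."""

    sample_id: str
    ct_target: Optional[float]
    ct_reference: Optional[float]
    role: str = "specimen"  # specimen | positive_control | negative_control | ntc

    def validate(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if ct is not None and not (0.0 < ct <= 40.0):
                raise ValueError(f"{name}={ct} outside detectable range (0, 40]")


@dataclass(frozen=True)
class QmspResult:
    sample_id: str
    score: Optional[float]
    call: str  # positive | negative | invalid | unclassified
    imputed: bool = False


@dataclass(frozen=True)
class RunQC:
    run_id: str
    positive_control_ok: bool
    negative_control_ok: bool
    ntc_ok: bool

    @property
    def run_valid(self) -> bool:
        return self.positive_control_ok and self.negative_control_ok and self.ntc_ok


def score_sample(
    rec: QmspRawRecord,
    reference_ct_max: float = REFERENCE_CT_MAX,
    imputed_score: float = IMPUTED_SCORE,
) -> QmspResult:
    """40-dCT score for one specimen, with reference gating and imputation."""
    if rec.role != "specimen":
        raise ValueError(f"score_sample expects a specimen record, got role={rec.role!r}")
    rec.validate()
    if rec.ct_reference is None or rec.ct_reference > reference_ct_max:
        # no amplifiable bisulfite-converted DNA: methylation state unknowable
        return QmspResult(rec.sample_id, None, "invalid")
    if rec.ct_target is None:
        return QmspResult(rec.sample_id, imputed_score, "unclassified", imputed=True)
    score = 40.0 - (rec.ct_target - rec.ct_reference)
    return QmspResult(rec.sample_id, score, "unclassified")


def classify(result: QmspResult, cutoff: float = DEFAULT_CUTOFF) -> QmspResult:
    """Binary methylation call: positive iff score > cutoff (strict)."""
    if result.call == "invalid" or result.score is None:
        raise ValueError(f"cannot classify invalid result for {result.sample_id!r}")
    call = "positive" if result.score > cutoff else "negative"
    return replace(result, call=call)


def qc_run(
    controls: list[QmspRawRecord],
    run_id: str = "run",
    cutoff: float = DEFAULT_CUTOFF,
    reference_ct_max: float = REFERENCE_CT_MAX,
) -> RunQC:
    """Batch adequacy from the three run controls.

    The fully methylated control must classify positive, the unmethylated
    control must not (undetected target or sub-cutoff score), and the
    non-template control must show no amplification in either channel.
    """
    by_role: dict[str, QmspRawRecord] = {}
    for rec in controls:
        if rec.role in by_role:
            raise QCError(f"duplicate control role {rec.role!r}")
        by_role[rec.role] = rec
    missing = [r for r in ("positive_control", "negative_control", "ntc") if r not in by_role]
    if missing:
        raise QCError(f"missing control role(s): {', '.join(missing)}")

    def _score(rec: QmspRawRecord) -> QmspResult:
        return score_sample(replace(rec, role="specimen"), reference_ct_max=reference_ct_max)

    pc = _score(by_role["positive_control"])
    pc_ok = pc.call != "invalid" and not pc.imputed and classify(pc, cutoff).call == "positive"

    nc_rec = by_role["negative_control"]
    if nc_rec.ct_target is None:
        nc_ok = True
    else:
        nc = _score(nc_rec)
        nc_ok = nc.call != "invalid" and classify(nc, cutoff).call == "negative"

    ntc = by_role["ntc"]
    ntc_ok = ntc.ct_target is None and ntc.ct_reference is None
    return RunQC(run_id, pc_ok, nc_ok, ntc_ok)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_qmsp_table(path) -> pd.DataFrame:
    """CT export CSV; undetected CTs are empty fields + a detected flag."""
    df = pd.read_csv(path)
    missing = [c for c in QMSP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"qMSP table missing column(s): {', '.join(missing)}")
    return df


def write_qmsp_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c in set(QMSP_COLUMNS) | {"group", "role", "run_id"}]
    df.to_csv(path, index=False, columns=cols)


def score_table(df: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Score and classify every specimen row of a CT table."""
    rows = []
    for _, r in df.iterrows():
        rec = QmspRawRecord(
            sample_id=str(r["sample_id"]),
            ct_target=float(r["ct_target"]) if bool(r["target_detected"]) else None,
            ct_reference=float(r["ct_reference"]) if bool(r["reference_detected"]) else None,
        )
        res = score_sample(rec)
        if res.call != "invalid":
            res = classify(res, cutoff)
        rows.append(
            {
                "sample_id": res.sample_id,
                "score": np.nan if res.score is None else res.score,
                "call": res.call,
                "imputed": res.imputed,
            }
        )
    return pd.DataFrame(rows)
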