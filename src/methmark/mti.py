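"""Bisulfite-pyrosequencing methylation index (MtI).

The MtI of a gene in a sample is 100 times the arithmetic mean of the
methylated-cytosine fraction mC/(mC + C) over the 3-5 interrogated CpGs
of the pyrosequencing amplicon, reported on the percent scale. A tissue
pair is methylation-positive when the tumor MtI strictly exceeds the
matched nontumor MtI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

PYRO_COLUMNS = ["sample_id", "gene", "cpg_index", "methylated_fraction"]


@dataclass(frozen=True)
class PyroMeasurement:
    sample_id: str
    gene_id: str
    cpg_fractions: tuple[float, ...]
    is_control: bool = False

    def validate(self) -> None:
        if len(self.cpg_fractions) == 0:
            raise ValueError("a pyrosequencing measurement needs at least one CpG")
        if any(not (0.0 <= f <= 1.0) for f in self.cpg_fractions):
            raise ValueError("CpG methylated fractions must lie in [0, 1]")


@dataclass(frozen=True)
class MtIProfile:
    sample_id: str
    gene_id: str
    mti: float  # percent, [0, 100]


def compute_mti(m: PyroMeasurement) -> MtIProfile:
    """MtI = 100 x mean per-CpG methylated fraction."""
    m.validate()
    return MtIProfile(m.sample_id, m.gene_id, 100.0 * float(np.mean(m.cpg_fractions)))


def call_tissue_positive(tumor: MtIProfile, nontumor: MtIProfile) -> bool:
    """Methylation-positive pair: tumor MtI strictly above nontumor MtI."""
    if tumor.gene_id != nontumor.gene_id:
        raise ValueError(
            f"gene mismatch: {tumor.gene_id!r} vs {nontumor.gene_id!r}"
        )
    return tumor.mti > nontumor.mti


def qc_negative_controls(
    measurements: list[PyroMeasurement], max_fraction: float = 0.05
) -> list[str]:
    """Sample ids of no-template controls whose signal exceeds the bound.

    A clean pyrosequencing batch shows (near-)zero methylated fraction in
    every control well; any control CpG above ``max_fraction`` flags the
    batch. Returns the failing control ids (empty list = batch passes).
    """
    return [
        m.sample_id
        for m in measurements
        if m.is_control and any(f > max_fraction for f in m.cpg_fractions)
    ]


def read_pyro_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PYRO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pyrosequencing table missing column(s): {', '.join(missing)}")
    bad = df.index[
        (df["methylated_fraction"] < 0) | (df["methylated_fraction"] > 1)
    ]
    if len(bad):
        raise SchemaError(
            f"methylated_fraction outside [0, 1] at line {int(bad[0]) + 2}"
        )
    return df


def write_pyro_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=PYRO_COLUMNS)


def mti_table(pyro: pd.DataFrame) -> pd.DataFrame:
    """Per-(sample, gene) MtI table from a long per-CpG fraction table."""
    out = (
        pyro.groupby(["sample_id", "gene"], sort=True)["methylated_fraction"]
        .mean()
        .mul(100.0)
        .rename("mti")
        .reset_index()
    )
    return out
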