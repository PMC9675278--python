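"""End-to-end orchestration: simulate -> discover -> MtI -> qMSP -> validate.

A single :class:`RunConfig` (loadable from YAML) drives a full synthetic
study. All randomness flows from one top-level seed; per-stage seeds are
derived deterministically, so a rerun with the same config produces
byte-identical outputs. Output files are staged to a temporary name and
atomically renamed, so a failed stage leaves no partial files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import samples, stats
from .discovery import candidates_to_frame, select_candidates
from .errors import MethmarkError
from .mti import mti_table, write_pyro_table
from .qmsp import DEFAULT_CUTOFF, score_table, write_qmsp_table
from .simulate import (
    MTI_CALIBRATION,
    PYRO_COHORT_SIZES,
    ArraySimConfig,
    CohortMtISpec,
    QmspSimSpec,
    generate_array_dataset,
    generate_pyro_table,
    generate_qmsp_cohort,
)

logger = logging.getLogger(__name__)

#: Validation-design qMSP strata: sizes from the 169-sample study design,
#: positivities from the explicitly printed fraction pairs (10/18 Ta
#: low-grade, 32/37 remaining cancers, 8/106 controls, 0/8 other cancers).
DEFAULT_QMSP_STRATA: tuple[tuple[str, int, float, bool], ...] = (
    ("BCa_TaLG", 18, 10 / 18, True),
    ("BCa_TaHG_T1_T4", 37, 32 / 37, True),
    ("BUD", 25, 8 / 106, False),
    ("healthy", 81, 8 / 106, False),
    ("other", 8, 0.0, False),
)


@dataclass
class RunConfig:
    seed: int = 0
    array: ArraySimConfig = None
    alpha: float = 0.01
    fc_min: float = 2.0
    min_probes: int = 2
    cutoff: float = DEFAULT_CUTOFF
    level: float = 0.95
    mti_n: dict = field(default_factory=lambda: dict(PYRO_COHORT_SIZES))
    qmsp_strata: tuple = DEFAULT_QMSP_STRATA
    fixture_mode: bool = True

    def __post_init__(self) -> None:
        if self.array is None:
            self.array = ArraySimConfig(seed=self._stage_seed(0))
        if isinstance(self.array, dict):
            self.array = ArraySimConfig(**self.array)
        self.array.validate()

    def _stage_seed(self, idx: int) -> int:
        return (self.seed * 1000003 + idx) % (2**31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        strata = data.pop("qmsp_strata", None)
        cfg = cls(**data)
        if strata is not None:
            cfg.qmsp_strata = tuple(tuple(s) for s in strata)
        return cfg


def _atomic_write(path: Path, writer) -> None:
    """Stage output under a temp name in the target dir, then rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_df(df: pd.DataFrame, path, **to_csv_kwargs) -> None:
    to_csv_kwargs.setdefault("index", False)
    _atomic_write(Path(path), lambda tmp: df.to_csv(tmp, **to_csv_kwargs))


def atomic_write_json(obj, path) -> None:
    def writer(tmp):
        with open(tmp, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")

    _atomic_write(Path(path), writer)


def _perf_block(perf: stats.DiagnosticPerformance) -> dict:
    return {
        "cutoff": perf.cutoff,
        "tp": perf.tp, "fp": perf.fp, "tn": perf.tn, "fn": perf.fn,
        "sensitivity": None if perf.sensitivity is None else round(perf.sensitivity, 1),
        "sensitivity_ci": None if perf.sensitivity_ci is None
        else [round(x, 1) for x in perf.sensitivity_ci],
        "specificity": None if perf.specificity is None else round(perf.specificity, 1),
        "specificity_ci": None if perf.specificity_ci is None
        else [round(x, 1) for x in perf.specificity_ci],
    }


def fixture_validation_report(cutoff: float = DEFAULT_CUTOFF, level: float = 0.95) -> dict:
    """The clinical-validation block computed from the fixture cohort.

    Per-sample calls come from the deterministic validation cohort whose
    margins encode the printed study counts, so every statistic here is
    reproduced exactly rather than in expectation.
    """
    records, calls = samples.validation_cohort()
    bca = [r for r in records if r.group == "BCa"]
    assoc = {
        p: stats.association_table(bca, calls, p)
        for p in ("sex", "age", "stage", "grade")
    }
    n_bca_pos = sum(calls[r.sample_id] for r in bca)
    headline = [r for r in bca if samples.is_headline_case(r)]
    n_head_pos = sum(calls[r.sample_id] for r in headline)
    controls = [r for r in records if samples.is_control(r)]
    n_ctrl_neg = sum(not calls[r.sample_id] for r in controls)
    overall_ci = stats.clopper_pearson(n_bca_pos, len(bca), level)
    headline_ci = stats.clopper_pearson(n_head_pos, len(headline), level)
    spec_ci = stats.clopper_pearson(n_ctrl_neg, len(controls), level)
    return {
        "cutoff": cutoff,
        "overall_sensitivity": {
            "k": n_bca_pos, "n": len(bca),
            "percent": round(100.0 * n_bca_pos / len(bca), 1),
            "ci": [round(x, 1) for x in overall_ci],
        },
        "headline_sensitivity": {
            "k": n_head_pos, "n": len(headline),
            "percent": round(100.0 * n_head_pos / len(headline), 1),
            "ci": [round(x, 1) for x in headline_ci],
        },
        "specificity": {
            "k": n_ctrl_neg, "n": len(controls),
            "percent": round(100.0 * n_ctrl_neg / len(controls), 1),
            "ci": [round(x, 1) for x in spec_ci],
        },
        "associations": {
            p: {
                "strata": list(a.strata),
                "n": list(a.n),
                "positives": list(a.positives),
                "positivity_percent": list(a.positivity),
                "p": a.p,
            }
            for p, a in assoc.items()
        },
    }


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute every stage, write all tables, return the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": {
            "seed": cfg.seed,
            "array": dataclasses.asdict(cfg.array),
            "alpha": cfg.alpha,
            "fc_min": cfg.fc_min,
            "min_probes": cfg.min_probes,
            "cutoff": cfg.cutoff,
            "level": cfg.level,
            "fixture_mode": cfg.fixture_mode,
        }
    }

    current_stage = "init"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate-arrays")
        ds = generate_array_dataset(cfg.array)
        atomic_write_df(ds.to_frame(), outdir / "arrays.csv")

        stage("discover")
        candidates = select_candidates(
            ds, alpha=cfg.alpha, fc_min=cfg.fc_min, min_probes=cfg.min_probes
        )
        atomic_write_df(candidates_to_frame(candidates), outdir / "candidates.csv")
        summary["discovery"] = {
            "n_candidates": len(candidates),
            "candidate_genes": [c.gene_id for c in candidates],
            "planted_genes": sorted(ds.planted_genes),
            "planted_recovered": sorted(
                set(c.gene_id for c in candidates) & ds.planted_genes
            ),
        }

        stage("simulate-mti")
        pyro_frames = []
        mti_block = {}
        for gi, (gene, groups) in enumerate(sorted(MTI_CALIBRATION.items())):
            group_values = {}
            for si, (group, (mean, sd)) in enumerate(sorted(groups.items())):
                spec = CohortMtISpec(
                    group_label=group, gene=gene, target_mean=mean, target_sd=sd,
                    n=cfg.mti_n.get(group, 12),
                    seed=cfg._stage_seed(100 + 10 * gi + si),
                )
                pyro = generate_pyro_table(spec)
                pyro_frames.append(pyro)
                group_values[group] = (
                    pyro.groupby("sample_id", sort=True)["methylated_fraction"]
                    .mean().mul(100.0).to_numpy()
                )
            h, p = stats.kruskal_wallis(
                [group_values[g] for g in ("healthy", "BUD", "BCa")]
            )
            mti_block[gene] = {
                "group_means": {g: round(float(v.mean()), 2) for g, v in group_values.items()},
                "kruskal_H": round(h, 3),
                "kruskal_p": round(p, 6),
            }
        pyro_all = pd.concat(pyro_frames, ignore_index=True)
        _atomic_write(outdir / "pyro.csv", lambda tmp: write_pyro_table(pyro_all, tmp))
        atomic_write_df(mti_table(pyro_all), outdir / "mti.csv")
        summary["mti"] = mti_block

        stage("simulate-qmsp")
        ct_frames = []
        for si, (label, n, positivity, _is_case) in enumerate(cfg.qmsp_strata):
            spec = QmspSimSpec(
                group_label=label, n=int(n), positivity=float(positivity),
                seed=cfg._stage_seed(200 + si),
            )
            ct_frames.append(generate_qmsp_cohort(spec, cutoff=cfg.cutoff))
        ct_all = pd.concat(ct_frames, ignore_index=True)
        _atomic_write(outdir / "qmsp_ct.csv", lambda tmp: write_qmsp_table(ct_all, tmp))

        stage("qmsp-score")
        calls = score_table(ct_all, cutoff=cfg.cutoff)
        calls = calls.merge(ct_all[["sample_id", "group"]], on="sample_id")
        atomic_write_df(calls, outdir / "qmsp_calls.csv")

        stage("validate")
        case_labels = {
            label for label, _n, _p, is_case in cfg.qmsp_strata if is_case
        }
        control_labels = {"BUD", "healthy"} & {s[0] for s in cfg.qmsp_strata}
        valid = calls[calls["call"] != "invalid"]
        in_roc = valid["group"].isin(case_labels | control_labels)
        roc = stats.roc_curve(
            valid.loc[in_roc, "score"].to_numpy(),
            valid.loc[in_roc, "group"].isin(case_labels).to_numpy(),
            level=cfg.level,
        )
        perf = stats.performance_at_cutoff(
            valid.loc[in_roc, "score"].to_numpy(),
            valid.loc[in_roc, "group"].isin(case_labels).to_numpy(),
            cfg.cutoff,
            level=cfg.level,
        )
        summary["qmsp_validation"] = {
            "auc": round(roc.auc, 3),
            "auc_ci": [round(x, 3) for x in roc.auc_ci],
            "youden_cutoff": stats.optimal_cutoff(roc),
            "performance": _perf_block(perf),
        }
        if cfg.fixture_mode:
            summary["clinical_report"] = fixture_validation_report(
                cutoff=cfg.cutoff, level=cfg.level
            )
            records, fix_calls = samples.validation_cohort()
            samples.write_sample_sheet(records, outdir / "sample_sheet.csv")
            atomic_write_df(
                pd.DataFrame(
                    {
                        "sample_id": [r.sample_id for r in records],
                        "call": [
                            "positive" if fix_calls[r.sample_id] else "negative"
                            for r in records
                        ],
                    }
                ),
                outdir / "fixture_calls.csv",
            )
    except MethmarkError as exc:
        raise MethmarkError(
            f"pipeline stage {current_stage!r} failed (outputs under {outdir}): {exc}"
        ) from exc

    atomic_write_json(summary, outdir / "summary.json")
    return summary
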