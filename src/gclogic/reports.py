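"""Tabular report writers/readers (long-format TSV, byte-stable ordering)."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .drugs import TreatmentOutcome, regimen_label
from .gc_model import AttractorProfile
from .pipeline import PatientReport

_STAGE_ORDER = ("LZ1", "Pre-GC", "DZ", "LZ2", "PC")


def wt_attractor_frame(profile: AttractorProfile) -> pd.DataFrame:
    """One row per input combination: id, name, compact state, markers, flag."""
    rows = []
    for sa in profile.stages:
        state = sa.fixpoints[0]
        rows.append(
            {
                "stage_id": sa.stage.stage_id,
                "stage_name": sa.stage.name,
                "physiological": int(sa.stage.physiological),
                "state": "".join(str(l) for l in state.levels),
                "markers": sa.label,
            }
        )
    return pd.DataFrame(rows, columns=["stage_id", "stage_name", "physiological", "state", "markers"])


def attractor_long_frame(profile: AttractorProfile) -> pd.DataFrame:
    """Long format: model_id, stage id/name, fixpoint index, component, level.

    Lost stages contribute no component rows; they are visible in the
    per-model summary reports instead.
    """
    rows = []
    for sa in profile.stages:
        if sa.lost:
            continue
        for fi, state in enumerate(sa.fixpoints):
            for name, level in state:
                rows.append(
                    (profile.model_id, sa.stage.stage_id, sa.stage.name, fi, name, level)
                )
    return pd.DataFrame(
        rows,
        columns=["model_id", "stage_id", "stage_name", "fixpoint_index", "component", "level"],
    )


COHORT_COLUMNS = (
    "model_id",
    "coo_label",
    "LZ1",
    "Pre-GC",
    "DZ",
    "LZ2",
    "PC",
    "changed_stages",
    "abnormal_combination",
    "wrong_stage",
    "pc_loss",
    "lz1_loss",
    "oncogenic",
    "nfkb_class",
    "n_clamps",
    "conflicts",
)


def cohort_report_frame(reports: Sequence[PatientReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        by_name = {sa.stage.name: sa for sa in rep.profile.stages}
        row = {
            "model_id": rep.model.model_id,
            "coo_label": rep.coo_label or "",
            **{name: by_name[name].label for name in _STAGE_ORDER},
            "changed_stages": rep.comparison.changed_stage_count,
            "abnormal_combination": int(rep.oncogenicity.abnormal_combination),
            "wrong_stage": int(rep.oncogenicity.wrong_stage),
            "pc_loss": int(rep.oncogenicity.pc_loss),
            "lz1_loss": int(rep.oncogenicity.lz1_loss),
            "oncogenic": int(rep.oncogenicity.oncogenic),
            "nfkb_class": rep.nfkb_class,
            "n_clamps": len(rep.model.genotype_clamps),
            "conflicts": "; ".join(rep.model.perturbations.conflicts),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def classification_summary_frame(reports: Sequence[PatientReport]) -> pd.DataFrame:
    """Counts per NF-kB class with oncogenic and LZ1-loss tallies."""
    df = cohort_report_frame(reports)
    rows = []
    for cls, group in df.groupby("nfkb_class", sort=True):
        rows.append(
            {
                "nfkb_class": cls,
                "n_models": len(group),
                "n_oncogenic": int(group["oncogenic"].sum()),
                "n_lz1_loss": int(group["lz1_loss"].sum()),
            }
        )
    return pd.DataFrame(
        rows, columns=["nfkb_class", "n_models", "n_oncogenic", "n_lz1_loss"]
    )


TREATMENT_COLUMNS = (
    "model_id",
    "regimen",
    "stage_id",
    "stage_name",
    "pattern",
    "no_marker_stage_count",
    "reachable_stage_count",
)


def treatment_report_frame(outcomes: Sequence[TreatmentOutcome]) -> pd.DataFrame:
    rows = []
    for out in outcomes:
        for sa in out.profile.stages:
            rows.append(
                (
                    out.model_id,
                    regimen_label(out.regimen),
                    sa.stage.stage_id,
                    sa.stage.name,
                    sa.label,
                    out.no_marker_stage_count,
                    out.reachable_stage_count,
                )
            )
    return pd.DataFrame(rows, columns=TREATMENT_COLUMNS)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
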