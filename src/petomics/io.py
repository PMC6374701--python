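"""Readers/writers for the pipeline's plain-text tabular formats.

All artifacts are TSV/CSV with header rows so intermediates are diffable.
Writers and readers are inverse up to byte identity (write -> read -> write
reproduces the file), which the pipeline's determinism contract relies on.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .kinetics import TimeActivityCurve


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene or sample IDs")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValidationError(f"{path}: non-finite expression values")
    return df


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "patient_id", "condition"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: annotation needs columns {sorted(required)}")
    return df


def write_tacs(tacs: list[TimeActivityCurve], path) -> None:
    rows = []
    for tac in tacs:
        for t, a, d in zip(tac.frame_mid_times, tac.activity, tac.frame_durations):
            rows.append(
                {
                    "patient_id": tac.patient_id or "",
                    "voi_label": tac.voi_label,
                    "frame_mid_time_min": t,
                    "activity_kBq_per_ml": a,
                    "frame_duration_s": d,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tacs(path) -> list[TimeActivityCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame_mid_time_min", "activity_kBq_per_ml", "frame_duration_s"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: TAC file needs columns {sorted(required)}")
    if "patient_id" not in df.columns:
        df["patient_id"] = ""
    if "voi_label" not in df.columns:
        df["voi_label"] = "tumor"
    out = []
    for (pid, voi), grp in df.groupby(["patient_id", "voi_label"], sort=False):
        out.append(
            TimeActivityCurve(
                grp["frame_mid_time_min"].to_numpy(),
                grp["activity_kBq_per_ml"].to_numpy(),
                grp["frame_duration_s"].to_numpy(),
                voi_label=str(voi),
                patient_id=str(pid) or None,
            )
        )
    return out


def write_pet_features(pet: pd.DataFrame, path) -> None:
    pet.to_csv(path, index_label="patient_id")


def read_pet_features(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, float_precision="round_trip")


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: survival table needs columns {sorted(required)}")
    return df


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
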