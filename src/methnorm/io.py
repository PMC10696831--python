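"""Plain-text readers and writers.

Everything moves through TSV/CSV so runs are inspectable and portable:
intensity tables in long format (one row per probe x sample), a probe
manifest, a sample sheet, probe x sample beta tables, and two-column
EpiScore coefficient tables with a reserved ``(Intercept)`` row.
Delimiters are auto-detected from the file content; writers emit
deterministic row and column order.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BetaMatrix, IntensityData, ProbeAnnotation, SampleSheet
from .episcore import EpiScoreModel
from .errors import ValidationError

logger = logging.getLogger(__name__)

_OPTIONAL_INTENSITY_COLS = ["oob_meth", "oob_unmeth", "beadcount",
                            "detection_p"]


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited UTF-8 table, sniffing tab/comma/semicolon."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        sample = fh.read(4096)
    try:
        delim = csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        delim = "\t"
    return pd.read_csv(path, sep=delim, float_precision="round_trip")


def read_manifest(path: str | Path) -> ProbeAnnotation:
    df = _read_table(path)
    if "probe_id" not in df.columns:
        raise ValidationError(f"{path}: manifest needs a probe_id column")
    return ProbeAnnotation(df.set_index("probe_id"))


def write_manifest(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: sample sheet needs sample_id")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(samples: SampleSheet, path: str | Path) -> None:
    samples.table.to_csv(path, index_label="sample_id",
                         float_format="%.17g")


def read_intensity_table(path: str | Path, manifest: ProbeAnnotation,
                         samples: SampleSheet) -> IntensityData:
    """Long-format intensity table: columns probe_id, sample_id, meth,
    unmeth and optionally oob_meth, oob_unmeth, beadcount, detection_p.
    """
    df = _read_table(path)
    need = {"probe_id", "sample_id", "meth", "unmeth"}
    if not need <= set(df.columns):
        raise ValidationError(
            f"{path}: intensity table needs columns {sorted(need)}")
    dup = df.duplicated(subset=["probe_id", "sample_id"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValidationError(
            f"{path}: duplicated (probe, sample) pair "
            f"({row['probe_id']}, {row['sample_id']}) at line "
            f"{int(dup.idxmax()) + 2}")
    counts = df.groupby("sample_id", sort=False)["probe_id"].count()
    if counts.nunique() > 1:
        raise ValidationError(
            f"{path}: inconsistent probe sets across samples "
            f"(counts {sorted(counts.unique())})")

    def pivot(col):
        wide = df.pivot(index="probe_id", columns="sample_id", values=col)
        return wide.reindex(index=manifest.probe_ids,
                            columns=samples.sample_ids)

    kw = {}
    for col in _OPTIONAL_INTENSITY_COLS:
        if col in df.columns:
            mat = pivot(col)
            kw[col] = mat.astype(int) if col == "beadcount" else mat
    meth, unmeth = pivot("meth"), pivot("unmeth")
    if meth.isna().any().any() or unmeth.isna().any().any():
        raise ValidationError(
            f"{path}: missing meth/unmeth entries after alignment with "
            "manifest and sample sheet")
    return IntensityData(meth=meth, unmeth=unmeth, annotation=manifest,
                         samples=samples, **kw)


def write_intensity_table(data: IntensityData, path: str | Path) -> None:
    frames = {"meth": data.meth, "unmeth": data.unmeth}
    for col in _OPTIONAL_INTENSITY_COLS:
        mat = getattr(data, col)
        if mat is not None:
            frames[col] = mat
    long = pd.concat(
        {name: mat.stack(future_stack=True) for name, mat in frames.items()},
        axis=1)
    long.index.names = ["probe_id", "sample_id"]
    long = long.reset_index().sort_values(["probe_id", "sample_id"],
                                          kind="stable")
    long.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_beta_table(path: str | Path, manifest: ProbeAnnotation,
                    samples: SampleSheet) -> BetaMatrix:
    df = _read_table(path).set_index("probe_id")
    values = df.reindex(index=manifest.probe_ids)[samples.sample_ids]
    return BetaMatrix(values, manifest, samples)


def write_beta_table(betas: BetaMatrix, path: str | Path) -> None:
    betas.values.to_csv(path, sep="\t", index_label="probe_id",
                        float_format="%.17g")


INTERCEPT_ROW = "(Intercept)"


def read_coefficients(path: str | Path) -> EpiScoreModel:
    """Two-column coefficient table ``probe_id\tweight`` with an
    optional ``(Intercept)`` row and an optional ``training_mean``
    column."""
    df = _read_table(path)
    if "probe_id" not in df.columns or "weight" not in df.columns:
        raise ValidationError(f"{path}: needs probe_id and weight columns")
    bad = pd.to_numeric(df["weight"], errors="coerce").isna()
    if bad.any():
        raise ValidationError(
            f"{path}: non-numeric weight at line {int(bad.idxmax()) + 2}")
    df["weight"] = df["weight"].astype(float)
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate probe row {dup!r}")
    inter = df["probe_id"] == INTERCEPT_ROW
    if inter.any():
        intercept = float(df.loc[inter, "weight"].iloc[0])
        df = df[~inter]
    else:
        logger.warning("%s: no (Intercept) row; intercept set to 0", path)
        intercept = 0.0
    weights = pd.Series(df["weight"].to_numpy(),
                        index=df["probe_id"].to_numpy(), name="weight")
    means = None
    if "training_mean" in df.columns:
        means = pd.Series(df["training_mean"].astype(float).to_numpy(),
                          index=weights.index, name="training_mean")
    return EpiScoreModel(intercept=intercept, weights=weights,
                         feature_means=means)


def write_coefficients(model: EpiScoreModel, path: str | Path) -> None:
    rows = {"probe_id": [INTERCEPT_ROW] + list(model.weights.index),
            "weight": [model.intercept] + list(model.weights.to_numpy())}
    if model.feature_means is not None:
        rows["training_mean"] = [0.0] + list(
            model.feature_means.reindex(model.weights.index).to_numpy())
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.17g")
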