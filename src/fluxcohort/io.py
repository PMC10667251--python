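"""Readers/writers and validation for the pipeline's tabular interfaces.

All tables are long-format UTF-8 CSV:

* MID table: ``patient,clone,replicate,condition,tracer,metabolite,fragment,
  mass_shift,fraction,sd``
* exchange-rate table: ``patient,clone,replicate,condition,metabolite,
  blank_mM,sample_mM,hours,dna_mg``
* clinical table: ``patient,dHY,dUPDRS3,dLDopa_mg,dADL,followup``
* extracellular-flux trace table: ``well,patient,clone,replicate,condition,
  celltype,meas_index,ocr,ecar``
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TableValidationError",
    "MidMeasurementTable",
    "ClinicalRecord",
    "read_mid_table",
    "read_clinical_table",
    "read_rates_table",
    "read_trace_table",
    "packaged_path",
]

SAMPLE_KEYS = ["patient", "clone", "replicate", "condition", "tracer"]
MID_COLUMNS = SAMPLE_KEYS + ["metabolite", "fragment", "mass_shift", "fraction", "sd"]
RATE_COLUMNS = [
    "patient", "clone", "replicate", "condition", "metabolite",
    "blank_mM", "sample_mM", "hours", "dna_mg",
]
TRACE_COLUMNS = [
    "well", "patient", "clone", "replicate", "condition", "celltype",
    "meas_index", "ocr", "ecar",
]


class TableValidationError(ValueError):
    pass


def packaged_path(name: str):
    """Path to a data file shipped with the package (e.g. ``tca_toy.tsv``)."""
    return importlib.resources.files("fluxcohort.data") / name


@dataclass
class MidMeasurementTable:
    """Validated long-format MID measurements with cohort keys."""

    df: pd.DataFrame

    def groups(self):
        """Iterate ``(keys, mid, sd)`` per (sample, tracer, metabolite, fragment)."""
        cols = SAMPLE_KEYS + ["metabolite", "fragment"]
        for keys, g in self.df.groupby(cols, sort=True):
            g = g.sort_values("mass_shift")
            yield keys, g["fraction"].to_numpy(), g["sd"].to_numpy()

    @property
    def conditions(self):
        return sorted(self.df["condition"].unique())


def validate_mid_frame(df: pd.DataFrame, sum_tol: float = 1e-3) -> pd.DataFrame:
    missing = [c for c in MID_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"MID table missing columns: {missing}")
    if (df["fraction"] < 0).any():
        rows = df.index[df["fraction"] < 0].tolist()
        raise TableValidationError(f"negative MID fractions at rows {rows}")
    if (df["sd"] <= 0).any():
        rows = df.index[df["sd"] <= 0].tolist()
        raise TableValidationError(f"non-positive measurement SD at rows {rows}")
    bad = []
    cols = SAMPLE_KEYS + ["metabolite", "fragment"]
    for keys, g in df.groupby(cols, sort=False):
        shifts = sorted(g["mass_shift"])
        if shifts != list(range(len(shifts))):
            bad.append((keys, "mass shifts not a complete 0..n range"))
            continue
        s = g["fraction"].sum()
        if abs(s - 1.0) > sum_tol:
            bad.append((keys, f"fractions sum to {s:.4f}, rows {g.index.tolist()}"))
    if bad:
        msgs = "; ".join(f"{k}: {m}" for k, m in bad[:5])
        raise TableValidationError(f"{len(bad)} invalid MID vectors: {msgs}")
    return df


def read_mid_table(path, sum_tol: float = 1e-3) -> MidMeasurementTable:
    df = pd.read_csv(path)
    return MidMeasurementTable(validate_mid_frame(df, sum_tol=sum_tol))


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical progression deltas over the follow-up period.

    ``d_hy``: change on the Hoehn & Yahr scale; ``d_updrs3``: change in UPDRS
    part III motor score (points); ``d_ldopa_mg``: change in L-Dopa equivalent
    dose (mg); ``d_adl``: change in the activities-of-daily-living score.
    Deltas may be missing only when ``followup_available`` is False.
    """

    patient: str
    d_hy: float | None
    d_updrs3: float | None
    d_ldopa_mg: float | None
    d_adl: float | None
    followup_available: bool = True

    def __post_init__(self):
        if self.followup_available:
            for f in (self.d_hy, self.d_updrs3, self.d_ldopa_mg, self.d_adl):
                if f is None or (isinstance(f, float) and np.isnan(f)):
                    raise TableValidationError(
                        f"patient {self.patient!r}: missing delta despite "
                        "follow-up being available"
                    )

    def deltas(self) -> dict[str, float | None]:
        return {
            "dHY": self.d_hy,
            "dUPDRS3": self.d_updrs3,
            "dLDopa_mg": self.d_ldopa_mg,
            "dADL": self.d_adl,
        }


def read_clinical_table(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path)
    need = ["patient", "dHY", "dUPDRS3", "dLDopa_mg", "dADL", "followup"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise TableValidationError(f"clinical table missing columns: {missing}")
    if df["patient"].duplicated().any():
        dups = df.loc[df["patient"].duplicated(), "patient"].tolist()
        raise TableValidationError(f"duplicate patient ids: {dups}")
    records = []
    for _, row in df.iterrows():
        avail = bool(row["followup"])

        def val(col):
            v = row[col]
            if pd.isna(v):
                return None
            return float(v)

        records.append(
            ClinicalRecord(
                patient=str(row["patient"]),
                d_hy=val("dHY"),
                d_updrs3=val("dUPDRS3"),
                d_ldopa_mg=val("dLDopa_mg"),
                d_adl=val("dADL"),
                followup_available=avail,
            )
        )
    return records


def clinical_records_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = r.deltas()
        rows.append(
            {
                "patient": r.patient,
                "dHY": d["dHY"],
                "dUPDRS3": d["dUPDRS3"],
                "dLDopa_mg": d["dLDopa_mg"],
                "dADL": d["dADL"],
                "followup": int(r.followup_available),
            }
        )
    return pd.DataFrame(rows)


def read_rates_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"rates table missing columns: {missing}")
    if (df["hours"] <= 0).any():
        raise TableValidationError("elapsed time must be positive")
    if (df["dna_mg"] <= 0).any():
        raise TableValidationError("DNA content must be positive")
    return df


def read_trace_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"trace table missing columns: {missing}")
    return df
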