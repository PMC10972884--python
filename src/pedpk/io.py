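"""Dataset and parameter-file I/O.

Datasets use a fixed NONMEM-style long-format CSV dialect with columns
ID, TIME, AMT, DV, EVID, MDV, AGE, SEX, WT, HT (case-insensitive header):
EVID=1 rows are dose events (AMT > 0, MDV=1), EVID=0 rows are
observations.  SEX is coded 0=male / 1=female; TIME is hours after first
dose; AMT is mg; DV is concentration in the configured reporting unit
(ug/L by default).  Lines starting with '#' are comments; writers prepend
a provenance comment header.

Parameter files are YAML with explicit units and fix-flags per parameter;
the loader validates completeness.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import Dataset, Observation, Subject
from .model import PARAMETER_NAMES, Covariates, DoseEvent, PopulationParameters

__all__ = ["read_dataset", "write_dataset", "load_params", "save_params"]

COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "AGE", "SEX", "WT", "HT"]

_UNITS = {
    "tvcl": "L/h", "cl_age": "1/yr", "cl_sex": "-", "tvv": "L", "v_age": "1/yr",
    "tvka": "1/h", "omega2_cl": "-", "omega2_v": "-", "sigma2_prop": "-",
    "sigma2_add": "(ug/L)^2",
}


class DatasetFormatError(ValueError):
    """The file violates the dataset dialect; the message carries a row number."""


def read_dataset(path) -> Dataset:
    """Parse a NONMEM-style CSV into a Dataset, validating the dialect.

    TAD is recomputed per observation from the preceding dose rows.
    Errors (observation before any dose, unknown SEX code, dose rows
    without amount) name the offending 1-based file row.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    df.columns = [c.strip().upper() for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns and c != "HT"]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing}")
    if "HT" not in df.columns:
        df["HT"] = np.nan

    # recover 1-based file row numbers for error messages (header + comments)
    with open(path) as fh:
        data_rows = [
            i + 1
            for i, line in enumerate(fh)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    row_no = dict(zip(df.index, data_rows[1:]))  # first non-comment line is the header

    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            bad = grp.index[int(np.flatnonzero(np.diff(times) < 0)[0]) + 1]
            raise DatasetFormatError(f"{path} row {row_no[bad]}: TIME decreases within ID {sid}")

        first = grp.iloc[0]
        age = float(first["AGE"])
        sex_code = first["SEX"]
        if pd.isna(age):
            raise DatasetFormatError(f"{path}: missing AGE for ID {sid}")
        if sex_code not in (0, 1, 0.0, 1.0):
            raise DatasetFormatError(
                f"{path} row {row_no[grp.index[0]]}: unknown SEX code {sex_code!r} for ID {sid}"
            )
        wt = float(first["WT"]) if not pd.isna(first["WT"]) else None
        ht = float(first["HT"]) if not pd.isna(first["HT"]) else None
        cov = Covariates(age=age, sex="female" if int(sex_code) == 1 else "male",
                         weight=wt, height=ht)

        doses: list[DoseEvent] = []
        obs: list[Observation] = []
        for idx, rec in grp.iterrows():
            evid = int(rec["EVID"])
            t = float(rec["TIME"])
            if evid == 1:
                amt = rec["AMT"]
                if pd.isna(amt) or float(amt) <= 0:
                    raise DatasetFormatError(
                        f"{path} row {row_no[idx]}: dose row (EVID=1) needs AMT > 0"
                    )
                if int(rec["MDV"]) != 1:
                    raise DatasetFormatError(
                        f"{path} row {row_no[idx]}: dose row must have MDV=1"
                    )
                doses.append(DoseEvent(t, float(amt)))
            elif evid == 0:
                if not pd.isna(rec["AMT"]) and float(rec["AMT"]) != 0:
                    raise DatasetFormatError(
                        f"{path} row {row_no[idx]}: observation row must have empty/zero AMT"
                    )
                if int(rec["MDV"]) == 1:
                    continue  # missing DV: design row, not an observation
                prior = [d.time for d in doses if d.time <= t]
                if not prior:
                    raise DatasetFormatError(
                        f"{path} row {row_no[idx]}: observation before any dose for ID {sid}"
                    )
                obs.append(Observation(t, float(rec["DV"]), t - max(prior)))
            else:
                raise DatasetFormatError(
                    f"{path} row {row_no[idx]}: unsupported EVID {evid}"
                )
        subjects.append(Subject(str(sid), cov, doses, obs))
    return Dataset(subjects=subjects, metadata={"source": str(path)})


def write_dataset(dataset: Dataset, path, header_comment: str | None = None) -> None:
    """Write a Dataset in the fixed dialect: by ID, then TIME, doses first."""
    rows = []
    for s in dataset.subjects:
        cov = s.covariates
        sex = 1 if cov.is_female else 0
        for d in s.doses:
            rows.append([s.id, d.time, d.amount, "", 1, 1, cov.age, sex,
                         cov.weight if cov.weight is not None else "",
                         cov.height if cov.height is not None else ""])
        for o in s.observations:
            rows.append([s.id, o.time, "", o.dv, 0, 0, cov.age, sex,
                         cov.weight if cov.weight is not None else "",
                         cov.height if cov.height is not None else ""])
    df = pd.DataFrame(rows, columns=COLUMNS)
    # stable ordering: ID (input order), TIME, dose rows before observations
    df["_ord"] = np.arange(len(df))
    df["_id_ord"] = df["ID"].map({s.id: i for i, s in enumerate(dataset.subjects)})
    df = df.sort_values(["_id_ord", "TIME", "EVID"], ascending=[True, True, False],
                        kind="stable").drop(columns=["_ord", "_id_ord"])
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def save_params(pop: PopulationParameters, path, comment: str | None = None) -> None:
    """Write a population-parameter YAML with units and fix-flags."""
    doc = {
        "parameters": {
            name: {
                "value": float(getattr(pop, name)),
                "unit": _UNITS[name],
                "fixed": bool(pop.is_fixed(name)),
            }
            for name in PARAMETER_NAMES
        },
        "age_ref": {"value": float(pop.age_ref), "unit": "yr"},
        "concentration_unit": "ug/L",
    }
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path) -> PopulationParameters:
    """Load and validate a population-parameter YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ValueError(f"{path}: not a parameter file (missing 'parameters')")
    params = doc["parameters"]
    missing = [n for n in PARAMETER_NAMES if n not in params]
    if missing:
        raise ValueError(f"{path}: incomplete parameter file, missing {missing}")
    values = {}
    fixed = {}
    for name in PARAMETER_NAMES:
        entry = params[name]
        if not isinstance(entry, dict) or "value" not in entry:
            raise ValueError(f"{path}: parameter {name} needs a 'value' entry")
        values[name] = float(entry["value"])
        fixed[name] = bool(entry.get("fixed", False))
    age_ref = float(doc.get("age_ref", {}).get("value", 0.0))
    return PopulationParameters(**values, age_ref=age_ref, fixed=fixed)
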