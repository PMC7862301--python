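"""Readers and writers for the tabular input formats.

CSV dialect: comma-separated, UTF-8, header row required, "." decimal,
one row per (mutant, condition, x-value).  Malformed rows are reported
with their line numbers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .datatypes import (
    DoseResponseCurve,
    DoseResponsePoint,
    IVCurve,
    IV_CONDITIONS,
    MutantSpec,
    ValidationError,
)

logger = logging.getLogger(__name__)

DOSE_COLUMNS = ["mutant_id", "ca_uM", "response", "sem", "n_patches"]
IV_COLUMNS = ["mutant_id", "condition", "voltage_mV", "current"]


class FormatError(ValueError):
    """The file does not match the declared CSV schema."""


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def _check_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based counting
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = coerced


def load_dose_response(path) -> list[DoseResponseCurve]:
    """Load dose-response curves, grouped by mutant and sorted by ca."""
    df = _read_csv(path, DOSE_COLUMNS)
    _check_numeric(df, ["ca_uM", "response", "sem", "n_patches"], path)
    dup = df.duplicated(subset=["mutant_id", "ca_uM"])
    if dup.any():
        line = df.index[dup][0] + 2
        raise ValidationError(f"{path}: duplicate (mutant, ca) at line {line}")
    curves = []
    for mutant_id, grp in df.groupby("mutant_id", sort=True):
        points = [
            DoseResponsePoint(
                ca=row.ca_uM, response=row.response,
                sem=row.sem, n_patches=int(row.n_patches),
            )
            for row in grp.itertuples()
        ]
        curves.append(DoseResponseCurve(str(mutant_id), points))
    return curves


def save_dose_response(curves: list[DoseResponseCurve], path) -> None:
    rows = [
        {
            "mutant_id": c.mutant_id, "ca_uM": p.ca, "response": p.response,
            "sem": p.sem, "n_patches": p.n_patches,
        }
        for c in curves
        for p in c.points
    ]
    pd.DataFrame(rows, columns=DOSE_COLUMNS).to_csv(path, index=False)


def load_iv(path) -> list[IVCurve]:
    """Load I-V relations, one curve per (mutant, condition)."""
    df = _read_csv(path, IV_COLUMNS)
    if df.empty:
        logger.warning("%s: empty I-V file, returning no curves", path)
        return []
    _check_numeric(df, ["voltage_mV", "current"], path)
    unknown = set(df["condition"]) - set(IV_CONDITIONS)
    if unknown:
        raise ValidationError(
            f"{path}: unknown condition label(s) {sorted(unknown)}; "
            f"expected one of {IV_CONDITIONS}"
        )
    curves = []
    for (mutant_id, condition), grp in df.groupby(
        ["mutant_id", "condition"], sort=True
    ):
        grp = grp.sort_values("voltage_mV")
        curves.append(
            IVCurve(
                str(mutant_id), str(condition),
                grp["voltage_mV"].to_numpy(), grp["current"].to_numpy(),
            )
        )
    return curves


def save_iv(curves: list[IVCurve], path) -> None:
    rows = [
        {
            "mutant_id": c.mutant_id, "condition": c.condition,
            "voltage_mV": v, "current": i,
        }
        for c in curves
        for v, i in zip(c.voltages, c.currents)
    ]
    pd.DataFrame(rows, columns=IV_COLUMNS).to_csv(path, index=False)


def load_mutants(path) -> dict[str, MutantSpec]:
    """Mutant metadata JSON: {"mutant_id": {"550": "I", "551": "A", "641": "I"}}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {mid: MutantSpec.from_mapping(m) for mid, m in raw.items()}


def save_mutants(mutants: dict[str, MutantSpec], path) -> None:
    payload = {mid: spec.to_mapping() for mid, spec in mutants.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def save_json(payload: dict, path) -> None:
    """Deterministic JSON: sorted keys, repr-based floats, trailing newline."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
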