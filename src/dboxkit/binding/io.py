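"""CSV dialects for titration data and JSON fit reports.

ITC CSV: header ``injection,volume_uL,heat_ucal``; the protocol's scalar
fields travel in a sidecar JSON or as CLI flags. Anisotropy CSV: header
``Pt_uM,anisotropy`` with the labelled-peptide total supplied separately.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .isotherm import ItcProtocol
from .models import BindingResults, TitrationSeries

ITC_COLUMNS = ["injection", "volume_uL", "heat_ucal"]
FA_COLUMNS = ["Pt_uM", "anisotropy"]


class DialectError(ValueError):
    """A CSV file does not match the declared dialect."""


def _require_columns(frame: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise DialectError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{','.join(cols)}"
        )


def read_itc_csv(path: str | Path, protocol_json: str | Path | None = None,
                 **protocol_overrides) -> TitrationSeries:
    """Read an ITC titration; injection volumes come from the CSV, the
    remaining protocol fields from a sidecar JSON and/or keyword overrides."""
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, ITC_COLUMNS, path)
    for i, col in enumerate(["volume_uL", "heat_ucal"], 1):
        bad = frame.index[frame[col].isna()]
        if len(bad):
            raise DialectError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
    fields = {}
    if protocol_json is not None:
        fields.update(json.loads(Path(protocol_json).read_text()))
    fields.update(protocol_overrides)
    fields["injection_volumes"] = tuple(float(v) for v in frame["volume_uL"])
    protocol = ItcProtocol(**fields)
    return TitrationSeries(
        "ITC", heats=tuple(float(h) for h in frame["heat_ucal"]), protocol=protocol
    )


def write_itc_csv(series: TitrationSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "injection": range(1, len(series.heats) + 1),
            "volume_uL": series.protocol.injection_volumes,
            "heat_ucal": series.heats,
        }
    ).to_csv(path, index=False)


def read_anisotropy_csv(path: str | Path, Lt: float) -> TitrationSeries:
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, FA_COLUMNS, path)
    return TitrationSeries(
        "ANISOTROPY",
        Pt=tuple(float(p) for p in frame["Pt_uM"]),
        Lt=Lt,
        A=tuple(float(a) for a in frame["anisotropy"]),
    )


def write_anisotropy_csv(series: TitrationSeries, path: str | Path) -> None:
    pd.DataFrame({"Pt_uM": series.Pt, "anisotropy": series.A}).to_csv(
        path, index=False
    )


def write_fit_report(results: BindingResults, path: str | Path,
                     mode: str = "") -> None:
    """JSON fit report: parameters, SEs, CIs, residual norm, convergence."""
    payload = results.to_dict()
    payload["mode"] = mode or type(results.model).__name__
    Path(path).write_text(json.dumps(payload, indent=2))
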