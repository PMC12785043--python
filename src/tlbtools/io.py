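"""Reading and writing thermogram data.

Three input dialects are recognized automatically, in CSV (RFC 4180,
UTF-8, "." decimal separator) or Excel (.xls/.xlsx) form:

``single``
    Two columns, temperature then heat capacity (any headers); the
    sample id is the file stem.
``multi`` (paired wide)
    Columns paired as (temperature, value): a temperature column is one
    whose header, after stripping non-alphanumerics and lowercasing, is
    ``t<id>`` or ``temperature<id>``, paired with the column headed
    ``<id>`` (e.g. ``T_A, A, T_B, B``). A wide layout whose first column
    is headed like "Temperature" with several value columns sharing that
    grid (the package's own wide export) is also accepted.
``long``
    Columns ``sample_id, temperature, value`` (flexible header
    synonyms); one profile per distinct sample id, in order of first
    appearance.

On load, rows with a missing temperature or value are dropped for that
sample only, points are sorted by ascending temperature, and duplicate
temperatures are collapsed by averaging their values.

Exports: a wide CSV (one shared temperature column) or a multi-sheet
Excel workbook with ``corrected`` (wide grid), ``classifications``,
optional ``metrics`` and a key-value ``metadata`` sheet. Numbers are
written at full precision so exports reload bit-identically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, GridMismatchError, ParseError
from .profiles import GriddedProfile, SignalClassification, ThermogramProfile

__all__ = [
    "load_thermograms",
    "write_thermograms",
    "write_export",
    "BatchMetadata",
]

_TEMP_NAMES = {"t", "temp", "temperature"}
_SAMPLE_NAMES = {"sampleid", "sample", "id"}


def _norm(header) -> str:
    return re.sub(r"[^0-9a-z]", "", str(header).lower())


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() == ".csv":
        try:
            return pd.read_csv(path, float_precision="round_trip")
        except OSError:
            raise
        except pd.errors.ParserError as exc:
            raise FormatError(f"{path}: unparseable CSV: {exc}") from exc
    if path.suffix.lower() in (".xls", ".xlsx"):
        return pd.read_excel(path)
    raise FormatError(
        f"{path}: unsupported extension {path.suffix!r}; expected .csv, "
        f".xls or .xlsx"
    )


def _numeric(series: pd.Series, column: str) -> pd.Series:
    """Coerce to float, locating any non-numeric cell for the error."""
    coerced = pd.to_numeric(series, errors="coerce")
    text = series.astype(str).str.strip()
    bad = series.notna() & coerced.isna() & (text != "") & (text.str.lower() != "nan")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {series.iloc[row]!r} in column "
            f"{column!r}, data row {row}"
        )
    return coerced.astype(float)


def _make_profile(sample_id: str, temps: pd.Series, values: pd.Series,
                  source: str) -> ThermogramProfile | None:
    """Clean one (temperature, value) pair into a profile.

    Returns None when fewer than 2 valid points remain.
    """
    df = pd.DataFrame({"t": temps.to_numpy(float), "v": values.to_numpy(float)})
    df = df.dropna()
    if len(df) < 2:
        return None
    df = df.groupby("t", sort=True, as_index=False)["v"].mean()
    return ThermogramProfile(
        sample_id=sample_id,
        temperatures=df["t"].to_numpy(),
        heat_capacity=df["v"].to_numpy(),
        source=source,
    )


def _pair_columns(columns: Sequence[str]) -> list[tuple[str, str]] | None:
    """Match paired-wide (temperature, value) columns, or None."""
    norms = {c: _norm(c) for c in columns}
    by_norm: dict[str, str] = {}
    for c, n in norms.items():
        by_norm.setdefault(n, c)
    pairs: list[tuple[str, str]] = []
    used: set[str] = set()
    for c in columns:  # preserve file column order
        n = norms[c]
        for prefix in ("temperature", "t"):
            if n.startswith(prefix) and len(n) > len(prefix):
                vid = n[len(prefix):]
                vcol = by_norm.get(vid)
                if vcol is not None and vcol not in used and c not in used:
                    pairs.append((c, vcol))
                    used.update((c, vcol))
                    break
    if pairs and used == set(columns):
        return pairs
    return None


def _detect(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    norms = [_norm(c) for c in cols]
    if len(cols) >= 3 and any(n in _SAMPLE_NAMES for n in norms) and any(
        n in _TEMP_NAMES for n in norms
    ):
        return "long"
    if len(cols) == 2:
        return "single"
    if _pair_columns(cols) is not None:
        return "multi"
    if len(cols) >= 2 and norms[0] in _TEMP_NAMES:
        return "multi_shared"
    raise FormatError(
        "no recognizable column structure; expected a two-column single-"
        "sample file, paired wide columns (T_<id>, <id>), a shared "
        "temperature column followed by sample columns, or long format "
        "(sample_id, temperature, value)"
    )


def load_thermograms(path, format_hint: str = "auto") -> list[ThermogramProfile]:
    """Load thermogram profiles from a CSV or Excel file.

    ``format_hint`` is one of ``auto`` (default), ``single``, ``multi``
    or ``long``. Samples are returned in file column (or first
    appearance) order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    if df.empty or len(df.columns) < 2:
        raise FormatError(f"{path}: no tabular data with >= 2 columns")
    if format_hint == "auto":
        dialect = _detect(df)
    elif format_hint in ("single", "long"):
        dialect = format_hint
    elif format_hint == "multi":
        dialect = "multi" if _pair_columns(list(df.columns)) else "multi_shared"
    else:
        raise ValueError(f"unknown format_hint {format_hint!r}")
    source = path.name

    profiles: list[ThermogramProfile] = []
    if dialect == "single":
        if len(df.columns) != 2:
            raise FormatError(
                f"{path}: single-sample dialect requires exactly 2 columns"
            )
        tcol, vcol = df.columns
        p = _make_profile(path.stem, _numeric(df[tcol], str(tcol)),
                          _numeric(df[vcol], str(vcol)), source)
        if p is None:
            raise FormatError(f"{path}: fewer than 2 valid data rows")
        profiles.append(p)
    elif dialect == "long":
        norms = {_norm(c): c for c in df.columns}
        scol = next((norms[n] for n in norms if n in _SAMPLE_NAMES), None)
        tcol = next((norms[n] for n in norms if n in _TEMP_NAMES), None)
        rest = [c for c in df.columns if c not in (scol, tcol)]
        if scol is None or tcol is None or len(rest) != 1:
            raise FormatError(
                f"{path}: long dialect requires sample_id, temperature and "
                f"one value column"
            )
        vcol = rest[0]
        temps = _numeric(df[tcol], str(tcol))
        values = _numeric(df[vcol], str(vcol))
        for sid in df[scol].astype(str).drop_duplicates():
            mask = df[scol].astype(str) == sid
            p = _make_profile(sid, temps[mask], values[mask], source)
            if p is not None:
                profiles.append(p)
    elif dialect == "multi":
        for tcol, vcol in _pair_columns(list(df.columns)):
            p = _make_profile(str(vcol), _numeric(df[tcol], str(tcol)),
                              _numeric(df[vcol], str(vcol)), source)
            if p is not None:
                profiles.append(p)
    else:  # multi_shared
        tcol = df.columns[0]
        temps = _numeric(df[tcol], str(tcol))
        for vcol in df.columns[1:]:
            p = _make_profile(str(vcol), temps,
                              _numeric(df[vcol], str(vcol)), source)
            if p is not None:
                profiles.append(p)
    if not profiles:
        raise FormatError(f"{path}: no sample had 2 or more valid data points")
    return profiles


def write_thermograms(profiles: Sequence[ThermogramProfile], path,
                      dialect: str = "multi") -> Path:
    """Write raw profiles in the ``single``, ``multi`` or ``long`` dialect.

    CSV or Excel is chosen by the file extension. The ``single`` dialect
    requires exactly one profile; ``multi`` writes paired
    (``T_<id>``, ``<id>``) columns padded with blanks.
    """
    path = Path(path)
    if not profiles:
        raise ValueError("no profiles to write")
    if dialect == "single":
        if len(profiles) != 1:
            raise ValueError("single dialect holds exactly one profile")
        p = profiles[0]
        df = pd.DataFrame({"Temperature": p.temperatures, "dCp": p.heat_capacity})
    elif dialect == "multi":
        pieces = {}
        n = max(p.n_points for p in profiles)
        for p in profiles:
            pad = n - p.n_points
            pieces[f"T_{p.sample_id}"] = np.concatenate(
                [p.temperatures, np.full(pad, np.nan)])
            pieces[p.sample_id] = np.concatenate(
                [p.heat_capacity, np.full(pad, np.nan)])
        df = pd.DataFrame(pieces)
    elif dialect == "long":
        df = pd.concat(
            [pd.DataFrame({"sample_id": p.sample_id,
                           "temperature": p.temperatures,
                           "value": p.heat_capacity}) for p in profiles],
            ignore_index=True,
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if path.suffix.lower() == ".csv":
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        df.to_excel(path, index=False)
    return path


@dataclass
class BatchMetadata:
    """Provenance of a batch run, exported on the metadata sheet.

    ``per_sample_endpoints`` maps sample id to (lower degC, upper degC,
    manually_adjusted) with None endpoints for unprocessed samples; its
    length must equal ``sample_count``.
    """

    source_name: str
    sample_count: int
    metrics_evaluated: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    per_sample_endpoints: dict[str, tuple[float | None, float | None, bool]] = field(
        default_factory=dict
    )
    created_at: datetime = field(
        default_factory=lambda: datetime.now(timezone.utc)
    )

    def __post_init__(self):
        if self.sample_count < 0:
            raise ValueError("sample_count must be non-negative")
        if self.per_sample_endpoints and (
            len(self.per_sample_endpoints) != self.sample_count
        ):
            raise ValueError(
                "sample_count must equal the number of per-sample entries"
            )

    def to_rows(self) -> list[tuple[str, str]]:
        rows = [
            ("created_at", self.created_at.isoformat()),
            ("source_name", self.source_name),
            ("sample_count", str(self.sample_count)),
            ("metrics_evaluated", ",".join(self.metrics_evaluated)),
        ]
        rows += [(f"parameter:{k}", str(v)) for k, v in self.parameters.items()]
        for sid, (lo, hi, adjusted) in self.per_sample_endpoints.items():
            rows.append(
                (f"endpoints:{sid}",
                 f"lower={lo},upper={hi},manually_adjusted={adjusted}")
            )
        return rows


def _corrected_frame(profiles: Sequence[GriddedProfile]) -> pd.DataFrame:
    grid = profiles[0].grid_temperatures
    for p in profiles[1:]:
        if p.grid_temperatures.shape != grid.shape or not np.allclose(
            p.grid_temperatures, grid, rtol=0, atol=1e-9
        ):
            raise GridMismatchError(
                f"profile {p.sample_id!r} is on a different temperature grid"
            )
    data = {"Temperature": grid}
    for p in profiles:
        data[p.sample_id] = p.corrected_values
    return pd.DataFrame(data)


def _classification_frame(
    classifications: Sequence[SignalClassification],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in classifications],
            "label": [c.label for c in classifications],
            "d_extra": [c.d_extra for c in classifications],
            "input_mode": [c.input_mode for c in classifications],
            "pvalues": [";".join(f"{p:.6g}" for p in c.test_pvalues)
                        for c in classifications],
        }
    )


def write_export(
    profiles: Sequence[GriddedProfile],
    classifications: Sequence[SignalClassification],
    metadata: BatchMetadata,
    path,
    format: str = "csv_wide",
    metrics: pd.DataFrame | None = None,
) -> Path:
    """Write processed results.

    ``csv_wide`` writes the corrected wide grid as CSV (and drops the
    classification/metadata sheets); ``xlsx_multi`` writes an Excel
    workbook with ``corrected``, ``classifications``, optional
    ``metrics`` and ``metadata`` sheets.
    """
    path = Path(path)
    if not profiles and format == "csv_wide":
        raise ValueError("no gridded profiles to export")
    if format == "csv_wide":
        _corrected_frame(profiles).to_csv(path, index=False,
                                          float_format="%.17g")
        return path
    if format != "xlsx_multi":
        raise ValueError(f"unknown export format {format!r}")
    if not profiles and not classifications:
        raise ValueError("nothing to export")
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        if profiles:
            _corrected_frame(profiles).to_excel(
                writer, sheet_name="corrected", index=False)
        else:
            pd.DataFrame({"Temperature": []}).to_excel(
                writer, sheet_name="corrected", index=False)
        _classification_frame(classifications).to_excel(
            writer, sheet_name="classifications", index=False)
        if metrics is not None:
            metrics.to_excel(writer, sheet_name="metrics", index=False)
        pd.DataFrame(metadata.to_rows(), columns=["key", "value"]).to_excel(
            writer, sheet_name="metadata", index=False)
    return path
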