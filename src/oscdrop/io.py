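"""CSV readers and writers for the single canonical dialect.

Traces: header ``time_s,area_mm2,tension_mN_m``, dot decimal separator,
comma field separator, UTF-8, with optional leading ``#``-prefixed
metadata lines of the form ``# key=value`` (``concentration_mM``,
``salt_mM``, ``frequency_hz``, ...). Isotherms: ``conc_mol_per_L,
tension_mN_m`` with the same metadata convention. All numeric output is
locale-independent and round-trip stable to 12 significant digits (values
are written with 17 significant digits).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .isotherm import IsothermDataset
from .trace import OscillationTrace

TRACE_COLUMNS = ("time_s", "area_mm2", "tension_mN_m")
ISOTHERM_COLUMNS = ("conc_mol_per_L", "tension_mN_m")
MODULUS_COLUMNS = (
    "concentration_mM",
    "frequency_hz",
    "eps_real_mN_m",
    "eps_imag_mN_m",
    "harmonic_ratio",
    "quality_flag",
)


def _parse_meta_value(raw: str):
    raw = raw.strip()
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        v = float(raw)
        return int(v) if v.is_integer() and "." not in raw and "e" not in low else v
    except ValueError:
        return raw


def _read_with_meta(path, columns) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict = {}
    header_line = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = _parse_meta_value(value)
                continue
            header_line = lineno
            break
    if header_line is None:
        raise ParseError(f"{path}: no header line found")
    try:
        df = pd.read_csv(
            path, comment="#", encoding="utf-8", float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}", line=header_line)
    for col in columns:
        if col == "quality_flag":
            continue
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col}",
                line=header_line + 1 + row,
            )
        df[col] = pd.to_numeric(df[col])
    df.attrs["header_line"] = header_line
    return df, meta


def read_trace_csv(path) -> OscillationTrace:
    """Read one oscillation trace; metadata lines populate ``trace.meta``."""
    df, meta = _read_with_meta(path, TRACE_COLUMNS)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 1
        raise ParseError(
            f"{path}: time_s not strictly increasing",
            line=df.attrs["header_line"] + 1 + bad,
        )
    nominal = meta.get("frequency_hz")
    if nominal is None:
        raise ParseError(f"{path}: missing '# frequency_hz=' metadata line")
    return OscillationTrace(
        t=t,
        area=df["area_mm2"].to_numpy(),
        tension=df["tension_mN_m"].to_numpy(),
        nominal_frequency=float(nominal),
        meta=meta,
    )


def _write_meta(fh, meta: dict) -> None:
    for key, value in meta.items():
        fh.write(f"# {key}={value}\n")


def write_trace_csv(trace: OscillationTrace, path) -> Path:
    """Write a trace in the canonical dialect (17 significant digits)."""
    path = Path(path)
    meta = dict(trace.meta)
    meta["frequency_hz"] = trace.nominal_frequency
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        _write_meta(fh, meta)
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for row in zip(trace.t, trace.area, trace.tension):
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_isotherm_csv(path) -> IsothermDataset:
    """Read an equilibrium isotherm dataset with its salt condition."""
    df, meta = _read_with_meta(path, ISOTHERM_COLUMNS)
    return IsothermDataset(
        concentrations=df["conc_mol_per_L"].to_numpy(),
        tensions=df["tension_mN_m"].to_numpy(),
        salt_mM=float(meta.get("salt_mM", 0.0)),
        meta=meta,
    )


def write_isotherm_csv(data: IsothermDataset, path) -> Path:
    path = Path(path)
    meta = {k: v for k, v in data.meta.items() if v is not None}
    meta["salt_mM"] = data.salt_mM
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        _write_meta(fh, meta)
        fh.write(",".join(ISOTHERM_COLUMNS) + "\n")
        for c, s in zip(data.concentrations, data.tensions):
            fh.write(f"{c:.17g},{s:.17g}\n")
    return path


def write_modulus_table(points, path) -> Path:
    """Write analysed modulus points as the canonical modulus table CSV."""
    rows = []
    for p in points:
        rows.append(
            {
                "concentration_mM": p.meta.get("concentration_mM", np.nan),
                "frequency_hz": p.frequency,
                "eps_real_mN_m": p.eps_real,
                "eps_imag_mN_m": p.eps_imag,
                "harmonic_ratio": p.harmonic_ratio,
                "quality_flag": p.quality_flag,
            }
        )
    df = pd.DataFrame(rows, columns=MODULUS_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_modulus_table(path) -> pd.DataFrame:
    df, _ = _read_with_meta(path, MODULUS_COLUMNS)
    return df
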