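"""Reading and writing long-format trial-level gaze CSV files.

The canonical on-disk format is a delimited UTF-8 text file with a header and
one row per gaze sample.  Logical column names (participant, item, condition,
trial, t_ms, aoi, correct) can be remapped to arbitrary file columns through a
``column_map``; AOI value labels (e.g. screen sides) can likewise be remapped
to the canonical factual/illusory/elsewhere labels.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (AOIS, CONDITIONS, SAMPLE_COLUMNS, SchemaError, TrialSet,
                   ValidationError, WindowConfig)

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def _parse_correct(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    s = col.astype(str).str.strip().str.lower()
    out = pd.Series(np.zeros(len(s), dtype=bool), index=col.index)
    out[s.isin(_TRUE)] = True
    bad = ~(s.isin(_TRUE) | s.isin(_FALSE))
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"unparseable 'correct' value {col.iloc[idx]!r} at data row {idx}")
    return out


def read_trials(source,
                column_map: dict | None = None,
                delimiter: str = ",",
                window_config: WindowConfig | None = None,
                metadata: dict | None = None) -> TrialSet:
    """Read gaze samples from a delimited text file (or file-like / path).

    Parameters
    ----------
    source : path or readable text stream
    column_map : dict, optional
        Maps logical column names to the file's column names, e.g.
        ``{"t_ms": "time"}``.  Two special keys control AOI handling:
        ``"aoi_values"`` maps raw AOI labels to canonical ones
        (``{"left": "factual", "right": "illusory"}``) and
        ``"unknown_aoi_to_elsewhere": True`` sends any unmapped label to
        ``elsewhere`` instead of rejecting it.
    delimiter : str
        Field delimiter, ``,`` by default.

    Raises
    ------
    SchemaError
        A required column is absent, or AOI values cannot be resolved to the
        canonical labels.
    ValidationError
        Non-numeric time (reported with its row index) or an unknown
        condition label.
    """
    cmap = dict(column_map or {})
    aoi_values = cmap.pop("aoi_values", None)
    unknown_to_elsewhere = bool(cmap.pop("unknown_aoi_to_elsewhere", False))

    raw = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    cols = {}
    for logical in SAMPLE_COLUMNS:
        actual = cmap.get(logical, logical)
        if actual not in raw.columns:
            raise SchemaError(f"required column {logical!r} (file column {actual!r}) is missing")
        cols[logical] = raw[actual]
    df = pd.DataFrame(cols)

    if not len(df):
        warnings.warn("input file has a header but no data rows; returning an empty TrialSet",
                      stacklevel=2)
        df = df.assign(t_ms=pd.Series([], dtype=float), correct=pd.Series([], dtype=bool))
        return TrialSet(samples=df, window_config=window_config or WindowConfig(),
                        metadata=dict(metadata or {}))

    t = pd.to_numeric(df["t_ms"], errors="coerce")
    if t.isna().any():
        idx = int(np.flatnonzero(t.isna().to_numpy())[0])
        raise ValidationError(f"non-numeric t_ms value {df['t_ms'].iloc[idx]!r} at data row {idx}")
    df["t_ms"] = t.astype(float)

    df["condition"] = df["condition"].str.strip()
    bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise ValidationError(f"unknown condition labels: {sorted(bad_cond)}; "
                              f"expected one of {CONDITIONS}")

    aoi = df["aoi"].str.strip()
    if aoi_values:
        aoi = aoi.map(lambda v: aoi_values.get(v, v))
    unknown = sorted(set(aoi.unique()) - set(AOIS))
    if unknown:
        if unknown_to_elsewhere:
            aoi = aoi.map(lambda v: v if v in AOIS else "elsewhere")
        else:
            raise SchemaError(
                f"AOI labels {unknown} are not canonical and no mapping covers them; "
                "provide column_map['aoi_values'] or set "
                "column_map['unknown_aoi_to_elsewhere']=True")
    df["aoi"] = aoi

    df["correct"] = _parse_correct(df["correct"])
    return TrialSet(samples=df.reset_index(drop=True),
                    window_config=window_config or WindowConfig(),
                    metadata=dict(metadata or {}))


def write_trials(ts: TrialSet, path) -> Path:
    """Write a TrialSet as canonical CSV plus a ``<path>.meta.json`` sidecar.

    The sidecar records metadata and the window bounds, so
    ``read_trials`` on the pair round-trips the logical content.
    """
    path = Path(path)
    cols = [c for c in (*SAMPLE_COLUMNS, "window") if c in ts.samples.columns]
    out = ts.samples[cols].copy()
    # canonical integer times when lossless, for byte-stable output
    t = out["t_ms"].to_numpy(dtype=float)
    if len(t) and np.all(t == np.round(t)):
        out["t_ms"] = t.astype(np.int64)
    out.to_csv(path, index=False)
    sidecar = {"metadata": ts.metadata, "windows": ts.window_config.to_dict(),
               "n_samples": int(ts.n_samples), "n_trials": int(ts.n_trials)}
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def read_trials_with_sidecar(path, **kwargs) -> TrialSet:
    """Read a canonical CSV written by :func:`write_trials`, restoring metadata."""
    side = Path(str(path) + ".meta.json")
    window_config = None
    metadata = None
    if side.exists():
        doc = json.loads(side.read_text(encoding="utf-8"))
        window_config = WindowConfig.from_dict(doc["windows"])
        metadata = doc.get("metadata", {})
    return read_trials(path, window_config=window_config, metadata=metadata, **kwargs)


__all__ = ["read_trials", "write_trials", "read_trials_with_sidecar"]
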