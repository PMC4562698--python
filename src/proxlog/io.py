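"""CSV interchange for pulse streams, encounter logs, records and uptime.

Core computations use integer seconds since the simulation epoch; on disk,
timestamps are ISO-8601 UTC.  Every file starts with ``#``-prefixed header
comments recording the package version, the seed and the epoch, so any
output can be regenerated and compared byte-for-byte.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

DEFAULT_EPOCH = "2014-07-17T00:00:00+00:00"

__all__ = [
    "DEFAULT_EPOCH",
    "write_table",
    "read_table",
    "write_logs_csv",
    "read_logs_csv",
    "write_pulses_csv",
    "read_pulses_csv",
    "write_records_csv",
    "write_uptime_csv",
    "read_uptime_csv",
]


def _header_lines(meta: dict) -> str:
    from . import __version__

    items = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# proxlog v{__version__} {items}\n"


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    with open(Path(path), "w") as fh:
        fh.write(_header_lines(meta or {}))
        df.to_csv(fh, index=False)


def read_table(path) -> Tuple[pd.DataFrame, dict]:
    meta: dict = {}
    with open(Path(path)) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            for tok in line.lstrip("# ").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def _to_iso(seconds, epoch: str) -> pd.Series:
    base = pd.Timestamp(epoch)
    return (base + pd.to_timedelta(seconds, unit="s")).dt.strftime("%Y-%m-%dT%H:%M:%SZ")


def _from_iso(series: pd.Series, epoch: str) -> pd.Series:
    base = pd.Timestamp(epoch)
    ts = pd.to_datetime(series, utc=True, format="%Y-%m-%dT%H:%M:%SZ")
    return ((ts - base).dt.total_seconds()).astype(int)


def write_logs_csv(
    logs: pd.DataFrame, path, seed: Optional[int] = None, epoch: str = DEFAULT_EPOCH,
    extra_meta: Optional[dict] = None,
) -> None:
    """Canonical encounter-log CSV: ids, ISO start/end, duration, RSSI stats."""
    out = pd.DataFrame(
        {
            "logger_id": logs["logger_id"],
            "partner_id": logs["partner_id"],
            "start_iso8601": _to_iso(logs["start"], epoch),
            "end_iso8601": _to_iso(logs["end"], epoch),
            "duration_s": logs["end"] - logs["start"],
            "min_rssi": logs["min_rssi"],
            "mean_rssi": logs["mean_rssi"].round(4),
            "max_rssi": logs["max_rssi"],
            "n_pulses": logs["n_pulses"],
        }
    )
    meta = {"epoch": epoch}
    if seed is not None:
        meta["seed"] = seed
    meta.update(extra_meta or {})
    write_table(out, path, meta)


_LOG_REQUIRED = {
    "logger_id", "partner_id", "start_iso8601", "end_iso8601",
    "min_rssi", "mean_rssi", "max_rssi", "n_pulses",
}


def read_logs_csv(path) -> Tuple[pd.DataFrame, dict]:
    df, meta = read_table(path)
    missing = _LOG_REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"log CSV {path} is missing column(s): {sorted(missing)}")
    epoch = meta.get("epoch", DEFAULT_EPOCH)
    out = pd.DataFrame(
        {
            "logger_id": df["logger_id"].astype(int),
            "partner_id": df["partner_id"].astype(int),
            "start": _from_iso(df["start_iso8601"], epoch),
            "end": _from_iso(df["end_iso8601"], epoch),
            "min_rssi": df["min_rssi"].astype(int),
            "mean_rssi": df["mean_rssi"].astype(float),
            "max_rssi": df["max_rssi"].astype(int),
            "n_pulses": df["n_pulses"].astype(int),
        }
    )
    out["duration"] = out["end"] - out["start"]
    return out, meta


def write_pulses_csv(
    pulses: pd.DataFrame, path, seed: Optional[int] = None, epoch: str = DEFAULT_EPOCH,
    listener_col: str = "listener_id",
) -> None:
    out = pd.DataFrame(
        {
            listener_col: pulses[listener_col],
            "source_id": pulses["source_id"],
            "t_iso8601": _to_iso(pulses["t"], epoch),
            "rssi": pulses["rssi"],
        }
    )
    meta = {"epoch": epoch}
    if seed is not None:
        meta["seed"] = seed
    write_table(out, path, meta)


def read_pulses_csv(path, listener_col: str = "listener_id") -> Tuple[pd.DataFrame, dict]:
    df, meta = read_table(path)
    epoch = meta.get("epoch", DEFAULT_EPOCH)
    out = pd.DataFrame(
        {
            listener_col: df[listener_col].astype(int),
            "source_id": df["source_id"].astype(int),
            "t": _from_iso(df["t_iso8601"], epoch),
            "rssi": df["rssi"].astype(int),
        }
    )
    return out, meta


_RECORD_EXPORT = [
    "pair_id", "tag_a", "tag_b", "status", "broken", "staggered",
    "start", "end", "duration", "max_rssi", "min_rssi", "mean_rssi",
    "min_rssi_a", "mean_rssi_a", "max_rssi_a", "n_fragments_a",
    "min_rssi_b", "mean_rssi_b", "max_rssi_b", "n_fragments_b",
]


def write_records_csv(
    records: pd.DataFrame, path, seed: Optional[int] = None, epoch: str = DEFAULT_EPOCH,
    extra_meta: Optional[dict] = None,
) -> None:
    out = records.reindex(columns=_RECORD_EXPORT).copy()
    out.insert(7, "start_iso8601", _to_iso(records["start"], epoch))
    out.insert(8, "end_iso8601", _to_iso(records["end"], epoch))
    out = out.drop(columns=["start", "end"])
    # per-side windows (seconds offsets; NaN for the absent side of singles)
    for side in ("a", "b"):
        out[f"start_{side}_s"] = records[f"start_{side}"]
        out[f"end_{side}_s"] = records[f"end_{side}"]
    for c in ("mean_rssi", "mean_rssi_a", "mean_rssi_b"):
        out[c] = out[c].astype(float).round(4)
    meta = {"epoch": epoch}
    if seed is not None:
        meta["seed"] = seed
    meta.update(extra_meta or {})
    write_table(out, path, meta)


def write_uptime_csv(
    uptime: Dict[int, List[Tuple[int, int]]], path, seed: Optional[int] = None,
    epoch: str = DEFAULT_EPOCH,
) -> None:
    rows = [
        {"tag_id": tag, "up_start": s, "up_end": e}
        for tag, ivs in sorted(uptime.items())
        for (s, e) in ivs
    ]
    df = pd.DataFrame(rows, columns=["tag_id", "up_start", "up_end"])
    df["up_start_iso8601"] = _to_iso(df["up_start"], epoch) if len(df) else []
    df["up_end_iso8601"] = _to_iso(df["up_end"], epoch) if len(df) else []
    meta = {"epoch": epoch}
    if seed is not None:
        meta["seed"] = seed
    write_table(df.drop(columns=["up_start", "up_end"]), path, meta)


def read_uptime_csv(path) -> Tuple[Dict[int, List[Tuple[int, int]]], dict]:
    df, meta = read_table(path)
    epoch = meta.get("epoch", DEFAULT_EPOCH)
    uptime: Dict[int, List[Tuple[int, int]]] = {}
    if len(df):
        starts = _from_iso(df["up_start_iso8601"], epoch)
        ends = _from_iso(df["up_end_iso8601"], epoch)
        for tag, s, e in zip(df["tag_id"].astype(int), starts, ends):
            uptime.setdefault(tag, []).append((int(s), int(e)))
    return uptime, meta
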