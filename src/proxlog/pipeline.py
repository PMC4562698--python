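"""Encounter-log reconciliation: merge, dyad calling, broken/staggered flags.

The raw tag logs split one social encounter into pieces in three ways: the
firmware's five-minute cap, missed pulse slots, and one-sided detection.
This module reverses what can be reversed and annotates what cannot:

1. :func:`merge_gap_logs` recombines same-pair logs separated by at most one
   pulse interval (20 s) on each logger;
2. :func:`call_dyads` matches complementary logs (A about B, B about A) whose
   closed time intervals overlap into *dyadic* records, leaving the rest as
   *single* records;
3. :func:`classify_broken` / :func:`classify_staggered` flag dyadic records
   where one side fragmented (internal gap > 21 s) or overhangs the other by
   more than 21 s at either end;
4. :func:`restrict_to_common_uptime` keeps records inside the window where
   every tag was operational, the precondition for network construction.

Zero-duration logs (one received pulse) are kept throughout: a single pulse
with high RSSI is a real close-proximity contact.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "merge_gap_logs",
    "call_dyads",
    "classify_broken",
    "classify_staggered",
    "restrict_to_common_uptime",
    "process_logs",
]

_MERGED_COLUMNS = [
    "logger_id", "partner_id", "start", "end", "duration",
    "min_rssi", "mean_rssi", "max_rssi", "n_pulses", "n_fragments", "fragments",
]


def merge_gap_logs(logs: pd.DataFrame, max_gap_s: int = 20) -> pd.DataFrame:
    """Coalesce same-pair logs on one logger separated by <= ``max_gap_s``.

    The merged log spans first start to last end; min/max RSSI are extrema,
    mean RSSI is the pulse-count-weighted mean, pulse counts add.  The
    pre-merge piece intervals are retained in a ``fragments`` column.
    Overlapping same-pair logs are rejected: the firmware cannot produce
    them, so they indicate a corrupted input.  Idempotent.
    """
    if len(logs) == 0:
        return pd.DataFrame(columns=_MERGED_COLUMNS)
    rows: List[tuple] = []
    for (logger, partner), grp in logs.groupby(["logger_id", "partner_id"], sort=True):
        grp = grp.sort_values("start", kind="mergesort")
        cur = None
        for r in grp.itertuples(index=False):
            frag = (int(r.start), int(r.end))
            if cur is None:
                cur = dict(
                    start=int(r.start), end=int(r.end), min=int(r.min_rssi),
                    max=int(r.max_rssi), total=float(r.mean_rssi) * int(r.n_pulses),
                    n=int(r.n_pulses), fragments=[frag],
                )
                continue
            gap = int(r.start) - cur["end"]
            if gap <= 0:
                raise ValueError(
                    f"overlapping logs for logger {logger} partner {partner} "
                    f"at t={r.start} (gap {gap})"
                )
            if gap <= max_gap_s:
                cur["end"] = max(cur["end"], int(r.end))
                cur["min"] = min(cur["min"], int(r.min_rssi))
                cur["max"] = max(cur["max"], int(r.max_rssi))
                cur["total"] += float(r.mean_rssi) * int(r.n_pulses)
                cur["n"] += int(r.n_pulses)
                cur["fragments"].append(frag)
            else:
                rows.append(_emit(logger, partner, cur))
                cur = dict(
                    start=int(r.start), end=int(r.end), min=int(r.min_rssi),
                    max=int(r.max_rssi), total=float(r.mean_rssi) * int(r.n_pulses),
                    n=int(r.n_pulses), fragments=[frag],
                )
        rows.append(_emit(logger, partner, cur))
    return pd.DataFrame(rows, columns=_MERGED_COLUMNS)


def _emit(logger, partner, cur) -> tuple:
    return (
        int(logger), int(partner), cur["start"], cur["end"], cur["end"] - cur["start"],
        cur["min"], cur["total"] / cur["n"], cur["max"], cur["n"],
        len(cur["fragments"]), tuple(cur["fragments"]),
    )


_RECORD_COLUMNS = [
    "pair_id", "tag_a", "tag_b", "status", "start", "end", "duration",
    "max_rssi", "min_rssi", "mean_rssi",
    "start_a", "end_a", "min_rssi_a", "mean_rssi_a", "max_rssi_a", "n_pulses_a",
    "n_fragments_a", "max_gap_a", "intervals_a",
    "start_b", "end_b", "min_rssi_b", "mean_rssi_b", "max_rssi_b", "n_pulses_b",
    "n_fragments_b", "max_gap_b", "intervals_b",
]


def _side_summary(side: List[tuple]) -> dict:
    """Summarize one side's merged logs within a record."""
    side = sorted(side, key=lambda r: r[0])
    starts = [r[0] for r in side]
    ends = [r[1] for r in side]
    n_pulses = sum(r[4] for r in side)
    gaps = [s2 - e1 for e1, s2 in zip(ends[:-1], starts[1:])]
    return dict(
        start=starts[0], end=max(ends),
        min_rssi=min(r[2] for r in side),
        max_rssi=max(r[3] for r in side),
        mean_rssi=sum(r[5] * r[4] for r in side) / n_pulses,
        n_pulses=n_pulses, n_fragments=len(side),
        max_gap=max(gaps) if gaps else 0,
        intervals=tuple(zip(starts, ends)),
        gap_windows=tuple((e1, s2) for e1, s2 in zip(ends[:-1], starts[1:])),
    )


def call_dyads(merged: pd.DataFrame) -> pd.DataFrame:
    """Match complementary merged logs into dyadic/single encounter records.

    For each unordered tag pair, logs from both sides are swept in start
    order; logs whose closed intervals overlap (touching endpoints count)
    accrete into one record, so two disjoint B-side logs bridged by one
    A-side log become a single dyadic record with a fragmented B side --
    exactly the broken-log topology.  Records with both sides present are
    ``dyadic``; the rest are ``single``.
    """
    records: List[dict] = []
    if len(merged) == 0:
        return pd.DataFrame(columns=_RECORD_COLUMNS + ["gaps_a", "gaps_b"])
    df = merged.copy()
    lo = np.minimum(df["logger_id"], df["partner_id"])
    hi = np.maximum(df["logger_id"], df["partner_id"])
    df["_a"], df["_b"] = lo, hi

    for (a, b), grp in df.groupby(["_a", "_b"], sort=True):
        items = sorted(
            (
                (int(r.start), int(r.end), int(r.min_rssi), int(r.max_rssi),
                 int(r.n_pulses), float(r.mean_rssi), int(r.logger_id))
                for r in grp.itertuples(index=False)
            ),
            key=lambda x: (x[0], x[1]),
        )
        comp: List[tuple] = []
        comp_end = None
        for it in items:
            if comp and it[0] > comp_end:
                records.append(_make_record(int(a), int(b), comp))
                comp = []
                comp_end = None
            comp.append(it)
            comp_end = it[1] if comp_end is None else max(comp_end, it[1])
        if comp:
            records.append(_make_record(int(a), int(b), comp))

    rec = pd.DataFrame(records)
    rec = rec.sort_values(["start", "pair_id"], kind="mergesort").reset_index(drop=True)
    return rec.reindex(columns=_RECORD_COLUMNS + ["gaps_a", "gaps_b"])


def _make_record(a: int, b: int, comp: List[tuple]) -> dict:
    side_a = [it for it in comp if it[6] == a]
    side_b = [it for it in comp if it[6] == b]
    rec: dict = {"pair_id": f"{a}-{b}", "tag_a": a, "tag_b": b}
    rec["status"] = "dyadic" if (side_a and side_b) else "single"
    for label, side in (("a", side_a), ("b", side_b)):
        if side:
            s = _side_summary(side)
            rec[f"start_{label}"] = s["start"]
            rec[f"end_{label}"] = s["end"]
            rec[f"min_rssi_{label}"] = s["min_rssi"]
            rec[f"mean_rssi_{label}"] = s["mean_rssi"]
            rec[f"max_rssi_{label}"] = s["max_rssi"]
            rec[f"n_pulses_{label}"] = s["n_pulses"]
            rec[f"n_fragments_{label}"] = s["n_fragments"]
            rec[f"max_gap_{label}"] = s["max_gap"]
            rec[f"intervals_{label}"] = s["intervals"]
            rec[f"gaps_{label}"] = s["gap_windows"]
        else:
            rec[f"start_{label}"] = np.nan
            rec[f"end_{label}"] = np.nan
            rec[f"min_rssi_{label}"] = np.nan
            rec[f"mean_rssi_{label}"] = np.nan
            rec[f"max_rssi_{label}"] = np.nan
            rec[f"n_pulses_{label}"] = 0
            rec[f"n_fragments_{label}"] = 0
            rec[f"max_gap_{label}"] = 0
            rec[f"intervals_{label}"] = ()
            rec[f"gaps_{label}"] = ()
    starts = [x for x in (rec["start_a"], rec["start_b"]) if not pd.isna(x)]
    ends = [x for x in (rec["end_a"], rec["end_b"]) if not pd.isna(x)]
    rec["start"] = int(min(starts))
    rec["end"] = int(max(ends))
    rec["duration"] = rec["end"] - rec["start"]
    rec["max_rssi"] = np.nanmax([rec["max_rssi_a"], rec["max_rssi_b"]])
    rec["min_rssi"] = np.nanmin([rec["min_rssi_a"], rec["min_rssi_b"]])
    tot = rec["n_pulses_a"] + rec["n_pulses_b"]
    rec["mean_rssi"] = (
        np.nansum([
            (rec["mean_rssi_a"] if rec["n_pulses_a"] else 0.0) * rec["n_pulses_a"],
            (rec["mean_rssi_b"] if rec["n_pulses_b"] else 0.0) * rec["n_pulses_b"],
        ]) / tot
    )
    return rec


def classify_broken(records: pd.DataFrame, gap_s: int = 21) -> pd.DataFrame:
    """Flag dyadic records where one side logged continuously while the
    other split into >= 2 logs with an internal gap > ``gap_s`` that the
    continuous side covers."""
    rec = records.copy()
    flags = []
    for r in rec.itertuples(index=False):
        flags.append(_is_broken(r, gap_s))
    rec["broken"] = flags
    return rec


def _is_broken(r, gap_s: int) -> bool:
    if r.status != "dyadic":
        return False
    for cont, frag_n, frag_gaps, cont_iv in (
        ("a", r.n_fragments_b, r.gaps_b, (r.start_a, r.end_a)),
        ("b", r.n_fragments_a, r.gaps_a, (r.start_b, r.end_b)),
    ):
        cont_n = r.n_fragments_a if cont == "a" else r.n_fragments_b
        if cont_n != 1 or frag_n < 2:
            continue
        big = [g for g in frag_gaps if (g[1] - g[0]) > gap_s]
        covered = [g for g in big if cont_iv[0] <= g[0] and g[1] <= cont_iv[1]]
        if covered:
            return True
    return False


def classify_staggered(records: pd.DataFrame, overhang_s: int = 21) -> pd.DataFrame:
    """Flag dyadic records where one side overhangs the other by more than
    ``overhang_s`` at the head and/or tail; overhangs reported per end."""
    rec = records.copy()
    dy = rec["status"] == "dyadic"
    head = (rec["start_a"] - rec["start_b"]).abs()
    tail = (rec["end_a"] - rec["end_b"]).abs()
    rec["overhang_head"] = np.where(dy, head, np.nan)
    rec["overhang_tail"] = np.where(dy, tail, np.nan)
    rec["staggered"] = dy & ((head > overhang_s) | (tail > overhang_s))
    return rec


def _intersect_many(interval_lists: Iterable[Sequence[Tuple[int, int]]]):
    """Intersection of unions of intervals, one union per tag."""
    common: List[Tuple[int, int]] | None = None
    for ivs in interval_lists:
        ivs = sorted((int(s), int(e)) for s, e in ivs)
        if common is None:
            common = list(ivs)
            continue
        nxt = []
        for (s1, e1) in common:
            for (s2, e2) in ivs:
                s, e = max(s1, s2), min(e1, e2)
                if s < e:
                    nxt.append((s, e))
        common = nxt
    return common or []


def restrict_to_common_uptime(
    records: pd.DataFrame, uptime: Dict[int, Sequence[Tuple[int, int]]]
) -> pd.DataFrame:
    """Keep records whose full window lies inside every tag's uptime.

    A record straddling any tag's downtime boundary is removed (strict
    containment), matching the practice of analysing only the period when
    all tags were functioning.
    """
    common = _intersect_many(uptime.values())
    if not common:
        warnings.warn("common uptime is empty; all records removed")
        return records.iloc[0:0].copy()
    keep = [
        any(s <= r.start and r.end <= e for (s, e) in common)
        for r in records.itertuples(index=False)
    ]
    return records.loc[keep].reset_index(drop=True)


def process_logs(
    logs: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    uptime: Dict[int, Sequence[Tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Full reconciliation chain: merge -> dyads -> broken/staggered [-> uptime]."""
    cfg = cfg or PipelineConfig()
    merged = merge_gap_logs(logs, cfg.merge_gap_s)
    rec = call_dyads(merged)
    rec = classify_broken(rec, cfg.break_gap_s)
    rec = classify_staggered(rec, cfg.stagger_s)
    if uptime is not None:
        rec = restrict_to_common_uptime(rec, uptime)
    return rec
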