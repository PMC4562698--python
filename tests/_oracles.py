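"""Brute-force oracles for the log-reconciliation pipeline.

Deliberately naive implementations (fix-point pairwise merging, boolean
transitive closure for dyad components) kept independent of the production
sweep-based code paths.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd


def oracle_merge(frags: List[Tuple[int, int]], max_gap: int = 20) -> List[Tuple[int, int]]:
    """Fix-point pairwise merging of one logger's same-pair intervals."""
    frags = sorted(frags)
    for prev, nxt in zip(frags, frags[1:]):
        if nxt[0] - prev[1] <= 0:
            raise ValueError("overlapping fragments")
    changed = True
    frags = [list(f) for f in frags]
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(frags)), 2):
            a, b = frags[i], frags[j]
            lo, hi = (a, b) if a[0] <= b[0] else (b, a)
            if 0 < hi[0] - lo[1] <= max_gap:
                lo[1] = max(lo[1], hi[1])
                frags.pop(frags.index(hi))
                changed = True
                break
    return sorted((f[0], f[1]) for f in frags)


def oracle_records(
    side_a: List[Tuple[int, int]],
    side_b: List[Tuple[int, int]],
    merge_gap: int = 20,
    break_gap: int = 21,
    stagger: int = 21,
) -> List[Dict]:
    """Full reconciliation of one tag pair via transitive-closure matching."""
    a = [("a", s, e) for (s, e) in oracle_merge(side_a, merge_gap)]
    b = [("b", s, e) for (s, e) in oracle_merge(side_b, merge_gap)]
    items = a + b
    n = len(items)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        adj[i, i] = True
        for j in range(n):
            # closed intervals overlap iff neither is strictly after the other
            if items[i][1] <= items[j][2] and items[j][1] <= items[i][2]:
                adj[i, j] = True
    # boolean transitive closure
    for _ in range(n):
        adj = adj | (adj @ adj)
    seen = set()
    records = []
    for i in range(n):
        if i in seen:
            continue
        comp = [j for j in range(n) if adj[i, j]]
        seen.update(comp)
        sa = sorted((items[j][1], items[j][2]) for j in comp if items[j][0] == "a")
        sb = sorted((items[j][1], items[j][2]) for j in comp if items[j][0] == "b")
        rec = {
            "status": "dyadic" if (sa and sb) else "single",
            "n_fragments_a": len(sa),
            "n_fragments_b": len(sb),
            "start": min(x[0] for x in sa + sb),
            "end": max(x[1] for x in sa + sb),
        }
        rec["broken"] = _oracle_broken(sa, sb, break_gap)
        if sa and sb:
            head = abs(sa[0][0] - sb[0][0])
            tail = abs(sa[-1][1] - sb[-1][1])
            rec["staggered"] = head > stagger or tail > stagger
        else:
            rec["staggered"] = False
        records.append(rec)
    return sorted(records, key=lambda r: (r["start"], r["end"]))


def _oracle_broken(sa, sb, break_gap) -> bool:
    if not (sa and sb):
        return False
    for cont, frag in ((sa, sb), (sb, sa)):
        if len(cont) != 1 or len(frag) < 2:
            continue
        (cs, ce) = cont[0]
        for (_, e1), (s2, _) in zip(frag[:-1], frag[1:]):
            if s2 - e1 > break_gap and cs <= e1 and s2 <= ce:
                return True
    return False


def frames_from_fragments(side_a, side_b, tag_a=1, tag_b=2) -> pd.DataFrame:
    """Raw-log DataFrame for a single tag pair from interval lists."""
    rows = []
    for (s, e) in side_a:
        rows.append((tag_a, tag_b, s, e, 1, 2.0, 3, (e - s) // 20 + 1))
    for (s, e) in side_b:
        rows.append((tag_b, tag_a, s, e, 1, 2.0, 3, (e - s) // 20 + 1))
    return pd.DataFrame(
        rows,
        columns=["logger_id", "partner_id", "start", "end",
                 "min_rssi", "mean_rssi", "max_rssi", "n_pulses"],
    )
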