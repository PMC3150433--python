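"""Shared gap-run detection and the high-quality indel screen.

Only '-' participates: '?' encodes missing data (unsequenced or
removed sequence), not alignment-derived deletions. A candidate event is
a maximal gap run of one taxon within one gene fragment; runs with
identical column bounds across taxa merge into a single event. The
"high quality" filter keeps events shared by at least ``min_taxa`` taxa
whose bounds are not straddled by a partially overlapping gap run in any
other taxon (no staggered ends, identical lengths); flanking sequence
identity is not required.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import pandas as pd

from degenkit.errors import CharsetError
from degenkit.matrix_io import NucMatrix

_GAP_RUN = re.compile(r"-+")


@dataclass(frozen=True)
class IndelEvent:
    """A shared gap run: fragment, 0-based half-open bounds, bearer taxa."""

    fragment: str
    start: int
    end: int
    taxa: frozenset[str]
    quality: str = "candidate"

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "IndelEvent") -> bool:
        return (
            self.fragment == other.fragment
            and self.start < other.end
            and other.start < self.end
        )


def _fragment_spans(m: NucMatrix) -> list[tuple[str, tuple[int, ...]]]:
    if m.fragments:
        spans = []
        for name in m.fragments:
            cols = m.charsets[name]
            if any(b - a != 1 for a, b in zip(cols, cols[1:])):
                raise CharsetError(f"fragment {name!r} is not contiguous")
            spans.append((name, cols))
        return spans
    return [("matrix", tuple(range(m.n_cols)))]


def gap_events(m: NucMatrix) -> list[IndelEvent]:
    """All candidate indel events, merged on identical (fragment, bounds).

    Events never span fragment boundaries. Bounds are global matrix
    columns (fragments must be contiguous column blocks).
    """
    merged: dict[tuple[str, int, int], set[str]] = {}
    for name, cols in _fragment_spans(m):
        if not cols:
            continue
        off = cols[0]
        for taxon, row in zip(m.taxa, m.rows):
            seg = row[cols[0] : cols[-1] + 1]
            for hit in _GAP_RUN.finditer(seg):
                key = (name, off + hit.start(), off + hit.end())
                merged.setdefault(key, set()).add(taxon)
    return [
        IndelEvent(f, s, e, frozenset(taxa))
        for (f, s, e), taxa in sorted(merged.items())
    ]


def quality_filter(events: list[IndelEvent], min_taxa: int = 2) -> list[IndelEvent]:
    """Keep shared, non-staggered events; idempotent.

    An event is rejected as staggered when any other event in the same
    fragment partially overlaps it (overlapping interval, different
    bounds) — singleton runs count as staggering evidence too.
    """
    survivors = []
    for ev in events:
        if len(ev.taxa) < min_taxa:
            continue
        staggered = any(
            ev.overlaps(other) and (ev.start, ev.end) != (other.start, other.end)
            for other in events
            if other is not ev
        )
        if not staggered:
            survivors.append(replace(ev, quality="high"))
    return survivors


def annotate_events(events: list[IndelEvent], min_taxa: int = 2) -> list[IndelEvent]:
    """Like :func:`quality_filter` but returns every event with a verdict."""
    out = []
    for ev in events:
        if len(ev.taxa) < min_taxa:
            out.append(replace(ev, quality="rejected(few_taxa)"))
            continue
        staggered = any(
            ev.overlaps(other) and (ev.start, ev.end) != (other.start, other.end)
            for other in events
            if other is not ev
        )
        out.append(replace(ev, quality="rejected(staggered)" if staggered else "high"))
    return out


def indel_report(events: list[IndelEvent]) -> pd.DataFrame:
    """TSV-ready table: fragment, 1-based inclusive bounds, length, taxa."""
    return pd.DataFrame(
        [
            {
                "fragment": ev.fragment,
                "first_col": ev.start + 1,
                "last_col": ev.end,
                "length": ev.length,
                "n_taxa": len(ev.taxa),
                "taxa": ",".join(sorted(ev.taxa)),
                "quality": ev.quality,
            }
            for ev in events
        ]
    )
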