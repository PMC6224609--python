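"""Intron splicing-order inference from paired-end read evidence.

For an internal exon, a read pair where one mate spans the spliced upstream
(C1-A) junction while the other lies within the still-present downstream
intron is evidence that the upstream intron was spliced first
(co-transcriptional order); the reciprocal pattern is evidence for the
downstream intron first.  Counts are summarised per exon and exons with
fewer than 10 informative pairs are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .alignio import ReadAlignment
from .annotation import InternalExonTrio

UPSTREAM_FIRST = "upstream_first"
DOWNSTREAM_FIRST = "downstream_first"
UNINFORMATIVE = "uninformative"


def _spans(mate: ReadAlignment, intron: tuple[int, int]) -> bool:
    """The alignment contains a gap exactly matching the intron."""
    return intron in mate.gaps


def _within_intron(mate: ReadAlignment, intron: tuple[int, int],
                   other_intron: tuple[int, int]) -> bool:
    """Overlaps the intron by >= 1 nt without spanning either junction.

    Conservative rule: a mate carrying any splice gap is never counted as
    intronic evidence; partially exonic but non-junctional (ungapped) overlap
    qualifies.
    """
    if mate.gapped:
        return False
    s, e = intron
    return any(bs < e and be > s for bs, be in mate.blocks)


def classify_pair(mate1: ReadAlignment, mate2: Optional[ReadAlignment],
                  trio: InternalExonTrio) -> str:
    """upstream_first / downstream_first / uninformative for one read pair."""
    if mate2 is None:
        return UNINFORMATIVE
    for m in (mate1, mate2):
        if m.chrom != trio.chrom or m.strand != trio.strand:
            return UNINFORMATIVE
    up, down = trio.upstream_intron, trio.downstream_intron
    up_first = ((_spans(mate1, up) and _within_intron(mate2, down, up))
                or (_spans(mate2, up) and _within_intron(mate1, down, up)))
    down_first = ((_spans(mate1, down) and _within_intron(mate2, up, down))
                  or (_spans(mate2, down) and _within_intron(mate1, up, down)))
    if up_first and not down_first:
        return UPSTREAM_FIRST
    if down_first and not up_first:
        return DOWNSTREAM_FIRST
    return UNINFORMATIVE


ORDER_COLUMNS = ["exon_id", "n_upstream_first", "n_downstream_first",
                 "total", "fraction_upstream_first"]


def summarize_order(classifications: Iterable[tuple[str, str]],
                    min_total: int = 10) -> pd.DataFrame:
    """Aggregate (exon_id, classification) pairs into per-exon order evidence.

    Exons whose informative-pair total is below ``min_total`` are dropped.
    """
    counts: dict[str, list[int]] = {}
    for exon_id, cls in classifications:
        rec = counts.setdefault(exon_id, [0, 0])
        if cls == UPSTREAM_FIRST:
            rec[0] += 1
        elif cls == DOWNSTREAM_FIRST:
            rec[1] += 1
    rows = []
    for exon_id in sorted(counts):
        n_up, n_down = counts[exon_id]
        total = n_up + n_down
        if total < min_total:
            continue
        rows.append((exon_id, n_up, n_down, total, n_up / total))
    return pd.DataFrame(rows, columns=ORDER_COLUMNS)


def order_evidence(pairs, trios: Sequence[InternalExonTrio],
                   min_total: int = 10) -> pd.DataFrame:
    """Classify every pair against every trio on its chromosome and summarise.

    ``pairs``: iterable of (mate1, mate2).  Trio lookup is by chromosome, so
    loci are expected to be non-overlapping (one gene per region).
    """
    by_chrom: dict[str, list[InternalExonTrio]] = {}
    for t in trios:
        by_chrom.setdefault(t.chrom, []).append(t)
    cls = []
    for m1, m2 in pairs:
        for t in by_chrom.get(m1.chrom, ()):
            c = classify_pair(m1, m2, t)
            if c != UNINFORMATIVE:
                cls.append((t.exon_id, c))
    return summarize_order(cls, min_total=min_total)
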