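"""Junction sequence libraries and Percent Usage of RS-5ss (PURS).

For each EJC-sensitive exon a small library of junction sequences is built:
the skip junction C1-C2, the two flanking canonical junctions C1-A and A-C2,
and one RS event junction per candidate donor offset k (0..15).  Using the
donor at offset k in the second splicing step joins C1 plus the first k nt of
A (a k-nt cryptic microexon; k = 0 is full RS-exon skipping, whose junction
sequence coincides with C1-C2) to C2.

Read counts on each junction are corrected by the number of read placements
that cross the junction with the required overhang on both sides, and

    PURS = 100 * RS / ((C1A + AC2) / 2)

estimates usage of the RS/internal donor relative to the canonical one.
dPURS = PURS_KD - PURS_control; positive values mean increased RS-exon
skipping or increased cryptic microexon inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import InternalExonTrio
from .scoring import MicroexonCandidate

DEFAULT_READ_LEN = 50
DEFAULT_MIN_OVERHANG = 8


def mappable_positions(read_len: int, min_overhang: int,
                       left_flank: int, right_flank: int) -> int:
    """Number of read start positions crossing the junction with at least
    ``min_overhang`` nt mapped on each side.

    With ample flanks this is read_len - 2*min_overhang + 1; shorter flanks
    reduce it, down to 0 when no placement fits.
    """
    if read_len <= 2 * min_overhang:
        raise ValueError("read_len must exceed twice the overhang")
    # positions p measured from the start of the left flank; junction at L
    lo = max(0, left_flank + min_overhang - read_len)
    hi = min(left_flank - min_overhang, left_flank + right_flank - read_len)
    return max(0, hi - lo + 1)


def corrected_count(raw_count: float, positions: int) -> Optional[float]:
    """Raw count divided by mappable positions; None when nothing is mappable."""
    if positions < 0:
        raise ValueError("positions must be >= 0")
    if positions == 0:
        return None
    return raw_count / positions


@dataclass(frozen=True)
class JunctionLibraryEntry:
    exon_id: str
    junction_type: str            # C1C2 | C1A | AC2 | RS_EVENT
    sequence: str
    left_flank: int
    right_flank: int
    offset: Optional[int] = None  # RS_EVENT only: 0..15

    @property
    def entry_id(self) -> str:
        if self.junction_type == "RS_EVENT":
            return f"{self.exon_id}|RS{self.offset}"
        return f"{self.exon_id}|{self.junction_type}"

    def mappable(self, read_len: int = DEFAULT_READ_LEN,
                 min_overhang: int = DEFAULT_MIN_OVERHANG) -> int:
        return mappable_positions(read_len, min_overhang,
                                  self.left_flank, self.right_flank)


def _exon_seq(genome, trio: InternalExonTrio, which: str) -> str:
    starts = {"C1": (trio.c1_start, trio.c1_end), "A": (trio.a_start, trio.a_end),
              "C2": (trio.c2_start, trio.c2_end)}
    s, e = starts[which]
    return genome.fetch(trio.chrom, s - 1, e, trio.strand)


def build_junction_library(trio: InternalExonTrio,
                           candidates: Sequence[MicroexonCandidate],
                           genome, flank_len: int = DEFAULT_READ_LEN - 1
                           ) -> list[JunctionLibraryEntry]:
    """One C1C2, C1A and AC2 entry for the exon plus one RS_EVENT entry per
    candidate offset.

    Flanks are taken from exonic sequence (plus the microexon nucleotides on
    the left side of RS events) and truncated where an exon is shorter than
    ``flank_len``; mappable positions are recomputed from the realised flanks.
    """
    c1 = _exon_seq(genome, trio, "C1")
    a = _exon_seq(genome, trio, "A")
    c2 = _exon_seq(genome, trio, "C2")
    eid = trio.exon_id

    def entry(jt, left_seq, right_seq, offset=None):
        left = left_seq[-flank_len:] if flank_len < len(left_seq) else left_seq
        right = right_seq[:flank_len]
        return JunctionLibraryEntry(eid, jt, left + right, len(left), len(right),
                                    offset)

    out = [
        entry("C1C2", c1, c2),
        entry("C1A", c1, a),
        entry("AC2", a, c2),
    ]
    for cand in sorted(candidates, key=lambda x: x.offset):
        k = cand.offset
        if not 0 <= k <= 15:
            raise ValueError(f"offset {k} outside 0..15")
        out.append(entry("RS_EVENT", c1 + a[:k], c2, offset=k))
    return out


# FASTA round trip with structured headers ----------------------------------

def write_library_fasta(entries: Iterable[JunctionLibraryEntry], path: str) -> None:
    with open(path, "w") as fh:
        for e in entries:
            off = "" if e.offset is None else f" offset={e.offset}"
            fh.write(f">{e.entry_id} type={e.junction_type} "
                     f"left={e.left_flank} right={e.right_flank}{off}\n")
            fh.write(e.sequence + "\n")


def read_library_fasta(path: str) -> list[JunctionLibraryEntry]:
    entries = []
    header, seq = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    entries.append(_entry_from_header(header, "".join(seq)))
                header, seq = line[1:], []
            else:
                seq.append(line)
    if header is not None:
        entries.append(_entry_from_header(header, "".join(seq)))
    return entries


def _entry_from_header(header: str, sequence: str) -> JunctionLibraryEntry:
    fields = header.split()
    entry_id = fields[0]
    kv = dict(f.split("=", 1) for f in fields[1:])
    exon_id = entry_id.rsplit("|", 1)[0]
    return JunctionLibraryEntry(
        exon_id=exon_id, junction_type=kv["type"], sequence=sequence,
        left_flank=int(kv["left"]), right_flank=int(kv["right"]),
        offset=int(kv["offset"]) if "offset" in kv else None)


# ---------------------------------------------------------------------------
# PURS


def compute_purs(rs_corr: float, c1a_corr: float, ac2_corr: float
                 ) -> Optional[float]:
    """100 * RS over the mean of the two flanking-junction corrected counts;
    None (undefined) when the denominator is zero."""
    denom = (c1a_corr + ac2_corr) / 2.0
    if denom == 0:
        return None
    return 100.0 * rs_corr / denom

PURS_COLUMNS = ["event_id", "exon_id", "offset", "condition",
                "rs_raw", "rs_corr", "c1a_corr", "ac2_corr", "purs"]


def purs_table(library: Sequence[JunctionLibraryEntry], counts: pd.DataFrame,
               read_len: int = DEFAULT_READ_LEN,
               min_overhang: int = DEFAULT_MIN_OVERHANG) -> pd.DataFrame:
    """PURS per RS event and condition.

    ``counts``: columns (entry_id, condition, count) of raw junction-library
    read counts.  Events whose RS junction has zero mappable positions or an
    all-zero denominator are dropped (purs undefined).
    """
    by_id = {e.entry_id: e for e in library}
    lut = {(r.entry_id, r.condition): r.count for r in counts.itertuples()}
    conditions = sorted(counts["condition"].unique())

    def corr(entry_id, condition):
        e = by_id[entry_id]
        return corrected_count(lut.get((entry_id, condition), 0),
                               e.mappable(read_len, min_overhang))

    rows = []
    for e in library:
        if e.junction_type != "RS_EVENT":
            continue
        for cond in conditions:
            rs_c = corr(e.entry_id, cond)
            c1a = corr(f"{e.exon_id}|C1A", cond)
            ac2 = corr(f"{e.exon_id}|AC2", cond)
            if rs_c is None or c1a is None or ac2 is None:
                continue
            p = compute_purs(rs_c, c1a, ac2)
            if p is None:
                continue
            rows.append((e.entry_id, e.exon_id, e.offset, cond,
                         lut.get((e.entry_id, cond), 0), rs_c, c1a, ac2, p))
    return pd.DataFrame(rows, columns=PURS_COLUMNS)


DPURS_COLUMNS = ["event_id", "exon_id", "offset", "purs_kd", "purs_control",
                 "dpurs", "read_support"]


def dpurs_table(purs_frame: pd.DataFrame, kd_condition: str,
                control_condition: str) -> pd.DataFrame:
    """dPURS = PURS_KD - PURS_control per event.

    ``read_support`` is the raw (uncorrected) read count on the RS junction,
    summed over the two conditions — the stricter support definition.
    Events without a defined PURS in both conditions are skipped.
    """
    piv = purs_frame.pivot_table(index=["event_id", "exon_id", "offset"],
                                 columns="condition", aggfunc="first")
    rows = []
    for (eid, exid, off) in piv.index:
        sub = piv.loc[(eid, exid, off)]
        try:
            pk = sub[("purs", kd_condition)]
            pc = sub[("purs", control_condition)]
        except KeyError:
            continue
        if np.isnan(pk) or np.isnan(pc):
            continue
        support = np.nansum([sub.get(("rs_raw", kd_condition), 0),
                             sub.get(("rs_raw", control_condition), 0)])
        rows.append((eid, exid, int(off), float(pk), float(pc),
                     float(pk - pc), int(support)))
    return pd.DataFrame(rows, columns=DPURS_COLUMNS)


def call_events(dpurs_frame: pd.DataFrame, scores: dict,
                min_reads: int = 10, min_score: float = 5.52,
                min_dpurs: float = 10.0) -> pd.DataFrame:
    """Flag events with sufficient read support, donor strength and dPURS.

    ``scores``: event_id -> donor (RS-5ss or internal 5ss) score.  All three
    rules are inclusive ("at least"): support >= min_reads, score >=
    min_score, dpurs >= min_dpurs.
    """
    out = dpurs_frame.copy()
    out["score"] = out["event_id"].map(scores)
    out["called"] = ((out["read_support"] >= min_reads)
                     & (out["score"] >= min_score)
                     & (out["dpurs"] >= min_dpurs))
    return out
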