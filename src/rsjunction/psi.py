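"""Junction-read ingestion and percent-spliced-in (PSI) quantification.

PSI per exon and sample is computed from the three trio junctions with the
weighted formula

    PSI = 50*(up + down) / (skip + 50*(up + down))

stored on the proportion scale [0, 1].  dPSI for a knockdown sample is its
PSI minus the mean PSI of control samples; negative dPSI means more exon
skipping upon knockdown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import InternalExonTrio


class SjParseError(ValueError):
    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


_STAR_STRAND = {"0": ".", "1": "+", "2": "-"}


@dataclass
class JunctionCounts:
    """Uniquely-mapped junction read counts for one sample.

    Keys are ``(chrom, strand, intron_start0, intron_end0)`` with the intron
    in 0-based half-open coordinates (STAR's SJ.out.tab is 1-based closed on
    the intron; the reader converts).
    """

    sample_id: str
    counts: dict = field(default_factory=dict)

    def get(self, key, default=0):
        return self.counts.get(key, default)

    def add(self, key, n: int) -> None:
        if n < 0:
            raise ValueError("junction counts must be >= 0")
        self.counts[key] = self.counts.get(key, 0) + n


def read_sj_table(path: str, sample_id: Optional[str] = None,
                  dialect: str = "star") -> JunctionCounts:
    """Read a STAR ``SJ.out.tab`` file (9 tab-separated columns).

    Columns: chrom, intron first base (1-based), intron last base (1-based),
    strand code (0 undefined / 1 '+' / 2 '-'), motif, annotated flag,
    unique-read count, multi-read count, max overhang.  Only uniquely-mapped
    counts are retained.
    """
    if dialect != "star":
        raise ValueError(f"unknown SJ dialect {dialect!r}")
    jc = JunctionCounts(sample_id or str(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise SjParseError(lineno, f"expected 9 columns, got {len(parts)}")
            try:
                chrom = parts[0]
                first, last = int(parts[1]), int(parts[2])
                strand = _STAR_STRAND[parts[3]]
                unique = int(parts[6])
            except (ValueError, KeyError) as exc:
                raise SjParseError(lineno, str(exc)) from exc
            if unique < 0 or first > last:
                raise SjParseError(lineno, "negative count or inverted intron")
            jc.add((chrom, strand, first - 1, last), unique)
    return jc


def collate(tables: Sequence[JunctionCounts], sample_id: str = "collated"
            ) -> JunctionCounts:
    """Sum junction counts across files (collation within a study/sample)."""
    out = JunctionCounts(sample_id)
    for t in tables:
        for k, n in t.counts.items():
            out.add(k, n)
    return out


def write_sj_table(jc: JunctionCounts, path: str) -> None:
    """Write counts in the STAR SJ.out.tab dialect (motif/annotated zeroed)."""
    code = {".": "0", "+": "1", "-": "2"}
    with open(path, "w") as fh:
        for (chrom, strand, s0, e0), n in sorted(jc.counts.items()):
            fh.write("\t".join([chrom, str(s0 + 1), str(e0), code[strand],
                                "0", "0", str(n), "0", "50"]) + "\n")


# ---------------------------------------------------------------------------
# PSI


def compute_psi(up_count: int, down_count: int, skip_count: int) -> Optional[float]:
    """The weighted inclusion proportion; None when all three counts are zero.

    Exact evaluation of 50*(up+down) / (skip + 50*(up+down)).
    """
    for c in (up_count, down_count, skip_count):
        if c < 0:
            raise ValueError("junction counts must be >= 0")
    inclusion = up_count + down_count
    if inclusion == 0 and skip_count == 0:
        return None
    return 50.0 * inclusion / (skip_count + 50.0 * inclusion)


PSI_COLUMNS = ["exon_id", "sample_id", "up_count", "down_count", "skip_count", "psi"]


def psi_table(trios: Sequence[InternalExonTrio],
              samples: Sequence[JunctionCounts]) -> pd.DataFrame:
    """Per-exon, per-sample junction counts and PSI (one row per pair).

    Rows where all three junction counts are zero carry NaN psi (exon not
    expressed in that sample).
    """
    rows = []
    for t in trios:
        c, s = t.chrom, t.strand
        ku, kd, ks = ((c, s) + t.upstream_intron, (c, s) + t.downstream_intron,
                      (c, s) + t.skip_intron)
        for jc in samples:
            up, down, skip = jc.get(ku), jc.get(kd), jc.get(ks)
            psi = compute_psi(up, down, skip)
            rows.append((t.exon_id, jc.sample_id, up, down, skip,
                         np.nan if psi is None else psi))
    return pd.DataFrame(rows, columns=PSI_COLUMNS)


def filter_exons(psi_frame: pd.DataFrame, min_total_junction_reads: int
                 ) -> tuple[pd.DataFrame, dict]:
    """Drop exons whose total junction reads across samples fall below the
    study threshold (inclusive: a total equal to the threshold is retained).

    Returns the retained frame and a report of dropped exon counts.
    """
    totals = (psi_frame[["up_count", "down_count", "skip_count"]].sum(axis=1)
              .groupby(psi_frame["exon_id"]).sum())
    keep = set(totals.index[totals >= min_total_junction_reads])
    out = psi_frame[psi_frame["exon_id"].isin(keep)].reset_index(drop=True)
    report = {"n_exons": int(totals.size), "n_retained": len(keep),
              "n_dropped": int(totals.size) - len(keep),
              "min_total_junction_reads": min_total_junction_reads}
    return out, report


DPSI_COLUMNS = ["exon_id", "kd_sample", "dpsi", "control_mean_psi", "n_control"]


def delta_psi(psi_kd: Optional[float], control_psis: Iterable[Optional[float]]
              ) -> Optional[tuple[float, float, int]]:
    """dPSI for one exon: PSI_KD minus the mean of defined control PSIs.

    Returns (dpsi, control_mean, n_control) or None when the KD value or all
    controls are undefined.
    """
    if psi_kd is None or (isinstance(psi_kd, float) and np.isnan(psi_kd)):
        return None
    ctrl = [p for p in control_psis
            if p is not None and not (isinstance(p, float) and np.isnan(p))]
    if not ctrl:
        return None
    mean = float(np.mean(ctrl))
    return float(psi_kd) - mean, mean, len(ctrl)


def delta_psi_table(psi_frame: pd.DataFrame, kd_sample: str,
                    control_samples: Sequence[str]) -> pd.DataFrame:
    """dPSI per exon for one knockdown sample against a set of controls.

    Exons undefined in the KD sample or in every control are skipped.
    """
    pivot = psi_frame.pivot_table(index="exon_id", columns="sample_id",
                                  values="psi", aggfunc="first")
    missing = [s for s in [kd_sample, *control_samples] if s not in pivot.columns]
    if missing:
        raise KeyError(f"samples absent from PSI table: {missing}")
    rows = []
    for eid, row in pivot.iterrows():
        res = delta_psi(row[kd_sample], [row[c] for c in control_samples])
        if res is None:
            continue
        dpsi, mean, n = res
        rows.append((eid, kd_sample, dpsi, mean, n))
    return pd.DataFrame(rows, columns=DPSI_COLUMNS)
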