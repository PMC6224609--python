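"""iCLIP crosslink extraction and junction-anchored crosslink profiles.

iCLIP cDNAs truncate at the protein-RNA crosslink site, so the nucleotide
immediately 5' of the read start marks the crosslink.  Ungapped reads profile
exon-intron junctions (canonical donors); gapped (splice-junction-spanning)
reads profile exon-exon junctions, where spliceosome assembly on a
reconstituted RS-5ss leaves a characteristic peak 12-14 nt upstream.

Profiles count crosslinks by distance to the junction within a window,
normalised by the number of evaluated junctions in the group and the total
number of crosslinks in the library, so they are comparable across groups
and libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alignio import ReadAlignment
from .smoothing import loess

CROSSLINK_COLUMNS = ["sample_id", "chrom", "strand", "pos", "gapped"]

DEFAULT_WINDOW = (-50, 0)
DEFAULT_PEAK_WINDOW = (-14, -12)


def extract_crosslinks(alignments: Iterable[ReadAlignment], sample_id: str,
                       offset: int = 1, strict: bool = False) -> pd.DataFrame:
    """Crosslink positions from alignments, PCR duplicates collapsed.

    The UMI is the final colon-separated field of the read name; reads with
    the same UMI mapping to the same position are one cDNA.  Missing UMIs are
    kept with a warning (or rejected in ``strict`` mode).  The crosslink is
    placed ``offset`` nt upstream of the read start (the truncation
    convention; 0 reproduces the read start itself).
    """
    import logging

    rows = []
    seen: set[tuple] = set()
    for a in alignments:
        name = a.name
        umi = name.rsplit(":", 1)[1] if ":" in name else None
        if umi is None:
            if strict:
                raise ValueError(f"read {name!r} carries no UMI")
            logging.getLogger(__name__).warning("read %s has no UMI; kept", name)
        if a.strand == "+":
            start = a.blocks[0][0]
            xl = start - offset
        else:
            start = a.blocks[-1][1] - 1   # 5' end on the minus strand
            xl = start + offset
        key = (umi, a.chrom, a.strand, start)
        if umi is not None and key in seen:
            continue
        seen.add(key)
        rows.append((sample_id, a.chrom, a.strand, xl, a.gapped))
    return pd.DataFrame(rows, columns=CROSSLINK_COLUMNS)


def read_crosslink_bed(path: str, sample_id: Optional[str] = None) -> pd.DataFrame:
    """6-column crosslink BED: chrom, start, end, name/count, score, strand.

    Each interval contributes ``score`` crosslinks (or 1 when score is absent
    or zero) at its start position.
    """
    rows = []
    sid = sample_id or str(path)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start = parts[0], int(parts[1])
            strand = parts[5] if len(parts) > 5 else "+"
            count = int(float(parts[4])) if len(parts) > 4 and parts[4] not in (".", "") else 1
            count = max(count, 1)
            rows.extend([(sid, chrom, strand, start, False)] * count)
    return pd.DataFrame(rows, columns=CROSSLINK_COLUMNS)


def write_crosslink_bed(crosslinks: pd.DataFrame, path: str) -> None:
    grouped = (crosslinks.groupby(["chrom", "strand", "pos"]).size()
               .reset_index(name="count"))
    with open(path, "w") as fh:
        for r in grouped.itertuples():
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t.\t{r.count}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# profiles


@dataclass
class CrosslinkProfile:
    """Normalized crosslink frequency by distance to the junction."""

    group: str
    replicate: str
    distances: np.ndarray           # window offsets, ascending
    frequency: np.ndarray           # counts / (n_junctions * library_total)
    n_junctions: int
    library_total: int

    @property
    def empty(self) -> bool:
        return self.n_junctions == 0 or self.library_total == 0


@dataclass(frozen=True)
class JunctionSite:
    """A junction anchor: ``pos`` is the genomic 0-based coordinate of the
    first base downstream of the junction in transcript orientation."""

    chrom: str
    strand: str
    pos: int
    group: str
    junction_id: str = ""


class _SortedPositions:
    """Crosslink positions sorted per (chrom, strand) for windowed counting."""

    def __init__(self, crosslinks: pd.DataFrame):
        self._by_key: dict[tuple, np.ndarray] = {
            key: np.sort(sub["pos"].to_numpy())
            for key, sub in crosslinks.groupby(["chrom", "strand"], sort=False)}

    def distance_counts(self, site: JunctionSite, window: tuple[int, int]
                        ) -> np.ndarray:
        """Counts per distance offset (ascending) within the window."""
        lo, hi = window
        pos = self._by_key.get((site.chrom, site.strand))
        n = hi - lo + 1
        if pos is None:
            return np.zeros(n)
        if site.strand == "+":
            a, b = site.pos + lo, site.pos + hi
        else:
            a, b = site.pos - hi, site.pos - lo
        i, j = np.searchsorted(pos, [a, b + 1])
        sub = pos[i:j]
        d = sub - site.pos if site.strand == "+" else site.pos - sub
        return np.bincount(d - lo, minlength=n).astype(float)


def junction_profile(crosslinks_by_replicate: Mapping[str, pd.DataFrame],
                     junctions: Sequence[JunctionSite],
                     window: tuple[int, int] = DEFAULT_WINDOW,
                     gapped: Optional[bool] = None,
                     single_read_filter: bool = True
                     ) -> list[CrosslinkProfile]:
    """Per-replicate, per-group normalized crosslink profiles.

    ``gapped`` restricts crosslinks to (un)gapped source reads — gapped reads
    for exon-exon junctions, ungapped for exon-intron junctions.  Junctions
    whose window holds at most one crosslink summed over all replicates are
    excluded before counting (the single-read filter), and excluded junctions
    do not count toward the per-group normalizer.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    filtered = {rep: (df if gapped is None else df[df["gapped"] == gapped])
                for rep, df in crosslinks_by_replicate.items()}
    libsizes = {rep: len(df) for rep, df in crosslinks_by_replicate.items()}
    sorted_reps = {rep: _SortedPositions(df) for rep, df in filtered.items()}

    per_site = {rep: {} for rep in filtered}
    kept: list[JunctionSite] = []
    for site in junctions:
        total = 0.0
        for rep, sp in sorted_reps.items():
            c = sp.distance_counts(site, window)
            per_site[rep][id(site)] = c
            total += c.sum()
        if single_read_filter and total <= 1:
            continue
        kept.append(site)

    groups = sorted({s.group for s in junctions})
    out = []
    for group in groups:
        sites = [s for s in kept if s.group == group]
        for rep in filtered:
            counts = np.zeros(offsets.size)
            for site in sites:
                counts += per_site[rep][id(site)]
            total = libsizes[rep]
            denom = len(sites) * total
            freq = counts / denom if denom else np.zeros_like(counts)
            out.append(CrosslinkProfile(group, rep, offsets.copy(), freq,
                                        len(sites), total))
    return out


def smooth_profile(replicates: Sequence[CrosslinkProfile], span: float = 0.2,
                   degree: int = 2) -> pd.DataFrame:
    """LOESS-smoothed mean profile with a 95% confidence band.

    Each replicate profile is smoothed, then the mean and mean +/- 1.96*SEM
    across replicates are reported per distance.  With a single replicate the
    CI columns are NaN.
    """
    if not replicates:
        raise ValueError("no profiles supplied")
    distances = replicates[0].distances
    curves = np.stack([loess(p.distances, p.frequency, span=span, degree=degree)
                       for p in replicates])
    mean = curves.mean(axis=0)
    if len(replicates) >= 2:
        sem = curves.std(axis=0, ddof=1) / np.sqrt(len(replicates))
        lo_ci, hi_ci = mean - 1.96 * sem, mean + 1.96 * sem
    else:
        lo_ci = hi_ci = np.full_like(mean, np.nan)
    return pd.DataFrame({"distance": distances, "mean": mean,
                         "ci_low": lo_ci, "ci_high": hi_ci})


def peak_means(profiles: Sequence[CrosslinkProfile],
               peak_window: tuple[int, int] = DEFAULT_PEAK_WINDOW) -> np.ndarray:
    """Per-replicate mean normalized frequency inside the peak window."""
    lo, hi = peak_window
    out = []
    for p in profiles:
        mask = (p.distances >= lo) & (p.distances <= hi)
        out.append(float(p.frequency[mask].mean()))
    return np.asarray(out)


def compare_peak(profiles_a: Sequence[CrosslinkProfile],
                 profiles_b: Sequence[CrosslinkProfile],
                 peak_window: tuple[int, int] = DEFAULT_PEAK_WINDOW
                 ) -> tuple[float, float]:
    """Two-sided independent-samples t-test on per-replicate peak means.

    Returns (t, p).  Requires >= 2 replicates per group.
    """
    from scipy import stats as sps

    a, b = peak_means(profiles_a, peak_window), peak_means(profiles_b, peak_window)
    if a.size < 2 or b.size < 2:
        raise ValueError("compare_peak requires >= 2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0  # identical degenerate groups: no difference
    res = sps.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def coverage_normalize(group_coverage: Mapping[str, np.ndarray],
                       reference_coverage: Mapping[str, np.ndarray]
                       ) -> tuple[dict, dict, list[str]]:
    """Divide each group's coverage by its reference-share factor.

    f(group) = sum(reference coverage of group) / sum over all groups; the
    factors sum to 1.  Groups with zero reference sum are dropped and
    reported.  Returns (normalized coverage, factors, dropped groups).
    """
    sums = {g: float(np.sum(reference_coverage[g])) for g in group_coverage}
    total = sum(sums.values())
    if total <= 0:
        raise ValueError("reference coverage sums to zero across all groups")
    dropped = [g for g, s in sums.items() if s <= 0]
    factors = {g: s / total for g, s in sums.items() if s > 0}
    normalized = {g: np.asarray(group_coverage[g], dtype=float) / factors[g]
                  for g in factors}
    return normalized, factors, dropped
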