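"""Gene annotation parsing and internal-exon trio construction.

An *internal* exon A (one with both an upstream and a downstream neighbour in
at least one transcript of a protein-coding gene) is paired with an upstream
partner C1 and a downstream partner C2.  The three junctions among them —
upstream (C1->A), downstream (A->C2) and skip (C1->C2) — are the coordinate
frame for every downstream analysis: PSI quantification, reconstituted
5' splice-site (RS-5ss) scoring at the C1A exon-exon junction, junction
libraries, and splicing-order classification.

Partners are chosen from splice-junction read evidence when a junction count
table is supplied (the junction with the highest uniquely-mapped read count
wins); otherwise the nearest annotated neighbour is used.  GTF coordinates
are 1-based closed; all junction arithmetic inside the package is 0-based
half-open, and the ``start0``/``end0`` properties are the only converters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)


class AnnotationParseError(ValueError):
    """A GTF record could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class ExonRecord:
    """One exon of one transcript, in GTF coordinates (1-based, closed)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    index: int = -1  # exon index within transcript, 5'->3' in transcript orientation

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")

    @property
    def start0(self) -> int:
        """0-based half-open start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end."""
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.strand, self.start, self.end)


def exon_id(gene_id: str, chrom: str, strand: str, start: int, end: int) -> str:
    return f"{gene_id}:{chrom}:{strand}:{start}-{end}"


class Annotation:
    """Exons grouped by transcript and gene, in deterministic order."""

    def __init__(self, exons: Iterable[ExonRecord]):
        by_tx: dict[str, list[ExonRecord]] = {}
        for ex in exons:
            by_tx.setdefault(ex.transcript_id, []).append(ex)
        self.transcripts: dict[str, list[ExonRecord]] = {}
        self.genes: dict[str, list[str]] = {}
        for tid in sorted(by_tx):
            txe = sorted(by_tx[tid], key=lambda e: e.start)
            for a, b in zip(txe, txe[1:]):
                if b.start <= a.end:
                    logger.warning(
                        "transcript %s has overlapping exons; transcript dropped", tid
                    )
                    break
            else:
                if txe[0].strand == "-":
                    txe = txe[::-1]
                txe = [
                    ExonRecord(e.gene_id, e.transcript_id, e.chrom, e.strand,
                               e.start, e.end, index=i)
                    for i, e in enumerate(txe)
                ]
                self.transcripts[tid] = txe
                self.genes.setdefault(txe[0].gene_id, []).append(tid)

    @property
    def exons(self) -> list[ExonRecord]:
        return [e for tid in self.transcripts for e in self.transcripts[tid]]

    def internal_exons(self) -> list[ExonRecord]:
        """Unique internal exons (>=1 neighbour on each side), one per locus per gene."""
        seen: set[tuple] = set()
        out = []
        for gid in sorted(self.genes):
            for tid in self.genes[gid]:
                txe = self.transcripts[tid]
                for ex in txe[1:-1]:
                    k = (gid,) + ex.key
                    if k not in seen:
                        seen.add(k)
                        out.append(ex)
        return out


_BIOTYPE_ATTRS = ("gene_biotype", "gene_type")


def load_annotation(source, protein_coding_only: bool = True) -> Annotation:
    """Parse exon features from a GTF file path or an iterable of lines.

    Only ``exon`` features are used.  When ``protein_coding_only`` is set,
    records carrying a ``gene_biotype``/``gene_type`` attribute other than
    ``protein_coding`` are dropped; records without any biotype attribute are
    kept, so annotations lacking biotypes behave as if the filter were off.

    Raises :class:`AnnotationParseError` for unparseable records; records
    missing gene/transcript attributes are rejected with a logged warning.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)

    exons = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise AnnotationParseError(
                lineno, f"expected 9 tab-separated fields, got "
                        f"{len(line.split(chr(9)))}")
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises bare ValueError subclasses
            raise AnnotationParseError(lineno, str(exc)) from exc
        if feat.featuretype != "exon":
            continue
        try:
            gid = feat.attributes["gene_id"][0]
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            logger.warning("line %d: exon missing mandatory attribute %s; record "
                           "rejected", lineno, exc)
            continue
        if protein_coding_only:
            biotype = None
            for attr in _BIOTYPE_ATTRS:
                if attr in feat.attributes:
                    biotype = feat.attributes[attr][0]
                    break
            if biotype is not None and biotype != "protein_coding":
                continue
        if feat.strand not in "+-":
            logger.warning("line %d: exon without strand rejected", lineno)
            continue
        exons.append(ExonRecord(gid, tid, feat.seqid, feat.strand, feat.start, feat.end))
    return Annotation(exons)


# ---------------------------------------------------------------------------
# trios


@dataclass(frozen=True)
class InternalExonTrio:
    """Internal exon A with its chosen partners C1 (upstream) and C2 (downstream).

    Coordinates are GTF-style 1-based closed; ``provenance`` records whether
    the partners were selected from junction read evidence or fall back to the
    nearest annotated neighbour.
    """

    gene_id: str
    chrom: str
    strand: str
    a_start: int
    a_end: int
    c1_start: int
    c1_end: int
    c2_start: int
    c2_end: int
    provenance: str  # "junction" | "annotated"

    @property
    def exon_id(self) -> str:
        return exon_id(self.gene_id, self.chrom, self.strand, self.a_start, self.a_end)

    def _intron(self, left_end: int, right_start: int) -> tuple[int, int]:
        # 0-based half-open intron between two 1-based closed exons
        return (left_end, right_start - 1)

    @property
    def upstream_intron(self) -> tuple[int, int]:
        """Genomic 0-based half-open intron between C1 and A."""
        if self.strand == "+":
            return self._intron(self.c1_end, self.a_start)
        return self._intron(self.a_end, self.c1_start)

    @property
    def downstream_intron(self) -> tuple[int, int]:
        if self.strand == "+":
            return self._intron(self.a_end, self.c2_start)
        return self._intron(self.c2_end, self.a_start)

    @property
    def skip_intron(self) -> tuple[int, int]:
        if self.strand == "+":
            return self._intron(self.c1_end, self.c2_start)
        return self._intron(self.c2_end, self.c1_start)


def _intron_key(chrom: str, strand: str, left: ExonRecord, right: ExonRecord) -> tuple:
    """Junction-count key for the intron between two exons (transcript order
    left->right); returns (chrom, strand, istart0, iend0)."""
    if strand == "+":
        return (chrom, strand, left.end0, right.start0)
    return (chrom, strand, right.end0, left.start0)


def _intron_length(strand: str, left: ExonRecord, right: ExonRecord) -> int:
    if strand == "+":
        return right.start0 - left.end0
    return left.start0 - right.end0


def _choose_partner(a: ExonRecord, candidates: list[ExonRecord],
                    counts: Optional[Mapping], chrom: str, strand: str,
                    upstream: bool) -> tuple[Optional[ExonRecord], str]:
    """Pick C1 (upstream=True) or C2 by junction evidence, else nearest neighbour.

    Ties in read count are broken by the shorter intron, then by coordinates,
    so the choice is deterministic.
    """
    if not candidates:
        return None, "annotated"

    def intron_len(c):
        return _intron_length(strand, c, a) if upstream else _intron_length(strand, a, c)

    if counts is not None:
        def count_of(c):
            key = (_intron_key(chrom, strand, c, a) if upstream
                   else _intron_key(chrom, strand, a, c))
            return counts.get(key, 0)

        best = max(candidates, key=lambda c: (count_of(c), -intron_len(c),
                                              -c.start, -c.end))
        if count_of(best) > 0:
            return best, "junction"
    best = min(candidates, key=lambda c: (intron_len(c), c.start, c.end))
    return best, "annotated"


def build_trios(annotation: Annotation,
                junction_counts: Optional[Mapping] = None
                ) -> tuple[list[InternalExonTrio], dict]:
    """Construct one C1/A/C2 trio per unique internal exon of each gene.

    ``junction_counts``: mapping ``(chrom, strand, intron_start0, intron_end0)
    -> read count`` (see :class:`rsjunction.psi.JunctionCounts`).  Returns
    the trios plus a skip report with counts of excluded exons.
    """
    report = {"n_internal": 0, "no_upstream": 0, "no_downstream": 0}
    # candidate neighbours per unique internal exon, across transcripts
    up_cands: dict[tuple, dict[tuple, ExonRecord]] = {}
    down_cands: dict[tuple, dict[tuple, ExonRecord]] = {}
    a_by_key: dict[tuple, ExonRecord] = {}
    order: list[tuple] = []
    for gid in sorted(annotation.genes):
        for tid in annotation.genes[gid]:
            txe = annotation.transcripts[tid]
            for i, ex in enumerate(txe):
                if i == 0 or i == len(txe) - 1:
                    continue
                k = (gid,) + ex.key
                if k not in a_by_key:
                    a_by_key[k] = ex
                    order.append(k)
                up_cands.setdefault(k, {})[txe[i - 1].key] = txe[i - 1]
                down_cands.setdefault(k, {})[txe[i + 1].key] = txe[i + 1]

    trios = []
    for k in order:
        a = a_by_key[k]
        report["n_internal"] += 1
        c1, prov1 = _choose_partner(a, list(up_cands[k].values()), junction_counts,
                                    a.chrom, a.strand, upstream=True)
        c2, prov2 = _choose_partner(a, list(down_cands[k].values()), junction_counts,
                                    a.chrom, a.strand, upstream=False)
        if c1 is None:
            report["no_upstream"] += 1
            continue
        if c2 is None:
            report["no_downstream"] += 1
            continue
        provenance = "junction" if (prov1 == "junction" and prov2 == "junction") \
            else "annotated"
        trios.append(InternalExonTrio(
            gene_id=k[0], chrom=a.chrom, strand=a.strand,
            a_start=a.start, a_end=a.end,
            c1_start=c1.start, c1_end=c1.end,
            c2_start=c2.start, c2_end=c2.end,
            provenance=provenance,
        ))
    return trios, report


# ---------------------------------------------------------------------------
# donor-context 9-mers

WINDOW_EXONIC = 3  # last nt of the upstream element
WINDOW_INTRONIC = 6  # first nt of the downstream element


class WindowUnavailable(ValueError):
    """The 9-nt window cannot be constructed (off-contig or undefined donor)."""


def junction_9mer(genome, trio: InternalExonTrio) -> str:
    """Reconstituted donor context at the C1A exon-exon junction.

    Last 3 nt of C1 plus first 6 nt of A, in transcript orientation: the
    sequence a part-spliced transcript presents as a candidate RS-5ss.
    """
    from .genome import GenomeOutOfBounds

    c, s = trio.chrom, trio.strand
    try:
        if s == "+":
            left = genome.fetch(c, trio.c1_end - WINDOW_EXONIC, trio.c1_end, "+")
            right = genome.fetch(c, trio.a_start - 1, trio.a_start - 1 + WINDOW_INTRONIC, "+")
        else:
            left = genome.fetch(c, trio.c1_start - 1, trio.c1_start - 1 + WINDOW_EXONIC, "-")
            right = genome.fetch(c, trio.a_end - WINDOW_INTRONIC, trio.a_end, "-")
    except GenomeOutOfBounds as exc:
        raise WindowUnavailable(str(exc)) from exc
    if trio.a_end - trio.a_start + 1 < WINDOW_INTRONIC:
        raise WindowUnavailable(
            f"exon {trio.exon_id} shorter than {WINDOW_INTRONIC} nt")
    return left + right


def canonical_9mer(genome, ex: ExonRecord, transcript_exons=None) -> str:
    """Donor context at the exon-intron junction: last 3 exonic + first 6 intronic nt.

    When ``transcript_exons`` is given and ``ex`` is the terminal exon of its
    transcript, the donor is undefined and :class:`WindowUnavailable` is raised.
    """
    from .genome import GenomeOutOfBounds

    if transcript_exons is not None and ex.key == transcript_exons[-1].key:
        raise WindowUnavailable(f"terminal exon {ex.key} has no downstream intron")
    c, s = ex.chrom, ex.strand
    try:
        if s == "+":
            left = genome.fetch(c, ex.end0 - WINDOW_EXONIC, ex.end0, "+")
            right = genome.fetch(c, ex.end0, ex.end0 + WINDOW_INTRONIC, "+")
        else:
            left = genome.fetch(c, ex.start0, ex.start0 + WINDOW_EXONIC, "-")
            right = genome.fetch(c, ex.start0 - WINDOW_INTRONIC, ex.start0, "-")
    except GenomeOutOfBounds as exc:
        raise WindowUnavailable(str(exc)) from exc
    if ex.length < WINDOW_EXONIC:
        raise WindowUnavailable(f"exon {ex.key} shorter than {WINDOW_EXONIC} nt")
    return left + right


# ---------------------------------------------------------------------------
# table I/O

TRIO_COLUMNS = ["exon_id", "gene_id", "chrom", "strand", "a_start", "a_end",
                "c1_start", "c1_end", "c2_start", "c2_end", "provenance"]


def trios_to_frame(trios: Iterable[InternalExonTrio]) -> pd.DataFrame:
    rows = [{
        "exon_id": t.exon_id, "gene_id": t.gene_id, "chrom": t.chrom,
        "strand": t.strand, "a_start": t.a_start, "a_end": t.a_end,
        "c1_start": t.c1_start, "c1_end": t.c1_end,
        "c2_start": t.c2_start, "c2_end": t.c2_end, "provenance": t.provenance,
    } for t in trios]
    return pd.DataFrame(rows, columns=TRIO_COLUMNS)


def write_trios(trios: Iterable[InternalExonTrio], path: str) -> None:
    trios_to_frame(trios).to_csv(path, sep="\t", index=False)


def read_trios(path: str) -> list[InternalExonTrio]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [InternalExonTrio(
        gene_id=r.gene_id, chrom=r.chrom, strand=r.strand,
        a_start=int(r.a_start), a_end=int(r.a_end),
        c1_start=int(r.c1_start), c1_end=int(r.c1_end),
        c2_start=int(r.c2_start), c2_end=int(r.c2_end),
        provenance=r.provenance,
    ) for r in df.itertuples()]
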