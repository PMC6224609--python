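"""Recursive-splicing lariat detection from branch-junction-traversing reads.

An RS-lariat joins the 5' end of an exon to a branchpoint (BP) in the
downstream intron through the 2'-5' bond.  Reverse transcription across the
branch produces reads whose sequence is an inverted junction: the intronic
window ending at the BP followed by the window starting at the exon's first
nucleotide.  Because the polymerase misreads the branched adenosine, a
genuine lariat read carries exactly one mismatch, located at the BP.

Candidate BPs are an input (by default every position 18-45 nt upstream of
an annotated 3'ss); reads are aligned ungapped against the constructed
references and hits require the single-BP-mismatch signature with a minimum
overhang on each side of the branch junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .genome import GenomeOutOfBounds

DEFAULT_FLANK = 50
DEFAULT_MIN_OVERHANG = 8
BP_SEARCH_WINDOW = (18, 45)  # nt upstream of the 3'ss searched for BPs

_ENC = np.zeros(128, dtype=np.uint8)
for i, b in enumerate("ACGTN"):
    _ENC[ord(b)] = i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class LariatReference:
    """Inverted branch-junction reference for one (exon start, BP) pairing.

    ``sequence`` = genomic window ending at the BP (inclusive) followed by the
    window starting at the exon 5' end, both in transcript orientation.  The
    BP is the last base of the left half (index ``bp_index``).
    """

    pairing_id: str
    chrom: str
    strand: str
    exon_start: int   # genomic 0-based coordinate of the exon's first base
    bp_pos: int       # genomic 0-based coordinate of the BP
    sequence: str
    bp_index: int     # position of the BP within `sequence`

    @property
    def bp_base(self) -> str:
        return self.sequence[self.bp_index]


def build_lariat_references(exon_starts: Sequence[tuple],
                            bp_positions: Mapping[tuple, Sequence[int]],
                            genome, flank: int = DEFAULT_FLANK
                            ) -> list[LariatReference]:
    """One reference per (exon 5' end, candidate BP) pairing.

    ``exon_starts``: (chrom, strand, pos0) triples, pos0 the genomic 0-based
    coordinate of the exon's first base in transcript orientation.
    ``bp_positions``: exon-start triple -> genomic 0-based BP coordinates in
    the downstream intron.  Pairings whose windows run off-contig are skipped.
    """
    refs = []
    for key in exon_starts:
        chrom, strand, pos = key
        for bp in bp_positions.get(key, ()):
            try:
                if strand == "+":
                    left = genome.fetch(chrom, bp - flank + 1, bp + 1, "+")
                    right = genome.fetch(chrom, pos, pos + flank, "+")
                else:
                    left = genome.fetch(chrom, bp, bp + flank, "-")
                    right = genome.fetch(chrom, pos - flank + 1, pos + 1, "-")
            except GenomeOutOfBounds:
                continue
            refs.append(LariatReference(
                pairing_id=f"{chrom}:{strand}:{pos}|bp{bp}",
                chrom=chrom, strand=strand, exon_start=pos, bp_pos=bp,
                sequence=left + right, bp_index=len(left) - 1))
    return refs


def candidate_bp_positions(acceptors: Sequence[tuple],
                           window: tuple[int, int] = BP_SEARCH_WINDOW
                           ) -> dict[tuple, list[int]]:
    """Default BP candidates: every position ``window`` nt upstream of a 3'ss.

    ``acceptors``: (chrom, strand, exon_start0) triples where exon_start0 is
    the first base of the exon downstream of the 3'ss.  Distances are counted
    from the last intronic base (distance 1).
    """
    out: dict[tuple, list[int]] = {}
    lo, hi = window
    for chrom, strand, pos in acceptors:
        if strand == "+":
            positions = [pos - d for d in range(lo, hi + 1)]
        else:
            positions = [pos + d for d in range(lo, hi + 1)]
        out[(chrom, strand, pos)] = positions
    return out


@dataclass(frozen=True)
class LariatHit:
    read_id: str
    pairing_id: str
    mismatch_index: int   # position within the reference
    bp_base: str          # genomic base at the BP


def detect_lariat_reads(reads: Mapping[str, str] | Sequence[tuple],
                        references: Sequence[LariatReference],
                        min_overhang: int = DEFAULT_MIN_OVERHANG
                        ) -> tuple[list[LariatHit], dict]:
    """Scan reads for ungapped branch-junction alignments with the single
    BP mismatch.

    A hit requires an alignment crossing the branch junction with at least
    ``min_overhang`` nt on each side and exactly one mismatch, lying at the
    BP.  Reads are (id, sequence) pairs or a mapping; they are assumed to be
    pre-filtered against the genome.  Returns hits plus a tally of rejected
    reads.
    """
    items = list(reads.items()) if isinstance(reads, Mapping) else list(reads)
    report = {"n_reads": len(items), "n_hits": 0, "n_no_alignment": 0}
    hits: list[LariatHit] = []
    if not items:
        return hits, report

    read_ids = [r[0] for r in items]
    lens = {len(r[1]) for r in items}
    by_len = {L: np.stack([_encode(r[1]) for r in items if len(r[1]) == L])
              for L in lens}
    ids_by_len = {L: [r[0] for r in items if len(r[1]) == L] for L in lens}

    matched: set[str] = set()
    for ref in references:
        enc_ref = _encode(ref.sequence)
        J = ref.bp_index + 1  # junction sits between bp_index and bp_index+1
        for L, mat in by_len.items():
            if L < 2 * min_overhang:
                continue
            # offsets where the read crosses the junction with both overhangs
            lo = max(0, J + min_overhang - L)
            hi = min(J - min_overhang, len(enc_ref) - L)
            if hi < lo:
                continue
            offsets = np.arange(lo, hi + 1)
            windows = np.stack([enc_ref[o:o + L] for o in offsets])
            # mismatches per (read, offset)
            mism = (mat[:, None, :] != windows[None, :, :])
            n_mm = mism.sum(axis=2)
            cand_r, cand_o = np.nonzero(n_mm == 1)
            for r, o in zip(cand_r, cand_o):
                pos_in_ref = int(np.nonzero(mism[r, o])[0][0]) + int(offsets[o])
                rid = ids_by_len[L][r]
                if pos_in_ref == ref.bp_index and rid not in matched:
                    matched.add(rid)
                    hits.append(LariatHit(rid, ref.pairing_id,
                                          pos_in_ref, ref.bp_base))
    report["n_hits"] = len(hits)
    report["n_no_alignment"] = len(items) - len(hits)
    return hits, report


def bp_composition(hits: Sequence[LariatHit]) -> dict[str, float]:
    """Fraction of hits per branchpoint nucleotide (sums to 1)."""
    if not hits:
        raise ValueError("no lariat hits")
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.bp_base] = counts.get(h.bp_base, 0) + 1
    n = len(hits)
    return {b: c / n for b, c in sorted(counts.items())}


def gu_enrichment(hit_exon_starts: Sequence[tuple],
                  background_exon_starts: Sequence[tuple],
                  genome) -> Optional[float]:
    """Fold enrichment of a GT (GU in RNA) dinucleotide at the exon start.

    freq(GT | lariat-hit exons) / freq(GT | background exons); None when the
    background frequency is zero (undefined fold).
    """
    def gt_freq(starts):
        if not starts:
            raise ValueError("empty exon-start set")
        n_gt = 0
        for chrom, strand, pos in starts:
            if strand == "+":
                dinuc = genome.fetch(chrom, pos, pos + 2, "+")
            else:
                dinuc = genome.fetch(chrom, pos - 1, pos + 1, "-")
            if dinuc == "GT":
                n_gt += 1
        return n_gt / len(starts)

    f_bg = gt_freq(background_exon_starts)
    f_hit = gt_freq(hit_exon_starts)
    if f_bg == 0:
        return None
    return f_hit / f_bg


def write_reference_fasta(refs: Sequence[LariatReference], path: str) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.pairing_id} chrom={r.chrom} strand={r.strand} "
                     f"exon_start={r.exon_start} bp={r.bp_pos} "
                     f"bp_index={r.bp_index}\n{r.sequence}\n")
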