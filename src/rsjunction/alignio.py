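"""Lightweight alignment records shared by the splicing-order and iCLIP modules.

Real data arrives as SAM/BAM (read via pysam); synthetic fixtures are emitted
directly as :class:`ReadAlignment` objects or as a simple tab-separated
dialect.  Blocks are genomic 0-based half-open intervals in ascending order;
a gap between consecutive blocks is a splice junction in the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional


@dataclass(frozen=True)
class ReadAlignment:
    name: str
    chrom: str
    strand: str
    blocks: tuple  # ((start0, end0), ...) ascending, non-overlapping
    is_read1: bool = True

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def gaps(self) -> tuple:
        """Gaps between consecutive blocks: the introns the alignment spans."""
        return tuple((a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:]))

    @property
    def gapped(self) -> bool:
        return len(self.blocks) > 1


def _merge_adjacent(blocks: list[tuple[int, int]]) -> tuple:
    """Collapse abutting blocks (zero-length gaps from e.g. indel cigars)."""
    out: list[list[int]] = []
    for s, e in blocks:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


def read_sam(path: str) -> Iterator[ReadAlignment]:
    """Iterate primary alignments from a SAM/BAM file via pysam."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield ReadAlignment(
                name=rec.query_name,
                chrom=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                blocks=_merge_adjacent([(s, e) for s, e in rec.get_blocks()]),
                is_read1=not rec.is_read2,
            )


def pair_up(alignments: Iterable[ReadAlignment]
            ) -> Iterator[tuple[ReadAlignment, Optional[ReadAlignment]]]:
    """Group alignments by read name into (mate1, mate2) pairs.

    Unpaired reads yield (read, None).  Input order is irrelevant.
    """
    by_name: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        by_name.setdefault(a.name, []).append(a)
    for name in sorted(by_name):
        group = sorted(by_name[name], key=lambda a: not a.is_read1)
        if len(group) >= 2:
            yield group[0], group[1]
        else:
            yield group[0], None


TSV_COLUMNS = ["name", "chrom", "strand", "blocks", "mate"]


def write_alignment_tsv(alignments: Iterable[ReadAlignment], path: str) -> None:
    """Write the SAM-level tabular dialect: blocks as 'start-end,start-end'."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for a in alignments:
            blocks = ",".join(f"{s}-{e}" for s, e in a.blocks)
            fh.write(f"{a.name}\t{a.chrom}\t{a.strand}\t{blocks}\t"
                     f"{1 if a.is_read1 else 2}\n")


def read_alignment_tsv(path: str) -> list[ReadAlignment]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(f"unexpected alignment TSV header: {header}")
        for line in fh:
            name, chrom, strand, blocks, mate = line.rstrip("\n").split("\t")
            parsed = tuple(tuple(map(int, b.split("-"))) for b in blocks.split(","))
            out.append(ReadAlignment(name, chrom, strand, parsed, mate == "1"))
    return out
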