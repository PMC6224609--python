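"""Synthetic genomes, annotations, reads and counts with known ground truth.

Every pipeline stage can be exercised end-to-end without external data.  The
generator emulates the statistical structure of the real inputs:

* a multi-gene genome + GTF in which a chosen fraction of internal exons
  reconstitute a strong donor at their upstream exon-exon junction (planted
  RS-exons), and a fraction of the remaining internal exons host a strong
  internal donor 3-15 nt into the exon (cryptic microexon hosts);
* per-sample splice-junction count tables under control and knockdown, where
  knockdown shifts inclusion (dPSI) only at RS-labelled exons;
* junction-library read counts with a known RS-5ss usage fraction per
  condition, raw counts scaled by mappable positions;
* iCLIP crosslink libraries with a planted peak upstream of RS junctions and
  a knockdown enrichment factor;
* paired-end fragments carrying a planted upstream-intron-first probability;
* lariat reads copied from branch-junction references with the single
  branchpoint mismatch, plus linear decoy reads.

Everything is driven by an integer seed; identical seeds give identical
outputs.  The truth manifest is serialised alongside every dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignio import ReadAlignment
from .annotation import Annotation, ExonRecord, InternalExonTrio, exon_id
from .genome import GenomeSequence, reverse_complement
from .iclip import JunctionSite
from .lariat import LariatReference, build_lariat_references
from .psi import JunctionCounts
from .scoring import _DEFAULT_DONOR_FREQS

_BASES = "ACGT"

# intron halves of strong donors planted at RS-5ss and internal 5ss; with the
# CAG exonic prefix these score >= 12 under the built-in PWM, comfortably
# clear of any threshold calibrated on the sampled canonical donors
STRONG_SIX = ("GTAAGT", "GTGAGT")
STRONG_PREFIX = "CAG"


def purs_from_usage(u: float) -> float:
    """Expected PURS when a fraction ``u`` of part-spliced molecules use the
    RS/internal donor: flanking intensities are C1A = 1, AC2 = 1 - u."""
    return 200.0 * u / (2.0 - u)


def usage_for_purs(p: float) -> float:
    """Inverse of :func:`purs_from_usage`."""
    return 2.0 * p / (200.0 + p)


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset, serialisable to JSON."""

    params: dict = field(default_factory=dict)
    exons: dict = field(default_factory=dict)  # exon_id -> per-exon truth

    def rs_exons(self) -> list[str]:
        return [e for e, t in self.exons.items() if t["rs"]]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"params": self.params, "exons": self.exons}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(params=d["params"], exons=d["exons"])

    def trio(self, eid: str) -> InternalExonTrio:
        t = self.exons[eid]
        return InternalExonTrio(
            gene_id=t["gene_id"], chrom=t["chrom"], strand=t["strand"],
            a_start=t["a_start"], a_end=t["a_end"],
            c1_start=t["c1_start"], c1_end=t["c1_end"],
            c2_start=t["c2_start"], c2_end=t["c2_end"],
            provenance="annotated")

    def trios(self) -> list[InternalExonTrio]:
        return [self.trio(e) for e in self.exons]


def _sample_canonical_donor(rng) -> str:
    freqs = np.asarray(_DEFAULT_DONOR_FREQS)
    return "".join(_BASES[rng.choice(4, p=f / f.sum())] for f in freqs)


def make_genome_annotation(
    n_genes: int = 20,
    rs_fraction: float = 0.3,
    microexon_fraction: float = 0.0,
    seed: int = 0,
    exons_per_gene: int = 3,
    exon_len: tuple[int, int] = (60, 120),
    intron_len: tuple[int, int] = (100, 200),
    control_psi: tuple[float, float] = (0.85, 0.999),
    kd_dpsi: float = -0.2,
    usage_control: float = 0.02,
    target_dpurs: float = 20.0,
    upstream_first_prob: float = 0.8,
    pad: int = 150,
) -> tuple[GenomeSequence, Annotation, SyntheticTruth]:
    """Generate a genome, a single-transcript-per-gene annotation and truth.

    One gene per chromosome, alternating strands.  Each gene has
    ``exons_per_gene`` exons (>= 3, so internal exons exist), canonical
    donors sampled from the built-in donor PWM at every exon-intron junction,
    and planted features at internal exons: RS-exons begin with a strong
    donor six-mer behind a CAG-ending upstream exon; cryptic-microexon hosts
    carry the same motif at a random offset 3-15 nt into the exon; all other
    internal exons begin with CC so their reconstituted window is dead.
    """
    if exons_per_gene < 3:
        raise ValueError("genes need >= 3 exons to contain internal exons")
    for frac in (rs_fraction, microexon_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    exon_records: list[ExonRecord] = []
    truth = SyntheticTruth(params={
        "seed": int(seed), "n_genes": n_genes, "rs_fraction": rs_fraction,
        "microexon_fraction": microexon_fraction, "exons_per_gene": exons_per_gene,
        "kd_dpsi": kd_dpsi, "usage_control": usage_control,
        "target_dpurs": target_dpurs, "upstream_first_prob": upstream_first_prob,
        "read_len": 50,
    })

    usage_kd = usage_for_purs(purs_from_usage(usage_control) + target_dpurs)

    for g in range(n_genes):
        gid = f"G{g:04d}"
        chrom = f"chr{g:04d}"
        strand = "+" if g % 2 == 0 else "-"
        ne = exons_per_gene
        elens = rng.integers(exon_len[0], exon_len[1] + 1, size=ne)
        ilens = rng.integers(intron_len[0], intron_len[1] + 1, size=ne - 1)

        # assemble in transcript orientation
        parts: list[np.ndarray] = []
        tx_bounds: list[tuple[int, int]] = []
        pos = 0
        for i in range(ne):
            parts.append(rng.integers(0, 4, size=elens[i]))
            tx_bounds.append((pos, pos + int(elens[i])))
            pos += int(elens[i])
            if i < ne - 1:
                parts.append(rng.integers(0, 4, size=ilens[i]))
                pos += int(ilens[i])
        seq = np.concatenate(parts)

        def put(at: int, s: str):
            seq[at:at + len(s)] = [_BASES.index(b) for b in s]

        # canonical donors at every exon-intron junction
        for i in range(ne - 1):
            donor = _sample_canonical_donor(rng)
            e_end = tx_bounds[i][1]
            put(e_end - 3, donor[:3])
            put(e_end, donor[3:])

        # internal-exon features
        internal_truth = {}
        for i in range(1, ne - 1):
            a_s, a_e = tx_bounds[i]
            is_rs = bool(rng.random() < rs_fraction)
            me_offset: Optional[int] = None
            donor: Optional[str] = None
            if is_rs:
                put(tx_bounds[i - 1][1] - 3, STRONG_PREFIX)  # C1 ends CAG
                six = STRONG_SIX[int(rng.integers(len(STRONG_SIX)))]
                put(a_s, six)
                donor = STRONG_PREFIX + six
                fill_from = a_s + 6
            else:
                if rng.random() < microexon_fraction:
                    me_offset = int(rng.integers(3, 16))
                    six = STRONG_SIX[int(rng.integers(len(STRONG_SIX)))]
                    motif = "C" * (me_offset - 3) + STRONG_PREFIX + six
                    put(a_s, motif)
                    donor = STRONG_PREFIX + six
                    fill_from = a_s + len(motif)
                else:
                    put(a_s, "CC")
                    fill_from = a_s + 2
            # keep the scanned region free of accidental donors
            fill_to = min(a_s + 24, a_e)
            if fill_to > fill_from:
                put(fill_from, "C" * (fill_to - fill_from))
            internal_truth[i] = (is_rs, me_offset, donor)

        gene_seq = "".join(_BASES[b] for b in seq)
        pad_left = "".join(_BASES[b] for b in rng.integers(0, 4, size=pad))
        pad_right = "".join(_BASES[b] for b in rng.integers(0, 4, size=pad))
        if strand == "+":
            sequences[chrom] = pad_left + gene_seq + pad_right
            genomic = [(pad + s, pad + e) for s, e in tx_bounds]  # 0-based half-open
        else:
            sequences[chrom] = pad_left + reverse_complement(gene_seq) + pad_right
            L = len(gene_seq)
            genomic = [(pad + L - e, pad + L - s) for s, e in tx_bounds]

        tid = f"{gid}.1"
        for i, (s0, e0) in enumerate(genomic):
            exon_records.append(ExonRecord(gid, tid, chrom, strand, s0 + 1, e0))

        for i, (is_rs, me_offset, donor) in internal_truth.items():
            a = genomic[i]
            c1 = genomic[i - 1]
            c2 = genomic[i + 1]
            eid = exon_id(gid, chrom, strand, a[0] + 1, a[1])
            psi0 = float(rng.uniform(*control_psi))
            truth.exons[eid] = {
                "gene_id": gid, "chrom": chrom, "strand": strand,
                "a_start": a[0] + 1, "a_end": a[1],
                "c1_start": c1[0] + 1, "c1_end": c1[1],
                "c2_start": c2[0] + 1, "c2_end": c2[1],
                "rs": is_rs, "microexon_offset": me_offset,
                "donor_window": donor,
                "control_psi": psi0,
                "kd_dpsi": kd_dpsi if is_rs else 0.0,
                "usage_control": usage_control if (is_rs or me_offset) else 0.0,
                "usage_kd": usage_kd if (is_rs or me_offset) else 0.0,
                "upstream_first_prob": upstream_first_prob,
                "bp_pos": None,
            }

    genome = GenomeSequence(sequences)
    annotation = Annotation(exon_records)
    _plant_branchpoints(truth, rng)
    return genome, annotation, truth


def _plant_branchpoints(truth: SyntheticTruth, rng) -> None:
    """One branchpoint per RS exon, 18-45 nt upstream of the downstream 3'ss."""
    for eid in truth.rs_exons():
        t = truth.exons[eid]
        d = int(rng.integers(18, 46))
        if t["strand"] == "+":
            acceptor = t["c2_start"] - 1     # first base of C2, 0-based
            t["bp_pos"] = acceptor - d
        else:
            acceptor = t["c2_end"] - 1
            t["bp_pos"] = acceptor + d


def write_gtf(annotation: Annotation, path: str) -> None:
    with open(path, "w") as fh:
        for tid in annotation.transcripts:
            for ex in sorted(annotation.transcripts[tid], key=lambda e: e.start):
                attrs = (f'gene_id "{ex.gene_id}"; transcript_id "{tid}"; '
                         f'gene_biotype "protein_coding";')
                fh.write("\t".join([ex.chrom, "synthetic", "exon", str(ex.start),
                                    str(ex.end), ".", ex.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# junction counts


def simulate_junction_counts(truth: SyntheticTruth, depth: int = 500,
                             n_control: int = 3, n_kd: int = 1,
                             noise: float = 0.02, seed: int = 0
                             ) -> dict[str, JunctionCounts]:
    """SJ count tables per sample: controls at the planted PSI, knockdowns
    shifted by the planted dPSI at RS-labelled exons only.

    Counts are binomial thinnings of a Poisson per-exon coverage, with the
    inclusion probability transformed so the weighted PSI formula recovers
    the planted PSI in expectation.  ``noise`` is a per-sample Gaussian
    jitter (sd, proportion scale) on the planted PSI.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    samples = {f"control_{i}": None for i in range(n_control)}
    samples.update({f"kd_{i}": None for i in range(n_kd)})
    out = {}
    for sid in samples:
        is_kd = sid.startswith("kd")
        jc = JunctionCounts(sid)
        for eid, t in truth.exons.items():
            psi = t["control_psi"] + (t["kd_dpsi"] if is_kd else 0.0)
            psi = float(np.clip(psi + rng.normal(0.0, noise), 0.0, 1.0))
            q = psi / (50.0 - 49.0 * psi)
            n = rng.poisson(depth)
            incl = rng.binomial(n, q)
            up = rng.binomial(incl, 0.5)
            down = incl - up
            skip = n - incl
            trio = truth.trio(eid)
            c, s = trio.chrom, trio.strand
            jc.add((c, s) + trio.upstream_intron, int(up))
            jc.add((c, s) + trio.downstream_intron, int(down))
            if skip:
                jc.add((c, s) + trio.skip_intron, int(skip))
        out[sid] = jc
    return out


# ---------------------------------------------------------------------------
# junction-library reads


def simulate_junction_library_reads(truth: SyntheticTruth, library,
                                    depth: int = 500, seed: int = 0,
                                    conditions: Sequence[str] = ("control", "kd"),
                                    read_len: int = 50, min_overhang: int = 8
                                    ) -> pd.DataFrame:
    """Raw junction-library counts (entry_id, condition, count).

    Intensities per part-spliced molecule: RS event = usage u, C1A = 1,
    A-C2 = 1 - u, C1-C2 = 0.05 (exon-definition skipping baseline).  Raw
    Poisson counts are scaled by each entry's mappable-position fraction so
    mappability-corrected counts are unbiased.
    """
    rng = np.random.default_rng(seed)
    full = read_len - 2 * min_overhang + 1
    rows = []
    for e in library:
        t = truth.exons.get(e.exon_id)
        if t is None:
            continue
        for cond in conditions:
            u = t["usage_kd"] if cond == "kd" else t["usage_control"]
            intensity = {"RS_EVENT": u, "C1A": 1.0, "AC2": 1.0 - u,
                         "C1C2": 0.05}[e.junction_type]
            m = e.mappable(read_len, min_overhang)
            lam = depth * intensity * m / full
            rows.append((e.entry_id, cond, int(rng.poisson(lam))))
    return pd.DataFrame(rows, columns=["entry_id", "condition", "count"])


# ---------------------------------------------------------------------------
# iCLIP


def exon_junction_sites(truth: SyntheticTruth) -> list[JunctionSite]:
    """Exon-exon junction anchors (C1A junction) grouped RS / nonRS."""
    sites = []
    for eid, t in truth.exons.items():
        pos = t["a_start"] - 1 if t["strand"] == "+" else t["a_end"] - 1
        sites.append(JunctionSite(t["chrom"], t["strand"], pos,
                                  "RS" if t["rs"] else "nonRS", eid))
    return sites


def simulate_iclip(truth: SyntheticTruth, n_replicates: int = 4,
                   n_crosslinks: int = 20000, peak_offset: int = -13,
                   peak_weight: float = 0.05, enrichment: float = 5.0,
                   window: tuple[int, int] = (-50, 0), seed: int = 0,
                   conditions: Sequence[str] = ("control", "kd")
                   ) -> tuple[dict, list[JunctionSite]]:
    """Crosslink libraries with a planted peak at RS exon-exon junctions.

    Background crosslinks are uniform over the window at every junction; a
    point mass at ``peak_offset`` is added at RS junctions, holding a
    ``peak_weight`` share of each control library and ``peak_weight *
    enrichment`` of each knockdown library (library totals are fixed).
    Returns ``{(condition, replicate): crosslink frame}`` and the junctions.
    """
    rng = np.random.default_rng(seed)
    sites = exon_junction_sites(truth)
    rs_sites = [s for s in sites if s.group == "RS"]
    if not rs_sites:
        raise ValueError("no RS junctions in truth; nothing to plant")
    lo, hi = window
    libraries = {}
    for cond in conditions:
        w = peak_weight * (enrichment if cond == "kd" else 1.0)
        if w >= 0.9:
            raise ValueError("peak share too large; reduce peak_weight or enrichment")
        chrom_all = np.array([s.chrom for s in sites])
        pos_all = np.array([s.pos for s in sites])
        sign_all = np.where(np.array([s.strand for s in sites]) == "+", 1, -1)
        strand_all = np.array([s.strand for s in sites])
        rs_idx = np.array([i for i, s in enumerate(sites) if s.group == "RS"])
        for rep in range(n_replicates):
            n_peak = rng.binomial(n_crosslinks, w)
            n_bg = n_crosslinks - n_peak
            pk = rs_idx[rng.integers(rs_idx.size, size=n_peak)]
            bg = rng.integers(len(sites), size=n_bg)
            dists = np.concatenate([np.full(n_peak, peak_offset),
                                    rng.integers(lo, hi + 1, size=n_bg)])
            jdx = np.concatenate([pk, bg])
            positions = pos_all[jdx] + sign_all[jdx] * dists
            sid = f"{cond}_{rep}"
            libraries[(cond, rep)] = pd.DataFrame({
                "sample_id": sid, "chrom": chrom_all[jdx],
                "strand": strand_all[jdx], "pos": positions, "gapped": True})
    return libraries, sites


# ---------------------------------------------------------------------------
# paired-end fragments


def simulate_read_pairs(truth: SyntheticTruth, n_pairs_per_exon: int = 50,
                        seed: int = 0, n_uninformative: int = 5,
                        anchor: int = 20
                        ) -> list[tuple[ReadAlignment, ReadAlignment]]:
    """Informative read pairs drawn with the planted upstream-first probability.

    Upstream-first pairs have one mate spliced exactly across the C1-A
    junction and the other inside the downstream intron; downstream-first
    pairs are the reciprocal.  A few fully exonic (uninformative) pairs are
    added per exon.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for eid, t in truth.exons.items():
        trio = truth.trio(eid)
        us, ue = trio.upstream_intron
        ds, de = trio.downstream_intron
        p = t["upstream_first_prob"]
        kinds = rng.random(n_pairs_per_exon) < p
        for i, up_first in enumerate(kinds):
            name = f"{eid}|pair{i}"
            if up_first:
                m1 = ReadAlignment(name, trio.chrom, trio.strand,
                                   ((us - anchor, us), (ue, ue + anchor)), True)
                m2 = ReadAlignment(name, trio.chrom, trio.strand,
                                   ((ds + 5, min(ds + 45, de)),), False)
            else:
                m1 = ReadAlignment(name, trio.chrom, trio.strand,
                                   ((ds - anchor, ds), (de, de + anchor)), True)
                m2 = ReadAlignment(name, trio.chrom, trio.strand,
                                   ((us + 5, min(us + 45, ue)),), False)
            pairs.append((m1, m2))
        a0, a1 = trio.a_start - 1, trio.a_end
        for i in range(n_uninformative):
            name = f"{eid}|exonic{i}"
            m1 = ReadAlignment(name, trio.chrom, trio.strand,
                               ((a0, min(a0 + anchor, a1)),), True)
            m2 = ReadAlignment(name, trio.chrom, trio.strand,
                               ((a0 + 5, min(a0 + 5 + anchor, a1)),), False)
            pairs.append((m1, m2))
    return pairs


# ---------------------------------------------------------------------------
# lariat reads


_SUBSTITUTE = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}


def lariat_truth_references(truth: SyntheticTruth, genome,
                            flank: int = 50) -> list[LariatReference]:
    """Branch-junction references for the planted (exon start, BP) pairings."""
    starts, bps = [], {}
    for eid in truth.rs_exons():
        t = truth.exons[eid]
        pos = t["a_start"] - 1 if t["strand"] == "+" else t["a_end"] - 1
        key = (t["chrom"], t["strand"], pos)
        starts.append(key)
        bps[key] = [t["bp_pos"]]
    return build_lariat_references(starts, bps, genome, flank=flank)


def simulate_lariat_reads(truth: SyntheticTruth, genome,
                          n_per_reference: int = 3, n_decoys: int = 100,
                          read_len: int = 50, min_overhang: int = 8,
                          seed: int = 0, flank: int = 50
                          ) -> tuple[list[tuple[str, str]],
                                     list[LariatReference], dict]:
    """Lariat reads copied from references with the BP base substituted, plus
    linear decoy reads drawn from the genome.

    Returns (reads, references, manifest) where manifest maps planted read
    ids to their pairing ids.
    """
    rng = np.random.default_rng(seed)
    refs = lariat_truth_references(truth, genome, flank=flank)
    reads: list[tuple[str, str]] = []
    manifest: dict[str, str] = {}
    for ref in refs:
        J = ref.bp_index + 1
        lo = max(0, J + min_overhang - read_len)
        hi = min(J - min_overhang, len(ref.sequence) - read_len)
        if hi < lo:
            continue
        offsets = rng.integers(lo, hi + 1, size=n_per_reference)
        for i, off in enumerate(offsets):
            s = ref.sequence[off:off + read_len]
            k = ref.bp_index - off
            s = s[:k] + _SUBSTITUTE[s[k]] + s[k + 1:]
            rid = f"lariat|{ref.pairing_id}|{i}"
            reads.append((rid, s))
            manifest[rid] = ref.pairing_id
    chroms = genome.chroms()
    for i in range(n_decoys):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, genome.length(chrom) - read_len))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append((f"decoy|{i}", genome.fetch(chrom, start, start + read_len,
                                                 strand)))
    return reads, refs, manifest
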