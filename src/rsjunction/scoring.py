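"""Donor (5' splice site) scoring, threshold calibration and RS-exon classification.

The donor context is always a 9-mer: 3 exonic nt followed by 6 intronic nt
(positions -3..-1, +1..+6).  An exon is a putative RS-exon when the 9-mer
reconstituted at its upstream exon-exon junction (last 3 nt of the preceding
exon + the exon's first 6 nt) scores above a per-species threshold, calibrated
so that a chosen fraction of canonical exon-intron donors (default 90%) lie at
or above it.

Three scorers are provided:

* :class:`MaxEntDonorScorer` — the maximum-entropy 5ss model.  The model
  table is an external input (the classic 16384-float ``me2x5`` list over the
  7 non-consensus positions, or a keyed ``7MER<TAB>value`` text file); the
  consensus GT dinucleotide at +1/+2 is scored against background exactly as
  in the published reference implementation.
* :class:`PwmScorer` — a position-weight-matrix log-odds scorer.
  :func:`default_donor_pwm` ships a human-like donor matrix used throughout
  the synthetic analyses, so nothing external is required.
* :class:`KmerPrevalenceScorer` — membership (0/1) in the top-k most
  prevalent canonical donor 9-mers of a species; the annotation-only scorer
  used for cross-species comparison.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import InternalExonTrio, canonical_9mer, junction_9mer, WindowUnavailable

WINDOW_LEN = 9
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class SpliceSiteWindow:
    """A 9-nt donor context with its provenance role."""

    seq: str
    role: str = "canonical"  # canonical | reconstituted | internal

    def __post_init__(self):
        if len(self.seq) != WINDOW_LEN:
            raise ValueError(f"window must be {WINDOW_LEN} nt, got {len(self.seq)}")
        if any(b not in "ACGTN" for b in self.seq):
            raise ValueError(f"invalid alphabet in window {self.seq!r}")

    @property
    def scoreable(self) -> bool:
        return "N" not in self.seq


def score_window(scorer, window) -> Optional[float]:
    """Score a 9-mer; returns None (unscorable) for windows containing N."""
    seq = window.seq if isinstance(window, SpliceSiteWindow) else str(window)
    if len(seq) != WINDOW_LEN:
        raise ValueError(f"window must be {WINDOW_LEN} nt, got {len(seq)}")
    if "N" in seq:
        return None
    return scorer.score(seq)


# ---------------------------------------------------------------------------
# MaxEnt 5ss


class ModelTableError(ValueError):
    """The MaxEnt model table is missing or malformed."""


# constants of the published 5ss maximum-entropy scorer
_ME_BGD = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
_ME_CONS1 = {"A": 0.004, "C": 0.0032, "G": 0.9896, "T": 0.0032}   # position +1
_ME_CONS2 = {"A": 0.0034, "C": 0.0039, "G": 0.0042, "T": 0.9884}  # position +2


def _sevenmer_index(rest: str) -> int:
    idx = 0
    for b in rest:
        idx = idx * 4 + _BASE_INDEX[b]
    return idx


class MaxEntDonorScorer:
    """Maximum-entropy 5ss scorer over 9-mers, driven by an external model table.

    score = log2( cons(+1)·cons(+2) / bgd(+1)·bgd(+2) · P_me(rest) ) where
    ``rest`` is the 7-mer with the consensus +1/+2 positions removed and
    ``P_me`` is the model table.
    """

    kind = "maxent_table"

    def __init__(self, table: Sequence[float]):
        if len(table) != 4 ** 7:
            raise ModelTableError(
                f"model table must have {4**7} entries, got {len(table)}")
        self._table = np.asarray(table, dtype=float)

    @classmethod
    def from_table(cls, path: str) -> "MaxEntDonorScorer":
        """Load a model table: either one float per line (lexicographic 7-mer
        order, A<C<G<T) or keyed lines ``SEVENMER<TAB>value``."""
        values = np.full(4 ** 7, np.nan)
        keyed = False
        plain: list[float] = []
        try:
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line:
                        continue
                    parts = line.split()
                    if len(parts) == 2 and not _is_float(parts[0]):
                        keyed = True
                        kmer = parts[0].upper()
                        if len(kmer) != 7 or any(b not in _BASES for b in kmer):
                            raise ModelTableError(f"bad key {parts[0]!r}")
                        values[_sevenmer_index(kmer)] = float(parts[1])
                    else:
                        plain.append(float(parts[0]))
        except OSError as exc:
            raise ModelTableError(f"cannot read model table {path}: {exc}") from exc
        if keyed:
            if np.isnan(values).any():
                raise ModelTableError("keyed model table does not cover all 7-mers")
            return cls(values)
        return cls(plain)

    def score(self, seq: str) -> float:
        seq = seq.upper()
        rest = seq[:3] + seq[5:]
        consensus = (_ME_CONS1[seq[3]] * _ME_CONS2[seq[4]]) / (
            _ME_BGD[seq[3]] * _ME_BGD[seq[4]])
        return math.log2(consensus * self._table[_sevenmer_index(rest)])


def _is_float(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# PWM


# Approximate human donor-site base frequencies, positions -3..+6.  Used as
# the package's self-contained scorer for synthetic data; the argmax per
# position is the consensus CAG|GTAAGT.
_DEFAULT_DONOR_FREQS = [
    # A      C      G      T
    [0.33, 0.37, 0.18, 0.12],   # -3
    [0.60, 0.13, 0.14, 0.13],   # -2
    [0.08, 0.04, 0.81, 0.07],   # -1
    [0.001, 0.001, 0.996, 0.002],  # +1
    [0.002, 0.002, 0.002, 0.994],  # +2 (GC donors folded into background)
    [0.60, 0.03, 0.35, 0.02],   # +3
    [0.72, 0.08, 0.10, 0.10],   # +4
    [0.07, 0.05, 0.84, 0.04],   # +5
    [0.16, 0.18, 0.21, 0.45],   # +6
]


class PwmScorer:
    """Log2-odds position-weight-matrix scorer over 9-mers (0.25 background)."""

    kind = "pwm"

    def __init__(self, freqs: Sequence[Sequence[float]]):
        mat = np.asarray(freqs, dtype=float)
        if mat.shape != (WINDOW_LEN, 4):
            raise ValueError(f"matrix must be {WINDOW_LEN}x4, got {mat.shape}")
        self._logodds = np.log2(mat / 0.25)
        self.freqs = mat

    def score(self, seq: str) -> float:
        return float(sum(self._logodds[i, _BASE_INDEX[b]]
                         for i, b in enumerate(seq.upper())))


def default_donor_pwm() -> PwmScorer:
    """The built-in human-like donor PWM."""
    return PwmScorer(_DEFAULT_DONOR_FREQS)


# ---------------------------------------------------------------------------
# k-mer prevalence


class KmerPrevalenceScorer:
    """Membership scorer: 1 if the 9-mer is among the top-k most prevalent
    canonical donor 9-mers, else 0."""

    kind = "kmer_prevalence"

    def __init__(self, members: Iterable[str]):
        self.members = frozenset(m.upper() for m in members)

    def score(self, seq: str) -> float:
        return 1.0 if seq.upper() in self.members else 0.0


def build_kmer_prevalence_scorer(canonical_windows: Iterable[str],
                                 top_k: int = 1000) -> KmerPrevalenceScorer:
    """Collect the ``top_k`` most frequent canonical donor 9-mers.

    Ties at rank ``top_k`` are broken lexicographically; if fewer than
    ``top_k`` distinct 9-mers exist, all are kept.
    """
    import logging

    counts = Counter(w.upper() for w in canonical_windows if "N" not in w.upper())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < top_k:
        logging.getLogger(__name__).warning(
            "only %d distinct canonical 9-mers (< top_k=%d); keeping all",
            len(ranked), top_k)
    return KmerPrevalenceScorer(k for k, _ in ranked[:top_k])


# ---------------------------------------------------------------------------
# calibration & classification


def calibrate_threshold(canonical_scores, detect_fraction: float = 0.90) -> float:
    """Score threshold detecting ``detect_fraction`` of positive canonical donors.

    Restricted to scores > 0 (the positive mode of the bimodal canonical
    distribution); returns the empirical (1 - detect_fraction) quantile with
    lower-value interpolation, so at least ``detect_fraction`` of the positive
    scores are >= the threshold.
    """
    import logging

    scores = np.asarray([s for s in canonical_scores if s is not None], dtype=float)
    positive = scores[scores > 0]
    if positive.size == 0:
        raise ValueError("no positive canonical scores; cannot calibrate threshold")
    if positive.size < 10:
        logging.getLogger(__name__).warning(
            "only %d positive canonical scores; threshold is unstable", positive.size)
    if not 0 < detect_fraction <= 1:
        raise ValueError("detect_fraction must be in (0, 1]")
    return float(np.quantile(positive, 1.0 - detect_fraction, method="lower"))


@dataclass(frozen=True)
class RsClassification:
    exon_id: str
    rs_5ss_score: Optional[float]
    canonical_5ss_score: Optional[float]
    threshold: float
    label: str                 # "RS" | "nonRS"
    unscorable: bool = False


def classify_exons(trios: Sequence[InternalExonTrio], genome, scorer,
                   threshold: float) -> list[RsClassification]:
    """Label each internal exon RS/nonRS by its reconstituted C1A donor score.

    The comparison is strict (> threshold).  Windows containing N or running
    off-contig are labelled nonRS with the ``unscorable`` flag set.
    """
    out = []
    for t in trios:
        try:
            w = junction_9mer(genome, t)
            rs_score = score_window(scorer, SpliceSiteWindow(w, "reconstituted"))
        except WindowUnavailable:
            rs_score = None
        from .annotation import ExonRecord

        a = ExonRecord(t.gene_id, "", t.chrom, t.strand, t.a_start, t.a_end)
        try:
            canon = score_window(scorer, SpliceSiteWindow(
                canonical_9mer(genome, a), "canonical"))
        except WindowUnavailable:
            canon = None
        if rs_score is None:
            out.append(RsClassification(t.exon_id, None, canon, threshold,
                                        "nonRS", unscorable=True))
        else:
            label = "RS" if rs_score > threshold else "nonRS"
            out.append(RsClassification(t.exon_id, rs_score, canon, threshold, label))
    return out


def classifications_to_frame(records: Iterable[RsClassification]) -> pd.DataFrame:
    return pd.DataFrame([{
        "exon_id": r.exon_id, "rs_5ss_score": r.rs_5ss_score,
        "canonical_5ss_score": r.canonical_5ss_score,
        "threshold": r.threshold, "label": r.label, "unscorable": r.unscorable,
    } for r in records])


# ---------------------------------------------------------------------------
# internal 5ss / microexon scan


@dataclass(frozen=True)
class MicroexonCandidate:
    """A candidate internal donor within the first nucleotides of a host exon.

    ``offset`` is the distance (nt) from the C1A junction to the donor
    cleavage point: offset 0 is the RS-5ss itself; offsets 1..15 imply a
    cryptic microexon of that length.
    """

    host_exon_id: str
    offset: int
    score: float

    @property
    def microexon_length(self) -> int:
        return self.offset


def scan_internal_5ss(host_seq_with_context: str, scorer, min_score: float,
                      host_exon_id: str = "", max_offset: int = 15,
                      min_host_len: int = 21) -> list[MicroexonCandidate]:
    """Scan the start of a host exon for donors within ``max_offset`` nt of the
    C1A junction.

    ``host_seq_with_context``: the last 3 nt of the upstream exon followed by
    the host exon sequence, in transcript orientation.  A candidate is emitted
    at every offset whose 9-mer (3 nt ending at the offset + next 6 nt) scores
    >= ``min_score`` (inclusive, matching the "at least" selection rule).
    Hosts shorter than ``min_host_len`` yield no candidates.
    """
    context = host_seq_with_context.upper()
    host_len = len(context) - 3
    if host_len < min_host_len:
        return []
    out = []
    for k in range(0, max_offset + 1):
        if k + WINDOW_LEN > len(context):
            break
        window = context[k:k + WINDOW_LEN]
        if "N" in window:
            continue
        s = scorer.score(window)
        if s >= min_score:
            out.append(MicroexonCandidate(host_exon_id, k, float(s)))
    return out


# ---------------------------------------------------------------------------
# cross-species summary


@dataclass(frozen=True)
class SpeciesRsSummary:
    threshold: float
    n_exons: int
    n_rs: int
    proportion: float
    n_unscorable: int = 0


def species_rs_proportion(annotation, genome, scorer,
                          detect_fraction: float = 0.90,
                          unique_donors: bool = False) -> SpeciesRsSummary:
    """Proportion of internal exons classified RS for one species.

    Calibrates the threshold on canonical exon-intron donors of all
    non-terminal exons (optionally de-duplicated to unique donor sites),
    builds trios from nearest annotated neighbours, and classifies.
    """
    from .annotation import build_trios

    canonical: list[float] = []
    seen_donors: set[tuple] = set()
    n_excluded = 0
    for tid, txe in annotation.transcripts.items():
        for ex in txe[:-1]:
            if unique_donors:
                donor_key = (ex.chrom, ex.strand,
                             ex.end if ex.strand == "+" else ex.start)
                if donor_key in seen_donors:
                    continue
                seen_donors.add(donor_key)
            try:
                w = canonical_9mer(genome, ex)
            except WindowUnavailable:
                n_excluded += 1
                continue
            s = score_window(scorer, SpliceSiteWindow(w, "canonical"))
            if s is None:
                n_excluded += 1
                continue
            canonical.append(s)
    threshold = calibrate_threshold(canonical, detect_fraction)
    trios, _ = build_trios(annotation)
    records = classify_exons(trios, genome, scorer, threshold)
    n_rs = sum(1 for r in records if r.label == "RS")
    n_unscorable = sum(1 for r in records if r.unscorable)
    n = len(records)
    return SpeciesRsSummary(threshold, n, n_rs, n_rs / n if n else 0.0, n_unscorable)
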