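# Methods

This note documents the models, conventions and numerical choices behind
`rsjunction`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate conventions

GTF input is 1-based closed; every internal junction computation is 0-based
half-open. The `start0`/`end0` properties on exon and trio records are the
only converters. STAR `SJ.out.tab` intron coordinates (1-based closed) are
converted on read. An intron is stored as `(first intronic base, one past
the last intronic base)` in genomic orientation; a junction anchor for
profiling is the genomic coordinate of the first transcript-downstream base.

## Internal exons and trios

An internal exon has at least one upstream and one downstream neighbour in
some transcript of its (protein-coding) gene; one trio is built per unique
internal exon per gene. When a junction-count table is supplied, C1 and C2
are the partners whose connecting junction has the highest uniquely-mapped
read count; otherwise the nearest annotated neighbour is used, and the
provenance flag records which rule applied. Ties in read count are broken by
the shorter intron — the more local splicing event, the biologically
conservative choice — then by coordinates, so partner selection is
deterministic. Exons lacking a neighbour on either side are excluded and
counted in the skip report. The biotype filter keys on
`gene_biotype`/`gene_type` and passes records without any biotype attribute,
so annotations lacking biotypes are usable without a switch.

## Donor windows and scorers

All donor contexts are 9-mers: 3 exonic + 6 intronic nt (positions −3…+6).
The reconstituted RS-5ss window is the last 3 nt of C1 joined to the first
6 nt of A; the canonical window is the last 3 nt of an exon joined to the
first 6 intronic nt. Windows containing N or running off-contig are
unscorable and are excluded from calibration (with counts reported) and
labelled nonRS with a flag in classification.

Three scorers share one interface (`score(9-mer) -> float`):

- **Maximum-entropy donor model.** The model table is an external input —
  either the classic list of 4^7 floats over the seven non-consensus
  positions (lexicographic, A<C<G<T) or keyed `7MER<TAB>value` lines. The
  consensus +1/+2 positions are scored against background with the published
  constants, and the final score is `log2(consensus_ratio · P_table(rest))`.
  Tests verify the implementation bit-for-bit against an independent
  re-derivation on a synthetic table; pointing `RSJUNCTION_MAXENT_5SS` at a
  real table extends the check to it.
- **Built-in donor PWM** (`default_donor_pwm`): log2-odds against a uniform
  background over a human-like donor frequency matrix whose per-position
  argmax is the consensus CAG|GTAAGT (score 12.9). This self-contained
  scorer drives all synthetic analyses.
- **Top-k 9-mer prevalence**: membership (0/1) in the `top_k = 1000` most
  frequent canonical donor 9-mers, ties at the boundary broken
  lexicographically — the annotation-only scorer for cross-species
  comparisons.

**Threshold calibration** restricts canonical scores to the positive mode
(> 0) of their bimodal distribution, then returns the empirical
`(1 − detect_fraction)` quantile with *lower* interpolation, so the
guarantee "at least `detect_fraction` of positive canonical donors score at
or above the threshold" holds exactly. RS classification uses the strict
`score > threshold` rule; the internal-5ss/microexon scan uses the inclusive
`score >= min_score` rule (default 5.52). The two comparisons follow the
two selection rules as stated, and both are exposed as configuration.
Unique-donor de-duplication before calibration is available
(`unique_donors=True`) but off by default.

The microexon scan examines hosts of ≥ 21 nt at offsets 0–15 from the C1A
junction; offset 0 is the RS-5ss itself, offset k ≥ 1 implies a k-nt cryptic
microexon.

## PSI, dPSI and categories

`PSI = 50·(up+down) / (skip + 50·(up+down))`, evaluated exactly and stored
as a proportion in [0, 1]; reports convert to percent at the printing layer
only. All three counts zero means PSI is undefined (the exon is not
expressed there) rather than zero, to avoid fabricating skipping. The
coverage filter on total junction reads per exon across samples (10 for
most datasets, 200 for deep compendia) is inclusive (≥). Collation sums
junction counts per key across the files of one study.

`dPSI = PSI_KD − mean(PSI_controls)`; negative = more skipping upon
knockdown. Inclusion categories on the proportion scale: alternative
(0.15, 0.85), highly-included alternative [0.85, 0.98], constitutive
(0.98, 1]; values at exactly 0.85 and 0.98 go to the middle band so the
partition is total, and PSI ≤ 0.15 is reported as lowly-included. The
coarse split is included (≥ 0.90) vs alternative.

## The signed rank-sum scan

At each threshold in the grid (default −20…8 step 1; a −40…8 preset ships
as well), dPSI values of exons with score > t are compared with the rest by
a two-sided Mann-Whitney test: the exact null distribution when both sides
have < 25 untied observations, otherwise the normal approximation with tie
correction. The sign is −1 when the high-score group's rank-sum statistic
falls below its null expectation. Thresholds with fewer than two exons on
either side yield a missing value rather than an error. The display value
is sign·(−log10 p); the raw (sign, p) pair is always emitted. No
multiple-testing correction is applied across thresholds — the scan is a
descriptive profile. Equal-count score bins (`bin_dpsi_by_score`) differ in
size by at most one and are labelled by the midpoint of their score range.

## PURS

Per sensitive exon the junction library holds C1–C2, C1–A, A–C2 and one RS
event junction per candidate offset k: the event joins C1 plus the first k
nt of A to C2 (for k = 0 the sequence coincides with the C1–C2 skip
junction, the full-skipping product). Flanks default to `read_len − 1 = 49`
nt — the shortest length at which every mappable placement exists — and are
truncated at exon boundaries, with mappable positions recomputed; the
closed-form count (`read_len − 2·min_overhang + 1` with ample flanks) is
tested against exhaustive placement enumeration. Raw counts are divided by
mappable positions; since PURS is a ratio, any common rescaling cancels.
`PURS = 100·RS / ((C1A + AC2)/2)`, undefined on a zero denominator. Event
calling requires dPURS ≥ 10, donor score ≥ 5.52 and raw RS-junction read
support ≥ 10 summed over the two conditions (the stricter, uncorrected
reading of read support).

## Splicing order

A pair votes upstream-first when one mate's alignment gap matches the
C1–A intron exactly and the other mate overlaps the downstream intron by
≥ 1 nt without carrying any splice gap; the reciprocal votes
downstream-first; everything else is uninformative, including mates whose
gap does not match the annotated intron. Requiring intronic mates to be
ungapped is the conservative resolution of an ambiguity in how far an
intron-overlapping mate may extend. Exons with fewer than 10 informative
pairs are dropped.

## iCLIP profiles

Crosslinks sit one nt upstream of the read start (truncation convention;
the offset is configurable, 0 reproduces read starts). PCR duplicates —
same UMI, same position — collapse to one cDNA; the UMI is the last
colon-separated field of the read name. Gapped reads profile exon–exon
junctions, ungapped reads exon–intron junctions, over a default window of
−50…0 nt. Junctions with ≤ 1 crosslink summed over all replicates are
excluded before counting and do not enter the normaliser. Frequencies are
counts divided by (number of evaluated junctions × library total).

LOESS smoothing uses tricube weights and local quadratic fits by default
(span 0.2); at degree 1 the implementation reproduces standard lowess, the
oracle used in tests. Confidence bands are mean ± 1.96·SEM across replicate
smoothed profiles — a pragmatic construction, since the band definition is
otherwise open. Peak comparison is a two-sided independent-samples t-test
on per-replicate mean frequencies in the −14…−12 window (the per-junction
alternative is not implemented). Group-coverage normalisation divides each
group by its share `f(group) = sum(ref_group)/Σ sums` of a reference
coverage; factors sum to 1 and zero-reference groups are dropped with a
reason. This normalisation and the per-junction normalisation are
independent switches, since how they compose is ambiguous.

## Lariat detection

Candidate branchpoints are an input; the default generator pairs every
position 18–45 nt upstream of a 3′ss with the exon's 5′ end. The full
branchpoint-inference machinery of prior lariat work is not re-implemented;
"high-confidence pairing" is operationalised as ≥ 2 independent supporting
reads and labelled as a stand-in in output metadata. A reference is the
genomic window ending at the branchpoint followed by the window starting at
the exon 5′ end, both strand-oriented. A hit is an ungapped alignment
crossing the branch junction with ≥ 8 nt on each side and exactly one
mismatch, located at the branchpoint; the branchpoint base is reported from
the genomic reference, because the read is mismatched there by
construction. Detection is vectorised (byte-encoded comparison over all
offsets), so ten thousand decoys scan in seconds.

## Synthetic data

Generators emulate the statistical structure of the real inputs, one gene
per chromosome with alternating strands, three exons per gene by default so
each internal exon owns its junctions (no sharing between measured exons):

- Canonical donors are sampled per position from the built-in PWM
  frequencies. Planted RS-exons start with GTAAGT/GTGAGT behind a
  CAG-ending C1, scoring ≥ 12 — above any calibrated threshold — so planted
  labels are unambiguous; non-RS internal exons start with CC, killing the
  reconstituted window. Microexon hosts carry the same strong motif at a
  random offset; offsets start at 3 so the motif sits wholly inside the
  exon, and the first ~24 nt outside planted motifs are C-filled so the
  scan finds exactly the planted donor.
- Junction counts: per exon and sample, coverage N ~ Poisson(depth) is
  thinned binomially with the inclusion probability q = ψ/(50 − 49ψ), the
  transform under which the weighted PSI formula recovers the planted ψ.
  Knockdown samples shift ψ by the planted dPSI at RS exons only; `noise`
  is a per-sample Gaussian jitter on ψ. An overdispersed variant was left
  out: the estimator tests target the formula's fixed point, not a
  dispersion model.
- Junction-library reads: per-molecule intensities RS = u, C1A = 1,
  A–C2 = 1 − u, C1–C2 = 0.05, with raw Poisson counts scaled by each
  entry's mappable fraction so corrected counts are unbiased; expected
  PURS = 200u/(2 − u), and the knockdown usage is solved from the planted
  dPURS target (default 20).
- iCLIP: library totals are fixed; a `peak_weight` (default 0.05) share of
  each library sits at the planted offset (−13) on RS junctions, multiplied
  by the enrichment factor in knockdown libraries; the rest is uniform over
  all junction windows. With these defaults the knockdown/control peak
  ratio recovers the enrichment to within the uniform-background dilution
  (a few percent).
- Read pairs are emitted directly at alignment level (blocks), with the
  planted upstream-first probability; lariat reads copy a reference window
  with the branchpoint base substituted, plus genomic decoy reads.

All generators consume an integer seed and reproduce outputs byte-for-byte.

**What passing tests show — and do not.** The synthetic data have planted,
well-separated donor scores, independent exons, uniform backgrounds, no
sequencing errors (beyond the lariat branchpoint mismatch), no multimapping
and no overlapping transcripts. Recovery on them validates the estimators,
conventions and statistics, not robustness to alignment artefacts, overdispersed
counts, annotation errors or donor-score ambiguity in real libraries.

## Problem sizes

Default test and acceptance runs use 10–200 genes, junction depths of
500–2000, 20k crosslinks per iCLIP library with 4+4 replicates, 50 read
pairs per exon across 100 exons, and 10k lariat decoys — sizes at which
every planted effect is comfortably detectable while the full suite runs in
well under ten minutes on one CPU.

## Known limitations

- Real-data alignment (STAR/bowtie/Hisat2) is upstream of this package;
  inputs are junction tables, alignment records or read sequences. The
  50-nt sliding-window read-trimming recipe for junction-library mapping is
  likewise an upstream preprocessing concern.
- No 3′ss model, no H-bond donor metric, no isoform-level PSI, no
  trans-splicing or liftover, no statistical branchpoint model or U2
  pairing energies.
- The scan reports raw per-threshold p-values by design; treat the profile
  descriptively rather than as a family of corrected tests.
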