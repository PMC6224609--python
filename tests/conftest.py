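"""Shared fixtures: synthetic datasets and a hand-built miniature locus."""

import pytest

import rsjunction as rj
from rsjunction import synth
from rsjunction.genome import GenomeSequence
from rsjunction.annotation import InternalExonTrio


@pytest.fixture(scope="session")
def small_dataset():
    """40 genes, 30% RS-exons, 20% microexon hosts."""
    return synth.make_genome_annotation(
        n_genes=40, rs_fraction=0.3, microexon_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def trios(small_dataset):
    _, annotation, _ = small_dataset
    trio_list, report = rj.build_trios(annotation)
    assert report["no_upstream"] == report["no_downstream"] == 0
    return trio_list


@pytest.fixture(scope="session")
def pwm():
    return rj.default_donor_pwm()


@pytest.fixture(scope="session")
def calibrated_threshold(small_dataset, pwm):
    genome, annotation, _ = small_dataset
    scores = []
    for tid, txe in annotation.transcripts.items():
        for ex in txe[:-1]:
            w = rj.canonical_9mer(genome, ex)
            scores.append(pwm.score(w))
    return rj.calibrate_threshold(scores, 0.90)


# A hand-built plus-strand locus with known sequence content:
#   C1 (30 nt, ends ...CAG) - intron1 (40 nt, starts GTGAGT) -
#   A  (30 nt, starts GTAAGT) - intron2 (40 nt) - C2 (30 nt)
MINI_C1 = "TTTTTTTTTTTTTTTTTTTTTTTTTTTCAG"
MINI_I1 = "GTGAGT" + "A" * 34
MINI_A = "GTAAGT" + "G" * 24
MINI_I2 = "C" * 40
MINI_C2 = "T" * 30
MINI_SEQ = MINI_C1 + MINI_I1 + MINI_A + MINI_I2 + MINI_C2


@pytest.fixture(scope="session")
def mini_locus():
    genome = GenomeSequence({"chrM": MINI_SEQ})
    trio = InternalExonTrio(
        gene_id="GM", chrom="chrM", strand="+",
        a_start=71, a_end=100, c1_start=1, c1_end=30,
        c2_start=141, c2_end=170, provenance="annotated")
    return genome, trio


def gtf_line(chrom, start, end, strand, gene, tx, biotype="protein_coding",
             feature="exon"):
    attrs = f'gene_id "{gene}"; transcript_id "{tx}"; gene_biotype "{biotype}";'
    return "\t".join([chrom, "test", feature, str(start), str(end), ".",
                      strand, ".", attrs])
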