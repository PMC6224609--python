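"""Classify putative RS-exons from reconstituted exon-exon donor windows.

Generates a synthetic genome in which 30% of internal exons begin with a
strong donor six-mer (so the junction to the preceding exon reconstitutes a
5' splice site), calibrates the score threshold on canonical exon-intron
donors, and labels every internal exon RS or nonRS.
"""

import rsjunction as rj
from rsjunction import synth
from rsjunction.scoring import SpliceSiteWindow, score_window

genome, annotation, truth = synth.make_genome_annotation(
    n_genes=60, rs_fraction=0.3, seed=1)
pwm = rj.default_donor_pwm()

canonical = [score_window(pwm, SpliceSiteWindow(rj.canonical_9mer(genome, ex)))
             for txe in annotation.transcripts.values() for ex in txe[:-1]]
threshold = rj.calibrate_threshold(canonical, detect_fraction=0.90)

trios, _ = rj.build_trios(annotation)
records = rj.classify_exons(trios, genome, pwm, threshold)
n_rs = sum(r.label == "RS" for r in records)
correct = sum((r.exon_id in set(truth.rs_exons())) == (r.label == "RS")
              for r in records)

print(f"threshold detecting 90% of canonical donors: {threshold:.2f}")
print(f"internal exons: {len(records)}; classified RS: {n_rs} "
      f"(planted: {len(truth.rs_exons())})")
print(f"agreement with planted labels: {correct}/{len(records)}")
# The threshold is the score exceeded by 90% of positive canonical donors;
# exons whose reconstituted window scores above it are putative RS-exons.
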