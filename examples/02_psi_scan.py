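"""Quantify exon inclusion (PSI), knockdown dPSI, and run the signed scan.

Simulates control and knockdown junction-count tables in which only
RS-labelled exons lose 0.2 PSI upon knockdown, then tests — at a sliding
RS-5ss score threshold — whether high-score exons skew toward skipping.
"""

import numpy as np

import rsjunction as rj
from rsjunction import synth

genome, annotation, truth = synth.make_genome_annotation(
    n_genes=200, rs_fraction=0.1, kd_dpsi=-0.2, seed=2)
trios = truth.trios()

samples = synth.simulate_junction_counts(truth, depth=500, n_control=3,
                                         n_kd=1, noise=0.02, seed=3)
frame = rj.psi_table(trios, list(samples.values()))
frame, report = rj.filter_exons(frame, min_total_junction_reads=10)
dpsi = rj.delta_psi_table(frame, "kd_0", ["control_0", "control_1",
                                          "control_2"])

records = rj.classify_exons(trios, genome, rj.default_donor_pwm(),
                            threshold=4.0)
scores = {r.exon_id: r.rs_5ss_score for r in records}
dpsi["score"] = dpsi["exon_id"].map(scores)

scan = rj.signed_wilcoxon_scan(dpsi["score"], dpsi["dpsi"], np.arange(-20, 9))
print(f"exons quantified: {report['n_retained']}; "
      f"mean dPSI at RS exons: "
      f"{dpsi[dpsi['score'] > 4]['dpsi'].mean():+.3f}")
print(scan[scan["threshold"].isin([0, 2, 4, 6])].to_string(index=False))
# A negative sign with small p at thresholds near the donor-strength boundary
# means exons with strong reconstituted donors skip more upon knockdown --
# the recursive-splicing signature.
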