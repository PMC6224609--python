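"""Profile spliceosome crosslinks upstream of exon-exon junctions.

Simulates iCLIP libraries with a crosslink peak 13 nt upstream of RS-exon
junctions that grows 5-fold upon knockdown, builds normalized profiles,
smooths them with LOESS, and tests the peak difference between conditions.
"""

import numpy as np

from rsjunction import synth
from rsjunction.iclip import compare_peak, junction_profile, smooth_profile

_, _, truth = synth.make_genome_annotation(n_genes=20, rs_fraction=0.4, seed=6)
libs, sites = synth.simulate_iclip(truth, n_replicates=4, n_crosslinks=20000,
                                   peak_offset=-13, enrichment=5.0, seed=7)

ctrl = {f"ctrl_{r}": df for (c, r), df in libs.items() if c == "control"}
kd = {f"kd_{r}": df for (c, r), df in libs.items() if c == "kd"}
ctrl_rs = [p for p in junction_profile(ctrl, sites, gapped=True)
           if p.group == "RS"]
kd_rs = [p for p in junction_profile(kd, sites, gapped=True)
         if p.group == "RS"]

smoothed = smooth_profile(kd_rs, span=0.2)
peak_row = smoothed.loc[smoothed["mean"].idxmax()]
t, p = compare_peak(kd_rs, ctrl_rs, peak_window=(-14, -12))

print(f"knockdown RS profile maximum at distance {peak_row['distance']:.0f} "
      f"(planted -13)")
print(f"peak comparison KD vs control: t = {t:.2f}, p = {p:.2e}")
# Crosslink distances are measured from read truncation sites to the
# junction; a peak 12-14 nt upstream marks spliceosome engagement of the
# reconstituted 5' splice site, which strengthens when the EJC is depleted.
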