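"""End-to-end orchestration: trios -> classification -> PSI/dPSI -> scan.

The pipeline consumes a declarative configuration, runs the stages whose
inputs are available, writes one TSV per stage plus a JSON run report with
seeds, thresholds and filter counts, and is idempotent for identical inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .annotation import (build_trios, canonical_9mer, load_annotation,
                         write_trios)
from .genome import GenomeSequence
from .psi import collate, delta_psi_table, filter_exons, psi_table, read_sj_table
from .scoring import (MaxEntDonorScorer, calibrate_threshold,
                      classifications_to_frame, classify_exons,
                      default_donor_pwm, score_window, SpliceSiteWindow)
from .stats import THRESHOLD_GRID_DEFAULT, signed_wilcoxon_scan

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths, thresholds and convention switches for a pipeline run.

    All thresholds are echoed into the run report.  PSI-scale values are
    proportions in [0, 1].
    """

    genome_fasta: str = ""
    annotation_gtf: str = ""
    out_dir: str = "rsjunction_out"
    scorer: str = "pwm"                  # pwm | maxent
    maxent_table: Optional[str] = None
    detect_fraction: float = 0.90
    min_total_junction_reads: int = 10
    control_sj: Sequence[str] = field(default_factory=list)
    kd_sj: Sequence[str] = field(default_factory=list)
    scan_grid: Sequence[float] = field(default_factory=lambda:
                                       [float(t) for t in THRESHOLD_GRID_DEFAULT])
    scan_min_psi: float = 0.98           # constitutive-exon restriction
    seed: int = 0

    def validate(self) -> None:
        if not self.genome_fasta or not Path(self.genome_fasta).exists():
            raise ConfigError(f"genome FASTA not found: {self.genome_fasta!r}")
        if not self.annotation_gtf or not Path(self.annotation_gtf).exists():
            raise ConfigError(f"annotation GTF not found: {self.annotation_gtf!r}")
        if self.scorer not in ("pwm", "maxent"):
            raise ConfigError(f"unknown scorer {self.scorer!r}")
        if self.scorer == "maxent" and not self.maxent_table:
            raise ConfigError("maxent scorer requires a model table path")
        for p in [*self.control_sj, *self.kd_sj]:
            if not Path(p).exists():
                raise ConfigError(f"SJ table not found: {p!r}")

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _make_scorer(config: PipelineConfig):
    if config.scorer == "maxent":
        return MaxEntDonorScorer.from_table(config.maxent_table)
    return default_donor_pwm()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages the configuration provides inputs for.

    Always: trios + RS classification (threshold calibrated on canonical
    donors at ``detect_fraction``).  With SJ tables: PSI, dPSI (first KD
    sample vs the mean of controls) and the signed rank-sum scan over
    constitutive exons.  Returns the run report (also written as JSON).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "stages": {}, "thresholds": {
                        "detect_fraction": config.detect_fraction,
                        "min_total_junction_reads": config.min_total_junction_reads,
                        "scan_min_psi": config.scan_min_psi}}
    t0 = time.time()

    genome = GenomeSequence.from_fasta(config.genome_fasta)
    annotation = load_annotation(config.annotation_gtf)
    scorer = _make_scorer(config)

    trios, trio_report = build_trios(annotation)
    write_trios(trios, out / "trios.tsv")
    report["stages"]["trios"] = trio_report

    canonical = []
    for tid, txe in annotation.transcripts.items():
        for ex in txe[:-1]:
            try:
                w = canonical_9mer(genome, ex)
            except ValueError:
                continue
            s = score_window(scorer, SpliceSiteWindow(w, "canonical"))
            if s is not None:
                canonical.append(s)
    threshold = calibrate_threshold(canonical, config.detect_fraction)
    records = classify_exons(trios, genome, scorer, threshold)
    cls_frame = classifications_to_frame(records)
    cls_frame.to_csv(out / "classification.tsv", sep="\t", index=False)
    report["stages"]["classification"] = {
        "threshold": threshold, "n_exons": len(records),
        "n_rs": int((cls_frame["label"] == "RS").sum())}

    if config.control_sj and config.kd_sj:
        controls = [collate([read_sj_table(p, sample_id=f"control_{i}")])
                    for i, p in enumerate(config.control_sj)]
        kds = [read_sj_table(p, sample_id=f"kd_{i}")
               for i, p in enumerate(config.kd_sj)]
        frame = psi_table(trios, controls + kds)
        frame, filt = filter_exons(frame, config.min_total_junction_reads)
        frame.to_csv(out / "psi.tsv", sep="\t", index=False)
        report["stages"]["psi"] = filt

        dpsi = delta_psi_table(frame, kds[0].sample_id,
                               [c.sample_id for c in controls])
        dpsi.to_csv(out / "dpsi.tsv", sep="\t", index=False)
        report["stages"]["dpsi"] = {"n_exons": len(dpsi)}

        merged = dpsi.merge(cls_frame[["exon_id", "rs_5ss_score"]], on="exon_id")
        merged = merged.dropna(subset=["rs_5ss_score"])
        scan_in = merged[merged["control_mean_psi"] > config.scan_min_psi]
        if len(scan_in) >= 4:
            scan = signed_wilcoxon_scan(scan_in["rs_5ss_score"],
                                        scan_in["dpsi"], config.scan_grid)
            scan.to_csv(out / "scan.tsv", sep="\t", index=False)
            report["stages"]["scan"] = {
                "n_exons": len(scan_in),
                "n_thresholds": int(scan["p"].notna().sum())}
        else:
            report["stages"]["scan"] = {"skipped": "too few constitutive exons",
                                        "n_exons": len(scan_in)}

    report["runtime_s"] = round(time.time() - t0, 3)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
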