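"""Exon inclusion categories, score binning, and the signed rank-sum scan.

The headline statistic: exons (typically constitutive ones, PSI > 0.98) are
split at a sliding RS-5ss score threshold into a high-score and a low-score
group, and the skew in dPSI between the groups is tested with the two-sided
Wilcoxon rank-sum (Mann-Whitney) test at each threshold.  The sign records
the direction: -1 when the high-score group's dPSI values rank lower (more
skipping upon knockdown, the recursive-splicing signature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

# inclusive/exclusive boundary choices make the partition total: values at
# exactly 0.85 and exactly 0.98 fall in the highly-included band.
CATEGORY_BANDS = (
    ("lowly_included", 0.0, 0.15),
    ("alternative", 0.15, 0.85),
    ("highly_included_alternative", 0.85, 0.98),
    ("constitutive", 0.98, 1.0),
)


def categorize(psi: Optional[float]) -> str:
    """Inclusion category on the proportion scale.

    alternative: 0.15 < psi < 0.85; highly_included_alternative:
    0.85 <= psi <= 0.98; constitutive: psi > 0.98; psi <= 0.15 is reported
    as lowly_included; undefined psi is uncategorized.
    """
    if psi is None or (isinstance(psi, float) and np.isnan(psi)):
        return "uncategorized"
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi must be a proportion in [0,1], got {psi}")
    if psi <= 0.15:
        return "lowly_included"
    if psi < 0.85:
        return "alternative"
    if psi <= 0.98:
        return "highly_included_alternative"
    return "constitutive"


def categorize_coarse(psi: Optional[float], cutoff: float = 0.90) -> str:
    """Coarse split into highly included (psi >= cutoff) vs alternative."""
    if psi is None or (isinstance(psi, float) and np.isnan(psi)):
        return "uncategorized"
    return "included" if psi >= cutoff else "alternative"


def as_percent(psi: float) -> float:
    """Proportion -> percentage, the single conversion point for reports."""
    return 100.0 * psi


# ---------------------------------------------------------------------------
# binning


@dataclass(frozen=True)
class ScoreBin:
    midpoint: float
    score_min: float
    score_max: float
    n: int
    dpsi: np.ndarray


def bin_dpsi_by_score(scores: Sequence[float], dpsis: Sequence[float],
                      n_bins: int) -> list[ScoreBin]:
    """Group dPSI values into equal-count bins ordered by RS-5ss score.

    Bin sizes differ by at most one; each bin is labelled by the midpoint of
    its score range.  Ties in score are ordered stably by input position.
    """
    scores = np.asarray(scores, dtype=float)
    dpsis = np.asarray(dpsis, dtype=float)
    if scores.shape != dpsis.shape:
        raise ValueError("scores and dpsis must have equal length")
    n = scores.size
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds number of records {n}")
    order = np.argsort(scores, kind="stable")
    out = []
    for idx in np.array_split(order, n_bins):
        s = scores[idx]
        out.append(ScoreBin(
            midpoint=float((s.min() + s.max()) / 2.0),
            score_min=float(s.min()), score_max=float(s.max()),
            n=int(idx.size), dpsi=dpsis[idx],
        ))
    return out


# ---------------------------------------------------------------------------
# signed scan

THRESHOLD_GRID_DEFAULT = np.arange(-20, 9)   # the Methods preset
THRESHOLD_GRID_WIDE = np.arange(-40, 9)      # the figure preset

SCAN_COLUMNS = ["threshold", "n_above", "n_below", "p", "sign", "signed_log10_p"]


def _ranksum_p(above: np.ndarray, below: np.ndarray, exact_max_n: int = 25
               ) -> tuple[float, int]:
    """Two-sided Mann-Whitney p and direction sign for the high-score group.

    Exact null distribution when both sides are small and untied, otherwise
    the normal approximation with tie correction.  The sign is -1 when the
    high-score group's rank-sum statistic falls below its null expectation
    (dPSI skewed lower), else +1.
    """
    n1, n2 = above.size, below.size
    ties = np.unique(np.concatenate([above, below])).size < n1 + n2
    method = "exact" if (max(n1, n2) < exact_max_n and not ties) else "asymptotic"
    res = sps.mannwhitneyu(above, below, alternative="two-sided", method=method)
    sign = -1 if res.statistic < n1 * n2 / 2.0 else 1
    return float(res.pvalue), sign


def signed_wilcoxon_scan(scores: Sequence[float], dpsis: Sequence[float],
                         thresholds: Sequence[float] = THRESHOLD_GRID_DEFAULT,
                         min_group: int = 2) -> pd.DataFrame:
    """Signed rank-sum p-value at each score threshold.

    At each threshold t the groups are dPSI of exons with score > t vs
    score <= t.  Thresholds where either side has fewer than ``min_group``
    records yield NaN (degenerate, not an error).  Columns: threshold,
    n_above, n_below, p, sign, signed_log10_p = sign * (-log10 p).
    """
    scores = np.asarray(scores, dtype=float)
    dpsis = np.asarray(dpsis, dtype=float)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != dpsis.shape:
        raise ValueError("scores and dpsis must have equal length")
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    rows = []
    for t in thresholds:
        mask = scores > t
        above, below = dpsis[mask], dpsis[~mask]
        if above.size < min_group or below.size < min_group:
            rows.append((t, int(above.size), int(below.size),
                         np.nan, 0, np.nan))
            continue
        p, sign = _ranksum_p(above, below)
        rows.append((t, int(above.size), int(below.size), p, sign,
                     sign * (-np.log10(p)) if p > 0 else np.inf * sign))
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)
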