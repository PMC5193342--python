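"""Family-based association testing directly on array intensity values.

With complete trios and every offspring affected, the within-family statistic
at a marker is the deviation of the offspring's log R ratio from the
midparent value,

    d_i = X_offspring - (X_father + X_mother) / 2,

summed over informative families.  Under the null of no transmission-linked
intensity shift E[d_i] = 0, and the conservative empirical variance
Sum d_i^2 gives the z-score z = Sum d_i / sqrt(Sum d_i^2) with a two-sided
normal reference.  Because every offspring shares the affected trait value,
any trait offset multiplies the statistic by a constant and cancels in z;
the unweighted deviation sum is therefore the whole test.

The module also provides p-value QC (genomic inflation factor, Q-Q data),
multiple-testing thresholds, and an analytic power approximation for the
log-additive case-parent transmission design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import IntensityPanel, Trio

__all__ = [
    "ScanSummary",
    "fbat_intensity_test",
    "genomic_inflation",
    "significance_thresholds",
    "qq_points",
    "tdt_power",
]

#: Median of the 1-df chi-square distribution (null expectation of the
#: median test statistic).
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))

#: Genome-wide significance threshold, fixed by convention.
GENOMEWIDE_ALPHA = 5e-8


@dataclass(frozen=True)
class ScanSummary:
    n_markers_tested: int
    bonferroni_alpha: float
    genomewide_alpha: float = GENOMEWIDE_ALPHA
    lambda_gc: float | None = None


def fbat_intensity_test(
    panel: IntensityPanel,
    pedigree: Sequence[Trio],
    marker_subset: np.ndarray | Sequence[str] | None = None,
    min_families: int = 10,
    mean_center_variance: bool = False,
) -> pd.DataFrame:
    """Scan markers with the midparent-deviation intensity test.

    A family is informative at a marker only if all three member intensities
    are finite; dropout is per marker, not per family.  Markers with fewer
    than ``min_families`` informative families, or with zero empirical
    variance, are reported but flagged untested (``tested=False``).

    ``mean_center_variance`` switches from the conservative Sum d^2 variance
    to the mean-centred Sum (d - dbar)^2 variant.

    Returns a DataFrame with one row per marker: marker_id, chromosome,
    position, n_fam, statistic_sum, empirical_variance, z, p, tested.
    """
    markers = panel.markers
    if marker_subset is not None:
        keep = np.isin(markers.marker_id, np.asarray(list(marker_subset)))
    else:
        keep = np.ones(markers.n_markers, dtype=bool)
    cols = np.flatnonzero(keep)

    idx = {s: i for i, s in enumerate(panel.sample_ids)}
    fa = np.array([idx[t.father_id] for t in pedigree])
    mo = np.array([idx[t.mother_id] for t in pedigree])
    off = np.array([idx[t.offspring_id] for t in pedigree])

    lrr = panel.lrr[:, cols]
    d = lrr[off] - 0.5 * (lrr[fa] + lrr[mo])
    finite = np.isfinite(lrr[off]) & np.isfinite(lrr[fa]) & np.isfinite(lrr[mo])
    d = np.where(finite, d, 0.0)

    n_fam = finite.sum(axis=0)
    s = d.sum(axis=0)
    if mean_center_variance:
        with np.errstate(invalid="ignore"):
            dbar = np.where(n_fam > 0, s / np.maximum(n_fam, 1), 0.0)
        v = (np.where(finite, (d - dbar) ** 2, 0.0)).sum(axis=0)
    else:
        v = (d**2).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(v > 0, s / np.sqrt(v), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)

    tested = (n_fam >= min_families) & (v > 0)
    degenerate = (n_fam > 0) & (v == 0)
    p = np.where(degenerate, 1.0, p)
    p = np.where(n_fam < min_families, np.nan, p)

    return pd.DataFrame(
        {
            "marker_id": markers.marker_id[cols],
            "chromosome": markers.chromosome[cols],
            "position": markers.position[cols],
            "n_fam": n_fam,
            "statistic_sum": s,
            "empirical_variance": v,
            "z": z,
            "p": p,
            "tested": tested,
        }
    )


def genomic_inflation(p_values: Sequence[float]) -> float:
    """Genomic inflation factor: median observed 1-df chi-square over 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def significance_thresholds(n_markers: int) -> ScanSummary:
    """Experiment-wide Bonferroni and fixed genome-wide thresholds."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return ScanSummary(n_markers_tested=n_markers, bonferroni_alpha=0.05 / n_markers)


def qq_points(p_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed p-value quantiles for a Q-Q plot.

    Expected quantiles are ranks/(n+1); observed are the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    observed = np.sort(p)
    expected = np.arange(1, p.size + 1) / (p.size + 1.0)
    return expected, observed


def tdt_power(
    n_trios: int,
    allele_frequency: float,
    odds_ratio: float,
    alpha: float = 5.6e-7,
    population_risk: float = 0.01,
) -> float:
    """Approximate power of the transmission test under a log-additive model.

    Uses the classical normal approximation to the TDT non-centrality: a
    heterozygous parent of an affected offspring transmits the risk allele
    with probability OR/(1+OR), and the expected number of heterozygous
    parents is adjusted for ascertainment under the multiplicative model.
    ``population_risk`` is accepted for interface completeness; under the
    multiplicative approximation it does not enter the non-centrality.
    Exact agreement with likelihood-based power calculators is not claimed.
    """
    del population_risk
    if not (0 < allele_frequency < 1) or odds_ratio <= 0 or not (0 < alpha < 1) or n_trios < 1:
        raise ValueError("arguments out of range")
    p, q = allele_frequency, 1.0 - allele_frequency
    tau = odds_ratio / (1.0 + odds_ratio)
    # transmitted-allele frequency given an affected child (multiplicative)
    p_star = p * odds_ratio / (p * odds_ratio + q)
    p_het = p_star * q + (1.0 - p_star) * p
    n_het = 2.0 * n_trios * p_het
    ncp = (2.0 * tau - 1.0) * np.sqrt(n_het)
    z_crit = stats.norm.isf(alpha / 2.0)
    power = stats.norm.sf(z_crit - ncp) + stats.norm.cdf(-z_crit - ncp)
    return float(power)
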