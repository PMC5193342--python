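"""Polygenic-score construction from trios and carrier-stratified association.

The trio design supplies its own controls: at each marker the affected
offspring carries the transmitted parental alleles and a matched
"pseudo-control" is built from the untransmitted ones.  A polygenic score
(risk-allele count, optionally log-OR weighted, averaged over non-missing
scored markers) is then compared between each case and its pseudo-control
by 1:1 matched conditional logistic regression (CLR).  For a matched pair
with score difference Delta_i the conditional likelihood contribution is
1 / (1 + exp(-beta * Delta_i)), so the null log-likelihood is n*log(1/2)
and the variance explained is summarized by Nagelkerke's pseudo-R^2,

    R^2 = (1 - exp(2(L0 - L1)/n)) / (1 - exp(2 L0 / n)).

The final analysis stratifies the fit by rare-CNV carrier status and
compares the carrier stratum against repeated random draws of equal size
from the non-carriers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .simulate import Trio, TrioGenotypes

__all__ = [
    "RiskAlleleSet",
    "MatchedPair",
    "ClrFit",
    "SubsampleComparison",
    "build_pseudo_controls",
    "score_prs",
    "clr_fit",
    "stratified_prs_analysis",
    "random_draw_comparison",
]


@dataclass(frozen=True)
class RiskAlleleSet:
    """Risk-allele entries with a discovery p-value inclusion threshold.

    ``entries`` maps marker index -> (weight, discovery_p); markers enter
    the score iff discovery_p < p_threshold.
    """

    entries: Mapping[int, tuple[float, float]]
    p_threshold: float = 0.1

    def included(self) -> list[int]:
        return sorted(j for j, (_, p) in self.entries.items() if p < self.p_threshold)

    def weights(self) -> dict[int, float]:
        return {j: w for j, (w, p) in self.entries.items() if p < self.p_threshold}


@dataclass(frozen=True)
class MatchedPair:
    """Transmitted (case) and untransmitted (pseudo-control) allele counts."""

    family_id: str
    case: np.ndarray  # risk-allele counts per marker, -1 missing
    pseudo_control: np.ndarray


@dataclass(frozen=True)
class ClrFit:
    beta: float
    se: float | None
    loglik_full: float
    loglik_null: float
    nagelkerke_r2: float
    p_value: float | None
    n_pairs: int
    separated: bool = False


@dataclass(frozen=True)
class SubsampleComparison:
    draws: np.ndarray  # R^2 per random draw
    mean: float
    ci_low: float
    ci_high: float
    shapiro_p: float
    comparison_p: float


def build_pseudo_controls(
    trios: Sequence[Trio],
    genotypes: TrioGenotypes,
    seed: int | None = 0,
) -> list[MatchedPair]:
    """Resolve transmission and build one matched pseudo-control per trio.

    At each marker the transmitted allele counts (t_f, t_m) must satisfy
    t_f + t_m = offspring count with t bounded by the parent's genotype;
    the pseudo-control takes the untransmitted alleles, so case plus
    pseudo-control always partition the parental alleles.  When both
    parents are heterozygous and the offspring is too, the split is
    ambiguous and resolved by a seeded coin flip.  Trios with any
    Mendelian-inconsistent marker are excluded (missing values are just
    skipped).
    """
    rng = np.random.default_rng(seed)
    fam_index = {f: i for i, f in enumerate(genotypes.families)}
    pairs: list[MatchedPair] = []
    n_markers = genotypes.n_markers
    for trio in trios:
        i = fam_index[trio.family_id]
        f, m, o = genotypes.father[i], genotypes.mother[i], genotypes.offspring[i]
        case = np.full(n_markers, -1, dtype=np.int8)
        pseudo = np.full(n_markers, -1, dtype=np.int8)
        consistent = True
        for j in range(n_markers):
            if f[j] < 0 or m[j] < 0 or o[j] < 0:
                continue
            solutions = [
                (tf, tm)
                for tf in range(2)
                for tm in range(2)
                if tf + tm == o[j]
                and (f[j] >= 1 or tf == 0)
                and (f[j] <= 1 or tf == 1)
                and (m[j] >= 1 or tm == 0)
                and (m[j] <= 1 or tm == 1)
            ]
            if not solutions:
                consistent = False
                break
            tf, tm = solutions[rng.integers(len(solutions))] if len(solutions) > 1 else solutions[0]
            case[j] = o[j]
            pseudo[j] = (f[j] - tf) + (m[j] - tm)
        if consistent:
            pairs.append(MatchedPair(trio.family_id, case, pseudo))
    return pairs


def score_prs(
    genotype_vector: np.ndarray,
    risk_set: RiskAlleleSet,
    weighted: bool = False,
) -> float:
    """Polygenic score: (weighted) risk-allele count averaged over the
    non-missing included markers.  Returns 0.0 when no marker is scorable."""
    weights = risk_set.weights()
    total = 0.0
    n_used = 0
    for j, w in weights.items():
        g = genotype_vector[j]
        if g < 0:
            continue
        total += (w if weighted else 1.0) * float(g)
        n_used += 1
    return total / n_used if n_used else 0.0


def _pair_deltas(
    pairs: Sequence[MatchedPair], risk_set: RiskAlleleSet, weighted: bool
) -> np.ndarray:
    return np.array(
        [
            score_prs(p.case, risk_set, weighted) - score_prs(p.pseudo_control, risk_set, weighted)
            for p in pairs
        ]
    )


def clr_fit(
    pairs: Sequence[MatchedPair],
    risk_set: RiskAlleleSet,
    weighted: bool = False,
    scores: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> ClrFit:
    """1:1 matched conditional logistic regression of the score on status.

    ``scores`` may directly supply the per-pair case-minus-control score
    differences, bypassing the risk set.  The conditional likelihood is
    maximized by Newton iteration; complete separation (all non-zero
    differences of one sign) is flagged and reported without a CI.
    """
    delta = np.asarray(scores, float) if scores is not None else _pair_deltas(pairs, risk_set, weighted)
    n = delta.size
    if n < 1:
        raise ValueError("at least one matched pair is required")
    l0 = n * np.log(0.5)
    nz = delta[delta != 0]
    if nz.size == 0:
        return ClrFit(0.0, None, l0, l0, 0.0, 1.0, n)
    separated = np.all(nz > 0) or np.all(nz < 0)

    beta = 0.0
    for _ in range(max_iter):
        eta = beta * delta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = float((delta * (1.0 - p)).sum())
        hess = float((delta**2 * p * (1.0 - p)).sum())
        if hess <= 0:
            break
        step = grad / hess
        beta += step
        if abs(step) < tol or abs(beta) > 30:
            break

    eta = beta * delta
    l1 = float(-np.logaddexp(0.0, -eta).sum())
    r2 = float((1.0 - np.exp(2.0 * (l0 - l1) / n)) / (1.0 - np.exp(2.0 * l0 / n)))
    r2 = min(max(r2, 0.0), 1.0)
    if separated:
        return ClrFit(beta, None, l1, l0, r2, None, n, separated=True)
    hess = float((delta**2 * (1.0 / (1.0 + np.exp(-beta * delta))) * (1.0 / (1.0 + np.exp(beta * delta)))).sum())
    se = 1.0 / np.sqrt(hess) if hess > 0 else None
    lrt = 2.0 * (l1 - l0)
    p_value = float(stats.chi2.sf(max(lrt, 0.0), 1))
    return ClrFit(beta, se, l1, l0, r2, p_value, n)


def stratified_prs_analysis(
    pairs: Sequence[MatchedPair],
    risk_set: RiskAlleleSet,
    carrier_labels: Mapping[str, bool],
    weighted: bool = False,
) -> dict[str, ClrFit]:
    """Fit the CLR separately in the carrier and non-carrier strata.

    ``carrier_labels`` maps family_id -> True for rare-CNV carrier
    families.  Families missing from the mapping are treated as
    non-carriers.
    """
    carrier = [p for p in pairs if carrier_labels.get(p.family_id, False)]
    noncarrier = [p for p in pairs if not carrier_labels.get(p.family_id, False)]
    out: dict[str, ClrFit] = {}
    if carrier:
        out["carrier"] = clr_fit(carrier, risk_set, weighted)
    if noncarrier:
        out["non_carrier"] = clr_fit(noncarrier, risk_set, weighted)
    return out


def random_draw_comparison(
    noncarrier_pairs: Sequence[MatchedPair],
    risk_set: RiskAlleleSet,
    carrier_r2: float,
    draw_size: int = 116,
    n_draws: int = 10,
    weighted: bool = False,
    seed: int | None = None,
) -> SubsampleComparison:
    """Compare the carrier-stratum R^2 against equal-size non-carrier draws.

    Draws ``n_draws`` subsamples of ``draw_size`` non-carrier pairs without
    replacement, refits the CLR in each, checks the R^2 draws for normality
    (Shapiro-Wilk) and tests the carrier R^2 against the draw distribution
    with a two-tailed one-sample t-test.
    """
    if n_draws < 3:
        raise ValueError("need at least 3 draws for the t-test")
    if draw_size > len(noncarrier_pairs):
        raise ValueError("draw_size exceeds the non-carrier stratum")
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_draws)
    pairs = list(noncarrier_pairs)
    for i in range(n_draws):
        idx = rng.choice(len(pairs), size=draw_size, replace=False)
        r2s[i] = clr_fit([pairs[j] for j in idx], risk_set, weighted).nagelkerke_r2
    mean = float(r2s.mean())
    sem = float(r2s.std(ddof=1) / np.sqrt(n_draws)) if n_draws > 1 else 0.0
    t_crit = stats.t.ppf(0.975, n_draws - 1)
    shapiro_p = float(stats.shapiro(r2s)[1]) if np.ptp(r2s) > 0 else 1.0
    t_res = stats.ttest_1samp(r2s, carrier_r2)
    return SubsampleComparison(
        draws=r2s,
        mean=mean,
        ci_low=mean - t_crit * sem,
        ci_high=mean + t_crit * sem,
        shapiro_p=shapiro_p,
        comparison_p=float(t_res.pvalue),
    )
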