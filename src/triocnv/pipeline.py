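"""Rare-CNV calling, trio validation and the QC filter chain.

The chain turns per-sample intensity data (or externally produced call
lists) into QC-passed, trio-validated, rare, large CNV regions.  The fixed
stage order is:

    call -> trio origin -> size/marker filter -> sample QC pass 1
         -> blacklist filter -> group/rarity -> sample QC pass 2
         (rare-call criterion) -> segmental-duplication filter -> merge

with a report recording the number of calls and trios removed at each stage.
Thresholds follow the conventions of array-CNV practice: calls need >= 30
markers and >= 100 kb, trios are dropped when any member has >= 50 calls or
LRR standard deviation > 0.3 (second pass: >= 10 rare calls), calls within
20 kb of each other group into one region, regions at frequency <= 1% are
rare, calls covered > 50% by segmental duplications are artifacts, and
same-type adjacent calls merge when the gap is < 20% of the merged span.

Inclusive boundaries apply to >=-style thresholds and strict ones to
>-style thresholds throughout.  Coordinates are 1-based inclusive; BED
input is converted at the reader boundary (see io module).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.special import gammaln

from .simulate import IntensityPanel, MarkerMap, Trio, TrioGenotypes

__all__ = [
    "CnvCall",
    "CnvRegion",
    "SampleQcStats",
    "MarkerQcStats",
    "CallerParams",
    "PipelineReport",
    "gc_correct",
    "lrr_sd_per_sample",
    "call_cnvs",
    "assign_trio_origin",
    "sample_qc",
    "rare_call_qc",
    "region_filter",
    "size_marker_filter",
    "group_into_regions",
    "rarity_filter",
    "segdup_filter",
    "merge_adjacent",
    "hwe_exact_test",
    "count_mendel_errors",
    "snp_qc",
    "run_pipeline",
]


@dataclass(frozen=True)
class CnvCall:
    """A single-sample called segment, 1-based inclusive coordinates."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    copy_number: int
    n_markers: int
    confidence: float | None = None
    origin: str = "unknown"  # maternal|paternal|biparental|de_novo|unknown
    in_any_parent: bool | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("call start must be <= end")
        if self.n_markers < 1:
            raise ValueError("call must span at least one marker")
        if not 0 <= self.copy_number <= 4:
            raise ValueError("copy_number must be in 0..4")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def cnv_type(self) -> str:
        return "del" if self.copy_number < 2 else "dup"


@dataclass
class CnvRegion:
    """A cross-sample grouped rare-CNV region."""

    region_id: str
    chromosome: str
    start: int
    end: int
    calls: list[CnvCall]
    carrier_count: int
    frequency: float | None
    cnv_type: str  # del | dup | mixed


@dataclass(frozen=True)
class SampleQcStats:
    sample_id: str
    n_calls: int
    lrr_sd: float
    n_rare_calls: int = 0


@dataclass(frozen=True)
class MarkerQcStats:
    marker_id: str
    call_rate: float
    hwe_p: float
    maf: float
    mendel_errors: int
    ld_pruned: bool = False


@dataclass
class PipelineReport:
    """Per-stage bookkeeping of removals, mirroring a QC supplement table."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    # (stage name, n_calls_after, n_removed)

    def record(self, stage: str, n_after: int, n_removed: int) -> None:
        self.stages.append((stage, n_after, n_removed))

    def __str__(self) -> str:
        lines = [f"{'stage':<28}{'kept':>8}{'removed':>9}"]
        for stage, kept, removed in self.stages:
            lines.append(f"{stage:<28}{kept:>8}{removed:>9}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# intensity preprocessing


def gc_correct(
    panel: IntensityPanel, window_kb: float | None = 1000.0
) -> IntensityPanel:
    """Remove the GC-correlated intensity wave from each sample's LRR.

    Per sample, LRR is regressed on local GC content (optionally smoothed
    over ``window_kb`` windows per chromosome) in a single global fit, and
    the fitted GC component ``slope * (gc - mean(gc))`` is subtracted.  The
    sample mean LRR is preserved and genuine copy-number shifts survive
    because only the GC-linear component is removed.  A window larger than
    every chromosome degenerates to the unsmoothed global fit.
    """
    markers = panel.markers
    gc = markers.gc_fraction.astype(float)
    if np.ptp(gc) == 0:
        warnings.warn("GC track is constant; gc_correct is a no-op", stacklevel=2)
        return IntensityPanel(list(panel.sample_ids), markers, panel.lrr.copy(), panel.baf.copy())

    if window_kb is not None and window_kb > 0:
        smooth = np.empty_like(gc)
        half = window_kb * 500.0  # half-window in bp
        for chrom in np.unique(markers.chromosome):
            m = markers.chrom_mask(chrom)
            pos = markers.position[m].astype(float)
            g = gc[m]
            # running mean over a +/- half-window neighbourhood
            left = np.searchsorted(pos, pos - half, side="left")
            right = np.searchsorted(pos, pos + half, side="right")
            csum = np.concatenate([[0.0], np.cumsum(g)])
            smooth[m] = (csum[right] - csum[left]) / (right - left)
        gc_pred = smooth
    else:
        gc_pred = gc

    x = gc_pred - gc_pred.mean()
    denom = float(x @ x)
    lrr = panel.lrr.copy()
    if denom > 0:
        slopes = (lrr @ x) / denom  # per-sample least-squares slope
        lrr -= slopes[:, None] * x[None, :]
    return IntensityPanel(list(panel.sample_ids), markers, lrr, panel.baf.copy())


def lrr_sd_per_sample(panel: IntensityPanel) -> dict[str, float]:
    """Per-sample LRR standard deviation, the LRR_SD QC statistic."""
    sds = panel.lrr.std(axis=1, ddof=1)
    return {s: float(sd) for s, sd in zip(panel.sample_ids, sds)}


# ---------------------------------------------------------------------------
# stand-in caller


@dataclass(frozen=True)
class CallerParams:
    """Emission/transition parameters of the stand-in 3-state segmenter.

    The loss/gain emission means are generator-matched conveniences, not
    estimates from any published HMM.
    """

    loss_mean: float = -0.6
    gain_mean: float = 0.35
    neutral_mean: float = 0.0
    stay_prob: float = 0.999
    min_markers: int = 10
    cn0_lrr: float = -1.5  # segment mean below this -> CN 0
    cn4_lrr: float = 0.55  # segment mean above this -> CN 4


def _viterbi_states(lrr: np.ndarray, params: CallerParams, sd: float) -> np.ndarray:
    """Most likely loss/neutral/gain state path for one chromosome of LRR."""
    means = np.array([params.loss_mean, params.neutral_mean, params.gain_mean])
    n = lrr.size
    log_emit = -0.5 * ((lrr[:, None] - means[None, :]) / sd) ** 2
    switch = (1.0 - params.stay_prob) / 2.0
    log_trans = np.log(
        np.full((3, 3), switch) + np.eye(3) * (params.stay_prob - switch)
    )
    log_init = np.log(np.array([0.005, 0.99, 0.005]))

    delta = log_init + log_emit[0]
    back = np.zeros((n, 3), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(3)] + log_emit[t]
    states = np.empty(n, dtype=np.int8)
    states[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


def call_cnvs(
    panel: IntensityPanel,
    params: CallerParams | None = None,
) -> list[CnvCall]:
    """Segment every sample's LRR into loss/neutral/gain calls.

    A simplified stand-in for a full CNV caller: a fixed-parameter 3-state
    Gaussian hidden-state model decoded by Viterbi per chromosome, with the
    per-sample noise level estimated robustly from the median absolute
    deviation.  Externally produced call lists can be used instead (io
    module reads the standard call-line dialect).
    """
    params = params or CallerParams()
    markers = panel.markers
    calls: list[CnvCall] = []
    chrom_order = list(dict.fromkeys(markers.chromosome.tolist()))
    masks = {c: markers.chrom_mask(c) for c in chrom_order}
    for i, sample in enumerate(panel.sample_ids):
        row = panel.lrr[i]
        sd = max(1.4826 * float(np.median(np.abs(row - np.median(row)))), 0.05)
        for chrom in chrom_order:
            m = masks[chrom]
            if m.sum() < params.min_markers:
                continue
            lrr = row[m]
            pos = markers.position[m]
            states = _viterbi_states(lrr, params, sd)
            # contiguous non-neutral runs
            boundaries = np.flatnonzero(np.diff(states) != 0)
            starts = np.concatenate([[0], boundaries + 1])
            ends = np.concatenate([boundaries, [states.size - 1]])
            for s0, e0 in zip(starts, ends):
                state = states[s0]
                n_mark = e0 - s0 + 1
                if state == 1 or n_mark < params.min_markers:
                    continue
                seg_mean = float(lrr[s0 : e0 + 1].mean())
                if state == 0:
                    cn = 0 if seg_mean < params.cn0_lrr else 1
                else:
                    cn = 4 if seg_mean > params.cn4_lrr else 3
                calls.append(
                    CnvCall(
                        sample_id=sample,
                        chromosome=chrom,
                        start=int(pos[s0]),
                        end=int(pos[e0]),
                        copy_number=cn,
                        n_markers=int(n_mark),
                        confidence=abs(seg_mean) / sd,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# trio origin


def _overlap_bp(a: CnvCall, b: CnvCall) -> int:
    if a.chromosome != b.chromosome:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def _reciprocal(a: CnvCall, b: CnvCall) -> float:
    ov = _overlap_bp(a, b)
    return min(ov / a.length, ov / b.length) if ov else 0.0


def assign_trio_origin(
    calls: Sequence[CnvCall],
    pedigree: Sequence[Trio],
    reciprocal_overlap_threshold: float = 0.5,
    samples_with_data: set[str] | None = None,
) -> list[CnvCall]:
    """Label each offspring call as inherited, biparental or de novo.

    An offspring call is maternal/paternal when a parental call of the same
    type (del vs dup) reaches the reciprocal overlap threshold; biparental
    when both parents do; de novo when neither does.  A secondary relaxed
    flag, ``in_any_parent``, records whether any same-type parental call
    overlaps by at least 1 bp — separating "de novo at the threshold" from
    "not found in any parent at all".  Offspring whose parents lack data
    (per ``samples_with_data``) are labelled unknown.
    """
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    parent_of = {t.offspring_id: (t.father_id, t.mother_id) for t in pedigree}

    out: list[CnvCall] = []
    for c in calls:
        if c.sample_id not in parent_of:
            out.append(c)
            continue
        father, mother = parent_of[c.sample_id]
        if samples_with_data is not None and not (
            father in samples_with_data and mother in samples_with_data
        ):
            out.append(replace(c, origin="unknown"))
            continue
        pat_calls = [p for p in by_sample.get(father, []) if p.cnv_type == c.cnv_type]
        mat_calls = [p for p in by_sample.get(mother, []) if p.cnv_type == c.cnv_type]
        pat = any(_reciprocal(c, p) >= reciprocal_overlap_threshold for p in pat_calls)
        mat = any(_reciprocal(c, p) >= reciprocal_overlap_threshold for p in mat_calls)
        any_parent = any(_overlap_bp(c, p) > 0 for p in pat_calls + mat_calls)
        if pat and mat:
            origin = "biparental"
        elif pat:
            origin = "paternal"
        elif mat:
            origin = "maternal"
        else:
            origin = "de_novo"
        out.append(replace(c, origin=origin, in_any_parent=any_parent))
    return out


# ---------------------------------------------------------------------------
# sample QC


def sample_qc(
    calls: Sequence[CnvCall],
    pedigree: Sequence[Trio],
    lrr_sd: Mapping[str, float],
    max_calls: int = 50,
    max_lrr_sd: float = 0.3,
) -> tuple[list[Trio], list[Trio], list[SampleQcStats]]:
    """First-pass trio QC: drop a trio if ANY member is an outlier.

    A member fails with >= ``max_calls`` CNV calls or LRR_SD >
    ``max_lrr_sd``.  Returns (kept trios, removed trios, per-sample stats).
    """
    n_calls: dict[str, int] = {}
    for c in calls:
        n_calls[c.sample_id] = n_calls.get(c.sample_id, 0) + 1
    stats_out = []
    kept, removed = [], []
    for trio in pedigree:
        bad = False
        for member in trio.members:
            nc = n_calls.get(member, 0)
            sd = float(lrr_sd.get(member, 0.0))
            stats_out.append(SampleQcStats(member, nc, sd))
            if nc >= max_calls or sd > max_lrr_sd:
                bad = True
        (removed if bad else kept).append(trio)
    return kept, removed, stats_out


def rare_call_qc(
    calls: Sequence[CnvCall],
    pedigree: Sequence[Trio],
    rare_calls: Iterable[CnvCall],
    max_rare: int = 10,
) -> tuple[list[Trio], list[Trio]]:
    """Second-pass trio QC on rare-call load (>= ``max_rare`` in any member)."""
    del calls
    n_rare: dict[str, int] = {}
    for c in rare_calls:
        n_rare[c.sample_id] = n_rare.get(c.sample_id, 0) + 1
    kept, removed = [], []
    for trio in pedigree:
        if any(n_rare.get(m, 0) >= max_rare for m in trio.members):
            removed.append(trio)
        else:
            kept.append(trio)
    return kept, removed


# ---------------------------------------------------------------------------
# interval filters


def _build_trees(intervals: Iterable[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if start > end:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        # IntervalTree is half-open; inclusive end -> end + 1
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    return trees


def region_filter(
    calls: Sequence[CnvCall],
    blacklist: Iterable[tuple[str, int, int]],
) -> list[CnvCall]:
    """Drop calls overlapping any blacklist interval by >= 1 bp.

    Blacklists cover centromeric, telomeric, immunoglobulin and T-cell
    receptor regions, where somatic rearrangement and assembly artifacts
    dominate the signal.
    """
    trees = _build_trees(blacklist)
    return [
        c
        for c in calls
        if not (c.chromosome in trees and trees[c.chromosome].overlaps(c.start, c.end + 1))
    ]


def size_marker_filter(
    calls: Sequence[CnvCall], min_markers: int = 30, min_kb: float = 100.0
) -> list[CnvCall]:
    """High-confidence filter: keep calls with >= 30 markers and >= 100 kb."""
    min_bp = min_kb * 1000.0
    return [c for c in calls if c.n_markers >= min_markers and c.length >= min_bp]


def group_into_regions(
    calls: Sequence[CnvCall],
    proximity_kb: float = 20.0,
    n_samples: int | None = None,
    offspring_ids: set[str] | None = None,
) -> list[CnvRegion]:
    """Single-linkage grouping of calls that overlap or lie within 20 kb.

    ``carrier_count`` counts distinct offspring (or distinct samples when
    ``offspring_ids`` is None) holding >= 1 member call; ``frequency``
    divides by ``n_samples`` when given (the QC-passed denominator).
    Idempotent: regrouping region spans changes nothing.
    """
    gap_bp = proximity_kb * 1000.0
    ordered = sorted(calls, key=lambda c: (c.chromosome, c.start, c.end))
    regions: list[CnvRegion] = []
    cluster: list[CnvCall] = []

    def flush() -> None:
        if not cluster:
            return
        start = min(c.start for c in cluster)
        end = max(c.end for c in cluster)
        chrom = cluster[0].chromosome
        carriers = {
            c.sample_id
            for c in cluster
            if offspring_ids is None or c.sample_id in offspring_ids
        }
        types = {c.cnv_type for c in cluster}
        regions.append(
            CnvRegion(
                region_id=f"{chrom}:{start}-{end}",
                chromosome=chrom,
                start=start,
                end=end,
                calls=list(cluster),
                carrier_count=len(carriers),
                frequency=(len(carriers) / n_samples) if n_samples else None,
                cnv_type=types.pop() if len(types) == 1 else "mixed",
            )
        )

    cur_end = None
    cur_chrom = None
    for c in ordered:
        if cluster and c.chromosome == cur_chrom and c.start - cur_end - 1 <= gap_bp:
            cluster.append(c)
            cur_end = max(cur_end, c.end)
        else:
            flush()
            cluster = [c]
            cur_chrom, cur_end = c.chromosome, c.end
    flush()
    return regions


def rarity_filter(regions: Sequence[CnvRegion], max_frequency: float = 0.01) -> list[CnvRegion]:
    """Keep regions observed at frequency <= 1% (inclusive)."""
    out = []
    for r in regions:
        if r.frequency is None:
            raise ValueError(f"region {r.region_id} has no frequency; pass n_samples when grouping")
        if r.frequency <= max_frequency:
            out.append(r)
    return out


def _union_coverage(call: CnvCall, tree: IntervalTree) -> int:
    """Basepairs of the call covered by the union of tree intervals."""
    hits = sorted(
        (max(iv.begin, call.start), min(iv.end - 1, call.end))
        for iv in tree.overlap(call.start, call.end + 1)
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in hits:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered


def segdup_filter(
    calls: Sequence[CnvCall],
    segdups: Iterable[tuple[str, int, int]],
    max_overlap_fraction: float = 0.5,
) -> list[CnvCall]:
    """Drop calls covered > 50% (strict) by the union of segmental duplications."""
    trees = _build_trees(segdups)
    out = []
    for c in calls:
        tree = trees.get(c.chromosome)
        frac = _union_coverage(c, tree) / c.length if tree is not None else 0.0
        if frac <= max_overlap_fraction:
            out.append(c)
    return out


def merge_adjacent(
    calls: Sequence[CnvCall], max_gap_fraction: float = 0.2
) -> list[CnvCall]:
    """Merge same-sample, same-type adjacent calls with small gaps.

    Two calls merge when the gap between them is < ``max_gap_fraction`` of
    the merged span length (strict).  Applied iteratively to a fixpoint;
    opposite types never merge.  When copy numbers differ within a type the
    larger call's copy number is kept.
    """
    groups: dict[tuple[str, str, str], list[CnvCall]] = {}
    for c in calls:
        groups.setdefault((c.sample_id, c.chromosome, c.cnv_type), []).append(c)
    out: list[CnvCall] = []
    for group in groups.values():
        group = sorted(group, key=lambda c: (c.start, c.end))
        changed = True
        while changed:
            changed = False
            merged: list[CnvCall] = []
            i = 0
            while i < len(group):
                c = group[i]
                if i + 1 < len(group):
                    nxt = group[i + 1]
                    span = max(c.end, nxt.end) - c.start + 1
                    gap = max(0, nxt.start - c.end - 1)
                    if gap < max_gap_fraction * span:
                        big = c if c.length >= nxt.length else nxt
                        c = CnvCall(
                            sample_id=c.sample_id,
                            chromosome=c.chromosome,
                            start=c.start,
                            end=max(c.end, nxt.end),
                            copy_number=big.copy_number,
                            n_markers=c.n_markers + nxt.n_markers,
                            origin=c.origin if c.origin == nxt.origin else "unknown",
                        )
                        group[i + 1] = c
                        i += 1
                        changed = True
                        continue
                merged.append(c)
                i += 1
            group = merged
        out.extend(group)
    return sorted(out, key=lambda c: (c.chromosome, c.start, c.sample_id))


# ---------------------------------------------------------------------------
# SNP genotype QC


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of configurations as or less
    probable than the observed heterozygote count, conditional on allele
    counts)."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    # heterozygote count shares the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    # log-probability of each configuration under the conditional law
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = n_ab
    p_obs = prob[hets == obs]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, prob[prob <= p_obs[0] * (1 + 1e-12)].sum()))


_MENDEL_BAD = {
    # (father, mother, offspring) combinations impossible under biallelic
    # Mendelian transmission
    (0, 0, 1), (0, 0, 2), (2, 2, 0), (2, 2, 1),
    (0, 1, 2), (1, 0, 2), (2, 1, 0), (1, 2, 0),
    (0, 2, 0), (2, 0, 0), (0, 2, 2), (2, 0, 2),
}


def count_mendel_errors(
    father: np.ndarray, mother: np.ndarray, offspring: np.ndarray
) -> np.ndarray:
    """Per-marker count of trios with Mendelian-impossible genotype combos.

    Inputs are (families x markers) allele-count matrices; -1 is missing.
    """
    errors = np.zeros(father.shape[1], dtype=int)
    valid = (father >= 0) & (mother >= 0) & (offspring >= 0)
    for f, m, o in _MENDEL_BAD:
        errors += ((father == f) & (mother == m) & (offspring == o) & valid).sum(axis=0)
    return errors


def snp_qc(
    genotypes: TrioGenotypes,
    min_call_rate: float = 0.95,
    min_hwe_p: float = 1e-6,
    min_maf: float = 0.01,
    ld_r2_threshold: float = 0.8,
    ld_window: int = 50,
) -> tuple[list[MarkerQcStats], list[str]]:
    """SNP QC: call rate, founder HWE, MAF, Mendelian errors, LD pruning.

    Thresholds are applied as call_rate >= 0.95, exact HWE p >= 1e-6 on
    founders, MAF >= 0.01, zero Mendelian errors; surviving markers are then
    greedily LD-pruned, removing the later member of any pair within
    ``ld_window`` markers whose r^2 exceeds the threshold.
    """
    fa, mo, off = genotypes.father, genotypes.mother, genotypes.offspring
    for mat in (fa, mo, off):
        bad = ~np.isin(mat, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("non-biallelic genotype codes present")

    founders = np.vstack([fa, mo])
    n_markers = genotypes.n_markers
    all_geno = np.vstack([fa, mo, off])
    call_rate = (all_geno >= 0).mean(axis=0)
    mendel = count_mendel_errors(fa, mo, off)

    stats_out: list[MarkerQcStats] = []
    passed = np.zeros(n_markers, dtype=bool)
    mafs = np.empty(n_markers)
    for j in range(n_markers):
        g = founders[:, j]
        g = g[g >= 0]
        n_bb = int((g == 2).sum())
        n_ab = int((g == 1).sum())
        n_aa = int((g == 0).sum())
        hwe_p = hwe_exact_test(n_aa, n_ab, n_bb)
        freq = g.mean() / 2.0 if g.size else 0.0
        maf = min(freq, 1 - freq)
        mafs[j] = maf
        ok = (
            call_rate[j] >= min_call_rate
            and hwe_p >= min_hwe_p
            and maf >= min_maf
            and mendel[j] == 0
        )
        passed[j] = ok
        stats_out.append(
            MarkerQcStats(genotypes.marker_ids[j], float(call_rate[j]), hwe_p, float(maf), int(mendel[j]))
        )

    # greedy LD pruning over surviving markers
    surviving = np.flatnonzero(passed)
    kept: list[int] = []
    geno_f = np.where(all_geno >= 0, all_geno, np.nan).astype(float)
    for j in surviving:
        prune = False
        for k in kept[-ld_window:]:
            both = ~(np.isnan(geno_f[:, j]) | np.isnan(geno_f[:, k]))
            if both.sum() < 3:
                continue
            a, b = geno_f[both, j], geno_f[both, k]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r * r > ld_r2_threshold:
                prune = True
                break
        if prune:
            stats_out[j] = replace(stats_out[j], ld_pruned=True)
        else:
            kept.append(j)
    kept_ids = [genotypes.marker_ids[j] for j in kept]
    return stats_out, kept_ids


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    calls: Sequence[CnvCall],
    pedigree: Sequence[Trio],
    lrr_sd: Mapping[str, float],
    blacklist: Iterable[tuple[str, int, int]] = (),
    segdups: Iterable[tuple[str, int, int]] = (),
    min_markers: int = 30,
    min_kb: float = 100.0,
    proximity_kb: float = 20.0,
    max_frequency: float = 0.01,
    reciprocal_overlap_threshold: float = 0.5,
    max_calls: int = 50,
    max_lrr_sd: float = 0.3,
    max_rare: int = 10,
    max_segdup_fraction: float = 0.5,
    max_gap_fraction: float = 0.2,
) -> tuple[list[CnvRegion], list[Trio], PipelineReport]:
    """Run the full filter chain in the fixed stage order.

    Returns the surviving rare regions (rebuilt on the merged calls), the
    QC-passed trios, and a per-stage removal report.  Region frequency uses
    all QC-passed samples as denominator (configurable by regrouping).
    """
    report = PipelineReport()
    report.record("input", len(calls), 0)

    calls = assign_trio_origin(list(calls), pedigree, reciprocal_overlap_threshold)
    report.record("trio_origin", len(calls), 0)

    n0 = len(calls)
    calls = size_marker_filter(calls, min_markers, min_kb)
    report.record("size_marker_filter", len(calls), n0 - len(calls))

    kept, removed, _ = sample_qc(calls, pedigree, lrr_sd, max_calls, max_lrr_sd)
    kept_samples = {m for t in kept for m in t.members}
    n0 = len(calls)
    calls = [c for c in calls if c.sample_id in kept_samples]
    report.record(f"sample_qc_pass1 (-{len(removed)} trios)", len(calls), n0 - len(calls))

    n0 = len(calls)
    calls = region_filter(calls, blacklist)
    report.record("blacklist_filter", len(calls), n0 - len(calls))

    n_samples = 3 * len(kept)
    regions = group_into_regions(calls, proximity_kb, n_samples=n_samples, offspring_ids=None)
    # rarity counts carriers among all QC-passed samples
    regions_rare = rarity_filter(regions, max_frequency)
    rare_calls = [c for r in regions_rare for c in r.calls]
    report.record("group_and_rarity", len(rare_calls), len(calls) - len(rare_calls))

    kept2, removed2 = rare_call_qc(calls, kept, rare_calls, max_rare)
    kept_samples2 = {m for t in kept2 for m in t.members}
    n0 = len(rare_calls)
    rare_calls = [c for c in rare_calls if c.sample_id in kept_samples2]
    report.record(f"sample_qc_pass2 (-{len(removed2)} trios)", len(rare_calls), n0 - len(rare_calls))

    n0 = len(rare_calls)
    rare_calls = segdup_filter(rare_calls, segdups, max_segdup_fraction)
    report.record("segdup_filter", len(rare_calls), n0 - len(rare_calls))

    n0 = len(rare_calls)
    rare_calls = merge_adjacent(rare_calls, max_gap_fraction)
    report.record("merge_adjacent", len(rare_calls), n0 - len(rare_calls))

    offspring2 = {t.offspring_id for t in kept2}
    final_regions = group_into_regions(
        rare_calls, proximity_kb, n_samples=3 * len(kept2), offspring_ids=offspring2
    )
    report.record("final_regions", len(final_regions), 0)
    return final_regions, kept2, report
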