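"""Synthetic trio SNP-array data with embedded copy-number variants.

This module generates everything the downstream stages consume: a marker map
(SNP + CNV probes with a GC track), father-mother-offspring pedigrees, ground
truth CNV events (inherited, de novo, or somatic artifacts), and per-sample
log R ratio (LRR) / B-allele frequency (BAF) matrices with copy-number
dependent signal structure.

The signal model is deliberately simple but carries the features the analysis
must be robust to: a diploid marker has LRR centred at 0 with Gaussian noise
and BAF bands at {0, 1/2, 1}; a one-copy deletion shifts LRR down and removes
the heterozygote band; a duplication shifts LRR up and splits the band into
{0, 1/3, 2/3, 1}; a GC-correlated intensity wave is added per sample; and
inside designated "artifact" regions every individual receives an independent
LRR offset regardless of inheritance, mimicking somatic T-cell-receptor
rearrangements in blood-derived DNA.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "Trio",
    "CnvEvent",
    "CnvLocus",
    "IntensityPanel",
    "TrioGenotypes",
    "LRR_SHIFT",
    "generate_marker_map",
    "generate_trios",
    "spike_cnvs",
    "emit_intensities",
    "simulate_trio_genotypes",
]

#: Mean LRR shift per copy number. CN=2 is the diploid baseline at 0.
#: These are generator conveniences chosen so a simple segmenter can separate
#: the states; they are not estimates of any particular array chemistry.
LRR_SHIFT: dict[int, float] = {0: -3.0, 1: -0.6, 2: 0.0, 3: 0.35, 4: 0.75}


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker positions with probe class and local GC content."""

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    is_cnv_probe: np.ndarray
    gc_fraction: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.marker_id)
        for name in ("chromosome", "position", "is_cnv_probe", "gc_fraction"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")
        if len(np.unique(self.marker_id)) != n:
            raise ValueError("marker ids must be unique")
        gc = np.asarray(self.gc_fraction, dtype=float)
        if np.any((gc < 0) | (gc > 1)):
            raise ValueError("gc_fraction must lie in [0, 1]")
        for chrom in np.unique(self.chromosome):
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chromosome == chrom

    def overlap_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of markers falling inside [start, end] on chrom."""
        return (self.chromosome == chrom) & (self.position >= start) & (self.position <= end)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position": self.position,
                "is_cnv_probe": self.is_cnv_probe,
                "gc_fraction": self.gc_fraction,
            }
        )


@dataclass(frozen=True)
class Trio:
    """A complete nuclear family with one affected offspring."""

    family_id: str
    father_id: str
    mother_id: str
    offspring_id: str
    offspring_sex: str = "M"
    offspring_affected: bool = True

    def __post_init__(self) -> None:
        if len({self.father_id, self.mother_id, self.offspring_id}) != 3:
            raise ValueError("trio member ids must be distinct")

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.father_id, self.mother_id, self.offspring_id)


@dataclass(frozen=True)
class CnvEvent:
    """Ground-truth copy-number event carried by one sample."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    copy_number: int
    origin: str  # maternal | paternal | de_novo | somatic_artifact

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("event start must be <= end")
        if self.copy_number == 2:
            raise ValueError("copy_number 2 is not an event")


@dataclass(frozen=True)
class CnvLocus:
    """A locus at which events may be spiked into a cohort."""

    chromosome: str
    start: int
    end: int
    copy_number: int
    name: str = ""


@dataclass
class IntensityPanel:
    """Per-sample, per-marker LRR and BAF values on a shared marker map."""

    sample_ids: list[str]
    markers: MarkerMap
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.sample_ids), self.markers.n_markers)
        if self.lrr.shape != shape or self.baf.shape != shape:
            raise ValueError(f"matrix shape must be {shape}")
        if np.isinf(self.lrr).any():
            raise ValueError("LRR must be finite (NaN marks missing values)")
        with np.errstate(invalid="ignore"):
            if np.any((self.baf < 0) | (self.baf > 1)):
                raise ValueError("BAF must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None


def generate_marker_map(
    n_markers: int,
    chromosome_lengths: Mapping[str, int],
    cnv_probe_fraction: float = 0.1,
    gc_model_params: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> MarkerMap:
    """Place markers uniformly on the given chromosomes.

    GC content follows a smooth positional wave (sinusoid plus noise) so that
    GC-wave correction has a signal to remove.  A scaled-down stand-in for a
    1M genotyping array.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not chromosome_lengths:
        raise ValueError("at least one chromosome is required")
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
    gc = {"baseline": 0.45, "amplitude": 0.08, "period_bp": 2e6, "noise_sd": 0.02}
    if gc_model_params:
        gc.update(gc_model_params)

    rng = np.random.default_rng(seed)
    chroms = list(chromosome_lengths)
    lengths = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(n_markers, lengths / lengths.sum())

    chrom_col, pos_col = [], []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        length = chromosome_lengths[chrom]
        if k > length:
            raise ValueError(f"more markers than basepairs on {chrom}")
        pos = np.sort(rng.choice(length, size=k, replace=False) + 1)
        chrom_col.append(np.full(k, chrom, dtype=object))
        pos_col.append(pos)
    chromosome = np.concatenate(chrom_col)
    position = np.concatenate(pos_col).astype(np.int64)

    wave = gc["baseline"] + gc["amplitude"] * np.sin(
        2 * np.pi * position / gc["period_bp"]
    )
    gc_fraction = np.clip(wave + rng.normal(0, gc["noise_sd"], len(position)), 0, 1)

    is_cnv = rng.random(len(position)) < cnv_probe_fraction
    marker_id = np.array(
        [
            (f"cnvi{i:07d}" if cnv else f"rs{i:07d}")
            for i, cnv in enumerate(is_cnv)
        ],
        dtype=object,
    )
    return MarkerMap(marker_id, chromosome, position, is_cnv, gc_fraction)


def generate_trios(n_trios: int, sex_ratio: float = 0.51, seed: int | None = None) -> list[Trio]:
    """Generate complete trios, every offspring flagged as affected."""
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    rng = np.random.default_rng(seed)
    sexes = np.where(rng.random(n_trios) < sex_ratio, "M", "F")
    trios = []
    for i in range(n_trios):
        fam = f"fam{i:04d}"
        trios.append(
            Trio(
                family_id=fam,
                father_id=f"{fam}-fa",
                mother_id=f"{fam}-mo",
                offspring_id=f"{fam}-off",
                offspring_sex=str(sexes[i]),
                offspring_affected=True,
            )
        )
    return trios


def spike_cnvs(
    pedigree: Sequence[Trio],
    locus_list: Sequence[CnvLocus],
    per_locus_frequency: float | Sequence[float],
    de_novo_rate: float = 0.0,
    seed: int | None = None,
    marker_map: MarkerMap | None = None,
) -> list[CnvEvent]:
    """Spike ground-truth CNV events into a cohort.

    Each offspring carries an event at a locus with the given per-locus
    frequency; a carried event is de novo with probability ``de_novo_rate``
    and otherwise inherited from one randomly chosen parent (the parent
    carries a matching event).
    """
    freqs = np.broadcast_to(np.atleast_1d(np.asarray(per_locus_frequency, float)), (len(locus_list),))
    if np.any((freqs < 0) | (freqs > 1)) or not 0 <= de_novo_rate <= 1:
        raise ValueError("frequencies must lie in [0, 1]")
    if marker_map is not None:
        for locus in locus_list:
            if not marker_map.overlap_mask(locus.chromosome, locus.start, locus.end).any():
                raise ValueError(
                    f"locus {locus.chromosome}:{locus.start}-{locus.end} outside marker map span"
                )
    rng = np.random.default_rng(seed)
    events: list[CnvEvent] = []
    for locus, freq in zip(locus_list, freqs):
        for trio in pedigree:
            if rng.random() >= freq:
                continue
            if rng.random() < de_novo_rate:
                events.append(
                    CnvEvent(trio.offspring_id, locus.chromosome, locus.start, locus.end, locus.copy_number, "de_novo")
                )
            else:
                maternal = rng.random() < 0.5
                parent = trio.mother_id if maternal else trio.father_id
                origin = "maternal" if maternal else "paternal"
                events.append(
                    CnvEvent(parent, locus.chromosome, locus.start, locus.end, locus.copy_number, origin)
                )
                events.append(
                    CnvEvent(trio.offspring_id, locus.chromosome, locus.start, locus.end, locus.copy_number, origin)
                )
    return events


def emit_intensities(
    pedigree: Sequence[Trio],
    marker_map: MarkerMap,
    events: Sequence[CnvEvent] = (),
    noise_sd: float | Mapping[str, float] = 0.15,
    artifact_regions: Sequence[tuple[str, int, int]] = (),
    artifact_sd: float = 0.5,
    artifact_offspring_shift: float = -0.25,
    gc_lrr_coeff: float = 0.2,
    baf_noise_sd: float = 0.03,
    seed: int | None = None,
) -> IntensityPanel:
    """Emit an LRR/BAF panel for every member of every trio.

    ``noise_sd`` is either a scalar or a per-sample mapping (the QC statistic
    LRR_SD estimates it back).  Inside ``artifact_regions`` each individual
    receives an independent random LRR offset regardless of inheritance,
    modelling somatic rearrangement signal; ``artifact_offspring_shift``
    additionally moves the offspring offset mean relative to the parents,
    the age-correlated component of somatic rearrangement burden that makes
    such regions light up in a within-family intensity test.
    ``gc_lrr_coeff`` scales a per-sample GC-correlated intensity wave.
    """
    samples: list[str] = []
    for trio in pedigree:
        samples.extend(trio.members)
    sample_set = set(samples)
    offspring_set = {t.offspring_id for t in pedigree}
    for ev in events:
        if ev.sample_id not in sample_set:
            raise ValueError(f"event references unknown sample {ev.sample_id!r}")

    def sd_of(sample: str) -> float:
        sd = noise_sd[sample] if isinstance(noise_sd, Mapping) else noise_sd
        if sd <= 0:
            raise ValueError("noise_sd must be positive")
        return float(sd)

    rng = np.random.default_rng(seed)
    n_s, n_m = len(samples), marker_map.n_markers
    gc_centered = marker_map.gc_fraction - marker_map.gc_fraction.mean()
    allele_freq = rng.uniform(0.05, 0.95, n_m)

    cn = np.full((n_s, n_m), 2, dtype=np.int8)
    index = {s: i for i, s in enumerate(samples)}
    for ev in events:
        cn[index[ev.sample_id], marker_map.overlap_mask(ev.chromosome, ev.start, ev.end)] = ev.copy_number

    lrr = np.empty((n_s, n_m))
    baf = np.empty((n_s, n_m))
    shift = np.vectorize(LRR_SHIFT.get)
    for i, sample in enumerate(samples):
        sd = sd_of(sample)
        coeff = gc_lrr_coeff * (1.0 + 0.2 * rng.normal())
        row_cn = cn[i]
        row = shift(row_cn).astype(float) + coeff * gc_centered + rng.normal(0, sd, n_m)
        shift_mu = artifact_offspring_shift if sample in offspring_set else 0.0
        for chrom, start, end in artifact_regions:
            mask = marker_map.overlap_mask(chrom, start, end)
            if mask.any():
                row[mask] += rng.normal(shift_mu, artifact_sd)
        lrr[i] = row
        # BAF: k B-alleles out of cn copies -> band at k/cn; CN=0 has no
        # allelic signal, modelled as uniform noise.
        k = rng.binomial(row_cn, allele_freq)
        with np.errstate(invalid="ignore", divide="ignore"):
            band = np.where(row_cn > 0, k / np.maximum(row_cn, 1), 0.5)
        b = band + rng.normal(0, baf_noise_sd, n_m)
        b[row_cn == 0] = rng.uniform(0, 1, int((row_cn == 0).sum()))
        baf[i] = np.clip(b, 0, 1)

    return IntensityPanel(samples, marker_map, lrr, baf)


@dataclass
class TrioGenotypes:
    """Risk-allele count matrices (0/1/2, -1 missing) for each trio member.

    Rows are families in pedigree order, columns are markers.
    """

    marker_ids: list[str]
    families: list[str]
    father: np.ndarray
    mother: np.ndarray
    offspring: np.ndarray
    transmitted_father: np.ndarray = field(default=None)  # type: ignore[assignment]
    transmitted_mother: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


def simulate_trio_genotypes(
    pedigree: Sequence[Trio],
    n_markers: int,
    maf: float | Sequence[float] = 0.3,
    risk_markers: Sequence[int] = (),
    transmission_or: float = 1.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> TrioGenotypes:
    """Mendelian trio genotypes with optional transmission distortion.

    Parents are drawn from Hardy-Weinberg proportions; each transmits one
    allele.  At ``risk_markers`` a heterozygous parent transmits the risk
    allele with probability OR/(1+OR) instead of 1/2, the log-additive
    over-transmission that a case-parent design detects.
    """
    n_fam = len(pedigree)
    p = np.broadcast_to(np.atleast_1d(np.asarray(maf, float)), (n_markers,))
    rng = np.random.default_rng(seed)
    tau = np.full(n_markers, 0.5)
    tau[np.asarray(risk_markers, dtype=int)] = transmission_or / (1.0 + transmission_or)

    father = rng.binomial(2, p, size=(n_fam, n_markers)).astype(np.int8)
    mother = rng.binomial(2, p, size=(n_fam, n_markers)).astype(np.int8)

    def transmit(parent: np.ndarray) -> np.ndarray:
        # homozygotes transmit deterministically; heterozygotes with bias tau
        t = (parent == 2).astype(np.int8)
        het = parent == 1
        t[het] = (rng.random(het.sum()) < np.broadcast_to(tau, parent.shape)[het]).astype(np.int8)
        return t

    t_f = transmit(father)
    t_m = transmit(mother)
    offspring = (t_f + t_m).astype(np.int8)

    if missing_rate > 0:
        for mat in (father, mother, offspring):
            mat[rng.random(mat.shape) < missing_rate] = -1

    return TrioGenotypes(
        marker_ids=[f"snp{j:05d}" for j in range(n_markers)],
        families=[t.family_id for t in pedigree],
        father=father,
        mother=mother,
        offspring=offspring,
        transmitted_father=t_f,
        transmitted_mother=t_m,
    )
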