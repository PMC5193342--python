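"""Locus-level and carrier-level rare-CNV burden statistics.

Case carrier counts at candidate loci are compared against published
control count tables in 2x2 contingency tables.  Conventions:

* **Continuity correction** — if any cell of the 2x2 table is zero, 0.5 is
  added to *every* cell before the odds ratio is formed; the exact test is
  always computed on the uncorrected integer counts.
* **Merged controls** — when several control studies are combined at a
  locus, studies whose carrier count is not available ("n/a") are excluded
  from both the numerator and the denominator at that locus.
* **Meta-analysis** — per-study (or per-locus) log odds ratios with Woolf
  variances are pooled by the DerSimonian-Laird random-effects estimator
  (tau^2 by method of moments, floored at 0); a Mantel-Haenszel fixed
  pooling of the raw tables is available as an alternative flavor.

A packaged fixture ships the 14 schizophrenia-associated loci with the case
and four-control-study carrier counts, used by the regression tests and the
worked examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import CnvCall, CnvRegion

__all__ = [
    "LocusDef",
    "ControlCounts",
    "ContingencyTable",
    "OddsRatioResult",
    "MetaResult",
    "N_CASES_QC",
    "load_scz_loci",
    "load_control_studies",
    "merged_control_counts",
    "locus_burden",
    "cc_odds_ratio",
    "fisher_exact",
    "pool_random_effects",
    "carrier_level_counts",
    "carrier_level_tables",
    "per_locus_tables",
    "sensitivity_nullify",
]

#: QC-passed affected offspring forming the case denominator of the
#: packaged burden tables.
N_CASES_QC = 582


@dataclass(frozen=True)
class LocusDef:
    """A candidate locus; coordinates in basepairs, 1-based."""

    name: str
    chromosome: str
    start: int
    end: int
    cnv_type: str  # del | dup | del_or_dup

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("locus start must be < end")
        if self.cnv_type not in ("del", "dup", "del_or_dup"):
            raise ValueError(f"untyped or invalid locus type {self.cnv_type!r}")

    def matches(self, call: CnvCall) -> bool:
        if self.cnv_type == "del_or_dup":
            return True
        return call.cnv_type == self.cnv_type


@dataclass(frozen=True)
class ControlCounts:
    study_id: str
    n_total: int
    carriers: int | None  # None = not available

    def __post_init__(self) -> None:
        if self.carriers is not None and self.carriers > self.n_total:
            raise ValueError("carriers cannot exceed sample size")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: (case, control) x (carrier, non-carrier)."""

    case_carriers: float
    case_noncarriers: float
    control_carriers: float
    control_noncarriers: float

    def __post_init__(self) -> None:
        if min(self.cells) < 0:
            raise ValueError("cells must be non-negative")

    @classmethod
    def from_counts(
        cls, case_carriers: int, n_cases: int, control_carriers: int, n_controls: int
    ) -> "ContingencyTable":
        return cls(
            case_carriers,
            n_cases - case_carriers,
            control_carriers,
            n_controls - control_carriers,
        )

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (
            self.case_carriers,
            self.case_noncarriers,
            self.control_carriers,
            self.control_noncarriers,
        )

    @property
    def is_integer(self) -> bool:
        return all(float(x).is_integer() for x in self.cells)

    def corrected(self) -> "ContingencyTable":
        """Add 0.5 to every cell iff any cell is zero."""
        if 0 in self.cells:
            return ContingencyTable(*(x + 0.5 for x in self.cells))
        return self


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_exact: float | None
    continuity_corrected: bool
    log_or: float
    var_log_or: float
    undefined: bool = False


@dataclass(frozen=True)
class MetaResult:
    pooled_or: float
    ci_low: float
    ci_high: float
    tau_squared: float
    q_statistic: float
    n_studies: int
    model: str  # fixed | random | mh
    p_value: float


# ---------------------------------------------------------------------------
# fixture loading


def _data_path(name: str):
    return resources.files("triocnv.data").joinpath(name)


def load_control_studies() -> dict[str, int]:
    """Control study sample sizes keyed by study id."""
    df = pd.read_csv(_data_path("control_studies.tsv"), sep="\t")
    return dict(zip(df["study_id"], df["n_total"].astype(int)))


def load_scz_loci() -> pd.DataFrame:
    """Packaged table of 14 schizophrenia-associated loci.

    Columns: locus, cnv_type, chromosome, start_mb, end_mb, case_carriers,
    case_de_novo, and one carrier-count column per control study ("n/a"
    parsed to NaN).
    """
    return pd.read_csv(_data_path("scz_loci.tsv"), sep="\t", na_values=["n/a"])


def merged_control_counts(
    row: pd.Series, studies: dict[str, int]
) -> tuple[int, int]:
    """(carriers, total) over control studies with available counts at a locus."""
    carriers = total = 0
    for study, n in studies.items():
        v = row[study]
        if pd.notna(v):
            carriers += int(v)
            total += n
    return carriers, total


# ---------------------------------------------------------------------------
# 2x2 statistics


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p on integer counts (tables with probability
    <= the observed table's are summed)."""
    if not table.is_integer:
        raise ValueError("exact test requires integer counts")
    a, b, c, d = (int(x) for x in table.cells)
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def cc_odds_ratio(table: ContingencyTable) -> OddsRatioResult:
    """Continuity-corrected odds ratio with Woolf CI and exact p.

    The correction adds 0.5 to every cell iff any cell is zero; the Woolf
    CI uses the (possibly corrected) table while the exact p always uses
    the uncorrected integer counts.
    """
    if not table.is_integer:
        raise ValueError("cc_odds_ratio expects an uncorrected integer table")
    a, b, c, d = table.cells
    if (a + c) == 0 and (b + d) == 0:
        return OddsRatioResult(
            math.nan, math.nan, math.nan, None, False, math.nan, math.nan, undefined=True
        )
    corr = table.corrected()
    ca, cb, cc, cd = corr.cells
    orr = (ca * cd) / (cb * cc)
    log_or = math.log(orr)
    var = 1 / ca + 1 / cb + 1 / cc + 1 / cd
    se = math.sqrt(var)
    return OddsRatioResult(
        odds_ratio=orr,
        ci_low=math.exp(log_or - 1.959963984540054 * se),
        ci_high=math.exp(log_or + 1.959963984540054 * se),
        p_exact=fisher_exact(table),
        continuity_corrected=corr is not table,
        log_or=log_or,
        var_log_or=var,
    )


# ---------------------------------------------------------------------------
# meta-analysis


def _dl_pool(y: np.ndarray, v: np.ndarray) -> MetaResult:
    w = 1.0 / v
    mu_fixed = float((w * y).sum() / w.sum())
    q = float((w * (y - mu_fixed) ** 2).sum())
    df = len(y) - 1
    if df > 0:
        c = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - df) / c)
    else:
        tau2 = 0.0
    wr = 1.0 / (v + tau2)
    mu = float((wr * y).sum() / wr.sum())
    se = float(1.0 / math.sqrt(wr.sum()))
    z = mu / se
    return MetaResult(
        pooled_or=math.exp(mu),
        ci_low=math.exp(mu - 1.959963984540054 * se),
        ci_high=math.exp(mu + 1.959963984540054 * se),
        tau_squared=tau2,
        q_statistic=q,
        n_studies=len(y),
        model="random",
        p_value=float(2 * stats.norm.sf(abs(z))),
    )


def pool_random_effects(
    inputs: Sequence[OddsRatioResult | ContingencyTable],
    method: str = "dl",
) -> MetaResult:
    """Pool study odds ratios on the log scale.

    ``method="dl"`` is DerSimonian-Laird random effects on log-ORs with
    Woolf variances (continuity-corrected tables where needed);
    ``method="mh"`` is Mantel-Haenszel fixed pooling of the raw tables
    (no between-study variance).
    """
    if not inputs:
        raise ValueError("at least one study is required")
    results = [
        cc_odds_ratio(x) if isinstance(x, ContingencyTable) else x for x in inputs
    ]
    results = [r for r in results if not r.undefined and math.isfinite(r.log_or)]
    if not results:
        raise ValueError("no study with a finite log odds ratio")

    if method == "dl":
        y = np.array([r.log_or for r in results])
        v = np.array([r.var_log_or for r in results])
        return _dl_pool(y, v)
    if method == "mh":
        tables = [x for x in inputs if isinstance(x, ContingencyTable)]
        if len(tables) != len(inputs):
            raise ValueError("Mantel-Haenszel pooling needs the raw tables")
        num = den = 0.0
        for t in tables:
            a, b, c, d = t.cells
            n = a + b + c + d
            num += a * d / n
            den += b * c / n
        orr = num / den
        # Robins-Breslow-Greenland variance for the MH log-OR
        r_sum = s_sum = prr = prs_psr = pss = 0.0
        for t in tables:
            a, b, c, d = t.cells
            n = a + b + c + d
            p_, q_ = (a + d) / n, (b + c) / n
            r_, s_ = a * d / n, b * c / n
            r_sum += r_
            s_sum += s_
            prr += p_ * r_
            prs_psr += p_ * s_ + q_ * r_
            pss += q_ * s_
        var = prr / (2 * r_sum**2) + prs_psr / (2 * r_sum * s_sum) + pss / (2 * s_sum**2)
        se = math.sqrt(var)
        mu = math.log(orr)
        return MetaResult(
            pooled_or=orr,
            ci_low=math.exp(mu - 1.959963984540054 * se),
            ci_high=math.exp(mu + 1.959963984540054 * se),
            tau_squared=0.0,
            q_statistic=0.0,
            n_studies=len(tables),
            model="mh",
            p_value=float(2 * stats.norm.sf(abs(mu / se))),
        )
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# locus burden on called data


def locus_burden(
    calls_or_regions: Sequence[CnvCall | CnvRegion],
    loci: Sequence[LocusDef],
    overlap_rule: str = "any",
) -> dict[str, set[str]]:
    """Per-locus sets of carrier samples among the supplied calls.

    A sample is a carrier at a locus when it holds a surviving call of the
    matching type overlapping the locus by >= 1 bp (``overlap_rule="any"``,
    the default and only rule implemented).
    """
    if overlap_rule != "any":
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")
    calls: list[CnvCall] = []
    for item in calls_or_regions:
        calls.extend(item.calls if isinstance(item, CnvRegion) else [item])
    carriers: dict[str, set[str]] = {locus.name: set() for locus in loci}
    for locus in loci:
        for c in calls:
            if (
                c.chromosome == locus.chromosome
                and c.start <= locus.end
                and c.end >= locus.start
                and locus.matches(c)
            ):
                carriers[locus.name].add(c.sample_id)
    return carriers


def carrier_level_counts(
    carriers_per_locus: dict[str, set[str]], n_cases: int
) -> tuple[int, float]:
    """Distinct carriers across all loci and their frequency among cases."""
    all_carriers = set().union(*carriers_per_locus.values()) if carriers_per_locus else set()
    return len(all_carriers), len(all_carriers) / n_cases


# ---------------------------------------------------------------------------
# packaged-table computations


def carrier_level_tables(
    case_carriers: int | None = None,
    n_cases: int = N_CASES_QC,
    loci: pd.DataFrame | None = None,
    studies: dict[str, int] | None = None,
) -> list[ContingencyTable]:
    """One carriers-vs-noncarriers table per control study, summed over loci.

    Control carrier totals sum each study's available locus counts; the case
    total defaults to the column sum of the packaged table.
    """
    loci = load_scz_loci() if loci is None else loci
    studies = load_control_studies() if studies is None else studies
    if case_carriers is None:
        case_carriers = int(loci["case_carriers"].sum())
    tables = []
    for study, n in studies.items():
        tables.append(
            ContingencyTable.from_counts(
                case_carriers, n_cases, int(loci[study].sum()), n
            )
        )
    return tables


def per_locus_tables(
    loci: pd.DataFrame | None = None,
    studies: dict[str, int] | None = None,
    case_n: int = N_CASES_QC,
) -> dict[str, ContingencyTable]:
    """SA-vs-merged-controls table per locus, excluding n/a studies."""
    loci = load_scz_loci() if loci is None else loci
    studies = load_control_studies() if studies is None else studies
    out: dict[str, ContingencyTable] = {}
    for _, row in loci.iterrows():
        carriers, total = merged_control_counts(row, studies)
        out[row["locus"]] = ContingencyTable.from_counts(
            int(row["case_carriers"]), case_n, carriers, total
        )
    return out


def sensitivity_nullify(
    loci_to_zero: Iterable[str],
    loci: pd.DataFrame | None = None,
    studies: dict[str, int] | None = None,
    method: str = "dl",
) -> MetaResult:
    """Zero the case carrier counts at named loci and re-pool per-locus ORs."""
    loci = (load_scz_loci() if loci is None else loci).copy()
    to_zero = set(loci_to_zero)
    unknown = to_zero - set(loci["locus"])
    if unknown:
        raise ValueError(f"unknown loci: {sorted(unknown)}")
    loci.loc[loci["locus"].isin(to_zero), "case_carriers"] = 0
    tables = per_locus_tables(loci, studies)
    return pool_random_effects(list(tables.values()), method=method)
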