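"""Readers and writers for the plain-text formats the pipeline exchanges.

* per-sample intensity reports: tab-delimited with header
  ``Name  Chr  Position  Log R Ratio  B Allele Freq``
* pedigrees: 6-column PED/FAM (family, individual, father, mother, sex,
  phenotype)
* CNV call lists: one call per line in the common caller dialect
  ``chr1:1000-2000  numsnp=40  length=1001  state2,cn=1  sample1``
* BED intervals (blacklists, segmental duplications, gene models): BED is
  0-based half-open on disk and converted to the package's 1-based
  inclusive convention at this boundary.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneModel
from .pipeline import CnvCall
from .simulate import CnvEvent, IntensityPanel, MarkerMap, Trio

__all__ = [
    "write_intensity_files",
    "read_intensity_files",
    "write_ped",
    "read_ped",
    "write_cnv_calls",
    "read_cnv_calls",
    "read_bed",
    "write_truth_events",
    "read_gene_models",
    "read_gene_set",
]

_INTENSITY_HEADER = ["Name", "Chr", "Position", "Log R Ratio", "B Allele Freq"]


def write_intensity_files(panel: IntensityPanel, out_dir: str | Path) -> list[Path]:
    """Write one tab-delimited intensity report per sample; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = panel.markers
    paths = []
    for i, sample in enumerate(panel.sample_ids):
        df = pd.DataFrame(
            {
                "Name": m.marker_id,
                "Chr": m.chromosome,
                "Position": m.position,
                "Log R Ratio": panel.lrr[i],
                "B Allele Freq": panel.baf[i],
            }
        )
        path = out_dir / f"{sample}.txt"
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")
        paths.append(path)
    return paths


def read_intensity_files(
    paths: Sequence[str | Path], marker_map: MarkerMap | None = None
) -> IntensityPanel:
    """Assemble a panel from per-sample reports (sample id = file stem).

    All files must share the marker order of the first; ``marker_map``
    supplies probe class and GC annotation when available (otherwise a
    minimal map is built from the first file).
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no intensity files supplied")
    first = pd.read_csv(paths[0], sep="\t")
    missing = [c for c in _INTENSITY_HEADER if c not in first.columns]
    if missing:
        raise ValueError(f"{paths[0]}: missing columns {missing}")
    if marker_map is None:
        marker_map = MarkerMap(
            marker_id=first["Name"].to_numpy(dtype=object),
            chromosome=first["Chr"].astype(str).to_numpy(dtype=object),
            position=first["Position"].to_numpy(dtype=np.int64),
            is_cnv_probe=np.array([str(x).startswith("cnvi") for x in first["Name"]]),
            gc_fraction=np.full(len(first), 0.5),
        )
    lrr = np.empty((len(paths), marker_map.n_markers))
    baf = np.empty_like(lrr)
    samples = []
    for i, path in enumerate(paths):
        df = first if i == 0 else pd.read_csv(path, sep="\t")
        if not np.array_equal(df["Name"].to_numpy(dtype=object), marker_map.marker_id):
            raise ValueError(f"{path}: marker order differs from the map")
        lrr[i] = df["Log R Ratio"].to_numpy(float)
        baf[i] = df["B Allele Freq"].to_numpy(float)
        samples.append(path.stem)
    return IntensityPanel(samples, marker_map, lrr, np.clip(baf, 0, 1))


def write_ped(trios: Sequence[Trio], path: str | Path) -> None:
    """Write trios as 6-column PED/FAM rows (parents then offspring)."""
    with open(path, "w") as fh:
        for t in trios:
            fh.write(f"{t.family_id}\t{t.father_id}\t0\t0\t1\t1\n")
            fh.write(f"{t.family_id}\t{t.mother_id}\t0\t0\t2\t1\n")
            sex = 1 if t.offspring_sex == "M" else 2
            pheno = 2 if t.offspring_affected else 1
            fh.write(f"{t.family_id}\t{t.offspring_id}\t{t.father_id}\t{t.mother_id}\t{sex}\t{pheno}\n")


def read_ped(path: str | Path) -> list[Trio]:
    """Reconstruct trios from a 6-column PED/FAM file.

    An individual with both parent ids set is the offspring of its family;
    each family must yield exactly one offspring whose parents appear.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns")
            rows.append(parts[:6])
    present = {(fam, iid) for fam, iid, *_ in rows}
    trios = []
    for fam, iid, father, mother, sex, pheno in rows:
        if father != "0" and mother != "0":
            if (fam, father) not in present or (fam, mother) not in present:
                raise ValueError(f"family {fam}: offspring {iid} has absent parents")
            trios.append(
                Trio(
                    family_id=fam,
                    father_id=father,
                    mother_id=mother,
                    offspring_id=iid,
                    offspring_sex="M" if sex == "1" else "F",
                    offspring_affected=pheno == "2",
                )
            )
    return trios


_CALL_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+numsnp=(?P<numsnp>\d+)\s+"
    r"length=(?P<length>[\d,]+)\s+state\d+,cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
)

_STATE_OF_CN = {0: 1, 1: 2, 2: 3, 3: 5, 4: 6}


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            state = _STATE_OF_CN[c.copy_number]
            fh.write(
                f"{c.chromosome}:{c.start}-{c.end}\tnumsnp={c.n_markers}\t"
                f"length={c.length}\tstate{state},cn={c.copy_number}\t{c.sample_id}\n"
            )


def read_cnv_calls(path: str | Path) -> list[CnvCall]:
    """Parse a caller-dialect CNV list (one call per line)."""
    calls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            m = _CALL_RE.match(line)
            if m is None:
                raise ValueError(f"{path}:{ln}: unparseable call line")
            calls.append(
                CnvCall(
                    sample_id=m["sample"],
                    chromosome=m["chrom"],
                    start=int(m["start"]),
                    end=int(m["end"]),
                    copy_number=int(m["cn"]),
                    n_markers=int(m["numsnp"]),
                )
            )
    return calls


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals, converting 0-based half-open to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from None
            if end0 <= start0:
                raise ValueError(f"{path}:{ln}: empty or inverted BED interval")
            out.append((parts[0], start0 + 1, end0))
    return out


def write_truth_events(events: Iterable[CnvEvent], path: str | Path) -> None:
    """Write ground-truth events as BED-plus (extra columns sample, CN, origin)."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                f"{ev.chromosome}\t{ev.start - 1}\t{ev.end}\t{ev.sample_id}\t"
                f"{ev.copy_number}\t{ev.origin}\n"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene models from BED (chrom, start0, end0, symbol) or 4-column TSV
    with a header (symbol, chromosome, start, end; 1-based)."""
    with open(path) as fh:
        first = fh.readline()
    if first.lower().startswith("symbol"):
        df = pd.read_csv(path, sep="\t")
        return [
            GeneModel(r.symbol, r.chromosome, int(r.start), int(r.end))
            for r in df.itertuples()
        ]
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: gene BED needs 4 columns")
            genes.append(GeneModel(parts[3], parts[0], int(parts[1]) + 1, int(parts[2])))
    return genes


def read_gene_set(path: str | Path) -> list[str]:
    """Newline-delimited gene symbol list (blank lines ignored)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
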