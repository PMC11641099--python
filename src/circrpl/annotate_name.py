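"""Classify circRNAs against gene models and assign standardized names.

Classes: *exonic* when both BSJ termini coincide (within a small boundary
tolerance) with annotated exon boundaries of one gene; *intronic* when the
whole span lies inside a single intron of one gene; *intergenic* when the
span overlaps no gene body.  Gene-overlapping records that fit none of the
above default to exonic on the best-overlapping gene.

Names follow the hsa-circHUGO-### / hsa-ciHUGO / hsa-circChrom#-### scheme:
exonic circRNAs take their host gene symbol and a three-digit serial number
ordered by genomic position within the gene; intronic ones take the ci
prefix (a serial suffix only when one gene hosts more than one); intergenic
ones are numbered by position within their chromosome.  Naming is a pure
function of the sorted record set, so input order never changes a name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .io_formats import AnnotationIndex, BSJKey

NAME_RE = re.compile(r"^hsa-(circ|ci)[A-Za-z0-9.\-]+(-\d{3})?$")

#: positional tolerance (nt) when matching BSJ termini to exon boundaries;
#: detectors wobble by a base or two at splice sites
BOUNDARY_TOL = 2


class NumberingOverflowError(RuntimeError):
    """More than 999 circRNAs would share one name stem."""


@dataclass
class CircRecord:
    key: BSJKey
    circ_class: str  # exonic | intronic | intergenic
    host_gene: str | None
    name: str | None = None
    known: bool = False


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def classify_circ(
    key: BSJKey, ann: AnnotationIndex, tol: int = BOUNDARY_TOL
) -> tuple[str, str | None]:
    """Return (circ_class, host_gene) for one BSJ."""
    hits = ann.genes_overlapping(key.chrom, key.start, key.end)
    if not hits:
        return ("intergenic", None)
    exonic, intronic = [], []
    for g in hits:
        bounds = ann.exon_boundaries(g)
        if any(abs(key.start - b) <= tol for b in bounds) and any(
            abs(key.end - b) <= tol for b in bounds
        ):
            exonic.append(g)
        for s, e in ann.introns(g):
            if s <= key.start and key.end <= e:
                intronic.append(g)
                break

    def best(genes: list[str]) -> str:
        # ties: largest overlap fraction, then alphabetical
        scored = sorted(
            genes,
            key=lambda g: (
                -_overlap_len((key.start, key.end), ann.genes[g][2:4]),
                g,
            ),
        )
        return scored[0]

    if exonic:
        return ("exonic", best(exonic))
    if intronic:
        return ("intronic", best(intronic))
    return ("exonic", best(hits))


def _chrom_stem(chrom: str) -> str:
    return "Chrom" + (chrom[3:] if chrom.lower().startswith("chr") else chrom)


def assign_names(records: list[CircRecord]) -> list[CircRecord]:
    """Assign unique names; deterministic in the record *set*, not its order."""
    ordered = sorted(
        records, key=lambda r: (r.key.chrom, r.key.start, r.key.end, r.key.strand)
    )
    # group intronic records per gene to decide whether a serial is needed
    intronic_per_gene: dict[str, int] = {}
    for r in ordered:
        if r.circ_class == "intronic":
            intronic_per_gene[r.host_gene] = intronic_per_gene.get(r.host_gene, 0) + 1
    counters: dict[tuple[str, str], int] = {}
    names: set[str] = set()
    for r in ordered:
        if r.circ_class == "exonic":
            stem, serial = f"hsa-circ{r.host_gene}", True
        elif r.circ_class == "intronic":
            stem = f"hsa-ci{r.host_gene}"
            serial = intronic_per_gene[r.host_gene] > 1
        else:
            stem, serial = f"hsa-circ{_chrom_stem(r.key.chrom)}", True
        if serial:
            n = counters.get((r.circ_class, stem), 0) + 1
            counters[(r.circ_class, stem)] = n
            if n > 999:
                raise NumberingOverflowError(f"more than 999 circRNAs named {stem}")
            r.name = f"{stem}-{n:03d}"
        else:
            r.name = stem
        if r.name in names:
            raise NumberingOverflowError(f"name collision on {r.name}")
        names.add(r.name)
    return ordered


def per_gene_summary(records: list[CircRecord]) -> pd.DataFrame:
    rows: dict[str, int] = {}
    for r in records:
        if r.host_gene is not None:
            rows[r.host_gene] = rows.get(r.host_gene, 0) + 1
    df = pd.DataFrame(
        sorted(rows.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "n_circRNAs"],
    )
    return df


def per_chrom_summary(records: list[CircRecord]) -> pd.DataFrame:
    rows: dict[str, int] = {}
    for r in records:
        rows[r.key.chrom] = rows.get(r.key.chrom, 0) + 1
    return pd.DataFrame(
        sorted(rows.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["chrom", "n_circRNAs"],
    )


def records_to_frame(records: list[CircRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "chrom": r.key.chrom,
                "start": r.key.start,
                "end": r.key.end,
                "strand": r.key.strand,
                "class": r.circ_class,
                "host_gene": r.host_gene if r.host_gene is not None else ".",
                "known": r.known,
            }
            for r in records
        ],
        columns=["name", "chrom", "start", "end", "strand", "class", "host_gene", "known"],
    )


def frame_to_records(df: pd.DataFrame) -> list[CircRecord]:
    out = []
    for _, r in df.iterrows():
        out.append(
            CircRecord(
                key=BSJKey(str(r["chrom"]), int(r["start"]), int(r["end"]), str(r["strand"])),
                circ_class=str(r["class"]),
                host_gene=None if str(r["host_gene"]) == "." else str(r["host_gene"]),
                name=str(r["name"]),
                known=bool(r["known"]),
            )
        )
    return out
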