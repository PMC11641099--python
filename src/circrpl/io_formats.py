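"""Readers and writers for every external table the pipeline touches.

All coordinates are held internally in a single canonical convention:
**1-based, fully closed intervals** (both endpoints are genomic bases that
belong to the feature).  Each reader declares the dialect of its source
format explicitly and converts on read; writers convert back.  The two
detector dialects supported are:

* DCC-style paired tables (``CircRNACount`` + ``CircCoordinates``), whose
  start column is 0-based and end column 1-based (BED-like half-open).
* CIRI2-style per-sample tables, natively 1-based closed, identified by a
  ``circRNA_ID`` of the form ``chrom:start|end``.

Sample order always comes from the sample sheet, never from file column
order, so per-stage files cannot silently permute samples.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

VALID_STRANDS = {"+", "-", "."}

__all__ = [
    "BSJKey",
    "CircCall",
    "AnnotationIndex",
    "LiftMap",
    "CountMatrix",
    "FormatError",
    "DialectError",
    "DuplicateError",
    "MetadataError",
    "read_dcc_calls",
    "write_dcc_calls",
    "read_ciri2_calls",
    "write_ciri2_calls",
    "read_gtf",
    "write_gtf",
    "read_gmt",
    "write_gmt",
    "read_catalogue",
    "write_catalogue",
    "read_liftmap",
    "write_liftmap",
    "read_samplesheet",
    "write_samplesheet",
    "read_counts",
    "write_counts",
    "read_gene_list",
    "write_gene_list",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class DialectError(FormatError):
    """Paired detector files disagree with each other."""


class DuplicateError(FormatError):
    """The same record occurs more than once where uniqueness is required."""


class MetadataError(ValueError):
    """Sample metadata and data tables are inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class BSJKey:
    """Canonical back-splice junction: 1-based closed genomic interval.

    ``start`` is the leftmost base of the circRNA, ``end`` the rightmost.
    Equality is exact on (chrom, start, end, strand).
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end < start for {self.chrom}:{self.start}|{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def id(self) -> str:
        """Serialize as ``chrom:start|end:strand``."""
        return f"{self.chrom}:{self.start}|{self.end}:{self.strand}"

    @classmethod
    def from_id(cls, s: str) -> "BSJKey":
        m = re.fullmatch(r"(.+):(\d+)\|(\d+):([+.\-])", s)
        if m is None:
            raise FormatError(f"unparsable BSJ id {s!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)), m.group(4))

    def unstranded(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class CircCall:
    """A detector-attributed BSJ with per-sample junction-read counts."""

    key: BSJKey
    detector: str
    counts: dict[str, int] = field(default_factory=dict)
    circ_type: str | None = None


class AnnotationIndex:
    """Gene/exon models from a GTF, queryable by point or interval.

    Exon intervals are 1-based closed and lie within their gene's span.
    """

    def __init__(
        self,
        genes: Mapping[str, tuple[str, str, int, int]],
        exons: Mapping[str, list[tuple[int, int]]],
    ) -> None:
        self.genes = dict(genes)  # name -> (chrom, strand, start, end)
        self.exons = {g: sorted(ivs) for g, ivs in exons.items()}
        for g, ivs in self.exons.items():
            chrom, strand, gs, ge = self.genes[g]
            for s, e in ivs:
                if s < gs or e > ge:
                    raise FormatError(
                        f"exon {s}-{e} outside span of gene {g} ({gs}-{ge})"
                    )
        self._trees: dict[str, IntervalTree] = {}
        for name, (chrom, _strand, s, e) in self.genes.items():
            self._trees.setdefault(chrom, IntervalTree()).addi(s, e + 1, name)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Gene names whose body overlaps [start, end] (1-based closed)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end + 1))

    def introns(self, gene: str) -> list[tuple[int, int]]:
        """Intron intervals (1-based closed) between consecutive exons."""
        ivs = self.exons.get(gene, [])
        out = []
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def exon_boundaries(self, gene: str) -> set[int]:
        out: set[int] = set()
        for s, e in self.exons.get(gene, []):
            out.add(s)
            out.add(e)
        return out


class LiftMap:
    """Interval map from one genome's coordinates to another's.

    Each source interval maps to an equal-length target interval; target
    strand ``-`` flips orientation within the interval.  Source intervals
    must not overlap.
    """

    def __init__(
        self,
        intervals: Iterable[
            tuple[str, int, int, str, int, int, str]
        ],
    ) -> None:
        # (src_chrom, src_start, src_end, tgt_chrom, tgt_start, tgt_end, strand)
        self._trees: dict[str, IntervalTree] = {}
        self.intervals = []
        for rec in intervals:
            sc, ss, se, tc, ts, te, st = rec
            if se - ss != te - ts:
                raise FormatError(
                    f"lift interval lengths differ: {sc}:{ss}-{se} vs {tc}:{ts}-{te}"
                )
            if st not in {"+", "-"}:
                raise FormatError(f"lift interval strand must be +/-, got {st!r}")
            tree = self._trees.setdefault(sc, IntervalTree())
            if tree.overlap(ss, se + 1):
                raise FormatError(
                    f"overlapping source intervals in lift map at {sc}:{ss}-{se}"
                )
            tree.addi(ss, se + 1, (tc, ts, te, st))
            self.intervals.append(tuple(rec))

    def lift(self, chrom: str, pos: int) -> tuple[str, int, str] | None:
        """Map a single 1-based position; None if it falls in no interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree.at(pos)
        if not hits:
            return None
        iv = next(iter(hits))
        tc, ts, te, st = iv.data
        if st == "+":
            return (tc, ts + (pos - iv.begin), st)
        return (tc, te - (pos - iv.begin), st)


@dataclass
class CountMatrix:
    """circRNAs x samples junction counts plus aligned sample metadata.

    ``counts`` is indexed by BSJ id strings; ``samples`` is the sample
    sheet indexed by sample_id, in the same order as the count columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise MetadataError("count columns do not match sample sheet order")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts in count matrix")
        if self.counts.index.has_duplicates:
            raise DuplicateError("duplicate feature keys in count matrix")

    @property
    def keys(self) -> list[BSJKey]:
        return [BSJKey.from_id(i) for i in self.counts.index]

    def subset_project(self, project_id: str) -> "CountMatrix":
        mask = self.samples["project_id"] == project_id
        if not mask.any():
            raise MetadataError(f"no samples for project {project_id!r}")
        samples = self.samples.loc[mask]
        return CountMatrix(self.counts.loc[:, samples.index], samples)

    def subset_features(self, ids: Iterable[str]) -> "CountMatrix":
        ids = [i for i in ids]
        return CountMatrix(self.counts.loc[ids], self.samples)


# ---------------------------------------------------------------------------
# Detector dialects
# ---------------------------------------------------------------------------


def read_dcc_calls(count_path, coords_path) -> list[CircCall]:
    """Read paired DCC-style tables into canonical calls.

    ``CircRNACount`` columns: Chr, Start, End, then one column per sample.
    ``CircCoordinates`` columns: Chr, Start, End, Gene, JunctionType, Strand.
    Both files share row order.  The dialect is 0-based start / 1-based end;
    the start is shifted +1 on read.
    """
    cnt = pd.read_csv(count_path, sep="\t", dtype={"Chr": str})
    coo = pd.read_csv(coords_path, sep="\t", dtype={"Chr": str})
    for col in ("Chr", "Start", "End"):
        if col not in cnt.columns or col not in coo.columns:
            raise FormatError(f"missing mandatory column {col!r} in DCC files")
    if "Strand" not in coo.columns:
        raise FormatError("missing Strand column in CircCoordinates file")
    if len(cnt) != len(coo):
        raise DialectError(
            f"row count mismatch: {len(cnt)} in {count_path} vs {len(coo)} in {coords_path}"
        )
    sample_cols = [c for c in cnt.columns if c not in ("Chr", "Start", "End")]
    calls = []
    for i in range(len(cnt)):
        r, c = cnt.iloc[i], coo.iloc[i]
        if (r["Chr"], r["Start"], r["End"]) != (c["Chr"], c["Start"], c["End"]):
            raise DialectError(f"coordinate mismatch between DCC files at row {i}")
        strand = str(c["Strand"])
        if strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand symbol {strand!r} at row {i}")
        counts = {}
        for s in sample_cols:
            v = int(r[s])
            if v < 0:
                raise ValueError(f"negative count at row {i}, sample {s}")
            counts[s] = v
        key = BSJKey(str(r["Chr"]), int(r["Start"]) + 1, int(r["End"]), strand)
        calls.append(
            CircCall(key, "DCC", counts, str(c["Gene"]) if "Gene" in coo.columns else None)
        )
    return calls


def write_dcc_calls(calls: list[CircCall], count_path, coords_path) -> None:
    """Write canonical calls back into the DCC dialect (start shifted -1)."""
    samples = sorted({s for c in calls for s in c.counts})
    rows_cnt, rows_coo = [], []
    for c in sorted(calls, key=lambda c: c.key):
        base = {"Chr": c.key.chrom, "Start": c.key.start - 1, "End": c.key.end}
        rows_cnt.append({**base, **{s: c.counts.get(s, 0) for s in samples}})
        rows_coo.append(
            {**base, "Gene": c.circ_type or ".", "JunctionType": 1, "Strand": c.key.strand}
        )
    cols = ["Chr", "Start", "End"] + samples
    pd.DataFrame(rows_cnt, columns=cols).to_csv(count_path, sep="\t", index=False)
    pd.DataFrame(
        rows_coo, columns=["Chr", "Start", "End", "Gene", "JunctionType", "Strand"]
    ).to_csv(coords_path, sep="\t", index=False)


CIRI2_COLUMNS = [
    "circRNA_ID",
    "chr",
    "start",
    "end",
    "junction_reads",
    "strand",
    "circRNA_type",
]


def read_ciri2_calls(path, sample_id: str | None = None) -> list[CircCall]:
    """Read a per-sample CIRI2-style table (1-based closed coordinates).

    The ``circRNA_ID`` field (``chrom:start|end``) is authoritative for
    coordinates.  ``sample_id`` defaults to the file stem.
    """
    if sample_id is None:
        sample_id = Path(path).stem
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    for col in CIRI2_COLUMNS[:-1]:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    calls, seen = [], set()
    for i, row in enumerate(df.itertuples(index=False)):
        m = re.fullmatch(r"(.+):(\d+)\|(\d+)", str(row.circRNA_ID))
        if m is None:
            raise ValueError(
                f"unparsable circRNA_ID {row.circRNA_ID!r} at row {i} of {path}"
            )
        strand = str(row.strand)
        if strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand symbol {strand!r} at row {i}")
        try:
            key = BSJKey(m.group(1), int(m.group(2)), int(m.group(3)), strand)
        except ValueError as exc:
            raise ValueError(f"row {i} of {path}: {exc}") from exc
        if key in seen:
            raise DuplicateError(f"duplicate call for {key.id()} in {path}")
        seen.add(key)
        reads = int(row.junction_reads)
        if reads < 0:
            raise ValueError(f"negative junction_reads at row {i}")
        ctype = getattr(row, "circRNA_type", None)
        calls.append(CircCall(key, "CIRI2", {sample_id: reads}, ctype))
    return calls


def write_ciri2_calls(calls: list[CircCall], path, sample_id: str) -> None:
    rows = []
    for c in sorted(calls, key=lambda c: c.key):
        k = c.key
        rows.append(
            {
                "circRNA_ID": f"{k.chrom}:{k.start}|{k.end}",
                "chr": k.chrom,
                "start": k.start,
                "end": k.end,
                "junction_reads": c.counts.get(sample_id, 0),
                "strand": k.strand,
                "circRNA_type": c.circ_type or "unknown",
            }
        )
    pd.DataFrame(rows, columns=CIRI2_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF / GMT / catalogue / lift map / sample sheet / counts
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> AnnotationIndex:
    """Load gene and exon features from an Ensembl-attribute-style GTF."""
    genes: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path} line {lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            if feature not in ("gene", "exon"):
                continue
            m = dict(_GTF_ATTR.findall(attrs))
            if "gene_name" not in m:
                raise FormatError(f"{path} line {lineno}: missing gene_name attribute")
            name = m["gene_name"]
            s, e = int(start), int(end)
            if feature == "gene":
                genes[name] = (chrom, strand, s, e)
            else:
                exons.setdefault(name, []).append((s, e))
    return AnnotationIndex(genes, exons)


def write_gtf(ann: AnnotationIndex, path) -> None:
    lines = []
    for name in sorted(ann.genes):
        chrom, strand, s, e = ann.genes[name]
        attrs = f'gene_id "{name}"; gene_name "{name}";'
        lines.append(f"{chrom}\tcircrpl\tgene\t{s}\t{e}\t.\t{strand}\t.\t{attrs}")
        for es, ee in ann.exons.get(name, []):
            lines.append(
                f"{chrom}\tcircrpl\texon\t{es}\t{ee}\t.\t{strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path} line {lineno}: GMT needs name, description, >=1 member"
                )
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions=None) -> None:
    lines = []
    for name in sorted(sets):
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc] + sorted(sets[name])))
    Path(path).write_text("\n".join(lines) + "\n")


def read_catalogue(path) -> set[BSJKey]:
    """Read a BED-like circRNA catalogue (1-based closed TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end", "strand"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    return {
        BSJKey(str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples(index=False)
    }


def write_catalogue(keys: Iterable[BSJKey], path) -> None:
    rows = [
        {"chrom": k.chrom, "start": k.start, "end": k.end, "strand": k.strand}
        for k in sorted(keys)
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


LIFTMAP_COLUMNS = [
    "src_chrom",
    "src_start",
    "src_end",
    "tgt_chrom",
    "tgt_start",
    "tgt_end",
    "tgt_strand",
]


def read_liftmap(path) -> LiftMap:
    df = pd.read_csv(path, sep="\t", dtype={"src_chrom": str, "tgt_chrom": str})
    for col in LIFTMAP_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    return LiftMap(
        (
            str(r.src_chrom),
            int(r.src_start),
            int(r.src_end),
            str(r.tgt_chrom),
            int(r.tgt_start),
            int(r.tgt_end),
            str(r.tgt_strand),
        )
        for r in df.itertuples(index=False)
    )


def write_liftmap(lm: LiftMap, path) -> None:
    pd.DataFrame(sorted(lm.intervals), columns=LIFTMAP_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


SAMPLESHEET_COLUMNS = ["sample_id", "project_id", "condition", "library_size"]


def read_samplesheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "project_id": str})
    for col in SAMPLESHEET_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    if df["sample_id"].duplicated().any():
        raise DuplicateError(f"duplicate sample_id in {path}")
    bad = ~df["condition"].isin(["control", "RPL"])
    if bad.any():
        raise FormatError(
            f"{path}: condition must be control/RPL, got {df.loc[bad, 'condition'].iloc[0]!r}"
        )
    if (df["library_size"] <= 0).any():
        raise FormatError(f"{path}: library_size must be > 0")
    return df.set_index("sample_id")


def write_samplesheet(samples: pd.DataFrame, path) -> None:
    samples.reset_index().to_csv(path, sep="\t", index=False)


def read_counts(path, samples: pd.DataFrame, allow_extra: bool = False) -> CountMatrix:
    """Read a junction-count matrix keyed by BSJ, ordered by the sample sheet.

    With ``allow_extra`` the file may carry columns for samples outside the
    (possibly project-restricted) sheet; they are dropped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    extra = [c for c in df.columns if c not in samples.index]
    if extra and not allow_extra:
        raise MetadataError(f"samples in counts but not in sample sheet: {extra}")
    missing = [s for s in samples.index if s not in df.columns]
    if missing:
        raise MetadataError(f"samples in sample sheet but not in counts: {missing}")
    df.index = df.index.astype(str)
    for i in df.index:
        BSJKey.from_id(i)  # validate
    return CountMatrix(df.loc[:, list(samples.index)].astype(int), samples)


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "bsj_id"
    out.to_csv(path, sep="\t")


def read_gene_list(path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def majority_strand(strands: Iterable[str]) -> str:
    """Resolve detector strand disagreement: majority vote, '.' on ties.

    '.' entries abstain; if all abstain the result is '.'.
    """
    votes = [s for s in strands if s in {"+", "-"}]
    if not votes:
        return "."
    plus = votes.count("+")
    minus = len(votes) - plus
    if plus > minus:
        return "+"
    if minus > plus:
        return "-"
    return "."
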