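"""Consolidate two detectors' BSJ calls into one canonical set per project.

A circRNA is retained only when both detectors report exactly the same
back-splice junction after dialect normalization — no positional fuzz is
applied at this stage.  Junction-read counts for downstream analysis come
from a single designated quantification table (the re-alignment-based
quantifier), never from the detectors' own counts, which are retained only
as provenance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .io_formats import BSJKey, CircCall, CountMatrix, MetadataError, majority_strand

log = logging.getLogger(__name__)


@dataclass
class ConsolidatedSet:
    """BSJs called by both detectors, with attached per-sample counts."""

    project_id: str
    records: dict[BSJKey, dict[str, int]] = field(default_factory=dict)
    provenance: dict[BSJKey, dict[str, dict[str, int]]] = field(default_factory=dict)
    known: dict[BSJKey, bool] = field(default_factory=dict)


def _collapse(calls: list[CircCall]) -> dict[BSJKey, dict[str, int]]:
    """Merge per-sample counts per key; duplicate (key, sample) keeps max."""
    out: dict[BSJKey, dict[str, int]] = {}
    for c in calls:
        slot = out.setdefault(c.key, {})
        for sample, n in c.counts.items():
            if sample in slot and slot[sample] != n:
                warnings.warn(
                    f"duplicate call for {c.key.id()} in sample {sample}; keeping max",
                    stacklevel=2,
                )
            slot[sample] = max(slot.get(sample, 0), n)
    return out


def intersect_calls(
    dcc: list[CircCall],
    ciri: list[CircCall],
    match_strand: bool = True,
    project_id: str = "NA",
) -> ConsolidatedSet:
    """Exact-match intersection of the two detectors' BSJ key sets.

    With ``match_strand`` off, keys are matched on (chrom, start, end) only
    and the consolidated strand is resolved by majority vote across the two
    detectors ('.' when they conflict).
    """
    d = _collapse(dcc)
    c = _collapse(ciri)
    cons = ConsolidatedSet(project_id=project_id)
    if match_strand:
        for key in sorted(set(d) & set(c)):
            cons.records[key] = {}
            cons.provenance[key] = {"DCC": d[key], "CIRI2": c[key]}
    else:
        d_by_pos: dict[tuple, list[BSJKey]] = {}
        for key in d:
            d_by_pos.setdefault(key.unstranded(), []).append(key)
        c_by_pos: dict[tuple, list[BSJKey]] = {}
        for key in c:
            c_by_pos.setdefault(key.unstranded(), []).append(key)
        for pos in sorted(set(d_by_pos) & set(c_by_pos)):
            dk, ck = sorted(d_by_pos[pos])[0], sorted(c_by_pos[pos])[0]
            strand = majority_strand([dk.strand, ck.strand])
            key = BSJKey(pos[0], pos[1], pos[2], strand)
            cons.records[key] = {}
            cons.provenance[key] = {"DCC": d[dk], "CIRI2": c[ck]}
    return cons


def attach_counts(cons: ConsolidatedSet, counts: CountMatrix) -> ConsolidatedSet:
    """Attach quantification counts for every sample in the sample sheet.

    Consolidated BSJs absent from the quantification table get explicit
    zeros (with a warning) rather than being dropped.
    """
    sample_ids = list(counts.samples.index)
    by_id = counts.counts
    for key in cons.records:
        kid = key.id()
        if kid in by_id.index:
            row = by_id.loc[kid]
            cons.records[key] = {s: int(row[s]) for s in sample_ids}
        else:
            log.warning("BSJ %s missing from quantification; using zeros", kid)
            cons.records[key] = {s: 0 for s in sample_ids}
    return cons


def flag_known(cons: ConsolidatedSet, catalogue: set[BSJKey]) -> dict[BSJKey, bool]:
    """Known iff exact (chrom, start, end, strand) match in the catalogue."""
    cons.known = {key: key in catalogue for key in cons.records}
    return cons.known
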