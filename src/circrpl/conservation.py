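"""Cross-species conservation of back-splice junctions.

Each BSJ's 5' and 3' splice positions are lifted to the target species
through an interval map, then compared against that species' circRNA
catalogue.  A catalogued circRNA *uses* a lifted site when either of its
boundaries (on the lifted chromosome) falls within a +/- window of it;
this boundary-set matching is strand-agnostic on the target side, which
keeps the classification invariant under orientation-flipping lifts.

Six mutually exclusive categories are assigned:

* ``not-aligned`` — at least one splice site failed to lift;
* ``no homologous`` — no catalogued circRNA near either lifted site;
* ``5' site utilized`` / ``3' site utilized`` — only one site is used;
* ``both sites utilized`` — both sites are used, but by different circRNAs;
* ``homologous`` — one catalogued circRNA uses both sites.

Site orientation follows the transcribed strand: on '+' the 5' acceptor is
the interval start and the 3' donor the end; flipped on '-'; unstranded
records use (start, end) as (5', 3').
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import BSJKey, LiftMap

CATEGORIES = [
    "not-aligned",
    "no homologous",
    "5' site utilized",
    "3' site utilized",
    "both sites utilized",
    "homologous",
]

DEFAULT_WINDOW = 2


@dataclass
class ConservationCall:
    key: BSJKey
    lifted_5p: tuple[str, int] | None
    lifted_3p: tuple[str, int] | None
    category: str


def splice_sites(key: BSJKey) -> tuple[int, int]:
    """(5' site, 3' site) genomic positions on the transcribed strand."""
    if key.strand == "-":
        return (key.end, key.start)
    return (key.start, key.end)


def lift_site(chrom: str, pos: int, liftmap: LiftMap):
    """Map one 1-based position; returns (chrom, pos, strand) or None."""
    return liftmap.lift(chrom, pos)


def classify_conservation(
    key: BSJKey,
    liftmap: LiftMap,
    catalogue: set[BSJKey],
    window: int = DEFAULT_WINDOW,
) -> ConservationCall:
    """Assign one of the six conservation categories to a BSJ."""
    p5, p3 = splice_sites(key)
    l5 = liftmap.lift(key.chrom, p5)
    l3 = liftmap.lift(key.chrom, p3)
    if l5 is None or l3 is None:
        return ConservationCall(
            key,
            None if l5 is None else l5[:2],
            None if l3 is None else l3[:2],
            "not-aligned",
        )

    def users(site: tuple[str, int, str]) -> set[BSJKey]:
        chrom, pos = site[0], site[1]
        return {
            m
            for m in catalogue
            if m.chrom == chrom
            and (abs(m.start - pos) <= window or abs(m.end - pos) <= window)
        }

    m5, m3 = users(l5), users(l3)
    if m5 & m3:
        category = "homologous"
    elif m5 and m3:
        category = "both sites utilized"
    elif m5:
        category = "5' site utilized"
    elif m3:
        category = "3' site utilized"
    else:
        category = "no homologous"
    return ConservationCall(key, l5[:2], l3[:2], category)


def classify_all(
    keys: list[BSJKey],
    liftmap: LiftMap,
    catalogue: set[BSJKey],
    window: int = DEFAULT_WINDOW,
) -> list[ConservationCall]:
    return [classify_conservation(k, liftmap, catalogue, window) for k in keys]


def conservation_summary(calls: list[ConservationCall]) -> pd.DataFrame:
    """Per-category count and percent; empty input yields an empty table."""
    if not calls:
        return pd.DataFrame(columns=["category", "count", "percent"])
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.category] = counts.get(c.category, 0) + 1
    total = len(calls)
    rows = [
        {"category": cat, "count": counts[cat], "percent": round(100 * counts[cat] / total, 2)}
        for cat in CATEGORIES
        if cat in counts
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def calls_to_frame(calls: list[ConservationCall], names=None) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(calls):
        rows.append(
            {
                "name": names[i] if names is not None else c.key.id(),
                "bsj_id": c.key.id(),
                "lifted_5p": f"{c.lifted_5p[0]}:{c.lifted_5p[1]}" if c.lifted_5p else ".",
                "lifted_3p": f"{c.lifted_3p[0]}:{c.lifted_3p[1]}" if c.lifted_3p else ".",
                "category": c.category,
            }
        )
    return pd.DataFrame(
        rows, columns=["name", "bsj_id", "lifted_5p", "lifted_3p", "category"]
    )
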