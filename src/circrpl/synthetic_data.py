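"""Synthetic world generator: every input the pipeline consumes, with truth.

From a seed and a parameter block this module lays out a small genome with
gene/exon models, plants circRNAs of the three locus classes on it, draws
negative-binomial junction counts with per-sample library-size scaling and
planted group effects, emulates two imperfect BSJ detectors (dropout and
1-nt coordinate jitter), and constructs a reference-species catalogue plus
an interval lift map that force a chosen conservation category for every
circRNA.  A truth table records, per circRNA, everything the downstream
modules are expected to recover.

Counts for circRNA *i* in sample *j* follow

    K_ij ~ NB(mu_ij, alpha),  Var = mu + alpha * mu^2
    mu_ij = base_i * (L_j / L_ref) * 2^(lfc_i * [j is RPL])

with ``L_j`` the sample's library size and ``L_ref`` the midpoint of the
library-size range, so counts scale linearly with sequencing depth in
expectation.  Base expressions are log-normal around ``mean_expression``.

Geometry guarantees: all circRNA splice sites are pairwise separated by
more than twice the conservation matching window, and lift-failure "holes"
remove single source positions, so planted conservation categories are
recoverable exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .conservation import splice_sites
from .diffexp import filter_expressed
from .io_formats import AnnotationIndex, BSJKey, CircCall, CountMatrix, LiftMap

CLASS_TO_CIRI_TYPE = {"exonic": "exon", "intronic": "intron", "intergenic": "intergenic_region"}

CONS_CATEGORIES = [
    "not-aligned",
    "homologous",
    "5' site utilized",
    "3' site utilized",
    "both sites utilized",
    "no homologous",
]


class ParameterError(ValueError):
    """Simulation parameters are infeasible or inconsistent."""


@dataclass
class SimParams:
    """Study-condition parameters for the synthetic world.

    Defaults mirror a four-project reproductive-tissue layout (5v5, 3v6,
    3v3, 3v3 control/RPL samples), library sizes of 20-60 million reads,
    moderately overdispersed junction counts, and a conservation category
    mix with ~45% homologous BSJs.  The gene universe is kept several times
    larger than the set of circRNA host genes, as in real total RNA-seq
    where circRNA-producing genes are a minority of all expressed genes;
    this is what makes the planted gene set enrichable against the
    expressed-gene background.
    """

    seed: int = 0
    n_genes: int = 1000
    exons_per_gene: tuple[int, int] = (4, 10)
    n_circ: int = 400
    frac_exonic: float = 0.85
    frac_intronic: float = 0.10
    frac_intergenic: float = 0.05
    n_projects: int = 4
    samples_per_group: object = ((5, 5), (3, 6), (3, 3), (3, 3))
    mean_expression: float = 50.0
    expr_log_sigma: float = 1.0
    dispersion: float = 0.1
    frac_de: float = 0.1
    lfc_de: float = 1.5
    detector_dropout: float = 0.05
    coord_jitter: float = 0.02
    frac_conserved: float = 0.45
    lift_fail_frac: float = 0.12
    frac_site5: float = 0.08
    frac_site3: float = 0.08
    frac_both_sites: float = 0.04
    frac_known: float = 0.9
    library_size_range: tuple[int, int] = (20_000_000, 60_000_000)
    n_chromosomes: int = 5
    n_gene_sets: int = 20
    gene_set_size: tuple[int, int] = (10, 40)
    planted_set_size: int = 20

    def validate(self) -> None:
        fr = (self.frac_exonic, self.frac_intronic, self.frac_intergenic)
        if any(not 0 <= f <= 1 for f in fr):
            raise ParameterError("class proportions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ParameterError("class proportions must sum to 1")
        for name in (
            "frac_de",
            "detector_dropout",
            "coord_jitter",
            "frac_conserved",
            "lift_fail_frac",
            "frac_site5",
            "frac_site3",
            "frac_both_sites",
            "frac_known",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        cons_sum = (
            self.lift_fail_frac
            + self.frac_conserved
            + self.frac_site5
            + self.frac_site3
            + self.frac_both_sites
        )
        if cons_sum > 1 + 1e-9:
            raise ParameterError("conservation category fractions exceed 1")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.n_circ < 1 or self.n_genes < 1:
            raise ParameterError("n_circ and n_genes must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ParameterError("invalid library_size_range")

    def groups(self) -> list[tuple[int, int]]:
        spg = self.samples_per_group
        if isinstance(spg, int):
            return [(spg, spg)] * self.n_projects
        spg = [tuple(g) for g in spg]
        return [spg[p % len(spg)] for p in range(self.n_projects)]

    def conservation_probs(self) -> list[float]:
        rest = 1.0 - (
            self.lift_fail_frac
            + self.frac_conserved
            + self.frac_site5
            + self.frac_site3
            + self.frac_both_sites
        )
        return [
            self.lift_fail_frac,
            self.frac_conserved,
            self.frac_site5,
            self.frac_site3,
            self.frac_both_sites,
            max(rest, 0.0),
        ]


@dataclass
class TrueCirc:
    circ_id: str
    key: BSJKey
    circ_class: str
    host_gene: str | None
    known: bool = False
    is_de: bool = False
    true_lfc: float = 0.0
    conservation: str = "no homologous"
    base_expression: float = 0.0
    dcc_key: BSJKey | None = None  # None = dropped by DCC
    ciri_key: BSJKey | None = None

    @property
    def in_intersection(self) -> bool:
        return (
            self.dcc_key is not None
            and self.ciri_key is not None
            and self.dcc_key == self.ciri_key
        )


@dataclass
class SyntheticBundle:
    params: SimParams
    outdir: Path
    annotation: AnnotationIndex
    samples: pd.DataFrame
    counts: CountMatrix
    circs: list[TrueCirc]
    truth: pd.DataFrame
    liftmap: LiftMap
    mouse_catalogue: set[BSJKey]
    known_catalogue: set[BSJKey]
    gene_sets: dict[str, set[str]]
    background: set[str]
    planted_set: str
    paths: dict[str, object] = field(default_factory=dict)

    def project_ids(self) -> list[str]:
        return list(dict.fromkeys(self.samples["project_id"]))


# ---------------------------------------------------------------------------
# genome / circRNA placement
# ---------------------------------------------------------------------------


def _build_genome(params: SimParams, rng: np.random.Generator):
    chroms = [f"chr{i + 1}" for i in range(params.n_chromosomes)]
    genes: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cursors = {c: 10_000 for c in chroms}
    gaps: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    lo, hi = params.exons_per_gene
    for i in range(params.n_genes):
        chrom = chroms[i % len(chroms)]
        n_ex = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"GENE{i + 1:04d}"
        pos = cursors[chrom]
        ivs = []
        for k in range(n_ex):
            elen = int(rng.integers(80, 201))
            ivs.append((pos, pos + elen - 1))
            pos = pos + elen + int(rng.integers(200, 501))
        gene_start, gene_end = ivs[0][0], ivs[-1][1]
        genes[name] = (chrom, strand, gene_start, gene_end)
        exons[name] = ivs
        gaps[chrom].append((gene_end + 1, gene_end + 10_000 - 1))
        cursors[chrom] = gene_end + 10_000
    chrom_len = {c: cursors[c] + 50_000 for c in chroms}
    return AnnotationIndex(genes, exons), gaps, chrom_len


def _place_circs(params: SimParams, ann: AnnotationIndex, gaps, rng) -> list[TrueCirc]:
    n_ex = round(params.frac_exonic * params.n_circ)
    n_in = round(params.frac_intronic * params.n_circ)
    n_ig = params.n_circ - n_ex - n_in

    exonic_slots = []
    for g in sorted(ann.genes):
        ivs = ann.exons[g]
        for j in range(len(ivs) // 2):
            exonic_slots.append((g, ivs[2 * j][0], ivs[2 * j + 1][1]))
    intronic_slots = []
    for g in sorted(ann.genes):
        for s, e in ann.introns(g):
            if e - s + 1 >= 60:
                intronic_slots.append((g, s + 10, e - 10))
    intergenic_slots = []
    for chrom in sorted(gaps):
        for gs, ge in gaps[chrom]:
            pos = gs + 2000
            while pos + 400 <= ge - 2000:
                intergenic_slots.append((chrom, pos, pos + 400))
                pos += 3000

    if n_ex > len(exonic_slots) or n_in > len(intronic_slots) or n_ig > len(intergenic_slots):
        raise ParameterError(
            "n_circ exceeds placeable loci: "
            f"need {n_ex}/{n_in}/{n_ig} exonic/intronic/intergenic, "
            f"have {len(exonic_slots)}/{len(intronic_slots)}/{len(intergenic_slots)}"
        )

    circs: list[TrueCirc] = []
    for g, s, e in [exonic_slots[i] for i in rng.permutation(len(exonic_slots))[:n_ex]]:
        strand = ann.genes[g][1]
        circs.append(TrueCirc("", BSJKey(ann.genes[g][0], s, e, strand), "exonic", g))
    for g, s, e in [intronic_slots[i] for i in rng.permutation(len(intronic_slots))[:n_in]]:
        strand = ann.genes[g][1]
        circs.append(TrueCirc("", BSJKey(ann.genes[g][0], s, e, strand), "intronic", g))
    for chrom, s, e in [
        intergenic_slots[i] for i in rng.permutation(len(intergenic_slots))[:n_ig]
    ]:
        strand = "+" if rng.random() < 0.5 else "-"
        circs.append(TrueCirc("", BSJKey(chrom, s, e, strand), "intergenic", None))

    circs.sort(key=lambda c: c.key)
    for i, c in enumerate(circs):
        c.circ_id = f"circ{i + 1:05d}"
    return circs


# ---------------------------------------------------------------------------
# main entry
# ---------------------------------------------------------------------------


def simulate_world(params: SimParams, outdir) -> SyntheticBundle:
    """Generate every pipeline input under ``outdir``; returns the bundle."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ann, gaps, chrom_len = _build_genome(params, rng)
    circs = _place_circs(params, ann, gaps, rng)
    n = len(circs)

    # planted attributes --------------------------------------------------
    n_de = round(params.frac_de * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    for i in de_idx:
        circs[i].is_de = True
        circs[i].true_lfc = params.lfc_de * (1 if rng.random() < 0.5 else -1)
    sigma = params.expr_log_sigma
    base = rng.lognormal(
        mean=np.log(params.mean_expression) - sigma**2 / 2, sigma=sigma, size=n
    )
    cats = rng.choice(len(CONS_CATEGORIES), size=n, p=params.conservation_probs())
    for i, c in enumerate(circs):
        c.base_expression = float(base[i])
        c.conservation = CONS_CATEGORIES[int(cats[i])]
        c.known = bool(rng.random() < params.frac_known)

    # detector imperfection ------------------------------------------------
    for c in circs:
        c.dcc_key, c.ciri_key = c.key, c.key
        if rng.random() < params.detector_dropout:
            if rng.random() < 0.5:
                c.dcc_key = None
            else:
                c.ciri_key = None
        if rng.random() < params.coord_jitter:
            det = "dcc" if rng.random() < 0.5 else "ciri"
            shift = 1 if rng.random() < 0.5 else -1
            which = "start" if rng.random() < 0.5 else "end"
            target = c.dcc_key if det == "dcc" else c.ciri_key
            if target is not None:
                s, e = target.start, target.end
                if which == "start":
                    s = max(1, s + shift)
                else:
                    e = e + shift
                if e >= s:
                    jit = BSJKey(target.chrom, s, e, target.strand)
                    if det == "dcc":
                        c.dcc_key = jit
                    else:
                        c.ciri_key = jit

    # samples and counts ---------------------------------------------------
    rows = []
    for p, (n_ctrl, n_rpl) in enumerate(params.groups()):
        pid = f"P{p + 1}"
        for i in range(n_ctrl):
            rows.append((f"{pid}_C{i + 1}", pid, "control"))
        for i in range(n_rpl):
            rows.append((f"{pid}_R{i + 1}", pid, "RPL"))
    lo, hi = params.library_size_range
    lib = rng.integers(lo, hi + 1, size=len(rows))
    samples = pd.DataFrame(
        {
            "sample_id": [r[0] for r in rows],
            "project_id": [r[1] for r in rows],
            "condition": [r[2] for r in rows],
            "library_size": lib,
        }
    ).set_index("sample_id")

    l_ref = (lo + hi) / 2.0
    is_rpl = (samples["condition"] == "RPL").to_numpy()
    mu = np.outer(base, lib / l_ref)
    lfc = np.array([c.true_lfc for c in circs])
    mu[:, is_rpl] *= np.power(2.0, lfc)[:, None]
    alpha = params.dispersion
    if alpha <= 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mu))
    count_df = pd.DataFrame(
        counts.astype(np.int64),
        index=[c.key.id() for c in circs],
        columns=samples.index,
    )
    count_df.index.name = "bsj_id"
    cm = CountMatrix(count_df, samples)

    # conservation plumbing: lift map with holes, forced mouse catalogue ---
    offset = 1_000_000
    holes: dict[str, list[int]] = {c: [] for c in chrom_len}
    for c in circs:
        if c.conservation == "not-aligned":
            p5, _p3 = splice_sites(c.key)
            holes[c.key.chrom].append(p5)
    lift_intervals = []
    for chrom in sorted(chrom_len):
        mchrom = "m" + chrom
        prev = 1
        for h in sorted(holes[chrom]):
            if h > prev:
                lift_intervals.append(
                    (chrom, prev, h - 1, mchrom, prev + offset, h - 1 + offset, "+")
                )
            prev = h + 1
        length = chrom_len[chrom]
        if length >= prev:
            lift_intervals.append(
                (chrom, prev, length, mchrom, prev + offset, length + offset, "+")
            )
    liftmap = LiftMap(lift_intervals)

    mouse: set[BSJKey] = set()
    decoy_next = {("m" + c): chrom_len[c] + offset + 5_000_000 for c in chrom_len}

    def decoy(mchrom: str) -> int:
        d = decoy_next[mchrom]
        decoy_next[mchrom] = d + 1000
        return d

    for c in circs:
        if c.conservation in ("not-aligned", "no homologous"):
            continue
        p5, p3 = splice_sites(c.key)
        mchrom = "m" + c.key.chrom
        l5, l3 = p5 + offset, p3 + offset
        if c.conservation == "homologous":
            mouse.add(BSJKey(mchrom, min(l5, l3), max(l5, l3), "+"))
        elif c.conservation == "5' site utilized":
            d = decoy(mchrom)
            mouse.add(BSJKey(mchrom, min(l5, d), max(l5, d), "+"))
        elif c.conservation == "3' site utilized":
            d = decoy(mchrom)
            mouse.add(BSJKey(mchrom, min(l3, d), max(l3, d), "+"))
        else:  # both sites utilized, by two different mouse circRNAs
            d1, d2 = decoy(mchrom), decoy(mchrom)
            mouse.add(BSJKey(mchrom, min(l5, d1), max(l5, d1), "+"))
            mouse.add(BSJKey(mchrom, min(l3, d2), max(l3, d2), "+"))

    # human known catalogue: planted known flags plus decoy entries --------
    known = {c.key for c in circs if c.known}
    for i in range(round(0.3 * n)):
        chrom = sorted(chrom_len)[i % len(chrom_len)]
        s = chrom_len[chrom] + 100_000 + i * 1000
        known.add(BSJKey(chrom, s, s + 500, "+"))

    # gene sets with one planted enriched set ------------------------------
    background = set(ann.genes)
    expressed_hosts: set[str] = set()
    for pid in dict.fromkeys(samples["project_id"]):
        sub = cm.subset_project(pid)
        kept = filter_expressed(sub).counts.index
        host_by_id = {c.key.id(): c.host_gene for c in circs}
        expressed_hosts |= {host_by_id[i] for i in kept if host_by_id[i] is not None}
    gene_sets: dict[str, set[str]] = {}
    k = params.planted_set_size
    n_hosts = min(round(0.8 * k), len(expressed_hosts))
    hosts = sorted(expressed_hosts)
    non_hosts = sorted(background - expressed_hosts)
    members = set(
        np.array(hosts)[rng.choice(len(hosts), size=n_hosts, replace=False)]
    )
    n_fill = min(k - n_hosts, len(non_hosts))
    if n_fill > 0:
        members |= set(
            np.array(non_hosts)[rng.choice(len(non_hosts), size=n_fill, replace=False)]
        )
    gene_sets["SET_PLANTED"] = members
    bg_sorted = sorted(background)
    slo, shi = params.gene_set_size
    for i in range(params.n_gene_sets - 1):
        size = int(rng.integers(slo, shi + 1))
        idx = rng.choice(len(bg_sorted), size=min(size, len(bg_sorted)), replace=False)
        gene_sets[f"SET_{i + 1:03d}"] = set(np.array(bg_sorted)[idx])

    # truth table ----------------------------------------------------------
    truth = pd.DataFrame(
        [
            {
                "circ_id": c.circ_id,
                "bsj_id": c.key.id(),
                "chrom": c.key.chrom,
                "start": c.key.start,
                "end": c.key.end,
                "strand": c.key.strand,
                "class": c.circ_class,
                "host_gene": c.host_gene if c.host_gene else ".",
                "known": c.known,
                "is_de": c.is_de,
                "true_lfc": c.true_lfc,
                "conservation": c.conservation,
                "dcc_key": c.dcc_key.id() if c.dcc_key else ".",
                "ciri_key": c.ciri_key.id() if c.ciri_key else ".",
                "in_intersection": c.in_intersection,
                "base_expression": c.base_expression,
            }
            for c in circs
        ]
    )

    # write everything -----------------------------------------------------
    paths: dict[str, object] = {}
    paths["annotation"] = outdir / "annotation.gtf"
    iof.write_gtf(ann, paths["annotation"])
    paths["samples"] = outdir / "samples.tsv"
    iof.write_samplesheet(samples, paths["samples"])
    paths["counts"] = outdir / "counts.tsv"
    iof.write_counts(cm, paths["counts"])
    paths["known_catalogue"] = outdir / "known_catalogue.tsv"
    iof.write_catalogue(known, paths["known_catalogue"])
    paths["mouse_catalogue"] = outdir / "mouse_catalogue.tsv"
    iof.write_catalogue(mouse, paths["mouse_catalogue"])
    paths["liftmap"] = outdir / "liftmap.tsv"
    iof.write_liftmap(liftmap, paths["liftmap"])
    paths["gmt"] = outdir / "gene_sets.gmt"
    iof.write_gmt(gene_sets, paths["gmt"])
    paths["background"] = outdir / "background_genes.txt"
    iof.write_gene_list(background, paths["background"])
    paths["truth"] = outdir / "truth_table.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["params"] = outdir / "params.yaml"
    Path(paths["params"]).write_text(
        yaml.safe_dump(_params_dict(params), sort_keys=True)
    )

    dcc_dir = outdir / "dcc"
    ciri_dir = outdir / "ciri"
    dcc_dir.mkdir(exist_ok=True)
    ciri_dir.mkdir(exist_ok=True)
    paths["dcc"] = {}
    paths["ciri"] = {}
    for pid in dict.fromkeys(samples["project_id"]):
        proj_samples = list(samples.index[samples["project_id"] == pid])
        dcc_calls = [
            CircCall(
                c.dcc_key,
                "DCC",
                {s: int(count_df.loc[c.key.id(), s]) for s in proj_samples},
                c.host_gene or ".",
            )
            for c in circs
            if c.dcc_key is not None
        ]
        cnt_path = dcc_dir / f"{pid}.CircRNACount.tsv"
        coo_path = dcc_dir / f"{pid}.CircCoordinates.tsv"
        iof.write_dcc_calls(dcc_calls, cnt_path, coo_path)
        paths["dcc"][pid] = (cnt_path, coo_path)
        paths["ciri"][pid] = []
        for s in proj_samples:
            ciri_calls = [
                CircCall(
                    c.ciri_key,
                    "CIRI2",
                    {s: int(count_df.loc[c.key.id(), s])},
                    CLASS_TO_CIRI_TYPE[c.circ_class],
                )
                for c in circs
                if c.ciri_key is not None
            ]
            sp = ciri_dir / f"{s}.tsv"
            iof.write_ciri2_calls(ciri_calls, sp, s)
            paths["ciri"][pid].append(sp)

    return SyntheticBundle(
        params=params,
        outdir=outdir,
        annotation=ann,
        samples=samples,
        counts=cm,
        circs=circs,
        truth=truth,
        liftmap=liftmap,
        mouse_catalogue=mouse,
        known_catalogue=known,
        gene_sets=gene_sets,
        background=background,
        planted_set="SET_PLANTED",
        paths=paths,
    )


def _params_dict(params: SimParams) -> dict:
    d = dataclasses.asdict(params)
    for key, v in d.items():
        if isinstance(v, tuple):
            d[key] = list(list(g) if isinstance(g, tuple) else g for g in v)
    return d


def expected_mu(bundle: SyntheticBundle) -> np.ndarray:
    """The mu_ij matrix the counts were drawn from (circRNAs x samples)."""
    params = bundle.params
    lo, hi = params.library_size_range
    l_ref = (lo + hi) / 2.0
    lib = bundle.samples["library_size"].to_numpy(dtype=float)
    base = np.array([c.base_expression for c in bundle.circs])
    lfc = np.array([c.true_lfc for c in bundle.circs])
    is_rpl = (bundle.samples["condition"] == "RPL").to_numpy()
    mu = np.outer(base, lib / l_ref)
    mu[:, is_rpl] *= np.power(2.0, lfc)[:, None]
    return mu


def empirical_moments(bundle: SyntheticBundle) -> pd.DataFrame:
    """Per-circRNA observed mean/variance vs the generating mean."""
    mu = expected_mu(bundle)
    k = bundle.counts.counts.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "circ_id": [c.circ_id for c in bundle.circs],
            "sample_mean": k.mean(axis=1),
            "sample_var": k.var(axis=1, ddof=1),
            "expected_mean": mu.mean(axis=1),
        }
    )
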