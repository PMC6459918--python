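"""Defence-gene neighbourhood mining and co-occurrence classification.

The Dnd modification component (dndCDEA) writes phosphorothioate marks;
its known partners are the bacterial restriction component dndFGH and the
archaeal PbeABCD cassette. This module takes filtered homology hits /
gene annotations and asks, genome by genome: which partner sits next to
which anchor?

Window semantics: a neighbourhood phrase like "1 bp–20 kb" is read as an
edge-to-edge gene gap in [0, W] — overlapping or abutting genes count as
within the window, and the gap is always measured from the anchor
cluster's span edges, never its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats_io import GeneAnnotation, HomologyHit

#: Default thresholds of the homology-hit filter.
E_VALUE_MAX = 1e-10
MIN_LEN_FRAC = 0.30
#: Default neighbourhood windows (bp).
DND_PAIR_MAX_GAP = 5_000
FGH_WINDOW = 20_000
PBE_WINDOW = 10_000

DND_CATEGORIES = ("pbe", "dndFGH", "both", "none")
PBE_CATEGORIES = ("dnd_only", "mtase_only", "both", "solitary")


@dataclass(frozen=True)
class DndCDLocus:
    """A paired dndC + dndD cluster (the modification-component anchor)."""

    genome_id: str
    contig: str
    span: tuple[int, int]
    pair_gap: int

    def __post_init__(self) -> None:
        if self.pair_gap > DND_PAIR_MAX_GAP:
            raise ValueError(
                f"dndC-dndD gap {self.pair_gap} exceeds {DND_PAIR_MAX_GAP} bp"
            )


@dataclass(frozen=True)
class SystemClassification:
    """What accompanies a dndCD cluster in its flanking windows."""

    genome_id: str
    has_dndFGH: bool
    has_pbeAC: bool
    category: str

    def __post_init__(self) -> None:
        expected = _dnd_category(self.has_dndFGH, self.has_pbeAC)
        if self.category != expected:
            raise ValueError(f"category {self.category!r} inconsistent with flags")


@dataclass(frozen=True)
class PbeNeighborhood:
    """What modification partner accompanies a pbeAC locus."""

    genome_id: str
    pbe_locus: tuple[str, int, int]
    has_dndCD: bool
    has_mtase: bool
    category: str

    def __post_init__(self) -> None:
        expected = _pbe_category(self.has_dndCD, self.has_mtase)
        if self.category != expected:
            raise ValueError(f"category {self.category!r} inconsistent with flags")


def _dnd_category(has_fgh: bool, has_pbe: bool) -> str:
    if has_fgh and has_pbe:
        return "both"
    if has_fgh:
        return "dndFGH"
    if has_pbe:
        return "pbe"
    return "none"


def _pbe_category(has_dnd: bool, has_mtase: bool) -> str:
    if has_dnd and has_mtase:
        return "both"
    if has_dnd:
        return "dnd_only"
    if has_mtase:
        return "mtase_only"
    return "solitary"


# ---------------------------------------------------------------------------
# Hit filtering and reduction to annotations
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Iterable[HomologyHit],
    e_max: float = E_VALUE_MAX,
    min_len_frac: float = MIN_LEN_FRAC,
) -> list[HomologyHit]:
    """Keep hits with e-value <= ``e_max`` and aligned length >=
    ``min_len_frac`` of the query protein; input order is preserved.

    Both thresholds are inclusive (a hit at exactly 1e-10 and exactly 30%
    coverage is kept).
    """
    return [
        h for h in hits
        if h.evalue <= e_max and h.aln_len / h.query_len >= min_len_frac
    ]


def hits_to_annotations(hits: Iterable[HomologyHit]) -> list[GeneAnnotation]:
    """Reduce kept hits to one annotation per (genome, query gene): the
    best hit, ranked by (e-value ascending, identity descending)."""
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        key = (h.subject_genome, h.query_id)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.pct_identity) < (cur.evalue, -cur.pct_identity):
            best[key] = h
    out = []
    for (genome, query), h in sorted(best.items()):
        symbol = query if query in (
            "dndA", "dndB", "dndC", "dndD", "dndE",
            "pbeA", "pbeB", "pbeC", "pbeD", "dndF", "dndG", "dndH", "mtase",
        ) else "other"
        out.append(GeneAnnotation(
            genome_id=genome, symbol=symbol, contig=h.subject_contig,
            start=h.subject_start, end=h.subject_end, strand=h.strand,
        ))
    return out


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def gene_gap(
    a: tuple[int, int], b: tuple[int, int],
    contig_a: str | None = None, contig_b: str | None = None,
) -> int | None:
    """Edge-to-edge distance between two half-open intervals.

    0 when they overlap or abut; ``None`` (not comparable) when they sit
    on different contigs.
    """
    if contig_a is not None and contig_b is not None and contig_a != contig_b:
        return None
    (a0, a1), (b0, b1) = a, b
    if a1 <= b0:
        return b0 - a1
    if b1 <= a0:
        return a0 - b1
    return 0


def _within(anchor_span: tuple[int, int], anchor_contig: str,
            gene: GeneAnnotation, window: int) -> bool:
    gap = gene_gap(anchor_span, gene.interval, anchor_contig, gene.contig)
    return gap is not None and gap <= window


# ---------------------------------------------------------------------------
# dndCD pairing
# ---------------------------------------------------------------------------

def locate_dndCD_pairs(
    annotations: Sequence[GeneAnnotation],
    max_gap: int = DND_PAIR_MAX_GAP,
) -> tuple[list[DndCDLocus], list[GeneAnnotation]]:
    """Pair each dndC with its nearest dndD at gap <= ``max_gap``.

    Ties break to the dndD with the smaller start. Genes that find no
    partner are returned separately, never dropped.
    """
    by_genome: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        by_genome.setdefault(a.genome_id, []).append(a)
    loci: list[DndCDLocus] = []
    unpaired: list[GeneAnnotation] = []
    for genome_id in sorted(by_genome):
        anns = by_genome[genome_id]
        cs = [a for a in anns if a.symbol == "dndC"]
        ds = [a for a in anns if a.symbol == "dndD"]
        paired_d: set[int] = set()
        for c in sorted(cs, key=lambda a: a.start):
            candidates = []
            for j, d in enumerate(ds):
                if j in paired_d:
                    continue
                gap = gene_gap(c.interval, d.interval, c.contig, d.contig)
                if gap is not None and gap <= max_gap:
                    candidates.append((gap, d.start, j, d))
            if not candidates:
                unpaired.append(c)
                continue
            gap, _, j, d = min(candidates)
            paired_d.add(j)
            loci.append(DndCDLocus(
                genome_id=genome_id,
                contig=c.contig,
                span=(min(c.start, d.start), max(c.end, d.end)),
                pair_gap=gap,
            ))
        unpaired.extend(d for j, d in enumerate(ds) if j not in paired_d)
    return loci, unpaired


# ---------------------------------------------------------------------------
# Flanking-window classification
# ---------------------------------------------------------------------------

def classify_dnd_system(
    locus: DndCDLocus,
    annotations: Sequence[GeneAnnotation],
    fgh_window: int = FGH_WINDOW,
    pbe_window: int = FGH_WINDOW,
) -> SystemClassification:
    """Search the flanks of a dndCD cluster for restriction partners.

    ``has_dndFGH`` requires all three of dndF, dndG, dndH within the
    window (all three are essential for restriction); ``has_pbeAC``
    requires both pbeA and pbeC (the annotatable proxies of the
    four-gene pbeABCD cassette). Both windows default to +-20 kb from the
    cluster span edges.
    """
    genes = [a for a in annotations if a.genome_id == locus.genome_id]
    near = lambda sym, w: any(
        _within(locus.span, locus.contig, g, w) for g in genes if g.symbol == sym
    )
    has_fgh = all(near(s, fgh_window) for s in ("dndF", "dndG", "dndH"))
    has_pbe = all(near(s, pbe_window) for s in ("pbeA", "pbeC"))
    return SystemClassification(
        genome_id=locus.genome_id,
        has_dndFGH=has_fgh,
        has_pbeAC=has_pbe,
        category=_dnd_category(has_fgh, has_pbe),
    )


def locate_pbe_loci(
    annotations: Sequence[GeneAnnotation],
    max_gap: int = DND_PAIR_MAX_GAP,
) -> list[tuple[str, str, int, int]]:
    """Pair pbeA with its nearest pbeC per genome (same pairing rule as
    dndCD); returns (genome_id, contig, start, end) spans."""
    by_genome: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        by_genome.setdefault(a.genome_id, []).append(a)
    out = []
    for genome_id in sorted(by_genome):
        anns = by_genome[genome_id]
        pas = [a for a in anns if a.symbol == "pbeA"]
        pcs = [a for a in anns if a.symbol == "pbeC"]
        used: set[int] = set()
        for pa in sorted(pas, key=lambda a: a.start):
            candidates = []
            for j, pc in enumerate(pcs):
                if j in used:
                    continue
                gap = gene_gap(pa.interval, pc.interval, pa.contig, pc.contig)
                if gap is not None and gap <= max_gap:
                    candidates.append((gap, pc.start, j, pc))
            if not candidates:
                continue
            _, _, j, pc = min(candidates)
            used.add(j)
            out.append((
                genome_id, pa.contig,
                min(pa.start, pc.start), max(pa.end, pc.end),
            ))
    return out


def classify_pbe_neighborhood(
    pbe_locus: tuple[str, str, int, int],
    annotations: Sequence[GeneAnnotation],
    window: int = PBE_WINDOW,
) -> PbeNeighborhood:
    """Search +-``window`` around a pbeAC locus for a modification
    partner: a paired dndCD cluster or an MTase gene. The partner is
    "DndCD" as a unit, so the gap is measured to the nearest edge of the
    paired cluster's span, not to each gene separately. The four
    categories (dnd_only / mtase_only / both / solitary) partition any
    input set."""
    genome_id, contig, start, end = pbe_locus
    span = (start, end)
    genes = [a for a in annotations if a.genome_id == genome_id]
    cd_loci, _ = locate_dndCD_pairs(genes)
    has_dnd = any(
        l.contig == contig
        and (g := gene_gap(span, l.span)) is not None and g <= window
        for l in cd_loci
    )
    has_mtase = any(
        _within(span, contig, g, window) for g in genes if g.symbol == "mtase"
    )
    return PbeNeighborhood(
        genome_id=genome_id,
        pbe_locus=(contig, start, end),
        has_dndCD=has_dnd,
        has_mtase=has_mtase,
        category=_pbe_category(has_dnd, has_mtase),
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def cooccurrence_summary(
    classifications: Sequence[SystemClassification | PbeNeighborhood],
) -> dict[str, tuple[int, float]]:
    """Category -> (count, percent to 1 decimal); counts partition the
    input, so percents sum to ~100."""
    if not classifications:
        raise ValueError("no classifications to summarise")
    counts: dict[str, int] = {}
    for c in classifications:
        counts[c.category] = counts.get(c.category, 0) + 1
    n = len(classifications)
    return {
        cat: (k, round(100.0 * k / n, 1)) for cat, k in sorted(counts.items())
    }


def fraction_with_partner(
    classifications: Sequence[SystemClassification | PbeNeighborhood],
    flag: str,
) -> tuple[int, float]:
    """Count and percent (1 decimal) of classifications whose boolean
    attribute ``flag`` (e.g. ``has_dndCD`` or ``has_dndFGH``) is set."""
    if not classifications:
        raise ValueError("no classifications to summarise")
    k = sum(1 for c in classifications if getattr(c, flag))
    return k, round(100.0 * k / len(classifications), 1)
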