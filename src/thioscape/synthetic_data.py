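"""Seeded generators for every fixture the pipeline consumes.

The generators emulate the statistical structure of the real inputs —
haloarchaeal genomes with a controlled number of GATC duplex loci,
strand-resolved PT call sets with a chosen full/hemi composition,
defence-gene annotation tables with planted neighbourhood categories, and
protein-family pairs with correlated divergence — and every generator
returns machine-readable ground truth next to its output, so downstream
classifiers can be scored without peeking at generator internals.

Motif counts are exact, not approximate: spontaneous GATC occurrences are
destroyed by local resampling until only the planted ones remain, so the
denominators of the worked examples (e.g. 94,316 GATC sites) are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats_io import FeatureRecord, GeneAnnotation, GenomeRecord, HomologyHit, PtCall

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_G, _A, _T, _C = (ord(x) for x in "GATC")
_AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

#: Neighbourhood categories the annotation generator can plant.
PBE_CATEGORIES = ("pbe_dnd_only", "pbe_mtase_only", "pbe_both", "pbe_solitary")
DND_CATEGORIES = ("dnd_with_dndFGH", "dnd_alone", "dnd_with_pbe", "dnd_with_both")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the conditions of the most deeply profiled genome in
    the study system (a ~4 Mb haloarchaeal chromosome, GC ~0.65, with
    94,316 GATC duplex sites of which 655 are fully modified, 574 carry a
    + strand-only call and 567 a − strand-only call — i.e. 1,229 (+) and
    1,222 (−) strand calls, 2,451 in total, 1,141 of them hemimodified),
    and a 553-genome defence-system survey partitioned 128/155/105/165
    among pbe-with-dndCD / pbe-with-MTase / both / solitary.
    """

    seed: int = 0
    genome_len: int = 4_000_000
    gc: float = 0.65
    n_motifs: int = 94_316
    n_full: int = 655
    n_hemi_plus: int = 574
    n_hemi_minus: int = 567
    n_genomes: int = 553
    category_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "pbe_dnd_only": 128,
            "pbe_mtase_only": 155,
            "pbe_both": 105,
            "pbe_solitary": 165,
        }
    )
    gap_range: tuple[int, int] = (0, 9_000)
    divergence_corr: float = 0.6
    n_strains: int = 200
    sub_rate_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.n_full + self.n_hemi_plus + self.n_hemi_minus > self.n_motifs:
            raise ValueError("modified-locus counts exceed n_motifs")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be a fraction in [0, 1]")
        if not (-1.0 <= self.divergence_corr <= 1.0):
            raise ValueError("divergence_corr must lie in [-1, 1]")
        if min(self.n_motifs, self.n_full, self.n_hemi_plus, self.n_hemi_minus,
               self.n_genomes, self.n_strains) < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.sub_rate_range
        if not (0.0 <= lo <= hi < 0.6):
            raise ValueError("sub_rate_range must satisfy 0 <= lo <= hi < 0.6")


# ---------------------------------------------------------------------------
# Genomes with an exact planted GATC count
# ---------------------------------------------------------------------------

def _find_gatc(arr: np.ndarray) -> np.ndarray:
    if arr.size < 4:
        return np.empty(0, dtype=np.int64)
    hit = (arr[:-3] == _G) & (arr[1:-2] == _A) & (arr[2:-1] == _T) & (arr[3:] == _C)
    return np.nonzero(hit)[0]


def gen_genome_with_motifs(
    cfg: SimConfig, contig_id: str = "chr", max_rounds: int = 100
) -> tuple[GenomeRecord, np.ndarray]:
    """Generate a genome containing *exactly* ``cfg.n_motifs`` + strand
    GATC occurrences, at the returned sorted start positions.

    Planted starts are pairwise >= 4 bp apart (non-overlapping).
    Spontaneous GATC occurrences elsewhere are eliminated by mutating one
    base of each, iterating until the scan is clean; positions inside
    planted motifs are never touched.
    """
    n, L = cfg.n_motifs, cfg.genome_len
    if n * 8 >= L:
        raise ValueError(f"{n} motifs cannot be placed in a {L} bp genome")
    rng = np.random.default_rng(cfg.seed)

    # starts with guaranteed >= 4 bp separation via the gap-insertion trick
    slack = L - 4 * n
    starts = np.sort(rng.integers(0, slack + 1, size=n)) + 4 * np.arange(n)

    p_at = (1.0 - cfg.gc) / 2.0
    p_gc = cfg.gc / 2.0
    arr = rng.choice(_BASES, size=L, p=[p_at, p_gc, p_gc, p_at])

    planted_mask = np.zeros(L, dtype=bool)
    for off, base in enumerate((_G, _A, _T, _C)):
        arr[starts + off] = base
        planted_mask[starts + off] = True

    planted_set = set(starts.tolist())
    for _ in range(max_rounds):
        occ = _find_gatc(arr)
        bad = [s for s in occ.tolist() if s not in planted_set]
        if not bad:
            break
        for s in bad:
            for off in range(4):
                if not planted_mask[s + off]:
                    cur = arr[s + off]
                    choices = _BASES[_BASES != cur]
                    arr[s + off] = rng.choice(choices)
                    break
    else:
        raise RuntimeError("motif cleanup did not converge")

    genome = GenomeRecord(id=contig_id, seq=arr.tobytes().decode("ascii"))
    return genome, starts


# ---------------------------------------------------------------------------
# PT calls with a planted full/hemi composition
# ---------------------------------------------------------------------------

def gen_pt_calls(
    motif_positions: Sequence[int] | np.ndarray,
    cfg: SimConfig,
    contig_id: str = "chr",
) -> tuple[list[PtCall], dict[int, str]]:
    """Assign duplex states to motif loci and emit the strand calls.

    Exactly ``n_full`` loci receive calls on both strands, ``n_hemi_plus``
    a + call only and ``n_hemi_minus`` a − call only, chosen uniformly at
    random. Returns the calls (sorted) and the ground-truth state of every
    locus (``full`` / ``hemi_plus`` / ``hemi_minus`` / ``none``).
    """
    positions = np.asarray(motif_positions)
    n_mod = cfg.n_full + cfg.n_hemi_plus + cfg.n_hemi_minus
    if n_mod > positions.size:
        raise ValueError("requested modified-locus counts exceed available motifs")
    rng = np.random.default_rng(cfg.seed + 1)
    chosen = rng.permutation(positions)[:n_mod]
    full = chosen[: cfg.n_full]
    hemi_p = chosen[cfg.n_full: cfg.n_full + cfg.n_hemi_plus]
    hemi_m = chosen[cfg.n_full + cfg.n_hemi_plus:]

    truth: dict[int, str] = {int(p): "none" for p in positions}
    calls: list[PtCall] = []
    for p in full:
        truth[int(p)] = "full"
        calls.append(PtCall(contig_id, int(p), "+"))
        calls.append(PtCall(contig_id, int(p) + 3, "-"))
    for p in hemi_p:
        truth[int(p)] = "hemi_plus"
        calls.append(PtCall(contig_id, int(p), "+"))
    for p in hemi_m:
        truth[int(p)] = "hemi_minus"
        calls.append(PtCall(contig_id, int(p) + 3, "-"))
    calls.sort(key=lambda c: (c.contig, c.pos, c.strand))
    return calls, truth


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def gen_feature_table(
    genome: GenomeRecord,
    n_cds: int,
    n_rrna: int,
    n_pseudo: int,
    seed: int,
    length_range: tuple[int, int] = (300, 1500),
) -> list[FeatureRecord]:
    """Plant non-overlapping CDS / rRNA / pseudogene intervals on a genome."""
    rng = np.random.default_rng(seed)
    kinds = ["CDS"] * n_cds + ["rRNA"] * n_rrna + ["pseudogene"] * n_pseudo
    n = len(kinds)
    if n == 0:
        return []
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n)
    total = int(lengths.sum())
    if total > genome.length:
        raise ValueError(
            f"total feature span {total} exceeds genome length {genome.length}"
        )
    slack = genome.length - total
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    starts = gaps + np.concatenate(([0], np.cumsum(lengths)[:-1]))
    order = rng.permutation(n)
    feats = []
    for i, idx in enumerate(order):
        kind = kinds[idx]
        feats.append(FeatureRecord(
            contig=genome.id,
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            strand="+" if rng.random() < 0.5 else "-",
            kind=kind,
            label=f"{kind.lower()}_{i:05d}",
        ))
    feats.sort(key=lambda f: f.start)
    return feats


# ---------------------------------------------------------------------------
# Defence-gene neighbourhoods with planted categories
# ---------------------------------------------------------------------------

_GENE_LEN = 1_200
_INTRA_CLUSTER_GAP = 150
_MTASE_LEN = 900


def _draw_gap(rng: np.random.Generator, gap_range: tuple[int, int]) -> int:
    return int(rng.integers(gap_range[0], gap_range[1] + 1))


def _plant_cluster(
    genome_id: str, contig: str, symbols: Sequence[str], start: int,
    gene_len: int = _GENE_LEN,
) -> tuple[list[GeneAnnotation], int]:
    """Lay consecutive genes from ``start``; returns annotations and end."""
    out = []
    pos = start
    for sym in symbols:
        length = _MTASE_LEN if sym == "mtase" else gene_len
        out.append(GeneAnnotation(genome_id, sym, contig, pos, pos + length))
        pos = pos + length + _INTRA_CLUSTER_GAP
    return out, pos - _INTRA_CLUSTER_GAP


def gen_defence_annotations(
    cfg: SimConfig,
    pbe_window: int = 10_000,
    fgh_window: int = 20_000,
) -> tuple[list[GeneAnnotation], dict[str, str]]:
    """Plant one defence-gene neighbourhood per genome, with the
    inter-cluster gap drawn from ``cfg.gap_range``.

    Categories are pbeAC-centric (``pbe_dnd_only``, ``pbe_mtase_only``,
    ``pbe_both``, ``pbe_solitary``) or dndCD-centric (``dnd_with_dndFGH``,
    ``dnd_alone``, ``dnd_with_pbe``, ``dnd_with_both``). For absent
    partners a decoy cluster is planted strictly beyond the window, so the
    boundary is actually exercised. Returns the annotations plus the
    ground-truth category per genome.

    Raises if ``gap_range`` straddles the window the category is defined
    against (a gap of 10,001 bp cannot be a "within 10 kb" neighbour).
    """
    for cat in cfg.category_counts:
        if cat not in PBE_CATEGORIES + DND_CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        window = pbe_window if cat in PBE_CATEGORIES else fgh_window
        if cat not in ("pbe_solitary", "dnd_alone") and cfg.gap_range[1] > window:
            raise ValueError(
                f"gap_range {cfg.gap_range} exceeds the {window} bp window "
                f"required by category {cat!r}"
            )
    rng = np.random.default_rng(cfg.seed + 2)
    annotations: list[GeneAnnotation] = []
    truth: dict[str, str] = {}
    i = 0
    for cat, count in cfg.category_counts.items():
        for _ in range(count):
            gid = f"g{i:04d}_{cat}"
            contig = "c0"
            anns: list[GeneAnnotation] = []
            # the anchor cluster starts deep enough that a second partner
            # (gap + its own span) always fits upstream
            anchor = max(pbe_window, fgh_window) + 10 * _GENE_LEN
            if cat in PBE_CATEGORIES:
                # pbeB/pbeD are too small to be annotated; pbeA+pbeC proxy the cassette
                cluster, end = _plant_cluster(gid, contig, ("pbeA", "pbeC"), anchor)
                anns += cluster
                if cat in ("pbe_dnd_only", "pbe_both"):
                    s = end + max(1, _draw_gap(rng, cfg.gap_range))
                    cl, _ = _plant_cluster(gid, contig, ("dndC", "dndD"), s)
                    anns += cl
                if cat in ("pbe_mtase_only", "pbe_both"):
                    # upstream of the anchor, so its gap to pbeAC is the drawn one
                    gap = max(1, _draw_gap(rng, cfg.gap_range))
                    cl, _ = _plant_cluster(gid, contig, ("mtase",), anchor - gap - _MTASE_LEN)
                    anns += cl
                if cat in ("pbe_solitary", "pbe_dnd_only"):
                    # decoy MTase strictly beyond the window
                    s = end + pbe_window + 1 + _draw_gap(rng, cfg.gap_range)
                    cl, _ = _plant_cluster(gid, contig, ("mtase",), s)
                    anns += cl
            else:
                cluster, end = _plant_cluster(gid, contig, ("dndC", "dndD"), anchor)
                anns += cluster
                if cat in ("dnd_with_dndFGH", "dnd_with_both"):
                    s = end + max(1, _draw_gap(rng, cfg.gap_range))
                    cl, _ = _plant_cluster(gid, contig, ("dndF", "dndG", "dndH"), s)
                    anns += cl
                if cat in ("dnd_with_pbe", "dnd_with_both"):
                    gap = max(1, _draw_gap(rng, cfg.gap_range))
                    width = 2 * _GENE_LEN + _INTRA_CLUSTER_GAP
                    cl, _ = _plant_cluster(gid, contig, ("pbeA", "pbeC"), anchor - gap - width)
                    anns += cl
                if cat == "dnd_alone":
                    s = end + fgh_window + 1 + _draw_gap(rng, cfg.gap_range)
                    cl, _ = _plant_cluster(gid, contig, ("dndF", "dndG", "dndH"), s)
                    anns += cl
            annotations.extend(anns)
            truth[gid] = cat
            i += 1
    return annotations, truth


# ---------------------------------------------------------------------------
# Protein-family pairs with correlated divergence
# ---------------------------------------------------------------------------

def _mutate(seq: str, d: float, rng: np.random.Generator) -> tuple[str, float]:
    """Substitute exactly round(d * len) positions to different residues."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    k = int(round(d * arr.size))
    if k == 0:
        return seq, 0.0
    sites = rng.choice(arr.size, size=k, replace=False)
    for s in sites:
        choices = _AMINO_ACIDS[_AMINO_ACIDS != arr[s]]
        arr[s] = rng.choice(choices)
    return arr.tobytes().decode("ascii"), k / arr.size


def gen_protein_family_pairs(
    ref_mod: str, ref_res: str, cfg: SimConfig
) -> list[tuple[str, str, str, float, float]]:
    """Derive per-strain (modification, restriction) protein pairs from two
    reference sequences, with substitution fractions drawn from a
    Gaussian copula whose rank correlation targets ``divergence_corr``.

    A rank correlation rho_s is achieved by a Gaussian correlation of
    2·sin(pi·rho_s/6) (the inverse of the Gaussian-copula Spearman map).
    Sequences carry exactly round(d·L) substitutions and no indels.
    Returns rows (strain_id, mod_seq, res_seq, true_d_mod, true_d_res).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    lo, hi = cfg.sub_rate_range
    n = cfg.n_strains
    if cfg.divergence_corr >= 1.0:
        u = rng.random(n)
        u1, u2 = u, u
    elif cfg.divergence_corr <= -1.0:
        u = rng.random(n)
        u1, u2 = u, 1.0 - u
    else:
        from scipy.stats import norm

        rho_g = 2.0 * math.sin(math.pi * cfg.divergence_corr / 6.0)
        cov = np.array([[1.0, rho_g], [rho_g, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        u1, u2 = norm.cdf(z[:, 0]), norm.cdf(z[:, 1])
    d_mod = lo + u1 * (hi - lo)
    d_res = lo + u2 * (hi - lo)
    out = []
    for i in range(n):
        mod_seq, dm = _mutate(ref_mod, float(d_mod[i]), rng)
        res_seq, dr = _mutate(ref_res, float(d_res[i]), rng)
        out.append((f"strain_{i:04d}", mod_seq, res_seq, dm, dr))
    return out


def random_protein(length: int, seed: int) -> str:
    """A uniform random protein sequence (20 canonical residues)."""
    rng = np.random.default_rng(seed)
    return rng.choice(_AMINO_ACIDS, size=length).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Homology-hit tables with labelled decoys
# ---------------------------------------------------------------------------

def gen_homology_hits(
    truth: Sequence[GeneAnnotation],
    query_lengths: Mapping[str, int],
    n_decoys: int = 0,
    seed: int = 0,
    e_max: float = 1e-10,
    min_len_frac: float = 0.30,
) -> tuple[list[HomologyHit], list[bool]]:
    """Emit one passing hit per planted annotation plus ``n_decoys`` rows
    that each violate exactly one filter rule (either the e-value cutoff
    or the aligned-length fraction, never both).

    Returns hits and a parallel is-true label list.
    """
    rng = np.random.default_rng(seed)
    hits: list[HomologyHit] = []
    labels: list[bool] = []
    qids = sorted(query_lengths)

    def _make(ann: GeneAnnotation, qid: str, evalue: float, aln_len: int) -> HomologyHit:
        return HomologyHit(
            query_id=qid,
            query_len=int(query_lengths[qid]),
            subject_genome=ann.genome_id,
            subject_prot=f"{ann.symbol}_prot",
            pct_identity=float(np.round(rng.uniform(35, 95), 2)),
            aln_len=aln_len,
            evalue=evalue,
            subject_contig=ann.contig,
            subject_start=ann.start,
            subject_end=ann.end,
            strand=ann.strand,
        )

    for ann in truth:
        qid = ann.symbol if ann.symbol in query_lengths else qids[0]
        qlen = query_lengths[qid]
        evalue = 10.0 ** rng.uniform(-180.0, math.log10(e_max))
        aln_len = int(rng.integers(math.ceil(min_len_frac * qlen), qlen + 1))
        hits.append(_make(ann, qid, evalue, aln_len))
        labels.append(True)

    for j in range(n_decoys):
        ann = truth[int(rng.integers(0, len(truth)))]
        qid = qids[int(rng.integers(0, len(qids)))]
        qlen = query_lengths[qid]
        if j % 2 == 0:  # bad e-value, good length
            evalue = 10.0 ** rng.uniform(math.log10(e_max) + 0.1, 0.0)
            aln_len = int(rng.integers(math.ceil(min_len_frac * qlen), qlen + 1))
        else:  # good e-value, short alignment
            evalue = 10.0 ** rng.uniform(-180.0, math.log10(e_max))
            aln_len = int(rng.integers(1, max(2, math.ceil(min_len_frac * qlen))))
            if aln_len / qlen >= min_len_frac:
                aln_len = max(1, math.ceil(min_len_frac * qlen) - 1)
        hits.append(_make(ann, qid, evalue, aln_len))
        labels.append(False)

    order = rng.permutation(len(hits))
    return [hits[i] for i in order], [labels[i] for i in order]
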