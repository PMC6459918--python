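"""Genome-wide phosphorothioate (PT) landscape analysis.

PT modification replaces a non-bridging phosphate oxygen with sulphur;
in the haloarchaeal systems modelled here it occurs at the G_PS_A linkage
of the palindromic 5'-GATC-3' motif. Each + strand GATC occurrence is a
*duplex locus*: because GATC is its own reverse complement, the bottom
strand reads GATC too, with its modifiable G opposite the top strand's
closing C. A locus is *fully* modified when both strands carry a call and
*hemimodified* when exactly one does.

Conventions pinned here (they decide the printed statistics):

* percent-modified counts strand-level calls over motif loci — the
  convention under which 1,229 (+) and 1,222 (−) calls over 94,316 GATC
  sites print as 2.6% (2451);
* the hemi percentage is hemi calls over all calls, printed to the
  nearest integer; percent-modified is printed to 1 decimal;
* ``calls_per_10kb`` is strand calls per 10^4 nt of double-stranded
  genome (calls / (2 x genome length) x 10^4). It is a genome-density
  proxy and is NOT comparable to chromatographic per-dinucleotide
  modification frequencies;
* genomes are treated as linear; circular wrap-around for spacing is
  opt-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import FeatureRecord, GenomeRecord, PtCall

DUPLEX_STATES = ("none", "hemi_plus", "hemi_minus", "full")


class DuplicateCallError(ValueError):
    """Two calls on the same strand of one locus."""


@dataclass(frozen=True)
class DuplexLocus:
    """One + strand GATC occurrence with its duplex modification state."""

    contig: str
    start: int  # 0-based position of the + strand G
    state: str = "none"

    def __post_init__(self) -> None:
        if self.state not in DUPLEX_STATES:
            raise ValueError(f"unknown duplex state {self.state!r}")

    @property
    def footprint(self) -> tuple[int, int]:
        """Half-open genomic interval of the 4 bp motif."""
        return (self.start, self.start + 4)


@dataclass(frozen=True)
class PtSummary:
    n_motifs: int
    n_modified_loci: int
    n_modified_calls: int
    pct_modified: float  # strand calls / motifs, 1 decimal
    n_full: int
    n_hemi: int
    pct_hemi: int  # hemi calls / all calls, nearest integer
    n_plus_calls: int
    n_minus_calls: int
    calls_per_10kb: float
    spacing_min: int | None
    spacing_max: int | None
    features_with_pt: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ContextBias:
    """Base composition at a flank offset, modified loci vs background."""

    offset: int  # -1 (before the motif G) or +1 (after the motif C)
    base: str
    obs_freq: float
    bg_freq: float
    log2_enrichment: float | None  # None when a frequency is zero


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def scan_gatc_loci(
    genome: GenomeRecord, motif: str = "GATC", duplex: bool = True
) -> list[DuplexLocus]:
    """Find every + strand occurrence of ``motif`` as an unmodified locus.

    Overlapping occurrences are each reported; occurrences that would
    overlap an N are impossible for an exact ACGT motif and N-containing
    windows are skipped by construction. For duplex (two-strand)
    semantics the motif must be its own reverse complement, as GATC is.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if duplex and motif != _revcomp(motif):
        raise ValueError(
            f"duplex-state semantics need a palindromic motif; {motif!r} is not"
        )
    loci = []
    start = genome.seq.find(motif)
    while start != -1:
        loci.append(DuplexLocus(genome.id, start))
        start = genome.seq.find(motif, start + 1)
    return loci


# ---------------------------------------------------------------------------
# Duplex-state classification
# ---------------------------------------------------------------------------

def classify_duplex_states(
    loci: Sequence[DuplexLocus], calls: Iterable[PtCall]
) -> tuple[list[DuplexLocus], list[PtCall]]:
    """Assign each locus its duplex state from the strand calls.

    A + call at position p belongs to the locus starting at p; a − call
    at q to the locus starting at q − 3 (pure integer arithmetic; GATC is
    palindromic so the bottom-strand G lies opposite the top-strand C).
    Returns the classified loci and any orphan calls that match no locus
    — orphans are reported, never silently dropped. Two calls on the same
    strand of one locus raise :class:`DuplicateCallError`.
    """
    index = {(l.contig, l.start): i for i, l in enumerate(loci)}
    plus: set[tuple[str, int]] = set()
    minus: set[tuple[str, int]] = set()
    orphans: list[PtCall] = []
    for call in calls:
        key = (call.contig, call.locus_start)
        if key not in index:
            orphans.append(call)
            continue
        bucket = plus if call.strand == "+" else minus
        if key in bucket:
            raise DuplicateCallError(
                f"duplicate {call.strand} strand call at locus {key[0]}:{key[1]}"
            )
        bucket.add(key)
    out = []
    for l in loci:
        key = (l.contig, l.start)
        has_p, has_m = key in plus, key in minus
        if has_p and has_m:
            state = "full"
        elif has_p:
            state = "hemi_plus"
        elif has_m:
            state = "hemi_minus"
        else:
            state = "none"
        out.append(replace(l, state=state))
    return out, orphans


def state_counts(loci: Iterable[DuplexLocus]) -> dict[str, int]:
    counts = {s: 0 for s in DUPLEX_STATES}
    for l in loci:
        counts[l.state] += 1
    return counts


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def modified_call_coordinates(
    loci: Iterable[DuplexLocus], strand: str
) -> list[tuple[str, int]]:
    """Coordinates of the modified G on one strand, in locus order.

    On the + strand that is the locus start; on the − strand it is the +
    strand coordinate of the base carrying the bottom-strand G (start+3).
    """
    out = []
    for l in loci:
        if strand == "+" and l.state in ("full", "hemi_plus"):
            out.append((l.contig, l.start))
        elif strand == "-" and l.state in ("full", "hemi_minus"):
            out.append((l.contig, l.start + 3))
    return out


def summarize_pt(
    loci: Sequence[DuplexLocus],
    genome: GenomeRecord,
    features: Sequence[FeatureRecord] = (),
) -> PtSummary:
    """Roll classified duplex loci up into the headline PT statistics."""
    if not loci:
        raise ValueError("cannot summarise an empty locus collection")
    counts = state_counts(loci)
    n_full = counts["full"]
    n_hemi = counts["hemi_plus"] + counts["hemi_minus"]
    n_loci_mod = n_full + n_hemi
    n_plus = n_full + counts["hemi_plus"]
    n_minus = n_full + counts["hemi_minus"]
    n_calls = n_plus + n_minus
    pct_modified = round(100.0 * n_calls / len(loci), 1)
    pct_hemi = int(round(100.0 * n_hemi / n_calls)) if n_calls else 0

    spacing_min = spacing_max = None
    plus_pos = [p for _, p in modified_call_coordinates(loci, "+")]
    minus_pos = [p for _, p in modified_call_coordinates(loci, "-")]
    dists: list[int] = []
    for pos in (plus_pos, minus_pos):
        pos = sorted(pos)
        dists.extend(b - a for a, b in zip(pos, pos[1:]))
    if dists:
        spacing_min, spacing_max = min(dists), max(dists)

    features_with_pt: dict[str, int] = {}
    if features:
        mod = [l for l in loci if l.state != "none"]
        starts = np.array([l.start for l in mod], dtype=np.int64)
        by_contig: dict[str, np.ndarray] = {}
        for c in {l.contig for l in mod}:
            by_contig[c] = np.sort(starts[[i for i, l in enumerate(mod) if l.contig == c]])
        for f in features:
            pos = by_contig.get(f.contig)
            # a locus footprint [s, s+4) intersects [start, end) iff s in (start-4, end)
            hit = pos is not None and bool(
                np.searchsorted(pos, f.end, side="left")
                > np.searchsorted(pos, f.start - 3, side="left")
            )
            if hit:
                features_with_pt[f.kind] = features_with_pt.get(f.kind, 0) + 1

    return PtSummary(
        n_motifs=len(loci),
        n_modified_loci=n_loci_mod,
        n_modified_calls=n_calls,
        pct_modified=pct_modified,
        n_full=n_full,
        n_hemi=n_hemi,
        pct_hemi=pct_hemi,
        n_plus_calls=n_plus,
        n_minus_calls=n_minus,
        calls_per_10kb=n_calls / (2.0 * genome.length) * 1e4,
        spacing_min=spacing_min,
        spacing_max=spacing_max,
        features_with_pt=features_with_pt,
    )


# ---------------------------------------------------------------------------
# Spacing
# ---------------------------------------------------------------------------

def spacing_stats(
    loci: Sequence[DuplexLocus],
    strand_mode: str = "per_strand",
    circular: bool = False,
    genome_length: int | None = None,
) -> tuple[int, int, list[int]]:
    """Distances between consecutive modified-G coordinates.

    ``per_strand`` (default) computes consecutive differences separately
    on each strand and pools the distances; ``combined`` merges both
    strands' coordinates first. The genome is treated as linear unless
    ``circular`` is set (then the wrap-around distance closes each ring
    and ``genome_length`` is required).
    """
    if strand_mode not in ("per_strand", "combined"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if circular and genome_length is None:
        raise ValueError("circular spacing requires genome_length")
    groups: list[list[tuple[str, int]]]
    if strand_mode == "per_strand":
        groups = [modified_call_coordinates(loci, "+"), modified_call_coordinates(loci, "-")]
    else:
        groups = [modified_call_coordinates(loci, "+") + modified_call_coordinates(loci, "-")]
    dists: list[int] = []
    for grp in groups:
        by_contig: dict[str, list[int]] = {}
        for contig, p in grp:
            by_contig.setdefault(contig, []).append(p)
        for pos in by_contig.values():
            pos.sort()
            dists.extend(b - a for a, b in zip(pos, pos[1:]))
            if circular and len(pos) >= 2:
                dists.append(genome_length - pos[-1] + pos[0])
    if len(dists) < 1:
        raise ValueError("need at least 2 modified calls on the relevant strand(s)")
    return min(dists), max(dists), dists


# ---------------------------------------------------------------------------
# Flanking-base context bias
# ---------------------------------------------------------------------------

def context_bias(
    loci: Sequence[DuplexLocus],
    genome: GenomeRecord,
    offsets: Sequence[int] = (-1, 1),
) -> list[ContextBias]:
    """Flanking-base composition of modified loci vs all motif loci.

    Offset −1 is the base 5' of the motif G, +1 the base 3' of the
    closing C. Loci lacking the flank (genome edge) are excluded from
    both numerator and background at that offset. ``log2_enrichment`` is
    log2(obs/bg), undefined (None) when either frequency is zero.
    """
    modified = [l for l in loci if l.state != "none"]
    if not modified:
        raise ValueError("no modified loci; context bias undefined")
    out: list[ContextBias] = []
    for off in offsets:
        if off not in (-1, 1):
            raise ValueError("offsets are relative flank positions -1 or +1")

        def flank(l: DuplexLocus) -> str | None:
            p = l.start - 1 if off == -1 else l.start + 4
            if 0 <= p < genome.length:
                return genome.seq[p]
            return None

        bg = [b for b in (flank(l) for l in loci) if b is not None and b in "ACGT"]
        obs = [b for b in (flank(l) for l in modified) if b is not None and b in "ACGT"]
        for base in "ACGT":
            bg_f = bg.count(base) / len(bg) if bg else 0.0
            obs_f = obs.count(base) / len(obs) if obs else 0.0
            enr = math.log2(obs_f / bg_f) if obs_f > 0 and bg_f > 0 else None
            out.append(ContextBias(off, base, obs_f, bg_f, enr))
    return out
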