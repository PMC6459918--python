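"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by a different route
than the package (recursive enumeration instead of the vectorised
dynamic programme, naive rescans instead of incremental bookkeeping) so
agreement is evidence, not tautology.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np
import pytest

from thioscape import SimConfig, blosum62, gen_genome_with_motifs, gen_pt_calls


@pytest.fixture(scope="session")
def b62():
    return blosum62()


@pytest.fixture(scope="session")
def small_pt_fixture():
    """A 50 kb genome with 300 motifs, 40 full / 30 hemi+ / 25 hemi− loci."""
    cfg = SimConfig(seed=42, genome_len=50_000, n_motifs=300,
                    n_full=40, n_hemi_plus=30, n_hemi_minus=25)
    genome, positions = gen_genome_with_motifs(cfg)
    calls, truth = gen_pt_calls(positions, cfg, genome.id)
    return cfg, genome, positions, calls, truth


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_align_score(
    a: str, b: str, score_fn, gap_open: float = 10.0, gap_extend: float = 0.5,
    end_gaps_penalized: bool = False,
) -> float:
    """Optimal affine-gap global score by exhaustive recursion over all
    gapped alignments (memoised on position and gap state).

    Cost convention mirrors the aligner under test: a gap of length k
    costs gap_open + k*gap_extend; leading/trailing gap runs are free
    unless penalised.
    """
    m, n = len(a), len(b)
    sys.setrecursionlimit(10_000)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == m and j == n:
            return 0.0
        options = []
        if i < m and j < n:
            options.append(score_fn(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < m:  # gap in b, consuming a
            free = not end_gaps_penalized and (j == 0 or j == n)
            cost = 0.0 if free else gap_extend + (gap_open if state != "Ix" else 0.0)
            options.append(best(i + 1, j, "Ix") - cost)
        if j < n:  # gap in a, consuming b
            free = not end_gaps_penalized and (i == 0 or i == m)
            cost = 0.0 if free else gap_extend + (gap_open if state != "Iy" else 0.0)
            options.append(best(i, j + 1, "Iy") - cost)
        return max(options)

    out = best(0, 0, "M")
    best.cache_clear()
    return out


def naive_motif_scan(seq: str, motif: str = "GATC") -> list[int]:
    """Sliding-window occurrence scan, one window at a time."""
    return [i for i in range(len(seq) - len(motif) + 1)
            if seq[i:i + len(motif)] == motif]


def naive_interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Edge distance by exhaustive min over endpoint differences, 0 on
    overlap (checked point-wise on small intervals)."""
    if a[1] <= b[0] or b[1] <= a[0]:
        return min(abs(a[0] - b[1]), abs(b[0] - a[1]),
                   abs(a[1] - b[0]), abs(b[1] - a[0]))
    return 0


def exhaustive_spearman(x, y) -> float:
    """Spearman rho from first principles: Pearson on midranks."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks
    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
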