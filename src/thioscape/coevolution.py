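"""Affine-gap global protein alignment and the coevolution analysis.

The coevolution question: if a modification component (DndCD) and a
restriction/exclusion component (PbeAC or DndFGH) were inherited and
transferred together, their divergence degrees (1 − similarity rate)
from a common reference strain should be linearly related across
strains. The statistic is the *similarity rate*: the percentage of
columns with a positive substitution score in a global alignment of the
strain's concatenated component proteins against the reference's.

The aligner is a Gotoh affine-gap global aligner in the conventions of
classic global protein aligners: BLOSUM62 scores, gap open 10, gap
extend 0.5 (a gap of length k costs open + k·extend), end gaps
unpenalized, and identity/similarity percentages whose denominator is
the full alignment length including gap columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

NEG = -1e30  # effectively -infinity for the DP


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-pair scoring matrix over a fixed alphabet."""

    alphabet: str
    matrix: np.ndarray  # (n, n) float, symmetric

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match alphabet")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    def index(self, seq: str) -> np.ndarray:
        try:
            return np.array([self.alphabet.index(c) for c in seq], dtype=np.intp)
        except ValueError:
            bad = sorted(set(seq) - set(self.alphabet))
            raise ValueError(f"residues {bad} not in matrix alphabet") from None

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[self.alphabet.index(a), self.alphabet.index(b)])


def blosum62() -> SubstitutionMatrix:
    """BLOSUM62 incl. ambiguity codes (B, Z, X) and stop (*)."""
    m = substitution_matrices.load("BLOSUM62")
    return SubstitutionMatrix("".join(m.alphabet), np.array(m, dtype=float))


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    pct_identity: float
    pct_similarity: float
    n_gap_cols: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")


@dataclass(frozen=True)
class CoevolutionFit:
    """Correlation/regression of restriction-component similarity on
    modification-component similarity across strains."""

    n: int
    rho: float  # Spearman rank correlation (the headline statistic)
    r: float  # Pearson
    slope: float
    intercept: float
    degenerate: bool = False  # a constant column made correlations undefined


# ---------------------------------------------------------------------------
# Affine-gap global alignment (Gotoh), end gaps free
# ---------------------------------------------------------------------------

def global_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_penalized: bool = False,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two protein sequences.

    Three-state Gotoh dynamic programme; a gap of length k costs
    ``gap_open + k * gap_extend``, except leading/trailing gaps, which
    are free unless ``end_gaps_penalized``. Traceback ties resolve
    diagonal > up (gap in b) > left (gap in a), so the alignment is
    deterministic. Identity is identical columns / alignment length;
    similarity is positive-scoring columns / alignment length; gap
    columns count in the denominators only.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if matrix is None:
        matrix = blosum62()
    ai = matrix.index(a)
    bi = matrix.index(b)
    m, n = len(a), len(b)
    S = matrix.matrix
    oe, e = gap_open + gap_extend, gap_extend

    M = np.full((m + 1, n + 1), NEG)
    Ix = np.full((m + 1, n + 1), NEG)  # gap in b (consumes a; "up")
    Iy = np.full((m + 1, n + 1), NEG)  # gap in a (consumes b; "left")
    M[0, 0] = 0.0
    if end_gaps_penalized:
        Ix[1:, 0] = -(gap_open + e * np.arange(1, m + 1))
        Iy[0, 1:] = -(gap_open + e * np.arange(1, n + 1))
    else:
        Ix[1:, 0] = 0.0
        Iy[0, 1:] = 0.0

    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[ai[i - 1], bi] + prev_best[:-1]
        # vertical gap: free extension only in the last column (trailing)
        open_cost = np.full(n + 1, oe)
        ext_cost = np.full(n + 1, e)
        if not end_gaps_penalized:
            open_cost[0] = 0.0
            ext_cost[0] = 0.0
            open_cost[n] = 0.0
            ext_cost[n] = 0.0
        Ix[i] = np.maximum(
            np.maximum(M[i - 1], Iy[i - 1]) - open_cost, Ix[i - 1] - ext_cost
        )
        # horizontal gap: in-row prefix-scan (a run entered at column k<j)
        entry = np.maximum(M[i], Ix[i])  # entry points within this row
        if i == m and not end_gaps_penalized:
            run = np.maximum.accumulate(np.maximum(entry, Iy[i]))
            Iy[i, 1:] = np.maximum(Iy[i, 1:], run[:-1])
        else:
            t = entry + e * np.arange(n + 1) - gap_open
            run = np.maximum.accumulate(t)
            Iy[i, 1:] = np.maximum(Iy[i, 1:], run[:-1] - e * np.arange(1, n + 1))

    aligned_a, aligned_b = _traceback(
        a, b, ai, bi, S, M, Ix, Iy, oe, e, end_gaps_penalized
    )
    score = float(max(M[m, n], Ix[m, n], Iy[m, n]))
    return _finish(aligned_a, aligned_b, score, matrix)


def _traceback(a, b, ai, bi, S, M, Ix, Iy, oe, e, end_pen):
    m, n = len(a), len(b)
    eps = 1e-6
    states = ("M", "Ix", "Iy")
    vals = (M[m, n], Ix[m, n], Iy[m, n])
    state = states[int(np.argmax(vals))]
    # ties: prefer M, then Ix (up), then Iy (left)
    best = max(vals)
    for s, v in zip(states, vals):
        if v >= best - eps:
            state = s
            break
    i, j = m, n
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - S[ai[i - 1], bi[j - 1]]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s, v in (("M", M[i, j]), ("Ix", Ix[i, j]), ("Iy", Iy[i, j])):
                if abs(v - target) <= eps:
                    state = s
                    break
        elif state == "Ix":
            out_a.append(a[i - 1])
            out_b.append("-")
            free = not end_pen and (j == 0 or j == n)
            o_c, e_c = (0.0, 0.0) if free else (oe, e)
            target = Ix[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - o_c - target) <= eps:
                state = "M"
            elif abs(Ix[i, j] - e_c - target) <= eps:
                state = "Ix"
            elif abs(Iy[i, j] - o_c - target) <= eps:
                state = "Iy"
            elif j == 0:
                state = "Ix"  # boundary run to the origin
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback lost in Ix")
        else:  # Iy
            out_a.append("-")
            out_b.append(b[j - 1])
            free = not end_pen and (i == 0 or i == m)
            o_c, e_c = (0.0, 0.0) if free else (oe, e)
            target = Iy[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - o_c - target) <= eps:
                state = "M"
            elif abs(Ix[i, j] - o_c - target) <= eps:
                state = "Ix"
            elif abs(Iy[i, j] - e_c - target) <= eps:
                state = "Iy"
            elif i == 0:
                state = "Iy"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback lost in Iy")
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _finish(aligned_a: str, aligned_b: str, score: float,
            matrix: SubstitutionMatrix) -> PairwiseAlignment:
    length = len(aligned_a)
    ident = sim = gaps = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            gaps += 1
            continue
        if ca == cb:
            ident += 1
        # identities count as similar even for the rare residues whose
        # self-score is non-positive (X), keeping identity <= similarity
        if ca == cb or matrix.score(ca, cb) > 0:
            sim += 1
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        pct_identity=100.0 * ident / length,
        pct_similarity=100.0 * sim / length,
        n_gap_cols=gaps,
    )


# ---------------------------------------------------------------------------
# Similarity-rate tables
# ---------------------------------------------------------------------------

def similarity_rates(
    strains: Sequence[tuple[str, Sequence[str], Sequence[str]]],
    ref_mod: Sequence[str],
    ref_res: Sequence[str],
    matrix: SubstitutionMatrix | None = None,
    concatenate: bool = True,
    **align_kwargs,
) -> pd.DataFrame:
    """Per-strain similarity rates of the modification and restriction
    components against fixed reference proteins.

    Each entry of ``strains`` is (id, mod component sequences, res
    component sequences); components are concatenated in the given,
    fixed order (C then D; A then C) before alignment — set
    ``concatenate=False`` to align components separately and average
    their similarities instead. Strains with a missing or empty
    component are skipped with a warning, never silently. Returns a
    DataFrame (strain_id, mod_similarity, res_similarity) sorted by id.
    """
    if matrix is None:
        matrix = blosum62()
    ref_mod_cat, ref_res_cat = "".join(ref_mod), "".join(ref_res)
    if not ref_mod_cat or not ref_res_cat:
        raise ValueError("reference components must be non-empty")
    rows = []
    for strain_id, mod_seqs, res_seqs in strains:
        if not mod_seqs or not res_seqs or any(not s for s in mod_seqs) \
                or any(not s for s in res_seqs):
            warnings.warn(
                f"strain {strain_id!r} skipped: missing or empty component",
                stacklevel=2,
            )
            continue
        if concatenate:
            mod_sim = global_align("".join(mod_seqs), ref_mod_cat,
                                   matrix, **align_kwargs).pct_similarity
            res_sim = global_align("".join(res_seqs), ref_res_cat,
                                   matrix, **align_kwargs).pct_similarity
        else:
            mod_sim = float(np.mean([
                global_align(s, r, matrix, **align_kwargs).pct_similarity
                for s, r in zip(mod_seqs, ref_mod)
            ]))
            res_sim = float(np.mean([
                global_align(s, r, matrix, **align_kwargs).pct_similarity
                for s, r in zip(res_seqs, ref_res)
            ]))
        rows.append((strain_id, mod_sim, res_sim))
    df = pd.DataFrame(rows, columns=["strain_id", "mod_similarity", "res_similarity"])
    return df.sort_values("strain_id", ignore_index=True)


# ---------------------------------------------------------------------------
# Divergence regression / correlation
# ---------------------------------------------------------------------------

def coevolution_fit(table: pd.DataFrame) -> CoevolutionFit:
    """Correlate and regress restriction-component similarity on
    modification-component similarity.

    rho is the Spearman rank correlation (invariant under the
    similarity ↔ divergence flip s → 100 − s applied to both columns),
    r the Pearson correlation, slope/intercept the least-squares line.
    A constant column leaves the correlations undefined; the fit is then
    flagged degenerate with NaN statistics.
    """
    x = table["mod_similarity"].to_numpy(dtype=float)
    y = table["res_similarity"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 strains for a coevolution fit")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CoevolutionFit(n=n, rho=float("nan"), r=float("nan"),
                              slope=float("nan"), intercept=float("nan"),
                              degenerate=True)
    rho = float(stats.spearmanr(x, y).statistic)
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)
    return CoevolutionFit(n=n, rho=rho, r=r,
                          slope=float(fit.slope), intercept=float(fit.intercept))
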