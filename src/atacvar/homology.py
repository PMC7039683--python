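"""Deep-homology testing for noncoding elements.

Global affine-gap alignment (Gotoh) of a test sequence against a
reference, with composition-preserving controls: the reverse complement,
the non-biological reversal, and Fisher-Yates shuffles.  Reported
statistics are percent identity, null-character (dash) counts, and counts
of >= 5 bp gap-free identity blocks; the test sequence's z-scores are
taken against the shuffle-control distribution.

Gap scoring convention: a gap of length g costs ``gap_open +
(g - 1) * gap_extend`` (both negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genome import reverse_complement

__all__ = [
    "AlignmentResult",
    "ControlSet",
    "global_align",
    "fisher_yates_shuffle",
    "make_controls",
    "identity_blocks",
    "three_way_align",
    "homology_report",
]

# traceback states, in tie-break preference order
_DIAG, _GAP_B, _GAP_A = 0, 1, 2
_NEG = float("-inf")


@dataclass
class AlignmentResult:
    aligned: list[str]  # rows with '-' null characters
    score: float
    percent_identity: float  # identical non-gap columns / total columns * 100
    n_null_chars: int  # total dashes over all rows
    identity_blocks_5bp: int
    row_null_chars: list[int] = field(default_factory=list)


@dataclass
class ControlSet:
    plus: str
    minus: str  # reverse complement
    reverse: str  # non-biological reversal
    shuffles: list[str]
    shuffle_seeds: list[int]

    def as_dict(self) -> dict[str, str]:
        d = {"minus": self.minus, "reverse": self.reverse}
        for i, s in enumerate(self.shuffles, start=1):
            d[f"shuffle_{i}"] = s
        return d


def _gotoh(
    n: int,
    m: int,
    sub: Callable[[int, int], float],
    gap_open: float,
    gap_extend: float,
) -> tuple[float, list[tuple[int, int, int]]]:
    """Affine-gap global DP over an n x m instance.

    ``sub(i, j)`` scores pairing item i of A with item j of B.  Returns
    (score, ops) where ops is the traceback as (state) steps from the
    origin; tie-breaking prefers diagonal > gap-in-B > gap-in-A.
    """
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in B (consumes A)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in A (consumes B)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        ptr_x[i, 0] = _GAP_B if i > 1 else _DIAG
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        ptr_y[0, j] = _GAP_A if j > 1 else _DIAG
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        pm, px = ptr_m[i], ptr_x[i]
        py = ptr_y[i]
        for j in range(1, m + 1):
            s = sub(i - 1, j - 1)
            best, state = Mi1[j - 1], _DIAG
            if Xi1[j - 1] > best:
                best, state = Xi1[j - 1], _GAP_B
            if Yi1[j - 1] > best:
                best, state = Yi1[j - 1], _GAP_A
            Mi[j] = best + s
            pm[j] = state
            # open from M/Y, extend X
            best, state = Mi1[j] + gap_open, _DIAG
            if Xi1[j] + gap_extend > best:
                best, state = Xi1[j] + gap_extend, _GAP_B
            if Yi1[j] + gap_open > best:
                best, state = Yi1[j] + gap_open, _GAP_A
            Xi[j] = best
            px[j] = state
            best, state = Mi[j - 1] + gap_open, _DIAG
            if Yi[j - 1] + gap_extend > best:
                best, state = Yi[j - 1] + gap_extend, _GAP_A
            if Xi[j - 1] + gap_open > best:
                best, state = Xi[j - 1] + gap_open, _GAP_B
            Yi[j] = best
            py[j] = state
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))  # argmax prefers _DIAG > _GAP_B > _GAP_A on ties
    score = finals[state]
    ops: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        ops.append(state)
        if state == _DIAG:
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == _GAP_B:
            state = int(ptr_x[i, j])
            i -= 1
        else:
            state = int(ptr_y[i, j])
            j -= 1
    ops.reverse()
    return float(score), ops


def _stats(rows: list[str], score: float) -> AlignmentResult:
    cols = len(rows[0])
    up = [r.upper() for r in rows]
    ident = sum(
        1
        for c in range(cols)
        if up[0][c] != "-" and all(r[c] == up[0][c] for r in up[1:])
    )
    nulls = [r.count("-") for r in rows]
    res = AlignmentResult(
        aligned=rows,
        score=score,
        percent_identity=100.0 * ident / cols if cols else 0.0,
        n_null_chars=sum(nulls),
        identity_blocks_5bp=0,
        row_null_chars=nulls,
    )
    res.identity_blocks_5bp = identity_blocks(res, 5)
    return res


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> AlignmentResult:
    """Optimal affine-gap global alignment of two DNA sequences.

    Deterministic tie-breaking: diagonal (match/mismatch) is preferred
    over a gap in ``b``, which is preferred over a gap in ``a``.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    au, bu = a.upper(), b.upper()

    def sub(i: int, j: int) -> float:
        return match if au[i] == bu[j] else mismatch

    score, ops = _gotoh(len(a), len(b), sub, gap_open, gap_extend)
    ra, rb = [], []
    i = j = 0
    for st in ops:
        if st == _DIAG:
            ra.append(a[i])
            rb.append(b[j])
            i += 1
            j += 1
        elif st == _GAP_B:
            ra.append(a[i])
            rb.append("-")
            i += 1
        else:
            ra.append("-")
            rb.append(b[j])
            j += 1
    return _stats(["".join(ra), "".join(rb)], score)


def fisher_yates_shuffle(seq: str, seed: int) -> str:
    """Uniform random permutation of the sequence (classic in-place walk)."""
    rng = np.random.default_rng(seed)
    chars = list(seq)
    for i in range(len(chars) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        chars[i], chars[j] = chars[j], chars[i]
    return "".join(chars)


def make_controls(seq: str, n_shuffles: int = 3, seed: int = 0) -> ControlSet:
    """Reverse complement, reversal, and ``n_shuffles`` Fisher-Yates
    shuffles of ``seq``; shuffle seeds are recorded."""
    seeds = [seed + i for i in range(n_shuffles)]
    return ControlSet(
        plus=seq,
        minus=reverse_complement(seq),
        reverse=seq[::-1],
        shuffles=[fisher_yates_shuffle(seq, s) for s in seeds],
        shuffle_seeds=seeds,
    )


def identity_blocks(
    alignment: AlignmentResult, block_len: int = 5, exact: bool = False
) -> int:
    """Maximal runs of identical, gap-free columns with length >= block_len
    (== block_len when ``exact``)."""
    rows = [r.upper() for r in alignment.aligned]
    cols = len(rows[0])
    count = 0
    run = 0
    for c in range(cols + 1):
        good = (
            c < cols
            and rows[0][c] != "-"
            and all(r[c] == rows[0][c] for r in rows[1:])
        )
        if good:
            run += 1
        else:
            if (run == block_len) if exact else (run >= block_len):
                count += 1
            run = 0
    return count


def three_way_align(
    a: str,
    b: str,
    c: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> AlignmentResult:
    """Progressive three-way alignment.

    The closest pair (highest pairwise identity) is aligned first; the
    remaining sequence is aligned to the pair's profile with column-average
    scoring (a gap in a profile row scores as a mismatch).  Reports the
    total null characters over all three rows.
    """
    seqs = [a, b, c]
    if any(not s for s in seqs):
        raise ValueError("cannot align an empty sequence")
    kw = dict(match=match, mismatch=mismatch, gap_open=gap_open, gap_extend=gap_extend)
    pairs = [(0, 1), (0, 2), (1, 2)]
    idents = [global_align(seqs[i], seqs[j], **kw).percent_identity for i, j in pairs]
    pi, pj = pairs[int(np.argmax(idents))]
    pk = ({0, 1, 2} - {pi, pj}).pop()
    pair_aln = global_align(seqs[pi], seqs[pj], **kw)
    prof = [pair_aln.aligned[0].upper(), pair_aln.aligned[1].upper()]
    third = seqs[pk]
    tu = third.upper()

    def sub(i: int, j: int) -> float:
        col = (prof[0][i], prof[1][i])
        total = 0.0
        for ch in col:
            total += match if ch == tu[j] else mismatch
        return total / 2.0

    score, ops = _gotoh(len(prof[0]), len(third), sub, gap_open, gap_extend)
    rows: list[list[str]] = [[], [], []]
    i = j = 0
    for st in ops:
        if st == _DIAG:
            rows[0].append(pair_aln.aligned[0][i])
            rows[1].append(pair_aln.aligned[1][i])
            rows[2].append(third[j])
            i += 1
            j += 1
        elif st == _GAP_B:  # consume profile column, gap in third
            rows[0].append(pair_aln.aligned[0][i])
            rows[1].append(pair_aln.aligned[1][i])
            rows[2].append("-")
            i += 1
        else:  # new column: gap in both profile rows
            rows[0].append("-")
            rows[1].append("-")
            rows[2].append(third[j])
            j += 1
    # restore input order a, b, c
    ordered = [""] * 3
    for row, orig in zip(rows, (pi, pj, pk)):
        ordered[orig] = "".join(row)
    return _stats(ordered, score)


def homology_report(
    test_seq: str,
    reference_seqs: Sequence[str],
    n_shuffles: int = 3,
    seed: int = 0,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> dict:
    """Compare the test sequence and its controls against the references.

    For each candidate (test, minus, reverse, shuffles) and each reference:
    percent identity, pairwise null characters, identity-block count; plus
    a three-way null-character count when >= 2 references are given.  The
    test's z-scores are computed against the shuffle-control mean/s.d.
    """
    if not reference_seqs:
        raise ValueError("need at least one reference sequence")
    kw = dict(match=match, mismatch=mismatch, gap_open=gap_open, gap_extend=gap_extend)
    controls = make_controls(test_seq, n_shuffles=n_shuffles, seed=seed)
    candidates = {"test": controls.plus, **controls.as_dict()}
    rows: dict[str, dict[str, float]] = {}
    for name, cand in candidates.items():
        idents, nulls, blocks = [], [], []
        for ref in reference_seqs:
            aln = global_align(cand, ref, **kw)
            idents.append(aln.percent_identity)
            nulls.append(aln.n_null_chars)
            blocks.append(aln.identity_blocks_5bp)
        stats = {
            "identity": float(np.mean(idents)),
            "pair_null_chars": float(np.mean(nulls)),
            "identity_blocks": float(np.mean(blocks)),
        }
        if len(reference_seqs) >= 2:
            tw = three_way_align(reference_seqs[0], reference_seqs[1], cand, **kw)
            stats["threeway_null_chars"] = float(tw.n_null_chars)
            stats["threeway_null_chars_candidate_row"] = float(
                tw.row_null_chars[2]
            )
        rows[name] = stats
    shuffle_names = [n for n in rows if n.startswith("shuffle_")]
    z_scores: dict[str, float] = {}
    control_summary: dict[str, dict[str, float]] = {}
    for stat in rows["test"]:
        vals = np.array([rows[n][stat] for n in shuffle_names])
        mu, sd = float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        control_summary[stat] = {"mean": mu, "sd": sd}
        z_scores[stat] = (rows["test"][stat] - mu) / sd if sd > 0 else 0.0
    return {
        "candidates": rows,
        "control_summary": control_summary,
        "z_scores": z_scores,
        "shuffle_seeds": controls.shuffle_seeds,
    }
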