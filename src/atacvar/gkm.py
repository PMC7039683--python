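"""Gapped k-mer SVM: exact string kernel, training, and 10-mer weight table.

The kernel between two sequences is the inner product of their gapped
k-mer count vectors (k informative columns out of word length l).  It is
computed two ways:

* :func:`gkm_kernel` — the mismatch-coefficient formulation: summing
  ``f(m) = C(l - m, k)`` over all pairs of l-mers at Hamming distance m
  (zero for ``m > l - k``).
* :func:`gram_matrix` — a per-position-pattern dense count/GEMM route used
  for whole training sets; exactly equal to the former (integer counts).

With ``rc_collapse`` each sequence's l-mer multiset is augmented with the
reverse complements before either computation, which makes every score
strand-insensitive.

Sequence scoring is linear: the trained model induces a weight per l-mer
(its unnormalized decision contribution), so ``score_sequence`` is a sum
of table lookups and deltaSVM decomposes over the l-mers covering a SNP.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .genome import Genome, GenomicInterval, gc_fraction, repeat_fraction, reverse_complement

__all__ = [
    "GkmParams",
    "GkmModel",
    "TrainingSet",
    "mismatch_coefficient",
    "gkm_kernel",
    "gram_matrix",
    "build_negative_set",
    "train",
    "score_sequence",
    "cross_validate",
    "write_model",
    "read_model",
]

_CODE = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_BASES = np.array(list("ACGT"))


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class GkmParams:
    """Kernel/SVM parameters; defaults l=10, k=6."""

    l: int = 10
    k: int = 6
    rc_collapse: bool = True
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.k > self.l:
            raise ValueError(f"k ({self.k}) must not exceed l ({self.l})")
        if not (1 <= self.k):
            raise ValueError("k must be >= 1")
        if self.l > 12:
            raise ValueError("l > 12 unsupported (weight table would be too large)")


@dataclass
class TrainingSet:
    """Positive and matched-negative sequence sets (negatives ~ratio x)."""

    positives: list[str]
    negatives: list[str]
    positive_intervals: list[GenomicInterval] | None = None
    negative_intervals: list[GenomicInterval] | None = None


def mismatch_coefficient(m: int, l: int, k: int) -> int:
    """Number of gapped k-mers shared by two l-mers differing at m positions."""
    if k > l:
        raise ValueError(f"k ({k}) must not exceed l ({l})")
    if not (0 <= m <= l):
        raise ValueError(f"m must be in [0, {l}], got {m}")
    if m > l - k:
        return 0
    return comb(l - m, k)


def _valid_windows(codes: np.ndarray, l: int) -> np.ndarray:
    """All l-windows (rows) that contain no N/invalid base."""
    if len(codes) < l:
        raise ValueError(f"sequence shorter than l = {l}")
    win = np.lib.stride_tricks.sliding_window_view(codes, l)
    return win[(win < 4).all(axis=1)]


def _f_table(l: int, k: int) -> np.ndarray:
    return np.array([mismatch_coefficient(m, l, k) for m in range(l + 1)], dtype=np.float64)


def _pair_kernel(A: np.ndarray, B: np.ndarray, ftab: np.ndarray, l: int) -> float:
    if len(A) == 0 or len(B) == 0:
        return 0.0
    total = 0.0
    step = max(1, 4_000_000 // (len(B) * l))  # bound the mismatch tensor
    for i in range(0, len(A), step):
        mm = (A[i : i + step, None, :] != B[None, :, :]).sum(axis=2)
        total += float(ftab[mm].sum())
    return total


def _augment_rc(W: np.ndarray) -> np.ndarray:
    return np.concatenate([W, (3 - W)[:, ::-1]], axis=0)


def gkm_kernel(
    seq_a: str, seq_b: str, params: GkmParams = GkmParams(), normalized: bool = True
) -> float:
    """Gapped k-mer kernel via the mismatch-coefficient formulation.

    l-mers containing N are skipped.  ``normalized`` divides by
    ``sqrt(K(A,A) K(B,B))``.
    """
    l = params.l
    ftab = _f_table(l, params.k)
    A = _valid_windows(encode_sequence(seq_a), l)
    B = _valid_windows(encode_sequence(seq_b), l)
    if params.rc_collapse:
        A, B = _augment_rc(A), _augment_rc(B)
    kab = _pair_kernel(A, B, ftab, l)
    if not normalized:
        return kab
    kaa = _pair_kernel(A, A, ftab, l)
    kbb = _pair_kernel(B, B, ftab, l)
    if kaa == 0 or kbb == 0:
        raise ValueError("cannot normalize: a sequence has no valid l-mers")
    return kab / np.sqrt(kaa * kbb)


class _Featurizer:
    """Shared pattern tables for one (l, k)."""

    def __init__(self, l: int, k: int):
        self.l, self.k = l, k
        self.patterns = list(itertools.combinations(range(l), k))
        self.n_kmers = 4**k
        self.pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        self.lpow = 4 ** np.arange(l - 1, -1, -1, dtype=np.int64)

    def pattern_codes(self, windows: np.ndarray, pat: tuple) -> np.ndarray:
        return windows[:, pat].astype(np.int64) @ self.pw


def gram_matrix(
    seqs: Sequence[str], params: GkmParams = GkmParams(), normalized: bool = True
) -> np.ndarray:
    """Kernel matrix over a sequence set (dense per-pattern count route)."""
    fz = _Featurizer(params.l, params.k)
    n = len(seqs)
    win_list = [_valid_windows(encode_sequence(s), params.l) for s in seqs]
    counts = np.array([len(w) for w in win_list])
    if (counts == 0).any():
        bad = int(np.argmax(counts == 0))
        raise ValueError(f"sequence {bad} has no valid l-mers")
    W = np.concatenate(win_list, axis=0)
    seq_idx = np.repeat(np.arange(n, dtype=np.int64), counts)
    offs = seq_idx * fz.n_kmers
    nbin = n * fz.n_kmers
    G = np.zeros((n, n))
    if params.rc_collapse:
        Wrc = (3 - W)[:, ::-1]
    for pat in fz.patterns:
        codes = fz.pattern_codes(W, pat)
        C = np.bincount(offs + codes, minlength=nbin).reshape(n, fz.n_kmers)
        C = C.astype(np.float32)
        if params.rc_collapse:
            codes_r = fz.pattern_codes(Wrc, pat)
            Cr = np.bincount(offs + codes_r, minlength=nbin).reshape(n, fz.n_kmers)
            Cr = Cr.astype(np.float32)
            G += 2.0 * (C @ C.T + Cr @ C.T).astype(np.float64)
        else:
            G += (C @ C.T).astype(np.float64)
    G = 0.5 * (G + G.T)  # pattern sum is symmetric; remove float noise
    if normalized:
        d = np.sqrt(np.diag(G))
        G = G / np.outer(d, d)
    return G


def build_negative_set(
    positives: Sequence[str],
    genome: Genome,
    ratio: int = 10,
    gc_tolerance: float = 0.02,
    repeat_tolerance: float = 0.10,
    exclusions: Sequence[GenomicInterval] = (),
    seed: int = 0,
    length: int | None = None,
    max_pool_factor: int = 200,
    max_relaxations: int = 4,
) -> TrainingSet:
    """Sample ``ratio`` genomic negatives per positive, matched on GC and
    repeat fraction, avoiding ``exclusions`` and sampling without
    replacement.  Deterministic given ``seed``.

    Tolerances are doubled up to ``max_relaxations`` times for positives
    whose composition is rare in the genome; an error reports the
    unmatched bin if that still fails.
    """
    if not positives:
        raise ValueError("no positive sequences given")
    length = length or len(positives[0])
    rng = np.random.default_rng(seed)
    # candidate pool of random windows
    chroms = [c for c in genome.chroms if genome.lengths[c] >= length]
    if not chroms:
        raise ValueError("no chromosome long enough for negative sampling")
    weights = np.array([genome.lengths[c] - length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    n_pool = min(
        int(sum(genome.lengths[c] - length + 1 for c in chroms)),
        max_pool_factor * ratio * len(positives),
    )
    chrom_draw = rng.choice(len(chroms), size=n_pool, p=weights)
    starts = np.array(
        [rng.integers(0, genome.lengths[chroms[ci]] - length + 1) for ci in chrom_draw]
    )
    # deduplicate candidate windows (sample without replacement)
    seen: set[tuple[int, int]] = set()
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exclusions:
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)
    cand: list[tuple[str, int, float, float]] = []  # seq, start-id, gc, rep
    cand_iv: list[GenomicInterval] = []
    for ci, st in zip(chrom_draw, starts):
        chrom = chroms[ci]
        key = (int(ci), int(st))
        if key in seen:
            continue
        seen.add(key)
        iv = GenomicInterval(chrom, int(st), int(st) + length)
        if any(iv.overlaps(e) for e in excl_by_chrom.get(chrom, [])):
            continue
        seq = genome.fetch(iv)
        if seq.upper().count("N") > length // 2:
            continue
        cand.append((seq, len(cand), gc_fraction(seq), repeat_fraction(seq)))
        cand_iv.append(iv)
    cand_gc = np.array([c[2] for c in cand])
    cand_rep = np.array([c[3] for c in cand])
    used = np.zeros(len(cand), dtype=bool)
    negatives: list[str] = []
    neg_iv: list[GenomicInterval] = []
    for pi, pos in enumerate(positives):
        pgc, prep = gc_fraction(pos), repeat_fraction(pos)
        gtol, rtol = gc_tolerance, repeat_tolerance
        for _ in range(max_relaxations + 1):
            ok = (
                ~used
                & (np.abs(cand_gc - pgc) <= gtol)
                & (np.abs(cand_rep - prep) <= rtol)
            )
            idx = np.flatnonzero(ok)
            if len(idx) >= ratio:
                break
            gtol, rtol = gtol * 2, rtol * 2
        if len(idx) < ratio:
            raise ValueError(
                f"cannot match positive {pi} (GC {pgc:.3f}, repeat {prep:.3f}): "
                f"only {len(idx)} candidates within tolerance; enlarge the genome "
                "or loosen tolerances"
            )
        pick = rng.choice(idx, size=ratio, replace=False)
        used[pick] = True
        for j in pick:
            negatives.append(cand[j][0])
            neg_iv.append(cand_iv[j])
    return TrainingSet(list(positives), negatives, negative_intervals=neg_iv)


@dataclass
class GkmModel:
    """Trained gapped k-mer SVM with its derived l-mer weight table.

    ``weight_table[code]`` is the unnormalized decision contribution of the
    l-mer with base-4 code ``code`` (A=0..T=3, big-endian); with
    ``rc_collapse`` it already includes the reverse-complement term, so
    ``weight_table`` is rc-symmetric.  Bias is kept separately and excluded
    from per-l-mer weights (deltaSVM is bias-free).
    """

    params: GkmParams
    weight_table: np.ndarray  # (4**l,) float64
    bias: float
    support_sequences: list[str] = field(default_factory=list)
    dual_coefs: np.ndarray | None = None  # alpha_i * y_i per support sequence
    support_diag: np.ndarray | None = None  # unnormalized K(sv, sv)

    def kmer_weight(self, kmer: str) -> float:
        codes = encode_sequence(kmer)
        if len(codes) != self.params.l or (codes >= 4).any():
            raise ValueError(f"need an N-free {self.params.l}-mer, got {kmer!r}")
        fz = _Featurizer(self.params.l, self.params.k)
        return float(self.weight_table[int(codes.astype(np.int64) @ fz.lpow)])

    def score(self, seq: str) -> float:
        return score_sequence(seq, self)

    def position_scores(self, codes: np.ndarray) -> np.ndarray:
        """Per-start l-mer weights along an encoded sequence (N windows -> 0)."""
        l = self.params.l
        if len(codes) < l:
            raise ValueError(f"sequence shorter than l = {l}")
        win = np.lib.stride_tricks.sliding_window_view(codes, l)
        valid = (win < 4).all(axis=1)
        fz = _Featurizer(l, self.params.k)
        idx = win.astype(np.int64) @ fz.lpow
        out = np.zeros(len(win))
        out[valid] = self.weight_table[idx[valid]]
        return out


def _sv_feature_weights(
    win_list: list[np.ndarray],
    row_weights: np.ndarray,
    fz: _Featurizer,
    rc_collapse: bool,
) -> np.ndarray:
    """Dense feature-space vector v = sum_sv w_sv * phi(sv) (rc-augmented)."""
    W = np.concatenate(win_list, axis=0)
    wts = np.repeat(row_weights, [len(w) for w in win_list])
    if rc_collapse:
        W = _augment_rc(W)
        wts = np.concatenate([wts, wts])
    v = np.zeros(len(fz.patterns) * fz.n_kmers)
    for p, pat in enumerate(fz.patterns):
        codes = fz.pattern_codes(W, pat)
        v[p * fz.n_kmers : (p + 1) * fz.n_kmers] = np.bincount(
            codes, weights=wts, minlength=fz.n_kmers
        )
    return v


def _weight_table_from_v(v: np.ndarray, fz: _Featurizer, rc_collapse: bool) -> np.ndarray:
    """Evaluate w(u) = <phi_aug(u), v> for every l-mer u."""
    l = fz.l
    n = 4**l
    codes = np.arange(n, dtype=np.int64)
    digits = np.empty((n, l), dtype=np.uint8)
    for i in range(l):
        digits[:, i] = (codes // int(fz.lpow[i])) % 4
    t_fwd = np.zeros(n)
    for p, pat in enumerate(fz.patterns):
        idx = digits[:, pat].astype(np.int64) @ fz.pw
        t_fwd += v[p * fz.n_kmers + idx]
    if not rc_collapse:
        return t_fwd
    rc_codes = (3 - digits[:, ::-1]).astype(np.int64) @ fz.lpow
    return t_fwd + t_fwd[rc_codes]


def train(
    training_set: TrainingSet,
    params: GkmParams = GkmParams(),
    gram: np.ndarray | None = None,
) -> GkmModel:
    """Fit a soft-margin SVM on the normalized gkm kernel and extract the
    l-mer weight table (per-l-mer unnormalized decision contributions).

    ``gram`` may supply the precomputed *unnormalized* kernel matrix (as
    from ``gram_matrix(seqs, params, normalized=False)``) to avoid
    recomputation, e.g. when cross-validating the same training set.
    """
    pos, neg = training_set.positives, training_set.negatives
    if not pos or not neg:
        raise ValueError("need non-empty positive and negative sets")
    seqs = list(pos) + list(neg)
    y = np.r_[np.ones(len(pos)), -np.ones(len(neg))]
    G = gram_matrix(seqs, params, normalized=False) if gram is None else gram
    d = np.sqrt(np.diag(G))
    Gn = G / np.outer(d, d)
    svc = SVC(C=params.svm_c, kernel="precomputed")
    svc.fit(Gn, y)
    sup = svc.support_
    coefs = svc.dual_coef_[0]
    fz = _Featurizer(params.l, params.k)
    win_list = [_valid_windows(encode_sequence(seqs[i]), params.l) for i in sup]
    v = _sv_feature_weights(win_list, coefs / d[sup], fz, params.rc_collapse)
    table = _weight_table_from_v(v, fz, params.rc_collapse)
    return GkmModel(
        params=params,
        weight_table=table,
        bias=float(svc.intercept_[0]),
        support_sequences=[seqs[i] for i in sup],
        dual_coefs=coefs.copy(),
        support_diag=(d[sup] ** 2).copy(),
    )


def score_sequence(seq: str, model: GkmModel) -> float:
    """Sum of l-mer weights over all (len - l + 1) windows; N windows add 0."""
    codes = encode_sequence(seq)
    return float(model.position_scores(codes).sum())


def _roc_prc(y_true: np.ndarray, scores: np.ndarray) -> dict:
    from sklearn.metrics import (
        average_precision_score,
        precision_recall_curve,
        roc_auc_score,
        roc_curve,
    )

    fpr, tpr, _ = roc_curve(y_true, scores)
    prec, rec, _ = precision_recall_curve(y_true, scores)
    return {
        "auROC": float(roc_auc_score(y_true, scores)),
        "auPRC": float(average_precision_score(y_true, scores)),
        "roc_points": (fpr, tpr),
        "pr_points": (rec, prec),
    }


def cross_validate(
    training_set: TrainingSet,
    params: GkmParams = GkmParams(),
    folds: int = 5,
    seed: int = 0,
    gram: np.ndarray | None = None,
) -> dict:
    """Stratified k-fold CV; returns pooled auROC/auPRC and curve points.

    ``gram`` may supply the precomputed unnormalized kernel matrix.
    """
    from sklearn.model_selection import StratifiedKFold

    pos, neg = training_set.positives, training_set.negatives
    if folds > min(len(pos), len(neg)):
        raise ValueError(f"folds ({folds}) exceeds smallest class size")
    seqs = list(pos) + list(neg)
    y = np.r_[np.ones(len(pos)), -np.ones(len(neg))]
    G = gram_matrix(seqs, params, normalized=False) if gram is None else gram
    d = np.sqrt(np.diag(G))
    Gn = G / np.outer(d, d)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(seqs))
    fold_auc = []
    for tr, te in skf.split(np.zeros(len(seqs)), y):
        svc = SVC(C=params.svm_c, kernel="precomputed")
        svc.fit(Gn[np.ix_(tr, tr)], y[tr])
        s = svc.decision_function(Gn[np.ix_(te, tr)])
        scores[te] = s
        from sklearn.metrics import roc_auc_score

        fold_auc.append(float(roc_auc_score(y[te], s)))
    out = _roc_prc(y, scores)
    out["fold_auROC"] = fold_auc
    out["scores"] = scores
    out["labels"] = y
    return out


def _canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def write_model(model: GkmModel, prefix: str, min_abs_weight: float = 0.0) -> None:
    """Serialize as ``<prefix>.json`` (params, bias) + ``<prefix>.weights.tsv``
    (canonical kmer, weight) for kmers with ``|w| > min_abs_weight``."""
    params = model.params
    with open(f"{prefix}.json", "w") as fh:
        json.dump(
            {
                "l": params.l,
                "k": params.k,
                "rc_collapse": params.rc_collapse,
                "svm_c": params.svm_c,
                "bias": model.bias,
            },
            fh,
            indent=1,
        )
    l = params.l
    n = 4**l
    codes = np.arange(n, dtype=np.int64)
    digits = np.empty((n, l), dtype=np.uint8)
    lpow = 4 ** np.arange(l - 1, -1, -1, dtype=np.int64)
    for i in range(l):
        digits[:, i] = (codes // int(lpow[i])) % 4
    if params.rc_collapse:
        rc_codes = (3 - digits[:, ::-1]).astype(np.int64) @ lpow
        keep = codes <= rc_codes  # canonical = lexicographic min(u, rc(u))
    else:
        keep = np.ones(n, dtype=bool)
    keep &= np.abs(model.weight_table) > min_abs_weight
    with open(f"{prefix}.weights.tsv", "w") as fh:
        fh.write("kmer\tweight\n")
        for code in np.flatnonzero(keep):
            kmer = "".join(_BASES[digits[code]])
            fh.write(f"{kmer}\t{model.weight_table[code]:.10g}\n")


def read_model(prefix: str) -> GkmModel:
    with open(f"{prefix}.json") as fh:
        hdr = json.load(fh)
    params = GkmParams(
        l=hdr["l"], k=hdr["k"], rc_collapse=hdr["rc_collapse"], svm_c=hdr["svm_c"]
    )
    l = params.l
    lpow = 4 ** np.arange(l - 1, -1, -1, dtype=np.int64)
    table = np.zeros(4**l)
    with open(f"{prefix}.weights.tsv") as fh:
        header = fh.readline()
        for line in fh:
            kmer, w = line.rstrip("\n").split("\t")
            codes = encode_sequence(kmer).astype(np.int64)
            table[int(codes @ lpow)] = float(w)
            if params.rc_collapse:
                rc = encode_sequence(reverse_complement(kmer)).astype(np.int64)
                table[int(rc @ lpow)] = float(w)
    return GkmModel(params=params, weight_table=table, bias=hdr["bias"])
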