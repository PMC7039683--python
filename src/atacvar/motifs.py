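"""PWM scanning, motif enrichment/combinations, Tn5 footprint aggregation,
allele-specific site gain/loss calls, and the TF-to-target network.

Scanning uses natural-log odds against a background model with a
pseudocount; ``relative_score`` is the min-max-normalized log-odds, and
hits are called at a relative threshold (default 80%).  The site-loss rule
compares raw log-odds between alleles at the same start/strand: lost means
ref >= 5.0 and alt < 2.0 (or undetected); gained is the mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome import Genome, GenomicInterval, reverse_complement
from .gkm import encode_sequence

__all__ = [
    "Pwm",
    "MotifHit",
    "FootprintProfile",
    "read_jaspar",
    "write_jaspar",
    "scan_pwm",
    "motif_presence",
    "motif_combinations",
    "motif_enrichment",
    "footprint",
    "allele_effect",
    "build_network",
    "cluster_elements_by_motifs",
]


@dataclass
class Pwm:
    """Position weight matrix (probabilities, column order A,C,G,T)."""

    id: str
    matrix: np.ndarray  # (width, 4) probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.id}: PWM matrix must be (width, 4)")
        if self.width < 4:
            raise ValueError(f"{self.id}: PWM width must be >= 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-4):
            self.matrix = self.matrix / sums[:, None]

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        return np.log(p / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds
        return float(lo.min(axis=1).sum()), float(lo.max(axis=1).sum())

    @classmethod
    def from_counts(cls, id: str, counts: np.ndarray, **kw) -> "Pwm":
        counts = np.asarray(counts, dtype=np.float64)
        return cls(id, counts / counts.sum(axis=1, keepdims=True), **kw)


@dataclass
class MotifHit:
    interval: GenomicInterval  # position within the scanned sequence/genome
    pwm_id: str
    strand: str
    raw_logodds: float
    relative_score: float


@dataclass
class FootprintProfile:
    pwm_id: str
    offsets: np.ndarray  # -flank .. width + flank - 1 relative to motif start
    cut_counts: np.ndarray
    flank_mean: float
    protection: float  # mean(core) / mean(flank); < 1 means protected
    n_sites: int


def read_jaspar(path) -> list[Pwm]:
    """Read JASPAR-format PFM files via Bio.motifs."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=np.float64).T
            name = m.matrix_id or m.name
            out.append(Pwm.from_counts(name, counts))
    return out


def write_jaspar(pwms: Sequence[Pwm], path, scale: int = 100) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.id}\n")
            counts = np.rint(pwm.matrix * scale).astype(int)
            for bi, base in enumerate("ACGT"):
                row = " ".join(str(c) for c in counts[:, bi])
                fh.write(f"{base}  [ {row} ]\n")


def _scores_one_strand(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds at every start; windows containing N get -inf."""
    w = lo.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (win < 4).all(axis=1)
    scores = np.full(n, -np.inf)
    if valid.any():
        idx = win[valid].astype(np.int64)
        scores[valid] = lo[np.arange(w)[None, :], idx].sum(axis=1)
    return scores


def scan_pwm(
    seq: str,
    pwm: Pwm,
    min_relative: float = 0.8,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands; report all hits with relative score >= threshold."""
    if len(seq) < pwm.width:
        return []
    codes = encode_sequence(seq)
    lo = pwm.log_odds
    smin, smax = pwm.score_range()
    span = smax - smin if smax > smin else 1.0
    hits: list[MotifHit] = []
    fwd = _scores_one_strand(codes, lo)
    rc_codes = np.where(codes < 4, 3 - codes, 4)[::-1]
    rev = _scores_one_strand(rc_codes, lo)[::-1]  # index by plus-strand start
    for strand, scores in (("+", fwd), ("-", rev)):
        rel = (scores - smin) / span
        for pos in np.flatnonzero(rel >= min_relative):
            hits.append(
                MotifHit(
                    GenomicInterval(
                        chrom, offset + int(pos), offset + int(pos) + pwm.width,
                        strand=strand,
                    ),
                    pwm.id,
                    strand,
                    float(scores[pos]),
                    float(rel[pos]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def motif_presence(
    elements: Sequence[GenomicInterval],
    genome: Genome,
    pwms: Sequence[Pwm],
    min_relative: float = 0.8,
    min_fraction: float = 0.05,
) -> dict:
    """Binary element x motif presence matrix plus per-motif fractions.

    Motifs present in fewer than ``min_fraction`` of elements are flagged.
    """
    mat = np.zeros((len(elements), len(pwms)), dtype=np.int8)
    for i, iv in enumerate(elements):
        seq = genome.fetch(iv)
        for j, pwm in enumerate(pwms):
            if scan_pwm(seq, pwm, min_relative=min_relative):
                mat[i, j] = 1
    frac = mat.mean(axis=0) if len(elements) else np.zeros(len(pwms))
    return {
        "matrix": mat,
        "motif_ids": [p.id for p in pwms],
        "presence_fraction": frac,
        "flagged_below_min": [p.id for p, f in zip(pwms, frac) if f < min_fraction],
    }


def motif_combinations(presence: dict | np.ndarray, order: int = 2) -> list[tuple[tuple[str, ...], int]]:
    """Element counts for every motif subset of the given order, descending."""
    if isinstance(presence, dict):
        mat, ids = presence["matrix"], presence["motif_ids"]
    else:
        mat = np.asarray(presence)
        ids = [f"m{i}" for i in range(mat.shape[1])]
    if order > mat.shape[1]:
        raise ValueError(f"order {order} exceeds number of motifs {mat.shape[1]}")
    out = []
    for combo in combinations(range(mat.shape[1]), order):
        count = int(mat[:, combo].all(axis=1).sum())
        out.append((tuple(ids[i] for i in combo), count))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def motif_enrichment(
    fg_elements: Sequence[GenomicInterval],
    bg_elements: Sequence[GenomicInterval],
    genome: Genome,
    pwms: Sequence[Pwm],
    min_relative: float = 0.8,
) -> list[dict]:
    """Known-motif enrichment of foreground vs background element sets.

    fold = presence fraction fg / bg; p = hypergeometric tail on hit
    counts (population = fg + bg); q = BH across motifs.
    """
    if not fg_elements or not bg_elements:
        raise ValueError("need non-empty foreground and background")
    fg = motif_presence(fg_elements, genome, pwms, min_relative)["matrix"]
    bg = motif_presence(bg_elements, genome, pwms, min_relative)["matrix"]
    n_fg, n_bg = len(fg_elements), len(bg_elements)
    rows = []
    pvals = []
    for j, pwm in enumerate(pwms):
        k_fg = int(fg[:, j].sum())
        k_bg = int(bg[:, j].sum())
        frac_fg, frac_bg = k_fg / n_fg, k_bg / n_bg
        fold = np.inf if frac_bg == 0 and frac_fg > 0 else (
            frac_fg / frac_bg if frac_bg > 0 else np.nan
        )
        p = float(hypergeom.sf(k_fg - 1, n_fg + n_bg, k_fg + k_bg, n_fg))
        pvals.append(p)
        rows.append(
            {"motif": pwm.id, "fg_fraction": frac_fg, "bg_fraction": frac_bg,
             "fold": fold, "pvalue": p}
        )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for row, q in zip(rows, qvals):
        row["qvalue"] = float(q)
    rows.sort(key=lambda r: r["pvalue"])
    return rows


def footprint(
    cut_sites: Mapping[str, np.ndarray],
    hits: Sequence[MotifHit],
    flank: int = 100,
) -> FootprintProfile:
    """Aggregate Tn5 cut counts around motif hits, oriented to motif strand.

    Profile covers motif start - flank .. motif end + flank; protection =
    mean core (motif) cut rate over mean flank cut rate.
    """
    if not hits:
        raise ValueError("no motif hits to aggregate")
    width = hits[0].interval.length
    span = width + 2 * flank + 1  # offsets -flank .. width + flank inclusive
    agg = np.zeros(span)
    n_used = 0
    for h in hits:
        iv = h.interval
        d = cut_sites.get(iv.chrom)
        if d is None:
            continue
        lo, hi = iv.start - flank, iv.end + flank + 1
        if lo < 0 or hi > len(d):
            continue
        window = np.asarray(d[lo:hi], dtype=np.float64)
        if h.strand == "-":
            window = window[::-1]
        agg += window
        n_used += 1
    if n_used == 0:
        raise ValueError("no motif hits with usable flanking windows")
    core = agg[flank : flank + width]
    flanks = np.concatenate([agg[:flank], agg[flank + width :]])
    flank_mean = float(flanks.mean())
    protection = float(core.mean() / flank_mean) if flank_mean > 0 else np.nan
    return FootprintProfile(
        pwm_id=hits[0].pwm_id,
        offsets=np.arange(-flank, width + flank + 1),
        cut_counts=agg,
        flank_mean=flank_mean,
        protection=protection,
        n_sites=n_used,
    )


def allele_effect(
    snp,
    genome: Genome,
    pwms: Sequence[Pwm],
    window: int = 19,
    lost_high: float = 5.0,
    lost_low: float = 2.0,
    min_relative: float = 0.8,
) -> dict:
    """Motif sites lost/gained between alleles over a window centered on a SNP.

    Per (pwm, start, strand): lost iff the ref-allele log-odds >= ``lost_high``
    and the alt-allele score is < ``lost_low`` or undetected (below the
    relative threshold); gained is the mirror image.
    """
    half = window // 2
    pos0 = snp.pos - 1  # 1-based to 0-based
    chrom_len = genome.lengths[snp.chrom]
    if pos0 - half < 0 or pos0 + half + 1 > chrom_len:
        raise ValueError(f"SNP {snp.id} too close to chromosome edge for window {window}")
    ref_win = genome.fetch(snp.chrom, pos0 - half, pos0 + half + 1)
    if ref_win[half].upper() != snp.ref.upper():
        raise ValueError(
            f"reference mismatch at {snp.chrom}:{snp.pos}: genome has "
            f"{ref_win[half]!r}, SNP table says {snp.ref!r}"
        )
    alt_win = ref_win[:half] + snp.alt + ref_win[half + 1 :]
    lost, gained, table = [], [], []
    for pwm in pwms:
        smin, smax = pwm.score_range()
        span = smax - smin if smax > smin else 1.0
        for strand in "+-":
            ref_scores = _allele_scores(ref_win, pwm, strand)
            alt_scores = _allele_scores(alt_win, pwm, strand)
            for start in range(len(ref_scores)):
                r, a = ref_scores[start], alt_scores[start]
                r_det = (r - smin) / span >= min_relative
                a_det = (a - smin) / span >= min_relative
                if not (r_det or a_det):
                    continue
                table.append(
                    {"motif": pwm.id, "start": start, "strand": strand,
                     "ref_score": float(r), "alt_score": float(a),
                     "ref_detected": r_det, "alt_detected": a_det}
                )
                if r_det and r >= lost_high and (not a_det or a < lost_low):
                    lost.append((pwm.id, start, strand))
                if a_det and a >= lost_high and (not r_det or r < lost_low):
                    gained.append((pwm.id, start, strand))
    return {"lost": lost, "gained": gained, "table": table}


def _allele_scores(seq: str, pwm: Pwm, strand: str) -> np.ndarray:
    codes = encode_sequence(seq)
    if strand == "-":
        rc = np.where(codes < 4, 3 - codes, 4)[::-1]
        return _scores_one_strand(rc, pwm.log_odds)[::-1]
    return _scores_one_strand(codes, pwm.log_odds)


def build_network(
    tf_table: Sequence[tuple[str, str]],  # (tf_gene, motif_id)
    presence: dict,
    element_genes: Sequence[Sequence[str]],
):
    """Directed TF network: edge A -> B iff an element assigned to gene B
    contains the motif bound by A; weight = number of such elements."""
    import networkx as nx

    mat, ids = presence["matrix"], presence["motif_ids"]
    motif_col = {m: j for j, m in enumerate(ids)}
    g = nx.DiGraph()
    tf_genes = {tf for tf, _ in tf_table}
    for tf, motif in tf_table:
        g.add_node(tf)
        if motif not in motif_col:
            import warnings

            warnings.warn(f"TF {tf}: motif {motif!r} not in annotation; isolated node")
    for tf, motif in tf_table:
        j = motif_col.get(motif)
        if j is None:
            continue
        for i in range(mat.shape[0]):
            if not mat[i, j]:
                continue
            for gene in element_genes[i]:
                if gene in tf_genes and gene != tf:
                    w = g.get_edge_data(tf, gene, {}).get("weight", 0)
                    g.add_edge(tf, gene, weight=w + 1)
    return g


def cluster_elements_by_motifs(presence: dict):
    """Complete-linkage hierarchical clustering on Jaccard distance of the
    element x motif presence matrix; returns the scipy linkage matrix."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist

    mat = presence["matrix"].astype(bool)
    d = pdist(mat, metric="jaccard")
    return linkage(d, method="complete")
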