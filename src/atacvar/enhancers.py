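"""Active-enhancer annotation: H3K27Ac integration, TSS removal, 400 bp
resizing to the ATAC-signal optimum, repeat filtering and gene assignment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import Genome, GenomicInterval, repeat_fraction, sort_intervals

__all__ = [
    "ActiveEnhancer",
    "flanked_regions",
    "classify_k27",
    "remove_tss_overlaps",
    "resize_to_400",
    "repeat_filter",
    "assign_genes",
    "build_active_enhancers",
    "write_enhancer_table",
]


@dataclass
class ActiveEnhancer:
    interval: GenomicInterval  # exactly the resized length (default 400 bp)
    source_nfr: GenomicInterval
    k27_cluster: int  # 1 = K27-supported, 2 = not
    atac_signal: float
    assigned_genes: list[str] = field(default_factory=list)


def flanked_regions(
    k27_peaks: Sequence[GenomicInterval], max_gap: int = 1500, min_gap: int = 0
) -> list[GenomicInterval]:
    """Inter-peak gaps of length in ``[min_gap, max_gap]`` (per chromosome)."""
    out: list[GenomicInterval] = []
    peaks = sort_intervals(k27_peaks)
    for prev, nxt in zip(peaks, peaks[1:]):
        if prev.chrom != nxt.chrom:
            continue
        gap_start, gap_end = prev.end, nxt.start
        gap = gap_end - gap_start
        if min_gap <= gap <= max_gap and gap > 0:
            out.append(GenomicInterval(prev.chrom, gap_start, gap_end))
    return out


def _overlaps_any(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in others)


def classify_k27(
    nfrs: Sequence[GenomicInterval],
    k27_tracks: Sequence[Sequence[GenomicInterval]],
    max_gap: int = 1500,
    min_gap: int = 0,
    require_all_tracks: bool = False,
) -> list[int]:
    """Cluster 1 iff an NFR overlaps (>= 1 bp) an H3K27Ac peak or a
    flanked inter-peak region in >= 1 track (or every track when
    ``require_all_tracks``); else cluster 2."""
    support_sets = []
    for peaks in k27_tracks:
        support = list(peaks) + flanked_regions(peaks, max_gap=max_gap, min_gap=min_gap)
        support_sets.append(support)
    labels = []
    for nfr in nfrs:
        hits = [_overlaps_any(nfr, sup) for sup in support_sets]
        supported = all(hits) if require_all_tracks else any(hits)
        labels.append(1 if (support_sets and supported) else 2)
    return labels


def remove_tss_overlaps(
    elements: Sequence[GenomicInterval],
    tss_intervals: Sequence[GenomicInterval],
    pad: int = 500,
) -> list[GenomicInterval]:
    """Drop elements overlapping any TSS interval padded by ``pad`` bp."""
    padded = [
        GenomicInterval(t.chrom, max(0, t.start - pad), t.end + pad)
        for t in tss_intervals
    ]
    return [e for e in elements if not _overlaps_any(e, padded)]


def resize_to_400(
    nfr: GenomicInterval,
    cut_density: Mapping[str, np.ndarray],
    length: int = 400,
    chrom_length: int | None = None,
) -> tuple[GenomicInterval, float]:
    """The ``length``-bp window (center inside the NFR) maximizing summed
    cut density.  Equal-signal windows prefer the one centered closest to
    the NFR midpoint, then the leftmost (so a uniform-density NFR that is
    already ``length`` bp is returned unchanged).  Returns (window, signal)."""
    d = np.asarray(cut_density[nfr.chrom], dtype=np.float64)
    n = chrom_length if chrom_length is not None else len(d)
    half = length // 2
    cs = np.concatenate([[0.0], np.cumsum(d)])
    centers = np.arange(nfr.start, nfr.end)
    starts = centers - half
    lo = np.clip(starts, 0, max(0, n - length))
    if (lo != starts).any():
        warnings.warn(
            f"{nfr}: resize window clipped to chromosome bounds", stacklevel=2
        )
    lo = np.unique(lo)
    sums = cs[np.minimum(lo + length, len(d))] - cs[np.minimum(lo, len(d))]
    top = sums == sums.max()
    dist = np.abs(lo + half - nfr.midpoint)
    candidates = lo[top]
    best = int(candidates[np.argmin(dist[top])])  # argmin -> leftmost on ties
    return GenomicInterval(nfr.chrom, best, best + length), float(sums.max())


def repeat_filter(
    elements: Sequence[GenomicInterval], genome: Genome, max_repeat: float = 0.70
) -> list[GenomicInterval]:
    """Remove elements with soft-masked fraction strictly above ``max_repeat``."""
    kept = []
    for iv in elements:
        if repeat_fraction(genome.fetch(iv)) <= max_repeat:
            kept.append(iv)
    return kept


def assign_genes(
    element: GenomicInterval,
    gene_tss: Sequence[tuple[str, str, int]],  # (gene_id, chrom, tss_position)
    max_dist: int = 100_000,
    max_genes: int = 2,
) -> list[str]:
    """Up to ``max_genes`` genes whose TSS is within ``max_dist`` of the
    element midpoint, nearest first; ties by gene id."""
    mid = element.midpoint
    scored = [
        (abs(pos - mid), gid)
        for gid, chrom, pos in gene_tss
        if chrom == element.chrom and abs(pos - mid) <= max_dist
    ]
    scored.sort()
    return [gid for _, gid in scored[:max_genes]]


def build_active_enhancers(
    nfrs: Sequence[GenomicInterval],
    cut_density: Mapping[str, np.ndarray],
    k27_tracks: Sequence[Sequence[GenomicInterval]],
    tss_intervals: Sequence[GenomicInterval],
    genome: Genome,
    gene_tss: Sequence[tuple[str, str, int]] = (),
    length: int = 400,
    k27_max_gap: int = 1500,
    tss_pad: int = 500,
    max_repeat: float = 0.70,
) -> list[ActiveEnhancer]:
    """Full annotation funnel: K27 classification, TSS removal, resizing
    and repeat filtering, keeping only K27-supported (cluster 1) elements."""
    labels = classify_k27(nfrs, k27_tracks, max_gap=k27_max_gap)
    cluster1 = [nfr for nfr, lab in zip(nfrs, labels) if lab == 1]
    kept = remove_tss_overlaps(cluster1, tss_intervals, pad=tss_pad)
    out: list[ActiveEnhancer] = []
    for nfr in kept:
        iv, signal = resize_to_400(
            nfr, cut_density, length=length, chrom_length=genome.lengths[nfr.chrom]
        )
        if repeat_fraction(genome.fetch(iv)) > max_repeat:
            continue
        genes = assign_genes(iv, gene_tss) if gene_tss else []
        out.append(ActiveEnhancer(iv, nfr, 1, signal, genes))
    return out


def write_enhancer_table(enhancers: Sequence[ActiveEnhancer], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tsource_start\tsource_end\tk27_cluster\t"
            "atac_signal\tgenes\n"
        )
        for e in enhancers:
            iv, src = e.interval, e.source_nfr
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{src.start}\t{src.end}\t"
                f"{e.k27_cluster}\t{e.atac_signal:.6g}\t{','.join(e.assigned_genes)}\n"
            )
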