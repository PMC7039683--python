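"""Nucleosome-free-region derivation and differential accessibility.

Fragments shorter than 100 bp define the nucleosome-free signal; Tn5 cut
sites are the strand-shifted fragment ends (+4 on plus, -5 on minus).  A
simplified local-background peak caller substitutes for an external one,
and per-region differential calls use a two-sided exact binomial test on
pooled group counts with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .genome import FragmentRecord, GenomicInterval, merge_intervals, sort_intervals

__all__ = [
    "CountMatrix",
    "DifferentialRegion",
    "select_nfr_fragments",
    "shift_cut_sites",
    "fragment_cut_sites",
    "cut_density",
    "call_peaks",
    "build_count_matrix",
    "differential_nfr",
    "write_differential_table",
]


@dataclass
class CountMatrix:
    regions: list[GenomicInterval]
    samples: list[str]
    counts: np.ndarray  # (n_regions, n_samples) int
    library_sizes: np.ndarray  # per-sample genome-wide fragment totals


@dataclass
class DifferentialRegion:
    interval: GenomicInterval
    log2fc: float
    pvalue: float
    qvalue: float
    call: str  # popA-enriched / popB-enriched / shared


def select_nfr_fragments(
    fragments: Iterable[FragmentRecord], max_len: int = 100
) -> list[FragmentRecord]:
    """Keep fragments strictly shorter than ``max_len`` bp."""
    return [f for f in fragments if f.length < max_len]


def shift_cut_sites(interval: GenomicInterval) -> int:
    """Tn5-corrected cut position of one stranded read/fragment end.

    Plus strand: 5' position + 4.  Minus strand: 5' position (interval
    end) - 5.
    """
    if interval.strand == "+":
        return interval.start + 4
    if interval.strand == "-":
        return interval.end - 5
    raise ValueError(f"cut-site shift requires a stranded record, got {interval}")


def fragment_cut_sites(fragment: FragmentRecord) -> tuple[int, int]:
    """Both Tn5 cut sites of a paired fragment (plus end +4, minus end -5)."""
    iv = fragment.interval
    return iv.start + 4, iv.end - 5


def cut_density(
    fragments: Iterable[FragmentRecord], chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-chromosome Tn5 cut-site counts from fragment ends."""
    cuts: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for f in fragments:
        c = f.interval.chrom
        if c not in cuts:
            continue
        a, b = fragment_cut_sites(f)
        for p in (a, b):
            if 0 <= p < chrom_lengths[c]:
                cuts[c].append(p)
    return {
        c: np.bincount(np.asarray(pos, dtype=np.int64), minlength=chrom_lengths[c])
        if pos
        else np.zeros(chrom_lengths[c], dtype=np.int64)
        for c, pos in cuts.items()
    }


def call_peaks(
    density: Mapping[str, np.ndarray],
    smoothing_window: int = 150,
    min_fold: float = 4.0,
    local_background_span: int = 10000,
    min_width: int = 50,
) -> list[GenomicInterval]:
    """Maximal runs where smoothed cut density >= fold x local background.

    Background is the max of the local mean over ``local_background_span``
    and the chromosome-wide mean (so sparse chromosomes are not all peak).
    Runs separated by less than ``smoothing_window`` are merged; runs
    shorter than ``min_width`` are dropped.  Deterministic.
    """
    peaks: list[GenomicInterval] = []
    for chrom in density:
        d = np.asarray(density[chrom], dtype=np.float64)
        if d.sum() == 0:
            continue
        sm = uniform_filter1d(d, size=smoothing_window, mode="nearest")
        local = uniform_filter1d(d, size=local_background_span, mode="nearest")
        bg = np.maximum(local, d.mean())
        mask = sm >= min_fold * bg
        if not mask.any():
            continue
        edges = np.diff(mask.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if mask[0]:
            starts.insert(0, 0)
        if mask[-1]:
            ends.append(len(mask))
        runs = [
            GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
        ]
        merged = merge_intervals(runs, gap=smoothing_window)
        peaks.extend(iv for iv in merged if iv.length >= min_width)
    return sort_intervals(peaks)


def build_count_matrix(
    regions: Sequence[GenomicInterval],
    fragments_by_sample: Mapping[str, Sequence[FragmentRecord]],
) -> CountMatrix:
    """Count fragments per region by midpoint membership (half-open)."""
    regions = sort_intervals(regions)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        lst = by_chrom.setdefault(iv.chrom, [])
        if lst and iv.start < lst[-1].end:
            raise ValueError(
                f"overlapping regions {lst[-1]} and {iv}: merge peaks first"
            )
        lst.append(iv)
    region_index = {id(iv): i for i, iv in enumerate(regions)}
    starts = {c: np.array([iv.start for iv in lst]) for c, lst in by_chrom.items()}
    ends = {c: np.array([iv.end for iv in lst]) for c, lst in by_chrom.items()}
    idx_of = {c: np.array([region_index[id(iv)] for iv in lst]) for c, lst in by_chrom.items()}
    samples = list(fragments_by_sample)
    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
    lib = np.zeros(len(samples), dtype=np.int64)
    for j, sample in enumerate(samples):
        frags = fragments_by_sample[sample]
        lib[j] = len(frags)
        mids: dict[str, list[int]] = {}
        for f in frags:
            mids.setdefault(f.interval.chrom, []).append(f.interval.midpoint)
        for chrom, positions in mids.items():
            if chrom not in by_chrom:
                continue
            pos = np.asarray(positions)
            ri = np.searchsorted(starts[chrom], pos, side="right") - 1
            ok = (ri >= 0) & (pos < ends[chrom][np.clip(ri, 0, None)])
            hit = idx_of[chrom][ri[ok]]
            counts[:, j] += np.bincount(hit, minlength=len(regions))
    return CountMatrix(list(regions), samples, counts, lib)


def differential_nfr(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.01,
    pseudocount: float = 1.0,
) -> list[DifferentialRegion]:
    """Two-group differential accessibility.

    log2FC is computed on library-size-normalized group means with a
    pseudocount; the per-region p-value is a two-sided exact binomial test
    of the pooled group-A count against the library-size expectation, with
    BH adjustment across all regions.
    """
    ia = [matrix.samples.index(s) for s in group_a]
    ib = [matrix.samples.index(s) for s in group_b]
    if not ia or not ib:
        raise ValueError("need at least one sample per group")
    lib = matrix.library_sizes.astype(float)
    if (lib[ia + ib] == 0).any():
        raise ValueError("zero library size in a selected sample")
    scale = lib.mean()
    norm = matrix.counts / lib[None, :] * scale
    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    pooled_a = matrix.counts[:, ia].sum(axis=1)
    pooled_b = matrix.counts[:, ib].sum(axis=1)
    lib_a, lib_b = lib[ia].sum(), lib[ib].sum()
    p0 = lib_a / (lib_a + lib_b)
    pvals = np.ones(len(matrix.regions))
    for i, (a, b) in enumerate(zip(pooled_a, pooled_b)):
        n = int(a + b)
        if n > 0:
            pvals[i] = binomtest(int(a), n, p0).pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = []
    for iv, lfc, p, q in zip(matrix.regions, log2fc, pvals, qvals):
        if q < fdr_threshold and lfc > lfc_threshold:
            call = "popA-enriched"
        elif q < fdr_threshold and lfc < -lfc_threshold:
            call = "popB-enriched"
        else:
            call = "shared"
        out.append(DifferentialRegion(iv, float(lfc), float(p), float(q), call))
    return out


def write_differential_table(regions: Sequence[DifferentialRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlog2fc\tpvalue\tqvalue\tcall\n")
        for r in regions:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.log2fc:.6g}\t"
                f"{r.pvalue:.6g}\t{r.qvalue:.6g}\t{r.call}\n"
            )
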