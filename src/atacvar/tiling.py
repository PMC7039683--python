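"""Genome tiling, model scoring of tiles, percentile binning and
annotation enrichment of the top bins."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binomtest

from .genome import Genome, GenomicInterval, sort_intervals
from .gkm import GkmModel, encode_sequence

__all__ = [
    "TileScore",
    "tile_genome",
    "score_tiles",
    "percentile_bins",
    "annotation_enrichment",
    "write_tile_scores",
]

DEFAULT_BIN_EDGES = (0.001, 0.002, 0.005, 0.010, 0.015, 0.020)


@dataclass
class TileScore:
    interval: GenomicInterval
    score: float
    percentile_bin: str = ""


def tile_genome(genome: Genome, length: int = 400, step: int = 100) -> list[GenomicInterval]:
    """Tiles starting at multiples of ``step``; partial end tiles dropped."""
    if step < 1:
        raise ValueError("step must be >= 1")
    tiles = []
    for chrom in genome.chroms:
        n = genome.lengths[chrom]
        for start in range(0, n - length + 1, step):
            tiles.append(GenomicInterval(chrom, start, start + length))
    return tiles


def score_tiles(
    tiles: Sequence[GenomicInterval], genome: Genome, model: GkmModel
) -> list[TileScore]:
    """Model score of every tile (sum of l-mer weights; N windows add 0).

    Per-position l-mer weights are computed once per chromosome and summed
    per tile by prefix sums, which is exactly ``score_sequence`` per tile.
    """
    l = model.params.l
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {t.chrom for t in tiles}:
        codes = encode_sequence(genome.fetch(chrom))
        if len(codes) < l:
            by_chrom[chrom] = np.zeros(1)
            continue
        pos_scores = model.position_scores(codes)
        by_chrom[chrom] = np.concatenate([[0.0], np.cumsum(pos_scores)])
    out = []
    for t in tiles:
        cs = by_chrom[t.chrom]
        lo = min(t.start, len(cs) - 1)
        hi = min(t.end - l + 1, len(cs) - 1)
        out.append(TileScore(t, float(cs[hi] - cs[lo])))
    return out


def percentile_bins(
    tile_scores: Sequence[TileScore],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> list[TileScore]:
    """Assign each tile a descending-score percentile-bin label.

    Cumulative bin sizes are ``round(n * edge)``; ties (and everything
    else) are ordered by coordinate so the binning is deterministic.  The
    remainder gets a "rest" label.  Returns tiles in ranked order.
    """
    if not tile_scores:
        raise ValueError("no tiles to bin")
    n = len(tile_scores)
    order = sorted(
        range(n),
        key=lambda i: (
            -tile_scores[i].score,
            tile_scores[i].interval.chrom,
            tile_scores[i].interval.start,
        ),
    )
    edges = sorted(bin_edges)
    cum_sizes = [int(round(n * e)) for e in edges]
    labels = []
    prev = 0.0
    for e in edges:
        labels.append(f"top {e * 100:g}%" if prev == 0 else f"{prev * 100:g}-{e * 100:g}%")
        prev = e
    ranked = []
    bin_i = 0
    for rank, i in enumerate(order):
        while bin_i < len(cum_sizes) and rank >= cum_sizes[bin_i]:
            bin_i += 1
        label = labels[bin_i] if bin_i < len(labels) else f">{edges[-1] * 100:g}%"
        ts = tile_scores[i]
        ranked.append(TileScore(ts.interval, ts.score, label))
    return ranked


def _overlap_flags(
    tiles: Sequence[TileScore], annotation: Sequence[GenomicInterval]
) -> np.ndarray:
    """>= 1 bp overlap flag per tile, via sorted sweep."""
    ann = sort_intervals(annotation)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for iv in ann:
        starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[union-attr]
        ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[union-attr]
    maxend: dict[str, np.ndarray] = {}
    for c in starts:
        starts[c] = np.array(starts[c])
        ends[c] = np.array(ends[c])
        maxend[c] = np.maximum.accumulate(ends[c])
    flags = np.zeros(len(tiles), dtype=bool)
    for i, t in enumerate(tiles):
        c = t.interval.chrom
        if c not in starts:
            continue
        j = np.searchsorted(starts[c], t.interval.end, side="left")
        flags[i] = j > 0 and maxend[c][j - 1] > t.interval.start
    return flags


def annotation_enrichment(
    binned_tiles: Sequence[TileScore],
    annotations: Mapping[str, Sequence[GenomicInterval]],
    top_bin: str | None = None,
) -> list[dict]:
    """Fold enrichment of top-bin tiles within each annotation set.

    fold = (fraction of top-bin tiles overlapping) / (fraction of all
    tiles overlapping), with a one-sided binomial p; NA when no tile
    anywhere overlaps the annotation.
    """
    if top_bin is None:
        top_bin = binned_tiles[0].percentile_bin
    top = [t for t in binned_tiles if t.percentile_bin == top_bin]
    out = []
    for name, ann in annotations.items():
        all_flags = _overlap_flags(binned_tiles, ann)
        top_flags = _overlap_flags(top, ann)
        frac_all = float(all_flags.mean())
        frac_top = float(top_flags.mean()) if len(top) else 0.0
        if frac_all == 0:
            out.append(
                {"annotation": name, "fold": np.nan, "pvalue": np.nan,
                 "top_fraction": frac_top, "genome_fraction": frac_all}
            )
            continue
        fold = frac_top / frac_all
        p = binomtest(
            int(top_flags.sum()), len(top), frac_all, alternative="greater"
        ).pvalue if len(top) else np.nan
        out.append(
            {"annotation": name, "fold": fold, "pvalue": float(p),
             "top_fraction": frac_top, "genome_fraction": frac_all}
        )
    return out


def write_tile_scores(tiles: Sequence[TileScore], path) -> None:
    """BED6-style output with score; bin label (if set) in column 7."""
    with open(path, "w") as fh:
        for t in tiles:
            iv = t.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), ".", f"{t.score:.6g}", "."]
            if t.percentile_bin:
                cols.append(t.percentile_bin)
            fh.write("\t".join(cols) + "\n")
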