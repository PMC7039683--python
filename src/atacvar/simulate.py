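"""Deterministic synthetic study universe.

Generates a miniature genome with planted enhancers for two cell
populations (plus shared regions), bimodal ATAC fragment sets (sub-100 bp
nucleosome-free + ~nucleosomal), H3K27Ac peaks overlapping or flanking a
subset of enhancers, TSS annotations, and a SNP catalog containing one
planted motif-disrupting variant.  Everything derives from one seed via
named `SeedSequence` children (draw order: genome, repeats, placement,
motifs, fragments, k27, tss, snps, homologs), so outputs are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import (
    FragmentRecord,
    Genome,
    GenomicInterval,
    write_bed,
    write_fasta,
    write_fragments,
)
from .motifs import Pwm, write_jaspar
from .variants import SnpRecord, write_snp_table

__all__ = [
    "SyntheticDatasetSpec",
    "SyntheticDataset",
    "EnhancerTruth",
    "default_motif_set",
    "plant_motif",
    "make_dataset",
]

_BASES = np.array(list("ACGT"))


def _sharp_pwm(name: str, consensus: str, major: float = 0.93) -> Pwm:
    minor = (1.0 - major) / 3.0
    mat = np.full((len(consensus), 4), minor)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = major
    return Pwm(name, mat)


def default_motif_set() -> list[tuple[Pwm, int]]:
    """Three invented sharp motifs, one planted instance each per enhancer."""
    return [
        (_sharp_pwm("MOTIF_A", "ACCGGAAGTG"), 1),
        (_sharp_pwm("MOTIF_B", "CATGCCAATC"), 1),
        (_sharp_pwm("MOTIF_C", "TTCGCACGAA"), 1),
    ]


@dataclass
class SyntheticDatasetSpec:
    seed: int = 1
    n_chroms: int = 4
    chrom_length: int = 400_000
    background_gc: float = 0.41
    motif_set: list[tuple[Pwm, int]] = field(default_factory=default_motif_set)
    n_enhancers_popA: int = 50
    n_enhancers_popB: int = 50
    n_shared: int = 50
    enhancer_length: int = 400
    fragment_depth: int = 40  # NFR fragments per open region per sample
    specific_fold: float = 4.0  # depth ratio, own vs other population
    nfr_length_dist: tuple[int, int] = (30, 90)
    nucleosomal_length_mean: int = 200
    n_replicates: int = 2
    k27_active_fraction: float = 0.7
    k27_flank_gap: int = 1500
    k27_peak_width: int = 300
    n_genes: int = 30
    n_background_snps: int = 3000
    n_tested_snps: int = 14
    snp_radius: int = 100_000
    planted_snp: int | None = 0  # index into the popA enhancer list
    repeat_density: float = 1e-4  # masked stretches per bp
    noise_fragments_per_kb: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "n_chroms", "chrom_length", "n_enhancers_popA", "n_enhancers_popB",
            "n_shared", "enhancer_length", "fragment_depth", "n_replicates",
            "n_background_snps", "n_tested_snps",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("background_gc", "k27_active_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class EnhancerTruth:
    enhancer_id: str
    interval: GenomicInterval
    population: str  # popA / popB / shared
    k27: bool
    k27_mode: str  # overlap / flank / none
    motif_sites: list[tuple[str, int, str]]  # (pwm_id, genome start, strand)


@dataclass
class SyntheticDataset:
    spec: SyntheticDatasetSpec
    genome: Genome
    fragments: dict[str, list[FragmentRecord]]  # sample label -> fragments
    k27_peaks: list[GenomicInterval]
    tss: list[GenomicInterval]
    gene_tss: list[tuple[str, str, int]]
    enhancers: list[EnhancerTruth]
    snps_tested: list[SnpRecord]
    snp_catalog: list[SnpRecord]
    snp_truth: dict
    homologs: dict[str, str]

    def enhancer_sequences(self, population: str | None = None) -> list[str]:
        return [
            self.genome.fetch(e.interval)
            for e in self.enhancers
            if population is None or e.population == population
        ]

    def samples(self, population: str) -> list[str]:
        return sorted(s for s in self.fragments if s.startswith(population))


def plant_motif(seq: str, pwm: Pwm, position: int, rng: np.random.Generator) -> str:
    """Replace ``seq[position:position+width]`` with a PWM-sampled instance."""
    w = pwm.width
    if position < 0 or position + w > len(seq):
        raise ValueError(
            f"motif of width {w} at {position} exceeds sequence of length {len(seq)}"
        )
    draw = [
        _BASES[rng.choice(4, p=pwm.matrix[i])] for i in range(w)
    ]
    return seq[:position] + "".join(draw) + seq[position + w :]


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mask_repeats(rng: np.random.Generator, seq: str, density: float) -> str:
    """Lowercase random tandem stretches (simulated repeat annotation)."""
    n = len(seq)
    chars = list(seq)
    for _ in range(rng.poisson(density * n)):
        start = int(rng.integers(0, max(1, n - 800)))
        length = int(rng.integers(200, 800))
        unit = "".join(_BASES[rng.integers(0, 4, size=int(rng.integers(2, 7)))])
        stretch = (unit * (length // len(unit) + 1))[:length].lower()
        chars[start : start + length] = list(stretch[: min(length, n - start)])
    return "".join(chars)


def _place_enhancers(
    rng: np.random.Generator, spec: SyntheticDatasetSpec, chroms: list[str]
) -> list[GenomicInterval]:
    """Non-overlapping slots with enough clearance for flanking K27 peaks."""
    margin = 3000
    spacing = spec.enhancer_length + 2 * (spec.k27_flank_gap + spec.k27_peak_width) + 1000
    slots: list[tuple[str, int]] = []
    for chrom in chroms:
        pos = margin
        while pos + spec.enhancer_length + margin <= spec.chrom_length:
            slots.append((chrom, pos))
            pos += spacing
    total = spec.n_enhancers_popA + spec.n_enhancers_popB + spec.n_shared
    if total > len(slots):
        raise ValueError(
            f"cannot place {total} non-overlapping enhancers in "
            f"{spec.n_chroms} x {spec.chrom_length} bp; increase chrom_length "
            f"or n_chroms (capacity {len(slots)})"
        )
    pick = rng.choice(len(slots), size=total, replace=False)
    jitter = rng.integers(0, 400, size=total)
    out = []
    for i, si in enumerate(sorted(pick)):
        chrom, start = slots[si]
        s = start + int(jitter[i])
        out.append(GenomicInterval(chrom, s, s + spec.enhancer_length))
    return out


def _sample_fragment(
    rng: np.random.Generator,
    enh: GenomicInterval,
    lo: int,
    hi: int,
    motif_zones: list[tuple[int, int]],
    chrom_length: int,
) -> GenomicInterval:
    """A sub-nucleosomal fragment inside the open region, with Tn5 cut
    points (start+4 / end-5) preferentially avoiding motif footprints."""
    for _ in range(20):
        length = int(rng.integers(lo, hi + 1))
        center = int(
            np.clip(
                rng.normal(enh.midpoint, enh.length / 5),
                enh.start + length // 2,
                enh.end - length // 2 - 1,
            )
        )
        start = center - length // 2
        end = start + length
        if start < 0 or end > chrom_length:
            continue
        cuts = (start + 4, end - 5)
        protected = any(lo_ <= c < hi_ for c in cuts for lo_, hi_ in motif_zones)
        if protected and rng.random() < 0.85:
            continue
        return GenomicInterval(enh.chrom, start, end)
    return GenomicInterval(enh.chrom, start, end)  # give up on protection


def make_dataset(
    spec: SyntheticDatasetSpec, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Generate (and optionally write) the full synthetic universe."""
    ss = np.random.SeedSequence(spec.seed)
    (rng_genome, rng_repeat, rng_place, rng_motif, rng_frag,
     rng_k27, rng_tss, rng_snp, rng_hom) = [
        np.random.default_rng(c) for c in ss.spawn(9)
    ]
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    sequences = {
        c: _random_sequence(rng_genome, spec.chrom_length, spec.background_gc)
        for c in chroms
    }
    sequences = {
        c: _mask_repeats(rng_repeat, s, spec.repeat_density)
        for c, s in sequences.items()
    }

    intervals = _place_enhancers(rng_place, spec, chroms)
    populations = (
        ["popA"] * spec.n_enhancers_popA
        + ["popB"] * spec.n_enhancers_popB
        + ["shared"] * spec.n_shared
    )
    order = rng_place.permutation(len(intervals))
    populations = [populations[i] for i in order]

    # plant motifs (uppercase, so planted enhancers are never repeat-heavy)
    enhancers: list[EnhancerTruth] = []
    for idx, (iv, pop) in enumerate(zip(intervals, populations)):
        seq = sequences[iv.chrom][iv.start : iv.end].upper()
        sites: list[tuple[str, int, str]] = []
        occupied: list[tuple[int, int]] = []
        for pwm, count in spec.motif_set:
            for _ in range(count):
                for _attempt in range(50):
                    pos = int(rng_motif.integers(0, spec.enhancer_length - pwm.width + 1))
                    if all(pos + pwm.width <= a or pos >= b for a, b in occupied):
                        break
                else:
                    continue
                occupied.append((pos, pos + pwm.width))
                strand = "+" if rng_motif.random() < 0.5 else "-"
                inst = plant_motif(seq, pwm, pos, rng_motif)
                if strand == "-":
                    from .genome import reverse_complement

                    core = reverse_complement(inst[pos : pos + pwm.width])
                    inst = inst[:pos] + core + inst[pos + pwm.width :]
                seq = inst
                sites.append((pwm.id, iv.start + pos, strand))
        sequences[iv.chrom] = (
            sequences[iv.chrom][: iv.start] + seq + sequences[iv.chrom][iv.end :]
        )
        enhancers.append(
            EnhancerTruth(f"enh{idx:04d}", iv, pop, False, "none", sites)
        )

    genome = Genome(sequences)

    # fragments: NFR mixture at open regions + nucleosomal/noise background
    samples = [
        f"{pop}_rep{r + 1}"
        for pop in ("popA", "popB")
        for r in range(spec.n_replicates)
    ]
    fragments: dict[str, list[FragmentRecord]] = {s: [] for s in samples}
    lo, hi = spec.nfr_length_dist
    motif_zones_by_enh = [
        [(p, p + next(pw.width for pw, _ in spec.motif_set if pw.id == mid))
         for mid, p, _ in e.motif_sites]
        for e in enhancers
    ]
    for e, zones in zip(enhancers, motif_zones_by_enh):
        for sample in samples:
            pop = sample.split("_")[0]
            if e.population == "shared" or e.population == pop:
                depth = spec.fragment_depth
            else:
                depth = spec.fragment_depth / spec.specific_fold
            n_frags = rng_frag.poisson(depth)
            for _ in range(n_frags):
                iv = _sample_fragment(
                    rng_frag, e.interval, lo, hi, zones, spec.chrom_length
                )
                fragments[sample].append(FragmentRecord(iv, sample))
    # genome-wide background: nucleosomal + sparse sub-100 noise
    for sample in samples:
        for chrom in chroms:
            n_nuc = rng_frag.poisson(
                spec.noise_fragments_per_kb * spec.chrom_length / 1000
            )
            starts = rng_frag.integers(0, spec.chrom_length - 400, size=n_nuc)
            lens = np.clip(
                rng_frag.normal(spec.nucleosomal_length_mean, 20, size=n_nuc),
                120, 350,
            ).astype(int)
            for s, ln in zip(starts, lens):
                fragments[sample].append(
                    FragmentRecord(
                        GenomicInterval(chrom, int(s), int(s + ln)), sample
                    )
                )
            n_noise = rng_frag.poisson(0.3 * spec.chrom_length / 1000)
            starts = rng_frag.integers(0, spec.chrom_length - 100, size=n_noise)
            lens = rng_frag.integers(lo, hi + 1, size=n_noise)
            for s, ln in zip(starts, lens):
                fragments[sample].append(
                    FragmentRecord(
                        GenomicInterval(chrom, int(s), int(s + ln)), sample
                    )
                )
    for sample in samples:
        fragments[sample].sort(
            key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end)
        )

    # H3K27Ac peaks for active popA/shared enhancers
    k27_peaks: list[GenomicInterval] = []
    w = spec.k27_peak_width
    for e in enhancers:
        if e.population == "popB":
            continue
        if rng_k27.random() >= spec.k27_active_fraction:
            continue
        iv = e.interval
        if rng_k27.random() < 0.5:
            e.k27, e.k27_mode = True, "overlap"
            k27_peaks.append(
                GenomicInterval(iv.chrom, max(0, iv.start - 100), iv.end + 100)
            )
        else:
            e.k27, e.k27_mode = True, "flank"
            gap = int(rng_k27.integers(iv.length + 100, spec.k27_flank_gap + 1))
            offset = int(rng_k27.integers(20, gap - iv.length - 20 + 1))
            gap_start = iv.start - offset
            k27_peaks.append(
                GenomicInterval(iv.chrom, max(0, gap_start - w), gap_start)
            )
            k27_peaks.append(
                GenomicInterval(iv.chrom, gap_start + gap, gap_start + gap + w)
            )
    k27_peaks.sort(key=lambda p: (p.chrom, p.start))

    # TSS / genes, kept clear of enhancer neighborhoods
    gene_tss: list[tuple[str, str, int]] = []
    tss_list: list[GenomicInterval] = []
    enh_by_chrom: dict[str, list[GenomicInterval]] = {}
    for e in enhancers:
        enh_by_chrom.setdefault(e.interval.chrom, []).append(e.interval)
    gi = 0
    while gi < spec.n_genes:
        chrom = chroms[int(rng_tss.integers(0, len(chroms)))]
        pos = int(rng_tss.integers(2000, spec.chrom_length - 2000))
        if any(
            iv.start - 2000 < pos < iv.end + 2000
            for iv in enh_by_chrom.get(chrom, [])
        ):
            continue
        name = f"gene{gi:03d}"
        gene_tss.append((name, chrom, pos))
        tss_list.append(GenomicInterval(chrom, pos, pos + 1, name=name))
        gi += 1
    tss_list.sort(key=lambda t: (t.chrom, t.start))
    gene_tss.sort(key=lambda g: (g[1], g[2]))

    # SNPs
    snps_tested: list[SnpRecord] = []
    snp_catalog: list[SnpRecord] = []
    snp_truth: dict = {}
    popA_idx = [i for i, e in enumerate(enhancers) if e.population == "popA"]
    if spec.planted_snp is not None and popA_idx:
        target = enhancers[popA_idx[spec.planted_snp % len(popA_idx)]]
        pwm_by_id = {pw.id: pw for pw, _ in spec.motif_set}
        best = None
        for mid, mstart, mstrand in target.motif_sites:
            pwm = pwm_by_id[mid]
            lo_mat = pwm.log_odds
            site = genome.fetch(target.interval.chrom, mstart, mstart + pwm.width)
            if mstrand == "-":
                from .genome import reverse_complement

                site = reverse_complement(site)
            for j, base in enumerate(site.upper()):
                bi = "ACGT".index(base) if base in "ACGT" else None
                if bi is None:
                    continue
                for ai in range(4):
                    if ai == bi:
                        continue
                    drop = lo_mat[j, bi] - lo_mat[j, ai]
                    if best is None or drop > best[0]:
                        best = (drop, mid, mstart, mstrand, j, bi, ai, pwm.width)
        assert best is not None, "planted enhancer has no motif instance"
        drop, mid, mstart, mstrand, j, bi, ai, width = best
        if mstrand == "+":
            gpos0 = mstart + j
            ref, alt = "ACGT"[bi], "ACGT"[ai]
        else:
            gpos0 = mstart + width - 1 - j
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            ref, alt = comp["ACGT"[bi]], comp["ACGT"[ai]]
        chrom = target.interval.chrom
        planted = SnpRecord(
            chrom, gpos0 + 1, ref, alt, id="snp_planted", assoc_p=1e-8
        )
        snps_tested.append(planted)
        snp_truth = {
            "snp_id": "snp_planted",
            "enhancer_id": target.enhancer_id,
            "motif": mid,
            "motif_logodds_drop": float(drop),
        }
        # additional benign tested SNPs within the locus, outside motifs
        motif_zones = [
            (s, s + pwm_by_id[m].width)
            for e in enhancers
            for m, s, _ in e.motif_sites
            if e.interval.chrom == chrom
        ]
        taken = {planted.pos}
        while len(snps_tested) < spec.n_tested_snps:
            pos = int(
                rng_snp.integers(
                    max(11, planted.pos - spec.snp_radius),
                    min(spec.chrom_length - 10, planted.pos + spec.snp_radius),
                )
            )
            if pos in taken or any(a <= pos - 1 < b for a, b in motif_zones):
                continue
            refb = genome.fetch(chrom, pos - 1, pos).upper()
            if refb not in "ACGT":
                continue
            altb = "ACGT".replace(refb, "")[int(rng_snp.integers(0, 3))]
            taken.add(pos)
            snps_tested.append(
                SnpRecord(
                    chrom, pos, refb, altb,
                    id=f"snp_{len(snps_tested):02d}",
                    assoc_p=float(10 ** rng_snp.uniform(-8, -5)),
                )
            )
        # background catalog for the resampling null
        while len(snp_catalog) < spec.n_background_snps:
            pos = int(
                rng_snp.integers(
                    max(11, planted.pos - spec.snp_radius),
                    min(spec.chrom_length - 10, planted.pos + spec.snp_radius),
                )
            )
            if pos in taken:
                continue
            refb = genome.fetch(chrom, pos - 1, pos).upper()
            if refb not in "ACGT":
                continue
            altb = "ACGT".replace(refb, "")[int(rng_snp.integers(0, 3))]
            taken.add(pos)
            snp_catalog.append(
                SnpRecord(chrom, pos, refb, altb, id=f"cat_{len(snp_catalog):04d}")
            )

    # diverged homolog pair of the first enhancer, for the homology stage
    homologs: dict[str, str] = {}
    if enhancers:
        base = genome.fetch(enhancers[0].interval).upper()
        homologs["element"] = base
        for name, rate in (("homolog_a", 0.15), ("homolog_b", 0.25)):
            chars = list(base)
            for i in range(len(chars)):
                if rng_hom.random() < rate:
                    chars[i] = _BASES[int(rng_hom.integers(0, 4))]
            # a couple of short indels
            for _ in range(3):
                p = int(rng_hom.integers(10, len(chars) - 10))
                if rng_hom.random() < 0.5:
                    del chars[p : p + int(rng_hom.integers(1, 5))]
                else:
                    ins = _BASES[rng_hom.integers(0, 4, size=int(rng_hom.integers(1, 5)))]
                    chars[p:p] = list(ins)
            homologs[name] = "".join(chars)

    ds = SyntheticDataset(
        spec=spec,
        genome=genome,
        fragments=fragments,
        k27_peaks=k27_peaks,
        tss=tss_list,
        gene_tss=gene_tss,
        enhancers=enhancers,
        snps_tested=snps_tested,
        snp_catalog=snp_catalog,
        snp_truth=snp_truth,
        homologs=homologs,
    )
    if outdir is not None:
        _write_dataset(ds, Path(outdir))
    return ds


def _write_dataset(ds: SyntheticDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.genome, outdir / "genome.fa")
    for pop in ("popA", "popB"):
        frags = [f for s in ds.samples(pop) for f in ds.fragments[s]]
        write_fragments(frags, outdir / f"fragments_{pop}.tsv")
    write_bed(ds.k27_peaks, outdir / "k27_peaks.bed")
    write_bed(ds.tss, outdir / "tss.bed")
    write_snp_table(ds.snps_tested + ds.snp_catalog, outdir / "snps.tsv")
    with open(outdir / "snp_groups.tsv", "w") as fh:
        fh.write("id\tgroup\n")
        for s in ds.snps_tested:
            fh.write(f"{s.id}\ttested\n")
        for s in ds.snp_catalog:
            fh.write(f"{s.id}\tcatalog\n")
    write_jaspar([pw for pw, _ in ds.spec.motif_set], outdir / "pwms.jaspar")
    with open(outdir / "motif_sites.bed", "w") as fh:
        pwm_w = {pw.id: pw.width for pw, _ in ds.spec.motif_set}
        for e in ds.enhancers:
            for mid, start, strand in e.motif_sites:
                fh.write(
                    f"{e.interval.chrom}\t{start}\t{start + pwm_w[mid]}\t"
                    f"{mid}\t.\t{strand}\n"
                )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(
            "enhancer_id\tchrom\tstart\tend\tpopulation\tk27\tk27_mode\t"
            "motif_sites\tsnp_id\tsnp_motif\tsnp_logodds_drop\n"
        )
        planted_enh = ds.snp_truth.get("enhancer_id", "")
        for e in ds.enhancers:
            sites = ",".join(f"{m}:{p}:{s}" for m, p, s in e.motif_sites)
            if e.enhancer_id == planted_enh:
                snp_cols = (
                    f"{ds.snp_truth['snp_id']}\t{ds.snp_truth['motif']}\t"
                    f"{ds.snp_truth['motif_logodds_drop']:.6g}"
                )
            else:
                snp_cols = "\t\t"
            fh.write(
                f"{e.enhancer_id}\t{e.interval.chrom}\t{e.interval.start}\t"
                f"{e.interval.end}\t{e.population}\t{int(e.k27)}\t{e.k27_mode}\t"
                f"{sites}\t{snp_cols}\n"
            )
    with open(outdir / "homologs.fa", "w") as fh:
        for name, seq in ds.homologs.items():
            fh.write(f">{name}\n{seq}\n")
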