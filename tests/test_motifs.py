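import numpy as np
import pytest
from scipy.stats import hypergeom

from atacvar.genome import Genome, GenomicInterval, reverse_complement
from atacvar.motifs import (
    Pwm,
    allele_effect,
    build_network,
    cluster_elements_by_motifs,
    footprint,
    motif_combinations,
    motif_enrichment,
    motif_presence,
    read_jaspar,
    scan_pwm,
    write_jaspar,
)
from atacvar.simulate import _sharp_pwm, plant_motif
from atacvar.variants import SnpRecord

from conftest import random_dna


@pytest.fixture
def pwm():
    return _sharp_pwm("TEST_MOTIF", "ACCGGAAGTG")


class TestPwm:
    def test_validation(self):
        with pytest.raises(ValueError):
            Pwm("bad", np.ones((3, 4)) / 4)  # width < 4
        with pytest.raises(ValueError):
            Pwm("bad", np.ones((6, 3)) / 3)

    def test_consensus(self, pwm):
        assert pwm.consensus == "ACCGGAAGTG"

    def test_jaspar_roundtrip(self, tmp_path, pwm):
        write_jaspar([pwm], tmp_path / "m.jaspar")
        back = read_jaspar(tmp_path / "m.jaspar")
        assert len(back) == 1
        assert back[0].consensus == pwm.consensus
        assert np.allclose(back[0].matrix, pwm.matrix, atol=0.01)

    def test_relative_score_invariant_to_uniform_background_scale(self, pwm):
        seq = "TTTT" + pwm.consensus + "TTTT"
        h1 = scan_pwm(seq, pwm, 0.8)
        scaled = Pwm(pwm.id, pwm.matrix, background=np.full(4, 0.1),
                     pseudocount=pwm.pseudocount)
        h2 = scan_pwm(seq, scaled, 0.8)
        assert [(h.interval.start, h.strand) for h in h1] == [
            (h.interval.start, h.strand) for h in h2
        ]
        for a, b in zip(h1, h2):
            assert a.relative_score == pytest.approx(b.relative_score, abs=1e-9)


class TestScan:
    def test_consensus_relative_one(self, pwm):
        hits = scan_pwm("TT" + pwm.consensus + "TT", pwm, 0.99)
        plus = [h for h in hits if h.strand == "+"]
        assert plus[0].relative_score == pytest.approx(1.0)
        assert plus[0].interval.start == 2

    def test_anticonsensus_relative_zero(self, pwm):
        lo = pwm.log_odds
        anti = "".join("ACGT"[i] for i in lo.argmin(axis=1))
        codes_scores = scan_pwm(anti, pwm, min_relative=-0.01)
        plus = [h for h in codes_scores if h.strand == "+" and h.interval.start == 0]
        assert plus[0].relative_score == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_position_scan(self, pwm, rng):
        seq = random_dna(rng, 1000)
        hits = scan_pwm(seq, pwm, 0.8)
        # independent per-position oracle
        lo = pwm.log_odds
        smin = lo.min(axis=1).sum()
        smax = lo.max(axis=1).sum()
        expected = set()
        for strand in "+-":
            s = seq if strand == "+" else reverse_complement(seq)
            for i in range(len(s) - pwm.width + 1):
                sub = s[i : i + pwm.width]
                score = sum(lo[j, "ACGT".index(c)] for j, c in enumerate(sub))
                if (score - smin) / (smax - smin) >= 0.8:
                    start = i if strand == "+" else len(seq) - pwm.width - i
                    expected.add((start, strand))
        assert {(h.interval.start, h.strand) for h in hits} == expected

    def test_strand_mirror(self, pwm, rng):
        seq = random_dna(rng, 300)
        fwd = scan_pwm(seq, pwm, 0.8)
        rev = scan_pwm(reverse_complement(seq), pwm, 0.8)
        mirrored = {
            (len(seq) - h.interval.end, {"+": "-", "-": "+"}[h.strand])
            for h in rev
        }
        assert {(h.interval.start, h.strand) for h in fwd} == mirrored


class TestPresenceAndCombinations:
    @pytest.fixture
    def annotated(self, pwm, rng):
        other = _sharp_pwm("OTHER", "TTGACGCATT")
        elements, seqs = [], {}
        chrom_parts = []
        pos = 0
        for i in range(20):
            seq = random_dna(rng, 400)
            if i < 15:
                seq = plant_motif(seq, pwm, 100, np.random.default_rng(i))
            if i % 2 == 0:
                seq = plant_motif(seq, other, 250, np.random.default_rng(100 + i))
            chrom_parts.append(seq)
            elements.append(GenomicInterval("c1", pos, pos + 400))
            pos += 400
        genome = Genome({"c1": "".join(chrom_parts)})
        return genome, elements, [pwm, other]

    def test_presence_recovers_planted(self, annotated):
        genome, elements, pwms = annotated
        pres = motif_presence(elements, genome, pwms)
        assert pres["presence_fraction"][0] >= 0.7  # planted in 75%
        assert pres["matrix"].shape == (20, 2)

    def test_absent_motif_flagged(self, annotated):
        genome, elements, _ = annotated
        absent = _sharp_pwm("ABSENT", "GTACGTACGCGT"[:10])
        pres = motif_presence(elements, genome, [absent], min_relative=0.99)
        if pres["presence_fraction"][0] < 0.05:
            assert "ABSENT" in pres["flagged_below_min"]

    def test_combinations_match_bruteforce(self, rng):
        mat = rng.integers(0, 2, size=(50, 5)).astype(np.int8)
        for order in (2, 3):
            combos = motif_combinations(mat, order)
            for ids, count in combos:
                cols = [int(i[1:]) for i in ids]
                expected = int(mat[:, cols].all(axis=1).sum())
                assert count == expected
            counts = [c for _, c in combos]
            assert counts == sorted(counts, reverse=True)

    def test_disjoint_pair_zero(self):
        mat = np.zeros((10, 2), dtype=np.int8)
        mat[:5, 0] = 1
        mat[5:, 1] = 1
        combos = motif_combinations(mat, 2)
        assert combos[0][1] == 0

    def test_order_too_large(self):
        with pytest.raises(ValueError):
            motif_combinations(np.zeros((5, 2), dtype=np.int8), 3)

    def test_clustering_runs(self, rng):
        mat = rng.integers(0, 2, size=(12, 4)).astype(np.int8)
        link = cluster_elements_by_motifs({"matrix": mat, "motif_ids": list("abcd")})
        assert link.shape == (11, 4)


class TestEnrichment:
    def test_fg_eq_bg_fold_one(self, pwm, rng):
        seq = random_dna(rng, 4000)
        genome = Genome({"c1": seq})
        els = [GenomicInterval("c1", i * 400, i * 400 + 400) for i in range(10)]
        rows = motif_enrichment(els, els, genome, [pwm])
        assert rows[0]["fold"] == pytest.approx(1.0) or np.isnan(rows[0]["fold"])

    def test_p_matches_hypergeometric_formula(self, pwm, rng):
        fg_seqs = [
            plant_motif(random_dna(rng, 400), pwm, 50, np.random.default_rng(i))
            for i in range(10)
        ]
        bg_seqs = [random_dna(rng, 400) for _ in range(30)]
        genome = Genome({"c1": "".join(fg_seqs + bg_seqs)})
        fg = [GenomicInterval("c1", i * 400, (i + 1) * 400) for i in range(10)]
        bg = [GenomicInterval("c1", i * 400, (i + 1) * 400) for i in range(10, 40)]
        rows = motif_enrichment(fg, bg, genome, [pwm])
        row = rows[0]
        k_fg = round(row["fg_fraction"] * 10)
        k_bg = round(row["bg_fraction"] * 30)
        expected = hypergeom.sf(k_fg - 1, 40, k_fg + k_bg, 10)
        assert row["pvalue"] == pytest.approx(float(expected), rel=1e-9)
        assert row["qvalue"] < 0.01  # planted motif strongly enriched


class TestFootprint:
    def _hits(self, pwm, starts, strand="+"):
        from atacvar.motifs import MotifHit

        return [
            MotifHit(
                GenomicInterval("c1", s, s + pwm.width, strand=strand),
                pwm.id, strand, 10.0, 0.9,
            )
            for s in starts
        ]

    def test_profile_length(self, pwm, rng):
        cuts = {"c1": rng.poisson(5, size=10_000).astype(float)}
        prof = footprint(cuts, self._hits(pwm, [2000, 5000]), flank=100)
        assert len(prof.cut_counts) == 201 + pwm.width
        assert len(prof.offsets) == 201 + pwm.width
        assert prof.n_sites == 2

    def test_uniform_cuts_protection_near_one(self, pwm):
        rng = np.random.default_rng(0)
        cuts = {"c1": rng.poisson(10, size=100_000).astype(float)}
        starts = list(range(1000, 90_000, 500))
        prof = footprint(cuts, self._hits(pwm, starts))
        assert abs(prof.protection - 1.0) < 0.1

    def test_depleted_core_protection_low(self, pwm):
        rng = np.random.default_rng(1)
        cuts = {"c1": rng.poisson(10, size=50_000).astype(float)}
        starts = list(range(1000, 45_000, 500))
        for s in starts:
            cuts["c1"][s : s + pwm.width] *= 0.1
        prof = footprint(cuts, self._hits(pwm, starts))
        assert prof.protection < 0.5

    def test_no_hits_error(self, pwm):
        with pytest.raises(ValueError):
            footprint({"c1": np.zeros(100)}, [])


class TestAlleleEffect:
    def _genome_with(self, core: str, rng):
        left = random_dna(rng, 5000)
        right = random_dna(rng, 5000)
        return Genome({"c1": left + core + right}), 5000

    def test_ref_eq_alt_rejected_by_snp_record(self):
        with pytest.raises(ValueError):
            SnpRecord("c1", 10, "A", "A")

    def test_planted_site_lost(self, rng):
        # crafted 5-column PWM with low pseudocount: consensus scores ~6.9
        # (>= 5.0) and the worst single substitution drops to ~0.4 (< 2.0)
        mat = np.full((5, 4), 0.0005)
        for j, b in enumerate("ACGTA"):
            mat[j, "ACGT".index(b)] = 0.9985
        sharp = Pwm("SHARP5", mat, pseudocount=0.001)
        genome, off = self._genome_with(sharp.consensus, rng)
        lo = sharp.log_odds
        j = 2
        ref = sharp.consensus[j]
        alt = "ACGT"[int(lo[j].argmin())]
        consensus_score = float(lo.max(axis=1).sum())
        alt_score = consensus_score - float(lo[j].max() - lo[j].min())
        assert consensus_score >= 5.0 and alt_score < 2.0
        snp = SnpRecord("c1", off + j + 1, ref, alt, id="dis")
        out = allele_effect(snp, genome, [sharp], lost_high=5.0, lost_low=2.0)
        assert any(m == "SHARP5" for m, _, _ in out["lost"])
        assert not out["gained"]

    def test_threshold_gap_case_neither(self, rng):
        # crafted: ref 6.1-ish, alt ~4 -> neither lost nor gained
        pwm = _sharp_pwm("GAPPY", "ACGTACGTA", major=0.7)
        genome, off = self._genome_with(pwm.consensus, rng)
        lo = pwm.log_odds
        j = int(np.argmax(lo.max(axis=1) - lo.min(axis=1)))
        ref = pwm.consensus[j]
        alts = [b for b in "ACGT" if b != ref]
        # pick the mildest substitution
        alt = max(alts, key=lambda b: lo[j, "ACGT".index(b)])
        snp = SnpRecord("c1", off + j + 1, ref, alt, id="mild")
        out = allele_effect(snp, genome, [pwm], lost_high=5.0, lost_low=2.0,
                            min_relative=0.5)
        for r in out["table"]:
            if r["ref_score"] >= 5.0 and r["alt_score"] >= 2.0 and r["alt_detected"]:
                assert (pwm.id, r["start"], r["strand"]) not in out["lost"]


class TestNetwork:
    def test_empty_elements_edgeless(self):
        g = build_network(
            [("TFA", "m1")],
            {"matrix": np.zeros((0, 1), dtype=np.int8), "motif_ids": ["m1"]},
            [],
        )
        assert g.number_of_edges() == 0
        assert "TFA" in g.nodes

    def test_single_edge(self):
        pres = {"matrix": np.array([[1]], dtype=np.int8), "motif_ids": ["m1"]}
        g = build_network([("TFA", "m1"), ("TFB", "m2")], pres, [["TFB"]])
        assert g.has_edge("TFA", "TFB")
        assert g["TFA"]["TFB"]["weight"] == 1

    def test_weights_match_bruteforce_join(self, rng):
        tfs = [(f"TF{i}", f"m{i}") for i in range(4)]
        mat = rng.integers(0, 2, size=(30, 4)).astype(np.int8)
        genes = [
            [f"TF{int(g)}" for g in rng.choice(4, size=rng.integers(0, 3), replace=False)]
            for _ in range(30)
        ]
        g = build_network(tfs, {"matrix": mat, "motif_ids": [m for _, m in tfs]}, genes)
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                expected = sum(
                    1
                    for i in range(30)
                    if mat[i, a] and f"TF{b}" in genes[i]
                )
                actual = (
                    g["TF" + str(a)]["TF" + str(b)]["weight"]
                    if g.has_edge(f"TF{a}", f"TF{b}")
                    else 0
                )
                assert actual == expected
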