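"""Gapped k-mer kernel and SVM tests, including the independent
feature-vector and rank-statistic oracles."""

import itertools
from collections import Counter

import numpy as np
import pytest

from atacvar.genome import reverse_complement
from atacvar.gkm import (
    GkmModel,
    GkmParams,
    TrainingSet,
    build_negative_set,
    cross_validate,
    gkm_kernel,
    gram_matrix,
    mismatch_coefficient,
    read_model,
    score_sequence,
    train,
    write_model,
)
from atacvar.simulate import SyntheticDatasetSpec, make_dataset

from conftest import random_dna

# ---------------------------------------------------------------- oracles


def subset_count_oracle(m: int, l: int, k: int) -> int:
    """Enumerate all C(l, k) position subsets; count those avoiding the m
    mismatched positions (taken WLOG as the first m)."""
    mism = set(range(m))
    return sum(
        1
        for sub in itertools.combinations(range(l), k)
        if not (set(sub) & mism)
    )


def feature_vector(seq: str, l: int, k: int, rc: bool) -> Counter:
    """Explicit gapped k-mer count vector (pattern, projected k-mer)."""
    seqs = [seq.upper()]
    if rc:
        seqs.append(reverse_complement(seq).upper())
    counts: Counter = Counter()
    for s in seqs:
        for i in range(len(s) - l + 1):
            lmer = s[i : i + l]
            if "N" in lmer:
                continue
            for pat in itertools.combinations(range(l), k):
                counts[(pat, "".join(lmer[p] for p in pat))] += 1
    return counts


def kernel_oracle(a: str, b: str, l: int, k: int, rc: bool) -> float:
    fa, fb = feature_vector(a, l, k, rc), feature_vector(b, l, k, rc)
    return float(sum(fa[key] * fb.get(key, 0) for key in fa))


def auc_oracle(labels: np.ndarray, scores: np.ndarray) -> float:
    """auROC as the Mann-Whitney U statistic."""
    from scipy.stats import mannwhitneyu

    pos = scores[labels > 0]
    neg = scores[labels < 0]
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


# ------------------------------------------------------- mismatch coeff


class TestMismatchCoefficient:
    @pytest.mark.parametrize("m,expected", [(0, 210), (1, 84), (5, 0), (4, 1)])
    def test_l10_k6(self, m, expected):
        assert mismatch_coefficient(m, 10, 6) == expected

    @pytest.mark.parametrize("l,k", [(10, 6), (8, 5), (6, 3)])
    def test_matches_subset_enumeration(self, l, k):
        for m in range(l + 1):
            assert mismatch_coefficient(m, l, k) == subset_count_oracle(m, l, k)

    def test_k_gt_l_error(self):
        with pytest.raises(ValueError):
            mismatch_coefficient(0, 5, 6)


# --------------------------------------------------------------- kernel


class TestKernel:
    def test_self_normalized_is_one(self, rng):
        s = random_dna(rng, 60)
        assert gkm_kernel(s, s) == pytest.approx(1.0)

    def test_single_lmer_one_mismatch(self):
        a, b = "ACGTACGTAC", "ACGTACGTAT"
        p = GkmParams(rc_collapse=False)
        assert gkm_kernel(a, b, p, normalized=False) == 84.0

    @pytest.mark.parametrize("rc", [False, True])
    def test_matches_feature_vector_oracle(self, rng, rc):
        p = GkmParams(rc_collapse=rc)
        for _ in range(5):
            a, b = random_dna(rng, 50), random_dna(rng, 50)
            expected = kernel_oracle(a, b, 10, 6, rc)
            assert gkm_kernel(a, b, p, normalized=False) == expected

    def test_symmetry(self, rng):
        a, b = random_dna(rng, 45), random_dna(rng, 61)
        assert gkm_kernel(a, b, normalized=False) == gkm_kernel(
            b, a, normalized=False
        )

    def test_n_lmers_skipped(self):
        p = GkmParams(rc_collapse=False)
        a = "ACGTACGTAC"
        k_plain = gkm_kernel(a, a, p, normalized=False)
        padded = "N" + a  # the N-containing windows contribute nothing
        assert gkm_kernel(padded, a, p, normalized=False) == k_plain

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            gkm_kernel("ACGT", "ACGTACGTAC")

    def test_gram_equals_pairwise(self, rng):
        seqs = [random_dna(rng, 40) for _ in range(6)]
        for rc in (False, True):
            p = GkmParams(rc_collapse=rc)
            G = gram_matrix(seqs, p, normalized=False)
            for i in range(6):
                for j in range(i, 6):
                    assert G[i, j] == pytest.approx(
                        gkm_kernel(seqs[i], seqs[j], p, normalized=False)
                    )

    def test_gram_psd(self, rng):
        seqs = [random_dna(rng, 60) for _ in range(12)]
        G = gram_matrix(seqs, normalized=True)
        assert np.linalg.eigvalsh(G).min() >= -1e-8


# --------------------------------------------------------------- model


class TestModel:
    def test_score_is_window_sum_of_weights(self, tiny_model):
        model, _ = tiny_model
        s = "ACGTACGTACGTACGTACG"  # 19 bp -> exactly 10 l-mers
        total = sum(
            model.kmer_weight(s[i : i + 10]) for i in range(10)
        )
        assert score_sequence(s, model) == pytest.approx(total)

    def test_all_n_scores_zero(self, tiny_model):
        model, _ = tiny_model
        assert score_sequence("N" * 30, model) == 0.0

    def test_short_sequence_error(self, tiny_model):
        model, _ = tiny_model
        with pytest.raises(ValueError):
            score_sequence("ACGT", model)

    def test_rc_collapse_score_symmetry(self, tiny_model, rng):
        model, _ = tiny_model
        s = random_dna(rng, 44)
        assert score_sequence(s, model) == pytest.approx(
            score_sequence(reverse_complement(s), model), rel=1e-9, abs=1e-9
        )

    def test_label_swap_negates_weights(self):
        rng = np.random.default_rng(5)
        pos = [random_dna(rng, 30) for _ in range(10)]
        neg = [random_dna(rng, 30) for _ in range(10)]
        m1 = train(TrainingSet(pos, neg))
        m2 = train(TrainingSet(neg, pos))
        scale = np.abs(m1.weight_table).max()
        # antisymmetric up to the SMO solver tolerance
        assert np.allclose(m1.weight_table, -m2.weight_table, atol=2e-3 * scale)

    def test_degenerate_one_class_error(self):
        with pytest.raises(ValueError):
            train(TrainingSet(["ACGTACGTACGT"], []))

    def test_decision_consistency_via_kernel(self, tiny_model):
        """Weight-sum score equals the kernel-evaluated decision sum."""
        from atacvar.gkm import _augment_rc, _f_table, _pair_kernel, _valid_windows, encode_sequence

        model, _ = tiny_model
        p = model.params
        ftab = _f_table(p.l, p.k)
        rng = np.random.default_rng(3)
        s = random_dna(rng, 27)
        S = _valid_windows(encode_sequence(s), p.l)
        if p.rc_collapse:
            S = _augment_rc(S)
        direct = 0.0
        for sv, c, dd in zip(
            model.support_sequences, model.dual_coefs, model.support_diag
        ):
            V = _valid_windows(encode_sequence(sv), p.l)
            if p.rc_collapse:
                V = _augment_rc(V)
            direct += c / np.sqrt(dd) * _pair_kernel(S, V, ftab, p.l)
        assert score_sequence(s, model) == pytest.approx(direct, rel=1e-6)

    def test_serialization_roundtrip(self, tiny_model, tmp_path):
        model, _ = tiny_model
        prefix = str(tmp_path / "model")
        write_model(model, prefix, min_abs_weight=1e-12)
        back = read_model(prefix)
        assert back.params == model.params
        assert back.bias == pytest.approx(model.bias)
        assert np.allclose(back.weight_table, model.weight_table, atol=1e-9)


# ------------------------------------------------------------ negatives


class TestNegativeSet:
    @pytest.fixture(scope="class")
    def genome_and_pos(self):
        spec = SyntheticDatasetSpec(
            seed=3, n_chroms=2, chrom_length=150_000,
            n_enhancers_popA=10, n_enhancers_popB=0, n_shared=0,
            planted_snp=None,
        )
        ds = make_dataset(spec)
        return ds, ds.enhancer_sequences("popA")

    def test_ratio(self, genome_and_pos):
        ds, pos = genome_and_pos
        ts = build_negative_set(pos, ds.genome, ratio=10, seed=1,
                                exclusions=[e.interval for e in ds.enhancers])
        assert len(ts.negatives) == 10 * len(pos)

    def test_no_overlap_with_exclusions(self, genome_and_pos):
        ds, pos = genome_and_pos
        excl = [e.interval for e in ds.enhancers]
        ts = build_negative_set(pos, ds.genome, ratio=5, seed=1, exclusions=excl)
        for iv in ts.negative_intervals:
            assert not any(iv.overlaps(e) for e in excl)

    def test_gc_matched_within_tolerance(self, genome_and_pos):
        from atacvar.genome import gc_fraction

        ds, pos = genome_and_pos
        tol = 0.02
        ts = build_negative_set(pos, ds.genome, ratio=5, gc_tolerance=tol,
                                seed=1, max_relaxations=0)
        for i, p in enumerate(pos):
            for n in ts.negatives[i * 5 : (i + 1) * 5]:
                assert abs(gc_fraction(n) - gc_fraction(p)) <= tol + 1e-12

    def test_deterministic(self, genome_and_pos):
        ds, pos = genome_and_pos
        a = build_negative_set(pos, ds.genome, ratio=3, seed=9)
        b = build_negative_set(pos, ds.genome, ratio=3, seed=9)
        assert a.negatives == b.negatives


# ------------------------------------------------------------------- CV


class TestCrossValidation:
    def test_perfectly_separable(self):
        pos = ["A" * 30 + "CCGGTTAACCGG" + "A" * 30] * 10
        neg = ["T" * 72] * 10
        cv = cross_validate(TrainingSet(pos, neg), folds=5, seed=0)
        assert cv["auROC"] == 1.0

    def test_auroc_equals_rank_statistic(self, tiny_model):
        _, ts = tiny_model
        cv = cross_validate(ts, folds=5, seed=1)
        assert cv["auROC"] == pytest.approx(
            auc_oracle(cv["labels"], cv["scores"]), abs=1e-9
        )

    def test_null_labels_auroc_near_half(self):
        rng = np.random.default_rng(42)
        seqs = [random_dna(rng, 50) for _ in range(60)]
        aucs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            perm = r.permutation(60)
            pos = [seqs[i] for i in perm[:30]]
            neg = [seqs[i] for i in perm[30:]]
            cv = cross_validate(TrainingSet(pos, neg), folds=3, seed=seed)
            aucs.append(cv["auROC"])
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_too_many_folds_error(self):
        ts = TrainingSet(["ACGTACGTACGT"] * 2, ["TGCATGCATGCA"] * 2)
        with pytest.raises(ValueError):
            cross_validate(ts, folds=5)
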