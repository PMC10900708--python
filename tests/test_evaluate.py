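"""SP/F1 metrics, binning with suppression, score-distribution sampling."""

import numpy as np
import pytest

from peba.align import AlignmentResult, GapPenalties, smith_waterman
from peba.embeddings import generate_synthetic_pair, random_pair_spec
from peba.evaluate import (
    SUPPRESS_BELOW,
    ColumnPairSet,
    EvaluationResult,
    bin_results,
    column_pairs,
    evaluate_alignment,
    f1_score,
    sample_score_distributions,
    sp_score,
)
from peba.scoring import embedding_score_matrix, load_substitution_table, substitution_score_matrix
from peba.seqio import make_pairwise_reference


def cps(*pairs):
    return ColumnPairSet(pairs=frozenset(pairs))


class TestColumnPairs:
    def test_reference_columns_indexed_into_ungapped_sequences(self):
        # columns (A,A),(C,-),(D,E) -> {(0,0),(2,1)}
        ref = make_pairwise_reference("a", "ACD", "b", "A-E")
        assert column_pairs(ref).pairs == {(0, 0), (2, 1)}

    def test_gapless_identity_alignment(self):
        ref = make_pairwise_reference("a", "ACDE", "b", "ACDE")
        assert column_pairs(ref).pairs == {(i, i) for i in range(4)}

    def test_empty_local_alignment(self):
        aln = AlignmentResult(pairs=(), score=0.0, mode="local")
        assert column_pairs(aln).pairs == frozenset()

    def test_one_to_one_enforced(self):
        with pytest.raises(ValueError, match="one-to-one"):
            ColumnPairSet(pairs=frozenset({(0, 0), (0, 1)}))


class TestSpScore:
    def test_identical_sets(self):
        x = cps((0, 0), (1, 1))
        assert sp_score(x, x) == 1.0

    def test_disjoint_sets(self):
        assert sp_score(cps((0, 1)), cps((1, 0))) == 0.0

    def test_half_recovered(self):
        ref = cps((0, 0), (1, 1), (2, 2), (3, 3))
        test = cps((0, 0), (1, 1), (9, 9))
        assert sp_score(test, ref) == 0.5

    def test_reference_anchored(self):
        """Extra non-intersecting test pairs never change SP."""
        ref = cps((0, 0), (1, 1))
        base = cps((0, 0), (5, 5))
        moved = cps((0, 0), (7, 9))
        assert sp_score(base, ref) == sp_score(moved, ref) == 0.5

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            sp_score(cps((0, 0)), ColumnPairSet(pairs=frozenset()))


class TestF1Score:
    def test_identical_sets(self):
        x = cps((0, 0), (1, 1), (2, 2))
        assert f1_score(x, x) == 1.0

    def test_empty_test_is_zero(self):
        assert f1_score(ColumnPairSet(pairs=frozenset()), cps((0, 0))) == 0.0

    def test_harmonic_mean_of_recall_and_precision(self):
        ref = cps((0, 0), (1, 1), (2, 2), (3, 3))
        test = cps((0, 0), (1, 1))
        # recall 0.5, precision 1.0
        assert f1_score(test, ref) == pytest.approx(2 / 3)

    def test_random_sets_self_score_one(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            i = rng.choice(200, size=n, replace=False)
            j = rng.choice(200, size=n, replace=False)
            x = cps(*zip(i.tolist(), j.tolist()))
            assert sp_score(x, x) == 1.0
            assert f1_score(x, x) == 1.0

    def test_bounded_and_equal_one_iff_equal_sets(self, rng):
        ref = cps((0, 0), (1, 1), (2, 2))
        for test in (cps((0, 0)), cps((0, 0), (1, 1), (2, 2), (3, 3)), cps((5, 5))):
            v = f1_score(test, ref)
            assert 0.0 <= v < 1.0


def _result(sp=0.5, f1=0.5, identity=15.0, length=100):
    return EvaluationResult(sp=sp, f1=f1, recall=sp, precision=f1,
                            identity_pct=identity, alignment_length=length)


class TestBinning:
    def test_sparse_bin_suppressed(self):
        results = [_result(identity=5.0)] * (SUPPRESS_BELOW - 1)
        summary = bin_results(results, axis="identity")
        assert summary.suppressed[0] is True
        assert summary.mean_sp[0] is None

    def test_ten_results_reported(self):
        results = [_result(sp=0.5, identity=5.0)] * 10
        summary = bin_results(results, axis="identity")
        assert summary.suppressed[0] is False
        assert summary.mean_sp[0] == pytest.approx(0.5)
        assert summary.counts[0] == 10

    def test_half_open_identity_edges(self):
        low = [_result(identity=9.99)] * 10
        high = [_result(identity=10.0)] * 10
        summary = bin_results(low + high, axis="identity")
        assert summary.counts[0] == 10 and summary.counts[1] == 10

    def test_length_axis_uses_reference_columns(self):
        results = [_result(length=499)] * 10 + [_result(length=500)] * 10
        summary = bin_results(results, axis="length")
        assert summary.counts[0] == 10 and summary.counts[1] == 10

    def test_out_of_range_clamped_with_warning(self, caplog):
        import logging

        results = [_result(length=99999)] * 10
        with caplog.at_level(logging.WARNING):
            summary = bin_results(results, axis="length")
        assert summary.counts[-1] == 10
        assert any("clamped" in r.message for r in caplog.records)

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            bin_results([_result()], axis="identity", edges=[0, 10, 10])

    def test_frame_layout(self):
        df = bin_results([_result(identity=25.0)] * 12, axis="identity").to_frame()
        assert list(df.columns) == ["bin", "count", "mean_sp", "mean_f1", "suppressed"]
        assert df.iloc[2]["bin"] == "20-29"


class TestEndToEndRecovery:
    def test_local_alignment_recovers_planted_reference(self):
        """SW over scaled-cosine scores recovers >= 95% of planted pairs
        at noise_sigma 0.2 (mean over 10 seeds)."""
        sps = []
        for seed in range(10):
            spec = random_pair_spec(n_pairs=100, dim=256, noise_sigma=0.2, seed=seed)
            a, b, ref = generate_synthetic_pair(spec)
            aln = smith_waterman(embedding_score_matrix(a, b), GapPenalties())
            res = evaluate_alignment(aln, ref)
            sps.append(res.sp)
            assert res.alignment_length == ref.alignment_length
        assert np.mean(sps) >= 0.95

    def test_embedding_scoring_beats_blosum_on_shuffled_labels(self):
        """With heavy noise the embedding scorer still recovers more of the
        planted alignment than BLOSUM62 run on random residue labels
        (the residue letters carry no signal off the planted pairs)."""
        table = load_substitution_table("BLOSUM62")
        emb_sps, blosum_sps = [], []
        for seed in range(5):
            spec = random_pair_spec(n_pairs=80, dim=256, noise_sigma=0.9, seed=seed)
            a, b, ref = generate_synthetic_pair(spec)
            aln_e = smith_waterman(embedding_score_matrix(a, b))
            S_b = substitution_score_matrix(ref.seq_a, ref.seq_b, table)
            aln_b = smith_waterman(S_b)
            rset = column_pairs(ref, source="reference")
            emb_sps.append(sp_score(column_pairs(aln_e), rset))
            blosum_sps.append(sp_score(column_pairs(aln_b), rset))
        assert np.mean(emb_sps) > np.mean(blosum_sps)


class TestScoreDistributionSampling:
    @staticmethod
    def _groups(noise, n_msas=3, n_refs=5, seed0=0):
        groups, mats = [], {}
        for g in range(n_msas):
            refs = []
            for k in range(n_refs):
                spec = random_pair_spec(n_pairs=40, dim=128, noise_sigma=noise,
                                        seed=seed0 + 37 * g + k)
                a, b, ref = generate_synthetic_pair(spec)
                mats[id(ref)] = embedding_score_matrix(a, b).values
                refs.append(ref)
            groups.append(refs)
        return groups, (lambda r: mats[id(r)])

    def test_zero_noise_aligned_scores_all_ten(self):
        groups, scorer = self._groups(noise=0.0, n_msas=1, n_refs=2)
        aligned, _ = sample_score_distributions(groups, scorer, seed=0)
        assert aligned and all(s == pytest.approx(10.0, abs=1e-9) for s in aligned)

    def test_same_seed_reproducible(self):
        groups, scorer = self._groups(noise=0.3)
        s1 = sample_score_distributions(groups, scorer, seed=42)
        s2 = sample_score_distributions(groups, scorer, seed=42)
        assert s1 == s2

    def test_aligned_mean_exceeds_background_mean(self):
        deltas = []
        for seed in range(20):
            groups, scorer = self._groups(noise=0.4, n_msas=2, seed0=100 * seed)
            aligned, background = sample_score_distributions(groups, scorer, seed=seed)
            deltas.append(np.mean(aligned) - np.mean(background))
        assert min(deltas) > 0


class TestPlotHook:
    def test_scatter_written(self, tmp_path):
        from peba.evaluate import plot_sp_comparison

        a = [_result(sp=s) for s in (0.1, 0.5, 0.9)]
        b = [_result(sp=s) for s in (0.2, 0.6, 0.8)]
        out = tmp_path / "cmp.png"
        plot_sp_comparison(a, b, out, label_x="blosum", label_y="embedding")
        assert out.exists() and out.stat().st_size > 0
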