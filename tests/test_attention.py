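"""Attention profiles, region calling, enrichment, motif merging, pair mining."""

import itertools

import numpy as np
import pandas as pd
import pytest
from collections import Counter

from epiattn import attention as attn
from epiattn.attention import (PWM, HighAttentionRegion, MotifCandidate,
                               average_heads, base_decompose, call_regions,
                               classify_common_specific, count_kmer_pairs,
                               discover_motifs, enrichment_pvalue, export_meme,
                               merge_candidates, normalize_profile,
                               position_density, read_meme, score_candidates,
                               summarize_kmer_pairs, token_profile)
from epiattn.tokenizer import Vocabulary, assemble_pair


def _stochastic(rng, h, L):
    m = rng.random((h, L, L))
    return m / m.sum(axis=-1, keepdims=True)


class TestAverageHeads:
    def test_identical_heads_mean_is_any_head(self, rng):
        m = _stochastic(rng, 1, 6)
        stacked = np.repeat(m, 4, axis=0)
        assert np.allclose(average_heads(stacked), m[0])

    def test_elementwise_mean(self):
        a = np.full((1, 2, 2), 0.2)
        b = np.full((1, 2, 2), 0.4)
        out = average_heads(np.concatenate([a, b]))
        assert np.allclose(out, 0.3)

    def test_mean_of_stochastic_is_stochastic(self, rng):
        out = average_heads(_stochastic(rng, 5, 9))
        assert np.allclose(out.sum(axis=-1), 1.0)

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError):
            average_heads(rng.random((2, 3, 4)))


class TestTokenProfile:
    def test_row_stochastic_gives_uniform(self, rng):
        L = 8
        m = _stochastic(rng, 1, L)[0]
        roles = np.array([0] + [1] * 3 + [2] + [3] * 3)
        assert np.allclose(token_profile(m, roles), 1.0 / L)

    def test_promoter_restricted_hand_computed(self):
        m = np.arange(16, dtype=float).reshape(4, 4)
        m = m / m.sum(axis=1, keepdims=True)
        roles = np.array([0, 1, 2, 3])  # CLS, ENH, SEP, PROM
        out = token_profile(m, roles, target="promoter")
        assert np.allclose(out, m[:, 3])

    def test_permutation_equivariance(self, rng):
        L = 7
        m = _stochastic(rng, 1, L)[0]
        roles = np.zeros(L, dtype=int)
        perm = rng.permutation(L)
        a = token_profile(m, roles)[perm]
        b = token_profile(m[np.ix_(perm, perm)], roles)
        assert np.allclose(a, b)

    def test_column_direction_scores_received_attention(self, rng):
        m = _stochastic(rng, 1, 5)[0]
        roles = np.zeros(5, dtype=int)
        assert np.allclose(token_profile(m, roles, direction="column"),
                           m.mean(axis=0))


class TestBaseDecompose:
    def test_k1_identity(self, rng):
        scores = rng.random(10)
        assert np.allclose(base_decompose(scores, 1, 10), scores)

    def test_single_token_spreads_to_all_bases(self):
        out = base_decompose(np.array([0.7]), 6, 6)
        assert np.allclose(out, 0.7)

    def test_two_token_covering_arithmetic(self):
        a, b = 0.2, 0.8
        out = base_decompose(np.array([a, b]), 6, 7)
        assert out[0] == pytest.approx(a)
        assert out[6] == pytest.approx(b)
        assert np.allclose(out[1:6], (a + b) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            base_decompose(np.ones(5), 6, 12)


class TestNormalizeProfile:
    def test_constant_vector_maps_to_zero(self):
        assert np.allclose(normalize_profile(np.full(5, 2.0)), 0.0)

    def test_printed_formula_values(self):
        assert np.allclose(normalize_profile(np.array([1.0, 3.0])), [0, 2 / 3])
        assert np.allclose(normalize_profile(np.array([0.0, 4.0])), [0, 1])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile(np.zeros(4))

    def test_scale_invariance_and_argmin_zero(self, rng):
        raw = rng.random(30) + 0.1
        a = normalize_profile(raw)
        b = normalize_profile(raw * 7.3)
        assert np.allclose(a, b)
        assert a[raw.argmin()] == 0.0

    def test_minmax_peak_is_one(self, rng):
        raw = rng.random(30) + 0.1
        out = normalize_profile(raw, method="minmax")
        assert out.max() == pytest.approx(1.0)
        assert out.min() == pytest.approx(0.0)


class TestCallRegions:
    def test_all_below_threshold_empty(self):
        assert call_regions(np.full(20, 0.1)) == []

    def test_plateau_bounds(self):
        prof = np.zeros(30)
        prof[10:18] = 0.9  # 8-base plateau
        (r,) = call_regions(prof, threshold=0.5, min_len=6)
        assert (r.start, r.end) == (10, 18)
        assert r.peak == pytest.approx(0.9)

    def test_short_plateau_filtered(self):
        prof = np.zeros(30)
        prof[10:14] = 0.9
        assert call_regions(prof, threshold=0.5, min_len=6) == []

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_regions(np.zeros(5), threshold=1.5)


class TestEnrichment:
    def test_k_zero_gives_one(self):
        assert enrichment_pvalue(0, 5, 4, 10) == pytest.approx(1.0)

    def test_exhaustive_case_k4(self):
        # all 4 draws positive out of C(10,4): C(5,4)/C(10,4) = 5/210
        assert enrichment_pvalue(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_exhaustive_case_k2(self):
        assert enrichment_pvalue(2, 5, 4, 10) == pytest.approx(155 / 210, rel=1e-12)

    def test_monotone_in_k(self):
        ps = [enrichment_pvalue(k, 6, 5, 12) for k in range(6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_pvalue(5, 4, 4, 10)

    def test_matches_enumeration_small_grid(self):
        # independent oracle: enumerate every n-subset of N elements
        for N in (6, 8):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    for k in range(min(K, n) + 1):
                        hits = total = 0
                        for draw in itertools.combinations(range(N), n):
                            total += 1
                            if sum(1 for d in draw if d < K) >= k:
                                hits += 1
                        assert enrichment_pvalue(k, K, n, N) == pytest.approx(
                            hits / total, abs=1e-12)


def _region(seq, role="enhancer", record=0, start=0, peak_off=None):
    return HighAttentionRegion(role=role, start=start, end=start + len(seq),
                               peak=1.0, mean=0.8,
                               peak_offset=peak_off if peak_off is not None
                               else start + len(seq) // 2,
                               record=record, seq=seq)


class TestMotifDiscovery:
    def _planted_setup(self, rng, n_pos=40, n_neg=40, plant="GTCACGTA"):
        def bg(n):
            return "".join(rng.choice(list("ACGT"), n))
        pairs, labels, regions = [], [], []
        for i in range(n_pos + n_neg):
            label = 1 if i < n_pos else 0
            enh, prom = bg(80), bg(60)
            if label and rng.random() < 0.8:
                pos = 20
                enh = enh[:pos] + plant + enh[pos + len(plant):]
                regions.append(_region(enh[pos - 2 : pos + len(plant) + 2],
                                       record=i, start=pos - 2))
            pairs.append((enh, prom))
            labels.append(label)
        return pairs, labels, regions

    def test_planted_consensus_recovered(self, rng):
        plant = "GTCACGTA"
        pairs, labels, regions = self._planted_setup(rng, plant=plant)
        pwms, table = discover_motifs(regions, pairs, labels, p_cutoff=0.005)
        assert pwms, "no motifs reported"
        top = pwms[0]
        # consensus contains the plant within Hamming distance 1
        best = min(
            sum(a != b for a, b in zip(top.consensus[off : off + len(plant)], plant))
            for off in range(max(1, len(top.consensus) - len(plant) + 1))
        )
        assert best <= 1

    def test_identical_candidates_merge_with_summed_support(self):
        cands = [
            MotifCandidate("GTCACGTA", ["GTCACGTA"] * 3, [0, 1, 2], 3, 5, 3, 20, 1e-4),
            MotifCandidate("GTCACGTA", ["GTCACGTA"] * 2, [3, 4], 2, 5, 2, 20, 1e-3),
        ]
        pwms, assignment = merge_candidates(cands)
        assert len(pwms) == 1
        assert pwms[0].support == 5
        assert assignment == {0: 0, 1: 0}

    def test_substring_merges_into_anchor(self):
        cands = [
            MotifCandidate("GTCACGTAGG", ["GTCACGTAGG"] * 4, [0, 1, 2, 3], 4, 5, 4, 20, 1e-5),
            MotifCandidate("TCACGTA", ["TCACGTA"] * 2, [4, 5], 2, 5, 2, 20, 1e-3),
        ]
        pwms, assignment = merge_candidates(cands)
        assert len(pwms) == 1 and pwms[0].support == 6

    def test_disjoint_candidates_stay_separate(self):
        cands = [
            MotifCandidate("AAAAAAAA", ["AAAAAAAA"] * 3, [0, 1, 2], 3, 5, 3, 20, 1e-4),
            MotifCandidate("CCCCCCCC", ["CCCCCCCC"] * 2, [3, 4], 2, 5, 2, 20, 1e-3),
        ]
        pwms, _ = merge_candidates(cands)
        assert len(pwms) == 2

    def test_empty_region_set_gives_empty_result(self):
        pwms, table = discover_motifs([], [("ACGT" * 10, "TGCA" * 10)], [1])
        assert pwms == [] and len(table) == 0

    def test_shuffled_labels_give_no_motifs(self, rng):
        pairs, labels, regions = self._planted_setup(rng)
        shuffled = list(labels)
        rng.shuffle(shuffled)
        # keep only regions whose record is still positive under the shuffle
        kept = [r for r in regions if shuffled[r.record] == 1]
        pwms, _ = discover_motifs(kept, pairs, shuffled, p_cutoff=0.005)
        # enrichment against shuffled labels should not reach significance
        assert len(pwms) <= 1


class TestMemeFormat:
    def _pwm(self, rng, w=8):
        m = rng.random((w, 4))
        m = m / m.sum(axis=1, keepdims=True)
        consensus = "".join("ACGT"[i] for i in m.argmax(axis=1))
        return PWM(matrix=m, consensus=consensus, support=7)

    def test_roundtrip(self, rng, tmp_path):
        pwm = self._pwm(rng)
        path = tmp_path / "m.meme"
        export_meme([pwm], path)
        (back,) = read_meme(path)
        assert np.allclose(back.matrix, pwm.matrix, atol=1e-6)
        assert back.consensus == pwm.consensus
        assert back.support == 7

    def test_empty_list_is_valid_header_only(self):
        text = export_meme([])
        assert text.startswith("MEME version")
        assert "MOTIF" not in text
        assert read_meme(text + "\n") == []

    def test_consensus_matches_argmax(self, rng):
        pwm = self._pwm(rng)
        assert pwm.consensus == "".join("ACGT"[i] for i in pwm.matrix.argmax(axis=1))

    def test_bad_columns_rejected(self, rng):
        pwm = self._pwm(rng)
        pwm.matrix[0, 0] += 0.5
        with pytest.raises(ValueError):
            export_meme([pwm])


class TestPositionDensity:
    def test_empty_regions_zero_histogram(self):
        counts, _ = position_density([], 100, bins=10)
        assert counts.sum() == 0

    def test_single_peaked_bin_at_tss_offset(self):
        # promoter TSS sits 1,500 bases in; all midpoints there -> one bin
        regions = [_region("ACGTACGT", role="promoter", start=1496)
                   for _ in range(9)]
        counts, edges = position_density(regions, 2000, bins=20, role="promoter")
        assert counts.max() == 9
        assert (counts > 0).sum() == 1
        peak_bin = counts.argmax()
        assert edges[peak_bin] <= 1500 < edges[peak_bin + 1]

    def test_count_conservation(self, rng):
        regions = [_region("ACGTAC", start=int(rng.integers(0, 90)))
                   for _ in range(25)]
        counts, _ = position_density(regions, 100, bins=7)
        assert counts.sum() == 25


class TestCommonSpecific:
    def test_recurrent_motif_is_common(self, rng):
        plant = "GTCACGTACG"
        pairs, labels, regions = [], [], []
        for i in range(30):
            enh = "".join(rng.choice(list("ACGT"), 60))
            if i < 20:
                enh = enh[:10] + plant + enh[10 + len(plant):]
                regions.append(_region(plant, record=i, start=10))
            pairs.append((enh, "".join(rng.choice(list("ACGT"), 40))))
            labels.append(1 if i < 20 else 0)
        out, per_seq = classify_common_specific(regions, pairs, labels,
                                                min_support=3)
        assert out and all(lbl == "common" for lbl in out)
        assert per_seq["common"].sum() == len(regions)

    def test_singleton_regions_are_specific(self, rng):
        pairs = [("".join(rng.choice(list("ACGT"), 60)),
                  "".join(rng.choice(list("ACGT"), 40))) for _ in range(10)]
        labels = [1] * 5 + [0] * 5
        regions = [_region(pairs[i][0][5:15], record=i, start=5) for i in range(5)]
        out, _ = classify_common_specific(regions, pairs, labels, min_support=3)
        assert all(lbl == "specific" for lbl in out)


class TestKmerPairs:
    def _toy(self, vocab):
        enh = "AAAAAA" + "ACGTAC"
        prom = "CCCCCC" + "TGCATG"
        tok = assemble_pair(enh, prom, vocab)
        L = len(tok)
        avg = np.full((L, L), 1.0 / L)
        # enhancer token 0 is AAAAAA at position 1; promoter CCCCCC at sep+1
        avg[1, tok.sep_index + 1] = 5.0
        avg = avg / avg.sum(axis=1, keepdims=True)
        return avg, tok

    def test_dominant_pair_flagged_exclusive(self, vocab):
        avg, tok = self._toy(vocab)
        pos = count_kmer_pairs(avg, tok, vocab)
        neg = Counter()
        table = summarize_kmer_pairs(pos, neg, top_m=10)
        row = table.iloc[0]
        assert (row.kmer_a, row.kmer_b) == ("AAAAAA", "CCCCCC")
        assert row.exclusive_to_pos

    def test_identical_statistics_give_no_exclusive_pairs(self, vocab):
        avg, tok = self._toy(vocab)
        c = count_kmer_pairs(avg, tok, vocab)
        table = summarize_kmer_pairs(c, Counter(c), top_m=10)
        assert not table.exclusive_to_pos.any()

    def test_counts_invariant_to_record_order(self, vocab):
        avg, tok = self._toy(vocab)
        a = count_kmer_pairs(avg, tok, vocab) + count_kmer_pairs(avg, tok, vocab)
        b = count_kmer_pairs(avg, tok, vocab) + count_kmer_pairs(avg, tok, vocab)
        assert a == b

    def test_nonpositive_threshold_rejected(self, vocab):
        avg, tok = self._toy(vocab)
        with pytest.raises(ValueError):
            count_kmer_pairs(avg, tok, vocab, threshold=0.0)

    def test_cross_segment_cells_only(self, vocab):
        avg, tok = self._toy(vocab)
        # boost a same-segment cell far above threshold
        avg = avg.copy()
        avg[1, 2] = 0.9
        counts = count_kmer_pairs(avg, tok, vocab)
        for (a, b) in counts:
            assert a != "CLS" and b != "SEP"
        # the boosted enh->enh cell must not appear
        assert ("AAAAAA", "AAAAAC") not in counts
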