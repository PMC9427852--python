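import itertools
from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from conftest import random_pwm
from tntseq import (PositionWeightMatrix, co_occurrence, enrich,
                    load_motif_compendium, normalize_and_filter,
                    occurrence_table, scan_pwm, scan_utrs)
from tntseq.motifs import (UNIFORM_BACKGROUND, demo_compendium, hits_to_frame,
                           score_distribution, score_pvalue,
                           write_motif_compendium)

MINIMAL_MEME = """MEME version 4

ALPHABET= ACGU

Background letter frequencies
A 0.25 C 0.25 G 0.25 U 0.25

MOTIF M1 RBP_A
letter-probability matrix: alphabet= ACGU w= 2 nsites= 20 E= 0
 0.970000 0.010000 0.010000 0.010000
 0.010000 0.010000 0.010000 0.970000

MOTIF M2 RBP_B
letter-probability matrix: alphabet= ACGU w= 3 nsites= 20 E= 0
 0.250000 0.250000 0.250000 0.250000
 0.970000 0.010000 0.010000 0.010000
 0.010000 0.970000 0.010000 0.010000
"""


class TestMemeParsing:
    def test_parse_two_motifs_with_exact_probabilities(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MINIMAL_MEME)
        pwms = load_motif_compendium(path)
        assert [p.motif_id for p in pwms] == ["M1", "M2"]
        assert pwms[0].rbp_name == "RBP_A"
        assert pwms[0].probabilities[0, 0] == pytest.approx(0.97, abs=1e-6)
        assert pwms[1].length == 3

    def test_unnormalised_row_is_renormalised(self, tmp_path, caplog):
        bad = MINIMAL_MEME.replace(" 0.970000 0.010000 0.010000 0.010000\n",
                                   " 0.870000 0.010000 0.010000 0.010000\n", 1)
        path = tmp_path / "bad.meme"
        path.write_text(bad)
        with caplog.at_level("WARNING"):
            pwms = load_motif_compendium(path)
        assert "renormalising" in caplog.text
        np.testing.assert_allclose(pwms[0].probabilities.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_duplicate_id_and_malformed_record_error(self, tmp_path):
        path = tmp_path / "dup.meme"
        path.write_text(MINIMAL_MEME.replace("MOTIF M2 RBP_B", "MOTIF M1 RBP_B"))
        with pytest.raises(ValueError, match="duplicate"):
            load_motif_compendium(path)
        path2 = tmp_path / "mal.meme"
        path2.write_text("MEME version 4\n\nMOTIF MX\nno matrix here\n")
        with pytest.raises(ValueError, match="MX"):
            load_motif_compendium(path2)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.meme"
        path.write_text("MEME version 4\n")
        assert load_motif_compendium(path) == []

    def test_roundtrip_and_demo_compendium(self, tmp_path):
        pwms = demo_compendium()
        assert len(pwms) >= 5
        out = tmp_path / "roundtrip.meme"
        write_motif_compendium(pwms, out)
        back = load_motif_compendium(out)
        np.testing.assert_allclose(back[0].probabilities, pwms[0].probabilities,
                                   atol=1e-5)


class TestScanPwm:
    def test_single_letter_motif(self):
        pwm = PositionWeightMatrix("m", "x", np.array([[1.0, 0, 0, 0]]))
        (hit,) = scan_pwm("A", pwm, pvalue_threshold=1.0)
        assert hit.raw_score == pytest.approx(2.0)
        assert hit.score_pvalue == pytest.approx(0.25)
        assert hit.start == 0 and hit.end == 1

    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = PositionWeightMatrix("m", "x", np.full((3, 4), 0.25))
        hits = scan_pwm("ACGUACGU", pwm, pvalue_threshold=1.1)
        assert len(hits) == 6
        assert all(h.raw_score == pytest.approx(0.0) for h in hits)

    def test_planted_consensus_is_recovered(self):
        rng = np.random.default_rng(77)
        pwm = PositionWeightMatrix(
            "m", "x", np.array([[0.94, 0.02, 0.02, 0.02],
                                [0.02, 0.94, 0.02, 0.02],
                                [0.02, 0.02, 0.94, 0.02]]))
        seq = list(rng.choice(list("ACGU"), size=50))
        seq[17:20] = list("ACG")
        hits = scan_pwm("".join(seq), pwm, pvalue_threshold=0.05)
        assert 17 in {h.start for h in hits}

    def test_short_sequence_and_n_windows(self):
        pwm = random_pwm(4, seed=1)
        assert scan_pwm("ACG", pwm) == []
        # N every 4th base: every length-4 window covers one and is skipped
        assert scan_pwm("ANGU" * 5, pwm, pvalue_threshold=1.1) == []
        # with the N-free tail appended, only windows inside the tail remain
        hits = scan_pwm("ANGU" * 5 + "ACGUACGU", pwm, pvalue_threshold=1.1)
        assert {h.start for h in hits} == set(range(18, 25))

    def test_position_covariance_under_prefix(self):
        pwm = random_pwm(5, seed=2)
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGU"), size=60))
        base = scan_pwm(seq, pwm, pvalue_threshold=0.5)
        shifted = scan_pwm("ACGU" + seq, pwm, pvalue_threshold=0.5)
        shifted_starts = {h.start for h in shifted if h.start >= 4}
        assert {h.start + 4 for h in base} <= shifted_starts

    def test_t_and_u_equivalent(self):
        pwm = random_pwm(4, seed=4)
        a = scan_pwm("ACGUACGUAA", pwm, pvalue_threshold=1.1)
        b = scan_pwm("acgtacgtaa", pwm, pvalue_threshold=1.1)
        assert [(h.start, h.raw_score) for h in a] == \
            [(h.start, h.raw_score) for h in b]


class TestExactScorePvalues:
    """DP p-values equal exhaustive enumeration over all 4^L windows."""

    @pytest.mark.parametrize("length,seed", [(1, 10), (2, 11), (3, 12),
                                             (5, 13), (8, 14)])
    @pytest.mark.parametrize("background", [UNIFORM_BACKGROUND,
                                            (0.3, 0.2, 0.2, 0.3)])
    def test_dp_matches_enumeration(self, length, seed, background):
        pwm = random_pwm(length, seed)
        int_scores, lo, tail = score_distribution(pwm, background)
        bg = np.array(background)
        dist = defaultdict(float)
        for word in itertools.product(range(4), repeat=length):
            s = sum(int(int_scores[i, b]) for i, b in enumerate(word))
            dist[s] += float(np.prod(bg[list(word)]))
        for s in sorted(dist):
            enum_tail = sum(v for k, v in dist.items() if k >= s)
            assert abs(score_pvalue(s, lo, tail) - min(enum_tail, 1.0)) < 1e-6


class TestNormalizeAndFilter:
    def _hits(self, pwm, seq):
        return hits_to_frame(scan_pwm(seq, pwm, pvalue_threshold=1.1,
                                      gene_id="g"))

    def test_extreme_scores_map_to_unit_interval(self):
        pwm = PositionWeightMatrix(
            "m", "x", np.array([[0.94, 0.02, 0.02, 0.02],
                                [0.94, 0.02, 0.02, 0.02]]))
        hits = self._hits(pwm, "AACC")
        by_start = hits.set_index("start")
        assert by_start.loc[0, "normalized_score"] == pytest.approx(1.0)
        assert by_start.loc[2, "normalized_score"] == pytest.approx(0.0)
        kept = normalize_and_filter(hits, 0.8)
        assert list(kept["start"]) == [0]

    def test_zero_threshold_is_identity(self):
        pwm = random_pwm(3, seed=20)
        hits = self._hits(pwm, "ACGUACGUACGU")
        assert len(normalize_and_filter(hits, 0.0)) == len(hits)

    def test_degenerate_pwm_dropped(self, caplog):
        pwm = PositionWeightMatrix("m", "x", np.full((2, 4), 0.25))
        hits = self._hits(pwm, "ACGU")
        with caplog.at_level("WARNING"):
            kept = normalize_and_filter(hits, 0.5)
        assert len(kept) == 0
        assert "degenerate" in caplog.text

    def test_normalized_score_monotone_in_raw_score(self):
        pwm = random_pwm(4, seed=21)
        hits = self._hits(pwm, "ACGUAGCUAGGCUAUGCAU")
        h = hits.sort_values("raw_score")
        assert h["normalized_score"].is_monotonic_increasing


class TestOccurrenceAndEnrichment:
    def _toy_hits(self):
        rows = []
        for gene, rbp, n in [("g1", "X", 3), ("g2", "X", 1), ("g1", "Y", 1)]:
            for i in range(n):
                rows.append(dict(gene_id=gene, motif_id=f"m{rbp}",
                                 rbp_name=rbp, start=i * 10, end=i * 10 + 5,
                                 raw_score=1.0, score_pvalue=1e-5,
                                 normalized_score=0.9))
        return pd.DataFrame(rows)

    def test_counting_and_per_kb(self):
        hits = self._toy_hits()
        occ = occurrence_table(hits, ["g1", "g2", "g3"])
        assert occ.loc["g1", "X"] == 3 and occ.loc["g3", "X"] == 0
        occ_kb = occurrence_table(hits, ["g1"], {"g1": 1500}, per_kb=True)
        assert occ_kb.loc["g1", "X"] == pytest.approx(2.0)

    def test_genes_without_utr_are_excluded(self):
        occ = occurrence_table(self._toy_hits(), ["g1", "g9"], {"g1": 100})
        assert list(occ.index) == ["g1"]

    def test_identical_groups_not_significant(self):
        occ = pd.DataFrame({"X": [3.0] * 8},
                           index=[f"g{i}" for i in range(8)])
        res = enrich([f"g{i}" for i in range(4)],
                     [f"g{i}" for i in range(4, 8)], occ)
        assert res.loc["X", "log2_fold_change"] == pytest.approx(0.0)
        assert res.loc["X", "p_value"] == 1.0
        assert not res.loc["X", "significant"]

    def test_target_background_swap_negates_lfc(self):
        rng = np.random.default_rng(30)
        genes = [f"g{i}" for i in range(40)]
        occ = pd.DataFrame({"X": rng.poisson(3.0, 40).astype(float)},
                           index=genes)
        fwd = enrich(genes[:20], genes[20:], occ)
        rev = enrich(genes[20:], genes[:20], occ)
        assert fwd.loc["X", "log2_fold_change"] == pytest.approx(
            -rev.loc["X", "log2_fold_change"])

    def test_overlapping_groups_error(self):
        occ = pd.DataFrame({"X": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="disjoint"):
            enrich(["a", "b"], ["b", "c"], occ)


class TestCoOccurrence:
    def _hits_for(self, pattern_by_gene):
        rows = []
        for gene, rbps in pattern_by_gene.items():
            for rbp in rbps:
                rows.append(dict(gene_id=gene, motif_id=f"m_{rbp}",
                                 rbp_name=rbp, start=0, end=5, raw_score=1.0,
                                 score_pvalue=1e-5, normalized_score=0.9))
        return pd.DataFrame(rows)

    def test_pairwise_intersections(self):
        hits = self._hits_for({"g1": ["A"], "g2": ["B"], "g3": ["A", "B"]})
        counts = co_occurrence(hits, ["A", "B"])
        assert counts[("A", "B")] == 1
        assert counts[("A",)] == 2 and counts[("B",)] == 2

    def test_all_five_rbps_fixture(self):
        five = ["R1", "R2", "R3", "R4", "R5"]
        genes = {f"full{i}": list(five) for i in range(4)}
        genes.update({f"partial{i}": five[:4] for i in range(7)})
        counts = co_occurrence(self._hits_for(genes), five)
        assert counts[tuple(five)] == 4
        assert counts[tuple(five[:4])] == 11
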