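"""Score ingestion, masked-marginal log-odds, window matching, normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from famvar.errors import DataError, DegenerateRangeError
from famvar.scoring import (EsmQuery, EveEntry, assemble_score_matrix,
                            esm_masked_marginal, esm_window,
                            frequency_stratum_comparison, match_eve_record,
                            minmax_normalize, normalize_model_scores,
                            pairwise_model_correlation, sequence_window)

from conftest import make_variant

SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"


class TestEveWindowMatch:
    def test_unique_match_returns_score(self):
        v = make_variant("v", [], wt=SEQ[29], position=30, mut="W")
        entry = EveEntry("P1", SEQ, scores={(30, "W"): 0.77},
                         source={(30, "W"): "direct"})
        score, src = match_eve_record(v, SEQ, entry)
        assert score == 0.77 and src == "direct"

    def test_offset_numbering_resolved_by_window(self):
        # database sequence has 10 extra N-terminal residues: the window
        # match must translate the variant position accordingly
        db = "XXXXXXXXXX" + SEQ
        v = make_variant("v", [], wt=SEQ[29], position=30, mut="W")
        entry = EveEntry("P1", db, scores={(40, "W"): 0.5},
                         source={(40, "W"): "knn-imputed"})
        score, src = match_eve_record(v, SEQ, entry)
        assert score == 0.5 and src == "knn-imputed"

    def test_ambiguous_window_absent_with_log(self):
        rep = "ABCDEFGHIJKLMNO"
        db = rep + rep  # every window occurs twice
        v = make_variant("v", [], wt=rep[7], position=8, mut="W")
        log = []
        score, src = match_eve_record(v, rep, EveEntry("P1", db), log=log)
        assert score is None and src == "absent"
        assert any("ambiguous" in m for m in log)

    def test_no_match_absent(self):
        v = make_variant("v", [], wt=SEQ[29], position=30, mut="W")
        log = []
        score, _ = match_eve_record(v, SEQ, EveEntry("P1", "AAAA"), log=log)
        assert score is None and log

    def test_wt_mismatch_logged(self):
        v = make_variant("v", [], wt="W", position=30, mut="A")
        assert SEQ[29] != "W"
        log = []
        score, _ = match_eve_record(v, SEQ, EveEntry("P1", SEQ), log=log)
        assert score is None and "mismatch" in log[0]

    @pytest.mark.parametrize("position", [1, 2, 3, len(SEQ) - 1, len(SEQ)])
    def test_clipped_window_matches_brute_force_scan(self, position):
        # independent oracle: brute-force substring scan over every start
        window, offset = sequence_window(SEQ, position)
        starts = [i for i in range(len(SEQ)) if SEQ[i:i + len(window)] == window]
        assert SEQ[position - 1] == window[offset]
        assert (position - 1 - offset) in starts
        assert len(window) <= 11
        if position <= 5:
            assert offset == position - 1  # clipped on the left


class TestTableReaders:
    def test_eve_table_with_fasta_sequences(self, tmp_path):
        from famvar.scoring import read_eve_table
        (tmp_path / "seqs.fasta").write_text(f">P1\n{SEQ}\n")
        (tmp_path / "eve.tsv").write_text(
            "protein_accession\tposition\tmut_aa\tscore\tsource\n"
            "P1\t30\tW\t0.66\tknn-imputed\n"
            "P1\t30\tA\t0.10\tdirect\n")
        entries = read_eve_table(tmp_path / "eve.tsv", tmp_path / "seqs.fasta")
        assert entries["P1"].sequence == SEQ
        v = make_variant("v", [], wt=SEQ[29], position=30, mut="W")
        score, src = match_eve_record(v, SEQ, entries["P1"])
        assert score == 0.66 and src == "knn-imputed"

    def test_logprob_table_feeds_masked_marginal(self, tmp_path):
        from famvar.scoring import read_logprob_table
        (tmp_path / "lp.tsv").write_text(
            "position\tamino_acid\tlogp\n5\tY\t-1.0\n5\tC\t-3.0\n")
        table = read_logprob_table(tmp_path / "lp.tsv")
        q = EsmQuery(sequence="MKTAYIAKQR", position_in_window=5, wt_aa="Y",
                     mut_aa="C", logp_wt=table[5]["Y"], logp_mut=table[5]["C"])
        assert esm_masked_marginal(q) == pytest.approx(-2.0)

    def test_per_variant_scores_skip_blanks(self, tmp_path):
        from famvar.scoring import read_per_variant_scores
        (tmp_path / "s.tsv").write_text("variant_id\tscore\nv1\t-5.5\nv2\t\n")
        assert read_per_variant_scores(tmp_path / "s.tsv") == {"v1": -5.5}


class TestEsmWindow:
    def test_short_sequence_passthrough(self):
        seq = "A" * 900
        out, idx = esm_window(seq, 450)
        assert out == seq and idx == 450

    @pytest.mark.parametrize("n,pos", [(1500, 10), (2000, 1000), (1500, 1495),
                                       (1023, 512), (5000, 1)])
    def test_long_sequence_window_contains_variant(self, n, pos):
        rng = np.random.default_rng(n + pos)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
        out, idx = esm_window(seq, pos)
        assert len(out) == 1022
        assert out in seq                       # window is a real subsequence
        assert out[idx - 1] == seq[pos - 1]     # index points at same residue
        if 512 <= pos <= n - 511:
            assert abs(idx - 511) <= 1          # centred when not clipped

    def test_out_of_bounds(self):
        with pytest.raises(DataError):
            esm_window("AAA", 4)


class TestMaskedMarginal:
    @pytest.mark.parametrize("lp_mut,lp_wt,expected", [
        (-3.0, -1.0, -2.0), (-1.0, -1.0, 0.0), (-0.5, -2.3, 1.8)])
    def test_log_odds(self, lp_mut, lp_wt, expected):
        q = EsmQuery(sequence="ACDEF", position_in_window=3, wt_aa="D",
                     mut_aa="W", logp_wt=lp_wt, logp_mut=lp_mut)
        assert esm_masked_marginal(q) == pytest.approx(expected)

    @given(lp_a=hst.floats(min_value=-20, max_value=0),
           lp_b=hst.floats(min_value=-20, max_value=0))
    def test_antisymmetric_under_wt_mut_swap(self, lp_a, lp_b):
        fwd = EsmQuery("ACDEF", 3, "D", "W", logp_wt=lp_a, logp_mut=lp_b)
        rev = EsmQuery("ACDEF", 3, "W", "D", logp_wt=lp_b, logp_mut=lp_a)
        assert esm_masked_marginal(fwd) == -esm_masked_marginal(rev)


class TestMinMaxNormalize:
    def test_higher_is_pathogenic(self):
        normed, stats = minmax_normalize([1, 2, 3], "higher_is_pathogenic")
        assert normed.tolist() == [0.0, 0.5, 1.0]
        assert (stats.min, stats.max, stats.n) == (1.0, 3.0, 3)

    def test_lower_is_pathogenic_flips(self):
        normed, _ = minmax_normalize([-2, 0], "lower_is_pathogenic")
        assert normed.tolist() == [1.0, 0.0]

    def test_degenerate_range(self):
        with pytest.raises(DegenerateRangeError):
            minmax_normalize([5, 5, 5], "higher_is_pathogenic")

    @given(raw=hst.lists(hst.floats(min_value=-100, max_value=100), min_size=2,
                         max_size=30).filter(lambda xs: len(set(xs)) >= 2))
    def test_range_and_rank_preservation(self, raw):
        up, _ = minmax_normalize(raw, "higher_is_pathogenic")
        down, _ = minmax_normalize(raw, "lower_is_pathogenic")
        assert up.min() == 0.0 and up.max() == 1.0
        assert np.all((0 <= up) & (up <= 1))
        order = np.argsort(raw, kind="stable")
        assert np.all(np.diff(up[order]) >= 0)    # rank preserved
        assert np.all(np.diff(down[order]) <= 0)  # orientation flips ranks


class TestScoreMatrix:
    def variants(self):
        return [make_variant(v, [("famA", "A1")]) for v in ("a", "b", "c")]

    def test_indicators_and_eligibility(self):
        normalized = {"EVE": {"a": 0.5, "b": 0.2}, "ESM": {"a": 0.9},
                      "FIRM": {"b": 0.1}}
        recs = {r.variant_id: r
                for r in assemble_score_matrix(self.variants(), normalized)}
        assert recs["a"].indicator == {"EVE": 1, "ESM": 1, "FIRM": 0}
        assert recs["a"].M == 2 and recs["a"].dsrank_eligible
        assert recs["b"].M == 2 and recs["b"].dsrank_eligible
        assert recs["c"].M == 0 and not recs["c"].dsrank_eligible

    def test_single_model_ineligible(self):
        recs = assemble_score_matrix(self.variants(), {"FIRM": {"a": 0.9}})
        rec = next(r for r in recs if r.variant_id == "a")
        assert rec.M == 1 and not rec.dsrank_eligible

    def test_unknown_variant_is_data_error(self):
        with pytest.raises(DataError, match="unknown variants"):
            assemble_score_matrix(self.variants(), {"EVE": {"zzz": 0.5}})

    def test_indicator_sum_conserves_ingested_counts(self, rng):
        variants = [make_variant(f"v{i}", [("famA", "A1")]) for i in range(50)]
        normalized = {
            m: {f"v{i}": float(rng.random()) for i in rng.choice(50, size=n, replace=False)}
            for m, n in (("EVE", 41), ("ESM", 48), ("FIRM", 36))}
        recs = assemble_score_matrix(variants, normalized)
        for m, n in (("EVE", 41), ("ESM", 48), ("FIRM", 36)):
            assert sum(r.indicator[m] for r in recs) == n


class TestPairwiseCorrelation:
    def test_identical_vectors(self, rng):
        vals = {f"v{i}": float(rng.random()) for i in range(20)}
        variants = [make_variant(v, [("famA", "A1")]) for v in vals]
        recs = assemble_score_matrix(variants, {"EVE": vals, "ESM": dict(vals)})
        corr = {(c.model_a, c.model_b): c for c in pairwise_model_correlation(recs)}
        assert corr[("EVE", "ESM")].r == pytest.approx(1.0)
        assert corr[("EVE", "ESM")].n == 20

    def test_reverse_affine_anticorrelated(self, rng):
        vals = {f"v{i}": float(rng.random()) for i in range(20)}
        flipped = {k: 1.0 - 0.5 * v for k, v in vals.items()}
        variants = [make_variant(v, [("famA", "A1")]) for v in vals]
        recs = assemble_score_matrix(variants, {"EVE": vals, "FIRM": flipped})
        corr = {(c.model_a, c.model_b): c for c in pairwise_model_correlation(recs)}
        assert corr[("EVE", "FIRM")].r == pytest.approx(-1.0)

    def test_insufficient_data(self):
        variants = [make_variant("a", [("famA", "A1")]),
                    make_variant("b", [("famA", "A1")])]
        recs = assemble_score_matrix(
            variants, {"EVE": {"a": 0.1, "b": 0.2}, "ESM": {"a": 0.3, "b": 0.4}})
        corr = pairwise_model_correlation(recs)
        assert all(c.r is None and "insufficient" in c.note for c in corr)

    def test_copula_pair_recovers_target_r(self, rng):
        # bivariate normal with r=0.5 at n=1000: estimate within +/- 0.1
        n, target = 1000, 0.5
        z = rng.multivariate_normal([0, 0], [[1, target], [target, 1]], size=n)
        eve = {f"v{i}": float(x) for i, x in enumerate(z[:, 0])}
        esm = {f"v{i}": float(-x) for i, x in enumerate(z[:, 1])}  # flipped raw
        variants = [make_variant(v, [("famA", "A1")]) for v in eve]
        normalized, _ = normalize_model_scores({"EVE": eve, "ESM": esm})
        recs = assemble_score_matrix(variants, normalized)
        corr = {(c.model_a, c.model_b): c for c in pairwise_model_correlation(recs)}
        assert corr[("EVE", "ESM")].r == pytest.approx(target, abs=0.1)


class TestFrequencyStrata:
    def build(self, rng, shift):
        variants, raw = [], {"ESM": {}}
        for i in range(400):
            af = 0.005 if i < 200 else 0.015
            vid = f"v{i}"
            variants.append(make_variant(vid, [("famA", "A1")], pop_af=af))
            raw["ESM"][vid] = float(rng.normal(-6.0 + (shift if i >= 200 else 0.0), 1.0))
        return variants, raw

    def test_null_case(self, rng):
        variants, raw = self.build(rng, shift=0.0)
        res = {c.model: c for c in frequency_stratum_comparison(variants, raw)}
        c = res["ESM"]
        assert abs(c.mean_low - c.mean_high) < 0.3 and c.p > 0.01

    def test_shift_detected(self, rng):
        variants, raw = self.build(rng, shift=1.0)
        c = {c.model: c for c in frequency_stratum_comparison(variants, raw)}["ESM"]
        assert c.mean_high - c.mean_low == pytest.approx(1.0, abs=0.35)
        assert c.p < 1e-3
        assert c.n_low == 200 and c.n_high == 200

    def test_empty_stratum(self):
        variants = [make_variant("a", [("famA", "A1")], pop_af=0.005)]
        res = frequency_stratum_comparison(variants, {"ESM": {"a": -5.0}})
        c = {c.model: c for c in res}["ESM"]
        assert c.p is None and c.note == "empty stratum"

    def test_mannwhitney_option(self, rng):
        variants, raw = self.build(rng, shift=1.0)
        c = {c.model: c for c in frequency_stratum_comparison(
            variants, raw, test="mannwhitney")}["ESM"]
        assert c.p < 1e-3 and c.test == "mannwhitney"
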