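"""Conservation scores and the A/B/C step logic, against brute-force
oracles and hand-traced alignment fixtures."""

import numpy as np
import pytest

from startalign.seqmodel import ScoringConfig, StartCandidate
from startalign.start_select import (
    block_conservation_score,
    candidate_score_s5,
    find_leftmost_conserved_block,
    intergenic_conservation_dc,
    overlap_stats_for_records,
    predict_start,
    step_a,
    step_b,
    step_c,
)
from conftest import (
    brute_block_score,
    brute_dc,
    brute_s5,
    build_columns,
    msa_from_codons,
    noise_column,
    random_dual_msa,
)

CFG = ScoringConfig()


class TestBlockScore:
    def test_identical_rows_reach_printed_maximum(self):
        # 11 identical rows over a 10-codon block: S = N/(N-1) = 1.1
        rows = [["GCT"] * 10 for _ in range(11)]
        msa = msa_from_codons(rows)
        blk = block_conservation_score(msa, 0, 10, CFG)
        assert blk.score == pytest.approx(11 / 10)
        assert blk.conserved

    def test_pair_count_normalization_caps_at_one(self):
        rows = [["GCT"] * 10 for _ in range(11)]
        msa = msa_from_codons(rows)
        cfg = CFG.replace(blk_norm="pair_count")
        assert block_conservation_score(msa, 0, 10, cfg).score == pytest.approx(1.0)

    def test_pairwise_distinct_rows_score_zero(self):
        cols = [noise_column(6) for _ in range(10)]
        msa = msa_from_codons(build_columns(cols))
        assert block_conservation_score(msa, 0, 10, CFG).score == 0.0

    def test_not_evaluable_near_three_prime_end(self):
        rows = [["GCT"] * 5 for _ in range(4)]
        msa = msa_from_codons(rows)
        assert block_conservation_score(msa, 0, 10, CFG) is None

    def test_matches_brute_force_on_random_msas(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            n, L = int(rng.integers(2, 7)), int(rng.integers(5, 12))
            msa = random_dual_msa(rng, n, L)
            r = int(rng.integers(1, 5))
            col = int(rng.integers(0, L))
            got = block_conservation_score(msa, col, r, CFG)
            want = brute_block_score(msa.aa_rows, 0, col, r)
            if want is None:
                assert got is None
            else:
                assert got.score == pytest.approx(want)


class TestLeftmostBlock:
    def _exhaustive(self, msa, cfg):
        for c in msa.query_ungapped_cols():
            s = brute_block_score(msa.aa_rows, 0, c, cfg.block_len_aa)
            if s is None:
                return None
            if s > cfg.t_blk:
                return c
        return None

    def test_conserved_region_found_against_exhaustive_scan(self):
        n = 6
        cols = [noise_column(n) for _ in range(12)] + [["GCT"] * n for _ in range(12)]
        msa = msa_from_codons(build_columns(cols))
        blk = find_leftmost_conserved_block(msa, CFG)
        assert blk.aa_col == self._exhaustive(msa, CFG)

    def test_fully_random_msa_has_no_conserved_block(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            msa = random_dual_msa(rng, 8, 25, gap_prob=0.1, start_codon_prob=0.05)
            blk = find_leftmost_conserved_block(msa, CFG)
            assert (blk is None) == (self._exhaustive(msa, CFG) is None)
            if blk is not None:  # pragma: no cover - rare under the null
                assert blk.aa_col == self._exhaustive(msa, CFG)

    def test_conservation_from_column_zero(self):
        msa = msa_from_codons([["GCT"] * 12 for _ in range(5)])
        assert find_leftmost_conserved_block(msa, CFG).aa_col == 0


class TestCandidateScore:
    def _candidate(self, msa, aa_col):
        off = 3 * msa.col_maps[0][aa_col]
        return StartCandidate(
            seq_offset=off, codon=msa.query.codon(off), msa_column=3 * aa_col
        )

    def test_support_fraction(self):
        # 10 targets: 8 with ATG at the column, 2 rows gapped there
        cols = [noise_column(11), ["ATG"] * 9 + ["CAT", "CAT"], noise_column(11)]
        rows = build_columns(cols)
        for r in (9, 10):
            rows[r] = [rows[r][0], None, rows[r][2]]
        # build with explicit gaps via aa-row surgery
        from startalign.msa_layer import backmap_to_nucleotide
        from startalign.seqmodel import LorfRecord

        records, aa_rows = [], []
        for i, row in enumerate(rows):
            nt = "".join(c for c in row if c) + "TAA"
            rec = LorfRecord(id=f"r{i}", nt=nt)
            records.append(rec)
            aa = "".join(
                "-" if c is None else rec.aa[sum(x is not None for x in row[:j])]
                for j, c in enumerate(row)
            )
            aa_rows.append(aa)
        msa = backmap_to_nucleotide(aa_rows, records)
        sc = candidate_score_s5(msa, self._candidate(msa, 1), CFG)
        assert sc.s5 == pytest.approx(0.8)
        assert (sc.n_support, sc.n_penalty) == (8, 0)

    def test_synonymous_nonstart_penalty(self):
        # 8 supporting targets, 1 with GTT (non-start valine), 1 neutral
        center = ["ATG"] * 9 + ["GTT", "GCT"]
        cols = [noise_column(11), center, noise_column(11)]
        msa = msa_from_codons(build_columns(cols))
        sc = candidate_score_s5(msa, self._candidate(msa, 1), CFG)
        assert sc.s5 == pytest.approx((8 - 1) / 10)
        assert (sc.n_support, sc.n_penalty) == (8, 1)

    def test_rows_without_coverage_contribute_nothing(self):
        from startalign.msa_layer import backmap_to_nucleotide
        from startalign.seqmodel import LorfRecord

        q = LorfRecord(id="q", nt="ATGGCTCATTAA")
        t = LorfRecord(id="t", nt="CATTAA")
        msa = backmap_to_nucleotide(["MAH", "--H"], [q, t])
        sc = candidate_score_s5(msa, self._candidate(msa, 0), CFG)
        assert sc.s5 == 0.0

    def test_matches_brute_force_on_random_msas(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            n, L = int(rng.integers(2, 8)), int(rng.integers(5, 15))
            msa = random_dual_msa(rng, n, L)
            aa_col = int(rng.choice(msa.query_ungapped_cols()))
            got = candidate_score_s5(msa, self._candidate(msa, aa_col), CFG)
            want = brute_s5(msa.nt_rows, 0, 3 * aa_col, CFG.neigh_codons)
            assert got.s5 == pytest.approx(want)


class TestIntergenicConservation:
    def test_uniform_overlap_is_fully_conserved(self):
        st = intergenic_conservation_dc([-4] * 8, f=0)
        assert (st.mode_x, st.dc) == (-4, 1.0)

    def test_hand_counted_example(self):
        d = [-4, -4, -4, -1, -1, 7, 0, -4, -4, 2]
        st = intergenic_conservation_dc(d, f=3)
        assert st.mode_x == -4
        # five -4s and two -1s lie in [-7, -1]
        assert st.dc == pytest.approx(0.7)

    def test_margin_zero_is_mode_frequency(self):
        d = [-4, -4, -1, 3]
        st = intergenic_conservation_dc(d, f=0)
        assert st.dc == pytest.approx(0.5)

    def test_mode_ties_resolve_to_smallest_abs_then_most_negative(self):
        assert intergenic_conservation_dc([-4, -4, 1, 1], f=0).mode_x == 1
        assert intergenic_conservation_dc([-1, -1, 1, 1], f=0).mode_x == -1

    def test_dc_nondecreasing_in_margin(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            d = rng.integers(-10, 10, size=int(rng.integers(1, 15))).tolist()
            vals = [intergenic_conservation_dc(d, f).dc for f in range(8)]
            assert vals == sorted(vals)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            d = rng.integers(-12, 12, size=int(rng.integers(1, 20))).tolist()
            f = int(rng.integers(0, 6))
            st = intergenic_conservation_dc(d, f)
            assert (st.mode_x, st.dc) == brute_dc(d, f)


# ---------------------------------------------------------------------------
# Step-logic traces on hand-constructed alignments
#
# Layout used below (4 rows, query = row 0): columns 0..9 are pairwise
# distinct (zero identity), a fully conserved region follows.  With N=4
# an r=10 window needs >= 4 conserved columns to clear t_blk = 0.5, so
# the leftmost conserved block anchors at column 4.

N_ROWS = 4


def _trace_msa(extra_query_starts=(), conserved_from=10, n_cols=26):
    cols = []
    for c in range(n_cols):
        if c < conserved_from:
            col = noise_column(N_ROWS)
        else:
            col = ["GCT"] * N_ROWS
        cols.append(col)
    rows = build_columns(cols)
    for c, codon in extra_query_starts:
        rows[0][c] = codon
    return msa_from_codons(rows)


class TestStepA:
    def test_single_upstream_candidate_is_predicted(self):
        msa = _trace_msa(extra_query_starts=[(2, "ATG")])
        pred = step_a(msa, CFG)
        assert pred is not None and pred.step == "A"
        assert pred.query_offset == 6
        assert pred.scores["block_aa_col"] == 4

    def test_two_upstream_candidates_fall_through(self):
        msa = _trace_msa(extra_query_starts=[(0, "GTG"), (2, "ATG")])
        assert step_a(msa, CFG) is None

    def test_no_conserved_block_falls_through(self):
        cols = [noise_column(N_ROWS) for _ in range(26)]
        rows = build_columns(cols)
        rows[0][2] = "ATG"
        assert step_a(msa_from_codons(rows), CFG) is None

    def test_start_inside_block_is_not_upstream(self):
        # candidate at the block anchor itself does not satisfy step A
        msa = _trace_msa(extra_query_starts=[(4, "ATG")])
        assert step_a(msa, CFG) is None


def _overlap_msa(support=N_ROWS - 1, cand_col=4, cand="ATG"):
    """Candidate at a fixed column with `support` targets carrying ATG."""
    cols = []
    for c in range(20):
        if c == cand_col:
            cols.append([cand] + ["ATG"] * support + ["GCT"] * (N_ROWS - 1 - support))
        else:
            cols.append(noise_column(N_ROWS))
    return msa_from_codons(build_columns(cols))


class TestStepB:
    def test_conserved_overlap_candidate_predicted(self):
        msa = _overlap_msa(support=3)
        # upstream gene 3' end 4 nt downstream of the candidate (-4 overlap)
        pred = step_b(msa, upstream_gene_end_offset=3 * 4 + 4, cfg=CFG)
        assert pred is not None and pred.step == "B"
        assert pred.query_offset == 12
        assert pred.scores["s5"] == pytest.approx(1.0)

    def test_weak_candidate_falls_through(self):
        msa = _overlap_msa(support=1)  # s5 = 1/3 < 0.5
        assert step_b(msa, upstream_gene_end_offset=16, cfg=CFG) is None

    def test_no_candidate_within_nine_nt_falls_through(self):
        msa = _overlap_msa(support=3)
        assert step_b(msa, upstream_gene_end_offset=40, cfg=CFG) is None

    def test_tie_resolves_to_most_upstream(self):
        cols = []
        for c in range(20):
            if c in (3, 5):
                cols.append(["ATG"] * N_ROWS)
            else:
                cols.append(noise_column(N_ROWS))
        msa = msa_from_codons(build_columns(cols))
        pred = step_b(msa, upstream_gene_end_offset=13, cfg=CFG)
        assert pred.query_offset == 9  # both score 1.0; 5'-most wins


class TestStepC:
    def test_single_strong_candidate_predicted(self):
        msa = _overlap_msa(support=3)  # lone ATG column, s5 = 1
        pred = step_c(msa, CFG)
        assert pred.step == "C" and pred.query_offset == 12

    def test_weak_candidates_decline_prediction(self):
        msa = _overlap_msa(support=1)
        pred = step_c(msa, CFG)
        assert pred.step == "none" and pred.query_offset is None
        assert pred.reason == "no_candidate_above_threshold"

    def _c2_msa(self, protected: bool):
        # u at column 4 (s5 = 2/3), d at column 8 (s5 = 1), 30 nt apart? 12 nt.
        cols = []
        for c in range(24):
            if c == 4:
                cols.append(["ATG", "ATG", "ATG", "GCT"])
            elif c == 8:
                cols.append(["ATG"] * 4)
            elif protected and c in (6, 7):
                cols.append(["CCT"] * 4)  # conserved 2-codon block between
            else:
                cols.append(noise_column(N_ROWS))
        return msa_from_codons(build_columns(cols))

    def test_downstream_switch_without_separating_block(self):
        pred = step_c(self._c2_msa(protected=False), CFG)
        assert pred.step == "C" and pred.query_offset == 24
        assert pred.scores["s5"] == pytest.approx(1.0)

    def test_block_between_protects_upstream_candidate(self):
        pred = step_c(self._c2_msa(protected=True), CFG)
        assert pred.step == "C" and pred.query_offset == 12
        assert "s5_downstream" in pred.scores

    def test_downstream_candidate_beyond_window_ignored(self):
        cols = []
        for c in range(30):
            if c == 2:
                cols.append(["ATG", "ATG", "ATG", "GCT"])
            elif c == 14:  # 36 nt downstream of u: outside the 30 nt window
                cols.append(["ATG"] * 4)
            else:
                cols.append(noise_column(N_ROWS))
        pred = step_c(msa_from_codons(build_columns(cols)), CFG)
        assert pred.query_offset == 6


class TestPredictStartDispatch:
    def test_too_few_targets_declines(self, plain_family):
        from startalign.msa_layer import GoldAligner, backmap_to_nucleotide, build_protein_msa

        recs = [plain_family.query] + [t for t in plain_family.targets[:5]]
        rows = build_protein_msa(recs, GoldAligner(plain_family.gold_aa))
        msa = backmap_to_nucleotide(rows, recs)
        pred = predict_start(msa, None, CFG)
        assert pred.step == "none" and pred.reason == "too_few_targets"

    def test_overlap_context_routes_to_step_b(self):
        cfg = CFG.replace(min_targets=3)
        msa = _overlap_msa(support=3)
        pred = predict_start(msa, upstream_gene_end_offset=16, cfg=cfg)
        assert pred.step == "B"

    def test_no_context_routes_to_a_then_c(self):
        cfg = CFG.replace(min_targets=3)
        msa = _trace_msa(extra_query_starts=[(2, "ATG")])
        assert predict_start(msa, None, cfg).step == "A"
        # two upstream candidates, the second supported by every target:
        # step A falls through, step C selects it
        cols = []
        for c in range(26):
            if c == 2:
                cols.append(["ATG"] * N_ROWS)
            elif c >= 10:
                cols.append(["GCT"] * N_ROWS)
            else:
                cols.append(noise_column(N_ROWS))
        rows = build_columns(cols)
        rows[0][0] = "GTG"
        pred = predict_start(msa_from_codons(rows), None, cfg)
        assert pred.step == "C" and pred.query_offset == 6

    def test_distant_upstream_gene_does_not_trigger_b(self):
        cfg = CFG.replace(min_targets=3)
        msa = _trace_msa(extra_query_starts=[(2, "ATG")])
        # 3' end 50 nt upstream of the LORF: not an overlap configuration
        assert predict_start(msa, upstream_gene_end_offset=-50, cfg=cfg).step == "A"

    def test_prediction_is_always_a_listed_candidate(self, family_msa, plain_family):
        from startalign.seqmodel import list_start_candidates

        pred = predict_start(family_msa, None, CFG)
        offsets = {c.seq_offset for c in list_start_candidates(plain_family.query)}
        assert pred.query_offset in offsets


def test_overlap_stats_from_records(overlap_family):
    st = overlap_stats_for_records(overlap_family.targets, f=3)
    assert st.mode_x == pytest.approx(-4, abs=1)
    assert st.dc >= 0.9
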