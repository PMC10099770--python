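import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dock1433.core_data import (
    CandidateSite,
    DataError,
    Dataset,
    LabeledSite,
    ObservationTable,
    ProteinRecord,
)
from dock1433.features import (
    DEFAULT_OFFSETS,
    SENTINEL,
    assemble_features,
    build_pssm,
    builtin_disorder,
    compute_ptm_score,
    extract_window,
    ingest_disorder,
    ingest_sequence_scores,
    score_pssm,
    uniform_background,
)
from Bio.SeqUtils.ProtParamData import kd


class TestPtmScore:
    def test_fraction_of_protein_total(self):
        t = ObservationTable.from_records([("P", 2, "S", 5), ("P", 4, "T", 15)])
        assert compute_ptm_score(CandidateSite("P", 2, "S", 5), t) == 0.25

    def test_only_observed_site_scores_one(self):
        t = ObservationTable.from_records([("P", 2, "S", 7)])
        assert compute_ptm_score(CandidateSite("P", 2, "S", 7), t) == 1.0

    def test_unobserved_site_scores_zero(self):
        t = ObservationTable.from_records([("P", 2, "S", 7)])
        assert compute_ptm_score(CandidateSite("P", 4, "T", 0), t) == 0.0
        assert compute_ptm_score(CandidateSite("Q", 1, "S", 0), ObservationTable()) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=12)
    )
    def test_scores_sum_to_one_over_observed_sites(self, counts):
        rows = [("P", 2 * i + 1, "S", c) for i, c in enumerate(counts)]
        t = ObservationTable.from_records(rows)
        total = sum(
            compute_ptm_score(CandidateSite("P", pos, "S", c), t)
            for _, pos, _, c in rows
        )
        assert abs(total - 1.0) < 1e-9

    def test_increasing_count_increases_own_share_decreases_others(self):
        t1 = ObservationTable.from_records([("P", 1, "S", 5), ("P", 3, "S", 5)])
        t2 = ObservationTable.from_records([("P", 1, "S", 9), ("P", 3, "S", 5)])
        s1 = compute_ptm_score(CandidateSite("P", 1, "S", 5), t1)
        s2 = compute_ptm_score(CandidateSite("P", 1, "S", 9), t2)
        o1 = compute_ptm_score(CandidateSite("P", 3, "S", 5), t1)
        o2 = compute_ptm_score(CandidateSite("P", 3, "S", 5), t2)
        assert s2 > s1 and o2 < o1


class TestExtractWindow:
    def test_out_of_range_offsets_are_sentinel(self):
        win = extract_window("MRSXSP", 5, (-3, 2))
        assert win == "R" + SENTINEL  # +2 runs past the C-terminus

    def test_interior_site_all_real(self):
        win = extract_window("ARNDCSQGHI", 6, DEFAULT_OFFSETS)
        assert SENTINEL not in win
        assert win == "ARNDC" + "QGHI"

    def test_unknown_residue_is_sentinel(self):
        assert extract_window("MRSXSP", 5, (-1,)) == SENTINEL

    def test_offsets_never_include_the_site_itself(self):
        assert 0 not in DEFAULT_OFFSETS


def brute_force_cell(windows, j, letter, background, pseudocount):
    """Independent log-odds computation straight from the counting formula."""
    real = [w[j] for w in windows if w[j] != SENTINEL]
    count = Counter(real)[letter]
    n = len(real)
    freq = (count + pseudocount * background[letter]) / (n + pseudocount)
    return math.log2(freq / background[letter])


class TestBuildPssm:
    def test_conserved_position_approaches_inverse_background(self):
        windows = ["RA", "RA", "RA", "RA"]
        model = build_pssm(windows, pseudocount=1e-9, offsets=(-3, 2))
        assert model.cell(-3, "R") == pytest.approx(math.log2(20), abs=1e-6)

    def test_absent_letter_finite_negative_with_pseudocount(self):
        model = build_pssm(["RA", "RA"], pseudocount=1.0, offsets=(-3, 2))
        cell = model.cell(-3, "W")
        assert cell < 0 and math.isfinite(cell)

    def test_cells_match_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            offsets = (-2, -1, 1)
            n = int(rng.integers(2, 8))
            windows = [
                "".join(rng.choice(list(letters), size=len(offsets)))
                for _ in range(n)
            ]
            pc = float(rng.uniform(0.1, 3.0))
            model = build_pssm(windows, pseudocount=pc, offsets=offsets)
            bg = uniform_background()
            for j in range(len(offsets)):
                for letter in "ARNW":
                    expected = brute_force_cell(windows, j, letter, bg, pc)
                    assert model.cell(offsets[j], letter) == pytest.approx(expected)

    def test_empty_positives_rejected(self):
        with pytest.raises(DataError, match="zero positive"):
            build_pssm([])

    def test_mismatched_window_width_rejected(self):
        with pytest.raises(DataError, match="width"):
            build_pssm(["RA", "RAA"], offsets=(-3, 2))


class TestScorePssm:
    def test_score_is_sum_of_cells(self):
        model = build_pssm(["RAP", "RSP", "RNP"], offsets=(-3, -1, 2))
        seq = "AARQRAPAA"
        pos = 5
        win = extract_window(seq, pos, model.offsets)
        expected = sum(
            model.cell(off, a)
            for off, a in zip(model.offsets, win)
            if a != SENTINEL
        )
        assert score_pssm(model, seq, pos) == pytest.approx(expected)

    def test_terminal_site_all_sentinel_scores_zero(self):
        model = build_pssm(["RA"], offsets=(-3, 2))
        assert score_pssm(model, "SA", 1) == 0.0  # -3 and +2 both out of range

    def test_invariant_to_sequence_outside_window(self):
        model = build_pssm(["RAPG", "RNPG"], offsets=(-3, -1, 1, 2))
        core = "AARQSAPAA"
        assert score_pssm(model, core, 5) == pytest.approx(
            score_pssm(model, "WWWW" + core + "HHHH", 9)
        )


class TestBuiltinDisorder:
    def test_charged_low_hydropathy_limit(self):
        profile = builtin_disorder("E" * 60)
        assert profile[30] > 0.5

    def test_hydrophobic_limit(self):
        profile = builtin_disorder("I" * 60)
        assert profile[30] < 0.5

    def test_profile_matches_closed_form_at_a_residue(self):
        seq = "MKRSEEDLLIVANNAGGSPQRST" * 3
        half = 25
        i = 33
        profile = builtin_disorder(seq, half_window=half)
        window = seq[max(0, i - half): i + half + 1]
        mean_h = np.mean([(kd[a] + 4.5) / 9.0 for a in window])
        charge = {"K": 1, "R": 1, "D": -1, "E": -1}
        mean_q = np.mean([charge.get(a, 0) for a in window])
        foldindex = 2.785 * mean_h - abs(mean_q) - 1.151
        assert profile[i] == pytest.approx(1 / (1 + math.exp(10 * foldindex)))

    def test_translation_invariance_in_interior(self):
        block = "MKRSEEDLLIVANNAGG"
        seq = block * 6
        profile = builtin_disorder(seq)
        # same local window => same score, anywhere in the deep interior
        assert profile[40] == pytest.approx(profile[40 + len(block)])

    def test_bounded_in_unit_interval(self):
        profile = builtin_disorder("MKRSEEDLLIVANNAGGSPQRST")
        assert (profile >= 0).all() and (profile <= 1).all()


class TestIngestion:
    def test_complete_disorder_profile(self, tmp_path):
        p = tmp_path / "dis.tsv"
        p.write_text(
            "protein_id\tposition\tscore\n"
            + "".join(f"P\t{i}\t0.{i}\n" for i in range(1, 5))
        )
        prof = ingest_disorder(p, {"P": ProteinRecord("P", "MSTA")})
        assert len(prof["P"]) == 4

    def test_incomplete_profile_rejected(self, tmp_path):
        p = tmp_path / "dis.tsv"
        p.write_text("protein_id\tposition\tscore\nP\t1\t0.5\nP\t2\t0.5\nP\t4\t0.5\n")
        with pytest.raises(DataError, match="incomplete"):
            ingest_disorder(p, {"P": ProteinRecord("P", "MSTA")})

    def test_out_of_range_score_rejected(self, tmp_path):
        p = tmp_path / "dis.tsv"
        p.write_text("protein_id\tposition\tscore\nP\t1\t1.2\n")
        with pytest.raises(DataError, match="outside"):
            ingest_disorder(p, {"P": ProteinRecord("P", "M")})

    def test_sequence_scores_retrievable(self, tmp_path):
        p = tmp_path / "seq.tsv"
        p.write_text("protein_id\tposition\tann\tsvm\tpssm\nP1\t2\t0.3\t0.4\t0.5\n")
        assert ingest_sequence_scores(p)[("P1", 2)] == (0.3, 0.4, 0.5)

    def test_empty_file_gives_empty_mapping(self, tmp_path):
        p = tmp_path / "seq.tsv"
        p.write_text("protein_id\tposition\tann\tsvm\tpssm\n")
        assert ingest_sequence_scores(p) == {}

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "seq.tsv"
        p.write_text(
            "protein_id\tposition\tann\tsvm\tpssm\n"
            "P1\t2\t0.3\t0.4\t0.5\nP1\t2\t0.1\t0.1\t0.1\n"
        )
        with pytest.raises(DataError, match="duplicate"):
            ingest_sequence_scores(p)


class TestAssembleFeatures:
    def _dataset(self):
        proteins = {"P": ProteinRecord("P", "MRRQSAPAATAAAAAAAAAA")}
        table = ObservationTable.from_records([("P", 5, "S", 6), ("P", 10, "T", 2)])
        return Dataset(proteins, table, [LabeledSite("P", 5, 1)])

    def test_builtin_fallback_replicates_pssm_into_all_three_slots(self):
        feats = assemble_features(self._dataset())
        assert (feats["ann"] == feats["svm"]).all()
        assert (feats["svm"] == feats["pssm"]).all()
        assert feats["builtin_seq"].all()

    def test_external_scores_override_fallback(self):
        ds = self._dataset()
        ds.seqscores = {("P", 5): (0.1, 0.2, 0.3)}
        feats = assemble_features(ds)
        row = feats[feats["position"] == 5].iloc[0]
        assert (row["ann"], row["svm"], row["pssm"]) == (0.1, 0.2, 0.3)
        assert not row["builtin_seq"]
        assert feats[feats["position"] == 10].iloc[0]["builtin_seq"]

    def test_unobserved_site_flagged_missing_ptm(self):
        feats = assemble_features(self._dataset())
        unobserved = feats[feats["n_obs"] == 0]
        assert unobserved["missing_ptm"].all()
        assert (unobserved["ptm_score"] == 0.0).all()
        observed = feats[feats["n_obs"] > 0]
        assert not observed["missing_ptm"].any()

    def test_missing_external_disorder_profile_is_error(self):
        ds = self._dataset()
        ds.disorder = {}  # external source mandated but protein not covered
        with pytest.raises(DataError, match="no disorder profile"):
            assemble_features(ds)

    def test_external_disorder_used_when_present(self):
        ds = self._dataset()
        ds.disorder = {"P": np.full(20, 0.77)}
        feats = assemble_features(ds)
        assert (feats["disorder"] == 0.77).all()
        assert not feats["builtin_disorder"].any()
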