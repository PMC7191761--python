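import numpy as np
import pytest

from cypome import identify
from cypome.identify import (
    AA_ORDER,
    build_profile,
    calibrate,
    consensus_sequence,
    decoy_scores,
    estimate_evalue,
    identify_cyps,
    load_profile,
    save_profile,
    scan_sequence,
)
from cypome.seqio import ProteinRecord
from cypome.synth import SynthConfig, generate_genomes

from _oracles import scan_all_windows


@pytest.fixture(scope="module")
def fixture_profile(reference):
    return build_profile(reference.domain_alignment, name="CYP_domain")


@pytest.fixture(scope="module")
def fixture_calibration(fixture_profile):
    return calibrate(fixture_profile, n_decoys=500, decoy_length=400, seed=7)


class TestBuildProfile:
    def test_two_identical_sequences(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        p = build_profile([seq, seq], name="t")
        assert p.length == 20
        for j, aa in enumerate(seq):
            assert np.argmax(p.scores[j]) == AA_ORDER.index(aa)

    def test_majority_gap_column_dropped(self):
        p = build_profile(["AC-DEFGHIKL", "AC-DEFGHIKL", "ACWDEFGHIKL"], name="t")
        assert p.length == 10

    def test_consensus_scores_at_least_any_input(self, fixture_profile, reference):
        cons = consensus_sequence(fixture_profile)
        cons_score, _, _ = scan_sequence(cons, fixture_profile)
        for seq in reference.domain_alignment[:5]:
            s, _, _ = scan_sequence(seq.replace("-", ""), fixture_profile)
            assert cons_score >= s

    def test_too_few_sequences_error(self):
        with pytest.raises(ValueError):
            build_profile(["ACD"], name="t")

    def test_all_gap_columns_error(self):
        with pytest.raises(ValueError):
            build_profile(["---", "---"], name="t")


class TestScanSequence:
    def test_consensus_hits_at_start(self, fixture_profile):
        cons = consensus_sequence(fixture_profile)
        score, start, end = scan_sequence(cons, fixture_profile)
        assert (start, end) == (1, fixture_profile.length)
        assert score == pytest.approx(fixture_profile.scores.max(axis=1).sum())

    def test_x_scores_zero(self, fixture_profile):
        q = "X" * fixture_profile.length
        score, _, _ = scan_sequence(q, fixture_profile)
        assert score == pytest.approx(0.0)

    def test_short_query_is_no_hit(self, fixture_profile):
        score, start, end = scan_sequence("MKL", fixture_profile)
        assert score == float("-inf") and (start, end) == (0, 0)

    def test_matches_all_window_oracle_on_decoy(self, fixture_profile):
        rng = np.random.default_rng(123)
        query = "".join(rng.choice(list(AA_ORDER), 200))
        got = scan_sequence(query, fixture_profile)
        exp = scan_all_windows(query, fixture_profile.scores, AA_ORDER)
        assert got[0] == pytest.approx(exp[0])
        assert got[1:] == exp[1:]

    def test_embedded_consensus_found_at_position(self, fixture_profile):
        rng = np.random.default_rng(5)
        cons = consensus_sequence(fixture_profile)
        flank = "".join(rng.choice(list(AA_ORDER), 50))
        score, start, end = scan_sequence(flank + cons + flank, fixture_profile)
        assert start == 51 and end == 50 + fixture_profile.length


class TestEvalue:
    def test_monotone_decreasing_in_score(self, fixture_profile, fixture_calibration):
        es = [
            estimate_evalue(s, fixture_profile, 400, 60, fixture_calibration)
            for s in (10.0, 50.0, 100.0, 200.0)
        ]
        assert es == sorted(es, reverse=True)
        assert es[-1] < 1e-10  # large scores drive E towards 0

    def test_linear_in_database_size(self, fixture_profile, fixture_calibration):
        e1 = estimate_evalue(80.0, fixture_profile, 400, 60, fixture_calibration)
        e2 = estimate_evalue(80.0, fixture_profile, 400, 120, fixture_calibration)
        assert e2 == pytest.approx(2 * e1)

    def test_missing_calibration_errors(self, fixture_profile):
        with pytest.raises(ValueError, match="calibrat"):
            estimate_evalue(80.0, fixture_profile, 400, 60, None)

    def test_gumbel_tail_tracks_holdout_decoys(self, fixture_profile, fixture_calibration):
        """Above the 95th percentile, the fitted tail is within 3x of the
        empirical exceedance fraction of a held-out decoy set."""
        rng = np.random.default_rng(7777)
        holdout = decoy_scores(fixture_profile, 500, 400, rng)
        cal = fixture_calibration
        for q in (0.95, 0.97, 0.99):
            s = np.quantile(holdout, q)
            empirical = np.mean(holdout >= s)
            fitted = cal.k * cal.decoy_length * fixture_profile.length * np.exp(-cal.lam * s)
            assert fitted / empirical < 3.0 and empirical / fitted < 3.0


class TestIdentifyCyps:
    def test_empty_centroids(self, fixture_profile, fixture_calibration):
        assert identify_cyps([], [fixture_profile], {"CYP_domain": fixture_calibration}) == []

    def test_zero_cutoff_rejects_everything(self, fixture_profile, fixture_calibration, reference):
        recs = [
            ProteinRecord(id="r", genome_id="g", sequence=reference.refs[0].sequence)
        ]
        hits = identify_cyps(
            recs, [fixture_profile], {"CYP_domain": fixture_calibration}, evalue_cutoff=0.0
        )
        assert hits == []

    def test_truth_separation_on_fixture(
        self, fixture_profile, fixture_calibration, reference, default_config
    ):
        """Every true CYP passes at E ≤ 1e-5 and no decoy comes close."""
        rng = np.random.default_rng(99)
        genomes, manifest = generate_genomes(
            default_config, reference, genome_prefix="idg", rng=rng
        )
        records = [r for g in genomes[:2] for r in g.records]
        truth = {
            f"{row.genome}|{row.seq_id}": row.is_cyp
            for row in manifest.itertuples()
        }
        cals = {"CYP_domain": fixture_calibration}
        hits = identify_cyps(records, [fixture_profile], cals, evalue_cutoff=1e-5)
        hit_ids = {h.query for h in hits}
        true_ids = {r.tagged_id for r in records if truth[r.tagged_id]}
        decoy_ids = {r.tagged_id for r in records if not truth[r.tagged_id]}
        assert hit_ids == true_ids
        assert not (hit_ids & decoy_ids)
        # engineered margin: every true hit at least 1e3 below the cutoff,
        # every decoy at least 1e3 above it
        all_hits = identify_cyps(records, [fixture_profile], cals, evalue_cutoff=float("inf"))
        for h in all_hits:
            if h.query in true_ids:
                assert h.evalue <= 1e-5 / 1e3
            else:
                assert h.evalue >= 1e-5 * 1e3

    def test_order_invariance(self, fixture_profile, fixture_calibration, reference):
        recs = [
            ProteinRecord(id=r.cyp_name, genome_id="ref", sequence=r.sequence)
            for r in reference.refs[:6]
        ]
        cals = {"CYP_domain": fixture_calibration}
        fwd = identify_cyps(recs, [fixture_profile], cals)
        rev = identify_cyps(recs[::-1], [fixture_profile], cals)
        assert {h.query: h.evalue for h in fwd} == {h.query: h.evalue for h in rev}

    def test_cutoff_monotonicity(self, fixture_profile, fixture_calibration, reference):
        recs = [
            ProteinRecord(id=r.cyp_name, genome_id="ref", sequence=r.sequence)
            for r in reference.refs[:6]
        ]
        cals = {"CYP_domain": fixture_calibration}
        strict = {h.query for h in identify_cyps(recs, [fixture_profile], cals, 1e-30)}
        loose = {h.query for h in identify_cyps(recs, [fixture_profile], cals, 1e-5)}
        assert strict <= loose


def test_profile_round_trip(tmp_path, fixture_profile):
    save_profile(fixture_profile, tmp_path / "p.tsv")
    loaded = load_profile(tmp_path / "p.tsv")
    assert loaded.name == fixture_profile.name
    np.testing.assert_allclose(loaded.scores, fixture_profile.scores, atol=1e-4)
    np.testing.assert_allclose(loaded.background, fixture_profile.background, atol=1e-6)
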