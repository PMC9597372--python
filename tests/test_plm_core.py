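import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plmkit as pk
from plmkit.genomic_io import FIVE_PRIME, THREE_PRIME, ProximalRegionSet
from plmkit.plm_core import (
    GROUP_SCHEMES,
    PositionalDistribution,
    default_neutral_interval,
    detect_plm,
    fit_neutral_model,
    motif_code,
    positional_distribution,
)


def make_regions(seqs, upstream=0, side=FIVE_PRIME):
    length = len(seqs[0])
    return ProximalRegionSet(
        side=side, upstream_extent=upstream,
        downstream_extent=length - upstream - 1,
        records=[(f"g{i}", s) for i, s in enumerate(seqs)],
    )


class TestCatalog:
    @pytest.mark.parametrize("kmin,kmax,expected", [(1, 1, 4), (2, 2, 16), (1, 3, 84)])
    def test_catalog_sizes(self, kmin, kmax, expected):
        assert len(pk.enumerate_kmers(kmin, kmax)) == expected

    def test_catalog_is_lexicographic_and_unique(self):
        cat = pk.enumerate_kmers(2, 3)
        for k in (2, 3):
            stratum = cat.by_length(k)
            assert list(stratum) == sorted(set(stratum))
            assert len(stratum) == 4 ** k

    def test_code_matches_catalog_index(self):
        cat = pk.enumerate_kmers(3, 3)
        for i in (0, 17, 63):
            assert motif_code(cat.motifs[i]) == i

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            pk.enumerate_kmers(0, 3)
        with pytest.raises(ValueError):
            pk.enumerate_kmers(5, 4)


class TestTally:
    def test_overlapping_occurrences_counted(self):
        regions = make_regions(["ATATAT"])
        tal = pk.tally_all(regions, pk.enumerate_kmers(3, 3))
        ata = tal.distribution("ATA")
        tat = tal.distribution("TAT")
        assert ata.counts.tolist() == [1, 0, 1, 0]
        assert tat.counts.tolist() == [0, 1, 0, 1]

    def test_aligned_plants_stack_counts(self):
        seq = "A" * 50
        seq = seq[:15] + "TGCGGT" + seq[21:]
        regions = make_regions([seq] * 3, upstream=35)
        tal = pk.tally_all(regions, pk.enumerate_kmers(6, 6))
        d = tal.distribution("TGCGGT")
        assert d.count_at(15 - 35) == 3

    def test_n_masks_overlapping_kmers_only(self):
        regions = make_regions(["ACGNTACG"])
        tal = pk.tally_all(regions, pk.enumerate_kmers(3, 3))
        total_per_offset = sum(
            tal.tables[3][motif_code(m)] for m in pk.enumerate_kmers(3, 3).motifs
        )
        # windows starting at 1,2,3 contain the N
        assert total_per_offset.tolist() == [1, 0, 0, 0, 1, 1]

    def test_conservation_full_length_stratum(self, planted_regions):
        regions, _ = planted_regions
        tal = pk.tally_all(regions, pk.enumerate_kmers(2, 2))
        column_sums = tal.tables[2].sum(axis=0)
        assert (column_sums == regions.n_sequences).all()  # no Ns planted
        assert (tal.tables[2] <= regions.n_sequences).all()

    def test_single_motif_shortcut_matches_full_tally(self, planted_regions):
        regions, _ = planted_regions
        tal = pk.tally_all(regions, pk.enumerate_kmers(6, 6))
        d_full = tal.distribution("TATAAA")
        d_one = positional_distribution(regions, "TATAAA")
        assert np.array_equal(d_full.counts, d_one.counts)
        assert np.array_equal(d_full.offsets, d_one.offsets)


class TestNeutralFit:
    def _dist(self, counts, upstream=0):
        counts = np.asarray(counts)
        return PositionalDistribution(
            motif="AAAA", side=FIVE_PRIME,
            offsets=np.arange(-upstream, len(counts) - upstream),
            counts=counts, n_sequences=int(counts.max(initial=1)),
        )

    def test_constant_counts_give_flat_fit(self):
        fit = fit_neutral_model(self._dist([7] * 20), (0, 19))
        assert fit.slope == pytest.approx(0.0)
        assert fit.intercept == pytest.approx(7.0)
        assert fit.residual_sd == pytest.approx(0.0)

    def test_exact_line_recovered(self):
        x = np.arange(30)
        fit = fit_neutral_model(self._dist(3 + 2 * x), (0, 29))
        assert fit.intercept == pytest.approx(3.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_poisson_counts_match_closed_form_ols(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(5, size=500)
        fit = fit_neutral_model(self._dist(counts, upstream=500), (-500, -1))
        x = np.arange(-500, 0).astype(float)
        slope_o, intercept_o = np.polyfit(x, counts.astype(float), 1)
        rss = ((counts - intercept_o - slope_o * x) ** 2).sum()
        assert fit.slope == pytest.approx(slope_o, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept_o, abs=1e-9)
        assert fit.residual_sd == pytest.approx(np.sqrt(rss / 498), abs=1e-9)
        # slope of pure noise is itself statistically null
        se = fit.residual_sd / np.sqrt(fit.sxx)
        assert abs(fit.slope) < 3 * se

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_neutral_model(self._dist([1, 2, 3]), (0, 1))


class TestBand:
    def test_zero_residual_band_equals_fit(self):
        fit = pk.NeutralFit(intercept=4.0, slope=0.5, residual_sd=0.0,
                            n_points=10, mean_x=4.5, sxx=82.5,
                            neutral_interval=(0, 9))
        assert pk.band_upper(fit, 20) == pytest.approx(4.0 + 0.5 * 20)

    def test_band_width_minimal_at_mean_offset(self):
        fit = pk.NeutralFit(intercept=10.0, slope=0.0, residual_sd=2.0,
                            n_points=500, mean_x=-750.0, sxx=1e7,
                            neutral_interval=(-1000, -501))
        offsets = np.arange(-1000, -400)
        widths = pk.band_upper(fit, offsets) - fit.predict(offsets)
        assert offsets[np.argmin(widths)] == -750

    def test_band_equals_hand_computed_formula(self):
        from scipy import stats

        fit = pk.NeutralFit(intercept=10.0, slope=0.0, residual_sd=2.0,
                            n_points=500, mean_x=-750.0, sxx=1.04e7,
                            neutral_interval=(-1000, -501))
        offset = -35
        t = stats.t.ppf(0.995, 498)
        expected = 10.0 + t * 2.0 * np.sqrt(1 + 1 / 500 + (offset + 750.0) ** 2 / 1.04e7)
        assert pk.band_upper(fit, offset) == pytest.approx(expected, abs=1e-12)

    def test_invalid_confidence_rejected(self):
        fit = pk.NeutralFit(1, 0, 1, 10, 0, 10, (0, 9))
        with pytest.raises(ValueError):
            pk.band_upper(fit, 0, confidence=0.4)


def oracle_detect(dist, fit, study, confidence):
    """Brute-force re-derivation of the exceedance set, peak, window, score."""
    exceed = {}
    for off, cnt in zip(dist.offsets, dist.counts):
        if study[0] <= off <= study[1]:
            ub = pk.band_upper(fit, int(off), confidence)
            if cnt > ub:
                exceed[int(off)] = float(cnt - ub)
    if not exceed:
        return None
    best = max(exceed.values())
    pp = min(o for o, d in exceed.items() if d == best)
    lo = pp
    while lo - 1 in exceed:
        lo -= 1
    hi = pp
    while hi + 1 in exceed:
        hi += 1
    return pp, (lo, hi), exceed[pp]


class TestDetect:
    def _flat_fit(self, intercept, sd, neutral=(-100, -51)):
        return pk.NeutralFit(intercept=intercept, slope=0.0, residual_sd=sd,
                             n_points=50, mean_x=(neutral[0] + neutral[1]) / 2,
                             sxx=float(((np.arange(*neutral) - np.mean(np.arange(*neutral))) ** 2).sum()),
                             neutral_interval=neutral)

    def test_counts_inside_band_yield_none(self):
        dist = PositionalDistribution("ACGT", FIVE_PRIME, np.arange(-100, 50),
                                      np.full(150, 10), 40)
        fit = self._flat_fit(10.0, 2.0)
        assert detect_plm(dist, fit, (-50, 49)) is None

    def test_single_spike_called_with_derived_score(self):
        counts = np.full(150, 10)
        counts[np.where(np.arange(-100, 50) == -35)[0][0]] = 40
        dist = PositionalDistribution("ACGT", FIVE_PRIME, np.arange(-100, 50),
                                      counts, 40)
        fit = self._flat_fit(10.0, 0.5)
        rec = detect_plm(dist, fit, (-50, 49))
        assert rec.preferential_position == -35
        assert rec.functional_window == (-35, -35)
        assert rec.score == pytest.approx(40 - pk.band_upper(fit, -35))

    def test_overlapping_study_interval_rejected(self):
        dist = PositionalDistribution("ACGT", FIVE_PRIME, np.arange(-100, 50),
                                      np.full(150, 10), 40)
        with pytest.raises(ValueError):
            detect_plm(dist, self._flat_fit(10.0, 1.0), (-60, 49))

    def test_agrees_with_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            counts = rng.poisson(8, size=150)
            counts[rng.integers(60, 150)] += rng.integers(0, 15)
            dist = PositionalDistribution("ACGT", FIVE_PRIME,
                                          np.arange(-100, 50), counts, 60)
            fit = fit_neutral_model(dist, (-100, -51))
            got = detect_plm(dist, fit, (-50, 49))
            want = oracle_detect(dist, fit, (-50, 49), 0.99)
            if want is None:
                assert got is None
            else:
                assert (got.preferential_position, got.functional_window) == want[:2]
                assert got.score == pytest.approx(want[2], abs=1e-9)

    def test_planted_motif_recovered_from_synthetic_truth(self, planted_regions):
        regions, _ = planted_regions
        dist = positional_distribution(regions, "TATAAA")
        fit = fit_neutral_model(dist, default_neutral_interval(300, 100))
        rec = detect_plm(dist, fit, (-200, 95))
        assert rec is not None and rec.score > 2
        assert -37 <= rec.preferential_position <= -33


class TestSelectionAndSummaries:
    def _rec(self, motif="ACGT", score=5.0, pp=-35, window=None):
        return pk.PLMRecord(motif=motif, side=FIVE_PRIME,
                            preferential_position=pp,
                            functional_window=window or (pp, pp), score=score,
                            gene_set=frozenset({"g"}))

    def test_score_filter_is_strict(self):
        kept = pk.select_by_score([self._rec(score=2.01), self._rec(score=2.0)])
        assert [p.score for p in kept] == [2.01]
        assert pk.select_by_score([]) == []

    def test_gene_set_only_counts_in_window_occurrences(self):
        regions = make_regions(["TATAAACC", "CCCCTATA", "GGGGGGGG"], upstream=4)
        plm = self._rec(motif="TATA", pp=-4, window=(-4, -4))
        assert pk.plm_gene_set(regions, plm) == {"g0"}
        whole = self._rec(motif="TATA", pp=0, window=(-4, 3))
        assert pk.plm_gene_set(regions, whole) == {"g0", "g1"}
        assert pk.plm_gene_set(regions, self._rec(motif="AAAA")) == frozenset()

    @pytest.mark.parametrize("pp,scheme,label", [
        (-60, "at5p", "G1"), (-300, "at5p", "Us"), (30, "at5p", "Ds"),
        (-10, "at5p", "G3"), (-100, "at3p", "NA"), (-30, "zm3p", "G2"),
    ])
    def test_group_assignment(self, pp, scheme, label):
        rec = self._rec(pp=pp)
        assert pk.assign_group(rec, GROUP_SCHEMES[scheme]) == label

    def test_nucleotide_composition_pooled(self):
        comp = pk.nucleotide_composition([self._rec(motif="AATAAA")])
        assert comp["A"] == pytest.approx(5 / 6)
        assert comp["T"] == pytest.approx(1 / 6)
        comp2 = pk.nucleotide_composition([self._rec(motif="AT"),
                                           self._rec(motif="CG")])
        assert all(v == pytest.approx(0.25) for v in comp2.values())
        assert sum(pk.nucleotide_composition([self._rec(motif="AAAA")]).values()) == 1.0


class TestPipeline:
    def test_vectorized_path_matches_per_motif_reference(self, planted_regions):
        regions, _ = planted_regions
        catalog = pk.enumerate_kmers(3, 3)
        plms = pk.find_plms(regions, catalog, neutral_length=100,
                            score_min=0.0, with_gene_sets=False)
        tal = pk.tally_all(regions, catalog)
        neutral = default_neutral_interval(regions.upstream_extent, 100)
        found = {p.motif: p for p in plms}
        for motif in catalog.motifs:
            dist = tal.distribution(motif)
            study = (neutral[1] + 1, int(dist.offsets[-1]))
            ref = detect_plm(tal.distribution(motif), fit_neutral_model(dist, neutral), study)
            if ref is None or ref.score <= 0.0:
                assert motif not in found
            else:
                got = found[motif]
                assert got.preferential_position == ref.preferential_position
                assert got.functional_window == ref.functional_window
                assert got.score == pytest.approx(ref.score, abs=1e-9)

    def test_full_run_recovers_plant_with_genes_and_groups(self, planted_regions):
        regions, truth = planted_regions
        plms = pk.find_plms(regions, pk.enumerate_kmers(6, 6), neutral_length=100,
                            scheme=GROUP_SCHEMES["at5p"])
        hit = {p.motif: p for p in plms}["TATAAA"]
        assert -37 <= hit.preferential_position <= -33
        assert hit.group_label == "G2"
        planted_genes = set(truth[truth.motif == "TATAAA"].gene_id)
        assert planted_genes <= set(hit.gene_set)

    def test_three_prime_records_reported_on_sense_axis(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=301)) for _ in range(150)]
        # plant at stored offset -40 -> sense offset +40
        planted = [s[:160] + "TGCAGT" + s[166:] for s in seqs]
        regions = make_regions(planted, upstream=200, side=THREE_PRIME)
        plms = pk.find_plms(regions, pk.enumerate_kmers(6, 6), neutral_length=100)
        rec = {p.motif: p for p in plms}["TGCAGT"]
        assert rec.preferential_position == 40
        lo, hi = rec.functional_window
        assert lo <= 40 <= hi

    def test_detection_is_deterministic(self, planted_regions):
        regions, _ = planted_regions
        cat = pk.enumerate_kmers(4, 4)
        t1 = pk.plm_table(pk.find_plms(regions, cat, neutral_length=100))
        t2 = pk.plm_table(pk.find_plms(regions, cat, neutral_length=100))
        assert t1.equals(t2)


@settings(max_examples=30, deadline=None)
@given(st.integers(1, 4), st.integers(0, 3))
def test_catalog_size_formula(kmin, extra):
    kmax = kmin + extra
    cat = pk.enumerate_kmers(kmin, kmax)
    assert len(cat) == sum(4 ** k for k in range(kmin, kmax + 1))
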