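"""Contamination-mixing simulator: AF spectrum, Hardy-Weinberg truth,
pairing constraints, the read model, the ML caller, and cohort emission."""

import dataclasses
import math

import numpy as np
import pytest
import scipy.stats

from charr import (
    HET,
    HOM_ALT,
    MISSING,
    CohortSim,
    SimScenario,
    assign_contaminants,
    call_genotypes,
    emit_cohort,
    read_genotypes,
    run_simulation_study,
    simulate_reads,
    simulate_site_afs,
    simulate_truth_genotypes,
)
from charr.simulate import make_strata


def rng(seed=0):
    return np.random.default_rng(seed)


class TestSiteAfs:
    def test_truncation_and_determinism(self):
        q1 = simulate_site_afs(5000, (1.0, 1.0), rng(3))
        q2 = simulate_site_afs(5000, (1.0, 1.0), rng(3))
        assert np.array_equal(q1, q2)
        assert q1.min() >= 0.05 and q1.max() <= 0.95

    def test_empty(self):
        assert simulate_site_afs(0, (1.0, 1.0), rng()).size == 0

    def test_u_shaped_spectrum_matches_truncated_beta(self):
        """Empirical CDF of Beta(0.2, 0.2) draws matches the truncated
        Beta CDF (resampling == truncation in distribution)."""
        a = b = 0.2
        q = simulate_site_afs(20000, (a, b), rng(5))
        dist = scipy.stats.beta(a, b)
        lo, hi = dist.cdf(0.05), dist.cdf(0.95)

        def trunc_cdf(x):
            return (dist.cdf(x) - lo) / (hi - lo)

        stat = scipy.stats.kstest(q, trunc_cdf).pvalue
        assert stat > 1e-3
        # truncation trims the extreme spikes, but the spectrum stays
        # U-shaped: far more mass near the bounds than a uniform's 40%
        assert np.mean((q < 0.2) | (q > 0.8)) > 0.45


class TestTruthGenotypes:
    def test_boundary_afs(self):
        assert np.all(simulate_truth_genotypes(np.array([1.0]), 50, rng()) == 2)
        assert np.all(simulate_truth_genotypes(np.array([0.0]), 50, rng()) == 0)

    def test_hardy_weinberg_hom_alt_fraction(self):
        n = 10_000
        g = simulate_truth_genotypes(np.array([0.5]), n, rng(7))
        frac = np.mean(g == 2)
        se = math.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) <= 3 * se


class TestAssignContaminants:
    def test_six_by_five_pairing(self):
        strata = make_strata(30, 6)
        partner = assign_contaminants(30, "two_way", strata, rng(11))
        assert sorted(partner) == list(range(30))  # contaminant exactly once
        assert np.all(partner != np.arange(30))  # no self-pairs
        assert np.all(strata[partner] != strata)  # never within-stratum

    def test_two_samples_two_strata_forced_swap(self):
        partner = assign_contaminants(2, "two_way", [0, 1], rng())
        assert partner.tolist() == [1, 0]

    def test_single_stratum_impossible(self):
        with pytest.raises(ValueError):
            assign_contaminants(3, "two_way", [0, 0, 0], rng())

    def test_dominant_stratum_impossible(self):
        with pytest.raises(ValueError):
            assign_contaminants(5, "two_way", [0, 0, 0, 1, 2], rng())

    def test_n_way_has_no_fixed_assignment(self):
        assert assign_contaminants(30, "n_way", make_strata(30, 6), rng()) is None


class TestSimulateReads:
    def _scenario(self, **kw):
        base = dict(n_sites=500, n_samples=4, n_strata=2, seq_error=0.0)
        base.update(kw)
        return SimScenario(**base)

    def test_clean_hom_alt_has_no_reference_reads(self):
        scen = self._scenario()
        truth = np.full((4, 500), 2, dtype=np.int8)
        ad_ref, ad_alt, dp = simulate_reads(truth, None, 0.0, scen, rng(1))
        assert np.all(ad_ref == 0)
        assert np.array_equal(ad_ref + ad_alt, dp)

    def test_full_replacement_by_hom_ref_partner(self):
        scen = self._scenario(mixing="two_way")
        truth = np.zeros((4, 500), dtype=np.int8)
        truth[0] = 2  # original hom-alt, partner hom-ref
        partner = np.array([1, 0, 3, 2])
        _, ad_alt, _ = simulate_reads(truth, partner, 1.0, scen, rng(2))
        assert np.all(ad_alt[0] == 0)

    def test_depth_conservation_with_errors(self):
        scen = self._scenario(seq_error=0.01)
        truth = simulate_truth_genotypes(np.full(500, 0.4), 4, rng(3))
        ad_ref, ad_alt, dp = simulate_reads(truth, None, 0.05, scen, rng(3))
        assert np.array_equal(ad_ref + ad_alt, dp)


class TestCallGenotypes:
    def test_unambiguous_hom_alt(self):
        # 10*(30 log(0.999) - 30 log(0.5))/ln10 rounds to 90
        gt, gq = call_genotypes(0, 30, 0.001)
        assert gt == HOM_ALT and gq == 90

    def test_balanced_reads_are_het(self):
        gt, _ = call_genotypes(15, 15, 0.001)
        assert gt == HET

    def test_zero_depth_is_missing(self):
        gt, gq = call_genotypes(0, 0, 0.001)
        assert gt == MISSING and gq == 0

    def test_error_free_caller_is_finite(self):
        # margin vs het is 25*log2 -> 10*25*log10(2) rounds to 75
        gt, gq = call_genotypes(0, 25, 0.0)
        assert gt == HOM_ALT and gq == 75

    def test_brute_force_likelihood_oracle_dp51(self):
        """Sweep ad_ref 0..51 at DP=51 against a pure-Python evaluation of
        the three genotype likelihoods; documents the hom-alt/het boundary."""
        e = 0.001
        boundary = None
        for ad_ref in range(52):
            ad_alt = 51 - ad_ref
            lls = [
                ad_ref * math.log(1 - e) + ad_alt * math.log(e),
                51 * math.log(0.5),
                ad_ref * math.log(e) + ad_alt * math.log(1 - e),
            ]
            expect_gt = max(range(3), key=lambda k: lls[k])
            pair = sorted(lls)
            expect_gq = min(99, round(10 * (pair[-1] - pair[-2]) / math.log(10)))
            gt, gq = call_genotypes(ad_ref, ad_alt, e)
            assert gt == expect_gt
            assert gq == expect_gq
            if boundary is None and expect_gt == HET:
                boundary = ad_ref
        # reference reads tip a DP=51 site from hom-alt to het at RR >= 6
        assert boundary == 6
        # the worked example stays hom-alt despite 3 reference reads
        gt, gq = call_genotypes(3, 48, e)
        assert gt == HOM_ALT and gq >= 20


class TestCohortEmission:
    def _scenario(self, **kw):
        base = dict(n_sites=300, n_samples=6, n_strata=3, seed=17)
        base.update(kw)
        return SimScenario(**base)

    def test_default_rates_give_150_simulated_samples(self, tmp_path):
        scen = SimScenario(n_sites=50, seed=1)  # 30 samples, 5 rates
        paths = emit_cohort(scen, tmp_path)
        vcfs = [p for k, p in paths.items() if k.startswith("vcf:")]
        assert len(vcfs) == 5
        total = 0
        for vcf in vcfs:
            header = [l for l in vcf.read_text().splitlines() if l.startswith("#CHROM")][0]
            total += len(header.split("\t")) - 9
        assert total == 150

    def test_same_seed_byte_identical(self, tmp_path):
        scen = self._scenario(contamination_rates=(0.02,))
        p1 = emit_cohort(scen, tmp_path / "a")
        p2 = emit_cohort(scen, tmp_path / "b")
        assert p1["truth"].read_bytes() == p2["truth"].read_bytes()
        assert p1["vcf:0.02"].read_bytes() == p2["vcf:0.02"].read_bytes()
        assert p1["truth_genotypes"].read_bytes() == p2["truth_genotypes"].read_bytes()

    def test_vcf_round_trip_is_bit_exact(self, tmp_path):
        """Reading an emitted VCF reproduces the caller's GT/AD/DP/GQ."""
        scen = self._scenario(contamination_rates=(0.05,))
        emit_cohort(scen, tmp_path)
        sim = CohortSim(scen)  # same seed -> same cohort
        called = sim.simulate_rate(0.05)
        recs = list(read_genotypes(tmp_path / "cohort_c0.05.vcf"))
        assert len(recs) == scen.n_sites * scen.n_samples
        idx = {sid: i for i, sid in enumerate(sim.sample_ids)}
        pos_to_site = {k.pos: j for j, k in enumerate(sim.keys)}
        for rec in recs:
            i, j = idx[rec.sample_id], pos_to_site[rec.key.pos]
            assert rec.gt == called.gt[i, j]
            assert rec.ad_ref == called.ad_ref[i, j]
            assert rec.ad_alt == called.ad_alt[i, j]
            assert rec.dp == called.dp[i, j]
            assert rec.gq == called.gq[i, j]

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            SimScenario(n_sites=100, n_samples=1)
        with pytest.raises(ValueError):
            SimScenario(n_sites=100, contamination_rates=(1.0,))
        with pytest.raises(ValueError):
            SimScenario(n_sites=100, mixing="three_way")


class TestSimulationStudy:
    def test_clean_limit_is_exactly_zero(self):
        scen = SimScenario(
            n_sites=2000, n_samples=4, n_strata=2, contamination_rates=(0.0,), seq_error=0.0, seed=5
        )
        summary, per = run_simulation_study(scen)
        assert summary.mean_charr.iloc[0] == 0.0
        assert (per.charr == 0.0).all()

    def test_mean_estimate_increases_with_rate(self):
        scen = SimScenario(n_sites=3000, n_samples=10, n_strata=5, seed=23)
        summary, _ = run_simulation_study(scen)
        means = summary.sort_values("true_c").mean_charr.to_numpy()
        assert np.all(np.diff(means) > 0)

    def test_hom_to_het_conversion_grows_with_contamination(self):
        """The deflation mechanism: true hom-alt sites called het."""
        scen = SimScenario(n_sites=8000, contamination_rates=(0.01, 0.10), seed=13)
        sim = CohortSim(scen)
        fracs = []
        for rate in scen.contamination_rates:
            called = sim.simulate_rate(rate)
            fracs.append(float(np.mean(called.gt[sim.truth == 2] == HET)))
        assert fracs[1] > 5 * fracs[0]
        assert fracs[1] > 0.01

    def test_n_way_closer_to_truth_than_two_way_at_high_rates(self):
        results = {}
        for mix in ("two_way", "n_way"):
            scen = SimScenario(n_sites=8000, contamination_rates=(0.05, 0.10), mixing=mix, seed=21)
            summary, _ = run_simulation_study(scen)
            results[mix] = summary.set_index("true_c").mean_charr
        for rate in (0.05, 0.10):
            assert abs(results["n_way"][rate] - rate) < abs(results["two_way"][rate] - rate)
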