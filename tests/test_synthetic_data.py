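from fractions import Fraction

import numpy as np
import pytest

from satzone import landscape_metrics as lm
from satzone import synthetic_data as syn
from satzone.hybrid_zone import allele_frequencies
from satzone.io_formats import GenotypeTable


class TestMutateSequence:
    def test_exact_count(self):
        rng = np.random.default_rng(0)
        seq = syn.random_monomer(200, rng)
        mut = syn.mutate_sequence(seq, 10.0, rng, exact=True)
        diffs = sum(a != b for a, b in zip(seq, mut))
        assert diffs == 20

    def test_zero_divergence_identity(self):
        rng = np.random.default_rng(0)
        seq = syn.random_monomer(100, rng)
        assert syn.mutate_sequence(seq, 0.0, rng) == seq

    def test_substitutions_change_base(self):
        rng = np.random.default_rng(1)
        seq = "A" * 500
        mut = syn.mutate_sequence(seq, 50.0, rng)
        assert all(c in "CGT" for c in mut if c != "A")

    def test_bad_divergence(self):
        with pytest.raises(ValueError):
            syn.mutate_sequence("ACGT", 120.0, np.random.default_rng(0))


class TestSimulateBurstFamily:
    def test_time_zero_all_identical(self):
        model = syn.BurstModel(burst_time_mya=0.0, copies=50, monomer_len=100, seed=1)
        monomers, hits = syn.simulate_burst_family(model)
        assert len({m.sequence for m in monomers}) == 1
        ls = lm.compute_landscape(hits, model.family, model.library_id)
        assert lm.divpeak(ls) == 0.0
        assert lm.amplification_time(lm.divpeak(ls)) == 0.0

    def test_deterministic_under_seed(self):
        model = syn.BurstModel(burst_time_mya=1.0, copies=30, monomer_len=120, seed=9)
        a = syn.simulate_burst_family(model)
        b = syn.simulate_burst_family(model)
        assert [m.sequence for m in a[0]] == [m.sequence for m in b[0]]
        assert a[1] == b[1]

    def test_recovers_planted_time_single_seed(self):
        model = syn.BurstModel(burst_time_mya=1.5, copies=500, monomer_len=400, seed=2)
        _, hits = syn.simulate_burst_family(model)
        t_hat = lm.amplification_time(
            lm.divpeak(lm.compute_landscape(hits, model.family, model.library_id))
        )
        assert abs(t_hat - 1.5) < 0.15

    def test_mean_divergence_converges(self):
        # law of large numbers: mean realized divergence -> 2 * rate * time
        model = syn.BurstModel(burst_time_mya=1.5, copies=10_000, monomer_len=300, seed=3)
        _, hits = syn.simulate_burst_family(model)
        mean = np.mean([h.divergence_pct for h in hits])
        p = model.expected_divergence_pct / 100
        se = 100 * np.sqrt(p * (1 - p) / 300) / np.sqrt(10_000)
        assert abs(mean - model.expected_divergence_pct) < 3 * se

    def test_two_bursts_peak_at_recent_mode(self):
        old = syn.BurstModel(burst_time_mya=3.5, copies=150, monomer_len=400, seed=4)
        recent = syn.BurstModel(burst_time_mya=0.5, copies=600, monomer_len=400, seed=5)
        _, hits_old = syn.simulate_burst_family(old)
        _, hits_recent = syn.simulate_burst_family(recent)
        ls = lm.compute_landscape(hits_old + hits_recent, "burstFam", "SIM")
        dp = lm.divpeak(ls)
        assert 0.5 <= dp <= 1.5  # recent mode near 2*1.11*0.5 = 1.11%
        # bimodality: abundance re-rises around the old mode (~7.8%)
        old_mass = sum(v for e, v in ls.bins.items() if 6.5 <= e <= 9.0)
        trough = sum(v for e, v in ls.bins.items() if 3.5 <= e <= 5.0)
        assert old_mass > trough

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            syn.BurstModel(burst_time_mya=-1, copies=10, monomer_len=50, seed=0)
        with pytest.raises(ValueError):
            syn.BurstModel(burst_time_mya=1, copies=0, monomer_len=50, seed=0)


class TestSimulateLibrary:
    def test_deterministic_under_seed(self):
        a, ta = syn.simulate_library(3, 2, seed=11, monomer_len=80)
        b, tb = syn.simulate_library(3, 2, seed=11, monomer_len=80)
        assert [m.sequence for m in a] == [m.sequence for m in b]
        assert ta == tb

    def test_truth_labels_nested(self):
        members, truth = syn.simulate_library(4, (2, 3), seed=12, monomer_len=60)
        sub_to_fam = {}
        for fam, sub in truth.values():
            assert sub_to_fam.setdefault(sub, fam) == fam

    def test_single_variant_families(self):
        members, truth = syn.simulate_library(
            3, 1, seed=13, members_per_variant=1, monomer_len=60
        )
        # one variant per family: subfamily partition == family partition
        assert len({t[1] for t in truth.values()}) == len({t[0] for t in truth.values()})

    def test_zero_variant_divergence_merges_members(self):
        from satzone.tr_catalog import monomer_identity

        members, truth = syn.simulate_library(
            1, 1, seed=14, members_per_variant=2,
            variant_divergence_pct=0.0, monomer_len=80, scramble_phase=True,
        )
        # identical up to rotation/strand -> merged at the 95% threshold
        assert monomer_identity(members[0], members[1]).identity_pct == 100.0

    def test_per_family_variant_counts(self):
        members, truth = syn.simulate_library(
            5, (2, 2, 2, 3, 3), seed=15, monomer_len=60
        )
        assert len(members) == 12
        assert len({t[1] for t in truth.values()}) == 12

    def test_invalid_divergences(self):
        with pytest.raises(ValueError):
            syn.simulate_library(2, 2, seed=0, family_divergence_pct=2, variant_divergence_pct=5)


class TestSimulateTransect:
    def _model(self, seed=0, center=4.0, width=0.5, n=30, n_sites=7):
        sites = syn.default_transect_sites(n_sites)
        return syn.ClineModel(
            center=center, width=width, sites=sites,
            sample_sizes=(n,) * n_sites, seed=seed,
        )

    def test_site_freq_monotone(self):
        model = self._model()
        freqs = [model.site_freq(i) for i in range(1, 8)]
        assert all(a < b for a, b in zip(freqs, freqs[1:]))
        assert all(0 <= f <= 1 for f in freqs)

    def test_q_zero_everywhere(self):
        model = self._model(center=1000.0)
        for gt in syn.simulate_transect(model, "autosomal"):
            assert gt.counts[1] == gt.counts[2] == 0
        for gt in syn.simulate_transect(model, "x_linked"):
            assert gt.counts[1] == 0

    def test_deterministic_under_seed(self):
        model = self._model(seed=21)
        assert syn.simulate_transect(model, "autosomal") == syn.simulate_transect(
            model, "autosomal"
        )

    def test_sample_sizes_respected(self):
        model = self._model(n=17)
        for gt in syn.simulate_transect(model, "autosomal"):
            assert gt.total == 17

    def test_published_profile_emulation(self):
        # sample sizes from the transect table, planted frequencies equal to
        # the exact published autosomal fractions: expected counts match
        # within binomial sampling error
        from satzone import datasets

        sites = tuple(datasets.load_transect_sites())
        n = tuple(s.n_males for s in sites)
        q_exact = [0, 0, Fraction(1, 14), Fraction(1, 8), Fraction(5, 16), 1, 1]
        model = syn.ClineModel(
            center=5.0, width=0.5, sites=sites, sample_sizes=n, seed=31,
        )
        reps = 300
        bb_cm = []
        for seed in range(reps):
            model_s = syn.ClineModel(
                center=5.0, width=0.5, sites=sites, sample_sizes=n, seed=seed,
            )
            tables = syn.simulate_transect(model_s, "autosomal", site_freqs=q_exact)
            by_pop = {t.population: t for t in tables}
            assert by_pop["ARU"].counts == (41, 0, 0)  # q = 0 is deterministic
            bb_cm.append(by_pop["CM"].counts[2])
        q = 5 / 16
        expected_bb = 8 * q * q
        se = np.sqrt(8 * q * q * (1 - q * q) / reps)
        assert abs(np.mean(bb_cm) - expected_bb) < 4 * se

    def test_hw_proportions(self):
        # genotype draws follow Hardy-Weinberg at the planted frequency
        model = self._model(n=4000, n_sites=1, center=1.0, width=1.0)
        q = model.site_freq(1)  # 0.5
        (gt,) = syn.simulate_transect(model, "autosomal")
        af = allele_frequencies(gt)
        assert abs(float(af.q_B) - q) < 0.03
        assert abs(gt.counts[1] / gt.total - 2 * q * (1 - q)) < 0.04

    def test_mismatched_site_freqs(self):
        model = self._model()
        with pytest.raises(ValueError, match="per site"):
            syn.simulate_transect(model, "autosomal", site_freqs=[0.5])

    def test_invalid_linkage(self):
        with pytest.raises(ValueError):
            syn.simulate_transect(self._model(), "z_linked")
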