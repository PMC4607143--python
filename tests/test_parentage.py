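"""Mendelian likelihoods, LOD/delta statistics, critical-delta simulation and
registry-level assignment, checked against brute-force genotype enumeration
and generator ground truth."""

import numpy as np
import pytest

from ampliped.genotypes import GenotypeMatrix, SampleRecord
from ampliped.panel import AmpliconPanel
from ampliped.parentage import (ParentageConfig, ParentageModel,
                                allele_frequencies, assign_parentage,
                                compare_marker_sets, critical_from_trials,
                                delta_statistic, hw_genotype_probs,
                                lod_single_parent, lod_trio,
                                mendelian_trio_prob, obs_given_true,
                                simulate_critical_delta, simulate_trials)
from ampliped.pedigree import PedigreeEntry, PedigreeRegistry
from test_filtering import biallelic_panel, matrix_from_dosages

GENOS = [(0, 0), (0, 1), (1, 1)]  # biallelic genotype codes 0, 1, 2


# ---------------------------------------------------------------------------
# brute-force oracles (explicit loops, independent of the table machinery)
# ---------------------------------------------------------------------------

def punnett(off, dam, sire) -> float:
    """Transmission probability by enumerating the four gamete combinations."""
    hits = 0
    for a in dam:
        for b in sire:
            if tuple(sorted((a, b))) == tuple(sorted(off)):
                hits += 1
    return hits / 4.0


def brute_force_trio_lod(go, gd, gc, p, eps) -> float:
    """Trio LOD by summing over all 27 true-genotype combinations."""
    hw = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]

    def E(obs, true):
        return (1 - eps) * (obs == true) + eps * hw[obs]

    num = den_od = 0.0
    for ot in range(3):
        for dt in range(3):
            for ct in range(3):
                m = punnett(GENOS[ot], GENOS[dt], GENOS[ct])
                num += hw[dt] * hw[ct] * m * E(go, ot) * E(gd, dt) * E(gc, ct)
            # offspring given dam and a random HW mate
        for dt in range(3):
            t = sum(hw[ct] * punnett(GENOS[ot], GENOS[dt], GENOS[ct])
                    for ct in range(3))
            den_od += hw[dt] * t * E(go, ot) * E(gd, dt)
    p_c = sum(hw[ct] * E(gc, ct) for ct in range(3))
    return np.log(num) - np.log(den_od * p_c)


def brute_force_single_lod(go, gc, p, eps) -> float:
    hw = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]

    def E(obs, true):
        return (1 - eps) * (obs == true) + eps * hw[obs]

    num = 0.0
    for ot in range(3):
        for ct in range(3):
            t = sum(hw[mt] * punnett(GENOS[ot], GENOS[ct], GENOS[mt])
                    for mt in range(3))
            num += hw[ct] * t * E(go, ot) * E(gc, ct)
    p_o = sum(hw[t] * E(go, t) for t in range(3))
    p_c = sum(hw[t] * E(gc, t) for t in range(3))
    return np.log(num) - np.log(p_o * p_c)


# ---------------------------------------------------------------------------
# single-locus building blocks
# ---------------------------------------------------------------------------

class TestMendelianTrioProb:
    def test_punnett_square(self):
        assert mendelian_trio_prob((0, 0), (0, 1), (0, 1)) == 0.25
        assert mendelian_trio_prob((0, 1), (0, 1), (0, 1)) == 0.5
        assert mendelian_trio_prob((1, 1), (0, 1), (0, 1)) == 0.25

    def test_fixed_parents(self):
        assert mendelian_trio_prob((0, 0), (0, 0), (0, 0)) == 1.0
        assert mendelian_trio_prob((0, 0), (0, 0), (1, 1)) == 0.0  # impossible

    def test_sums_to_one_over_all_27_combinations(self):
        for gd in GENOS:
            for gs in GENOS:
                total = sum(mendelian_trio_prob(go, gd, gs) for go in GENOS)
                assert total == pytest.approx(1.0)

    def test_allele_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mendelian_trio_prob((0, 2), (0, 0), (0, 0), n_alleles=2)


class TestObsGivenTrue:
    def test_zero_error_is_indicator(self):
        for obs in range(3):
            for true in range(3):
                assert obs_given_true(obs, true, 0.0, [0.7, 0.3]) == float(obs == true)

    def test_full_error_is_hw(self):
        assert obs_given_true(1, 0, 1.0, [0.5, 0.5]) == pytest.approx(0.5)

    def test_normalisation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            eps = rng.random() * 0.5
            p = rng.random()
            total = sum(obs_given_true(o, 1, eps, [1 - p, p]) for o in range(3))
            assert total == pytest.approx(1.0)


class TestLodScores:
    def test_het_candidate_het_offspring_is_zero(self):
        lod, shared, excl = lod_single_parent([1], [1], [np.array([0.5, 0.5])], 0.0)
        assert lod == pytest.approx(0.0)
        assert (shared, excl) == (1, 0)

    def test_mendelian_impossibility_gives_minus_inf_and_exclusion(self):
        lod, _, excl = lod_single_parent([2], [0], [np.array([0.5, 0.5])], 0.0)
        assert lod == -np.inf
        assert excl == 1

    def test_error_model_makes_exclusion_finite_but_costly(self):
        freqs = [np.array([0.5, 0.5]), np.array([0.7, 0.3])]
        with_bad, _, _ = lod_single_parent([2, 1], [0, 1], freqs, 0.01)
        without, _, _ = lod_single_parent([1], [1], [freqs[1]], 0.01)
        assert np.isfinite(with_bad)
        assert with_bad < without

    def test_single_parent_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.uniform(0.05, 0.95)
            eps = rng.uniform(0, 0.2)
            go, gc = rng.integers(0, 3, size=2)
            got, _, _ = lod_single_parent([go], [gc], [np.array([1 - p, p])], eps)
            want = brute_force_single_lod(go, gc, p, eps)
            if np.isfinite(want):
                assert got == pytest.approx(want, abs=1e-10)
            else:
                assert got == want

    def test_trio_matches_brute_force_27_combinations(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = rng.uniform(0.05, 0.95)
            eps = rng.uniform(0.001, 0.2)
            go, gd, gc = rng.integers(0, 3, size=3)
            got, _, _ = lod_trio([go], [gd], [gc], [np.array([1 - p, p])], eps)
            want = brute_force_trio_lod(go, gd, gc, p, eps)
            assert got == pytest.approx(want, abs=1e-10)

    def test_trio_zero_eps_impossible_counts_exclusion(self):
        # offspring hom-alt, dam het, candidate hom-ref: impossible from candidate
        lod, _, excl = lod_trio([2], [1], [0], [np.array([0.5, 0.5])], 0.0)
        assert lod == -np.inf and excl == 1

    def test_no_shared_loci_undefined(self):
        lod, shared, _ = lod_single_parent([-1], [1], [np.array([0.5, 0.5])], 0.0)
        assert np.isnan(lod) and shared == 0

    def test_true_parent_lod_positive_on_simulated_trios(self):
        """Candidate = true sire over 100 informative loci: LOD > 0 in nearly
        all replicates without genotyping error."""
        rng = np.random.default_rng(5)
        L, p = 100, 0.3
        freqs = [np.array([1 - p, p])] * L
        model = ParentageModel(freqs, 0.0)
        deltas, correct = simulate_trials(model, 2, 1000, 1.0, 1.0, "trio", rng)
        # with eps=0 and full typing, the true parent is never excluded and
        # nearly always top-ranked
        assert correct.mean() >= 0.99

    def test_lod_advantage_grows_with_locus_count(self):
        """Mean LOD gap between true parent and an unrelated candidate rises
        with the number of loci and falls as the MAF spectrum approaches 0."""
        rng = np.random.default_rng(6)

        def mean_advantage(L, maf_mean, n=400):
            mafs = np.full(L, maf_mean)
            model = ParentageModel([np.array([1 - m, m]) for m in mafs], 0.01)
            deltas, _ = simulate_trials(model, 2, n, 1.0, 1.0, "single", rng,
                                        min_shared_loci=1)
            return deltas.mean()

        adv = [mean_advantage(L, 0.3) for L in (25, 50, 100, 200)]
        assert all(b > a for a, b in zip(adv, adv[1:]))
        low_div = [mean_advantage(100, m) for m in (0.3, 0.1, 0.03)]
        assert all(b < a for a, b in zip(low_div, low_div[1:]))


class TestDeltaStatistic:
    def test_two_positive(self):
        assert delta_statistic([12.1, 7.3, -2]) == pytest.approx(4.8)

    def test_single_positive(self):
        assert delta_statistic([5.0]) == 5.0
        assert delta_statistic([5.0, -1.0, -np.inf]) == 5.0

    def test_none_positive(self):
        assert delta_statistic([-1.0, 0.0, -np.inf]) == 0.0


# ---------------------------------------------------------------------------
# critical-delta simulation
# ---------------------------------------------------------------------------

class TestCriticalDelta:
    def _cfg(self, **kw):
        base = dict(error_rate=0.0, sim_cycles=2000, prop_loci_typed=1.0,
                    rng_seed=42, min_shared_loci=20)
        base.update(kw)
        return ParentageConfig(**base)

    def test_informative_panel_gives_near_zero_threshold(self):
        freqs = [np.array([0.7, 0.3])] * 200
        crit = simulate_critical_delta(self._cfg(), freqs, "single", 5)
        assert crit.thresholds["strict"] <= 0.5
        assert crit.correct[crit.deltas > 0].mean() > 0.95

    def test_true_parent_never_sampled(self):
        freqs = [np.array([0.7, 0.3])] * 50
        with pytest.warns(UserWarning, match="positive-delta"):
            crit = simulate_critical_delta(
                self._cfg(prop_candidates_sampled=0.0), freqs, "single", 5)
        assert crit.thresholds["strict"] == np.inf
        assert crit.correct.sum() == 0

    def test_seed_reproducibility(self):
        freqs = [np.array([0.8, 0.2])] * 60
        a = simulate_critical_delta(self._cfg(), freqs, "trio", 4)
        b = simulate_critical_delta(self._cfg(), freqs, "trio", 4)
        assert a.thresholds == b.thresholds
        assert np.array_equal(a.deltas, b.deltas)

    def test_too_few_positive_trials_warns_inf(self):
        deltas = np.zeros(1500)
        correct = np.zeros(1500, dtype=bool)
        with pytest.warns(UserWarning, match="positive-delta"):
            crit = critical_from_trials(deltas, correct,
                                        {"strict": 0.95, "relaxed": 0.80})
        assert crit.thresholds == {"strict": np.inf, "relaxed": np.inf}

    def test_calibration_guarantee_on_holdout(self):
        """Among fresh trials with delta above the calibrated strict threshold,
        the true parent tops the ranking at least 95% (minus MC noise)."""
        rng_fit = np.random.default_rng(1)
        rng_new = np.random.default_rng(2)
        mafs = 0.5 * np.random.default_rng(0).beta(0.7, 2.8, 120)
        freqs = [np.array([1 - m, m]) for m in np.clip(mafs, 0.01, 0.5)]
        model = ParentageModel(freqs, 0.01)
        fit = simulate_trials(model, 5, 3000, 0.6, 1.0, "single", rng_fit)
        crit = critical_from_trials(*fit, {"strict": 0.95})
        t = crit.thresholds["strict"]
        deltas, correct = simulate_trials(model, 5, 3000, 0.6, 1.0, "single",
                                          rng_new)
        sel = deltas > t
        assert sel.sum() > 100
        frac = correct[sel].mean()
        se = np.sqrt(0.95 * 0.05 / sel.sum())
        assert frac >= 0.95 - 3 * se


# ---------------------------------------------------------------------------
# registry-level assignment
# ---------------------------------------------------------------------------

def _sim_assignment_setup(n_off=30, n_sires=2, L=80, missing=0.3, seed=0,
                          eps_sim=0.0):
    """Small ground-truthed facility: known dam, candidate sires."""
    from ampliped.simulate import (FacilitySpec, SimPanelSpec, SimPopSpec,
                                   apply_observation_model, generate_panel,
                                   simulate_population)

    panel, pools = generate_panel(
        SimPanelSpec(n_amplicons=12, snps_per_amplicon=(8, 20),
                     haplotypes_per_amplicon=(3, 6)), seed=seed)
    pop = SimPopSpec(n_founders=20,
                     facilities=[FacilitySpec("fac", n_off, True, 0, n_sires)],
                     missing_rate=missing, error_rate=eps_sim,
                     amplicon_dropout_rate=min(0.1, missing), rng_seed=seed + 1)
    truth, recs, reg = simulate_population(panel, pools, pop)
    obs = apply_observation_model(truth, pop, seed=seed + 2)
    return panel, truth, recs, reg, obs


class TestAssignParentage:
    def test_true_sire_recovered_with_known_dam(self):
        panel, truth, recs, reg, obs = _sim_assignment_setup(seed=10)
        cfg = ParentageConfig(sim_cycles=1500, rng_seed=3)
        results = assign_parentage(reg, obs, panel, cfg, recs)
        hits = sum(r.assignment == truth.pedigree[r.offspring_id][1]
                   for r in results)
        assert hits / len(results) >= 0.9

    def test_identical_candidates_tie_no_assignment(self):
        """Candidate sires with identical genotypes (e.g. fully homozygous
        sibs) cannot be told apart: the LODs tie and no parent is assigned."""
        panel, truth, recs, reg, obs = _sim_assignment_setup(n_off=5, seed=20)
        entry = next(iter(reg))
        true_sire = truth.pedigree[entry.offspring_id][1]
        for other in entry.candidate_sires - {true_sire}:
            obs.pairs[obs.sample_index(other)] = \
                obs.pairs[obs.sample_index(true_sire)]
        cfg = ParentageConfig(sim_cycles=1500, rng_seed=3)
        results = assign_parentage(reg, obs, panel, cfg, recs)
        res = [r for r in results if r.offspring_id == entry.offspring_id][0]
        assert res.assignment is None
        assert "tie" in res.notes

    def test_all_candidates_excluded(self):
        """Offspring unrelated to every candidate: exclusions pile up and no
        assignment is made."""
        panel = biallelic_panel(60, amp_size=10)
        rng = np.random.default_rng(8)
        hw = [0.25, 0.5, 0.25]
        dos = rng.choice(3, size=(4, 60), p=hw)
        # force >= 5 opposing-homozygote loci against each candidate
        dos[0, :10] = 0
        dos[1:, :10] = 2
        m = matrix_from_dosages(dos, panel)
        m.samples = ["kid", "c1", "c2", "c3"]
        m._sample_idx = {s: k for k, s in enumerate(m.samples)}
        reg = PedigreeRegistry([PedigreeEntry(
            "kid", "f", candidate_dams={"c1"}, candidate_sires={"c2", "c3"})])
        cfg = ParentageConfig(error_rate=0.0, sim_cycles=1000, rng_seed=1,
                              min_shared_loci=10)
        results = assign_parentage(reg, m, panel, cfg)
        for r in results:
            assert r.assignment is None
            assert r.confidence == "excluded_only"
            assert all(s.exclusions >= 5 for s in r.candidates)

    def test_below_min_shared_loci_downgraded(self):
        panel = biallelic_panel(30, amp_size=10)
        dos = np.ones((2, 30), dtype=int)
        dos[1, 15:] = -1  # candidate typed at 15 loci < default 20
        m = matrix_from_dosages(dos, panel)
        m.samples = ["kid", "dam1"]
        m._sample_idx = {s: k for k, s in enumerate(m.samples)}
        reg = PedigreeRegistry([PedigreeEntry(
            "kid", "f", candidate_dams={"dam1"}, candidate_sires={"dam1"})])
        # a sire candidate equal to the dam candidate is artificial but keeps
        # the fixture tiny; only the dam analysis is inspected
        cfg = ParentageConfig(sim_cycles=1000, rng_seed=1)
        results = assign_parentage(reg, m, panel, cfg)
        dam_res = [r for r in results if r.mode == "single_parent_dam"][0]
        assert dam_res.confidence == "excluded_only"
        assert dam_res.assignment is None

    def test_ungenotyped_offspring_insufficient_data(self):
        panel = biallelic_panel(10)
        m = matrix_from_dosages(np.full((2, 10), -1), panel)
        m.samples = ["kid", "c"]
        m._sample_idx = {s: k for k, s in enumerate(m.samples)}
        reg = PedigreeRegistry([PedigreeEntry(
            "kid", "f", candidate_dams={"c"}, candidate_sires={"c"})])
        results = assign_parentage(reg, m, panel,
                                   ParentageConfig(sim_cycles=1000, rng_seed=1))
        assert results[0].confidence == "insufficient_data"


class TestCompareMarkerSets:
    def test_identical_inputs_full_agreement(self):
        panel, truth, recs, reg, obs = _sim_assignment_setup(n_off=6, seed=30)
        cfg = ParentageConfig(sim_cycles=1500, rng_seed=3)
        results = assign_parentage(reg, obs, panel, cfg, recs)
        table = compare_marker_sets(results, results)
        assigned = table[table.assigned_a != ""]
        assert assigned.agree.all()

    def test_mismatched_offspring_error(self):
        panel, truth, recs, reg, obs = _sim_assignment_setup(n_off=4, seed=31)
        cfg = ParentageConfig(sim_cycles=1500, rng_seed=3)
        results = assign_parentage(reg, obs, panel, cfg, recs)
        with pytest.raises(ValueError, match="differ"):
            compare_marker_sets(results, results[:-1])

    def test_snp_panel_outpowers_low_diversity_microsatellites(self):
        """A large biallelic panel yields higher mean trio LODs for the true
        sire than a 12-locus low-diversity multi-allelic set."""
        rng = np.random.default_rng(40)

        def mean_true_lod(freqs, n=300):
            model = ParentageModel(freqs, 0.01)
            deltas, correct = simulate_trials(model, 2, n, 1.0, 1.0, "trio", rng,
                                              min_shared_loci=1)
            return deltas.mean(), correct.mean()

        snp_freqs = [np.array([0.75, 0.25])] * 192
        # 12 microsatellites, 3 alleles each, one dominant allele
        ms_freqs = [np.array([0.8, 0.15, 0.05])] * 12
        snp_lod, snp_acc = mean_true_lod(snp_freqs)
        ms_lod, ms_acc = mean_true_lod(ms_freqs)
        assert snp_lod > ms_lod
        assert snp_acc >= ms_acc


class TestAlleleFrequencies:
    def test_floored_and_normalised(self):
        m = matrix_from_dosages(np.zeros((10, 2), dtype=int))  # monomorphic ref
        freqs = allele_frequencies(m)
        for f in freqs:
            assert f.min() > 0
            assert f.sum() == pytest.approx(1.0)

    def test_hw_probs_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            f = rng.dirichlet(np.ones(rng.integers(2, 6)))
            assert hw_genotype_probs(f).sum() == pytest.approx(1.0)
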