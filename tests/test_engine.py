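"""Coalescent engine against closed-form and msprime oracles."""

import numpy as np
import pytest
from scipy import stats

from metapopabc.models import Event, EventSchedule, ParameterDraw, build_schedule
from metapopabc.simulate import (
    LocusPanel,
    SamplingScheme,
    draw_locus_panel,
    mean_tmrca,
    simulate_dataset,
    simulate_sfs_counts,
)


def harmonic(n):
    return sum(1.0 / i for i in range(1, n + 1))


def cos_schedule(n):
    return build_schedule(ParameterDraw("COS", {"N": float(n)}))


ONE_LOCUS = LocusPanel([600.0], [1e-8], [0.0])


class TestNeutralOracles:
    def test_mean_segregating_sites_matches_watterson(self):
        # E[S] = 4*N*mu*L*H_{2n-1} for a constant-size diploid coalescent
        sched = cos_schedule(10_000)
        rng = np.random.default_rng(10)
        scheme = SamplingScheme.scd(9)
        s = np.array(
            [simulate_sfs_counts(sched, ONE_LOCUS, scheme, rng).sum() for _ in range(6000)]
        )
        expect = 4 * 10_000 * 1e-8 * 600 * harmonic(17)
        assert abs(s.mean() - expect) < 3 * s.std() / np.sqrt(len(s))

    def test_folded_sfs_matches_one_over_i_shape(self):
        # folded neutral expectation: phi_i ~ (1/i + 1/(2n-i)) / (1 + [i == n])
        n_ind, n_loci = 9, 8000
        panel = LocusPanel(np.full(n_loci, 600.0), np.full(n_loci, 1e-8), np.zeros(n_loci))
        counts = simulate_sfs_counts(
            cos_schedule(10_000), panel, SamplingScheme.scd(n_ind), np.random.default_rng(11)
        )
        i = np.arange(1, n_ind + 1)
        phi = (1.0 / i + 1.0 / (2 * n_ind - i)) / (1.0 + (i == n_ind))
        phi /= phi.sum()
        res = stats.chisquare(counts, f_exp=phi * counts.sum())
        assert res.pvalue > 0.01

    def test_pairwise_tmrca_is_two_n(self):
        sched = cos_schedule(5000)
        t = mean_tmrca(sched, ONE_LOCUS, SamplingScheme.scd(1), 6000, seed=12)
        assert abs(t.mean() - 10_000.0) < 3 * t.std() / np.sqrt(len(t))

    def test_single_replicate_returns_scalar_nonnegative(self):
        t = mean_tmrca(cos_schedule(100), ONE_LOCUS, SamplingScheme.scd(2), 1, seed=13)
        assert t.shape == (1,) and t[0] >= 0


class TestIslandModel:
    D, ND, M = 100, 200.0, 0.01  # Nm = 2

    def island(self, t_i=1e9, n_anc=1000.0):
        return EventSchedule(
            self.D, self.ND, self.M, (Event(t_i, "merge_demes", size=n_anc),)
        )

    def test_pair_coalescence_times_match_island_theory(self):
        # same deme: E[T2] = 2*N*D; different demes: + (D-1)/(2m)
        from metapopabc._engine import sim_locus

        sched = self.island()
        rng = np.random.default_rng(14)
        same = mean_tmrca(sched, LocusPanel([600.0], [0.0], [0.0]), SamplingScheme("X", [0]), 4000, rng)
        eps = sched.epochs()
        diff = np.array([sim_locus(eps, np.array([0, 1]), self.D, rng)[2] for _ in range(4000)])
        e_same = 2 * self.ND * self.D
        e_diff = e_same + (self.D - 1) / (2 * self.M)
        assert abs(same.mean() - e_same) < 3 * same.std() / np.sqrt(len(same))
        assert abs(diff.mean() - e_diff) < 3 * diff.std() / np.sqrt(len(diff))

    def test_against_msprime_exact_structured_coalescent(self):
        # independent oracle: msprime simulates the same non-equilibrium island
        # model exactly; compare mean TMRCA of a 3-individual scatter sample
        # (50 demes: msprime caps population splits at 100 populations)
        import msprime

        d_demes, t_i, n_anc = 50, 30_000.0, 5000.0
        sched = EventSchedule(
            d_demes, self.ND, self.M, (Event(t_i, "merge_demes", size=n_anc),)
        )
        panel = LocusPanel([600.0], [0.0], [0.0])
        ours = mean_tmrca(sched, panel, SamplingScheme.scd(3), 3000, seed=15)

        demog = msprime.Demography.island_model([self.ND] * d_demes, self.M / (d_demes - 1))
        demog.add_population(name="anc", initial_size=n_anc)
        demog.add_population_split(time=t_i, derived=[f"pop_{i}" for i in range(d_demes)], ancestral="anc")
        other = []
        for seed in range(1, 401):
            ts = msprime.sim_ancestry(
                samples={0: 1, 1: 1, 2: 1}, demography=demog, random_seed=seed
            )
            tree = ts.first()
            other.append(tree.time(tree.root))
        other = np.array(other)
        se = np.sqrt(ours.var() / len(ours) + other.var() / len(other))
        assert abs(ours.mean() - other.mean()) < 3 * se

    def test_strong_migration_limit_is_panmictic(self):
        # Nm = 10^4: mean S within 5% of Watterson with the matched total size D*N
        nd = 1000.0
        sched = EventSchedule(
            self.D, nd, 1e4 / nd, (Event(5e7, "merge_demes", size=1000.0),)
        )
        n_loci = 2500
        panel = LocusPanel(np.full(n_loci, 600.0), np.full(n_loci, 1e-8), np.zeros(n_loci))
        counts = simulate_sfs_counts(sched, panel, SamplingScheme.scd(9), np.random.default_rng(16))
        mean_s = counts.sum() / n_loci
        expect = 4 * (self.D * nd) * 1e-8 * 600 * harmonic(17)
        assert mean_s == pytest.approx(expect, rel=0.05)

    def test_single_deme_sample_has_shorter_genealogies_than_scatter(self):
        # the scattering phase adds fast within-deme coalescences for SID,
        # shortening the genealogy's lower tail; the mean effect is less than
        # 1% of the TMRCA, so the sign test needs ~4e4 genealogies per scheme
        d = ParameterDraw(
            "FIM", {"Nm": 40.0, "N_anc": 31_000.0, "T_i": 59_000.0}, {"N_deme": 3000.0}
        )
        sched = build_schedule(d)
        panel = LocusPanel(np.full(100, 600.0), np.zeros(100), np.zeros(100))
        sid = mean_tmrca(sched, panel, SamplingScheme.sid(9), 400, seed=17)
        scd = mean_tmrca(sched, panel, SamplingScheme.scd(9), 400, seed=18)
        assert sid.mean() < scd.mean()


class TestDatasetGeneration:
    def test_zero_mutation_rate_gives_monomorphic_loci(self):
        panel = LocusPanel(np.full(4, 600.0), np.zeros(4), np.zeros(4))
        ds = simulate_dataset(cos_schedule(1000), panel, SamplingScheme.sid(3), seed=19)
        assert ds.n_sites == 0 and ds.n_loci == 4

    def test_identical_seeds_identical_datasets(self):
        panel = draw_locus_panel(20, 600.0, seed=1)
        sched = cos_schedule(20_000)
        a = simulate_dataset(sched, panel, SamplingScheme.scd(5), seed=77)
        b = simulate_dataset(sched, panel, SamplingScheme.scd(5), seed=77)
        assert all((x == y).all() for x, y in zip(a.genotypes, b.genotypes))
        assert all((x == y).all() for x, y in zip(a.positions, b.positions))

    def test_genotypes_are_biallelic_diploid_counts(self):
        panel = draw_locus_panel(30, 600.0, seed=2)
        ds = simulate_dataset(cos_schedule(50_000), panel, SamplingScheme.sid(11), seed=20)
        assert ds.n_sites > 0
        for g in ds.genotypes:
            assert g.dtype == np.int8 and g.shape[1] == 11
            assert g.min(initial=0) >= 0 and g.max(initial=0) <= 2
        for g, pos in zip(ds.genotypes, ds.positions):
            assert len(pos) == g.shape[0]
            assert len(np.unique(pos)) == len(pos)  # infinite sites: distinct positions

    def test_recombination_goes_through_msprime_for_unstructured_models(self):
        panel = LocusPanel(np.full(6, 2000.0), np.full(6, 1e-7), np.full(6, 1e-7))
        sched = build_schedule(
            ParameterDraw("CHG1", {"N_mod": 20_000.0, "N_anc": 5000.0, "T_c": 10_000.0})
        )
        ds = simulate_dataset(sched, panel, SamplingScheme.scd(4), seed=21)
        assert ds.n_sites > 0
        assert all(g.max(initial=0) <= 2 for g in ds.genotypes)

    def test_recombination_unsupported_for_island_models(self):
        d = ParameterDraw("FIM", {"Nm": 1.0, "N_anc": 100.0, "T_i": 100.0}, {"N_deme": 100.0})
        panel = LocusPanel([600.0], [1e-8], [1e-8])
        with pytest.raises(NotImplementedError, match="recombination"):
            simulate_dataset(build_schedule(d), panel, SamplingScheme.scd(2), seed=22)

    def test_scheme_deme_indices_validated(self):
        d = ParameterDraw("FIM", {"Nm": 1.0, "N_anc": 100.0, "T_i": 100.0}, {"N_deme": 100.0})
        scheme = SamplingScheme("BAD", np.array([0, 250]))
        with pytest.raises(ValueError, match="deme indices"):
            simulate_dataset(build_schedule(d), ONE_LOCUS, scheme, seed=23)


class TestLocusPanel:
    def test_fixed_length_panel_totals(self):
        panel = draw_locus_panel(995, 600.0, seed=3)
        assert panel.n_loci == 995
        assert panel.total_bp == 995 * 600
        # within 2% of the real scatter-set total of 606,647 bp
        assert panel.total_bp == pytest.approx(606_647, rel=0.02)

    def test_zero_mu_hyperprior(self):
        from metapopabc.models import PriorSpec

        panel = draw_locus_panel(50, 600.0, mu_hyperprior=PriorSpec("mu", "fixed", (0.0,)), seed=4)
        assert (panel.mu == 0).all()

    def test_lognormal_hyperprior_mean_matches_closed_form(self):
        from metapopabc.models import PriorSpec

        med, sig = 3e-9, 0.4
        panel = draw_locus_panel(
            100_000, 600.0, mu_hyperprior=PriorSpec("mu", "lognormal", (med, sig)), seed=5
        )
        expect = med * np.exp(sig**2 / 2)
        se = panel.mu.std() / np.sqrt(panel.n_loci)
        assert abs(panel.mu.mean() - expect) < 3 * se

    def test_invalid_panels_rejected(self):
        with pytest.raises(ValueError):
            LocusPanel([0.0], [1e-8], [0.0])
        with pytest.raises(ValueError):
            LocusPanel([600.0], [-1e-8], [0.0])
        with pytest.raises(ValueError):
            draw_locus_panel(0)
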