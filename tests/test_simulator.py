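import numpy as np
import pytest
from scipy import stats

from poreselect import (
    ChannelState,
    FragmentModel,
    RunConfig,
    TimeModel,
    build_observation_matrix,
    draw_fragment,
    make_community,
    run_experiment,
    sequence_step,
)
from poreselect.read_model import FORWARD, REVERSE
from poreselect.simulator import Fragment, emit_read, random_references


@pytest.fixture(scope="module")
def flat_community():
    refs = random_references(2, 2000, seed=3)
    return make_community(refs, [0.9, 0.1], seed=3, bias_sd=0.0)


class TestMakeCommunity:
    def test_no_variants_means_identical_sample(self):
        refs = random_references(1, 5000, seed=1)
        comm = make_community(refs, [1.0], snp_rate=0.0, seed=1)
        sp = comm.species[0]
        np.testing.assert_array_equal(sp.sample_codes, sp.ref_codes)
        assert len(comm.truth) == 0

    def test_planted_snp_count_within_poisson_3_sigma(self):
        refs = random_references(1, 100_000, seed=5)
        comm = make_community(refs, [1.0], snp_rate=0.01, seed=5)
        n = len(comm.truth)
        assert abs(n - 1000) < 3 * np.sqrt(1000)

    def test_abundances_normalized_exactly(self):
        refs = random_references(2, 1000, seed=2)
        comm = make_community(refs, [9.0, 1.0], seed=2)
        assert comm.species[0].abundance == pytest.approx(0.9)
        assert comm.species[1].abundance == pytest.approx(0.1)

    def test_rate_out_of_range_rejected(self):
        refs = random_references(1, 100, seed=0)
        with pytest.raises(ValueError):
            make_community(refs, [1.0], snp_rate=0.3)

    def test_every_variant_recorded_and_vcf_round_trips(self):
        refs = random_references(1, 20_000, seed=9)
        comm = make_community(refs, [1.0], snp_rate=0.01, deletion_rate=0.002, seed=9)
        sp = comm.species[0]
        planted = set(np.nonzero(sp.sample_codes != sp.ref_codes)[0].tolist())
        recorded = set(comm.truth["pos"].tolist())
        assert planted == recorded
        vcf = comm.to_vcf()
        body = [l for l in vcf.strip().split("\n") if not l.startswith("#")]
        assert len(body) == len(comm.truth)
        # SNP positions round-trip through the 1-based VCF POS column
        snps = comm.truth[comm.truth["type"] == "snp"]
        vcf_pos = {
            int(l.split("\t")[1]) - 1
            for l in body if "TYPE=snp" in l
        }
        assert vcf_pos == set(snps["pos"].tolist())

    def test_reproducible_by_seed(self):
        refs = random_references(1, 10_000, seed=4)
        a = make_community(refs, [1.0], snp_rate=0.01, seed=11)
        b = make_community(refs, [1.0], snp_rate=0.01, seed=11)
        assert a.truth.equals(b.truth)
        np.testing.assert_array_equal(a.species[0].bias, b.species[0].bias)


class TestDrawFragment:
    FM = FragmentModel(mean_length=400, sigma_log=0.5, min_length=50,
                       max_length=1500, p_unid=0.0)

    def test_flat_bias_gives_uniform_starts(self, flat_community):
        rng = np.random.default_rng(0)
        frags = [draw_fragment(flat_community, self.FM, rng) for _ in range(50_000)]
        starts = [f.start for f in frags if f.species == 0]
        # chi-square goodness of fit over 20 bins of the first species' genome
        hist, _ = np.histogram(starts, bins=20, range=(0, 2000))
        result = stats.chisquare(hist)
        assert result.pvalue > 0.01

    def test_species_fractions_track_abundance(self, flat_community):
        rng = np.random.default_rng(1)
        species = np.array([
            draw_fragment(flat_community, self.FM, rng).species
            for _ in range(50_000)
        ])
        assert abs((species == 0).mean() - 0.9) < 0.02

    def test_orientation_is_fair(self, flat_community):
        rng = np.random.default_rng(2)
        orients = np.array([
            draw_fragment(flat_community, self.FM, rng).orientation
            for _ in range(50_000)
        ])
        assert abs(orients.mean() - 0.5) < 0.02

    def test_fragment_fits_in_genome(self, flat_community):
        rng = np.random.default_rng(3)
        for _ in range(2000):
            f = draw_fragment(flat_community, self.FM, rng)
            lo, hi = f.ref_interval()
            assert 0 <= lo < hi <= flat_community.species[f.species].length
            assert f.length >= 1


class TestSequenceStep:
    def _phi(self, eps=0.0):
        return build_observation_matrix(eps, (0.0, 0.0), ploidy=1).phi

    def test_accepted_fragment_time_arithmetic(self, flat_community):
        tm = TimeModel(alpha=300, rho=300, mu=360)
        ch = ChannelState(0, "control")
        frag = Fragment(species=0, start=0, orientation=FORWARD, length=1000,
                        haplotype=0, unidentifiable=False)
        read = sequence_step(ch, frag, None, tm, flat_community, self._phi(),
                             np.random.default_rng(0))
        assert ch.clock == 300 + 1000
        assert read["accepted"] and read["obs_length"] == 1000

    def test_rejected_fragment_time_arithmetic(self, flat_community):
        tm = TimeModel(alpha=300, rho=300, mu=360)
        ch = ChannelState(0, "dynamic")
        frag = Fragment(species=0, start=0, orientation=FORWARD, length=1000,
                        haplotype=0, unidentifiable=False)
        from poreselect import DecisionStrategy
        strat = DecisionStrategy.reject_all(flat_community.contig_lengths)
        read = sequence_step(ch, frag, strat, tm, flat_community, self._phi(),
                             np.random.default_rng(0))
        assert ch.clock == 960
        assert not read["accepted"] and read["obs_length"] == 360

    def test_short_fragments_never_rejected(self, flat_community):
        tm = TimeModel(alpha=300, rho=300, mu=360)
        ch = ChannelState(0, "dynamic")
        frag = Fragment(species=0, start=0, orientation=FORWARD, length=200,
                        haplotype=0, unidentifiable=False)
        from poreselect import DecisionStrategy
        strat = DecisionStrategy.reject_all(flat_community.contig_lengths)
        read = sequence_step(ch, frag, strat, tm, flat_community, self._phi(),
                             np.random.default_rng(0))
        assert read["accepted"] and ch.clock == 500

    def test_error_free_read_reproduces_sample_genome(self, flat_community):
        frag = Fragment(species=0, start=100, orientation=FORWARD, length=500,
                        haplotype=0, unidentifiable=False)
        positions, obs = emit_read(frag, 500, flat_community, self._phi(0.0),
                                   np.random.default_rng(0))
        sp = flat_community.species[0]
        np.testing.assert_array_equal(obs, sp.sample_codes[100:600])
        np.testing.assert_array_equal(positions, np.arange(100, 600))

    def test_reverse_read_interval(self, flat_community):
        frag = Fragment(species=0, start=599, orientation=REVERSE, length=500,
                        haplotype=0, unidentifiable=False)
        positions, obs = emit_read(frag, 500, flat_community, self._phi(0.0),
                                   np.random.default_rng(0))
        np.testing.assert_array_equal(positions, np.arange(100, 600))


@pytest.fixture(scope="module")
def small_run():
    refs = random_references(2, 20_000, seed=6)
    comm = make_community(refs, [0.9, 0.1], snp_rate=0.005, seed=6)
    cfg = RunConfig(time_budget=150_000.0, n_channels=2, n_snapshots=5, seed=6)
    return run_experiment(cfg, community=comm)


class TestRunExperiment:
    def test_zero_length_run_is_empty(self):
        refs = random_references(1, 5000, seed=7)
        comm = make_community(refs, [1.0], seed=7)
        cfg = RunConfig(time_budget=0.0, seed=7)
        res = run_experiment(cfg, community=comm)
        assert len(res.read_log) == 0
        assert res.final_strategy.step == 0
        assert all(m.all() for m in res.final_strategy.masks.values())

    def test_time_conservation_per_channel(self, small_run):
        log = small_run.read_log
        for (cond, ch), grp in log.groupby(["condition", "channel"]):
            assert grp["clock"].iloc[-1] == grp["cost"].sum()

    def test_rejected_reads_observe_exactly_mu(self, small_run):
        log = small_run.read_log
        rejected = log[~log["accepted"]]
        assert len(rejected) > 0
        mu = small_run.config.mu
        assert (rejected["obs_length"] == np.minimum(rejected["true_length"], mu)).all()
        accepted = log[log["accepted"]]
        assert (accepted["obs_length"] == accepted["true_length"]).all()

    def test_costs_follow_the_process_model(self, small_run):
        log = small_run.read_log
        cfg = small_run.config
        accepted = log[log["accepted"]]
        assert (accepted["cost"] == cfg.alpha + accepted["true_length"]).all()
        rejected = log[~log["accepted"]]
        assert (rejected["cost"]
                == cfg.alpha + rejected["obs_length"] + cfg.rho).all()

    def test_accepted_fraction_declines_for_dominant_species(self, small_run):
        hist = small_run.strategy_history
        series = hist["accepted_species1"].to_numpy()
        assert series[0] == 1.0
        assert series[-1] < series[0]

    def test_coverage_conservation(self, small_run):
        """Total depth equals total observed bases of identified reads."""
        log = small_run.read_log
        for cond in ("dynamic", "control"):
            ident = log[(log["condition"] == cond) & log["identified"]]
            total_bases = int(ident["obs_length"].sum())
            total_depth = int(sum(d.sum() for d in small_run.depth[cond].values()))
            assert total_depth == total_bases

    def test_accepted_lengths_reproduce_fragment_distribution(self, small_run):
        """Accepted reads keep the fragment-length distribution (two-sample KS
        against fresh draws from the same fragment model); rejected observed
        lengths are degenerate at mu."""
        from poreselect.simulator import FragmentModel, draw_fragment
        log = small_run.read_log
        cfg = small_run.config
        accepted = log[(log["condition"] == "control") & log["accepted"]]
        fm = FragmentModel(
            mean_length=cfg.mean_fragment_length,
            sigma_log=cfg.fragment_sigma_log,
            min_length=min(cfg.mu + 1, cfg.max_read_length),
            max_length=cfg.max_read_length,
            p_unid=cfg.p_unid,
        )
        rng = np.random.default_rng(123)
        fresh = [draw_fragment(small_run.community, fm, rng).length
                 for _ in range(5000)]
        result = stats.ks_2samp(accepted["obs_length"], fresh)
        assert result.pvalue > 0.01

    def test_reproducible_bit_for_bit(self):
        refs = random_references(1, 10_000, seed=8)
        comm = make_community(refs, [1.0], seed=8)
        cfg = RunConfig(time_budget=50_000.0, n_channels=1, seed=8)
        a = run_experiment(cfg, community=comm)
        b = run_experiment(cfg, community=comm)
        assert a.read_log.equals(b.read_log)

    def test_accept_all_groups_are_exchangeable(self):
        """With no unidentifiable fragments and updates disabled, the dynamic
        group's accept-all behaviour is indistinguishable from the control."""
        refs = random_references(1, 10_000, seed=9)
        comm = make_community(refs, [1.0], seed=9)
        cfg = RunConfig(time_budget=80_000.0, n_channels=2, p_unid=0.0,
                        update_reads=10**9, update_interval_seconds=0.0, seed=9)
        res = run_experiment(cfg, community=comm)
        dyn = res.read_log[res.read_log["condition"] == "dynamic"].drop(
            columns=["condition"]).reset_index(drop=True)
        ctl = res.read_log[res.read_log["condition"] == "control"].drop(
            columns=["condition"]).reset_index(drop=True)
        assert dyn.equals(ctl)
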