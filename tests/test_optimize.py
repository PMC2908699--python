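import itertools

import numpy as np
import pytest

from dcmotif import synth
from dcmotif.encode import build_pwm, score_sequence
from dcmotif.errors import ConfigurationError
from dcmotif.optimize import (
    Chromosome,
    FitnessConfig,
    apply_chromosome,
    crossover_maxmin,
    fitness,
    ga_optimize,
    leave_one_out,
    measure_from_scores,
    mutate,
)


def family_setup(seed, n_families=4, n_per=15):
    cfg = synth.SynthConfig(
        seed=seed, n_families=n_families, sites_per_submotif=n_per,
        parent_conservation=0.9, n_negatives=60, n_decoy_pwms=4,
    )
    ds = synth.make_dataset(cfg)
    fams = sorted(set(ds.site_family.values()))
    subs = [
        build_pwm(
            ds.positives.subset(
                [sid for sid, f in ds.site_family.items() if f == fam]
            ),
            name=fam,
        )
        for fam in fams
    ]
    pos_scores = np.array(
        [[score_sequence(p, s) for p in subs] for s in ds.positives.sequences]
    )
    neg_scores = np.array(
        [[score_sequence(p, s) for p in subs] for s in ds.negatives.sequences]
    )
    return ds, subs, pos_scores, neg_scores


class TestFitness:
    def test_w2_zero_equals_measure(self):
        _, _, ps, ns = family_setup(0)
        config = FitnessConfig(w2=0.0)
        chrom = Chromosome(np.column_stack([np.ones(4), np.full(4, 0.8)]))
        assert fitness(chrom, ps, ns, config) == pytest.approx(
            measure_from_scores(chrom, ps, ns, "scc")
        )

    def test_complexity_term_half(self):
        _, _, ps, ns = family_setup(0)
        al = np.zeros((12, 2))
        al[:6, 0] = 1.0
        al[:, 1] = 0.5
        chrom = Chromosome(al)
        config = FitnessConfig(w1=0.0, w2=1.0)
        # 6 of 12 active -> complexity penalty exactly 0.5
        assert fitness(chrom, ps[:, :12] if ps.shape[1] >= 12 else
                       np.tile(ps, (1, 3)), np.tile(ns, (1, 3)), config
                       ) == pytest.approx(-0.5)

    def test_fewer_submotifs_higher_fitness_at_equal_measure(self):
        _, _, ps, ns = family_setup(0)
        config = FitnessConfig()
        a = Chromosome(np.column_stack([np.ones(4), np.zeros(4)]))
        b = Chromosome(
            np.column_stack([np.array([1.0, 0, 0, 0]), np.zeros(4)])
        )
        # both accept everything (thresholds 0) so measures are equal
        ma = measure_from_scores(a, ps, ns, "scc")
        mb = measure_from_scores(b, ps, ns, "scc")
        assert ma == pytest.approx(mb)
        assert fitness(b, ps, ns, config) > fitness(a, ps, ns, config)

    def test_no_active_alleles_is_worst(self):
        _, _, ps, ns = family_setup(0)
        config = FitnessConfig()
        empty = Chromosome(np.zeros((4, 2)))
        anything = Chromosome(np.column_stack([np.ones(4), np.full(4, 0.99)]))
        assert fitness(empty, ps, ns, config) < fitness(anything, ps, ns, config)


class TestCrossover:
    def test_identical_parents(self):
        p = Chromosome(np.array([[0.7, 0.3], [0.2, 0.9]]))
        child = crossover_maxmin(p, p, a=0.3, scorer=lambda c: 0.0)
        np.testing.assert_allclose(child.alleles, p.alleles)

    def test_candidate_set_of_extreme_parents(self):
        p0 = Chromosome(np.zeros((3, 2)))
        p1 = Chromosome(np.ones((3, 2)))
        seen = []
        crossover_maxmin(p0, p1, a=0.5, scorer=lambda c: seen.append(
            c.alleles.copy()) or 0.0)
        arr = np.array(seen)
        assert any(np.allclose(x, 0.0) for x in arr)
        assert any(np.allclose(x, 1.0) for x in arr)
        assert any(np.allclose(x, 0.5) for x in arr)

    def test_returns_argmax_of_scorer(self):
        p0 = Chromosome(np.zeros((3, 2)))
        p1 = Chromosome(np.ones((3, 2)))
        scorer = lambda c: float(c.alleles.sum())  # noqa: E731
        child = crossover_maxmin(p0, p1, a=0.25, scorer=scorer)
        np.testing.assert_allclose(child.alleles, 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            crossover_maxmin(
                Chromosome(np.zeros((2, 2))), Chromosome(np.zeros((3, 2))),
                a=0.5, scorer=lambda c: 0.0,
            )


class _NeverFireRng:
    """random() alternates 1.0 (no flip) and 0.5 (jitter factor 1.0)."""

    def __init__(self):
        self.calls = 0

    def random(self):
        self.calls += 1
        return 1.0 if self.calls % 2 == 1 else 0.5


class TestMutate:
    def test_forced_no_op(self):
        chrom = Chromosome(np.array([[0.9, 0.8], [0.1, 0.4]]))
        out = mutate(chrom, _NeverFireRng())
        np.testing.assert_allclose(out.alleles, chrom.alleles)

    def test_threshold_stays_within_ten_percent(self):
        rng = np.random.default_rng(0)
        chrom = Chromosome(np.array([[0.9, 0.8]]))
        for _ in range(200):
            out = mutate(chrom, rng)
            assert 0.72 - 1e-12 <= out.alleles[0, 1] <= 0.88 + 1e-12

    def test_on_off_rate_monte_carlo(self):
        rng = np.random.default_rng(1)
        chrom = Chromosome(np.column_stack([np.ones(1), np.full(1, 0.5)]))
        flips = sum(
            mutate(chrom, rng).alleles[0, 0] < 0.5 for _ in range(10_000)
        )
        # binomial(10^4, 0.05): 3 sigma ~ 65
        assert abs(flips - 500) < 70

    def test_off_on_rate_monte_carlo(self):
        rng = np.random.default_rng(2)
        chrom = Chromosome(np.column_stack([np.zeros(1), np.full(1, 0.5)]))
        flips = sum(
            mutate(chrom, rng).alleles[0, 0] > 0.5 for _ in range(10_000)
        )
        # binomial(10^4, 0.005): 3 sigma ~ 21
        assert abs(flips - 50) < 25


class TestGaOptimize:
    def test_single_submotif_matches_exhaustive_threshold(self):
        ds, subs, ps, ns = family_setup(1, n_families=1, n_per=25)
        config = FitnessConfig(seed=3, population=30, generations=50, w2=0.0)
        result = ga_optimize(subs[:1], ds.positives, ds.negatives, config)
        best_thr, best_val = None, -np.inf
        for thr in np.linspace(0.0, 1.0, 201):
            c = Chromosome(np.array([[1.0, thr]]))
            v = fitness(c, ps[:, :1], ns[:, :1], config)
            if v > best_val:
                best_thr, best_val = thr, v
        assert result.best_fitness >= best_val - 1e-9 or abs(
            result.best.thresholds[0] - best_thr
        ) <= 0.02

    def test_beats_nine_point_grid_oracle(self):
        ds, subs, ps, ns = family_setup(2)
        config = FitnessConfig(seed=5, population=40, generations=60, w2=0.25)
        grid = np.arange(0.1, 0.91, 0.1)
        best_ex = -np.inf
        for mask in itertools.product([0, 1], repeat=4):
            if not any(mask):
                continue
            active = [i for i in range(4) if mask[i]]
            for thrs in itertools.product(grid, repeat=len(active)):
                al = np.zeros((4, 2))
                al[:, 0] = mask
                for i, t in zip(active, thrs):
                    al[i, 1] = t
                best_ex = max(best_ex, fitness(Chromosome(al), ps, ns, config))
        result = ga_optimize(subs, ds.positives, ds.negatives, config)
        assert result.best_fitness >= 0.99 * best_ex

    def test_seed_determinism(self):
        ds, subs, _, _ = family_setup(3)
        config = FitnessConfig(seed=9, population=20, generations=15)
        r1 = ga_optimize(subs, ds.positives, ds.negatives, config)
        r2 = ga_optimize(subs, ds.positives, ds.negatives, config)
        np.testing.assert_array_equal(r1.best.alleles, r2.best.alleles)
        assert r1.history == r2.history

    def test_elitism_monotone_history(self):
        ds, subs, _, _ = family_setup(4)
        config = FitnessConfig(seed=11, population=20, generations=25)
        result = ga_optimize(subs, ds.positives, ds.negatives, config)
        assert all(
            b >= a - 1e-12 for a, b in zip(result.history, result.history[1:])
        )

    def test_pareto_mutually_non_dominated(self):
        ds, subs, _, _ = family_setup(5)
        config = FitnessConfig(seed=13, population=30, generations=30, w2=0.25)
        result = ga_optimize(subs, ds.positives, ds.negatives, config)
        for a in result.pareto:
            for b in result.pareto:
                if a is b:
                    continue
                dominates = (
                    b.measure >= a.measure and b.n_active <= a.n_active
                ) and (b.measure > a.measure or b.n_active < a.n_active)
                assert not dominates

    def test_population_too_small(self):
        with pytest.raises(ConfigurationError):
            FitnessConfig(population=1)

    def test_all_families_survive_at_accuracy_weights(self):
        """Every planted family keeps >= 1 active submotif in the
        best configuration under accuracy-dominant selection pressures."""
        cfg = synth.SynthConfig(
            seed=6, n_families=3, submotifs_per_family=2,
            sites_per_submotif=12, parent_conservation=0.9,
            n_negatives=60, n_decoy_pwms=3,
        )
        ds = synth.make_dataset(cfg)
        subs = []
        names = []
        for pwm in ds.pwms:
            ids = [
                sid for sid, f in ds.site_family.items()
                if sid.startswith(pwm.name + "_")
            ]
            subs.append(build_pwm(ds.positives.subset(ids), name=pwm.name))
            names.append(pwm.name)
        fam_of = ds.family_of
        for w2 in (0.05, 0.15):
            config = FitnessConfig(seed=21, population=40, generations=50, w2=w2)
            result = ga_optimize(subs, ds.positives, ds.negatives, config)
            active_fams = {
                fam_of[names[i]]
                for i in range(len(subs))
                if result.best.active[i]
            }
            assert active_fams == set(fam_of.values())


class TestApplyAndLoo:
    def test_apply_chromosome_flags_and_thresholds(self):
        ds, subs, _, _ = family_setup(7)
        chrom = Chromosome(
            np.column_stack([np.array([1.0, 0.0, 1.0, 0.0]),
                             np.array([0.6, 0.2, 0.9, 0.1])])
        )
        mc = apply_chromosome(subs, chrom)
        assert [v.active for v in mc.voters] == [True, False, True, False]
        assert mc.voters[2].threshold == pytest.approx(0.9)

    def test_leave_one_out_counts(self):
        ds, subs, ps, _ = family_setup(8)
        thresholds = np.full(len(subs), 0.85)
        table = leave_one_out(subs, thresholds, ds.positives)
        hits = ps >= 0.85
        for i, pwm in enumerate(subs):
            own = hits[:, i]
            others = np.delete(hits, i, axis=1).any(axis=1)
            assert table[pwm.name]["recovered"] == int(own.sum())
            assert table[pwm.name]["lost_without"] == int((own & ~others).sum())
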