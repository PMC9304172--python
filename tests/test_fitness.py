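import numpy as np
import pandas as pd
import pytest

from selsig.fitness import (
    GeneFitness,
    aggregate_gene_fitness,
    area_ratio_filter,
    compare_fitness_by_class,
    correlate_fitness_with_stats,
    relative_fitness,
    zscore_by_chamber,
)
from selsig.simulate import simulate_fitness_table


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "line_id",
            "gene_id",
            "replicate_id",
            "chamber_id",
            "ko_fruit_count",
            "wt_fruit_count",
            "area_ratio",
        ],
    )


def _rows(gene, ratios, chamber="ch1", area=1.0, wt=40):
    return [
        (f"L_{gene}", gene, f"rep{i}", chamber, int(round(r * wt)), wt, area)
        for i, r in enumerate(ratios)
    ]


class TestRelativeFitness:
    def test_ratio(self):
        assert relative_fitness(30, 40) == pytest.approx(0.75)

    def test_identity(self):
        assert relative_fitness(17, 17) == 1.0

    def test_zero_wild_type_dropped(self):
        assert relative_fitness(10, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            relative_fitness(-1, 10)


class TestAggregate:
    def test_mean_of_four_replicates(self):
        table = _table(_rows("g1", [0.8, 1.0, 1.2, 1.0]))
        [g] = aggregate_gene_fitness(table)
        assert g.w == pytest.approx(1.0)
        assert g.n_obs == 4

    def test_three_observations_excluded(self):
        table = _table(_rows("g1", [1.0, 1.0, 1.0]))
        assert aggregate_gene_fitness(table) == []

    def test_zero_wt_replicate_dropped_from_mean(self):
        rows = _rows("g1", [0.8, 1.0, 1.2, 1.0]) + [
            ("L_g1", "g1", "rep9", "ch1", 10, 0, 1.0)
        ]
        [g] = aggregate_gene_fitness(_table(rows))
        assert g.n_obs == 4
        assert g.w == pytest.approx(1.0)

    def test_permutation_invariant(self, rng):
        rows = _rows("g1", [0.5, 0.9, 1.4, 1.1]) + _rows("g2", [1.0, 1.2, 0.7, 0.9])
        table = _table(rows)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = aggregate_gene_fitness(table)
        b = aggregate_gene_fitness(shuffled)
        assert [g.gene_id for g in a] == [g.gene_id for g in b]
        assert [g.n_obs for g in a] == [g.n_obs for g in b]
        assert [g.w for g in a] == pytest.approx([g.w for g in b])


class TestAreaRatioFilter:
    def _genes(self, ratios):
        return [
            GeneFitness(f"g{i}", 1.0, 4, area_ratio=r) for i, r in enumerate(ratios)
        ]

    def test_strictly_greater_dropped(self):
        kept = area_ratio_filter(self._genes([1.6, 1.5, None]))
        assert [g.gene_id for g in kept] == ["g1", "g2"]

    def test_missing_retained(self):
        kept = area_ratio_filter(self._genes([None]))
        assert len(kept) == 1


class TestZscore:
    def test_single_chamber_population_sd(self):
        table = _table(_rows("g1", [1.0, 2.0, 3.0]) + _rows("g2", [1.0, 2.0, 3.0]))
        genes = zscore_by_chamber(table, min_obs=3)
        # ratios approximated by integer fruit counts; the standardised
        # values of {1,2,3} are -1.2247, 0, 1.2247 and average to z = 0
        for g in genes:
            assert g.z == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_chamber_dropped(self):
        table = _table(_rows("g1", [1.0, 1.0, 1.0, 1.0]))
        assert zscore_by_chamber(table) == []

    def test_chamber_offset_removed(self):
        rows = _rows("g1", [0.5, 0.8, 1.1, 1.4], chamber="ch1") + _rows(
            "g2", [1.5, 1.8, 2.1, 2.4], chamber="ch2"
        )
        genes = zscore_by_chamber(_table(rows))
        zs = {g.gene_id: g.z for g in genes}
        # identical within-chamber shapes -> identical z despite offset means
        assert zs["g1"] == pytest.approx(zs["g2"], abs=1e-9)


class TestCompareByClass:
    def test_identical_groups_not_significant(self):
        genes = [GeneFitness(f"g{i}", 1.0 + 0.01 * (i % 5), 4) for i in range(40)]
        flags = pd.Series(
            [i < 20 for i in range(40)], index=[f"g{i}" for i in range(40)]
        )
        res = compare_fitness_by_class(genes, flags)
        assert res["p"] > 0.5

    def test_empty_class_skipped(self):
        genes = [GeneFitness("g0", 1.0, 4)]
        flags = pd.Series([False], index=["g0"])
        assert compare_fitness_by_class(genes, flags) is None

    def test_detects_shifted_group(self, rng):
        n = 150
        w_rest = rng.normal(1.0, 0.2, size=n)
        w_cand = rng.normal(0.5, 0.2, size=n)
        genes = [GeneFitness(f"a{i}", max(w, 0.0), 4) for i, w in enumerate(w_cand)]
        genes += [GeneFitness(f"b{i}", max(w, 0.0), 4) for i, w in enumerate(w_rest)]
        flags = pd.Series(
            {g.gene_id: g.gene_id.startswith("a") for g in genes}
        )
        res = compare_fitness_by_class(genes, flags)
        assert res["p"] < 0.05
        assert res["median_candidate"] < res["median_other"]


class TestCorrelate:
    def test_identical_ranks_give_rho_one(self):
        genes = [GeneFitness(f"g{i}", float(i + 1), 4) for i in range(20)]
        prof = pd.DataFrame(
            {"omega": np.arange(20, dtype=float)},
            index=[f"g{i}" for i in range(20)],
        )
        out = correlate_fitness_with_stats(genes, prof)
        assert out.loc[out.statistic == "omega", "rho"].iloc[0] == pytest.approx(1.0)

    def test_constant_fitness_flagged_undefined(self):
        genes = [GeneFitness(f"g{i}", 1.0, 4) for i in range(10)]
        prof = pd.DataFrame(
            {"omega": np.arange(10, dtype=float)}, index=[f"g{i}" for i in range(10)]
        )
        out = correlate_fitness_with_stats(genes, prof)
        assert np.isnan(out["rho"].iloc[0])

    def test_bh_adjustment_present(self, rng):
        genes = [
            GeneFitness(f"g{i}", float(v), 4)
            for i, v in enumerate(rng.uniform(0.5, 1.5, size=30))
        ]
        prof = pd.DataFrame(
            {
                "omega": rng.normal(size=30),
                "ni": rng.normal(size=30),
            },
            index=[f"g{i}" for i in range(30)],
        )
        out = correlate_fitness_with_stats(genes, prof)
        assert (out["p_bh"] >= out["p"] - 1e-12).all()


class TestSimulatedFitnessGenerator:
    def test_null_mean_near_one(self, rng):
        genes = [f"g{i}" for i in range(379)]
        table = simulate_fitness_table(
            genes, [False] * 379, effect=0.0, noise_sd=0.2,
            n_replicates=5, n_chambers=3, rng=rng,
        )
        agg = aggregate_gene_fitness(table)
        ws = np.array([g.w for g in agg])
        assert abs(ws.mean() - 1.0) < 2 * ws.std() / np.sqrt(len(ws))

    def test_candidate_effect_recovered(self, rng):
        genes = [f"g{i}" for i in range(200)]
        cand = [i < 100 for i in range(200)]
        table = simulate_fitness_table(
            genes, cand, effect=0.2, noise_sd=0.2,
            n_replicates=6, n_chambers=2, rng=rng,
        )
        agg = {g.gene_id: g.w for g in aggregate_gene_fitness(table)}
        w_cand = np.mean([w for g, w in agg.items() if int(g[1:]) < 100])
        w_rest = np.mean([w for g, w in agg.items() if int(g[1:]) >= 100])
        assert w_cand == pytest.approx(0.8, abs=0.1)
        assert w_rest == pytest.approx(1.0, abs=0.1)

    def test_four_replicates_pass_observation_filter(self, rng):
        genes = [f"g{i}" for i in range(20)]
        table = simulate_fitness_table(
            genes, [False] * 20, effect=0.0, noise_sd=0.2,
            n_replicates=4, n_chambers=2, rng=rng, wt_mean_fruits=60.0,
        )
        assert len(aggregate_gene_fitness(table)) == 20
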