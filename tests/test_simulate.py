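import numpy as np
import pandas as pd
import pytest

from trasplice import (
    ParameterError,
    SimulationParams,
    count_reads,
    entropy_score,
    make_design,
    simulate_atlas,
    simulate_counts,
    simulate_gene_models,
    simulate_read_intervals,
    simulation_truth,
)
from trasplice.simulate import AFFECTED_GENOTYPES, GENOTYPES, _draw_counts, _substream
from conftest import small_params


class TestParams:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"frac_tra": 1.5},
            {"category_probs": {"prmt5_only": 0.5, "aire_only": 0.5, "shared": 0.5, "other": -0.5}},
            {"category_probs": {"prmt5_only": 1.0}},
            {"n_replicates": 1},
            {"deficient_intron_frac": 0.05, "base_intron_frac": 0.05},
            {"n_tissues": 3},
            {"tra_breadth": (0, 3)},
        ],
    )
    def test_invalid_params_rejected(self, overrides):
        with pytest.raises(ParameterError):
            small_params(**overrides)

    def test_dict_round_trip(self, params):
        assert SimulationParams.from_dict(params.to_dict()) == params


class TestTruth:
    def test_every_gene_has_one_category(self, params):
        truth = simulation_truth(params)
        cats = truth.table["true_category"]
        assert cats.isin(
            ["TRA_Prmt5", "TRA_Aire", "TRA_shared", "TRA_other", "non_TRA", "not_expressed"]
        ).all()
        n_tra_cats = cats.str.startswith("TRA_").sum()
        n_planted_tra = truth.table["is_tra"].sum()
        # TRA categories cover the planted TRAs except those silenced
        silent_tra = (truth.table["is_tra"] & (cats == "not_expressed")).sum()
        assert n_tra_cats + silent_tra == n_planted_tra

    def test_pi_and_mu_consistent_with_params(self, params):
        truth = simulation_truth(params)
        t = truth.table
        for g in GENOTYPES:
            affected = t["planted_class"].map(
                lambda c: g in AFFECTED_GENOTYPES.get(c, ())
            )
            expect_mu = t["baseline"] * np.where(affected, params.downreg_fc, 1.0)
            assert np.allclose(t[f"mu_{g}"], expect_mu)
            multi = ~t["single_exon"]
            assert (
                t.loc[affected & multi, f"pi_{g}"] == params.deficient_intron_frac
            ).all()
            assert (
                t.loc[~affected & multi, f"pi_{g}"] == params.base_intron_frac
            ).all()
            assert (t.loc[t["single_exon"], f"pi_{g}"] == 0.0).all()
        assert (t.loc[t["true_category"] == "not_expressed", "baseline"] == 0).all()
        # depth floor: every expressed gene gets at least the minimum depth
        assert (t.loc[t["baseline"] > 0, "baseline"] >= params.depth_range[0]).all()


class TestAtlas:
    def test_planted_rows_are_tissue_restricted(self, simulated, params):
        atlas, truth, *_ = simulated
        h = atlas.values.apply(entropy_score, axis=1)
        assert (h[truth.table["is_tra"]] < 3.0).all()
        assert (h[~truth.table["is_tra"]] >= 3.0).all()

    def test_noiseless_planted_entropy(self):
        p = small_params(atlas_noise_sd=0.0, tra_breadth=(1, 1), n_tissues=8, atlas_low=0.0)
        atlas, truth = simulate_atlas(p)
        h = atlas.values.apply(entropy_score, axis=1)
        # single-tissue genes with zero background: exactly 0 bits
        assert np.allclose(h[truth.table["is_tra"]], 0.0)
        # uniform genes over 8 tissues: exactly 3 bits
        assert np.allclose(h[~truth.table["is_tra"]], 3.0)


class TestGeneModels:
    def test_intron_counts_and_non_overlap(self, simulated, params):
        _, truth, models, *_ = simulated
        assert [m.gene_id for m in models] == list(truth.gene_ids)
        prev_end = -1
        for m in models:
            assert m.start > prev_end, "genes must not overlap"
            prev_end = m.end
            assert len(m.introns) == len(m.exons) - 1
        single = truth.table["single_exon"]
        by_id = {m.gene_id: m for m in models}
        for gid, is_single in single.items():
            assert (len(by_id[gid].exons) == 1) == is_single
        # all spliceable genes have at least one intron
        assert all(len(by_id[g].introns) >= 1 for g in single.index[~single])


class TestCounts:
    def test_deterministic_expectation_split(self):
        rng = _substream(0, "x")
        out = _draw_counts(rng, np.array([80.0, 20.0]), None)
        assert list(out) == [80, 20]

    def test_deterministic_counts_equal_rounded_expectations(self, det_simulated, det_params):
        _, truth, models, design, counts = det_simulated
        for _, row in design.iterrows():
            mu = truth.table[f"mu_{row['genotype']}"]
            pi = truth.table[f"pi_{row['genotype']}"]
            assert (counts.exon[row["sample_id"]] == np.round(mu * (1 - pi))).all()
            assert (counts.intron[row["sample_id"]] == np.round(mu * pi)).all()

    def test_prmt5_only_gene_arithmetic(self, det_simulated, det_params):
        # spot-check the generative formula on a splicing-deficient gene:
        # baseline B, fc 0.2, pi 0.05 -> 0.35 gives control (0.95B, 0.05B)
        # and knockout (0.13B, 0.07B); retention index jumps 0.05 -> 0.35 (x7)
        _, truth, models, design, counts = det_simulated
        gid = truth.genes_in_class("TRA_Prmt5")[0]
        b = truth.table.at[gid, "baseline"]
        ctrl = design.loc[design["genotype"] == "control", "sample_id"].iloc[0]
        ko = design.loc[design["genotype"] == "prmt5_ko", "sample_id"].iloc[0]
        assert counts.exon.at[gid, ctrl] == round(b * 0.95)
        assert counts.intron.at[gid, ctrl] == round(b * 0.05)
        assert counts.exon.at[gid, ko] == round(b * 0.2 * 0.65)
        assert counts.intron.at[gid, ko] == round(b * 0.2 * 0.35)
        iri_ctrl = counts.intron.at[gid, ctrl] / (counts.exon.at[gid, ctrl] + counts.intron.at[gid, ctrl])
        iri_ko = counts.intron.at[gid, ko] / (counts.exon.at[gid, ko] + counts.intron.at[gid, ko])
        assert iri_ctrl == pytest.approx(0.05, abs=0.005)
        assert iri_ko == pytest.approx(0.35, abs=0.005)
        assert iri_ko / iri_ctrl == pytest.approx(7.0, rel=0.15)

    def test_poisson_limit_monte_carlo(self):
        # 10,000 replicate draws at mu=100, pi=0.2: mean intron count ~ 20
        rng = _substream(123, "mc")
        draws = _draw_counts(rng, np.full(10_000, 100 * 0.2), 0.0)
        assert draws.mean() == pytest.approx(20.0, rel=0.01)

    def test_nb_dispersion_inflates_variance(self):
        rng = _substream(5, "nb")
        mean = np.full(20_000, 200.0)
        pois = _draw_counts(_substream(5, "p"), mean, 0.0)
        nb = _draw_counts(rng, mean, 0.5)
        assert nb.var() > 4 * pois.var()
        assert nb.mean() == pytest.approx(200.0, rel=0.05)

    def test_unknown_genotype_rejected(self, params):
        models = simulate_gene_models(params)
        design = pd.DataFrame({"sample_id": ["x1", "x2"], "genotype": ["mutant", "mutant"], "replicate": [1, 2]})
        with pytest.raises(ParameterError, match="mutant"):
            simulate_counts(params, models, design)


class TestDeterminism:
    def test_same_seed_bit_identical(self, params):
        a1, t1 = simulate_atlas(params)
        a2, t2 = simulate_atlas(params)
        pd.testing.assert_frame_equal(a1.values, a2.values)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        design = make_design(params)
        models = simulate_gene_models(params)
        c1, _ = simulate_counts(params, models, design)
        c2, _ = simulate_counts(params, models, design)
        pd.testing.assert_frame_equal(c1.exon, c2.exon)
        pd.testing.assert_frame_equal(c1.intron, c2.intron)

    def test_different_seeds_differ(self, params):
        other = small_params(seed=params.seed + 1)
        a1, _ = simulate_atlas(params)
        a2, _ = simulate_atlas(other)
        assert not a1.values.equals(a2.values)


class TestReadIntervals:
    def test_round_trip_reproduces_counts(self, det_params):
        # oracle for the placement is the counting module itself
        models = simulate_gene_models(det_params)
        design = make_design(det_params)
        counts, _ = simulate_counts(det_params, models, design)
        beds = simulate_read_intervals(counts, models, read_length=det_params.read_length, seed=11)
        recounted = count_reads(beds, models)
        pd.testing.assert_frame_equal(recounted.exon, counts.exon, check_dtype=False)
        pd.testing.assert_frame_equal(recounted.intron, counts.intron, check_dtype=False)

    def test_zero_counts_empty_bed(self, det_params):
        models = simulate_gene_models(det_params)[:3]
        from trasplice import FeatureCountMatrix

        genes = [m.gene_id for m in models]
        zero = pd.DataFrame({"s1": [0, 0, 0]}, index=genes)
        counts = FeatureCountMatrix(
            exon=zero, intron=zero.copy(),
            exonic_length=pd.Series([m.exonic_length for m in models], index=genes),
            intronic_length=pd.Series([m.intronic_length for m in models], index=genes),
        )
        beds = simulate_read_intervals(counts, models, read_length=50, seed=0)
        assert len(beds["s1"]) == 0

    def test_read_length_guard(self, det_params):
        models = simulate_gene_models(det_params)
        design = make_design(det_params)
        counts, _ = simulate_counts(det_params, models, design)
        with pytest.raises(ParameterError, match="read_length"):
            simulate_read_intervals(counts, models, read_length=10_000, seed=0)
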