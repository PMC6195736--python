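"""Model-space enumeration, sub-model expansion, fallback scoring, ranking."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from mitosub import (
    ModelSpec,
    StateExposureTable,
    enumerate_models,
    expand_submodels,
    fallback_score,
    rank_models,
    score_model,
)
from mitosub.search import (
    INCLUDE,
    NONCODING_FACTORS,
    OMIT,
    OPTIONS,
    PARTITION,
    PROTEIN_FACTORS,
    TRNA_FACTORS,
    saturated_poisson_loglik,
    spec_is_valid,
)


def _brute_force_count(factors, constraint) -> int:
    return sum(
        1
        for assignment in product(OPTIONS, repeat=len(factors))
        if constraint(dict(zip(factors, assignment)))
    )


class TestEnumeration:
    def test_protein_coding_space_size(self):
        assert len(enumerate_models("protein_coding")) == 31185

    @pytest.mark.parametrize(
        "region,expected", [("rRNA", 486), ("control", 486), ("tRNA", 1458)]
    )
    def test_noncoding_space_sizes(self, region, expected):
        assert len(enumerate_models(region)) == expected

    def test_subproducts_against_brute_force(self):
        # codon/amino-acid/nucleotide block: 11 of 27
        n_codon = _brute_force_count(
            ["codon", "amino_acid", "nucleotide"],
            lambda o: not (
                o["codon"] != OMIT
                and (o["amino_acid"] != OMIT or o["nucleotide"] != OMIT)
            ),
        )
        # gene/cluster block: 5 of 9
        n_gene = _brute_force_count(
            ["gene", "cluster"],
            lambda o: not (o["gene"] != OMIT and o["cluster"] != OMIT),
        )
        # codon-position/neighbors block: 21 of 27
        n_pos = _brute_force_count(
            ["codon_position", "left_neighbor", "right_neighbor"],
            lambda o: not (
                o["codon_position"] == PARTITION
                and o["left_neighbor"] != o["right_neighbor"]
            ),
        )
        assert (n_codon, n_gene, n_pos) == (11, 5, 21)
        # directionality x cpg x response scheme contributes the final 3^3
        assert n_codon * n_gene * n_pos * 27 == 31185

    def test_full_filter_equals_structured_product(self):
        brute = sum(
            1
            for assignment in product(OPTIONS, repeat=len(PROTEIN_FACTORS))
            if spec_is_valid(dict(zip(PROTEIN_FACTORS, assignment)))
        )
        assert brute * 3 == len(enumerate_models("protein_coding"))

    def test_redundant_specs_flagged_not_removed(self):
        specs = enumerate_models("protein_coding")
        flagged = [s for s in specs if s.redundancy_flag]
        assert flagged  # gene + directionality combinations exist
        for spec in flagged:
            assert spec.option("gene") != OMIT
            assert spec.option("directionality") != OMIT

    def test_syn_nonsyn_only_for_protein(self):
        with pytest.raises(ValueError, match="protein-coding"):
            enumerate_models("rRNA", response_schemes=["SYN_NONSYN"])

    def test_reduced_factor_subsets(self):
        reduced = enumerate_models(
            "protein_coding",
            factors=["codon_position", "right_neighbor", "cpg"],
            response_schemes=["ALL"],
        )
        assert len(reduced) == 27


def _toy_table(df: pd.DataFrame, covariates=()) -> StateExposureTable:
    return StateExposureTable(
        data=df,
        region_class="protein_coding",
        total_tree_length=float(df.exposure.max()),
        covariate_columns=list(covariates),
    )


def _spec(region="protein_coding", scheme="ALL", **options) -> ModelSpec:
    factors = {
        "protein_coding": PROTEIN_FACTORS,
        "rRNA": NONCODING_FACTORS,
        "tRNA": TRNA_FACTORS,
    }[region]
    inclusions = tuple((f, options.get(f, OMIT)) for f in factors)
    return ModelSpec(region, inclusions, scheme)


def _synthetic_codon_table(rng) -> pd.DataFrame:
    """All 64 codons at all 3 positions, one row each."""
    from mitosub.genetic_code import codon_from_index

    rows = []
    site = 1
    for ci in range(64):
        for pos in (1, 2, 3):
            rows.append(
                {
                    "site": site,
                    "codon": codon_from_index(ci),
                    "codon_position": pos,
                    "left_neighbor": "A",
                    "right_neighbor": "G",
                    "cpg": "none",
                    "gene": "G1",
                    "cluster": "G1",
                    "nucleotide": codon_from_index(ci)[pos - 1],
                    "amino_acid": "X",
                    "directionality": 0,
                    "exposure": float(rng.uniform(1, 2)),
                    "n_total": int(rng.poisson(1)),
                    "n_ts": 0,
                    "n_tv": 0,
                    "n_syn": 0,
                    "n_nonsyn": 0,
                    "poss_syn_ts": 1,
                    "poss_syn_tv": 0,
                    "poss_nonsyn_ts": 0,
                    "poss_nonsyn_tv": 2,
                }
            )
            site += 1
    df = pd.DataFrame(rows)
    df["n_ts"] = df["n_total"]
    return df


class TestExpandSubmodels:
    def test_codon_by_position_yields_192(self, rng):
        table = _toy_table(_synthetic_codon_table(rng))
        spec = _spec(codon=PARTITION, codon_position=PARTITION)
        subs = expand_submodels(spec, table)
        assert len(subs) == 192

    def test_no_partition_single_submodel(self, rng):
        table = _toy_table(_synthetic_codon_table(rng))
        spec = _spec(codon=INCLUDE)
        subs = expand_submodels(spec, table)
        assert len(subs) == 1
        assert len(subs[0].data) == len(table.data)

    def test_partition_row_counts_sum(self, rng):
        table = _toy_table(_synthetic_codon_table(rng))
        spec = _spec(codon_position=PARTITION)
        subs = expand_submodels(spec, table)
        assert len(subs) == 3
        assert sum(len(s.data) for s in subs) == len(table.data)

    def test_out_of_codon_neighbor_rule(self, rng):
        table = _toy_table(_synthetic_codon_table(rng))
        spec = _spec(
            codon=INCLUDE,
            codon_position=PARTITION,
            left_neighbor=INCLUDE,
            right_neighbor=INCLUDE,
        )
        subs = expand_submodels(spec, table)
        by_pos = {dict(s.partition_values)["codon_position"]: s for s in subs}
        assert set(by_pos["1"].predictors.categorical) >= {"left_neighbor"}
        assert "right_neighbor" not in by_pos["1"].predictors.categorical
        assert "left_neighbor" not in by_pos["2"].predictors.categorical
        assert "right_neighbor" not in by_pos["2"].predictors.categorical
        assert "right_neighbor" in by_pos["3"].predictors.categorical
        assert "left_neighbor" not in by_pos["3"].predictors.categorical


class TestFallbackScore:
    def test_one_state_zero_events(self):
        assert fallback_score([0.0]) == (0.0, 1)

    def test_many_states_zero_events(self):
        assert fallback_score([0.0, 0.0, 0.0, 0.0]) == (0.0, 1)

    def test_one_state_with_events_saturated(self):
        import math

        ll, dof = fallback_score([3.0])
        assert dof == 1
        assert ll == pytest.approx(-3 + 3 * math.log(3) - math.log(6))

    def test_multi_state_saturated(self):
        import math

        ll, dof = fallback_score([2.0, 0.0, 1.0])
        assert dof == 3
        expected = (-2 + 2 * math.log(2) - math.log(2)) + 0.0 + (-1 + 0 - 0)
        assert ll == pytest.approx(expected)

    def test_saturated_loglik_zero_counts_convention(self):
        assert saturated_poisson_loglik(np.array([0.0, 0.0])) == 0.0


class TestScoreAndRank:
    def test_single_submodel_score_equals_fit_aic(self, sim_dataset):
        from mitosub import build_state_table

        table = build_state_table(
            sim_dataset.tree,
            sim_dataset.true_times,
            sim_dataset.genome,
            region_class="protein_coding",
        )
        spec = _spec(codon_position=INCLUDE)
        score = score_model(spec, table, r=0.05, keep_fits=True)
        assert score.n_submodels == 1
        po = [f for f in score.fits if f.family == "poisson"]
        assert len(po) == 1
        assert score.aic_poisson == pytest.approx(po[0].aic)

    def test_partition_aic_is_sum_of_submodel_aics(self, sim_dataset):
        from mitosub import build_state_table

        table = build_state_table(
            sim_dataset.tree,
            sim_dataset.true_times,
            sim_dataset.genome,
            region_class="protein_coding",
        )
        spec = _spec(codon_position=PARTITION)
        score = score_model(
            spec, table, r=0.05, families=("poisson",), keep_fits=True
        )
        assert score.n_submodels == 3
        assert score.aic_poisson == pytest.approx(sum(f.aic for f in score.fits))

    def test_two_response_scheme_doubles_fits(self, sim_dataset):
        from mitosub import build_state_table

        table = build_state_table(
            sim_dataset.tree,
            sim_dataset.true_times,
            sim_dataset.genome,
            region_class="protein_coding",
        )
        spec = _spec(scheme="TS_TV")
        score = score_model(spec, table, r=0.05, families=("poisson",), keep_fits=True)
        assert len(score.fits) == 2  # one fit per response on the same rows

    def test_rank_orders_by_min_aic(self):
        scores = []
        for aic_p, aic_nb in [(12.0, 14.0), (10.0, 15.0), (11.0, 9.0)]:
            spec = _spec()
            from mitosub.search import ModelScore

            scores.append(
                ModelScore(
                    spec,
                    aic_poisson=aic_p,
                    aic_negbin=aic_nb,
                    n_submodels=1,
                    n_params={"poisson": 2, "negbin": 3},
                    n_nonconverged={},
                )
            )
        report = rank_models(scores)
        assert report.min_aic.tolist() == [9.0, 10.0, 12.0]
        assert report.best_family.tolist() == ["negbin", "poisson", "poisson"]

    def test_tie_break_prefers_fewer_parameters(self):
        from mitosub.search import ModelScore

        lean = ModelScore(
            _spec(), 10.0, 20.0, 1, {"poisson": 3, "negbin": 4}, {}
        )
        rich = ModelScore(
            _spec(cpg=INCLUDE), 10.0, 20.0, 1, {"poisson": 5, "negbin": 6}, {}
        )
        report = rank_models([rich, lean])
        assert report.iloc[0].cpg == "omit"
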