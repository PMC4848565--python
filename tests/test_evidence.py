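import numpy as np
import pandas as pd
import pytest

from interomap.evidence import (
    ScoringConfig,
    aggregate_score,
    coevolution_count,
    coexpression_score,
    colocalization,
    colocalized_fraction,
    ddi_support,
    domain_density,
    expression_missing_fraction,
    shared_go_namespaces,
    tier_of,
)
from interomap.types import (
    AnnotationSet,
    EvidenceTables,
    ExpressionMatrix,
    OrthologMap,
)
from conftest import balanced_expression


class TestSharedGoNamespaces:
    def test_same_bp_term_scores_one(self, chain_dag):
        annos = AnnotationSet(
            [("P1", "GO:0000003", "BP", "IDA"), ("P2", "GO:0000003", "BP", "IDA")],
            chain_dag,
        )
        assert shared_go_namespaces("P1", "P2", annos, chain_dag) == 1

    def test_sharing_only_the_root_scores_zero(self, diamond_dag):
        # left leaf vs right: only common propagated term is the BP root
        annos = AnnotationSet(
            [("P1", "GO:0000011", "BP", "IDA"), ("P2", "GO:0000020", "BP", "IDA")],
            diamond_dag,
        )
        assert shared_go_namespaces("P1", "P2", annos, diamond_dag) == 0

    def test_ancestor_sharing_counts(self, chain_dag):
        # P1 at B, P2 at A: propagation gives both the shared ancestor A
        annos = AnnotationSet(
            [("P1", "GO:0000003", "BP", "IDA"), ("P2", "GO:0000002", "BP", "IDA")],
            chain_dag,
        )
        assert shared_go_namespaces("P1", "P2", annos, chain_dag) == 1

    def test_identical_annotations_in_all_namespaces(self):
        from interomap.synthetic import _build_ontology

        dag = _build_ontology()
        records = []
        for p in ("P1", "P2"):
            records += [(p, "GO:1001001", "BP", "IDA"), (p, "GO:2001001", "MF", "IDA"),
                        (p, "GO:3001001", "CC", "IDA")]
        annos = AnnotationSet(records, dag)
        assert shared_go_namespaces("P1", "P2", annos, dag) == 3

    def test_unannotated_protein_scores_zero(self, chain_dag):
        annos = AnnotationSet([("P1", "GO:0000003", "BP", "IDA")], chain_dag)
        assert shared_go_namespaces("P1", "Pmissing", annos, chain_dag) == 0


class TestCoevolutionCount:
    def test_common_species_intersection(self):
        omap = OrthologMap(
            [("arabidopsis", "r1", "A", 1.0), ("rice", "r2", "A", 1.0),
             ("arabidopsis", "r3", "B", 1.0), ("rice", "r4", "B", 1.0)]
        )
        assert coevolution_count("A", "B", omap) == 2

    def test_no_common_species(self):
        omap = OrthologMap([("yeast", "r1", "A", 1.0), ("fly", "r2", "B", 1.0)])
        assert coevolution_count("A", "B", omap) == 0

    def test_five_vs_three_species_intersecting_in_three(self):
        omap = OrthologMap()
        for i, sp in enumerate(["s1", "s2", "s3", "s4", "s5"]):
            omap.add(sp, f"ra{i}", "A", 1.0)
        for i, sp in enumerate(["s1", "s2", "s3"]):
            omap.add(sp, f"rb{i}", "B", 1.0)
        assert coevolution_count("A", "B", omap) == 3


class TestDdiSupport:
    def _tables(self):
        t = EvidenceTables()
        t.domains |= {("A", "PF00001", 1, 50, 1e-9), ("B", "PF00002", 1, 50, 1e-9),
                      ("C", "PF00003", 1, 50, 1e-9)}
        t.ddis.add(("PF00001", "PF00002"))
        return t

    def test_supported_pair(self):
        assert ddi_support("A", "B", self._tables()) == 1

    def test_symmetric_under_swap(self):
        assert ddi_support("B", "A", self._tables()) == 1

    def test_no_domains_scores_zero(self):
        assert ddi_support("A", "Z", self._tables()) == 0

    def test_homotypic_self_domain(self):
        t = EvidenceTables()
        t.domains |= {("A", "PF00009", 1, 10, 0.0), ("B", "PF00009", 1, 10, 0.0)}
        t.ddis.add(("PF00009", "PF00009"))
        assert ddi_support("A", "B", t) == 1


class TestColocalization:
    def _tables(self, loc_a, loc_b):
        t = EvidenceTables()
        t.localizations.add(("A", loc_a, "IDA", "curated"))
        t.localizations.add(("B", loc_b, "IDA", "curated"))
        return t

    def test_shared_compartment(self):
        assert colocalization("A", "B", self._tables("nucleus", "nucleus")) == 1

    def test_adjacent_group_golgi_er(self):
        t = self._tables("Golgi", "endoplasmic reticulum")
        assert colocalization("A", "B", t) == 1

    def test_no_covering_group(self):
        assert colocalization("A", "B", self._tables("nucleus", "chloroplast")) == 0

    @pytest.mark.parametrize("comp", ["undefined", "unknown"])
    def test_undefined_and_unknown_never_match(self, comp):
        assert colocalization("A", "B", self._tables(comp, comp)) == 0


class TestCoexpressionScore:
    def test_hand_computed_sign_pattern(self):
        # deviation signs (+,+), (-,-), (+,-), (+,+) over N=4 -> CS = 3/4
        expr = balanced_expression({
            "g1": [12, 8, 12, 12],
            "g2": [12, 8, 8, 12],
        })
        res = coexpression_score("g1", "g2", expr)
        assert res.cs == pytest.approx(0.75)
        assert res.gamma == (1, 1, 0, 1)

    def test_always_concordant_gives_one(self):
        expr = balanced_expression({"g1": [11, 12, 13], "g2": [14, 12, 11.5]})
        assert coexpression_score("g1", "g2", expr).cs == pytest.approx(1.0)

    def test_always_discordant_gives_zero(self):
        expr = balanced_expression({"g1": [11, 12], "g2": [9, 8]})
        assert coexpression_score("g1", "g2", expr).cs == pytest.approx(0.0)

    def test_zero_deviation_scores_zero(self):
        expr = balanced_expression({"g1": [10, 12], "g2": [12, 12]})
        # sample 0: g1 sits exactly on the mean -> gamma 0
        res = coexpression_score("g1", "g2", expr)
        assert res.gamma[0] == 0 and res.cs == pytest.approx(0.5)

    def test_missing_sample_depresses_cs(self):
        expr = balanced_expression({"g1": [12, 12, 12, 12], "g2": [12, 12, 12, 12]})
        expr.frame.loc["g2", "s0"] = np.nan
        res = coexpression_score("g1", "g2", expr)
        assert res.cs == pytest.approx(0.75)  # denominator stays N=4
        assert res.n_used == 3

    def test_pair_with_no_measurements_is_missing(self):
        expr = balanced_expression({"g1": [11, 12]})
        res = coexpression_score("absent1", "absent2", expr)
        assert res.cs is None and res.n_used == 0

    def test_one_measured_gene_gives_zero_not_missing(self):
        expr = balanced_expression({"g1": [11, 12]})
        assert coexpression_score("g1", "absent", expr).cs == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_sample_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(50, 96))
        values[rng.random(values.shape) < 0.05] = np.nan
        frame = pd.DataFrame(values, index=[f"g{i}" for i in range(50)],
                             columns=[f"s{j}" for j in range(96)])
        expr = ExpressionMatrix(frame)
        genes = [f"g{i}" for i in rng.choice(50, size=8, replace=False)]
        for a, b in zip(genes[::2], genes[1::2]):
            # oracle: explicit per-sample loop
            gamma = []
            for j, s in enumerate(expr.samples):
                col = frame[s]
                mean = col.mean(skipna=True)
                x1, x2 = frame.at[a, s], frame.at[b, s]
                if pd.isna(x1) or pd.isna(x2):
                    gamma.append(0)
                else:
                    gamma.append(int((x1 - mean) * (x2 - mean) > 0))
            expected = sum(gamma) / 96
            res = coexpression_score(a, b, expr)
            assert res.cs == pytest.approx(expected)
            assert list(res.gamma) == gamma


class TestAggregateScore:
    def test_maximal_evidence_is_high_tier_twelve(self):
        s = aggregate_score(s_species=6, s_go=3, s_ddi=1, s_loc=1, cs=1.0)
        assert (s.total, s.tier) == (12, "high")

    def test_minimal_evidence_is_low_tier_one(self):
        s = aggregate_score(s_species=1, s_go=0, s_ddi=0, s_loc=0, cs=None)
        assert (s.total, s.tier) == (1, "low")

    def test_boundary_two_is_medium(self):
        s = aggregate_score(s_species=1, s_go=1, s_ddi=0, s_loc=0, cs=0.0)
        assert (s.total, s.tier) == (2, "medium")

    def test_boundary_seven_is_high(self):
        s = aggregate_score(s_species=2, s_go=3, s_ddi=1, s_loc=1, cs=None)
        assert (s.total, s.tier) == (7, "high")

    def test_cs_below_tau_gives_no_point(self):
        assert aggregate_score(1, 0, 0, 0, cs=0.49).s_coexp == 0
        assert aggregate_score(1, 0, 0, 0, cs=0.5).s_coexp == 1

    def test_coevolution_recorded_but_unweighted_by_default(self):
        s = aggregate_score(1, 0, 0, 0, cs=None, s_coevo=6)
        assert s.s_coevo == 6 and s.total == 1

    def test_coevolution_weight_is_configurable(self):
        cfg = ScoringConfig(w_coevo=0.5)
        s = aggregate_score(1, 0, 0, 0, cs=None, s_coevo=4, config=cfg)
        assert s.total == 3

    @pytest.mark.parametrize("kwargs", [
        dict(s_species=0, s_go=0, s_ddi=0, s_loc=0, cs=None),
        dict(s_species=7, s_go=0, s_ddi=0, s_loc=0, cs=None),
        dict(s_species=1, s_go=4, s_ddi=0, s_loc=0, cs=None),
        dict(s_species=1, s_go=0, s_ddi=2, s_loc=0, cs=None),
        dict(s_species=1, s_go=0, s_ddi=0, s_loc=0, cs=1.5),
        dict(s_species=1, s_go=0, s_ddi=0, s_loc=0, cs=None, s_coevo=7),
    ])
    def test_out_of_range_components_rejected(self, kwargs):
        with pytest.raises(ValueError):
            aggregate_score(**kwargs)

    def test_tier_partition_is_exhaustive(self):
        for total in np.arange(1, 12.5, 0.5):
            assert tier_of(float(total)) in {"high", "medium", "low"}


class TestRatioStatistics:
    def test_domain_density(self):
        assert domain_density(15057, 10626) == pytest.approx(1.417, abs=5e-4)

    def test_colocalized_fraction(self):
        assert colocalized_fraction(86778, 208351) == pytest.approx(0.4165, abs=5e-5)

    def test_expression_missing_fraction(self):
        assert expression_missing_fraction(8152, 357946) == pytest.approx(0.0228, abs=5e-5)

    def test_zero_denominators_rejected(self):
        for fn in (domain_density, colocalized_fraction, expression_missing_fraction):
            with pytest.raises(ValueError):
                fn(1, 0)


class TestComponentSymmetry:
    def test_all_components_invariant_under_swap(self, loaded_bundle):
        from interomap.evidence import score_pair
        from interomap.interolog import map_interologs
        from interomap.types import PredictedInteraction

        b = loaded_bundle
        predictions = map_interologs(b["ref_ppis"], b["orthologs"])
        some = sorted(predictions)[:25]
        for a, c in some:
            orig = predictions[(a, c)]
            swapped = PredictedInteraction(
                pair=(a, c), supporting_species=set(orig.supporting_species)
            )
            args = (b["annotations"], b["dag"], b["orthologs"], b["tables"], b["expr"])
            s1 = score_pair(orig, *args)
            # manual component-wise swap check
            from interomap.evidence import (
                coevolution_count, colocalization, coexpression_score,
                ddi_support, shared_go_namespaces,
            )
            assert shared_go_namespaces(a, c, b["annotations"], b["dag"]) == \
                shared_go_namespaces(c, a, b["annotations"], b["dag"])
            assert ddi_support(a, c, b["tables"]) == ddi_support(c, a, b["tables"])
            assert colocalization(a, c, b["tables"]) == colocalization(c, a, b["tables"])
            assert coevolution_count(a, c, b["orthologs"]) == \
                coevolution_count(c, a, b["orthologs"])
            assert coexpression_score(a, c, b["expr"]).cs == \
                coexpression_score(c, a, b["expr"]).cs
            assert 1 <= s1.total <= 12
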