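"""Experiment drivers: recovery tallies, mixing, ranking, cross-validation."""

from dataclasses import replace

import numpy as np
import pytest

import lbasim as lb
from lbasim.core import TreeError
from lbasim.experiments import (
    RecoveryRow,
    branch_length_experiment,
    clade_mean_depth,
    cross_validation,
    mixing_experiment,
    monophyly_rank,
    recovery_experiment,
)
from lbasim.models import SiteModel
from lbasim.simulate import simulate_alignment
from lbasim.synthetic_data import (
    BackboneConfig,
    GeneSetConfig,
    make_backbone,
    make_gene_set,
)
from lbasim.topology import CandidateSet


class TestRecoveryTable:
    def test_counts_must_sum_to_replicates(self):
        with pytest.raises(ValueError, match="sum"):
            RecoveryRow("a", "m", "i", "all", "all",
                        counts={"x": 3, "y": 2}, n_replicates=6)

    def test_homogeneous_generation_always_correct(self, candidates,
                                                   hom_model, het_model):
        """Correctly specified or over-specified models both recover the
        generating topology when the data evolved homogeneously."""
        table = recovery_experiment(
            candidates, "felsenstein", hom_model,
            {"LG+G": hom_model, "C20-PMSF": het_model},
            n_replicates=5, n_sites=2000, seed=21,
            tol=1e-2, max_cycles=6)
        for row in table.rows:
            assert row.counts["felsenstein"] == 5
            assert sum(row.counts.values()) == row.n_replicates

    def test_reproducible_under_seed(self, candidates, hom_model, tmp_path):
        kw = dict(n_replicates=3, n_sites=500, seed=99,
                  tol=1e-2, max_cycles=4)
        t1 = recovery_experiment(candidates, "farris", hom_model,
                                 {"LG+G": hom_model}, **kw)
        t2 = recovery_experiment(candidates, "farris", hom_model,
                                 {"LG+G": hom_model}, **kw)
        assert t1.rows[0].counts == t2.rows[0].counts
        assert t1.replicates == t2.replicates
        assert all(rec["logL_margin"] >= 0 for rec in t1.replicates)
        path = tmp_path / "winners.tsv"
        t1.write_winners_tsv(path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "replicate\tinfer_model\twinner\tlogL_margin"
        assert len(lines) == 4

    def test_unknown_generating_name_rejected(self, candidates, hom_model):
        with pytest.raises(KeyError):
            recovery_experiment(candidates, "star", hom_model,
                                {"LG+G": hom_model}, 2, 100, seed=0)

    def test_taxon_removal_improves_recovery(self, het_model, hom_model):
        """Dropping the long-branch focal subclade (keeping the slow
        member) raises correct recovery under the misspecified model."""
        cfg = BackboneConfig(focal_terminal=2.0, focal_slow_terminal=0.3)
        cands = CandidateSet({
            "farris": make_backbone(replace(cfg, arrangement="farris")),
            "felsenstein": make_backbone(
                replace(cfg, arrangement="felsenstein"))})
        kw = dict(n_replicates=30, n_sites=2000, seed=77,
                  tol=1e-2, max_cycles=6)
        base = recovery_experiment(cands, "felsenstein", het_model,
                                   {"LG+G": hom_model}, **kw)
        dropped = recovery_experiment(cands, "felsenstein", het_model,
                                      {"LG+G": hom_model},
                                      drop_taxa={"Foc2", "Foc3"}, **kw)
        gain = (dropped.rows[0].fraction("felsenstein")
                - base.rows[0].fraction("felsenstein"))
        assert gain >= 0.15


class TestMixingLimits:
    def test_pure_proportions_favor_their_topology(self, hom_model):
        """p=1 gives topology A every pair; p=0 gives topology B."""
        t_a = lb.parse_newick(
            "((A:0.2,B:0.25):0.3,(C:0.2,D:0.25):0.3,(E:0.2,F:0.25):0.3);")
        t_b = lb.parse_newick(
            "((A:0.2,C:0.25):0.3,(B:0.2,D:0.25):0.3,(E:0.2,F:0.25):0.3);")
        df = mixing_experiment(t_a, hom_model, t_b, hom_model,
                               proportions=[0.0, 1.0], n_pairs=2,
                               n_sites=1500, infer_model=hom_model,
                               seed=9, tol=1e-2, max_cycles=4)
        at = df.set_index("proportion")
        assert at.loc[0.0, "wins_b"] == 2 and at.loc[0.0, "wins_a"] == 0
        assert at.loc[1.0, "wins_a"] == 2 and at.loc[1.0, "wins_b"] == 0

    def test_invalid_proportion_rejected(self, hom_model):
        t = lb.parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            mixing_experiment(t, hom_model, t, hom_model, [1.5], 1, 100,
                              hom_model, seed=0)


class TestMonophylyRank:
    def test_quarter_arithmetic_eight_genes(self, hom_model):
        """Eight equal-length genes: each pool covers exactly two genes."""
        backbone = make_backbone(BackboneConfig(
            n_outgroup=2, n_focal=2, ingroup_sizes=(2, 2),
            outgroup_terminal=0.4, focal_terminal=0.3))
        pairs = make_gene_set(backbone,
                              GeneSetConfig(n_genes=8, sites_per_gene=100),
                              hom_model, seed=43)
        genes = [a for a, _ in pairs]
        ranked, best, worst = monophyly_rank(genes, backbone.clades,
                                             hom_model, seed=44)
        assert len(ranked) == 8
        assert best.n_sites == worst.n_sites == 2 * 100
        assert all(0 <= s.score <= s.n_clades for s in ranked)
        # stable descending order of normalized scores
        norm = [s.normalized for s in ranked]
        assert norm == sorted(norm, reverse=True)

    def test_too_few_genes_rejected(self, hom_model):
        with pytest.raises(ValueError):
            monophyly_rank([], {}, hom_model, seed=0)


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def hom_alignment(self, backbone_pair_default, hom_model):
        farris, _ = backbone_pair_default
        aln, _ = simulate_alignment(farris, hom_model, 3000, seed=47)
        return farris, aln

    def test_identical_models_give_zero_delta(self, hom_alignment,
                                              hom_model):
        tree, aln = hom_alignment
        res = cross_validation(aln, tree, hom_model, hom_model,
                               train_sites=1500, test_sites=500,
                               n_reps=3, seed=3, fit_alpha=False,
                               tol=1e-2, max_cycles=4)
        assert abs(res.mean) <= max(2 * res.sd, 1e-9)

    def test_true_model_resists_overfitting(self, hom_alignment,
                                            hom_model, het_model):
        """On homogeneous data the homogeneous model is never beaten by
        more than 5 logL per 1,000 test sites."""
        tree, aln = hom_alignment
        res = cross_validation(aln, tree, het_model, hom_model,
                               train_sites=2000, test_sites=500,
                               n_reps=3, seed=5, fit_alpha=False,
                               tol=1e-2, max_cycles=5)
        assert np.all(res.deltas < 5 * 500 / 1000)

    def test_insufficient_sites_rejected(self, hom_alignment, hom_model):
        tree, aln = hom_alignment
        with pytest.raises(ValueError):
            cross_validation(aln, tree, hom_model, hom_model,
                             train_sites=2900, test_sites=500, n_reps=1)


class TestBranchLengthExperiment:
    def test_requires_named_clades(self, hom_model):
        t = lb.parse_newick("((A:1,B:1):0.2,(C:1,D:1):0.2);")
        with pytest.raises(TreeError, match="clades"):
            branch_length_experiment(t, hom_model, {"m": hom_model},
                                     100, seed=0)

    def test_zero_length_branch_estimated_at_bound(self, hom_model):
        t = lb.parse_newick(
            "((A:0.2,B:0.25):0.0,(C:0.2,D:0.25):0.2,(E:0.2,F:0.25):0.2);")
        t.clades = {"left": frozenset({"A", "B"})}
        df = branch_length_experiment(t, hom_model, {"LG+G": hom_model},
                                      n_sites=2000, seed=61,
                                      tol=1e-3, max_cycles=15)
        zero_rows = df[(df.kind == "internal") & (df.truth == 0.0)]
        assert len(zero_rows) == 1
        assert zero_rows.estimate.iloc[0] < 5e-3

    def test_clade_mean_depth_hand_computed(self):
        t = lb.parse_newick("(((A:1,B:3):0.5,C:2):0.1,(D:1,E:1):0.1,F:4);")
        assert clade_mean_depth(t, {"A", "B"}) == pytest.approx(2.0)
        assert clade_mean_depth(t, {"A", "B", "C"}) == pytest.approx(
            (1.5 + 3.5 + 2.0) / 3)
        with pytest.raises(TreeError):
            clade_mean_depth(t, {"A", "C"})
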