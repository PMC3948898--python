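"""Two-phase ranking, cutoff evaluation, valid-conformer and consensus logic."""

import math

import numpy as np
import pandas as pd
import pytest

from consilience.metrics import ConfusionCounts, MetricTriple, TruthSet, compute_metrics
from consilience.screen import (
    ConformerScoreTable,
    CutoffEvaluation,
    consensus_hits,
    evaluate_conformer_at_cutoffs,
    k_of_n_comparison,
    select_valid_conformers,
    top_fraction_set,
    two_phase_rank,
)
from consilience.synthetic import DockConfig, SyntheticConfig, gen_docking_scores


def make_table(rows, reference="ref"):
    return ConformerScoreTable(
        pd.DataFrame(
            rows,
            columns=["compound_id", "conformer_id", "primary_score", "secondary_score"],
        ),
        reference=reference,
    )


class TestConformerScoreTable:
    def test_duplicate_cells_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_table([("c1", "ref", 1.0, 1.0), ("c1", "ref", 2.0, 2.0)])

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            make_table([("c1", "other", 1.0, 1.0)])

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            make_table([("c1", "ref", float("inf"), 1.0)])


class TestTwoPhaseRank:
    def test_secondary_orders_first_phase(self):
        t = make_table([("a", "ref", 9.0, 7.0), ("b", "ref", 1.0, 5.0)])
        assert two_phase_rank(t, "ref") == ["b", "a"]

    def test_missing_secondary_ranks_behind_rescored(self):
        # three-compound toy covering all branches of the contract
        t = make_table(
            [
                ("gridonly", "ref", -10.0, None),
                ("worse", "ref", 5.0, 8.0),
                ("best", "ref", 7.0, 2.0),
            ]
        )
        assert two_phase_rank(t, "ref") == ["best", "worse", "gridonly"]

    def test_failed_compound_ranks_last(self):
        t = make_table(
            [
                ("ok", "ref", 1.0, 1.0),
                ("fail", "ref", None, None),
                ("ok", "alt", 1.0, 1.0),
                ("fail", "alt", 0.0, 0.0),
            ]
        )
        assert two_phase_rank(t, "ref") == ["ok", "fail"]
        assert t.scored_compounds("ref") == {"ok"}

    def test_ties_break_lexicographically(self):
        t = make_table(
            [("zeta", "ref", 1.0, 3.0), ("alpha", "ref", 2.0, 3.0)]
        )
        assert two_phase_rank(t, "ref") == ["alpha", "zeta"]
        assert two_phase_rank(t, "ref") == two_phase_rank(t, "ref")

    def test_unknown_conformer_errors(self):
        t = make_table([("c1", "ref", 1.0, 1.0)])
        with pytest.raises(ValueError, match="unknown conformer"):
            two_phase_rank(t, "nope")


class TestTopFractionSet:
    @pytest.mark.parametrize(
        "n, q, size",
        [(10, 0.10, 1), (15, 0.10, 2), (10, 1.0, 10), (7, 0.5, 4), (1, 0.1, 1)],
    )
    def test_ceiling_rule(self, n, q, size):
        ranked = [f"c{i}" for i in range(n)]
        top = top_fraction_set(ranked, q)
        assert len(top) == size
        assert top == frozenset(ranked[:size])

    @pytest.mark.parametrize("q", [0.0, -0.2, 1.5])
    def test_fraction_out_of_range(self, q):
        with pytest.raises(ValueError):
            top_fraction_set(["a"], q)


def _label_truth(table, actives):
    actives = frozenset(actives)
    return TruthSet(
        true_set=actives,
        false_set=frozenset(table.compounds) - actives,
    )


class TestEvaluateAtCutoffs:
    def build(self):
        # 2 actives among 10; actives hold the two best secondary scores
        rows = [(f"act{i}", "ref", float(i), float(i)) for i in range(2)]
        rows += [(f"dec{i}", "ref", 10.0 + i, 10.0 + i) for i in range(8)]
        return make_table(rows), [f"act{i}" for i in range(2)]

    def test_hand_enumeration_top20(self):
        table, actives = self.build()
        truth = _label_truth(table, actives)
        ev = evaluate_conformer_at_cutoffs(table, "ref", truth, [0.2])[0]
        assert (ev.counts.tp, ev.counts.fp, ev.counts.tn, ev.counts.fn) == (2, 0, 8, 0)
        assert ev.metrics.acc == 100.0

    def test_cutoff_one_flags_everything(self):
        table, actives = self.build()
        truth = _label_truth(table, actives)
        ev = evaluate_conformer_at_cutoffs(table, "ref", truth, [1.0])[0]
        assert ev.metrics.acc == pytest.approx(100.0 * 2 / 10)
        assert ev.metrics.fpr == 100.0

    def test_unlabelled_compound_errors(self):
        table, actives = self.build()
        truth = TruthSet(true_set=frozenset(actives), false_set=frozenset({"dec0"}))
        with pytest.raises(ValueError, match="lack active/decoy labels"):
            evaluate_conformer_at_cutoffs(table, "ref", truth, [0.1])

    def test_random_scores_fpr_near_cutoff(self, rng):
        """Under scrambled scores the top-10% set is a uniform sample, so
        FPR ~ 10% within 3 binomial standard errors."""
        n_act, n_dec = 50, 950
        rows = [
            (f"act{i:03d}", "ref", 0.0, rng.standard_normal()) for i in range(n_act)
        ] + [
            (f"dec{i:03d}", "ref", 0.0, rng.standard_normal()) for i in range(n_dec)
        ]
        table = make_table(rows)
        truth = _label_truth(table, [f"act{i:03d}" for i in range(n_act)])
        ev = evaluate_conformer_at_cutoffs(table, "ref", truth, [0.1])[0]
        se = 100.0 * math.sqrt(0.1 * 0.9 / n_dec)
        assert abs(ev.metrics.fpr - 10.0) <= 3 * se


def _eval(conf, cutoff, acc, ppv, fpr):
    # counts are irrelevant for selection; metrics drive it
    return CutoffEvaluation(
        conformer=conf, cutoff=cutoff,
        counts=ConfusionCounts(1, 1, 1, 1),
        metrics=MetricTriple(acc=acc, ppv=ppv, fpr=fpr),
    )


class TestSelectValidConformers:
    def test_reference_plus_strictly_better(self):
        # 25 candidates, exactly three strictly beat the reference -> 4 kept
        ref = _eval("t0000ps", 0.1, 89.4, 5.512, 8.602)
        evals = [ref]
        better = {"t3000ps", "t3200ps", "t4800ps"}
        for i in range(1, 26):
            conf = f"t{200*i:04d}ps"
            if conf in better:
                evals.append(_eval(conf, 0.1, 95.0, 10.0, 2.0))
            else:
                evals.append(_eval(conf, 0.1, 85.0, 4.0, 9.0))
        valid = select_valid_conformers(evals, "t0000ps")
        assert valid == better | {"t0000ps"}

    def test_no_winner_keeps_reference_only(self):
        evals = [_eval("ref", 0.1, 90.0, 10.0, 5.0), _eval("c1", 0.1, 80.0, 5.0, 9.0)]
        assert select_valid_conformers(evals, "ref") == {"ref"}

    def test_equal_fpr_excluded_strict(self):
        evals = [_eval("ref", 0.1, 90.0, 10.0, 5.0), _eval("c1", 0.1, 95.0, 12.0, 5.0)]
        assert select_valid_conformers(evals, "ref") == {"ref"}

    def test_undefined_ppv_never_qualifies(self):
        evals = [_eval("ref", 0.1, 90.0, 10.0, 5.0), _eval("c1", 0.1, 99.0, None, 0.0)]
        assert select_valid_conformers(evals, "ref") == {"ref"}

    def test_mixed_cutoffs_error(self):
        evals = [_eval("ref", 0.1, 90.0, 10.0, 5.0), _eval("c1", 0.2, 95.0, 12.0, 1.0)]
        with pytest.raises(ValueError, match="mixed"):
            select_valid_conformers(evals, "ref")

    def test_missing_reference_error(self):
        with pytest.raises(ValueError, match="reference"):
            select_valid_conformers([_eval("c1", 0.1, 95.0, 12.0, 1.0)], "ref")


class TestConsensusHits:
    def two_conformer_table(self):
        rows = []
        for conf in ("ref", "alt"):
            # c3 best everywhere; remaining order differs per conformer
            rows.append(("c3", conf, 0.0, 0.0))
            for i in range(9):
                bump = i if conf == "ref" else (9 - i)
                rows.append((f"c{i}x", conf, 1.0 + bump, 1.0 + bump))
        return make_table(rows)

    def test_shared_top_compound(self):
        t = self.two_conformer_table()
        res = consensus_hits(t, ["ref", "alt"], q=0.1, required_hits=2)
        assert res.hits == {"c3"}

    def test_disjoint_top_sets_give_empty_consensus(self):
        rows = [
            ("a", "ref", 0.0, 0.0), ("b", "ref", 5.0, 5.0),
            ("a", "alt", 5.0, 5.0), ("b", "alt", 0.0, 0.0),
        ]
        t = make_table(rows)
        res = consensus_hits(t, ["ref", "alt"], q=0.5, required_hits=2)
        assert res.hits == frozenset()

    def test_k1_is_union_of_top_sets(self):
        rows = [
            ("a", "ref", 0.0, 0.0), ("b", "ref", 5.0, 5.0),
            ("a", "alt", 5.0, 5.0), ("b", "alt", 0.0, 0.0),
        ]
        t = make_table(rows)
        res = consensus_hits(t, ["ref", "alt"], q=0.5, required_hits=1)
        assert res.hits == {"a", "b"}

    def test_k_defaults_to_all_conformers(self):
        t = self.two_conformer_table()
        assert consensus_hits(t, ["ref", "alt"], q=0.1).required_hits == 2

    @pytest.mark.parametrize("k", [0, 3])
    def test_k_out_of_range(self, k):
        t = self.two_conformer_table()
        with pytest.raises(ValueError):
            consensus_hits(t, ["ref", "alt"], q=0.1, required_hits=k)

    def test_single_conformer_consensus_matches_cutoff_positives(self):
        cfg = SyntheticConfig(
            seed=5, dock=DockConfig(n_actives=10, n_decoys=90, n_conformers=3)
        )
        table, truth = gen_docking_scores(cfg)
        conf = table.reference
        for q in (0.1, 0.3):
            ev = evaluate_conformer_at_cutoffs(table, conf, truth, [q])[0]
            hits = consensus_hits(table, [conf], q=q, required_hits=1).hits
            assert len(hits & truth.true_set) == ev.counts.tp
            assert len(hits & truth.false_set) == ev.counts.fp


class TestKofN:
    def toy(self):
        cfg = SyntheticConfig(
            seed=7,
            dock=DockConfig(n_actives=3, n_decoys=9, n_conformers=4,
                            conformer_loading=0.6),
        )
        return gen_docking_scores(cfg)

    def test_nestedness_and_monotone_fp(self):
        table, truth = self.toy()
        valid = table.conformers
        prev = None
        for k in range(1, len(valid) + 1):
            hits = consensus_hits(table, valid, q=0.25, required_hits=k).hits
            if prev is not None:
                assert hits <= prev
            prev = hits
        reports = k_of_n_comparison(table, valid, 0.25, truth)
        fps = [r.counts.fp for r in reports]
        assert fps == sorted(fps, reverse=True)
        fprs = [r.metrics.fpr for r in reports]
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))

    def test_counts_match_brute_force(self):
        table, truth = self.toy()
        valid = table.conformers
        q = 0.25
        # brute force: recompute per-compound hit counts from the top sets
        tops = []
        for conf in valid:
            ranked = two_phase_rank(table, conf)
            m = math.ceil(q * len(ranked))
            tops.append(set(ranked[:m]) & table.scored_compounds(conf))
        for k, rep in enumerate(k_of_n_comparison(table, valid, q, truth), start=1):
            hits = {
                c for c in table.compounds
                if sum(c in t for t in tops) >= k
            }
            assert rep.counts.tp == len(hits & truth.true_set)
            assert rep.counts.fp == len(hits & truth.false_set)
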