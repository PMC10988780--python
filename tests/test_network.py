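"""Motif enrichment cuts, ex-vivo affiliation, sharing network, public motifs."""

import math

import numpy as np
import pandas as pd
import pytest

from clonotrack import ConfigurationError, EmptyRepertoireError
from clonotrack import motifs as mo
from clonotrack import network as net
from conftest import make_repertoire
from oracles import binom_two_sided_oracle, brute_force_edge_weights


class TestFoldAndPoisson:
    def test_symmetric_counts_equal_totals(self):
        fold, p = net.motif_fold_and_poisson(20, 20, 10000, 10000)
        assert fold == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_one_sided_counts_closed_form(self):
        # 12 events all on one side with equal exposures: p = 2 * (1/2)^12
        fold, p = net.motif_fold_and_poisson(12, 0, 10000, 10000)
        assert p == pytest.approx(2 * 0.5 ** 12, abs=1e-15)
        assert fold > 0

    def test_degenerate_group_flagged(self):
        fold, p = net.motif_fold_and_poisson(0, 0, 10000, 10000)
        assert (fold, p) == (0.0, 1.0)

    def test_matches_exact_binomial_oracle_on_unequal_totals(self):
        total_a, total_b = 30000, 20000
        for c_a, c_b in [(5, 9), (40, 11), (0, 7), (123, 77)]:
            _, p = net.motif_fold_and_poisson(c_a, c_b, total_a, total_b)
            expected = binom_two_sided_oracle(c_a, c_a + c_b, total_a, total_a + total_b)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_bad_totals_raise(self):
        with pytest.raises(ConfigurationError):
            net.motif_fold_and_poisson(1, 1, 0, 100)


class TestSelectApobMotifs:
    def _scored(self, rows):
        return pd.DataFrame(rows)

    def test_failing_only_fold_is_excluded(self):
        rows = [{"pattern": "AAA", "kind": "LOCAL", "n_unique_cdr3": 3,
                 "sum_templates_a": 10, "sum_templates_b": 1,
                 "log2_fold": 1.5, "poisson_p": 1e-9,
                 "fisher_ref_p": 1e-4, "expansion_p": 0.001}]
        assert len(net.select_apob_motifs(self._scored(rows))) == 0

    def test_zero_thresholds_return_all_expansion_significant(self):
        rows = [
            {"pattern": "AAA", "kind": "LOCAL", "n_unique_cdr3": 3,
             "sum_templates_a": 5, "sum_templates_b": 5, "log2_fold": 0.0,
             "poisson_p": 1.0, "fisher_ref_p": 0.5, "expansion_p": 0.01},
            {"pattern": "BBB", "kind": "LOCAL", "n_unique_cdr3": 3,
             "sum_templates_a": 5, "sum_templates_b": 5, "log2_fold": 0.0,
             "poisson_p": 1.0, "fisher_ref_p": 0.5, "expansion_p": 0.5},
        ]
        out = net.select_apob_motifs(self._scored(rows), log2_fold_min=0.0,
                                     neg_log10_p_min=0.0)
        assert list(out["pattern"]) == ["AAA"]

    def test_tightening_cuts_never_grows_selection(self):
        rng = np.random.default_rng(2)
        rows = [{"pattern": f"P{i}", "kind": "LOCAL", "n_unique_cdr3": 3,
                 "sum_templates_a": 1, "sum_templates_b": 1,
                 "log2_fold": float(rng.normal(2, 2)),
                 "poisson_p": float(10 ** -rng.uniform(0, 12)),
                 "fisher_ref_p": 0.01, "expansion_p": float(rng.uniform(0, 0.2))}
                for i in range(120)]
        scored = self._scored(rows)
        loose = set(net.select_apob_motifs(scored, 1.0, 3.0, 0.10)["pattern"])
        for fold, logp, exp in [(2.0, 3.0, 0.10), (1.0, 6.0, 0.10), (1.0, 3.0, 0.02)]:
            tight = set(net.select_apob_motifs(scored, fold, logp, exp)["pattern"])
            assert tight <= loose


def _exvivo_reps(naive_rows=None, tcm_rows=None, tem_rows=None, donor="D1"):
    filler = [{"aa_seq": "CASWWWWWWWF", "templates": 1}]
    return [
        make_repertoire(donor, "NAIVE", naive_rows or filler),
        make_repertoire(donor, "TCM", tcm_rows or filler),
        make_repertoire(donor, "TEM", tem_rows or filler),
    ]


def _motif_df(patterns_kinds):
    return pd.DataFrame([{"pattern": p, "kind": k} for p, k in patterns_kinds])


class TestClassifyAffiliation:
    def test_tcm_only_match_is_memory_only(self):
        reps = _exvivo_reps(tcm_rows=[{"aa_seq": "CASSLEYEQYF", "templates": 2}])
        affs, _ = net.classify_affiliation(_motif_df([("LEYEQ", mo.LOCAL)]), reps)
        aff = affs[0]
        assert aff.category == net.MEMORY_ONLY
        assert aff.subset_detail == "TCM_ONLY"
        assert net.is_memory_affiliated(aff)
        assert aff.donors_memory == ("D1",)

    def test_unmatched_motif_is_absent(self):
        affs, _ = net.classify_affiliation(_motif_df([("QQQQ", mo.LOCAL)]), _exvivo_reps())
        assert affs[0].category == net.ABSENT
        assert not net.is_memory_affiliated(affs[0])

    def test_both_pools_with_strong_memory_expansion_is_enriched(self):
        reps = _exvivo_reps(
            naive_rows=[{"aa_seq": "CASSLEYEQYF", "templates": 1}]
            + [{"aa_seq": f"CASN{i:04d}NNF", "templates": 1} for i in range(400)],
            tcm_rows=[{"aa_seq": "CASSLEFEQYF", "templates": 40}]
            + [{"aa_seq": f"CAST{i:04d}TTF", "templates": 1} for i in range(360)],
        )
        affs, _ = net.classify_affiliation(_motif_df([("SLE", mo.LOCAL)]), reps)
        aff = affs[0]
        assert aff.category == net.BOTH
        assert aff.memory_enriched
        assert net.is_memory_affiliated(aff)

    def test_affiliation_partition_is_exhaustive(self, full_results):
        table = full_results["motif"].affiliation_table
        counts = table["category"].value_counts()
        assert counts.sum() == len(full_results["motif"].apob_motifs)
        assert set(counts.index) <= {net.NAIVE_ONLY, net.MEMORY_ONLY, net.BOTH, net.ABSENT}


class TestSharingNetwork:
    def _aff(self, pattern, matches, exvivo):
        idx = np.asarray(matches, dtype=int)
        donors = sorted(set(exvivo["donor_id"].to_numpy()[idx]))
        return net.MotifAffiliation(
            pattern=pattern, kind=mo.LOCAL, category=net.MEMORY_ONLY,
            memory_enriched=False, memory_log2_fold=math.nan,
            memory_poisson_p=math.nan, subset_detail="NA",
            donors_memory=tuple(donors), match_index=idx)

    def _exvivo_frame(self, rows):
        return pd.DataFrame(rows)

    def test_one_motif_two_nodes_single_edge(self):
        exvivo = self._exvivo_frame([
            {"donor_id": "D1", "compartment": "TCM", "aa_seq": "A", "templates": 1,
             "frequency": 0.5, "trimmed": "A"},
            {"donor_id": "D2", "compartment": "TCM", "aa_seq": "B", "templates": 1,
             "frequency": 0.5, "trimmed": "B"},
        ])
        sn = net.build_sharing_network([self._aff("M1", [0, 1], exvivo)], exvivo)
        edges = sn.edge_table()
        assert len(edges) == 1
        assert edges.iloc[0]["weight"] == 1
        assert set(sn.graph.nodes) == {"D1_TCM", "D2_TCM"}

    def test_single_node_connection_kept_without_edge(self):
        exvivo = self._exvivo_frame([
            {"donor_id": "D1", "compartment": "TEM", "aa_seq": "A", "templates": 1,
             "frequency": 1.0, "trimmed": "A"},
        ])
        sn = net.build_sharing_network([self._aff("M1", [0], exvivo)], exvivo)
        assert len(sn.edge_table()) == 0
        assert sn.connections.iloc[0]["n_nodes"] == 1

    def test_edge_weights_match_brute_force(self):
        rng = np.random.default_rng(10)
        donors = [f"D{i}" for i in range(1, 5)]
        rows, affs_spec = [], {}
        row_id = 0
        for m in range(12):
            matches = []
            for d in donors:
                for subset in ("TCM", "TEM"):
                    if rng.random() < 0.3:
                        rows.append({"donor_id": d, "compartment": subset,
                                     "aa_seq": f"S{row_id}", "templates": 1,
                                     "frequency": 0.01, "trimmed": f"S{row_id}"})
                        matches.append(row_id)
                        row_id += 1
            affs_spec[f"M{m}"] = matches
        exvivo = self._exvivo_frame(rows)
        affs = [self._aff(p, idx, exvivo) for p, idx in affs_spec.items() if idx]
        sn = net.build_sharing_network(affs, exvivo)
        motif_nodes = {
            p: {f"{exvivo.iloc[i]['donor_id']}_{exvivo.iloc[i]['compartment']}"
                for i in idx}
            for p, idx in affs_spec.items() if idx
        }
        expected = brute_force_edge_weights(motif_nodes)
        got = {tuple(sorted((a, b))): d["weight"]
               for a, b, d in sn.graph.edges(data=True)}
        assert got == {k: v for k, v in expected.items() if v > 0}


class TestPublicMotifs:
    def _exvivo_mem(self, donors):
        rows = []
        for i, d in enumerate(donors):
            rows.append({"donor_id": d, "compartment": "TCM", "aa_seq": f"S{i}",
                         "templates": 2, "frequency": 0.001, "trimmed": f"S{i}"})
        return pd.DataFrame(rows)

    def _aff(self, pattern, exvivo):
        idx = np.arange(len(exvivo))
        return net.MotifAffiliation(
            pattern=pattern, kind=mo.LOCAL, category=net.MEMORY_ONLY,
            memory_enriched=False, memory_log2_fold=math.nan,
            memory_poisson_p=math.nan, subset_detail="NA",
            donors_memory=tuple(sorted(set(exvivo["donor_id"]))), match_index=idx)

    def test_five_of_six_donors_is_public_at_default_fraction(self):
        exvivo = self._exvivo_mem(["D1", "D2", "D3", "D4", "D5"])
        pub, freqs = net.public_motifs([self._aff("M1", exvivo)], exvivo, n_donors=6)
        assert list(pub["pattern"]) == ["M1"]
        assert freqs["frequency"].iloc[0] == pytest.approx(0.001)

    def test_single_donor_is_not_public(self):
        exvivo = self._exvivo_mem(["D1"])
        pub, _ = net.public_motifs([self._aff("M1", exvivo)], exvivo, n_donors=6)
        assert len(pub) == 0


class TestPositionFrequencyMatrix:
    def test_single_sequence_one_hot(self):
        pfm = net.position_frequency_matrix(mo.MotifPattern("SLE%E", mo.GLOBAL),
                                            ["SLEYE"])
        assert pfm.shape[1] == 5
        assert (pfm.max(axis=0) == 1.0).all()
        assert pfm.loc["Y", 3] == 1.0

    def test_two_sequences_split_column(self):
        pfm = net.position_frequency_matrix(mo.MotifPattern("SLE%E", mo.GLOBAL),
                                            ["SLEYE", "SLEFE"])
        assert pfm.loc["Y", 3] == 0.5 and pfm.loc["F", 3] == 0.5

    def test_columns_sum_to_one_with_local_anchor(self):
        rng = np.random.default_rng(14)
        alphabet = list("ACDEFG")
        seqs = []
        for _ in range(25):
            left = "".join(rng.choice(alphabet, size=int(rng.integers(0, 4))))
            right = "".join(rng.choice(alphabet, size=int(rng.integers(0, 4))))
            seqs.append(left + "QWER" + right)
        pfm = net.position_frequency_matrix(mo.MotifPattern("QWER", mo.LOCAL), seqs)
        assert np.allclose(pfm.sum(axis=0), 1.0)
        assert pfm.loc["Q", 0] == 1.0  # anchored at motif start

    def test_empty_matches_raise(self):
        with pytest.raises(EmptyRepertoireError):
            net.position_frequency_matrix(mo.MotifPattern("QWER", mo.LOCAL), [])
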