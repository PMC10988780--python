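"""Threshold derivation, clone enrichment testing and V-gene usage."""

import math

import numpy as np
import pandas as pd
import pytest

from clonotrack import ConfigurationError, EmptyRepertoireError
from clonotrack import enrichment as en
from clonotrack.io import aggregate_clonotypes
from conftest import make_repertoire
from oracles import fisher_two_sided_oracle


def _rep_with_max_freq(donor, max_templates, total, comp="AIM_NEG"):
    """Repertoire whose top clonotype frequency is max_templates/total exactly."""
    rows = [{"aa_seq": "CASSTOPF", "templates": max_templates}]
    filler = total - max_templates
    i = 0
    while filler > 0:
        t = min(filler, max(1, max_templates - 1))
        rows.append({"aa_seq": f"CASS{i:05d}F", "templates": t})
        filler -= t
        i += 1
    return make_repertoire(donor, comp, rows)


class TestCopyNumberSpectrum:
    def test_micro_bins(self):
        rep = make_repertoire("D1", "AIM_NEG", [
            {"aa_seq": "CAAAF", "templates": 1},
            {"aa_seq": "CBBBF", "templates": 2},
            {"aa_seq": "CCCCF", "templates": 11},
        ])
        spec = en.copy_number_spectrum(aggregate_clonotypes(rep))
        assert spec["fraction"].tolist() == pytest.approx([2 / 3, 1 / 3])

    def test_all_singletons(self):
        rep = make_repertoire("D1", "AIM_NEG", [
            {"aa_seq": f"CAS{i}F", "templates": 1} for i in range(5)
        ])
        spec = en.copy_number_spectrum(aggregate_clonotypes(rep))
        assert spec["fraction"].tolist() == [1.0, 0.0]

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        t = rng.integers(1, 40, 60)
        rep = make_repertoire("D1", "AIM_NEG", [
            {"aa_seq": f"CAS{i:03d}F", "templates": int(x)} for i, x in enumerate(t)
        ])
        spec = en.copy_number_spectrum(aggregate_clonotypes(rep))
        assert spec["n_clonotypes"].tolist() == [
            int(((t >= 1) & (t <= 10)).sum()), int((t > 10).sum())]
        assert spec["fraction"].sum() == pytest.approx(1.0)


class TestGlobalThreshold:
    def _three_donor_reps(self):
        # per-donor maxima 1.387e-3, 5e-3, 2e-3
        return [
            _rep_with_max_freq("D1", 1387, 1_000_000),
            _rep_with_max_freq("D2", 5000, 1_000_000),
            _rep_with_max_freq("D3", 2000, 1_000_000),
        ]

    def test_raw_minimum_of_maxima(self):
        assert en.derive_global_threshold(self._three_donor_reps()) == pytest.approx(1.387e-3, rel=1e-12)

    def test_sig3_up_rounding(self):
        t = en.derive_global_threshold(self._three_donor_reps(), rounding="sig3_up")
        assert t == pytest.approx(1.39e-3, rel=1e-12)

    def test_single_donor(self):
        rep = make_repertoire("D1", "AIM_NEG", [
            {"aa_seq": "CAAAF", "templates": 1},
            {"aa_seq": "CBBBF", "templates": 1},
        ])
        assert en.derive_global_threshold([rep]) == pytest.approx(0.5)

    def test_empty_repertoire_raises(self):
        empty = make_repertoire("D1", "AIM_NEG", [{"aa_seq": "CAAAF", "templates": 1}])
        empty.df = empty.df.iloc[:0]
        with pytest.raises(EmptyRepertoireError):
            en.derive_global_threshold([empty])

    def test_unknown_rounding_raises(self):
        with pytest.raises(ConfigurationError):
            en.derive_global_threshold(self._three_donor_reps(), rounding="sig2")

    @pytest.mark.parametrize("x,expected", [
        (1.387e-3, 1.39e-3), (0.0012341, 0.00124), (0.5, 0.5), (1.0, 1.0),
    ])
    def test_round_up_sig3(self, x, expected):
        assert en.round_up_sig3(x) == pytest.approx(expected, rel=1e-12)


class TestCloneEnrichment:
    def _paired(self, pos_rows, neg_rows):
        return (make_repertoire("D1", "AIM_POS", pos_rows),
                make_repertoire("D1", "AIM_NEG", neg_rows))

    def test_equal_rates_not_selected(self):
        pos_rows = [{"aa_seq": "CTARGETF", "templates": 20}] + [
            {"aa_seq": f"CAS{i:03d}F", "templates": 1} for i in range(80)]
        neg_rows = [{"aa_seq": "CTARGETF", "templates": 20}] + [
            {"aa_seq": f"CBS{i:03d}F", "templates": 1} for i in range(80)]
        pos, neg = self._paired(pos_rows, neg_rows)
        res = en.clone_enrichment_test(pos, neg, threshold=0.1)
        row = res[res["aa_seq"] == "CTARGETF"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["log10_odds"] == pytest.approx(0.0)
        assert not row["selected"]

    def test_zero_neg_cell_uses_continuity_correction_and_oracle_p(self):
        pos_rows = [{"aa_seq": "CTARGETF", "templates": 50}] + [
            {"aa_seq": f"CAS{i:04d}F", "templates": 1} for i in range(950)]
        neg_rows = [{"aa_seq": f"CBS{i:04d}F", "templates": 1} for i in range(1000)]
        pos, neg = self._paired(pos_rows, neg_rows)
        res = en.clone_enrichment_test(pos, neg, threshold=0.04)
        row = res[res["aa_seq"] == "CTARGETF"].iloc[0]
        a, b, c, d = 50, 0, 950, 1000
        expected_or = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        assert row["odds_ratio"] == pytest.approx(expected_or)
        assert row["log10_odds"] > 1
        assert row["fisher_p"] == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-10)
        assert row["selected"]

    def test_nonpositive_threshold_raises(self):
        pos, neg = self._paired([{"aa_seq": "CAAAF", "templates": 5}],
                                [{"aa_seq": "CBBBF", "templates": 5}])
        with pytest.raises(ConfigurationError):
            en.clone_enrichment_test(pos, neg, threshold=0.0)

    def test_monotonicity_in_threshold_and_fdr(self):
        rng = np.random.default_rng(8)
        pos_rows = [{"aa_seq": f"CAS{i:03d}F", "templates": int(t)}
                    for i, t in enumerate(rng.integers(1, 60, 120))]
        neg_rows = [{"aa_seq": f"CAS{i:03d}F", "templates": int(t)}
                    for i, t in enumerate(rng.integers(1, 12, 120))]
        pos, neg = self._paired(pos_rows, neg_rows)
        res_lo = en.clone_enrichment_test(pos, neg, threshold=0.005)
        res_hi = en.clone_enrichment_test(pos, neg, threshold=0.012)
        assert set(res_hi["aa_seq"]) <= set(res_lo["aa_seq"])
        strict = en.clone_enrichment_test(pos, neg, threshold=0.005, q_max=0.001)
        assert set(strict[strict["selected"]]["aa_seq"]) <= set(res_lo[res_lo["selected"]]["aa_seq"])


class TestVGeneUsage:
    def test_balanced_gene_gives_or_one(self):
        selected = pd.DataFrame({
            "donor_id": "D1", "aa_seq": [f"C{i}F" for i in range(4)],
            "v_gene": ["TRBV5", "TRBV5", "TRBV9", "TRBV9"],
        })
        control = make_repertoire("D1", "AIM_NEG", [
            {"aa_seq": f"CB{i}F", "templates": 1, "v_gene": g}
            for i, g in enumerate(["TRBV5", "TRBV5", "TRBV9", "TRBV9"])
        ])
        usage = en.vgene_usage_odds(selected, control)
        assert usage.set_index("v_gene").loc["TRBV5", "odds_ratio"] == pytest.approx(1.0)

    def test_documented_arithmetic_example(self):
        # 10/100 selected vs 1/100 control -> OR = (10/1)/(90/99) = 11.0
        selected = pd.DataFrame({
            "donor_id": "D1",
            "aa_seq": [f"C{i}F" for i in range(100)],
            "v_gene": ["TRBV15"] * 10 + ["TRBV5"] * 90,
        })
        control = make_repertoire("D1", "AIM_NEG", [
            {"aa_seq": f"CB{i:03d}F", "templates": 1,
             "v_gene": "TRBV15" if i == 0 else "TRBV5"}
            for i in range(100)
        ])
        usage = en.vgene_usage_odds(selected, control)
        assert usage.set_index("v_gene").loc["TRBV15", "odds_ratio"] == pytest.approx(11.0)

    def test_empty_selection_raises(self):
        control = make_repertoire("D1", "AIM_NEG", [{"aa_seq": "CBF", "templates": 1}])
        with pytest.raises(EmptyRepertoireError):
            en.vgene_usage_odds(pd.DataFrame(columns=["donor_id", "v_gene"]), control)


class TestCrossDonorUsage:
    def _usage_frame(self, rows):
        return pd.DataFrame(rows)

    def test_identical_frequencies_give_p_one(self):
        rows = [{"donor_id": f"D{d}", "v_gene": "TRBV5", "odds_ratio": 1.0,
                 "freq_in_selected": 0.2, "freq_in_control": 0.2} for d in range(6)]
        rep = en.cross_donor_usage_test(self._usage_frame(rows))
        assert rep["mannwhitney_p"].iloc[0] == 1.0
        assert not rep["flagged"].any()

    def test_single_donor_raises(self):
        rows = [{"donor_id": "D1", "v_gene": "TRBV5", "odds_ratio": 2.0,
                 "freq_in_selected": 0.3, "freq_in_control": 0.1}]
        with pytest.raises(ConfigurationError):
            en.cross_donor_usage_test(self._usage_frame(rows))

    def test_null_flag_rate_controlled_under_permutation(self):
        """With exchangeable selected/control frequencies the flag rate stays near alpha."""
        rng = np.random.default_rng(21)
        n_rep, n_genes, n_donors = 40, 12, 6
        flags = 0
        total = 0
        for _ in range(n_rep):
            rows = []
            for g in range(n_genes):
                base = rng.uniform(0.01, 0.2)
                for d in range(n_donors):
                    fs, fc = base * rng.lognormal(0, 0.3, 2)
                    rows.append({"donor_id": f"D{d}", "v_gene": f"TRBV{g}",
                                 "odds_ratio": fs / fc,
                                 "freq_in_selected": fs, "freq_in_control": fc})
            rep = en.cross_donor_usage_test(self._usage_frame(rows),
                                            min_donors_preferred=0, p_max=0.05)
            flags += int(rep["flagged"].sum())
            total += len(rep)
        rate = flags / total
        assert rate <= 0.05 + 3 * math.sqrt(0.05 / total)


class TestPlantedVGenePreference:
    def test_reactive_gene_preferred_in_every_donor_and_flagged(self, full_results):
        usage = full_results["selection"].vgene_usage
        cfg = full_results["cfg"]
        gene = cfg.reactive_v_gene
        per_donor = usage[usage["v_gene"] == gene]
        assert len(per_donor) == cfg.n_donors
        assert (per_donor["odds_ratio"] > 1).all()
        report = full_results["selection"].vgene_report
        row = report[report["v_gene"] == gene].iloc[0]
        assert row["flagged"]
        assert row["mannwhitney_p"] < 0.01
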