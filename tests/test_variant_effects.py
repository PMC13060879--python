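import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mprakit.genomic_core import GenomicInterval
from mprakit.variant_effects import (
    PWM,
    call_effects,
    classify_sharing,
    motif_delta,
    score_agreement,
    variant_logfc,
    window_summary,
)


class TestVariantLogfc:
    def test_identical_alleles_null(self):
        res = variant_logfc([0.2, 0.5, 0.3], [0.2, 0.5, 0.3])
        assert res["logFC"] == 0.0
        assert res["p"] == 1.0

    def test_swap_negates_logfc_exactly(self):
        ref = [0.1, 0.4, 0.2]
        alt = [0.6, 0.8, 0.9]
        fwd = variant_logfc(ref, alt)
        rev = variant_logfc(alt, ref)
        assert fwd["logFC"] == -rev["logFC"]
        assert fwd["p"] == rev["p"]

    def test_permutation_test_seeded_and_sane(self):
        # 6 replicates: the sharpest attainable sign-flip p is 2/64
        ref = [0.0, 0.05, -0.02, 0.01, 0.03, -0.01]
        alt = [0.5, 0.55, 0.48, 0.51, 0.53, 0.49]
        a = variant_logfc(ref, alt, test="permutation", seed=3)
        b = variant_logfc(ref, alt, test="permutation", seed=3)
        assert a == b
        assert a["p"] < 0.05

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            variant_logfc([0.1], [0.2])


class TestCallEffects:
    def frame(self, rows):
        return pd.DataFrame(rows)

    def test_effect_size_gate(self):
        # significant but tiny effect stays ns
        df = self.frame(
            [
                {"variant_key": "v1", "var_class": "SNV", "logFC": 0.09, "p": 1e-6},
                {"variant_key": "v2", "var_class": "SNV", "logFC": 0.50, "p": 1e-6},
                {"variant_key": "v3", "var_class": "SNV", "logFC": -0.50, "p": 1e-6},
                {"variant_key": "v4", "var_class": "SNV", "logFC": 0.50, "p": 0.9},
            ]
        )
        out = call_effects(df).set_index("variant_key")
        assert out.loc["v1", "call"] == "ns"
        assert out.loc["v2", "call"] == "gain"
        assert out.loc["v3", "call"] == "loss"
        assert out.loc["v4", "call"] == "ns"

    def test_strict_inequality_at_cutoff(self):
        df = self.frame(
            [{"variant_key": "v", "var_class": "SNV", "logFC": 0.1, "p": 1e-9}]
        )
        assert call_effects(df).loc[0, "call"] == "ns"

    def test_snv_and_indel_families_adjusted_separately(self):
        rows = [
            {"variant_key": "s0", "var_class": "SNV", "logFC": 0.5, "p": 0.03},
            {"variant_key": "s1", "var_class": "SNV", "logFC": 0.5, "p": 0.05},
            {"variant_key": "i0", "var_class": "InDel", "logFC": 0.5, "p": 0.03},
        ]
        out = call_effects(self.frame(rows)).set_index("variant_key")
        # lone indel keeps its raw p; the SNV with the same raw p is inflated
        # by step-up within its own two-test family
        assert out.loc["i0", "adj_p"] == pytest.approx(0.03)
        assert out.loc["s0", "adj_p"] == pytest.approx(0.05)

    def test_log2_rescaling(self):
        df = self.frame(
            [{"variant_key": "v", "var_class": "SNV", "logFC": np.log(2), "p": 1e-9}]
        )
        out = call_effects(df, log_base="2")
        assert out.loc[0, "logFC"] == pytest.approx(1.0)


class TestClassifySharing:
    def test_exhaustive_truth_table(self):
        def oracle(a, b):
            called = {"gain", "loss"}
            if a in called and b in called:
                return "shared" if a == b else "discordant"
            if a in called:
                return "A_only"
            if b in called:
                return "B_only"
            return "none"

        for a, b in itertools.product(["gain", "loss", "ns"], repeat=2):
            assert classify_sharing(a, b) == oracle(a, b), (a, b)

    def test_unknown_call_rejected(self):
        with pytest.raises(ValueError):
            classify_sharing("gain", "maybe")


class TestWindowSummary:
    def effects(self):
        return pd.DataFrame(
            {
                "variant_key": [f"v{i}" for i in range(6)],
                "chrom": ["c"] * 6,
                "focal_pos": [100, 150, 200, 250, 300, 350],
                "call": ["gain", "loss", "ns", "gain", "ns", "loss"],
            }
        )

    def test_empty_window(self):
        out = window_summary(self.effects(), GenomicInterval("c", 1000, 2000))
        assert out == {"gain": 0, "loss": 0, "total_called": 0,
                       "total_tested": 0, "fraction_called": 0.0}

    def test_planted_counts_recovered(self):
        out = window_summary(self.effects(), GenomicInterval("c", 100, 250))
        assert out["gain"] == 2 and out["loss"] == 1
        assert out["total_tested"] == 4

    def test_global_window_conserves_calls(self):
        eff = self.effects()
        out = window_summary(eff, GenomicInterval("c", 1, 10_000))
        assert out["total_called"] == int((eff["call"] != "ns").sum())
        assert out["total_tested"] == len(eff)

    def test_inclusive_boundaries(self):
        out = window_summary(self.effects(), GenomicInterval("c", 150, 350))
        assert out["total_tested"] == 5


def consensus_pwm(strong=0.97):
    """4-column motif with consensus ACGT."""
    rest = (1 - strong) / 3
    cols = []
    for b in "ACGT":
        col = [rest] * 4
        col["ACGT".index(b)] = strong
        cols.append(tuple(col))
    return PWM("toy", tuple(cols))


class TestMotifDelta:
    def test_identical_sequences_zero(self):
        pwm = consensus_pwm()
        assert motif_delta(pwm, "TTACGTTT", "TTACGTTT") == 0.0

    def test_uniform_motif_uninformative(self):
        pwm = PWM("flat", tuple([(0.25,) * 4] * 4))
        assert motif_delta(pwm, "ACGTACGT", "AAAATTTT") == pytest.approx(0.0)

    def test_consensus_breaking_substitution_hand_computed(self):
        strong, rest = 0.97, 0.01
        pwm = consensus_pwm(strong)
        ref = "TTACGTTT"  # contains the consensus ACGT
        alt = "TTATGTTT"  # center C->T breaks it
        delta = motif_delta(pwm, ref, alt, pseudo=0.0)
        # best ref hit: 4 * log2(0.97/0.25); best alt hit computed by hand over
        # all offsets/strands of TTATGTTT = 3 consensus matches + one 0.01 base
        best_ref = 4 * np.log2(strong / 0.25)
        best_alt = 3 * np.log2(strong / 0.25) + np.log2(rest / 0.25)
        assert delta == pytest.approx(best_alt - best_ref)
        assert delta < 0  # disruption

    def test_reverse_strand_hit_found(self):
        pwm = consensus_pwm()
        # revcomp of ACGT is ACGT; use an asymmetric motif instead
        cols = []
        for b in "AACG":
            col = [0.01] * 4
            col["ACGT".index(b)] = 0.97
            cols.append(tuple(col))
        pwm = PWM("asym", tuple(cols))
        fwd = motif_delta(pwm, "TTAACGTT", "TTAACGTT")
        # CGTT on the forward strand reads AACG on the reverse
        assert motif_delta(pwm, "AAAACGTT", "AAAACGTT") == 0.0
        assert fwd == 0.0

    def test_background_shift_invariance(self):
        pwm = consensus_pwm()
        ref, alt = "TTACGTTT", "TTATGTTT"
        d1 = motif_delta(pwm, ref, alt, background=(0.25,) * 4)
        d2 = motif_delta(pwm, ref, alt, background=(0.1,) * 4)
        assert d1 == pytest.approx(d2)


class TestScoreAgreement:
    def effects(self, logfcs, calls=None):
        n = len(logfcs)
        return pd.DataFrame(
            {
                "variant_key": [f"v{i}" for i in range(n)],
                "logFC": logfcs,
                "call": calls if calls is not None else ["gain"] * n,
            }
        )

    def scores(self, values):
        return pd.DataFrame(
            {"variant_key": [f"v{i}" for i in range(len(values))], "score": values}
        )

    def test_identical_scores_rho_one(self):
        lf = [0.5, -0.2, 0.9, 0.1, -0.7]
        out = score_agreement(self.effects(lf), self.scores(lf))
        assert out["rho"] == pytest.approx(1.0)
        assert out["sign_concordance"] == pytest.approx(1.0)

    def test_negated_scores_rho_minus_one(self):
        lf = [0.5, -0.2, 0.9, 0.1, -0.7]
        out = score_agreement(self.effects(lf), self.scores([-x for x in lf]))
        assert out["rho"] == pytest.approx(-1.0)
        assert out["sign_concordance"] == pytest.approx(0.0)

    def test_ten_pair_toy_matches_rank_formula(self):
        rng = np.random.default_rng(21)
        lf = rng.normal(size=10)
        sc = rng.normal(size=10)
        out = score_agreement(self.effects(lf), self.scores(sc))
        # brute-force Spearman: Pearson correlation of ranks
        def ranks(x):
            order = np.argsort(x)
            r = np.empty(len(x))
            r[order] = np.arange(1, len(x) + 1)
            return r
        rx, ry = ranks(lf), ranks(sc)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out["rho"] == pytest.approx(expected)

    def test_unmatched_keys_reported(self):
        eff = self.effects([0.1, 0.2, 0.3, 0.4])
        out = score_agreement(eff, self.scores([1.0, 2.0, 3.0]))
        assert out["unmatched_keys"] == ["v3"]
        assert out["n_matched"] == 3


@given(st.lists(st.floats(-2, 2), min_size=2, max_size=6))
@settings(deadline=None, max_examples=50)
def test_swap_negation_property(deltas):
    ref = np.zeros(len(deltas))
    alt = np.array(deltas)
    fwd = variant_logfc(ref, alt)
    rev = variant_logfc(alt, ref)
    assert fwd["logFC"] == -rev["logFC"]
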