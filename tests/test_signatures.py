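"""Signature enumeration, scoring, selection and enrichment curves."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from plifscreen.curation import ACTIVE, INACTIVE
from plifscreen.signatures import (
    EnrichmentCurve,
    SignatureMiner,
    SignatureRule,
    apply_signature_filter,
    enrichment_curve,
    enumerate_signatures,
    ligand_efficiency,
    score_signature,
    select_best_signature,
)


def random_bits_and_labels(rng, n, residues, p=0.4):
    bits = pd.DataFrame(
        (rng.random((n, len(residues))) < p).astype(np.uint8), columns=list(residues)
    )
    labels = np.where(rng.random(n) < 0.5, ACTIVE, INACTIVE)
    # guarantee both classes
    labels[0], labels[1] = ACTIVE, INACTIVE
    return bits, labels


class TestEnumerate:
    @pytest.mark.parametrize(
        "n_residues,min_size,max_size,expected",
        [
            (6, 2, 6, 57),   # the key-residue panel
            (2, 2, 2, 1),
            (4, 2, 3, 10),   # C(4,2) + C(4,3)
            (5, 1, 5, 31),
        ],
    )
    def test_counts(self, n_residues, min_size, max_size, expected):
        residues = [f"R{i}" for i in range(n_residues)]
        assert len(enumerate_signatures(residues, min_size, max_size)) == expected

    def test_cardinality_matches_binomial_sum(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            lo = int(rng.integers(1, n + 1))
            hi = int(rng.integers(lo, n + 1))
            residues = [f"R{i:02d}" for i in range(n)]
            got = enumerate_signatures(residues, lo, hi)
            want = sum(math.comb(n, k) for k in range(lo, hi + 1))
            assert len(got) == want
            assert len(set(got)) == len(got)  # exactly once

    def test_order_is_size_then_lexicographic(self):
        out = enumerate_signatures(["B", "A", "C"], 2, 3)
        assert out == [("A", "B"), ("A", "C"), ("B", "C"), ("A", "B", "C")]

    def test_bad_bounds_raise(self):
        with pytest.raises(ValueError):
            enumerate_signatures(["A", "B"], 0, 2)
        with pytest.raises(ValueError):
            enumerate_signatures(["A", "B"], 2, 3)


class TestScoreSignature:
    def test_documented_counts(self, small_vocab):
        # 6 of 10 actives match, 2 of 10 inactives match
        rows = []
        for i in range(10):
            rows.append([1, 1, 0, 0, 0, 0] if i < 6 else [0, 1, 0, 0, 0, 0])
        for i in range(10):
            rows.append([1, 1, 0, 0, 0, 0] if i < 2 else [0, 0, 0, 0, 0, 0])
        bits = pd.DataFrame(rows, columns=list(small_vocab))
        labels = np.array([ACTIVE] * 10 + [INACTIVE] * 10)
        rule = score_signature(("LEU70", "VAL75"), bits, labels)
        assert rule.freq_active == pytest.approx(0.6)
        assert rule.freq_inactive == pytest.approx(0.2)
        assert rule.ratio == pytest.approx(3.0)
        assert rule.coverage == rule.freq_active

    def test_zero_inactive_matches_gives_inf_sentinel(self, small_vocab):
        bits = pd.DataFrame(
            [[1] * 6, [1] * 6, [0] * 6, [0] * 6], columns=list(small_vocab)
        )
        labels = np.array([ACTIVE, ACTIVE, INACTIVE, INACTIVE])
        rule = score_signature(("LEU70",), bits, labels)
        assert math.isinf(rule.ratio)

    def test_empty_subset_and_single_class_raise(self, small_vocab):
        bits = pd.DataFrame([[1] * 6, [0] * 6], columns=list(small_vocab))
        with pytest.raises(ValueError, match="empty"):
            score_signature((), bits, np.array([ACTIVE, INACTIVE]))
        with pytest.raises(ValueError, match="both classes"):
            score_signature(("LEU70",), bits, np.array([ACTIVE, ACTIVE]))

    def test_matches_counting_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        residues = [f"R{i}" for i in range(12)]
        for _ in range(100):
            n = int(rng.integers(10, 120))
            bits, labels = random_bits_and_labels(rng, n, residues)
            size = int(rng.integers(1, 5))
            subset = tuple(rng.choice(residues, size=size, replace=False))
            rule = score_signature(subset, bits, labels)
            # brute-force counting oracle
            match = [all(bits.iloc[i][r] for r in subset) for i in range(n)]
            n_a = sum(labels == ACTIVE)
            n_i = sum(labels == INACTIVE)
            fa = sum(m for m, l in zip(match, labels) if l == ACTIVE) / n_a
            fi = sum(m for m, l in zip(match, labels) if l == INACTIVE) / n_i
            assert rule.freq_active == pytest.approx(fa)
            assert rule.freq_inactive == pytest.approx(fi)

    def test_monotone_in_subset_growth(self):
        rng = np.random.default_rng(5)
        residues = [f"R{i}" for i in range(8)]
        bits, labels = random_bits_and_labels(rng, 200, residues)
        for _ in range(30):
            size = int(rng.integers(1, 6))
            subset = tuple(rng.choice(residues, size=size, replace=False))
            extra = rng.choice([r for r in residues if r not in subset])
            small = score_signature(subset, bits, labels)
            big = score_signature(subset + (extra,), bits, labels)
            assert big.freq_active <= small.freq_active
            assert big.freq_inactive <= small.freq_inactive


class TestSelectBest:
    def rule(self, residues, ratio, coverage):
        return SignatureRule(
            residues=frozenset(residues), freq_active=coverage,
            freq_inactive=coverage / ratio if ratio else 0.0,
            ratio=ratio, coverage=coverage,
        )

    def test_coverage_floor_excludes_high_ratio(self):
        a = self.rule(["R1", "R2"], 3.0, 0.6)
        b = self.rule(["R3"], 5.0, 0.1)
        assert select_best_signature([a, b], min_coverage=0.5) is a

    def test_tie_breaks_prefer_coverage_then_size_then_lex(self):
        a = self.rule(["R1"], 2.0, 0.55)
        b = self.rule(["R2"], 2.0, 0.70)
        assert select_best_signature([a, b]) is b
        c = self.rule(["R1", "R2"], 2.0, 0.70)
        assert select_best_signature([b, c]) is c
        d = self.rule(["R0", "R3"], 2.0, 0.70)
        assert select_best_signature([c, d]) is d  # (R0,R3) < (R1,R2)

    def test_inf_ratio_ranks_above_finite(self):
        a = self.rule(["R1"], 100.0, 0.9)
        b = self.rule(["R2"], math.inf, 0.6)
        assert select_best_signature([a, b]) is b

    def test_empty_and_uncovered_raise(self):
        with pytest.raises(ValueError):
            select_best_signature([])
        with pytest.raises(ValueError, match="coverage"):
            select_best_signature([self.rule(["R1"], 9.0, 0.2)])


class TestApplyFilter:
    def test_all_four_residues_required(self, small_vocab):
        rule = SignatureRule(
            residues=frozenset(["LEU70", "VAL75", "ASP156", "LEU157"]),
            freq_active=0.6, freq_inactive=0.25, ratio=2.4, coverage=0.6,
        )
        bits = pd.DataFrame(
            [
                [1, 1, 0, 0, 1, 1],  # all four on -> pass
                [1, 1, 0, 0, 1, 0],  # missing LEU157 -> fail
                [0, 0, 0, 0, 0, 0],  # all-zero -> fail
            ],
            columns=list(small_vocab),
        )
        mask = apply_signature_filter(bits, rule)
        assert mask.tolist() == [True, False, False]

    def test_missing_rule_residue_raises(self, small_vocab):
        rule = SignatureRule(
            residues=frozenset(["GLY999"]), freq_active=1, freq_inactive=1,
            ratio=1, coverage=1,
        )
        bits = pd.DataFrame([[0] * 6], columns=list(small_vocab))
        with pytest.raises(ValueError, match="absent"):
            apply_signature_filter(bits, rule)


def test_ligand_efficiency():
    assert ligand_efficiency(50.0, 25) == pytest.approx(2.0)
    assert ligand_efficiency(0.0, 7) == 0.0
    with pytest.raises(ValueError):
        ligand_efficiency(10.0, 0)


class TestEnrichmentCurve:
    def test_perfect_separation_reaches_full_precision(self):
        scores = np.concatenate([np.linspace(10, 20, 30), np.linspace(30, 40, 30)])
        labels = np.array([INACTIVE] * 30 + [ACTIVE] * 30)
        curve = enrichment_curve(scores, labels, percentiles=[50, 60, 70, 80])
        assert np.allclose(curve.precision, 1.0)

    def test_all_active_gives_full_precision_everywhere(self):
        scores = np.arange(20.0)
        labels = np.array([ACTIVE] * 20)
        curve = enrichment_curve(scores, labels, percentiles=[0, 25, 50, 75])
        assert np.allclose(curve.precision, 1.0)

    def test_empty_selection_reports_nan_not_zero(self):
        curve = enrichment_curve([1.0, 1.0, 1.0], [ACTIVE] * 3, percentiles=[50])
        assert curve.n_selected[0] == 0
        assert np.isnan(curve.precision[0])

    def test_matches_selection_and_count_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(10, 150))
            scores = rng.normal(size=n)
            labels = np.where(rng.random(n) < 0.4, ACTIVE, INACTIVE)
            pcts = sorted(rng.choice(np.arange(0, 96), size=4, replace=False))
            curve = enrichment_curve(scores, labels, percentiles=pcts)
            for j, p in enumerate(pcts):
                # independent percentile: manual linear interpolation
                srt = np.sort(scores)
                rank = p / 100 * (n - 1)
                lo, hi = int(math.floor(rank)), int(math.ceil(rank))
                cut = srt[lo] + (rank - lo) * (srt[hi] - srt[lo])
                sel = scores > cut
                assert curve.n_selected[j] == sel.sum()
                if sel.sum():
                    want = (labels[sel] == ACTIVE).mean()
                    assert curve.precision[j] == pytest.approx(want)

    def test_n_selected_non_increasing(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=200)
        labels = np.where(rng.random(200) < 0.5, ACTIVE, INACTIVE)
        curve = enrichment_curve(scores, labels, percentiles=range(0, 100, 5))
        assert (np.diff(curve.n_selected) <= 0).all()


class TestSignatureMiner:
    def test_fit_selects_planted_rule_and_predict_applies_it(self, small_vocab):
        rng = np.random.default_rng(9)
        n = 200
        carrier = rng.random(n) < 0.6
        labels = np.where(rng.random(n) < 0.5, ACTIVE, INACTIVE)
        carrier[labels == INACTIVE] &= rng.random((labels == INACTIVE).sum()) < 0.3
        bits = np.zeros((n, 6), dtype=np.uint8)
        bits[carrier, :4] = 1   # LEU70, VAL75, LEU78, LEU129 as planted block
        frame = pd.DataFrame(bits, columns=list(small_vocab))
        miner = SignatureMiner(min_coverage=0.3).fit(frame, labels)
        assert set(miner.rule_.residues) == set(small_vocab[:4])
        mask = miner.predict(frame)
        assert (mask == carrier).all()
        assert len(miner.rules_) == 57

    def test_sklearn_param_interface(self):
        miner = SignatureMiner(min_size=3)
        assert miner.get_params()["min_size"] == 3
        miner.set_params(max_size=4)
        assert miner.max_size == 4
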