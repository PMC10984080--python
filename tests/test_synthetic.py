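"""Synthetic corpus generator: determinism, calibration, ground truth, oracle."""

import numpy as np
import pytest
from scipy.stats import binom, poisson

from psychnote.baselines import classify_by_icd, classify_by_keywords, load_packaged_icd_codes
from psychnote.evaluation import confusion_metrics
from psychnote.lexicon import load_packaged_lexicon
from psychnote.selection import match_keywords
from psychnote.synthetic import (
    PAPER_PREVALENCE,
    SynthConfig,
    bayes_optimal_auroc,
    generate_corpus,
)


class TestConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            SynthConfig(prevalence=1.5)
        with pytest.raises(ValueError, match="emission"):
            SynthConfig(emission_rates={"base": (-1.0, 0.5)})
        with pytest.raises(ValueError):
            SynthConfig(n_notes=0)

    def test_default_effect_direction_is_case_dominant(self):
        cfg = SynthConfig()
        for rc, r0 in cfg.emission_rates.values():
            assert rc >= r0


class TestGenerateCorpus:
    def test_same_seed_byte_identical(self):
        cfg = SynthConfig(n_notes=40, seed=11)
        c1, c2 = generate_corpus(cfg), generate_corpus(cfg)
        assert [n.text for n in c1] == [n.text for n in c2]
        assert [n.icd_codes for n in c1] == [n.icd_codes for n in c2]
        assert [n.label for n in c1] == [n.label for n in c2]

    def test_case_fraction_within_binomial_bounds(self):
        n = 1000
        corpus = generate_corpus(SynthConfig(n_notes=n, seed=13))
        k = sum(note.label == "case" for note in corpus)
        # 99.9% central bounds: tight enough to catch a miscalibrated
        # prevalence, wide enough for a single pinned seed
        lo, hi = binom.ppf([0.0005, 0.9995], n, PAPER_PREVALENCE)
        assert lo <= k <= hi

    def test_guarantee_base_keyword(self, paper_like_corpus):
        base = load_packaged_lexicon("base")
        assert all(classify_by_keywords(n, base) for n in paper_like_corpus)

    def test_ground_truth_spans_index_real_text(self, paper_like_corpus):
        for note in paper_like_corpus[:50]:
            for s in note.keyword_spans:
                assert s.term in note.text[s.start : s.end].lower()
            for s in note.phi_spans:
                assert note.text[s.start : s.end] == s.surface

    def test_filler_cannot_match_lexicon(self):
        """Zero-emission corpora contain zero keyword matches anywhere."""
        lex = load_packaged_lexicon("all")
        corpus = generate_corpus(
            SynthConfig(
                n_notes=60,
                emission_rates={"base": (0.0, 0.0)},
                guarantee_base_keyword=False,
                seed=3,
            )
        )
        assert all(match_keywords(n.text, lex) == {} for n in corpus)

    def test_note_lengths_follow_configured_lognormal(self):
        cfg = SynthConfig(n_notes=2000, seed=17)
        toks = np.array([len(n.text.split()) for n in generate_corpus(cfg)])
        logs = np.log(toks)
        assert abs(logs.mean() - cfg.length_log_mean) < 0.15
        assert abs(logs.std() - cfg.length_log_sd) < 0.15

    def test_negation_breaks_rule_precision(self, paper_like_corpus):
        """With negation frames on, keyword-rule precision sits below 1."""
        lex = load_packaged_lexicon("all")
        y = [1 if n.label == "case" else 0 for n in paper_like_corpus]
        pred = [int(classify_by_keywords(n, lex)) for n in paper_like_corpus]
        rep = confusion_metrics(y, pred)
        assert rep["ppv"] < 1.0
        assert any(s.negated for n in paper_like_corpus for s in n.keyword_spans)

    def test_icd_agreement_matches_configured_accuracy(self):
        corpus = generate_corpus(SynthConfig(n_notes=2000, icd_accuracy=0.85, seed=23))
        codes = load_packaged_icd_codes()
        y = np.array([n.label == "case" for n in corpus])
        pred = np.array([classify_by_icd(n.icd_codes, codes) for n in corpus])
        assert np.mean(y == pred) == pytest.approx(0.85, abs=0.03)

    def test_poisson_override_filler_count(self):
        cfg = SynthConfig.high_noise(n_notes=100, seed=5)
        corpus = generate_corpus(cfg)
        n_sent = np.mean([len(n.sentence_spans) for n in corpus])
        # ~80 filler + 4 headers + keywords + PHI
        assert 70 < n_sent < 100


class TestBayesOptimalAuroc:
    def test_uninformative_rates_give_half(self):
        cfg = SynthConfig(emission_rates={"base": (1.0, 1.0)}, guarantee_base_keyword=False)
        assert bayes_optimal_auroc(cfg) == pytest.approx(0.5)

    def test_disjoint_supports_give_one(self):
        cfg = SynthConfig(emission_rates={"base": (30.0, 0.0)}, guarantee_base_keyword=False)
        assert bayes_optimal_auroc(cfg) == pytest.approx(1.0, abs=1e-9)

    def test_single_tier_matches_direct_summation(self):
        """Poisson(2) vs Poisson(0.5): independent exhaustive summation."""
        cfg = SynthConfig.poisson_recovery()
        ks = np.arange(0, 60)
        pc, p0 = poisson.pmf(ks, 2.0), poisson.pmf(ks, 0.5)
        oracle = float(
            sum(pc[i] * p0[j] for i in ks for j in ks if i > j)
            + 0.5 * sum(pc[i] * p0[i] for i in ks)
        )
        assert bayes_optimal_auroc(cfg) == pytest.approx(oracle, abs=1e-9)

    def test_guarantee_truncation_handled(self):
        base = SynthConfig(emission_rates={"base": (2.0, 0.5)}, guarantee_base_keyword=False)
        trunc = SynthConfig(emission_rates={"base": (2.0, 0.5)}, guarantee_base_keyword=True)
        # truncation removes the 0-vs-positive contrast, lowering separability
        assert bayes_optimal_auroc(trunc) < bayes_optimal_auroc(base)

    def test_monte_carlo_fallback_close_to_exact(self):
        cfg = SynthConfig(
            emission_rates={"base": (2.0, 0.5)},
            guarantee_base_keyword=False,
        )
        exact = bayes_optimal_auroc(cfg, method="exact")
        mc, se = bayes_optimal_auroc(
            cfg, mc_samples=60_000, seed=1, return_se=True, method="mc"
        )
        assert se > 0
        assert abs(mc - exact) < 5 * se
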