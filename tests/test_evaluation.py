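"""Subject-level folds, patient aggregation, metrics, kappa, error analysis."""

import numpy as np
import pytest

from emrcase import (
    BaseLearnerSpec,
    ConfusionCounts,
    Corpus,
    GroundTruthRecord,
    SamplingPlan,
    SyntheticConfig,
    build_vocabulary,
    categorize_false_negatives,
    classify_patient,
    cohen_kappa,
    generate,
    make_folds,
    run_experiment,
    sensitivity,
    specificity,
)
from emrcase.evaluation import MetricError
from emrcase.learners import TrainedModel
from emrcase.rebalance import assemble_training_set

from conftest import make_patient, random_corpus


class TestFolds:
    def test_exact_division(self):
        corpus = Corpus([make_patient(f"p{i}", "negative", ["x"]) for i in range(10)])
        folds = make_folds(corpus, k=5, seed=0)
        sizes = sorted(len(folds.patients_in(f)) for f in range(1, 6))
        assert sizes == [2, 2, 2, 2, 2]

    def test_sizes_differ_by_at_most_one(self):
        corpus = Corpus([make_patient(f"p{i}", "negative", ["x"]) for i in range(11)])
        folds = make_folds(corpus, k=5, seed=1)
        sizes = sorted(len(folds.patients_in(f)) for f in range(1, 6))
        assert sizes == [2, 2, 2, 2, 3]

    def test_same_seed_same_assignment(self):
        corpus = Corpus([make_patient(f"p{i}", "negative", ["x"]) for i in range(23)])
        a = make_folds(corpus, k=5, seed=7)
        b = make_folds(corpus, k=5, seed=7)
        assert a.assignment == b.assignment

    def test_too_few_patients_rejected(self):
        corpus = Corpus([make_patient("p", "negative", ["x"])])
        with pytest.raises(ValueError):
            make_folds(corpus, k=5, seed=0)

    def test_no_patient_spans_train_and_test(self, nl_lexicon):
        """Subject-level integrity over many random corpora."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            corpus = random_corpus(rng, n_patients=int(rng.integers(6, 25)))
            folds = make_folds(corpus, k=3, seed=seed)
            for f in range(1, 4):
                test_ids = set(folds.patients_in(f))
                train = [p for p in corpus if p.patient_id not in test_ids]
                examples = assemble_training_set(train, use_set_expansion=True)
                assert not {e.patient_id for e in examples} & test_ids
                assert {p.patient_id for p in corpus} == test_ids | {
                    p.patient_id for p in train
                }


class _FixedModel(TrainedModel):
    """Predicts positive iff any feature is on (for aggregation tests)."""

    def predict(self, X):
        return (np.atleast_2d(X).sum(axis=1) > 0).astype(int)


class TestClassifyPatient:
    @pytest.fixture
    def vocab(self):
        return build_vocabulary([(["marker"], 1)] * 5 + [(["anders"], 0)] * 5)

    def test_any_positive_entry_makes_patient_positive(self, vocab, nl_lexicon):
        p = make_patient("p", "negative", ["niks", "ook niks", "marker hier", "niks"])
        assert classify_patient(_FixedModel(), p, vocab, nl_lexicon) == "positive"

    def test_all_negative_entries_make_patient_negative(self, vocab, nl_lexicon):
        p = make_patient("p", "positive", ["niks", "leeg", "stil"])
        assert classify_patient(_FixedModel(), p, vocab, nl_lexicon) == "negative"

    def test_singleton_patient_equals_entry_prediction(self, vocab, nl_lexicon):
        p = make_patient("p", "positive", ["marker"])
        assert classify_patient(_FixedModel(), p, vocab, nl_lexicon) == "positive"


class TestMetrics:
    def test_sensitivity_specificity_quotients(self):
        c = ConfusionCounts(tp=9, fn=1, tn=0, fp=5)
        assert sensitivity(c) == pytest.approx(0.9)
        assert specificity(c) == 0.0

    def test_zero_denominators_raise(self):
        with pytest.raises(MetricError):
            sensitivity(ConfusionCounts(tn=3, fp=2))
        with pytest.raises(MetricError):
            specificity(ConfusionCounts(tp=3, fn=2))


class TestCohenKappa:
    def test_worked_table(self):
        kappa, (lo, hi) = cohen_kappa([[40, 10], [5, 45]])
        assert kappa == pytest.approx(0.70)
        assert lo < 0.70 < hi
        assert hi - lo == pytest.approx(2 * 1.96 * np.sqrt(0.85 * 0.15 / (100 * 0.25)))

    def test_matches_sklearn_on_random_tables(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        for _ in range(50):
            t = rng.integers(1, 30, size=(2, 2))
            a = [0] * (t[0, 0] + t[0, 1]) + [1] * (t[1, 0] + t[1, 1])
            b = [0] * t[0, 0] + [1] * t[0, 1] + [0] * t[1, 0] + [1] * t[1, 1]
            kappa, _ = cohen_kappa(t)
            assert kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_perfect_and_chance_agreement(self):
        assert cohen_kappa([[30, 0], [0, 20]])[0] == pytest.approx(1.0)
        assert cohen_kappa([[25, 25], [25, 25]])[0] == pytest.approx(0.0)


class TestRunExperiment:
    def test_noise_free_corpus_is_fully_recovered(self, nl_lexicon):
        cfg = SyntheticConfig(
            n_positive=30, n_negative=120,
            negation_rate=0, misspelling_rate=0, circumstantial_rate=0, seed=5,
        )
        corpus, _ = generate(cfg)
        folds = make_folds(corpus, k=5, seed=5)
        res = run_experiment(
            corpus, folds, SamplingPlan(use_set_expansion=True, seed=5),
            BaseLearnerSpec("myc"), None, nl_lexicon,
        )
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_label_independent_text_gives_chance_balanced_accuracy(self, nl_lexicon):
        rng = np.random.default_rng(17)
        words = [f"w{i}" for i in range(40)]
        patients = []
        for i in range(120):
            texts = [" ".join(rng.choice(words, size=8)) for _ in range(3)]
            label = "positive" if i % 2 == 0 else "negative"
            patients.append(make_patient(f"p{i}", label, texts))
        corpus = Corpus(patients)
        folds = make_folds(corpus, k=5, seed=17)
        res = run_experiment(
            corpus, folds, SamplingPlan(seed=17), BaseLearnerSpec("myc"), None, nl_lexicon
        )
        balanced = (res.sensitivity + res.specificity) / 2
        assert abs(balanced - 0.5) < 0.15  # ~3 binomial SDs at n=60 per class

    def test_deterministic_given_seed(self, nl_lexicon):
        corpus, _ = generate(SyntheticConfig(n_positive=15, n_negative=60, seed=2))
        folds = make_folds(corpus, k=4, seed=2)
        plan = SamplingPlan(use_set_expansion=True, undersample_pct=40, seed=2)
        runs = [
            run_experiment(corpus, folds, plan, BaseLearnerSpec("myc"), None, nl_lexicon)
            for _ in range(2)
        ]
        assert runs[0].predictions == runs[1].predictions
        assert runs[0].pooled == runs[1].pooled

    def test_pooled_counts_equal_fold_sums(self, nl_lexicon):
        corpus, _ = generate(SyntheticConfig(n_positive=12, n_negative=50, seed=8))
        folds = make_folds(corpus, k=3, seed=8)
        res = run_experiment(
            corpus, folds, SamplingPlan(seed=8), BaseLearnerSpec("myc"), None, nl_lexicon
        )
        total = ConfusionCounts()
        for c in res.per_fold:
            total = total + c
        assert total == res.pooled
        assert total.tp + total.fn == 12
        assert total.tn + total.fp == 50


class TestErrorAnalysis:
    def _setup(self, nl_lexicon):
        vocab = build_vocabulary([(["hepatitis"], 1)] * 5 + [(["rest"], 0)] * 5)
        model = _FixedModel()
        return model, vocab

    def test_cascade_categories(self, nl_lexicon):
        model, vocab = self._setup(nl_lexicon)
        patients = [
            make_patient("flt", "positive", ["echo bb: hepatitis aanwezig?"]),
            make_patient("spl", "positive", ["status na hepatitus vorig jaar"]),
            make_patient("mis", "positive", ["duidelijke hepatitis vastgesteld"]),
            make_patient("lbl", "positive", ["alles rustig vandaag"]),
        ]
        truth = {
            "flt": GroundTruthRecord("flt", "flt-e0", "hepatitis", True, False, False),
            "spl": GroundTruthRecord("spl", "spl-e0", "hepatitus", False, True, False),
            "mis": GroundTruthRecord("mis", "mis-e0", "hepatitis", False, False, False),
            "lbl": GroundTruthRecord("lbl", None, None, False, False, True),
        }
        breakdown = categorize_false_negatives(patients, model, vocab, nl_lexicon, truth)
        assert breakdown.counts == {
            "evidence_removed_by_filter": 1,
            "spelling_variant": 1,
            "evidence_not_in_model": 1,
            "labeling_error": 1,
        }
        assert breakdown.total == 4
        assert sum(breakdown.percentages().values()) == pytest.approx(100.0)

    def test_missing_sidecar_record_names_patient(self, nl_lexicon):
        model, vocab = self._setup(nl_lexicon)
        p = make_patient("orphan", "positive", ["x y z"])
        with pytest.raises(KeyError, match="orphan"):
            categorize_false_negatives([p], model, vocab, nl_lexicon, {})
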