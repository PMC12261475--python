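import numpy as np
import pytest

from asmscan.alphabet import decode, encode
from asmscan.background import swissprot_background
from asmscan.model import (
    ModelConfig,
    TrainConfig,
    build_model,
    count_trainable_params,
    cv_split,
    train_fold,
)


def brute_force_param_count(cfg: ModelConfig) -> int:
    """Enumerate every weight tensor of the architecture explicitly."""
    shapes = [
        (cfg.vocab_size, cfg.embed_dim),  # embedding
    ]
    for _direction in range(2):  # bidirectional recurrent layer
        shapes += [
            (cfg.embed_dim, 4 * cfg.bi_units),   # input kernel
            (cfg.bi_units, 4 * cfg.bi_units),    # recurrent kernel
            (4 * cfg.bi_units,),                 # single bias per gate
        ]
    shapes += [
        (2 * cfg.bi_units, 4 * cfg.uni_units),   # unidirectional input kernel
        (cfg.uni_units, 4 * cfg.uni_units),      # unidirectional recurrent kernel
        (4 * cfg.uni_units,),
        (cfg.uni_units, 1),                      # sigmoid output
        (1,),
    ]
    return sum(int(np.prod(s)) for s in shapes)


class TestParameterCount:
    @pytest.mark.parametrize(
        "cfg,expected",
        [
            (ModelConfig(), 1637),
            (ModelConfig(vocab_size=4, embed_dim=2, bi_units=2, uni_units=2), 147),
            (ModelConfig(vocab_size=1, embed_dim=1, bi_units=1, uni_units=1), 43),
        ],
    )
    def test_closed_form_examples(self, cfg, expected):
        assert count_trainable_params(cfg) == expected
        assert brute_force_param_count(cfg) == expected

    def test_closed_form_matches_built_model_on_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cfg = ModelConfig(
                vocab_size=int(rng.integers(1, 40)),
                embed_dim=int(rng.integers(1, 16)),
                bi_units=int(rng.integers(1, 16)),
                uni_units=int(rng.integers(1, 16)),
            )
            model = build_model(cfg, seed=0)
            assert model.n_params == count_trainable_params(cfg)


class TestBuildModel:
    def test_default_has_1637_parameters(self):
        assert build_model().n_params == 1637

    def test_output_is_probability(self):
        model = build_model(seed=1)
        tokens = np.random.default_rng(0).integers(0, 26, size=(16, 40))
        probs = model.predict_proba(tokens)
        assert ((probs > 0) & (probs < 1)).all()

    def test_same_seed_same_initial_outputs(self):
        tokens = np.random.default_rng(0).integers(1, 26, size=(8, 40))
        a = build_model(seed=5).predict_proba(tokens)
        b = build_model(seed=5).predict_proba(tokens)
        assert np.array_equal(a, b)

    def test_inference_is_pure(self):
        model = build_model(seed=2)
        tokens = np.random.default_rng(1).integers(1, 26, size=(4, 40))
        assert np.array_equal(model.predict_proba(tokens), model.predict_proba(tokens))

    def test_wrong_window_length_is_error(self):
        model = build_model()
        with pytest.raises(ValueError, match="length 40"):
            model.predict_proba(np.ones((2, 30), dtype=int))

    def test_invalid_config_is_error(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=0)
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)

    def test_save_load_round_trip(self, tmp_path):
        model = build_model(seed=3)
        model.save(tmp_path / "m.npz")
        from asmscan.model import BiLSTMClassifier

        back = BiLSTMClassifier.load(tmp_path / "m.npz", ModelConfig())
        tokens = np.random.default_rng(2).integers(1, 26, size=(4, 40))
        assert np.array_equal(model.predict_proba(tokens), back.predict_proba(tokens))


class TestCvSplit:
    def test_partition_properties(self):
        pos = [f"p{i}" for i in range(12)]
        neg = [f"n{i}" for i in range(12)]
        folds = cv_split(pos, neg, k=6, seed=0)
        assert len(folds) == 6
        all_val = []
        for train, val in folds:
            assert len(val) == 4  # 2 positives + 2 negatives
            assert set(train).isdisjoint(val)
            all_val.extend(val)
        assert sorted(all_val) == sorted(pos + neg)

    def test_near_equal_blocks_with_remainder(self):
        folds = cv_split([f"p{i}" for i in range(13)], [f"n{i}" for i in range(7)], k=3, seed=1)
        val_sizes = [len(v) for _, v in folds]
        assert sum(val_sizes) == 20
        assert max(val_sizes) - min(val_sizes) <= 2  # each class differs by <= 1

    def test_same_seed_identical_split(self):
        pos, neg = list("abcdefgh"), list("ABCDEFGH")
        assert cv_split(pos, neg, k=4, seed=9) == cv_split(pos, neg, k=4, seed=9)

    def test_too_few_items_is_error(self):
        with pytest.raises(ValueError):
            cv_split(["a"], ["b", "c"], k=2)


def _toy_problem(n=20, seed=5):
    """Positives carry a conserved 10-residue anchor; negatives are background."""
    rng = np.random.default_rng(seed)
    bg = swissprot_background()
    anchor = "QNGQYGNSQG"
    pos, neg = [], []
    for _ in range(n):
        flank = decode(bg.sample_tokens(30, rng))
        pos.append(flank[:15] + anchor + flank[15:])
        neg.append(decode(bg.sample_tokens(40, rng)))
    X = np.stack([encode(s) for s in pos + neg])
    y = np.array([1.0] * n + [0.0] * n)
    return X, y


class TestTrainFold:
    def test_separable_toy_problem_reaches_full_accuracy(self):
        X, y = _toy_problem()
        fm = train_fold(
            X, y, X, y,
            train_config=TrainConfig(epochs=30, batch_size=8, seed=1),
        )
        acc = np.mean((fm.predict_proba(X) >= 0.5) == y)
        assert acc == 1.0
        assert all(np.isfinite(v) for v in fm.history["train_loss"])
        assert all(np.isfinite(v) for v in fm.history["val_loss"])

    def test_loss_decreases_on_frozen_separable_problem(self):
        X, y = _toy_problem()
        fm = train_fold(
            X, y, X, y, train_config=TrainConfig(epochs=5, batch_size=8, seed=2)
        )
        losses = fm.history["train_loss"]
        assert losses[-1] < losses[0]

    def test_same_seed_identical_final_val_loss(self):
        X, y = _toy_problem()
        tc = TrainConfig(epochs=3, batch_size=8, seed=4)
        a = train_fold(X, y, X, y, train_config=tc)
        b = train_fold(X, y, X, y, train_config=tc)
        assert a.history["val_loss"][-1] == b.history["val_loss"][-1]
        assert all(
            np.array_equal(a.model.params[k], b.model.params[k])
            for k in a.model.params
        )

    def test_single_class_training_is_error(self):
        X, _ = _toy_problem(n=4)
        with pytest.raises(ValueError, match="both classes"):
            train_fold(X, np.ones(len(X)), X, np.ones(len(X)))

    def test_runs_exactly_configured_epochs(self):
        X, y = _toy_problem(n=4)
        fm = train_fold(X, y, X, y, train_config=TrainConfig(epochs=7, seed=0))
        assert len(fm.history["train_loss"]) == 7

    def test_negative_subsampling_reduces_training_set(self):
        X, y = _toy_problem(n=10)
        fm = train_fold(
            X, y, X, y,
            train_config=TrainConfig(epochs=2, seed=0, neg_per_pos=0.5),
        )
        assert np.isfinite(fm.history["train_loss"][-1])
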