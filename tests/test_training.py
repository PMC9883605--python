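import numpy as np
import pytest

from squigclass.classifier import ModelConfig, build_classifier
from squigclass.nn import Adam, Parameter
from squigclass.training import (
    EarlyStopping,
    ReduceLROnPlateau,
    SegmentData,
    TrainConfig,
    make_folds,
    select_best_model,
    split_train_val,
    train_fold,
)


def toy_data(n_reads_per_class=10, segments_per_read=2, length=64, seed=0):
    """Separable toy segments: class decided by the sign of the mean."""
    rng = np.random.default_rng(seed)
    X, y, rid = [], [], []
    for c in (0, 1):
        for r in range(n_reads_per_class):
            for _ in range(segments_per_read):
                mu = 0.5 if c == 1 else -0.5
                X.append(rng.normal(mu, 1.0, length).astype(np.float32))
                y.append(c)
                rid.append(f"c{c}_r{r}")
    return SegmentData(np.stack(X), np.array(y), np.array(rid))


TINY_MODEL = ModelConfig(input_length=64, initial_channels=6, n_stages=1,
                         blocks_per_stage=1, first_kernel=5, first_stride=2)


def test_split_is_stratified_read_level_and_deterministic():
    data = toy_data(10, 2)
    tr, val = split_train_val(data, 0.7, seed=1)
    # 7 + 3 reads per class; all segments of a read stay together
    tr_ids, tr_labels = tr.unique_reads()
    val_ids, val_labels = val.unique_reads()
    assert sorted(np.bincount(tr_labels)) == [7, 7]
    assert sorted(np.bincount(val_labels)) == [3, 3]
    assert set(tr_ids) & set(val_ids) == set()
    tr2, val2 = split_train_val(data, 0.7, seed=1)
    assert np.array_equal(tr.read_ids, tr2.read_ids)


def test_split_requires_both_classes():
    data = toy_data(6, 1)
    single = data.subset_by_reads({r for r in data.read_ids if r.startswith("c1")})
    with pytest.raises(ValueError):
        split_train_val(single, 0.7, 0)


def test_folds_partition_exhaustively_and_are_balanced():
    data = toy_data(50, 2)  # 100 reads
    folds = make_folds(data, 5, seed=3)
    assert len(folds) == 5
    val_sets = [set(val.read_ids) for _, val in folds]
    for i in range(5):
        assert len(val_sets[i]) == 20
        for j in range(i + 1, 5):
            assert val_sets[i] & val_sets[j] == set()
    assert set.union(*val_sets) == set(data.read_ids)
    for train, val in folds:
        assert set(train.read_ids) & set(val.read_ids) == set()
        _, val_labels = val.unique_reads()
        assert abs(np.mean(val_labels) - 0.5) <= 0.05


def test_each_read_validates_exactly_once():
    data = toy_data(2, 1)  # 4 reads, 2 folds
    folds = make_folds(data, 2, seed=0)
    seen = [rid for _, val in folds for rid in set(val.read_ids)]
    assert sorted(seen) == sorted(set(data.read_ids))


def test_folds_error_when_too_few_reads():
    data = toy_data(3, 1)
    with pytest.raises(ValueError):
        make_folds(data, 5, seed=0)


def test_lr_halves_after_exactly_the_plateau_patience():
    opt = Adam([Parameter(np.zeros(1))], lr=1.0)
    sched = ReduceLROnPlateau(opt, factor=0.5, patience=3)
    sched.step(0.8)  # baseline improvement
    sched.step(0.8)
    sched.step(0.8)
    assert opt.lr == 1.0  # only 2 plateau epochs so far
    sched.step(0.8)  # 3rd plateau epoch -> halve
    assert opt.lr == 0.5
    sched.step(0.9)  # improvement resets the counter
    sched.step(0.9)
    sched.step(0.9)
    assert opt.lr == 0.5
    sched.step(0.9)
    assert opt.lr == 0.25


def test_early_stopping_fires_after_patience():
    stop = EarlyStopping(patience=30)
    assert stop.step(0.7) is False  # epoch 1: baseline
    fired_at = None
    for epoch in range(2, 40):
        if stop.step(0.7):
            fired_at = epoch
            break
    assert fired_at == 31  # flat from epoch 1 -> stops by 1 + 30


def test_improvement_below_min_delta_does_not_reset():
    stop = EarlyStopping(patience=2)
    stop.step(0.5)
    assert stop.step(0.50005) is False  # within min delta: counts as plateau
    assert stop.step(0.50007) is True


def test_select_best_model_argmax_and_tie_break():
    from squigclass.training import FoldResult

    def fr(i, acc):
        return FoldResult(fold_index=i, model=None, best_val_acc=acc)

    results = [fr(i, a) for i, a in enumerate([0.91, 0.95, 0.93, 0.94, 0.92])]
    assert select_best_model(results).fold_index == 1
    assert select_best_model([fr(0, 0.9)]).fold_index == 0
    assert select_best_model([fr(0, 0.9), fr(1, 0.9)]).fold_index == 0
    with pytest.raises(ValueError):
        select_best_model([])


def test_train_fold_is_deterministic_and_lr_monotone():
    data = toy_data(10, 2, seed=5)
    tr, val = split_train_val(data, 0.7, seed=0)
    cfg = TrainConfig(n_folds=2, batch_reads=4, max_epochs=4,
                      lr_patience_epochs=2, early_stop_patience_epochs=3,
                      initial_lr=3e-3, rng_seed=9)
    histories = []
    for _ in range(2):
        model = build_classifier(TINY_MODEL, seed=1)
        res = train_fold(model, tr, val, cfg, segments_per_read=2)
        histories.append(res.history)
    assert histories[0] == histories[1]
    lrs = histories[0]["lr"]
    assert all(b <= a for a, b in zip(lrs, lrs[1:]))
    assert len(histories[0]["epoch"]) <= cfg.max_epochs


def test_train_fold_early_stops_on_flat_metric():
    """With lr=0 the model never changes, so validation accuracy is flat
    and training must stop after 1 + patience epochs."""
    data = toy_data(8, 2, seed=6)
    tr, val = split_train_val(data, 0.7, seed=0)
    cfg = TrainConfig(batch_reads=4, max_epochs=50, lr_patience_epochs=20,
                      early_stop_patience_epochs=5, initial_lr=0.0, rng_seed=3)
    model = build_classifier(TINY_MODEL, seed=2)
    for _ in range(60):  # settle BN running statistics so the metric is flat
        model.forward_logits(tr.X, training=True)
    res = train_fold(model, tr, val, cfg, segments_per_read=2)
    assert len(res.history["epoch"]) == 1 + 5


def test_no_read_crosses_split_boundaries():
    data = toy_data(20, 3, seed=7)
    tr, val = split_train_val(data, 0.7, seed=2)
    assert set(tr.read_ids).isdisjoint(set(val.read_ids))
    for train, valf in make_folds(data, 4, seed=2):
        assert set(train.read_ids).isdisjoint(set(valf.read_ids))
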