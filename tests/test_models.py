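"""Decision-tree training, prediction, evaluation, serialization."""

import numpy as np
import pytest

from bpsdmon.datagen import Dataset, Sample, generate_dataset, variant_table
from bpsdmon.models import (
    TreeParams,
    JSONTreeModel,
    evaluate,
    predict,
    train_eval_variant,
    train_tree,
)


def _tiny_dataset(X, y, names=("f0", "f1", "f2"), kind="bephyen_nohrv"):
    samples = [
        Sample(values=dict(zip(names, row)), label=int(lab), bpsd_type=0, severity="high")
        for row, lab in zip(X, y)
    ]
    ds = Dataset(samples=samples, model_kind=kind)
    # bypass the variant feature list for synthetic minimal datasets
    ds.__class__ = _TinyDataset
    ds._names = tuple(names)
    return ds


class _TinyDataset(Dataset):
    @property
    def feature_names(self):
        return self._names


# ---------------------------------------------------------------------------
# exhaustive small-instance oracle
# ---------------------------------------------------------------------------


def best_tree_correct(X, y, splits):
    """Maximum training-set hits achievable by any axis-aligned threshold
    tree with at most ``splits`` internal nodes (exhaustive recursion with
    split-budget allocation; independent of the library trainer)."""
    X = np.asarray(X)
    y = np.asarray(y)

    def rec(idx, budget):
        labels = y[idx]
        majority = int(np.bincount(labels).max()) if len(idx) else 0
        if budget == 0 or len(set(map(tuple, X[idx]))) <= 1:
            return majority
        best = majority
        for f in range(X.shape[1]):
            values = sorted(set(X[idx, f]))
            for lo, hi in zip(values, values[1:]):
                thr = (lo + hi) / 2
                left = idx[X[idx, f] <= thr]
                right = idx[X[idx, f] > thr]
                for bl in range(budget):
                    br = budget - 1 - bl
                    best = max(best, rec(left, bl) + rec(right, br))
        return best

    return rec(np.arange(len(y)), splits)


def test_trained_tree_matches_exhaustive_oracle_on_small_instances():
    """With a split budget that admits a full tree over 3 binary features,
    greedy Gini training reaches the best achievable training accuracy."""
    rng = np.random.default_rng(0)
    for trial in range(8):
        n = int(rng.integers(6, 13))
        X = rng.integers(0, 2, size=(n, 3))
        y = rng.integers(0, 3, size=n)
        ds = _tiny_dataset(X, y)
        model = train_tree(ds, TreeParams(max_splits=7), seed=trial)
        got = int(
            (model.predict_dataset(ds) == np.array([s.label for s in ds.samples])).sum()
        )
        want = best_tree_correct(X, y, 7)
        assert got == want, f"trial {trial}: greedy {got} vs oracle {want}"


# ---------------------------------------------------------------------------
# training behavior and structure
# ---------------------------------------------------------------------------


def test_split_cap_limits_internal_nodes(bephyen_table):
    ds = generate_dataset(bephyen_table, seed=0)
    model = train_tree(ds, TreeParams(max_splits=20), seed=0)
    assert model.n_internal_nodes <= 20
    small = train_tree(ds, TreeParams(max_splits=3), seed=0)
    assert small.n_internal_nodes <= 3


def test_single_class_dataset_gives_single_leaf(bephyen_table):
    comp = {(0, "high"): 10}
    ds = generate_dataset(bephyen_table, comp, seed=0)
    model = train_tree(ds, seed=0)
    assert model.n_internal_nodes == 0
    assert predict(model, ds.samples[0].values) == 0


def test_empty_dataset_rejected(bephyen_table):
    with pytest.raises(ValueError):
        train_tree(Dataset(samples=[], model_kind="bephyen"))


@pytest.mark.parametrize(
    "kind,root", [("psyco", "mmse"), ("bephyen", "hrv"), ("bephyen_nohrv", "walking_speed")]
)
def test_majority_root_feature(kind, root):
    """The most informative factor heads the tree: MMSE for the
    psycho-cognitive model, HRV for the sensor model, walking speed once
    HRV is removed (majority over 5 seeds)."""
    roots = []
    for seed in range(5):
        table = variant_table(kind)
        ds = generate_dataset(table, seed=1000 + seed)
        roots.append(train_tree(ds, seed=seed).root_feature)
    assert sum(r == root for r in roots) >= 3, roots


def test_psyco_root_threshold_is_mmse_cut():
    """The learned MMSE root cut falls at the 26/27 boundary separating
    no-BPSD scores from symptomatic ones."""
    thresholds = []
    for seed in range(5):
        ds = generate_dataset(variant_table("psyco"), seed=2000 + seed)
        model = train_tree(ds, seed=seed)
        if model.root_feature == "mmse":
            thresholds.append(model.root_threshold)
    assert thresholds, "MMSE never at the root"
    assert sum(22.0 < t < 28.0 for t in thresholds) >= len(thresholds) // 2 + 1


def test_high_mmse_predicts_no_bpsd():
    ds = generate_dataset(variant_table("psyco"), seed=5)
    model = train_tree(ds, seed=5)
    healthy = {f: 0 for f in ds.feature_names}
    healthy["mmse"] = 30
    healthy["anxiety"] = 1
    assert predict(model, healthy) == 3


def test_predict_totality_and_missing_feature(bephyen_table):
    ds = generate_dataset(bephyen_table, seed=3)
    model = train_tree(ds, seed=3)
    for s in ds.samples[:20]:
        assert predict(model, s.values) in (0, 1, 2, 3)
    with pytest.raises(KeyError, match="hrv"):
        predict(model, {k: v for k, v in ds.samples[0].values.items() if k != "hrv"})


def test_leaf_ties_break_to_smallest_label():
    # two identical feature vectors with different labels force a tied leaf
    X = [[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 1, 1]]
    y = [2, 1, 3, 3]
    ds = _tiny_dataset(X, y)
    model = train_tree(ds, TreeParams(max_splits=5), seed=0)
    assert model.predict_one({"f0": 0, "f1": 0, "f2": 0}) == 1


def test_json_round_trip_preserves_predictions(tmp_path, bephyen_table):
    train = generate_dataset(bephyen_table, seed=11)
    test = generate_dataset(bephyen_table, seed=12)
    model = train_tree(train, seed=11)
    path = tmp_path / "tree.json"
    model.save_json(path)
    back = JSONTreeModel.load_json(path)
    for s in test.samples:
        assert back.predict_one(s.values) == model.predict_one(s.values)
    assert "label" in model.render_text()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def test_eval_report_consistency(bephyen_table):
    train = generate_dataset(bephyen_table, seed=21)
    test = generate_dataset(bephyen_table, seed=22)
    model = train_tree(train, seed=21)
    rep = evaluate(model, test)
    assert rep.confusion.sum() == 120
    assert rep.confusion.sum(axis=1).tolist() == [30, 30, 30, 30]
    assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / 120)
    assert 0.0 <= rep.macro_auc <= 1.0


def test_resubstitution_not_worse_than_held_out():
    gaps = []
    for seed in range(5):
        table = variant_table("bephyen")
        train = generate_dataset(table, seed=3000 + 2 * seed)
        test = generate_dataset(table, seed=3001 + 2 * seed)
        model = train_tree(train, seed=seed)
        gaps.append(evaluate(model, train).accuracy - evaluate(model, test).accuracy)
    assert np.mean(gaps) >= 0


def test_all_variants_clear_chance_floor():
    for kind in ("psyco", "psyco_hrv", "bephyen", "bephyen_nohrv"):
        _, rep = train_eval_variant(kind, seed=0)
        assert rep.accuracy > 0.55  # 4 balanced classes: chance is 0.25


def test_variant_accuracy_ranking():
    """Mean held-out accuracy orders the variants: adding HRV helps, and
    the sensor-side model beats the caregiver-side one (each pairwise
    comparison allowed 2 pp of seed noise)."""
    means = {}
    for kind in ("psyco", "psyco_hrv", "bephyen", "bephyen_nohrv"):
        accs = [train_eval_variant(kind, seed)[1].accuracy for seed in range(10)]
        means[kind] = float(np.mean(accs))
    tol = 0.02
    assert means["psyco_hrv"] >= means["bephyen"] - tol
    assert means["bephyen"] >= means["bephyen_nohrv"] - tol
    assert means["bephyen_nohrv"] >= means["psyco"] - tol
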