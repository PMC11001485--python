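"""Scaffold splitting, AUC evaluation, fine-tuning and retrieval."""

import numpy as np
import pytest

from molemcl import (
    EncoderConfig,
    FeatureVocab,
    LabeledDataset,
    evaluate_auc,
    finetune,
    generate_fixture_molecules,
    make_synthetic_labels,
    retrieve_similar,
    scaffold_of,
    scaffold_split,
    smiles_to_graph,
    tanimoto,
)
from molemcl.downstream import morgan_fingerprint
from molemcl.encoder import cosine_similarity, encode, init_params


def dataset_from(smiles, vocab, labels=None):
    graphs = [smiles_to_graph(s, vocab) for s in smiles]
    if labels is None:
        labels = np.zeros((len(graphs), 1))
        labels[::2] = 1.0
    return LabeledDataset(graphs, labels, ["y"])


SMALL_CFG = EncoderConfig(num_layers=2, hidden_dim=24, projection_hidden_dim=24, projection_out_dim=24)


class TestScaffoldSplit:
    def test_ten_distinct_scaffolds_split_8_1_1(self, vocab):
        smiles = [
            "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
            "C1CCCCC1", "C1CCNCC1", "C1CCOC1", "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1",
        ]
        ds = dataset_from(smiles, vocab)
        split = scaffold_split(ds)
        assert (split.train.size, split.valid.size, split.test.size) == (8, 1, 1)

    def test_hand_walked_group_sizes_9_1_1(self, vocab):
        # scaffold groups of sizes 6, 2, 1, 1, 1 (n = 11)
        smiles = (
            ["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "CCCc1ccccc1", "Oc1ccccc1", "Nc1ccccc1"]
            + ["c1ccncc1", "Cc1ccncc1"]
            + ["c1ccoc1", "C1CCCCC1", "C1CCNCC1"]
        )
        ds = dataset_from(smiles, vocab)
        split = scaffold_split(ds)
        assert (split.train.size, split.valid.size, split.test.size) == (9, 1, 1)
        # the largest groups land in train
        train_scaffolds = {scaffold_of(ds.graphs[i].smiles) for i in split.train}
        assert scaffold_of("c1ccccc1") in train_scaffolds
        assert scaffold_of("c1ccncc1") in train_scaffolds

    def test_single_shared_scaffold_overflows_into_train(self, vocab, caplog):
        smiles = ["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1"]
        ds = dataset_from(smiles, vocab)
        split = scaffold_split(ds)
        assert split.train.size == 4 and split.valid.size == 0 and split.test.size == 0

    def test_scaffold_disjointness_on_fixtures(self, vocab):
        smiles = generate_fixture_molecules(128, seed=2)
        ds = dataset_from(smiles, vocab)
        split = scaffold_split(ds)
        parts = [
            {scaffold_of(ds.graphs[i].smiles) for i in part}
            for part in (split.train, split.valid, split.test)
        ]
        assert not parts[0] & parts[1] and not parts[0] & parts[2] and not parts[1] & parts[2]
        assert split.train.size + split.valid.size + split.test.size == len(ds)

    def test_deterministic(self, vocab):
        smiles = generate_fixture_molecules(64, seed=5)
        ds = dataset_from(smiles, vocab)
        a, b = scaffold_split(ds), scaffold_split(ds)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)


def brute_force_auc(labels, scores):
    """Concordant-pair counting with ties worth half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestEvaluateAUC:
    def test_printed_toy_case(self):
        per_task, mean = evaluate_auc(np.array([1, 0, 1, 0.0]), np.array([0.9, 0.8, 0.7, 0.1]))
        assert mean == pytest.approx(0.75)

    def test_perfect_separation(self):
        labels = np.array([1, 0, 1, 0.0])
        _, mean = evaluate_auc(labels, labels.copy())
        assert mean == 1.0

    def test_constant_scores_give_half(self):
        _, mean = evaluate_auc(np.array([1, 0, 1, 0.0]), np.full(4, 0.3))
        assert mean == pytest.approx(0.5)

    def test_matches_concordant_pair_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n).astype(float)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            _, mean = evaluate_auc(labels, scores)
            assert mean == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)

    def test_degenerate_task_excluded_from_mean(self):
        labels = np.array([[1, 1], [0, 1], [1, np.nan], [0, 1.0]])
        scores = np.array([[0.9, 0.1], [0.2, 0.4], [0.8, 0.5], [0.1, 0.2]])
        per_task, mean = evaluate_auc(labels, scores)
        assert np.isnan(per_task[1]) and mean == per_task[0] == 1.0

    def test_all_degenerate_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate_auc(np.ones(4), np.random.rand(4))

    def test_missing_labels_ignored(self):
        labels = np.array([1, 0, np.nan, 1, 0.0])
        scores = np.array([0.9, 0.1, 0.99, 0.8, 0.2])
        _, mean = evaluate_auc(labels, scores)
        assert mean == 1.0


@pytest.fixture(scope="module")
def task(vocab):
    smiles = generate_fixture_molecules(96, seed=6)
    graphs = [smiles_to_graph(s, vocab) for s in smiles]
    ds = make_synthetic_labels(graphs, "a1aaaaa1", noise_rate=0.0, missing_rate=0.0, seed=0)
    return ds, scaffold_split(ds)


class TestFinetune:
    def test_identical_seed_gives_identical_result(self, task):
        ds, split = task
        a = finetune(None, ds, split, seeds=[3], epochs=3, encoder_config=SMALL_CFG)
        b = finetune(None, ds, split, seeds=[3], epochs=3, encoder_config=SMALL_CFG)
        assert a.per_seed_test_auc == b.per_seed_test_auc
        assert a.best_epochs == b.best_epochs

    def test_capacity_overfits_noise_free_train_partition(self, task):
        """On a clean substructure task the model separates its own train set."""
        ds, split = task
        res = finetune(
            None, ds, split, seeds=[0], epochs=40, encoder_config=SMALL_CFG, eval_train=True
        )
        assert res.per_seed_train_auc[0] == pytest.approx(1.0, abs=1e-9)

    def test_fully_missing_task_column_is_excluded(self, task):
        ds, split = task
        labels = np.column_stack([ds.labels[:, 0], np.full(len(ds), np.nan)])
        ds2 = LabeledDataset(ds.graphs, labels, ["y", "empty"])
        res = finetune(None, ds2, split, seeds=[0], epochs=2, encoder_config=SMALL_CFG)
        assert np.isnan(res.per_task_aucs[0][1])
        assert np.isfinite(res.mean_auc)

    def test_empty_partition_is_refused(self, task, vocab):
        ds, _ = task
        from molemcl.downstream import SplitIndices
        bad = SplitIndices(np.arange(len(ds)), np.array([], dtype=int), np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            finetune(None, ds, bad, seeds=[0], epochs=1, encoder_config=SMALL_CFG)


class TestTanimoto:
    def test_identical_nonempty(self):
        assert tanimoto({1, 5, 9}, {1, 5, 9}) == 1.0

    def test_disjoint(self):
        assert tanimoto({1, 2}, {3, 4}) == 0.0

    def test_arithmetic(self):
        assert tanimoto({1, 2, 3, 4}, {3, 4, 5}) == pytest.approx(0.4)

    def test_both_empty_convention(self):
        assert tanimoto(set(), set()) == 1.0

    def test_bit_array_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            tanimoto(np.zeros(8), np.zeros(16))

    def test_bit_arrays_agree_with_sets(self):
        a = np.array([1, 0, 1, 1, 0])
        b = np.array([1, 1, 0, 1, 0])
        assert tanimoto(a, b) == tanimoto({0, 2, 3}, {0, 1, 3})


@pytest.fixture(scope="module")
def setup(vocab):
    smiles = generate_fixture_molecules(10, seed=9)
    graphs = [smiles_to_graph(s, vocab) for s in smiles]
    params = init_params(SMALL_CFG, vocab, seed=1)
    return graphs, params


class TestRetrieval:
    def test_self_query_ranks_first_with_cosine_one(self, setup):
        graphs, params = setup
        hits = retrieve_similar(graphs[4], graphs, params, k=3)
        idx, cos, tan = hits[0]
        assert idx == 4 and cos == pytest.approx(1.0, abs=1e-12) and tan == 1.0

    def test_full_ranking_matches_exhaustive_pairwise_oracle(self, setup):
        graphs, params = setup
        hits = retrieve_similar(graphs[0], graphs, params, k=len(graphs))
        emb = encode(graphs, params).graph_embeddings
        oracle = sorted(
            range(len(graphs)),
            key=lambda i: (-cosine_similarity(emb[0], emb[i]), i),
        )
        assert [h[0] for h in hits] == oracle
        scores = [h[1] for h in hits]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_invariant_to_corpus_ordering(self, setup):
        graphs, params = setup
        perm = [3, 1, 4, 0, 2, 9, 7, 5, 8, 6]
        hits_a = retrieve_similar(graphs[0], graphs, params, k=4)
        hits_b = retrieve_similar(graphs[0], [graphs[i] for i in perm], params, k=4)
        smiles_a = [graphs[i].smiles for i, _, _ in hits_a]
        smiles_b = [[graphs[i] for i in perm][j].smiles for j, _, _ in hits_b]
        assert smiles_a == smiles_b

    def test_k_exceeding_corpus_is_an_error(self, setup):
        graphs, params = setup
        with pytest.raises(ValueError):
            retrieve_similar(graphs[0], graphs, params, k=11)

    def test_tanimoto_annotations_match_rdkit(self, setup):
        from rdkit import DataStructs

        graphs, params = setup
        hits = retrieve_similar(graphs[2], graphs, params, k=5)
        fp_q = morgan_fingerprint(graphs[2].smiles)
        for idx, _, tan in hits:
            expected = DataStructs.TanimotoSimilarity(fp_q, morgan_fingerprint(graphs[idx].smiles))
            assert tan == pytest.approx(expected, abs=1e-12)
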