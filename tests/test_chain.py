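"""The iterated-learning engine: bottleneck sampling, the shuffling channel,
generation transitions, and whole-chain reproducibility."""

import numpy as np
import pytest

from quantevo import (
    AgentConfig,
    ChainConfig,
    extract_quantifier,
    init_agent,
    next_generation,
    run_chain,
    sample_bottleneck,
    shuffle_channel,
    snapshots_to_jsonl,
)
from quantevo.chain import shuffle_structures


@pytest.fixture
def parent():
    return init_agent(AgentConfig(input_size=5), 17)


class TestSampleBottleneck:
    def test_size_and_label_consistency(self, parent):
        rng = np.random.default_rng(0)
        X, y = sample_bottleneck(parent, 200, rng)
        assert X.shape == (200, 5) and y.shape == (200,)
        table = extract_quantifier(parent).table
        idx = X @ (2 ** np.arange(4, -1, -1))
        assert np.array_equal(y.astype(bool), table[idx])

    def test_same_seed_same_sample(self, parent):
        X1, y1 = sample_bottleneck(parent, 64, np.random.default_rng(5))
        X2, y2 = sample_bottleneck(parent, 64, np.random.default_rng(5))
        assert np.array_equal(X1, X2) and np.array_equal(y1, y2)

    def test_label_frequency_tracks_table(self, parent):
        table = extract_quantifier(parent).table
        p = table.mean()
        _, y = sample_bottleneck(parent, 4000, np.random.default_rng(1))
        se = np.sqrt(p * (1 - p) / 4000)
        assert abs(y.mean() - p) < 3 * se + 1e-9

    def test_without_replacement_covers_space(self, parent):
        X, _ = sample_bottleneck(parent, 32, np.random.default_rng(2), with_replacement=False)
        idx = X @ (2 ** np.arange(4, -1, -1))
        assert len(set(idx.tolist())) == 32

    def test_zero_size_rejected(self, parent):
        with pytest.raises(ValueError):
            sample_bottleneck(parent, 0, np.random.default_rng(0))


class TestShuffleChannel:
    def test_count_conserved_label_unchanged(self):
        rng = np.random.default_rng(3)
        m = np.array([True, False, False])
        for _ in range(20):
            out, bit = shuffle_channel((m, 1), rng)
            assert out.sum() == 1 and bit == 1

    def test_all_true_unchanged(self):
        rng = np.random.default_rng(3)
        out, _ = shuffle_channel((np.ones(6, bool), 0), rng)
        assert out.all()

    def test_batch_shuffle_conserves_row_counts(self):
        rng = np.random.default_rng(4)
        X = np.random.default_rng(0).random((50, 8)) < 0.4
        out = shuffle_structures(X, rng)
        assert np.array_equal(out.sum(axis=1), X.sum(axis=1))

    def test_equal_counts_can_collide(self):
        # two structures with the same count but different labels can be
        # shuffled onto the same child-visible structure
        rng = np.random.default_rng(0)
        a = np.array([True, False])
        b = np.array([False, True])
        seen = set()
        for _ in range(20):
            out_a, _ = shuffle_channel((a, 1), rng)
            out_b, _ = shuffle_channel((b, 0), rng)
            seen.add((tuple(out_a), tuple(out_b)))
        assert any(x == y for x, y in seen)


class TestGenerationTransition:
    def test_population_and_parent_indices(self):
        cfg = ChainConfig(n=4, population=6, bottleneck=16, epochs=1, generations=2, master_seed=0)
        parents = [init_agent(cfg.agent_config(), s) for s in range(6)]
        children, parent_idx = next_generation(parents, cfg, np.random.SeedSequence(1))
        assert len(children) == 6
        assert parent_idx.shape == (6,)
        assert ((parent_idx >= 0) & (parent_idx < 6)).all()

    def test_wrong_population_rejected(self):
        cfg = ChainConfig(n=4, population=3, bottleneck=8, epochs=1, generations=2)
        parents = [init_agent(cfg.agent_config(), s) for s in range(2)]
        with pytest.raises(ValueError):
            next_generation(parents, cfg, np.random.SeedSequence(0))

    def test_empty_bottleneck_rejected_by_config(self):
        with pytest.raises(ValueError):
            ChainConfig(bottleneck=0)


class TestRunChain:
    def test_snapshot_count_and_fields(self):
        cfg = ChainConfig(n=4, population=3, bottleneck=16, epochs=1, generations=4, master_seed=2)
        snaps = run_chain(cfg)
        assert len(snaps) == 4
        assert all(len(s.records) == 3 for s in snaps)
        assert all(r.parent_index is None for r in snaps[0].records)
        for s in snaps[1:]:
            assert all(0 <= r.parent_index < 3 for r in s.records)
        r = snaps[-1].records[0]
        assert 0 <= r.monotonicity <= 1 and 0 <= r.quantity <= 1 and 0.5 <= r.degeneracy <= 1

    def test_same_master_seed_identical_runs(self):
        cfg = ChainConfig(n=5, population=3, bottleneck=32, epochs=2, generations=3, master_seed=33)
        s1, s2 = run_chain(cfg), run_chain(cfg)
        for a, b in zip(s1, s2):
            for ra, rb in zip(a.records, b.records):
                assert ra.quantifier == rb.quantifier
                assert ra.parent_index == rb.parent_index
                assert ra.monotonicity == rb.monotonicity

    def test_different_seeds_diverge(self):
        base = dict(n=5, population=3, bottleneck=32, epochs=2, generations=3)
        s1 = run_chain(ChainConfig(master_seed=1, **base))
        s2 = run_chain(ChainConfig(master_seed=2, **base))
        assert any(
            ra.quantifier != rb.quantifier
            for a, b in zip(s1, s2)
            for ra, rb in zip(a.records, b.records)
        )

    def test_confidences_stored_on_request(self):
        cfg = ChainConfig(n=4, population=2, bottleneck=8, epochs=1, generations=2, master_seed=0)
        snaps = run_chain(cfg, store_confidences=True)
        conf = snaps[0].records[0].confidences
        assert conf is not None and conf.shape == (16,)
        assert np.array_equal(conf >= 0.5, snaps[0].records[0].quantifier.table)


class TestJsonlRoundTrip:
    def test_round_trip(self, tmp_path):
        from quantevo.analysis import read_jsonl, snapshots_from_frame

        cfg = ChainConfig(n=4, population=3, bottleneck=16, epochs=1, generations=3, master_seed=5)
        snaps = run_chain(cfg)
        path = tmp_path / "run.jsonl"
        snapshots_to_jsonl(snaps, cfg, path, run_id="t")
        header, frame = read_jsonl(path)
        assert header["run_id"] == "t"
        assert header["config"]["n"] == 4
        assert len(frame) == 9
        rebuilt = snapshots_from_frame(frame)
        for orig, new in zip(snaps, rebuilt):
            for ra, rb in zip(orig.records, new.records):
                assert ra.quantifier == rb.quantifier
                assert ra.monotonicity == pytest.approx(rb.monotonicity)
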