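"""The iterated-learning engine.

A chain starts from a generation of randomly initialized agents.  Each later
generation is built by, for every one of ``population`` children: picking a
cultural parent uniformly at random (with replacement), sampling
``bottleneck`` structures uniformly at random, labelling them with the
parent's deterministic productions, optionally passing every example through
the shuffling channel (Experiment 2), and training a freshly initialized
child on the result for ``epochs`` epochs.  Children never inherit weights.

The shuffling channel applies a fresh uniform random permutation to the bits
of each training structure independently, conserving the number of True bits
but destroying object identity; it is what pressures the evolving meanings
toward permutation invariance (quantity).

All randomness descends from one master seed through
``numpy.random.SeedSequence`` spawning: one child sequence per generation,
and within a generation one per agent (covering its initialization, its
bottleneck sample, its channel noise, and its minibatch shuffling), plus one
for parent assignment.  Two runs with equal configs are identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .agents import Agent, AgentConfig, init_agent, train_agent, extract_quantifier
from .measures import score_table
from .quantifiers import Quantifier, all_structures

__all__ = [
    "ChainConfig",
    "AgentRecord",
    "GenerationSnapshot",
    "sample_bottleneck",
    "shuffle_channel",
    "shuffle_structures",
    "next_generation",
    "run_chain",
    "snapshots_to_jsonl",
]


@dataclass(frozen=True)
class ChainConfig:
    """All parameters of one iterated-learning run."""

    n: int = 10
    population: int = 10
    bottleneck: int = 1024
    epochs: int = 8
    generations: int = 301
    shuffle: bool = False
    master_seed: int = 0
    #: bottleneck structures drawn with replacement (the default) or without
    with_replacement: bool = True
    batch_size: int = 32
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("n", "population", "bottleneck", "epochs", "generations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not self.with_replacement and self.bottleneck > 2**self.n:
            raise ValueError("without replacement the bottleneck cannot exceed the structure space")

    def agent_config(self) -> AgentConfig:
        return AgentConfig(
            input_size=self.n,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
        )


@dataclass(frozen=True)
class AgentRecord:
    """One agent's language and its measures within a generation."""

    agent_index: int
    parent_index: int | None
    quantifier: Quantifier
    upward: float
    downward: float
    monotonicity: float
    quantity: float
    degeneracy: float
    confidences: np.ndarray | None = None


@dataclass(frozen=True)
class GenerationSnapshot:
    generation_index: int
    records: tuple[AgentRecord, ...]

    @property
    def quantifiers(self) -> list[Quantifier]:
        return [r.quantifier for r in self.records]


def _seed_from(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def sample_bottleneck(
    parent: Agent,
    size: int,
    rng: np.random.Generator,
    with_replacement: bool = True,
    parent_table: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """``size`` structures drawn uniformly from the structure space, labelled
    with the parent's deterministic productions.

    Returns ``(X, y)``: a (size, n) Boolean matrix and a length-``size`` bit
    vector.  ``parent_table`` may pass the parent's already-extracted truth
    table to avoid recomputation; labels are identical either way because
    production is deterministic.
    """
    if size < 1:
        raise ValueError(f"bottleneck size must be >= 1, got {size}")
    n = parent.config.input_size
    space = all_structures(n)
    if with_replacement:
        idx = rng.integers(0, 2**n, size=size)
    else:
        idx = rng.choice(2**n, size=size, replace=False)
    X = space[idx]
    if parent_table is not None:
        y = np.asarray(parent_table, dtype=bool)[idx]
    else:
        y = parent.produce_bits(X)
    return X, y.astype(np.int64)


def shuffle_structures(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply an independent fresh uniform permutation to the bits of every row."""
    return rng.permuted(np.asarray(X), axis=1)


def shuffle_channel(example: tuple[np.ndarray, int], rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Experiment-2 channel for a single (structure, bit) pair: the structure's
    bits are permuted uniformly at random, the label is unchanged."""
    structure, bit = example
    return shuffle_structures(np.asarray(structure, dtype=bool)[None, :], rng)[0], bit


def _measure_record(
    agent_index: int,
    parent_index: int | None,
    q: Quantifier,
    confidences: np.ndarray | None,
) -> AgentRecord:
    scores = score_table(q)
    return AgentRecord(
        agent_index=agent_index,
        parent_index=parent_index,
        quantifier=q,
        confidences=confidences,
        **scores,
    )


def next_generation(
    parents: Sequence[Agent],
    config: ChainConfig,
    gen_seed: np.random.SeedSequence,
    parent_tables: Sequence[np.ndarray] | None = None,
) -> tuple[list[Agent], np.ndarray]:
    """One transmission step: returns the child agents and their parent indices."""
    if len(parents) != config.population:
        raise ValueError(f"expected {config.population} parents, got {len(parents)}")
    assign_ss, *child_ss = gen_seed.spawn(1 + config.population)
    assign_rng = np.random.default_rng(assign_ss)
    parent_idx = assign_rng.integers(0, config.population, size=config.population)
    if parent_tables is None:
        parent_tables = [extract_quantifier(p).table for p in parents]
    children: list[Agent] = []
    for c, ss in enumerate(child_ss):
        init_ss, data_ss = ss.spawn(2)
        data_rng = np.random.default_rng(data_ss)
        pi = int(parent_idx[c])
        X, y = sample_bottleneck(
            parents[pi],
            config.bottleneck,
            data_rng,
            with_replacement=config.with_replacement,
            parent_table=parent_tables[pi],
        )
        if config.shuffle:
            X = shuffle_structures(X, data_rng)
        child = init_agent(config.agent_config(), _seed_from(init_ss))
        train_agent(child, (X.astype(np.float64), y.astype(np.float64)))
        children.append(child)
    return children, parent_idx


def run_chain(
    config: ChainConfig,
    store_confidences: bool = False,
    progress: bool = False,
) -> list[GenerationSnapshot]:
    """Run one full iterated-learning chain and return per-generation snapshots.

    Generation 0 is a population of randomly initialized agents; each later
    snapshot records, for every agent, its extracted quantifier, its
    monotonicity/quantity/degeneracy measures, and its parent's index.
    ``store_confidences`` additionally keeps each agent's raw confidence for
    every structure (needed for threshold profiles).
    """
    root = np.random.SeedSequence(config.master_seed)
    gen_seeds = root.spawn(config.generations)
    space = all_structures(config.n)

    iterator: Iterable[int] = range(config.generations)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="generations", total=config.generations)

    snapshots: list[GenerationSnapshot] = []
    agents: list[Agent] = []
    parent_idx: np.ndarray | None = None
    tables: list[np.ndarray] = []
    for g in iterator:
        if g == 0:
            init_seeds = gen_seeds[0].spawn(config.population)
            agents = [init_agent(config.agent_config(), _seed_from(s)) for s in init_seeds]
        else:
            agents, parent_idx = next_generation(agents, config, gen_seeds[g], parent_tables=tables)
        records = []
        tables = []
        for a_i, agent in enumerate(agents):
            conf = agent.respond_batch(space)
            table = conf >= 0.5
            tables.append(table)
            q = Quantifier(table)
            records.append(
                _measure_record(
                    a_i,
                    None if parent_idx is None else int(parent_idx[a_i]),
                    q,
                    conf if store_confidences else None,
                )
            )
        snapshots.append(GenerationSnapshot(generation_index=g, records=tuple(records)))
    return snapshots


def snapshots_to_jsonl(
    snapshots: Sequence[GenerationSnapshot],
    config: ChainConfig,
    path,
    run_id: str = "run",
) -> None:
    """Stream snapshots to JSON lines: a header carrying the full config, then
    one record per agent per generation tagged with the config hash."""
    import hashlib

    cfg = asdict(config)
    cfg_hash = hashlib.sha1(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(json.dumps({"run_id": run_id, "config": cfg, "config_hash": cfg_hash}) + "\n")
        for snap in snapshots:
            for rec in snap.records:
                row = {
                    "run_id": run_id,
                    "config_hash": cfg_hash,
                    "generation": snap.generation_index,
                    "agent": rec.agent_index,
                    "parent": rec.parent_index,
                    "quantifier": rec.quantifier.to_bitstring(),
                    "upward": rec.upward,
                    "downward": rec.downward,
                    "monotonicity": rec.monotonicity,
                    "quantity": rec.quantity,
                    "degeneracy": rec.degeneracy,
                }
                fh.write(json.dumps(row) + "\n")
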