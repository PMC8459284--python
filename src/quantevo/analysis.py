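"""Post-hoc analyses of evolved languages.

Covers the result surfaces of the simulations: random baselines for the
monotonicity distribution, classification of perfectly monotone quantifiers
into the recurring patterns (single-index "proper-noun" ultrafilters,
two-index conjunctions, degenerate, count thresholds), per-agent confidence
profiles over the count classes, and tidy per-generation summaries of whole
runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agents import Agent, AgentConfig, init_agent, extract_quantifier
from .chain import GenerationSnapshot
from .measures import score_table
from .quantifiers import (
    Quantifier,
    all_structures,
    structure_counts,
    named_quantifier,
    degeneracy,
    is_quantitative,
    is_monotone,
)

__all__ = [
    "PatternLabel",
    "random_baselines",
    "classify_pattern",
    "threshold_profile",
    "summarize_run",
    "read_jsonl",
]


def random_baselines(
    sample_size: int, n: int, rng: np.random.Generator
) -> tuple[list[Quantifier], list[Quantifier]]:
    """Two reference samples of quantifiers at structure size ``n``.

    The first contains tables with i.i.d. fair-coin entries (uniform over the
    whole quantifier space); the second the extracted quantifiers of freshly
    initialized, untrained agents.  Both distributions sit at low degrees of
    monotonicity, which is the baseline evolved runs are compared against.
    """
    if sample_size < 1:
        raise ValueError(f"sample_size must be >= 1, got {sample_size}")
    uniform = [Quantifier(rng.random(2**n) < 0.5) for _ in range(sample_size)]
    agents = []
    cfg = AgentConfig(input_size=n)
    for _ in range(sample_size):
        seed = int(rng.integers(0, 2**31 - 1))
        agents.append(extract_quantifier(init_agent(cfg, seed)))
    return uniform, agents


@dataclass(frozen=True)
class PatternLabel:
    """Classification of a quantifier into one of the recurring evolved patterns.

    ``input_flipped`` / ``output_flipped`` record the 0/1 switch (applied
    uniformly to the structures, the outputs, or both) under which the exact
    match was found; ``indices`` is the witnessing index set for the
    index-based patterns.
    """

    label: str  # degenerate | single_index | two_index_conjunction | threshold_like | other
    input_flipped: bool = False
    output_flipped: bool = False
    indices: tuple[int, ...] = ()


def _flip_input(table: np.ndarray) -> np.ndarray:
    # reindex by the bitwise-complement structure index
    return table[::-1].copy()


def _polarity_variants(q: Quantifier) -> list[tuple[bool, bool, np.ndarray]]:
    t = np.asarray(q.table)
    return [
        (False, False, t),
        (True, False, _flip_input(t)),
        (False, True, ~t),
        (True, True, ~_flip_input(t)),
    ]


def _is_threshold_table(q: Quantifier) -> bool:
    if not is_quantitative(q):
        return False
    counts = structure_counts(q.n)
    by_count = np.array([q.table[counts == k][0] for k in range(q.n + 1)], dtype=np.int8)
    d = np.diff(by_count)
    return bool(((d >= 0).all() or (d <= 0).all()) and by_count.min() != by_count.max())


def classify_pattern(q: Quantifier) -> PatternLabel:
    """Assign a quantifier to a pattern class by exact match.

    Tests in order: degenerate (constant table); single-index ultrafilter
    ``Q_i`` under any of the four 0/1 switches; two-index conjunction
    ``Q_{j,k}`` likewise; quantitative one-sided count threshold; otherwise
    ``other``.  Noisy near-misses deliberately fall through to ``other``.
    """
    if degeneracy(q) == 1.0:
        return PatternLabel("degenerate")
    n = q.n
    structs = all_structures(n)
    for in_f, out_f, table in _polarity_variants(q):
        for i in range(n):
            if np.array_equal(table, structs[:, i]):
                return PatternLabel("single_index", in_f, out_f, (i,))
    for in_f, out_f, table in _polarity_variants(q):
        for j in range(n):
            for k in range(j + 1, n):
                if np.array_equal(table, structs[:, j] & structs[:, k]):
                    return PatternLabel("two_index_conjunction", in_f, out_f, (j, k))
    if _is_threshold_table(q):
        return PatternLabel("threshold_like")
    return PatternLabel("other")


def threshold_profile(agent: Agent) -> pd.DataFrame:
    """Mean and dispersion of the agent's raw confidence per count class.

    One row for each ``k = |A ∩ B|`` in 0..n, aggregating the agent's
    unrounded outputs over all C(n, k) structures with that count; dispersion
    is the standard deviation.
    """
    n = agent.config.input_size
    conf = agent.respond_batch(all_structures(n))
    counts = structure_counts(n)
    rows = []
    for k in range(n + 1):
        c = conf[counts == k]
        rows.append(
            {"count": k, "mean_confidence": float(c.mean()), "sd_confidence": float(c.std()), "n_structures": int(c.size)}
        )
    return pd.DataFrame(rows)


_PATTERN_ORDER = ["single_index", "two_index_conjunction", "threshold_like", "other"]


def summarize_run(snapshots: Sequence[GenerationSnapshot]) -> dict[str, pd.DataFrame]:
    """Tidy summaries of one run.

    Returns three frames:

    - ``trajectory``: per-generation mean and 95% CI of monotonicity and
      quantity, plus the degenerate share;
    - ``pattern_shares``: per-generation shares of each pattern class among
      the *perfectly monotone, non-degenerate* quantifiers (monotonicity
      degree exactly 1; degenerate ones reported separately in
      ``trajectory``), rows summing to 1 where any such quantifier exists;
    - ``pattern_shares_pooled``: the same shares pooled over all generations.
    """
    if not snapshots:
        raise ValueError("summarize_run requires at least one snapshot")
    traj_rows, share_rows = [], []
    pooled = {k: 0 for k in _PATTERN_ORDER}
    for snap in snapshots:
        mono = np.array([r.monotonicity for r in snap.records])
        quan = np.array([r.quantity for r in snap.records])
        deg = np.array([r.degeneracy for r in snap.records])
        m = len(snap.records)
        half = 1.96 * mono.std(ddof=1) / np.sqrt(m) if m > 1 else 0.0
        halfq = 1.96 * quan.std(ddof=1) / np.sqrt(m) if m > 1 else 0.0
        traj_rows.append(
            {
                "generation": snap.generation_index,
                "mean_monotonicity": mono.mean(),
                "ci95_monotonicity": half,
                "mean_quantity": quan.mean(),
                "ci95_quantity": halfq,
                "degenerate_share": float((deg == 1.0).mean()),
            }
        )
        counts = {k: 0 for k in _PATTERN_ORDER}
        for rec in snap.records:
            if rec.monotonicity == 1.0 and rec.degeneracy < 1.0:
                label = classify_pattern(rec.quantifier).label
                counts[label] += 1
                pooled[label] += 1
        total = sum(counts.values())
        row = {"generation": snap.generation_index, "n_monotone_nondegenerate": total}
        for k in _PATTERN_ORDER:
            row[f"share_{k}"] = counts[k] / total if total else np.nan
        share_rows.append(row)
    pooled_total = sum(pooled.values())
    pooled_row = {"n_monotone_nondegenerate": pooled_total}
    for k in _PATTERN_ORDER:
        pooled_row[f"share_{k}"] = pooled[k] / pooled_total if pooled_total else np.nan
    return {
        "trajectory": pd.DataFrame(traj_rows),
        "pattern_shares": pd.DataFrame(share_rows),
        "pattern_shares_pooled": pd.DataFrame([pooled_row]),
    }


def read_jsonl(path) -> tuple[dict, pd.DataFrame]:
    """Read a chain run written by :func:`quantevo.chain.snapshots_to_jsonl`.

    Returns the header metadata (run id and full config) and a DataFrame with
    one row per agent per generation.
    """
    with open(path) as fh:
        header = json.loads(fh.readline())
        rows = [json.loads(line) for line in fh if line.strip()]
    return header, pd.DataFrame(rows)


def snapshots_from_frame(frame: pd.DataFrame) -> list[GenerationSnapshot]:
    """Rebuild snapshots (without raw confidences) from a run DataFrame."""
    from .chain import AgentRecord

    snaps = []
    for g, grp in frame.groupby("generation", sort=True):
        records = tuple(
            AgentRecord(
                agent_index=int(r.agent),
                parent_index=None if pd.isna(r.parent) else int(r.parent),
                quantifier=Quantifier.from_bitstring(r.quantifier),
                upward=float(r.upward),
                downward=float(r.downward),
                monotonicity=float(r.monotonicity),
                quantity=float(r.quantity),
                degeneracy=float(r.degeneracy),
            )
            for r in grp.itertuples()
        )
        snaps.append(GenerationSnapshot(generation_index=int(g), records=records))
    return snaps
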