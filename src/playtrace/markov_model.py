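"""Pooled first-order Markov chain over the 7 play symbols.

Play at any level, pooled across children and levels, is modeled as a
discrete, time-homogeneous, first-order chain on (S, 1, 2, 3, 4, 5, E).
Transition probabilities are raw maximum-likelihood proportions of observed
adjacent pairs (self-pairs included); no smoothing is applied, and rows that
were never left (zero observed outgoing pairs) are reported as undefined
rather than filled in as uniform.  E is absorbing: a level ends there, so its
outgoing row is identically zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .sequence_builder import SYMBOLS, LevelPlay

__all__ = [
    "STATES",
    "TransitionMatrix",
    "estimate_transition_matrix",
    "simulate_sequence",
    "filter_by_probability",
]

#: Canonical state order of the chain.
STATES = SYMBOLS
_INDEX = {s: i for i, s in enumerate(STATES)}
_N = len(STATES)


@dataclass(frozen=True)
class TransitionMatrix:
    """Transition counts and row-normalized probabilities of the pooled chain."""

    counts: np.ndarray
    n_sequences: int
    states: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (_N, _N):
            raise ValueError(f"counts must be {_N}x{_N}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts[_INDEX["E"], :].any():
            raise ValueError("E is absorbing: its outgoing row must be zero")
        if counts[:, _INDEX["S"]].any():
            raise ValueError("no transition may enter S")
        object.__setattr__(self, "counts", counts)

    @property
    def probs(self) -> np.ndarray:
        """Row-normalized probabilities; undefined (all-zero) rows stay zero."""
        rowsums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rowsums > 0, self.counts / np.maximum(rowsums, 1), 0.0)
        return p

    @property
    def undefined_rows(self) -> tuple[str, ...]:
        """States with no observed outgoing transition (probability row undefined)."""
        rowsums = self.counts.sum(axis=1)
        return tuple(s for s, r in zip(self.states, rowsums) if r == 0)

    def prob(self, src: str, dst: str) -> float:
        return float(self.probs[_INDEX[src], _INDEX[dst]])

    def count(self, src: str, dst: str) -> int:
        return int(self.counts[_INDEX[src], _INDEX[dst]])

    @property
    def n_pairs(self) -> int:
        """Total adjacent pairs pooled over the input sequences."""
        return int(self.counts.sum())

    def to_frame(self, kind: str = "probs") -> pd.DataFrame:
        data = self.probs if kind == "probs" else self.counts
        return pd.DataFrame(data, index=list(self.states), columns=list(self.states))

    @classmethod
    def from_probs(cls, probs: np.ndarray, scale: int = 10_000_000,
                   n_sequences: int = 0) -> "TransitionMatrix":
        """Build a matrix from given row distributions (for simulation configs).

        Probabilities are stored as integer counts at a large common scale, so
        ``probs`` reproduces the input rows to ~1e-7.
        """
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (_N, _N):
            raise ValueError(f"probs must be {_N}x{_N}, got {probs.shape}")
        if (probs < 0).any():
            raise ValueError("probabilities must be nonnegative")
        rowsums = probs.sum(axis=1)
        live = rowsums > 0
        if not np.allclose(rowsums[live], 1.0, atol=1e-9):
            raise ValueError("nonzero rows must sum to 1")
        counts = np.rint(probs * scale).astype(np.int64)
        return cls(counts=counts, n_sequences=n_sequences)


def _symbols_of(play: Union[str, LevelPlay]) -> str:
    return play.symbols if isinstance(play, LevelPlay) else play


def estimate_transition_matrix(plays: Sequence[Union[str, LevelPlay]]) -> TransitionMatrix:
    """Pool adjacent-pair counts over sequences into a :class:`TransitionMatrix`.

    Accepts :class:`LevelPlay` objects or raw symbol strings.  Self-pairs
    (e.g. 3->3) are counted; the total count equals the number of adjacent
    pairs summed over all sequences.
    """
    plays = list(plays)
    if not plays:
        raise ValueError("cannot estimate a transition matrix from zero sequences")
    counts = np.zeros((_N, _N), dtype=np.int64)
    for play in plays:
        seq = _symbols_of(play)
        idx = [_INDEX[s] for s in seq]
        for a, b in zip(idx, idx[1:]):
            counts[a, b] += 1
    return TransitionMatrix(counts=counts, n_sequences=len(plays))


def simulate_sequence(tm: TransitionMatrix, max_len: int = 250,
                      rng: Union[int, np.random.Generator, None] = None) -> str:
    """Draw one play sequence from the chain, starting at S.

    Each next symbol is drawn from the current state's probability row; the
    walk stops at E or after ``max_len`` symbols (truncation — the returned
    string then has no E, like a play cut off mid-level).  Hitting an
    undefined row before E also truncates.  Deterministic given the seed.
    """
    if max_len < 2:
        raise ValueError("max_len must be at least 2")
    probs = tm.probs
    s_row = probs[_INDEX["S"]]
    if not np.isclose(s_row.sum(), 1.0):
        raise ValueError("the S row of the matrix is undefined; cannot start a walk")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cum = np.cumsum(probs, axis=1)
    out = ["S"]
    state = _INDEX["S"]
    e_idx = _INDEX["E"]
    while len(out) < max_len:
        if cum[state, -1] <= 0.0:
            break  # undefined row: truncated walk
        u = gen.random() * cum[state, -1]
        state = int(np.searchsorted(cum[state], u, side="right"))
        state = min(state, _N - 1)
        out.append(STATES[state])
        if state == e_idx:
            break
    return "".join(out)


def filter_by_probability(tm: TransitionMatrix, threshold: float) -> list[tuple[str, str, float]]:
    """Edges with transition probability strictly above ``threshold``.

    Mirrors the simplified chain plots that keep only edges with p > 0.1.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    probs = tm.probs
    edges = []
    for i, src in enumerate(tm.states):
        for j, dst in enumerate(tm.states):
            p = float(probs[i, j])
            if p > threshold:
                edges.append((src, dst, p))
    return edges
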