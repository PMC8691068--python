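"""Path sampling and exact enumeration over probability trees.

A woman's year is one root-to-terminal path.  Monte Carlo runs sample the
path by independent categorical draws at each non-terminal state (branch
order = file order, so runs are bit-stable); :func:`enumerate_paths` lists
every complete path with its product-of-transitions probability and serves
as the exact oracle the sampler is tested against.

Outcome flags are declarative: a flag is a named set of state ids, and a
path carries the flag iff it visits any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import ProbabilityTree

DEFAULT_PATH_CAP = 1_000_000


class TreeCapacityError(RuntimeError):
    """Raised when enumeration would exceed the configured path-count cap."""


@dataclass
class WomanOutcome:
    """One sampled root-to-terminal path with its outcome flags and costs."""
    path: tuple[str, ...]
    age: int | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    cost_by_category: dict[str, float] = field(default_factory=dict)


class PathDistribution:
    """Complete root-to-terminal paths with exact probabilities.

    ``flag_matrix[flag]`` is a boolean vector over paths (path visits any
    state of the flag's defining set).
    """

    def __init__(self, paths: list[tuple[str, ...]], probs: np.ndarray,
                 flag_defs: Mapping[str, frozenset[str]] | None = None):
        self.paths = paths
        self.probs = np.asarray(probs, dtype=float)
        flag_defs = flag_defs or {}
        self.flag_defs = dict(flag_defs)
        self.flag_matrix = {
            flag: np.array([bool(set(p) & members) for p in paths])
            for flag, members in flag_defs.items()
        }

    def __len__(self) -> int:
        return len(self.paths)

    def total_mass(self) -> float:
        return float(self.probs.sum())

    def prob_of(self, path: tuple[str, ...]) -> float:
        try:
            return float(self.probs[self.paths.index(tuple(path))])
        except ValueError:
            return 0.0

    def to_frame(self) -> pd.DataFrame:
        """Exportable view: one row per path with probability and flags."""
        df = pd.DataFrame({
            "path": ["->".join(p) for p in self.paths],
            "probability": self.probs,
        })
        for flag, col in self.flag_matrix.items():
            df[flag] = col
        return df


def enumerate_paths(tree: ProbabilityTree,
                    flag_defs: Mapping[str, frozenset[str]] | None = None,
                    max_paths: int = DEFAULT_PATH_CAP) -> PathDistribution:
    """List every root-to-terminal path with its product probability.

    Raises :class:`TreeCapacityError` if more than ``max_paths`` complete
    paths would be produced.
    """
    problems = tree.violations()
    if problems:
        raise ValueError("invalid tree:\n  " + "\n  ".join(problems))
    paths: list[tuple[str, ...]] = []
    probs: list[float] = []
    stack: list[tuple[str, tuple[str, ...], float]] = [(tree.root, (tree.root,), 1.0)]
    while stack:
        node, path, p = stack.pop()
        kids = tree.children(node)
        if not kids:
            paths.append(path)
            probs.append(p)
            if len(paths) > max_paths:
                raise TreeCapacityError(
                    f"tree has more than {max_paths} root-to-terminal paths"
                )
            continue
        # reversed so file order comes out first (stack is LIFO)
        for t in reversed(kids):
            stack.append((t.to_state, path + (t.to_state,), p * t.prob))
    return PathDistribution(paths, np.array(probs), flag_defs)


def expected_flag_rate(dist: PathDistribution, flag: str) -> float:
    """Exact probability that a sampled path carries ``flag``."""
    if flag not in dist.flag_matrix:
        raise KeyError(f"flag {flag!r} not defined on this distribution")
    return float(dist.probs[dist.flag_matrix[flag]].sum())


def compute_flags(path: tuple[str, ...],
                  flag_defs: Mapping[str, frozenset[str]]) -> dict[str, bool]:
    visited = set(path)
    return {flag: bool(visited & members) for flag, members in flag_defs.items()}


def sample_path(tree: ProbabilityTree, rng: np.random.Generator,
                flag_defs: Mapping[str, frozenset[str]] | None = None,
                age: int | None = None,
                _validated: bool = False) -> WomanOutcome:
    """Sample one root-to-terminal path by a categorical draw at each state.

    Deterministic given the generator state.  ``_validated`` skips the
    structural check when the caller has already validated the tree (the
    per-woman simulation loop).
    """
    if not _validated:
        problems = tree.violations()
        if problems:
            raise ValueError("invalid tree:\n  " + "\n  ".join(problems))
    node = tree.root
    path = [node]
    while True:
        kids = tree.children(node)
        if not kids:
            break
        u = rng.random()
        acc = 0.0
        chosen = kids[-1]  # guard against fp round-off at u ~ 1
        for t in kids:
            acc += t.prob
            if u < acc:
                chosen = t
                break
        node = chosen.to_state
        path.append(node)
    flags = compute_flags(tuple(path), flag_defs or {})
    return WomanOutcome(path=tuple(path), age=age, flags=flags)
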