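"""Hyperparameter search: exhaustive grid, seeded random sampling, and an
adaptive strategy based on a tree-structured Parzen estimator.

The objective is any callable mapping a parameter dict to a scalar score
(typically cross-validated mean accuracy); higher is better.  All strategies
are deterministic under a fixed seed; the best trial is the argmax of the
score, ties broken by earliest trial index.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "Categorical",
    "IntRange",
    "FloatRange",
    "TrialRecord",
    "search",
]


@dataclass(frozen=True)
class Categorical:
    """Finite set of choices."""

    choices: tuple

    def __init__(self, choices: Sequence):
        if len(choices) == 0:
            raise ValidationError("Categorical domain must be non-empty")
        object.__setattr__(self, "choices", tuple(choices))

    def sample(self, rng: np.random.Generator):
        return self.choices[rng.integers(len(self.choices))]

    def contains(self, value) -> bool:
        return value in self.choices


@dataclass(frozen=True)
class IntRange:
    """Inclusive integer range, optionally sampled on a log scale."""

    low: int
    high: int
    log: bool = False

    def __post_init__(self):
        if self.low > self.high:
            raise ValidationError("IntRange requires low <= high")
        if self.log and self.low < 1:
            raise ValidationError("log-scale IntRange requires low >= 1")

    def sample(self, rng: np.random.Generator) -> int:
        if self.log:
            v = math.exp(rng.uniform(math.log(self.low), math.log(self.high + 1)))
            return int(min(self.high, math.floor(v)))
        return int(rng.integers(self.low, self.high + 1))

    def contains(self, value) -> bool:
        return isinstance(value, (int, np.integer)) and self.low <= value <= self.high


@dataclass(frozen=True)
class FloatRange:
    """Continuous range, optionally log-uniform."""

    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if self.low >= self.high:
            raise ValidationError("FloatRange requires low < high")
        if self.log and self.low <= 0:
            raise ValidationError("log-scale FloatRange requires low > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(math.exp(rng.uniform(math.log(self.low), math.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    def contains(self, value) -> bool:
        return isinstance(value, (float, int, np.floating, np.integer)) and \
            self.low <= value <= self.high


SearchSpace = Mapping[str, Categorical | IntRange | FloatRange]


@dataclass(frozen=True)
class TrialRecord:
    params: dict
    score: float
    strategy: str
    trial_index: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "params": self.params,
            "score": self.score,
            "strategy": self.strategy,
            "trial_index": self.trial_index,
            "seed": self.seed,
        }


def _run_trials(params_list, objective, strategy, seed) -> list[TrialRecord]:
    history = []
    for i, params in enumerate(params_list):
        history.append(
            TrialRecord(params=dict(params), score=float(objective(params)),
                        strategy=strategy, trial_index=i, seed=seed)
        )
    return history


def _best(history: list[TrialRecord]) -> TrialRecord:
    # ties broken by earliest trial: max is stable on first occurrence
    best = history[0]
    for rec in history[1:]:
        if rec.score > best.score:
            best = rec
    return best


def _grid(space: SearchSpace) -> list[dict]:
    for name, dom in space.items():
        if not isinstance(dom, Categorical):
            raise ValidationError(
                f"grid search requires finite Categorical domains; "
                f"parameter {name!r} is {type(dom).__name__}"
            )
    names = list(space)
    combos = itertools.product(*(space[n].choices for n in names))
    return [dict(zip(names, c)) for c in combos]


def _tpe_propose(
    space: SearchSpace,
    history: list[TrialRecord],
    rng: np.random.Generator,
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> dict:
    """Sample candidates from a Parzen density over good trials and keep the
    one maximising the good/bad density ratio, per parameter independently."""
    scores = np.array([t.score for t in history])
    n_good = max(1, int(math.ceil(gamma * len(history))))
    good_idx = np.argsort(-scores, kind="stable")[:n_good]
    good = [history[i] for i in good_idx]
    bad = [history[i] for i in range(len(history)) if i not in set(good_idx.tolist())]
    params = {}
    for name, dom in space.items():
        if isinstance(dom, Categorical):
            counts = np.ones(len(dom.choices))  # Laplace smoothing
            for t in good:
                counts[dom.choices.index(t.params[name])] += 1
            params[name] = dom.choices[rng.choice(len(dom.choices),
                                                  p=counts / counts.sum())]
            continue
        to_x = (lambda v: math.log(v)) if dom.log else (lambda v: float(v))
        lo, hi = to_x(dom.low), to_x(dom.high if not isinstance(dom, IntRange) else dom.high)
        gx = np.array([to_x(t.params[name]) for t in good])
        bx = np.array([to_x(t.params[name]) for t in bad]) if bad else gx
        bw = max((hi - lo) / 20.0, np.std(gx) * len(gx) ** -0.2, 1e-6)

        def density(x, centers):
            z = (x[:, None] - centers[None, :]) / bw
            return np.exp(-0.5 * z**2).mean(axis=1) + 1e-12

        cand = gx[rng.integers(len(gx), size=n_candidates)] + rng.normal(
            0.0, bw, size=n_candidates
        )
        cand = np.clip(cand, lo, hi)
        ratio = density(cand, gx) / density(cand, bx)
        x = float(cand[int(np.argmax(ratio))])
        v = math.exp(x) if dom.log else x
        if isinstance(dom, IntRange):
            v = int(min(dom.high, max(dom.low, round(v))))
        params[name] = v
    return params


def search(
    strategy: str,
    space: SearchSpace,
    objective: Callable[[dict], float],
    budget: int = 20,
    seed: int = 42,
    n_startup: int = 8,
) -> tuple[TrialRecord, list[TrialRecord]]:
    """Run one search strategy and return (best trial, full history).

    ``grid`` enumerates the full Cartesian product (budget ignored);
    ``random`` draws ``budget`` i.i.d. configurations; ``adaptive`` warms up
    with random draws then proposes via the Parzen-estimator ratio.
    """
    if not space:
        raise ValidationError("search space must be non-empty")
    if strategy == "grid":
        history = _run_trials(_grid(space), objective, "grid", seed)
        return _best(history), history
    if budget < 1:
        raise ValidationError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    if strategy == "random":
        params_list = [
            {name: dom.sample(rng) for name, dom in space.items()}
            for _ in range(budget)
        ]
        history = _run_trials(params_list, objective, "random", seed)
        return _best(history), history
    if strategy == "adaptive":
        history: list[TrialRecord] = []
        for i in range(budget):
            if i < n_startup or len(history) < 2:
                params = {name: dom.sample(rng) for name, dom in space.items()}
            else:
                params = _tpe_propose(space, history, rng)
            history.append(
                TrialRecord(params=dict(params), score=float(objective(params)),
                            strategy="adaptive", trial_index=i, seed=seed)
            )
        return _best(history), history
    raise ValidationError(f"unknown strategy {strategy!r}; expected grid/random/adaptive")


def history_to_json(history: list[TrialRecord]) -> str:
    return json.dumps([t.as_dict() for t in history], indent=2)
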