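"""Seeded generators for datasets with known discretization structure.

Emulates the shape of high-dimensional expression matrices: a minority of
informative variables whose value intervals carry class signal at a chosen
purity, plus class-independent noise variables.  Because the true cut
points and the informative/noise split are returned alongside the data,
every stage of the pipeline can be tested end to end without external
downloads.  All randomness flows from a single seed through spawned
per-variable streams, so individual columns are reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import SortedSample, build_sorted_sample

__all__ = [
    "InformativeVariable",
    "SyntheticSpec",
    "two_class_one_cut",
    "noise_only",
    "generate_dataset",
    "spec_from_dict",
    "toy_sample",
    "toy_frame",
]


@dataclass(frozen=True)
class InformativeVariable:
    """One predictor whose interval membership predicts the class.

    ``cuts`` split ``value_range`` into W intervals;
    ``class_interval_probs[j, i]`` is the probability that a class-j
    instance falls in interval i.  Values are drawn uniformly within the
    interval, shrunk by ``margin`` on each side that touches a cut, so the
    recoverable gap around each true cut is well defined.
    """

    cuts: tuple[float, ...]
    value_range: tuple[float, float]
    class_interval_probs: np.ndarray
    margin: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.value_range
        cuts = tuple(float(c) for c in self.cuts)
        probs = np.asarray(self.class_interval_probs, dtype=float)
        if not lo < hi:
            raise ValueError("value_range must be increasing")
        if any(c2 <= c1 for c1, c2 in zip(cuts, cuts[1:])):
            raise ValueError("cuts must be strictly increasing")
        if cuts and (cuts[0] <= lo or cuts[-1] >= hi):
            raise ValueError("cuts must lie strictly inside value_range")
        w = len(cuts) + 1
        if probs.ndim != 2 or probs.shape[1] != w:
            raise ValueError("class_interval_probs must be (n_classes, n_intervals)")
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0):
            raise ValueError("class_interval_probs rows must be distributions")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        edges = np.array([lo, *cuts, hi])
        lows = edges[:-1] + np.where(np.arange(w) > 0, self.margin, 0.0)
        highs = edges[1:] - np.where(np.arange(w) < w - 1, self.margin, 0.0)
        if np.any(lows >= highs):
            raise ValueError("margin leaves an empty sampling interval")
        object.__setattr__(self, "cuts", cuts)
        object.__setattr__(self, "class_interval_probs", probs)

    @property
    def n_intervals(self) -> int:
        return len(self.cuts) + 1

    def interval_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.value_range
        w = self.n_intervals
        edges = np.array([lo, *self.cuts, hi])
        lows = edges[:-1] + np.where(np.arange(w) > 0, self.margin, 0.0)
        highs = edges[1:] - np.where(np.arange(w) < w - 1, self.margin, 0.0)
        return lows, highs


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic dataset."""

    n: int
    class_probs: tuple[float, ...]
    informative: tuple[InformativeVariable, ...] = ()
    n_noise: int = 0
    noise_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.ndim != 1 or probs.size < 1:
            raise ValueError("class_probs must be a 1-d distribution")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("class_probs must sum to 1")
        if self.n < probs.size:
            raise ValueError("need at least one instance per class on average")
        if self.n_noise < 0:
            raise ValueError("n_noise must be non-negative")
        lo, hi = self.noise_range
        if not lo < hi:
            raise ValueError("noise_range must be increasing")
        for var in self.informative:
            if var.class_interval_probs.shape[0] != probs.size:
                raise ValueError(
                    "informative variable class count disagrees with class_probs"
                )
        object.__setattr__(self, "class_probs", tuple(float(p) for p in probs))
        object.__setattr__(self, "informative", tuple(self.informative))

    @property
    def n_classes(self) -> int:
        return len(self.class_probs)


def two_class_one_cut(
    n: int = 200,
    purity: float = 0.95,
    cut: float = 0.5,
    value_range: tuple[float, float] = (0.0, 1.0),
    margin: float = 0.05,
    class_probs: tuple[float, float] = (0.5, 0.5),
    n_noise: int = 0,
) -> SyntheticSpec:
    """Two classes separated (at the given purity) by a single cut point."""
    probs = np.array([[purity, 1 - purity], [1 - purity, purity]])
    var = InformativeVariable(
        cuts=(cut,),
        value_range=value_range,
        class_interval_probs=probs,
        margin=margin,
    )
    return SyntheticSpec(n=n, class_probs=class_probs, informative=(var,), n_noise=n_noise)


def noise_only(n: int = 100, n_noise: int = 50, n_classes: int = 2) -> SyntheticSpec:
    """Only class-independent variables: nothing should be selected."""
    probs = tuple([1.0 / n_classes] * n_classes)
    return SyntheticSpec(n=n, class_probs=probs, n_noise=n_noise)


def generate_dataset(
    spec: SyntheticSpec, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Draw a dataset and return it with its ground-truth record.

    For informative variables the class label is drawn first, then an
    interval according to that class's interval distribution, then a value
    uniformly within the (margin-shrunk) interval — so interval membership
    predicts the class at the specified purity.  Noise variables are drawn
    independently of the class.
    """
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(1 + len(spec.informative) + spec.n_noise)
    rng_labels = np.random.default_rng(streams[0])
    labels = rng_labels.choice(spec.n_classes, size=spec.n, p=spec.class_probs)

    frame = pd.DataFrame(index=range(spec.n))
    truth: dict = {
        "seed": int(seed),
        "informative": [],
        "cuts": {},
        "class_probs": list(spec.class_probs),
    }
    for v, var in enumerate(spec.informative):
        rng = np.random.default_rng(streams[1 + v])
        lows, highs = var.interval_bounds()
        intervals = np.empty(spec.n, dtype=np.int64)
        for j in range(spec.n_classes):
            mask = labels == j
            intervals[mask] = rng.choice(
                var.n_intervals, size=int(mask.sum()), p=var.class_interval_probs[j]
            )
        values = rng.uniform(lows[intervals], highs[intervals])
        name = f"inf{v + 1}"
        frame[name] = values
        truth["informative"].append(name)
        truth["cuts"][name] = list(var.cuts)
    for v in range(spec.n_noise):
        rng = np.random.default_rng(streams[1 + len(spec.informative) + v])
        frame[f"noise{v + 1}"] = rng.uniform(*spec.noise_range, size=spec.n)
    frame["target"] = labels
    return frame, truth


def spec_from_dict(d: Mapping) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a plain (YAML-friendly) mapping."""
    informative = tuple(
        InformativeVariable(
            cuts=tuple(v["cuts"]),
            value_range=tuple(v.get("range", (0.0, 1.0))),
            class_interval_probs=np.asarray(v["class_interval_probs"], dtype=float),
            margin=float(v.get("margin", 0.0)),
        )
        for v in d.get("informative", [])
    )
    return SyntheticSpec(
        n=int(d["n"]),
        class_probs=tuple(d["class_probs"]),
        informative=informative,
        n_noise=int(d.get("n_noise", 0)),
        noise_range=tuple(d.get("noise_range", (0.0, 1.0))),
    )


#: the six-instance worked example used throughout the docs and tests:
#: three low expression values of class 0, three high of class 1, with a
#: single clean class boundary whose midpoint cut is 2.65.
_TOY_PAIRS = [(1.2, 0), (1.4, 0), (1.6, 0), (3.7, 1), (3.9, 1), (4.1, 1)]


def toy_sample() -> SortedSample:
    """Six-instance, two-class worked example (optimal cut at 2.65)."""
    return build_sorted_sample(_TOY_PAIRS)


def toy_frame() -> pd.DataFrame:
    """The worked example as a two-column table (expression, target)."""
    return pd.DataFrame(
        {
            "expression": [p[0] for p in _TOY_PAIRS],
            "target": [p[1] for p in _TOY_PAIRS],
        }
    )
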