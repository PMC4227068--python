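"""Combinatorics and priors over divergence models.

A *divergence model* is an assignment of the ``Y`` population pairs to
divergence-time classes ("divergence events").  An *ordered* model keeps the
identity of each pair and is a set partition of ``{1..Y}``; an *unordered*
model keeps only the multiset of class sizes and is an integer partition of
``Y``.  Three priors over models are provided:

* a Dirichlet process (Chinese restaurant process) over ordered models,
  governed by a concentration parameter ``chi``;
* a discrete-uniform prior over the unordered models;
* the classic "U-shaped" prior induced by drawing the number of classes
  uniformly on ``{1..Y}`` and then assigning pairs by a symmetric multinomial
  conditioned on every class being occupied.

All counting is done in exact integer arithmetic (Python ints), so Bell and
Stirling numbers are exact for any practical ``Y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "DivergenceModel",
    "ModelPriorSpec",
    "stirling2",
    "stirling1_unsigned",
    "bell_number",
    "integer_partitions",
    "dpp_ncat_pmf",
    "dpp_coclustering_prob",
    "sample_partition_dpp",
    "sample_partition_uniform",
    "sample_partition_msbayes",
    "sample_partition_identity",
    "partition_signature",
    "canonicalize",
]


@dataclass(frozen=True)
class DivergenceModel:
    """An ordered divergence model: class indices plus the class times.

    ``t`` uses canonical first-appearance labeling: pair 0 is always in class
    1 and a new class label is one greater than the largest label seen so
    far.  ``tau`` holds the time of each class (4N_C generations), indexed by
    class label - 1, and may be empty when only the partition is known.
    """

    t: tuple[int, ...]
    tau: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.t) == 0:
            raise ValueError("divergence model needs at least one pair")
        if self.t != canonicalize(self.t):
            raise ValueError(f"class indices {self.t} are not in canonical "
                             "first-appearance order")
        if self.tau and len(self.tau) != self.ntau:
            raise ValueError("tau must have one time per class")
        if any(x <= 0 for x in self.tau):
            raise ValueError("divergence times must be strictly positive")

    @property
    def Y(self) -> int:
        return len(self.t)

    @property
    def ntau(self) -> int:
        """Number of divergence-time classes, |tau|."""
        return max(self.t)

    @property
    def times(self) -> np.ndarray:
        """Per-pair divergence times: T_i = tau[t_i]."""
        if not self.tau:
            raise ValueError("model carries no divergence times")
        return np.asarray([self.tau[i - 1] for i in self.t])

    def signature(self) -> tuple[int, ...]:
        return partition_signature(self.t)


@dataclass(frozen=True)
class ModelPriorSpec:
    """Which prior to place on divergence models.

    kind
        ``"dpp"`` (Dirichlet process over ordered models), ``"uniform"``
        (discrete uniform over unordered models), ``"msbayes"`` (U-shaped),
        or ``"identity"`` (every pair its own class; used to generate
        data with no clustering).
    chi
        Concentration parameter for the DPP: a positive float for a fixed
        value, or a ``(shape, scale)`` pair for a gamma hyperprior drawn
        afresh for every prior sample.
    """

    kind: str
    chi: float | tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("dpp", "uniform", "msbayes", "identity"):
            raise ValueError(f"unknown model-prior kind {self.kind!r}")
        if self.kind == "dpp":
            if self.chi is None:
                raise ValueError("DPP prior requires chi or a (shape, scale) "
                                 "hyperprior")
            if isinstance(self.chi, tuple):
                if len(self.chi) != 2 or any(v <= 0 for v in self.chi):
                    raise ValueError("chi hyperprior must be two positive "
                                     "values (shape, scale)")
            elif self.chi <= 0:
                raise ValueError("chi must be positive")
        elif self.chi is not None:
            raise ValueError(f"chi is only meaningful for the DPP prior, "
                             f"not {self.kind!r}")

    def draw_chi(self, rng: np.random.Generator) -> float | None:
        if self.kind != "dpp":
            return None
        if isinstance(self.chi, tuple):
            shape, scale = self.chi
            return float(rng.gamma(shape, scale))
        return float(self.chi)

    def sample(self, Y: int, rng: np.random.Generator,
               chi: float | None = None) -> tuple[int, ...]:
        """Draw a canonical class-index vector ``t`` for ``Y`` pairs."""
        if self.kind == "dpp":
            if chi is None:
                chi = self.draw_chi(rng)
            return sample_partition_dpp(Y, chi, rng)
        if self.kind == "uniform":
            return sample_partition_uniform(Y, rng)
        if self.kind == "msbayes":
            return sample_partition_msbayes(Y, rng)
        return sample_partition_identity(Y)


def canonicalize(t: Sequence[int]) -> tuple[int, ...]:
    """Relabel class indices by order of first appearance (1-based)."""
    mapping: dict[int, int] = {}
    out = []
    for c in t:
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out.append(mapping[c])
    return tuple(out)


def partition_signature(t: Sequence[int]) -> tuple[int, ...]:
    """Block-size multiset of ``t``, sorted descending.

    Identical for every relabeling of the same unordered model.
    """
    if len(t) == 0:
        raise ValueError("empty class-index vector")
    counts: dict[int, int] = {}
    for c in t:
        counts[c] = counts.get(c, 0) + 1
    return tuple(sorted(counts.values(), reverse=True))


@lru_cache(maxsize=None)
def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind: set partitions of ``n`` items
    into exactly ``k`` non-empty blocks.  Exact integer."""
    if n < 1 or k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    if k == 1 or k == n:
        return 1
    return stirling2(n - 1, k - 1) + k * stirling2(n - 1, k)


@lru_cache(maxsize=None)
def stirling1_unsigned(n: int, k: int) -> int:
    """Unsigned Stirling number of the first kind: permutations of ``n``
    elements with exactly ``k`` cycles.  Exact integer."""
    if n < 1 or k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    if k == n:
        return 1
    if k == 1:
        out = 1
        for i in range(1, n):
            out *= i
        return out
    return stirling1_unsigned(n - 1, k - 1) + (n - 1) * stirling1_unsigned(n - 1, k)


def bell_number(Y: int) -> int:
    """Number of ordered divergence models for ``Y`` pairs (Bell number)."""
    if Y < 1:
        raise ValueError("Y must be >= 1")
    return sum(stirling2(Y, k) for k in range(1, Y + 1))


def integer_partitions(Y: int) -> list[tuple[int, ...]]:
    """All integer partitions of ``Y`` (the unordered divergence models),
    each a non-increasing tuple, in reverse-lexicographic order."""
    return list(_integer_partitions(Y))


@lru_cache(maxsize=None)
def _integer_partitions(Y: int) -> tuple[tuple[int, ...], ...]:
    if Y < 1:
        raise ValueError("Y must be >= 1")
    out: list[tuple[int, ...]] = []

    def extend(prefix: list[int], remaining: int, cap: int) -> None:
        if remaining == 0:
            out.append(tuple(prefix))
            return
        for part in range(min(cap, remaining), 0, -1):
            prefix.append(part)
            extend(prefix, remaining - part, part)
            prefix.pop()

    extend([], Y, Y)
    return tuple(out)


def dpp_ncat_pmf(Y: int, chi: float, k: int) -> float:
    """Prior probability that the Dirichlet process with concentration
    ``chi`` partitions ``Y`` pairs into exactly ``k`` classes:

        p(k) = c(Y, k) chi^k / prod_{i=1..Y} (chi + i - 1)

    with ``c`` the unsigned Stirling numbers of the first kind.
    """
    if chi <= 0:
        raise ValueError("chi must be positive")
    if k < 1 or k > Y:
        raise ValueError(f"need 1 <= k <= Y, got k={k}, Y={Y}")
    log_num = float(np.log(chi)) * k
    log_den = float(np.sum(np.log(chi + np.arange(Y))))
    return float(stirling1_unsigned(Y, k)) * np.exp(log_num - log_den)


def dpp_coclustering_prob(chi: float) -> float:
    """Prior probability that any two pairs share a divergence time under
    the Dirichlet process: 1 / (1 + chi)."""
    if chi <= 0:
        raise ValueError("chi must be positive")
    return 1.0 / (1.0 + chi)


def sample_partition_dpp(Y: int, chi: float,
                         rng: np.random.Generator) -> tuple[int, ...]:
    """One Chinese-restaurant-process draw over ``Y`` pairs.

    Pair ``i`` joins an existing class with probability proportional to its
    occupancy and opens a new class with probability proportional to
    ``chi``.  Output is canonical by construction.
    """
    if Y < 1:
        raise ValueError("Y must be >= 1")
    if chi <= 0:
        raise ValueError("chi must be positive")
    t = [1]
    counts = [1]
    for i in range(1, Y):
        u = rng.random() * (i + chi)
        acc = 0.0
        for c, n_c in enumerate(counts):
            acc += n_c
            if u < acc:
                t.append(c + 1)
                counts[c] += 1
                break
        else:
            counts.append(1)
            t.append(len(counts))
    return tuple(t)


def sample_partition_uniform(Y: int,
                             rng: np.random.Generator) -> tuple[int, ...]:
    """Draw an unordered model uniformly from the integer partitions of
    ``Y``, then a uniformly random set partition with those block sizes.

    Shuffling the pairs and filling blocks of the drawn sizes in order hits
    every set partition with a given signature equally often, so the
    completion is the unique label-exchangeable one.
    """
    if Y < 1:
        raise ValueError("Y must be >= 1")
    parts = _integer_partitions(Y)
    sizes = parts[int(rng.integers(len(parts)))]
    order = rng.permutation(Y)
    t = [0] * Y
    pos = 0
    for label, size in enumerate(sizes, start=1):
        for j in order[pos:pos + size]:
            t[j] = label
        pos += size
    return canonicalize(t)


def sample_partition_msbayes(Y: int,
                             rng: np.random.Generator) -> tuple[int, ...]:
    """The original msBayes "U-shaped" prior: the number of classes is
    uniform on ``{1..Y}``; conditional on it, pairs are assigned by a
    symmetric multinomial rejected until every class is occupied.

    Because all surjective assignments are equally likely and each set
    partition with ``k`` blocks corresponds to exactly ``k!`` of them, the
    conditional law is uniform over set partitions with ``k`` blocks.
    """
    if Y < 1:
        raise ValueError("Y must be >= 1")
    k = int(rng.integers(1, Y + 1))
    if k == 1:
        return (1,) * Y
    # batched rejection: acceptance can be rare when k is close to Y
    while True:
        batch = rng.integers(1, k + 1, size=(64, Y))
        occupied = np.zeros((64, k + 1), dtype=bool)
        np.put_along_axis(occupied, batch, True, axis=1)
        ok = np.where(occupied[:, 1:].all(axis=1))[0]
        if len(ok):
            return canonicalize(batch[ok[0]].tolist())


def sample_partition_identity(Y: int) -> tuple[int, ...]:
    """Every pair in its own class (no clustering): t = (1, 2, ..., Y)."""
    if Y < 1:
        raise ValueError("Y must be >= 1")
    return tuple(range(1, Y + 1))


def msbayes_ordered_pmf(t: Sequence[int], Y: int) -> float:
    """Exact prior probability of an ordered model under the U-shaped
    prior: p(t) = (1/Y) / S(Y, k) with k the number of classes."""
    k = max(canonicalize(t))
    return 1.0 / (Y * stirling2(Y, k))
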