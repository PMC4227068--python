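"""Sequence simulation along gene trees under the HKY85 substitution model.

Two exact samplers are provided.  The default (``method="jump"``) uses
uniformization: the number of jump-chain events on a branch is Poisson with
rate ``mu_max * branch_length * L`` and each event applies one step of the
transition kernel ``I + Q / mu_max``; this is exact and fast when branches
are short (few expected substitutions).  The ``method="matrix"`` sampler
draws every site's child state from the closed-form transition-probability
matrix ``P(t) = exp(Q t)`` obtained by eigen-decomposition; it is used as
the independent route in the test suite and for long branches.

Nucleotides are coded A=0, C=1, G=2, T=3; transitions are A<->G and C<->T.
Rate matrices are normalized so branch lengths are in expected
substitutions per site at stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .coalescent import GeneTree, LocusSpec, PairSpec, simulate_gene_tree
from .priors import ParameterDraw, PriorConfig, theta_C as _theta_C

__all__ = ["HKYModel", "Alignment", "simulate_alignment",
           "simulate_dataset", "NUCLEOTIDES"]

NUCLEOTIDES = "ACGT"
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _a, _b in ((0, 2), (2, 0), (1, 3), (3, 1)):
    _TRANSITION[_a, _b] = True


@dataclass(frozen=True)
class Alignment:
    """A gapless alignment of simulated (or observed) sequences.

    ``seqs`` is (n, L) int8 with nucleotide codes 0..3; observed data may
    contain -1 for missing (gaps/ambiguities).  ``pops`` gives each
    sequence's population of origin (0 or 1).
    """

    seqs: np.ndarray
    pops: np.ndarray
    pair_label: str
    locus_id: str

    def __post_init__(self) -> None:
        if self.seqs.ndim != 2:
            raise ValueError("seqs must be 2-D (sequences x sites)")
        if len(self.pops) != self.seqs.shape[0]:
            raise ValueError("one population label per sequence required")

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.seqs < 0).any())


class HKYModel:
    """HKY85 rate matrix with cached eigen-decomposition.

    Reversibility lets ``Q`` be symmetrized as ``D S D^-1`` with
    ``D = diag(sqrt(pi))``, so the decomposition uses a symmetric solver
    and ``P(t)`` is computed stably for any ``t >= 0``.
    """

    def __init__(self, kappa: float, freqs) -> None:
        f = np.asarray(freqs, dtype=float)
        if f.shape != (4,) or (f <= 0).any() or abs(f.sum() - 1) > 1e-9:
            raise ValueError("freqs must be four positive values summing "
                             "to 1")
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        self.kappa = float(kappa)
        self.freqs = f
        q = np.where(_TRANSITION, kappa, 1.0) * f[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        rate = -float(np.dot(f, np.diag(q)))
        q /= rate
        self.Q = q
        self.mu_max = float(-np.diag(q).min())
        jump = np.eye(4) + q / self.mu_max
        self.jump_cum = np.cumsum(jump, axis=1)
        self.jump_cum[:, -1] = 1.0  # guard float rounding at the edge
        self._jump_rows = tuple(tuple(row) for row in self.jump_cum)
        self.freqs_cum = np.cumsum(f)
        self.freqs_cum[-1] = 1.0
        d = np.sqrt(f)
        sym = (q * d[:, None]) / d[None, :]
        w, u = np.linalg.eigh(0.5 * (sym + sym.T))
        # Q = D^-1 S D with D = diag(sqrt(pi)), so
        # P(t) = D^-1 U exp(w t) U^T D
        self._w = w
        self._right = u / d[:, None]
        self._left = u.T * d[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to one."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        p = (self._right * np.exp(self._w * t)) @ self._left
        return np.clip(p, 0.0, None)

    @classmethod
    def for_locus(cls, locus: LocusSpec) -> "HKYModel":
        return _cached_model(locus.kappa, tuple(locus.freqs))


@lru_cache(maxsize=128)
def _cached_model(kappa: float, freqs: tuple[float, ...]) -> HKYModel:
    return HKYModel(kappa, freqs)


def _sample_root(model: HKYModel, L: int,
                 rng: np.random.Generator) -> np.ndarray:
    u = rng.random(L)
    return np.searchsorted(model.freqs_cum, u).astype(np.int8)


def _evolve_jump(model: HKYModel, seq: np.ndarray, blen: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Exact branch evolution by uniformization; returns the child
    sequence (shared with the parent when no event occurs)."""
    L = len(seq)
    n_ev = rng.poisson(model.mu_max * blen * L)
    if n_ev == 0:
        return seq
    child = seq.copy()
    sites = rng.integers(0, L, size=n_ev)
    us = rng.random(n_ev)
    rows = model._jump_rows
    for site, u in zip(sites.tolist(), us.tolist()):
        row = rows[child[site]]
        k = 0
        while u > row[k]:
            k += 1
        child[site] = k
    return child


def _evolve_matrix(model: HKYModel, seq: np.ndarray, blen: float,
                   rng: np.random.Generator) -> np.ndarray:
    p_cum = np.cumsum(model.transition_matrix(blen), axis=1)
    p_cum[:, -1] = 1.0
    u = rng.random(len(seq))
    rows = p_cum[seq]
    return (u[:, None] > rows).sum(axis=1).astype(np.int8)


def simulate_alignment(tree: GeneTree, locus: LocusSpec,
                       rng: np.random.Generator, *, pair_label: str = "",
                       method: str = "jump") -> Alignment:
    """Evolve a root sequence drawn from the stationary frequencies down
    the genealogy; branch lengths are the tree's per-site substitution
    lengths."""
    if method not in ("jump", "matrix"):
        raise ValueError(f"unknown method {method!r}")
    model = HKYModel.for_locus(locus)
    L = locus.length
    n = tree.n_tips
    evolve = _evolve_jump if method == "jump" else _evolve_matrix

    seqs: list[np.ndarray | None] = [None] * (2 * n - 1)
    seqs[tree.root] = _sample_root(model, L, rng)
    for node in range(tree.root - 1, -1, -1):
        parent_seq = seqs[tree.parent[node]]
        seqs[node] = evolve(model, parent_seq, tree.branch_subs[node], rng)

    mat = np.vstack([seqs[i] for i in range(n)])
    return Alignment(mat, tree.tip_pops.copy(), pair_label, locus.locus_id)


def simulate_dataset(draw: ParameterDraw, pair_specs, theta_C: float,
                     rng: np.random.Generator, *,
                     method: str = "jump",
                     return_trees: bool = False):
    """Simulate one alignment per (pair, locus) for a parameter draw.

    Mutation-rate multipliers are shared between loci with the same
    ``locus_id``; ``draw.upsilon`` must have one entry per unique locus in
    order of first appearance across ``pair_specs``.
    """
    locus_index: dict[str, int] = {}
    for pair in pair_specs:
        for locus in pair.loci:
            locus_index.setdefault(locus.locus_id, len(locus_index))
    if len(draw.upsilon) != len(locus_index):
        raise ValueError(f"draw has {len(draw.upsilon)} rate multipliers "
                         f"but the dataset has {len(locus_index)} loci")

    T = draw.T
    if len(T) != len(pair_specs):
        raise ValueError("parameter draw and pair specs disagree on Y")
    alignments = []
    trees = []
    for i, pair in enumerate(pair_specs):
        demo = draw.demographics[i]
        for locus in pair.loci:
            ups = draw.upsilon[locus_index[locus.locus_id]]
            tree = simulate_gene_tree(pair, locus, float(T[i]), demo, ups,
                                      theta_C, rng)
            aln = simulate_alignment(tree, locus, rng,
                                     pair_label=pair.label, method=method)
            alignments.append(aln)
            if return_trees:
                trees.append(tree)
    if return_trees:
        return alignments, trees
    return alignments
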