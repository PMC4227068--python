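"""Gene-tree simulation under the pair-wise multi-population coalescent.

Each taxon pair is modelled pastward from the present in units of 4N_C
generations (the coalescent time scale of a reference population of
mutation-scaled size theta_C):

* on ``[0, tauB * T)`` the two descendant populations shrink (pastward)
  exponentially from their present size theta_D down to the bottleneck
  size theta_D * zeta reached at ``tauB * T``;
* on ``[tauB * T, T)`` they stay at the bottleneck size;
* at ``T`` both merge into the ancestral population of size theta_A;
* before ``T`` lineages migrate symmetrically between the descendants at
  rate ``m`` per lineage.

All sizes for a locus are multiplied by ``rho * nu * upsilon`` (ploidy,
rate-constant, and rate-multiplier scalings).  The pairwise coalescence
rate inside a population of mutation-scaled size theta' is
``2 * theta_C / theta'`` per unit time, so a population at theta_C has
expected pairwise coalescence time 0.5 and E[pi] = theta' exactly; one
time unit equals theta_C expected substitutions per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .priors import DemographicParams

__all__ = ["LocusSpec", "PairSpec", "GeneTree", "simulate_gene_tree"]


@dataclass(frozen=True)
class LocusSpec:
    """One locus: alignment length, HKY85 parameters, and the fixed
    investigator-supplied theta scalings rho (ploidy/generation time) and
    nu (relative mutation rate)."""

    locus_id: str
    length: int = 1000
    kappa: float = 1.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rho: float = 1.0
    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("locus length must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or (f <= 0).any() or abs(f.sum() - 1) > 1e-9:
            raise ValueError("freqs must be four positive values summing "
                             "to 1")
        if self.rho <= 0 or self.nu <= 0:
            raise ValueError("rho and nu must be positive")


@dataclass(frozen=True)
class PairSpec:
    """One taxon pair: sample sizes and its loci."""

    label: str
    n1: int
    n2: int
    loci: tuple[LocusSpec, ...]

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1 or self.n1 + self.n2 < 2:
            raise ValueError("need n1, n2 >= 1 and at least two samples")
        if not self.loci:
            raise ValueError("at least one locus is required")

    @property
    def n(self) -> int:
        return self.n1 + self.n2


@dataclass
class GeneTree:
    """A coalescent genealogy over ``n`` tips.

    Nodes ``0..n-1`` are tips (height 0); internal nodes are numbered in
    coalescence order, so every parent index exceeds its children's and a
    single reverse sweep visits parents before children.  ``branch_subs``
    holds each node's parent-edge length in expected substitutions per
    site (time difference times theta_C); the root entry is 0.
    """

    tip_pops: np.ndarray  # (n,) int8: 0 or 1, population of origin
    parent: np.ndarray    # (2n-1,) int: parent index, -1 for the root
    time: np.ndarray      # (2n-1,) float: node heights in 4N_C units
    branch_subs: np.ndarray  # (2n-1,) float

    @property
    def n_tips(self) -> int:
        return len(self.tip_pops)

    @property
    def root(self) -> int:
        return 2 * self.n_tips - 2

    def tmrca(self) -> float:
        return float(self.time[self.root])

    def cross_population_mrca(self) -> float:
        """Height of the oldest node below which no tips from both
        populations descend; equivalently the youngest coalescence joining
        lineages that carry tips of different populations."""
        n = self.n_tips
        has = np.zeros((2 * n - 1, 2), dtype=bool)
        has[np.arange(n), self.tip_pops] = True
        youngest = self.time[self.root]
        for node in range(n, 2 * n - 1):
            kids = np.where(self.parent == node)[0]
            for k in kids:
                has[node] |= has[k]
            if has[node].all():
                youngest = min(youngest, float(self.time[node]))
        return youngest

    def to_newick(self) -> str:
        n = self.n_tips
        children: list[list[int]] = [[] for _ in range(2 * n - 1)]
        for i in range(2 * n - 2):
            children[self.parent[i]].append(i)

        def fmt(node: int) -> str:
            blen = self.branch_subs[node]
            if node < n:
                return f"t{node}_p{self.tip_pops[node] + 1}:{blen:.10g}"
            inner = ",".join(fmt(c) for c in children[node])
            return f"({inner}):{blen:.10g}"

        return fmt(self.root) + ";"


def _growth_wait(n_pairs: int, lam0: float, beta: float, s: float,
                 rng: np.random.Generator) -> float:
    """Waiting time to the next coalescence when the per-pair rate is
    lam0 * exp(beta * s) (pastward-shrinking population), starting at
    absolute time s."""
    e = rng.exponential()
    arg = beta * e * math.exp(-beta * s) / (n_pairs * lam0)
    return math.log1p(arg) / beta


def simulate_gene_tree(pair: PairSpec, locus: LocusSpec, T_i: float,
                       demo: DemographicParams, upsilon_j: float,
                       theta_C: float,
                       rng: np.random.Generator) -> GeneTree:
    """Simulate one genealogy for a locus of a taxon pair.

    ``T_i`` is the pair's divergence time in 4N_C units; ``upsilon_j`` the
    locus mutation-rate multiplier; ``theta_C`` the reference size defining
    the time scale.
    """
    for name, v in (("T_i", T_i), ("upsilon_j", upsilon_j),
                    ("theta_C", theta_C)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and positive")
    if (demo.zetaD1 <= 0 or demo.zetaD2 <= 0):
        raise ValueError("zeta must be > 0 (a zero-size bottleneck has "
                         "infinite coalescence rate)")

    g = locus.rho * locus.nu * upsilon_j
    # per-pair coalescence rates at present and in the ancestral population
    lam_d = (2.0 * theta_C / (demo.thetaD1 * g),
             2.0 * theta_C / (demo.thetaD2 * g))
    lam_anc = 2.0 * theta_C / (demo.thetaA * g)
    zeta = (demo.zetaD1, demo.zetaD2)
    t_growth_end = demo.tauB * T_i  # pastward time at which growth stops

    n = pair.n
    tip_pops = np.concatenate([np.zeros(pair.n1, dtype=np.int8),
                               np.ones(pair.n2, dtype=np.int8)])
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1, dtype=float)

    active: list[list[int]] = [list(range(pair.n1)),
                               list(range(pair.n1, n))]
    next_node = n
    s = 0.0
    merged = False

    def coal(pop_lineages: list[int], at: float) -> None:
        nonlocal next_node
        k = len(pop_lineages)
        a = int(rng.integers(k))
        b = int(rng.integers(k - 1))
        if b >= a:
            b += 1
        ia, ib = pop_lineages[a], pop_lineages[b]
        parent[ia] = parent[ib] = next_node
        time[next_node] = at
        for idx in sorted((a, b), reverse=True):
            pop_lineages.pop(idx)
        pop_lineages.append(next_node)
        next_node += 1

    while next_node < 2 * n - 1:
        if not merged and s >= T_i:
            active = [active[0] + active[1]]
            merged = True

        if merged:
            k = len(active[0])
            dt = rng.exponential() / (0.5 * k * (k - 1) * lam_anc)
            coal(active[0], s + dt)
            s += dt
            continue

        in_growth = s < t_growth_end
        boundary = t_growth_end if in_growth else T_i

        best_dt = math.inf
        best_event: tuple[str, int] | None = None
        for p in (0, 1):
            k = len(active[p])
            if k < 2:
                continue
            n_pairs = 0.5 * k * (k - 1)
            if in_growth and zeta[p] < 1.0:
                beta = -math.log(zeta[p]) / t_growth_end
                dt = _growth_wait(n_pairs, lam_d[p], beta, s, rng)
            else:
                rate = lam_d[p] * (1.0 if in_growth else 1.0 / zeta[p])
                dt = rng.exponential() / (n_pairs * rate)
            if dt < best_dt:
                best_dt, best_event = dt, ("coal", p)
        if demo.m > 0:
            k_tot = len(active[0]) + len(active[1])
            dt = rng.exponential() / (demo.m * k_tot)
            if dt < best_dt:
                best_dt, best_event = dt, ("mig", -1)

        if best_event is None or s + best_dt >= boundary:
            s = boundary
            continue

        s += best_dt
        kind, p = best_event
        if kind == "coal":
            coal(active[p], s)
        else:
            k_tot = len(active[0]) + len(active[1])
            j = int(rng.integers(k_tot))
            src = 0 if j < len(active[0]) else 1
            if src == 1:
                j -= len(active[0])
            active[1 - src].append(active[src].pop(j))

    branch_subs = np.zeros(2 * n - 1, dtype=float)
    has_parent = parent >= 0
    branch_subs[has_parent] = (time[parent[has_parent]]
                               - time[has_parent]) * theta_C
    return GeneTree(tip_pops, parent, time, branch_subs)
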