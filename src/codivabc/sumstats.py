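"""Population-genetic summary statistics per taxon pair.

Four statistics are computed for each pair from the pooled two-population
sample: nucleotide diversity pi, Watterson's theta_W, Nei's net
between-population divergence pi_net, and SD(pi - theta_W), the square
root of the Tajima (1989) variance estimator of the difference.  The mean
between-population diversity pi_b is also computed as the key for the
optional descending re-sort of the per-pair blocks (the layout the
original msBayes uses to sample unordered divergence models).

All per-site statistics divide by the number of comparable sites; missing
data (negative codes) are excluded pairwise, and the comparable length is
averaged over sequence pairs where a single L is needed.  Simulated data
contain no missing values and take a vectorized fast path over the
segregating columns only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .mutate import Alignment

__all__ = [
    "STAT_NAMES",
    "SummaryVector",
    "pi",
    "watterson_theta",
    "pi_net",
    "pi_between",
    "sd_pi_minus_thetaW",
    "alignment_stats",
    "summarize_dataset",
]

STAT_NAMES = ("pi", "theta_w", "pi_net", "sd_pi_theta")


def _pairwise_diffs(seqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair difference counts and comparable lengths for all
    unordered sequence pairs.  Returns (diffs, lengths), both (n, n)
    symmetric with zero diagonals."""
    n, L = seqs.shape
    missing = seqs < 0
    if missing.any():
        valid = ~missing
        ok = valid[:, None, :] & valid[None, :, :]
        diffs = ((seqs[:, None, :] != seqs[None, :, :]) & ok).sum(axis=2)
        lengths = ok.sum(axis=2)
    else:
        # restrict to segregating columns: identical columns add nothing
        seg = (seqs != seqs[0]).any(axis=0)
        sub = seqs[:, seg]
        diffs = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
        lengths = np.full((n, n), L, dtype=np.int64)
    np.fill_diagonal(diffs, 0)
    np.fill_diagonal(lengths, 0)
    return diffs, lengths


def _mean_per_site(diffs, lengths, rows, cols) -> float:
    d = diffs[np.ix_(rows, cols)].astype(float)
    l = lengths[np.ix_(rows, cols)].astype(float)
    if (l == 0).any():
        raise ValueError("a sequence pair shares no comparable sites")
    return float((d / l).mean())


def _check(aln: Alignment) -> None:
    if aln.n < 2:
        raise ValueError("need at least two sequences")


def pi(aln: Alignment) -> float:
    """Mean per-site pairwise difference over the pooled sample."""
    _check(aln)
    diffs, lengths = _pairwise_diffs(aln.seqs)
    iu = np.triu_indices(aln.n, k=1)
    d = diffs[iu].astype(float)
    l = lengths[iu].astype(float)
    if (l == 0).any():
        raise ValueError("a sequence pair shares no comparable sites")
    return float((d / l).mean())


def _segregating(seqs: np.ndarray) -> tuple[int, float]:
    """Number of segregating sites and the comparable length, with
    pairwise-average length under missing data."""
    n, L = seqs.shape
    missing = seqs < 0
    if not missing.any():
        S = int((seqs != seqs[0]).any(axis=0).sum())
        return S, float(L)
    S = 0
    for col in seqs.T:
        obs = col[col >= 0]
        if len(obs) >= 2 and (obs != obs[0]).any():
            S += 1
    valid = ~missing
    iu = np.triu_indices(n, k=1)
    lens = (valid[:, None, :] & valid[None, :, :]).sum(axis=2)[iu]
    return S, float(lens.mean())


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n, dtype=float)
    return float((1.0 / i ** power).sum())


def watterson_theta(aln: Alignment) -> float:
    """S / (a_{n-1} * L) with a the harmonic number."""
    _check(aln)
    S, L = _segregating(aln.seqs)
    return S / (_harmonic(aln.n) * L)


def pi_between(aln: Alignment) -> float:
    """Mean per-site difference over between-population sequence pairs
    (the pi_b sort key)."""
    _check(aln)
    pops = np.asarray(aln.pops)
    r1 = np.where(pops == 0)[0]
    r2 = np.where(pops == 1)[0]
    if len(r1) == 0 or len(r2) == 0:
        raise ValueError("both populations need at least one sequence")
    diffs, lengths = _pairwise_diffs(aln.seqs)
    return _mean_per_site(diffs, lengths, r1, r2)


def pi_net(aln: Alignment) -> tuple[float, bool]:
    """Nei's net divergence pi_b - (pi_1 + pi_2) / 2.

    Returns ``(value, degenerate)`` where ``degenerate`` flags that a
    population had a single sequence so its within-population diversity
    was set to 0 by convention.
    """
    _check(aln)
    pops = np.asarray(aln.pops)
    r1 = np.where(pops == 0)[0]
    r2 = np.where(pops == 1)[0]
    if len(r1) == 0 or len(r2) == 0:
        raise ValueError("both populations need at least one sequence")
    diffs, lengths = _pairwise_diffs(aln.seqs)
    pb = _mean_per_site(diffs, lengths, r1, r2)
    degenerate = False
    within = []
    for rows in (r1, r2):
        if len(rows) < 2:
            within.append(0.0)
            degenerate = True
            continue
        iu = np.triu_indices(len(rows), k=1)
        d = diffs[np.ix_(rows, rows)][iu].astype(float)
        l = lengths[np.ix_(rows, rows)][iu].astype(float)
        if (l == 0).any():
            raise ValueError("a sequence pair shares no comparable sites")
        within.append(float((d / l).mean()))
    return pb - 0.5 * (within[0] + within[1]), degenerate


def tajima_variance_coefficients(n: int) -> tuple[float, float]:
    """The e1, e2 coefficients of Tajima's (1989) variance estimator
    V(d) = e1*S + e2*S*(S-1) for d = pi_total - S/a1."""
    if n < 2:
        raise ValueError("need n >= 2")
    a1 = _harmonic(n)
    a2 = _harmonic(n, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    return c1 / a1, c2 / (a1 ** 2 + a2)


def sd_pi_minus_thetaW(aln: Alignment) -> float:
    """Per-site standard deviation of pi - theta_W from the Tajima's D
    denominator."""
    _check(aln)
    S, L = _segregating(aln.seqs)
    if S == 0:
        return 0.0
    e1, e2 = tajima_variance_coefficients(aln.n)
    return float(np.sqrt(e1 * S + e2 * S * (S - 1)) / L)


def _complete_stats(seqs: np.ndarray, pops: np.ndarray) -> dict[str, float]:
    """All five statistics in one pass over a gap-free alignment.

    Only segregating columns enter the pairwise-difference matrix;
    invariant columns contribute no differences.
    """
    n, L = seqs.shape
    seg = (seqs != seqs[0]).any(axis=0)
    S = int(seg.sum())
    if S == 0:
        return dict.fromkeys(("pi", "theta_w", "pi_net", "sd_pi_theta",
                              "pi_b"), 0.0)
    sub = np.ascontiguousarray(seqs[:, seg])
    diffs = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
    p0 = pops == 0
    p1 = ~p0
    n1 = int(p0.sum())
    n2 = n - n1
    tot = float(diffs.sum()) / 2.0
    cross = float(diffs[p0][:, p1].sum())
    w1 = float(diffs[p0][:, p0].sum()) / 2.0
    w2 = float(diffs[p1][:, p1].sum()) / 2.0
    pi_total = tot / (n * (n - 1) / 2) / L
    pi_b = cross / (n1 * n2) / L
    piw1 = w1 / (n1 * (n1 - 1) / 2) / L if n1 >= 2 else 0.0
    piw2 = w2 / (n2 * (n2 - 1) / 2) / L if n2 >= 2 else 0.0
    e1, e2 = tajima_variance_coefficients(n)
    return {
        "pi": pi_total,
        "theta_w": S / (_harmonic(n) * L),
        "pi_net": pi_b - 0.5 * (piw1 + piw2),
        "sd_pi_theta": float(np.sqrt(e1 * S + e2 * S * (S - 1)) / L),
        "pi_b": pi_b,
    }


def alignment_stats(aln: Alignment) -> dict[str, float]:
    """All five per-alignment statistics as a dict (the four summary
    statistics plus the pi_b sort key)."""
    if not aln.has_missing:
        return _complete_stats(aln.seqs, np.asarray(aln.pops))
    net, _ = pi_net(aln)
    return {
        "pi": pi(aln),
        "theta_w": watterson_theta(aln),
        "pi_net": net,
        "sd_pi_theta": sd_pi_minus_thetaW(aln),
        "pi_b": pi_between(aln),
    }


@dataclass(frozen=True)
class SummaryVector:
    """Per-pair blocks of the four summary statistics.

    ``values`` is (blocks, 4) in STAT_NAMES order; ``pi_b`` holds the sort
    key per block.  In ``pi_b_sorted`` mode the blocks are in
    non-increasing pi_b (ties broken by original pair index) and labels
    are dropped, matching the unordered-model layout of msBayes; in
    ``ordered`` mode input pair order and labels are preserved.
    """

    values: np.ndarray
    pi_b: np.ndarray
    ordering_mode: str
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.ordering_mode not in ("ordered", "pi_b_sorted"):
            raise ValueError(f"unknown ordering {self.ordering_mode!r}")
        if self.values.shape != (len(self.pi_b), len(STAT_NAMES)):
            raise ValueError("values must be (blocks, 4)")
        if self.ordering_mode == "pi_b_sorted":
            if (np.diff(self.pi_b) > 0).any():
                raise ValueError("sorted mode requires non-increasing pi_b")

    @property
    def flat(self) -> np.ndarray:
        """The distance vector: blocks concatenated, pi_b excluded."""
        return self.values.reshape(-1)

    @property
    def n_blocks(self) -> int:
        return len(self.pi_b)


def summarize_dataset(alignments: Sequence[Alignment], *,
                      mean_across_loci: bool = True,
                      ordering_mode: str = "pi_b_sorted",
                      pair_order: Sequence[str] | None = None
                      ) -> SummaryVector:
    """Assemble the summary vector for a dataset of per-(pair, locus)
    alignments.

    With ``mean_across_loci`` each pair contributes the across-locus mean
    of each statistic (and of pi_b); otherwise each (pair, locus) is its
    own block.  ``pair_order`` fixes the pair ordering (defaults to first
    appearance).
    """
    by_pair: dict[str, list[dict[str, float]]] = {}
    order: list[str] = list(pair_order) if pair_order is not None else []
    for aln in alignments:
        if pair_order is None and aln.pair_label not in by_pair:
            order.append(aln.pair_label)
        by_pair.setdefault(aln.pair_label, []).append(alignment_stats(aln))
    missing = [p for p in order if p not in by_pair]
    if missing:
        raise ValueError(f"no alignments for pair(s) {missing}")

    blocks: list[list[float]] = []
    keys: list[float] = []
    labels: list[str] = []
    for pair_label in order:
        stats = by_pair[pair_label]
        if mean_across_loci:
            stats = [{k: float(np.mean([s[k] for s in stats]))
                      for k in stats[0]}]
        for s in stats:
            blocks.append([s[name] for name in STAT_NAMES])
            keys.append(s["pi_b"])
            labels.append(pair_label)

    values = np.asarray(blocks, dtype=float)
    pi_b = np.asarray(keys, dtype=float)
    if ordering_mode == "pi_b_sorted":
        idx = np.argsort(-pi_b, kind="stable")
        return SummaryVector(values[idx], pi_b[idx], "pi_b_sorted")
    return SummaryVector(values, pi_b, "ordered", labels=tuple(labels))
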