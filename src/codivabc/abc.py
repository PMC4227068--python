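"""Rejection ABC with optional local-linear regression adjustment.

The prior sample is a table with one row per draw from the joint prior,
holding the drawn parameters (number of divergence events ``ntau``, the
partition signature, divergence-time summaries ``T_bar``, ``s2_T``,
``D_T``, per-pair times and sizes) and the simulated summary-statistic
vector.  Rejection standardizes every summary column by its prior-sample
mean and standard deviation, ranks rows by Euclidean distance from the
(identically standardized) observed vector, and retains the requested
number of closest rows; the realized tolerance is the largest retained
distance.

Continuous parameters can be adjusted by weighted local-linear regression
on the standardized summaries (Epanechnikov kernel with bandwidth equal
to the realized tolerance), evaluated at the observed summaries.
Discrete model quantities (``ntau``, the partition) are never adjusted:
their retained-sample frequencies are the model-probability estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PriorTable",
    "PosteriorEstimate",
    "standardize",
    "reject",
    "glm_adjust",
    "model_probabilities",
    "hpd_interval",
    "summarize_posterior",
]

SCHEMA_VERSION = 1
SUMMARY_PREFIX = "s_"


@dataclass(frozen=True)
class PriorTable:
    """A sample from the joint prior with its summary statistics.

    ``df`` has a fixed column schema: parameter columns first, then the
    summary columns (prefix ``s_``) that enter the distance.
    """

    df: pd.DataFrame
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.df) < 1:
            raise ValueError("prior table needs at least one row")
        if not self.summary_columns:
            raise ValueError("prior table has no summary columns")
        s = self.df[self.summary_columns]
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError("summary columns must be finite")

    @property
    def summary_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(SUMMARY_PREFIX)]

    @property
    def parameter_columns(self) -> list[str]:
        return [c for c in self.df.columns
                if not c.startswith(SUMMARY_PREFIX)]

    @property
    def n(self) -> int:
        return len(self.df)

    def summaries(self) -> np.ndarray:
        return self.df[self.summary_columns].to_numpy(dtype=float)


@dataclass(frozen=True)
class PosteriorEstimate:
    """Retained draws from a rejection step, plus optional adjustment."""

    retained: pd.DataFrame       # unadjusted retained rows (params+stats)
    indices: np.ndarray          # row indices into the prior table
    distances: np.ndarray        # distances of retained rows, ascending
    epsilon: float               # realized tolerance (last retained)
    observed: np.ndarray         # raw observed summary vector (kept cols)
    observed_std: np.ndarray     # standardized observed vector
    means: np.ndarray            # standardization constants (kept cols)
    sds: np.ndarray
    summary_columns: tuple[str, ...]
    adjusted: pd.DataFrame | None = None

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def standardize(summaries: np.ndarray, observed: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                           np.ndarray, np.ndarray]:
    """Center and scale summary columns by their prior-sample mean/SD.

    Zero-SD columns carry no ranking information and are dropped with a
    warning.  Returns (Z, z_obs, means, sds, kept_mask).
    """
    summaries = np.asarray(summaries, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if summaries.ndim != 2 or observed.shape != (summaries.shape[1],):
        raise ValueError("observed vector must match the table columns")
    means = summaries.mean(axis=0)
    sds = summaries.std(axis=0)
    kept = sds > 0
    if not kept.all():
        dropped = np.where(~kept)[0]
        warnings.warn(f"dropping constant summary column(s) at index "
                      f"{dropped.tolist()} from the distance",
                      stacklevel=2)
    z = (summaries[:, kept] - means[kept]) / sds[kept]
    z_obs = (observed[kept] - means[kept]) / sds[kept]
    return z, z_obs, means[kept], sds[kept], kept


def reject(table: PriorTable, observed, n_retain: int) -> PosteriorEstimate:
    """Retain the ``n_retain`` prior rows closest to the observed summary
    vector in standardized Euclidean distance; ties break by row index."""
    if not 1 <= n_retain <= table.n:
        raise ValueError(f"n_retain must be in 1..{table.n}, got "
                         f"{n_retain}")
    obs = observed.flat if hasattr(observed, "flat") and not isinstance(
        observed, np.ndarray) else np.asarray(observed, dtype=float)
    cols = table.summary_columns
    z, z_obs, means, sds, kept = standardize(table.summaries(), obs)
    dist = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    order = np.lexsort((np.arange(len(dist)), dist))
    idx = order[:n_retain]
    kept_cols = tuple(c for c, k in zip(cols, kept) if k)
    return PosteriorEstimate(
        retained=table.df.iloc[idx].reset_index(drop=True),
        indices=idx,
        distances=dist[idx],
        epsilon=float(dist[idx[-1]]),
        observed=np.asarray(obs, dtype=float)[kept],
        observed_std=z_obs,
        means=means,
        sds=sds,
        summary_columns=kept_cols,
    )


# Support-aware transforms for regression adjustment, by column-name rule.
def _transform_for(col: str, values: np.ndarray) -> str:
    positive = ("T_bar", "s2_T", "D_T", "tau", "T_", "theta", "m",
                "upsilon", "chi")
    unit = ("zeta", "tauB")
    if any(col == p or col.startswith(p) for p in unit):
        if ((values > 0) & (values < 1)).all():
            return "logit"
        return "raw"
    if any(col == p or col.startswith(p) for p in positive):
        if (values > 0).all():
            return "log"
        return "raw"
    return "raw"


def _apply(values: np.ndarray, how: str) -> np.ndarray:
    if how == "log":
        return np.log(values)
    if how == "logit":
        return np.log(values) - np.log1p(-values)
    return values


def _unapply(values: np.ndarray, how: str) -> np.ndarray:
    if how == "log":
        return np.exp(values)
    if how == "logit":
        return 1.0 / (1.0 + np.exp(-values))
    return values


def glm_adjust(posterior: PosteriorEstimate,
               params: list[str] | None = None) -> PosteriorEstimate:
    """Local-linear regression adjustment of continuous parameters.

    Each parameter (on a log/logit scale where its support allows) is
    regressed on the standardized retained summaries with Epanechnikov
    weights ``1 - (d / eps)^2``, and shifted to the observed summaries:
    ``y* = y - (Z - z_obs) beta``.  Discrete columns (``ntau``,
    ``signature``, ``t``) are excluded.  Requires at least 10 retained
    draws per summary column; a singular design falls back to the
    unadjusted values with a warning.
    """
    import statsmodels.api as sm

    n_r = posterior.n_retained
    p = len(posterior.summary_columns)
    if n_r < 10 * p:
        raise ValueError(f"regression adjustment needs >= {10 * p} "
                         f"retained draws for {p} summary columns; have "
                         f"{n_r}")
    retained = posterior.retained
    if params is None:
        skip = {"ntau", "signature", "t", "row"}
        params = [c for c in retained.columns
                  if c not in skip and not c.startswith(SUMMARY_PREFIX)
                  and pd.api.types.is_numeric_dtype(retained[c])]

    z = (retained[list(posterior.summary_columns)].to_numpy(dtype=float)
         - posterior.means) / posterior.sds
    dz = z - posterior.observed_std
    eps = posterior.epsilon
    if eps > 0:
        w = 1.0 - (posterior.distances / eps) ** 2
        w = np.clip(w, 1e-12, None)  # the boundary row keeps tiny weight
    else:
        w = np.ones(n_r)

    design = np.column_stack([np.ones(n_r), dz])
    adjusted = retained.copy()
    for col in params:
        y = retained[col].to_numpy(dtype=float)
        how = _transform_for(col, y)
        ty = _apply(y, how)
        try:
            fit = sm.WLS(ty, design, weights=w).fit()
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"adjustment of {col!r} failed ({exc}); "
                          "keeping unadjusted values", stacklevel=2)
            continue
        beta = fit.params[1:]
        ty_adj = ty - dz @ beta
        vals = _unapply(ty_adj, how)
        if how == "raw":
            lo = y.min()
            if lo >= 0:
                vals = np.clip(vals, 0.0, None)
        adjusted[col] = vals
    return replace(posterior, adjusted=adjusted)


def model_probabilities(posterior: PosteriorEstimate) -> dict:
    """Posterior pmfs over the number of divergence events and over
    unordered (and, when recorded, ordered) divergence models, from the
    unadjusted retained draws."""
    retained = posterior.retained
    if len(retained) == 0:
        raise ValueError("empty retained set")
    out: dict = {}
    ntau = retained["ntau"].astype(int)
    pmf_ntau = (ntau.value_counts(normalize=True).sort_index())
    out["ntau"] = {int(k): float(v) for k, v in pmf_ntau.items()}
    if "signature" in retained:
        pmf_sig = retained["signature"].value_counts(normalize=True)
        out["signature"] = {str(k): float(v) for k, v in pmf_sig.items()}
        best = sorted(out["signature"].items(),
                      key=lambda kv: (-kv[1], _sig_ntau(kv[0]), kv[0]))
        out["map_signature"] = best[0][0]
    if "t" in retained:
        pmf_t = retained["t"].value_counts(normalize=True)
        out["t"] = {str(k): float(v) for k, v in pmf_t.items()}
    out["map_ntau"] = int(min(
        (k for k, v in out["ntau"].items()
         if v == max(out["ntau"].values()))))
    return out


def _sig_ntau(signature: str) -> int:
    return len(signature.split("+"))


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing the requested mass of the
    empirical distribution."""
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for an HPD interval")
    m = max(1, int(math.ceil(mass * n)))
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize_posterior(posterior: PosteriorEstimate,
                        hpd_mass: float = 0.95) -> dict:
    """JSON-ready posterior summary: model pmfs, realized tolerance, and
    median + HPD for the continuous divergence-time summaries."""
    src = posterior.adjusted if posterior.adjusted is not None \
        else posterior.retained
    out = {
        "schema_version": SCHEMA_VERSION,
        "n_retained": posterior.n_retained,
        "epsilon": posterior.epsilon,
        "adjusted": posterior.adjusted is not None,
        "models": model_probabilities(posterior),
        "parameters": {},
    }
    for col in src.columns:
        if col in ("ntau", "signature", "t") or \
                col.startswith(SUMMARY_PREFIX):
            continue
        vals = src[col].to_numpy(dtype=float)
        if len(vals) >= 10:
            lo, hi = hpd_interval(vals, hpd_mass)
        else:
            lo = hi = float("nan")
        out["parameters"][col] = {
            "median": float(np.median(vals)),
            "hpd_low": lo,
            "hpd_high": hi,
        }
    return out
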