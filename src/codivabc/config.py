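"""Structured-text (YAML) configuration for analyses and experiments.

A config file has sections ``pairs``, ``priors``, ``model_prior``,
``abc``, and optionally ``experiment``.  Unknown keys anywhere are
errors: silent defaults hide typos in prior specifications.

Example::

    pairs: {Y: 8, n1: 10, n2: 10, length: 1000, kappa: 1.0}
    priors:
      tau: {dist: exponential, mean: 2.887}
      theta_d: {dist: exponential, mean: 0.025}
      zeta: {dist: beta, a: 1.0, b: 1.0}
      tau_b: {dist: uniform, low: 0.0, high: 1.0}
      migration: off
      mu: 1.0e-8
    model_prior: {kind: dpp, chi: [2.0, 2.0]}
    abc: {n_retain: 1000, ordering: pi_b_sorted, mean_across_loci: true}
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .coalescent import LocusSpec, PairSpec
from .partitions import ModelPriorSpec
from .priors import ConfigError, Distribution, PriorConfig

__all__ = ["AnalysisSettings", "ExperimentSettings", "FullConfig",
           "load_config", "parse_config", "ConfigError"]


def _require_keys(section: str, mapping: dict, allowed: set[str],
                  required: set[str] = frozenset()) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section "
                          f"{section!r}; allowed: {sorted(allowed)}")
    missing = required - set(mapping)
    if missing:
        raise ConfigError(f"section {section!r} is missing required "
                          f"key(s) {sorted(missing)}")


_DIST_KEYS = {
    "gamma": ("shape", "scale"),
    "exponential": ("mean",),
    "uniform": ("low", "high"),
    "beta": ("a", "b"),
}


def _parse_dist(name: str, node) -> Distribution | None:
    if node is None or node is False or node == "off":
        return None
    _require_keys(name, node, {"dist", *sum(_DIST_KEYS.values(), ())},
                  {"dist"})
    kind = node["dist"]
    if kind not in _DIST_KEYS:
        raise ConfigError(f"{name}: unknown distribution {kind!r}")
    keys = _DIST_KEYS[kind]
    extra = set(node) - {"dist", *keys}
    if extra:
        raise ConfigError(f"{name}: key(s) {sorted(extra)} do not apply "
                          f"to a {kind} distribution")
    try:
        params = tuple(float(node[k]) for k in keys)
    except KeyError as exc:
        raise ConfigError(f"{name}: missing parameter {exc}") from None
    return Distribution(kind, params)


@dataclass(frozen=True)
class AnalysisSettings:
    n_retain: int = 1000
    ordering_mode: str = "pi_b_sorted"
    mean_across_loci: bool = True

    def __post_init__(self) -> None:
        if self.n_retain < 1:
            raise ConfigError("n_retain must be >= 1")
        if self.ordering_mode not in ("ordered", "pi_b_sorted"):
            raise ConfigError(f"unknown ordering {self.ordering_mode!r}")


@dataclass(frozen=True)
class ExperimentSettings:
    n_prior: int = 20_000
    n_reps: int = 500

    def __post_init__(self) -> None:
        if self.n_prior < 1 or self.n_reps < 1:
            raise ConfigError("experiment sizes must be >= 1")


@dataclass(frozen=True)
class FullConfig:
    prior: PriorConfig
    pair_specs: tuple[PairSpec, ...]
    abc: AnalysisSettings
    experiment: ExperimentSettings


def _parse_pairs(node) -> tuple[PairSpec, ...]:
    if isinstance(node, list):
        pairs = []
        for i, p in enumerate(node):
            _require_keys(f"pairs[{i}]", p,
                          {"label", "n1", "n2", "loci"},
                          {"label", "n1", "n2", "loci"})
            loci = []
            for j, l in enumerate(p["loci"]):
                _require_keys(f"pairs[{i}].loci[{j}]", l,
                              {"locus_id", "length", "kappa", "freqs",
                               "rho", "nu"}, {"locus_id", "length"})
                loci.append(LocusSpec(
                    locus_id=str(l["locus_id"]),
                    length=int(l["length"]),
                    kappa=float(l.get("kappa", 1.0)),
                    freqs=tuple(l.get("freqs",
                                      (0.25, 0.25, 0.25, 0.25))),
                    rho=float(l.get("rho", 1.0)),
                    nu=float(l.get("nu", 1.0))))
            pairs.append(PairSpec(label=str(p["label"]), n1=int(p["n1"]),
                                  n2=int(p["n2"]), loci=tuple(loci)))
        return tuple(pairs)
    _require_keys("pairs", node,
                  {"Y", "n1", "n2", "n_loci", "length", "kappa", "freqs"},
                  {"Y"})
    from .experiments import default_pair_specs
    return default_pair_specs(
        int(node["Y"]), n1=int(node.get("n1", 10)),
        n2=int(node.get("n2", 10)), length=int(node.get("length", 1000)),
        kappa=float(node.get("kappa", 1.0)),
        freqs=tuple(node.get("freqs", (0.25, 0.25, 0.25, 0.25))),
        n_loci=int(node.get("n_loci", 1)))


def _parse_model_prior(node) -> ModelPriorSpec:
    _require_keys("model_prior", node, {"kind", "chi"}, {"kind"})
    kind = node["kind"]
    chi = node.get("chi")
    if isinstance(chi, list):
        chi = tuple(float(v) for v in chi)
    elif chi is not None:
        chi = float(chi)
    return ModelPriorSpec(kind, chi)


def parse_config(data: dict) -> FullConfig:
    _require_keys("<root>", data,
                  {"schema_version", "pairs", "priors", "model_prior",
                   "abc", "experiment"},
                  {"pairs", "priors", "model_prior"})
    pair_specs = _parse_pairs(data["pairs"])

    pr = data["priors"]
    _require_keys("priors", pr,
                  {"tau", "theta_d", "theta_a", "zeta", "tau_b",
                   "migration", "recombination", "alpha", "mu",
                   "theta_constraint", "zeta_constraint",
                   "msbayes_joint_theta_d"},
                  {"tau", "theta_d"})
    recomb = pr.get("recombination")
    if recomb not in (None, False, "off", 0):
        raise ConfigError(
            "a non-zero intra-locus recombination rate is accepted in the "
            "schema but not supported at runtime; set recombination: off")

    zeta_constraint = pr.get("zeta_constraint", "free")
    zeta_default = None if zeta_constraint == "off" \
        else Distribution("beta", (1.0, 1.0))
    taub_default = None if zeta_constraint == "off" \
        else Distribution("uniform", (0.0, 1.0))
    prior = PriorConfig(
        Y=len(pair_specs),
        tau_prior=_parse_dist("priors.tau", pr["tau"]),
        thetaD_prior=_parse_dist("priors.theta_d", pr["theta_d"]),
        thetaA_prior=_parse_dist("priors.theta_a", pr.get("theta_a")),
        zeta_prior=(_parse_dist("priors.zeta", pr["zeta"])
                    if "zeta" in pr else zeta_default),
        tauB_prior=(_parse_dist("priors.tau_b", pr["tau_b"])
                    if "tau_b" in pr else taub_default),
        migration_prior=_parse_dist("priors.migration",
                                    pr.get("migration")),
        alpha_prior=(_parse_dist("priors.alpha", pr["alpha"])
                     if "alpha" in pr
                     else Distribution("uniform", (1.0, 20.0))),
        model_prior=_parse_model_prior(data["model_prior"]),
        theta_constraint=pr.get("theta_constraint", "three_free"),
        zeta_constraint=zeta_constraint,
        msbayes_joint_thetaD=bool(pr.get("msbayes_joint_theta_d", False)),
        mu=float(pr.get("mu", 1e-8)),
    )

    abc_node = data.get("abc", {})
    _require_keys("abc", abc_node,
                  {"n_retain", "ordering", "mean_across_loci"})
    abc = AnalysisSettings(
        n_retain=int(abc_node.get("n_retain", 1000)),
        ordering_mode=abc_node.get("ordering", "pi_b_sorted"),
        mean_across_loci=bool(abc_node.get("mean_across_loci", True)))

    exp_node = data.get("experiment", {})
    _require_keys("experiment", exp_node, {"n_prior", "n_reps"})
    experiment = ExperimentSettings(
        n_prior=int(exp_node.get("n_prior", 20_000)),
        n_reps=int(exp_node.get("n_reps", 500)))

    return FullConfig(prior, pair_specs, abc, experiment)


def load_config(path) -> FullConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path} is not a YAML mapping")
    return parse_config(data)
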