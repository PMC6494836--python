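"""Monte-Carlo parameter ensembles over the pathway ODE models.

Kinetic constants for the THP pathways are only loosely pinned down by the
literature, so each scenario is run as an ensemble: every iteration draws the
named parameters uniformly (or log-uniformly) within configured ranges,
integrates the model over 0-50 h, and records the molar THP yield.  Scenario
comparisons (pathway topology x DHPAA drain x product feedback) are then made
on the box statistics of the yield distributions, not on single runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway_model import (PathwaySpec, SolverError, simulate, thp_yield_pct)


class RangeConfigError(ValueError):
    """A parameter range does not resolve to a numeric PathwaySpec field."""


@dataclass(frozen=True)
class ParameterRange:
    """A sampling range for one spec field, addressed by dotted path.

    ``name`` examples: ``"k_cond"``, ``"ddc.vmax"``, ``"mao.ki.amine"``.
    ``scale`` is ``"linear"`` (uniform) or ``"log"`` (log-uniform; requires
    ``low > 0``).
    """

    name: str
    low: float
    high: float
    scale: str = "linear"

    def __post_init__(self):
        if self.scale not in ("linear", "log"):
            raise RangeConfigError(f"unknown scale {self.scale!r}")
        if self.low > self.high:
            raise RangeConfigError(f"{self.name}: low > high")
        if self.scale == "log" and self.low <= 0:
            raise RangeConfigError(f"{self.name}: log scale requires low > 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.low == self.high:
            return float(self.low)
        if self.scale == "log":
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))


@dataclass
class EnsembleSpec:
    base: PathwaySpec
    ranges: list[ParameterRange]
    n_iter: int = 10_000
    t_end: float = 50.0
    seed: int | np.random.SeedSequence = 0

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        # fail fast on unresolvable paths
        probe = self.base.copy()
        for r in self.ranges:
            _set_field(probe, r.name, _get_field(probe, r.name))


@dataclass
class EnsembleSummary:
    """Per-iteration yields plus the box statistics used for comparison."""

    yields: np.ndarray
    median: float
    q1: float
    q3: float
    mean: float
    min: float
    max: float
    n_failed: int = 0
    warnings: list[str] = field(default_factory=list)


def _get_field(spec: PathwaySpec, path: str) -> float:
    obj = spec
    parts = path.split(".")
    try:
        for i, part in enumerate(parts):
            if isinstance(obj, dict):
                obj = obj[part]
            else:
                obj = getattr(obj, part)
            if obj is None and i < len(parts) - 1:
                raise AttributeError(part)
    except (AttributeError, KeyError) as exc:
        raise RangeConfigError(f"cannot resolve parameter path {path!r}") from exc
    if not isinstance(obj, (int, float)) or isinstance(obj, bool):
        raise RangeConfigError(f"parameter path {path!r} is not numeric")
    return float(obj)


def _set_field(spec: PathwaySpec, path: str, value: float) -> None:
    parts = path.split(".")
    obj = spec
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        if obj is None:
            raise RangeConfigError(f"cannot resolve parameter path {path!r}")
    leaf = parts[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise RangeConfigError(f"cannot resolve parameter path {path!r}")
        obj[leaf] = value
    else:
        if not hasattr(obj, leaf):
            raise RangeConfigError(f"cannot resolve parameter path {path!r}")
        setattr(obj, leaf, value)


def sample_parameters(ranges: list[ParameterRange], base: PathwaySpec,
                      rng: np.random.Generator) -> PathwaySpec:
    """Draw one PathwaySpec: a deep copy of ``base`` with each ranged field
    resampled, drawing in the listed order (the reproducibility contract)."""
    spec = base.copy()
    for r in ranges:
        _get_field(spec, r.name)  # validate path before mutating
        _set_field(spec, r.name, r.draw(rng))
    return spec


def summarize_ensemble(yields, n_failed: int = 0,
                       warnings: list[str] | None = None) -> EnsembleSummary:
    """Box statistics with the linear-interpolation percentile convention."""
    y = np.asarray(yields, dtype=float)
    if y.size == 0:
        raise ValueError("cannot summarize an empty yield list")
    q1, med, q3 = np.percentile(y, [25, 50, 75], method="linear")
    return EnsembleSummary(yields=y, median=float(med), q1=float(q1),
                           q3=float(q3), mean=float(np.mean(y)),
                           min=float(np.min(y)), max=float(np.max(y)),
                           n_failed=n_failed, warnings=list(warnings or []))


def run_ensemble(spec: EnsembleSpec, n_points: int = 2) -> EnsembleSummary:
    """Run the Monte-Carlo ensemble and summarize the THP yields.

    Failed integrations are excluded from the statistics and counted in
    ``n_failed``; a failure fraction above 1% raises a warning entry, and a
    fully failed ensemble is a hard error.  Only the final state matters for
    the yield, so trajectories are evaluated on a coarse output grid.
    """
    rng = np.random.default_rng(spec.seed)
    yields: list[float] = []
    n_failed = 0
    for _ in range(spec.n_iter):
        draw = sample_parameters(spec.ranges, spec.base, rng)
        try:
            traj = simulate(draw, t_end=spec.t_end, n_points=max(n_points, 2))
            yields.append(thp_yield_pct(traj))
        except SolverError:
            n_failed += 1
    if not yields:
        raise SolverError(f"all {spec.n_iter} ensemble integrations failed")
    warnings = []
    if n_failed > 0.01 * spec.n_iter:
        warnings.append(f"{n_failed}/{spec.n_iter} integrations failed (>1%)")
    return summarize_ensemble(yields, n_failed=n_failed, warnings=warnings)


def compare_scenarios(scenarios: list[tuple[str, EnsembleSpec]],
                      master_seed: int | None = None) -> pd.DataFrame:
    """Run labelled scenarios under independent RNG streams and tabulate.

    With ``master_seed`` given, each scenario receives a child stream spawned
    from one SeedSequence, so scenarios are mutually independent yet the whole
    comparison is reproducible from a single integer.  Rows keep the input
    order; the table is sorted by nothing so median orderings can be read off.
    """
    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios to compare")
    labels = [lab for lab, _ in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate scenario labels")
    if master_seed is not None:
        children = np.random.SeedSequence(master_seed).spawn(len(scenarios))
    else:
        children = [es.seed for _, es in scenarios]
    rows = []
    for (label, es), seed in zip(scenarios, children):
        es_run = EnsembleSpec(base=es.base, ranges=es.ranges, n_iter=es.n_iter,
                              t_end=es.t_end, seed=seed)
        s = run_ensemble(es_run)
        rows.append({"label": label, "median": s.median, "q1": s.q1,
                     "q3": s.q3, "mean": s.mean, "min": s.min, "max": s.max,
                     "n": len(s.yields), "n_failed": s.n_failed})
    return pd.DataFrame(rows)
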