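"""YAML round-trip for pathway specs and CSV round-trip for range tables."""

from __future__ import annotations

import yaml
import pandas as pd

from .monte_carlo import ParameterRange
from .pathway_model import PathwaySpec


def load_pathway_spec(path) -> PathwaySpec:
    with open(path) as fh:
        return PathwaySpec.from_dict(yaml.safe_load(fh))


def dump_pathway_spec(spec: PathwaySpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def load_ranges(path) -> list[ParameterRange]:
    """Read a range table CSV with columns name,low,high,scale."""
    df = pd.read_csv(path)
    return [ParameterRange(r["name"], float(r["low"]), float(r["high"]),
                           str(r.get("scale", "linear")))
            for r in df.to_dict("records")]


def dump_ranges(ranges: list[ParameterRange], path) -> None:
    pd.DataFrame([{"name": r.name, "low": r.low, "high": r.high,
                   "scale": r.scale} for r in ranges]).to_csv(path, index=False)
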