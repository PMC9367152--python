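"""Plain-text readers and writers for the pipeline's tabular artifacts.

Methylation matrices are tab-delimited (first column ``sample_id``, header
row of probe ids), gzipped when the path ends in ``.gz``.  Annotations,
phenotypes and probe sets are tab-delimited; simulation truth is a JSON
sidecar; configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MethylationMatrix, PhenotypeTable, ProbeSet
from .simulate import SimulationConfig, TraitSpec

__all__ = [
    "write_methylation", "read_methylation",
    "write_annotation", "read_annotation",
    "write_phenotypes", "read_phenotypes",
    "write_probe_sets", "read_probe_sets",
    "write_truth", "read_truth",
    "write_config", "read_config",
]


def write_methylation(meth: MethylationMatrix, path: str | Path) -> None:
    df = meth.values.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_methylation(path: str | Path, state: str = "raw") -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.columns.name = "probe_id"
    return MethylationMatrix(df, state=state)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pheno.data.copy()
    df.index.name = "sample_id"
    df.attrs["traits"] = pheno.traits
    df.to_csv(path, sep="\t")
    # trait list kept in a sidecar so the table alone stays standard TSV
    Path(str(path) + ".traits.json").write_text(json.dumps(pheno.traits))


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    sidecar = Path(str(path) + ".traits.json")
    if sidecar.exists():
        traits = json.loads(sidecar.read_text())
    else:
        from .containers import COVARIATE_COLUMNS
        traits = [c for c in df.columns if c not in COVARIATE_COLUMNS]
    return PhenotypeTable(df, traits=traits)


def write_probe_sets(sets: list[ProbeSet], path: str | Path) -> None:
    """Two-column (set name, probe id) table plus a JSON criteria manifest."""
    rows = [(s.name, p) for s in sets for p in s.probe_ids]
    pd.DataFrame(rows, columns=["set_name", "probe_id"]).to_csv(
        path, sep="\t", index=False)
    manifest = {s.name: dict(s.criteria) for s in sets}
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1))


def read_probe_sets(path: str | Path) -> list[ProbeSet]:
    df = pd.read_csv(path, sep="\t")
    manifest = json.loads(Path(str(path) + ".manifest.json").read_text())
    sets = []
    for name, grp in df.groupby("set_name", sort=False):
        sets.append(ProbeSet(name=str(name), criteria=manifest.get(str(name), {}),
                             probe_ids=[str(p) for p in grp["probe_id"]]))
    return sets


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, cls=_NumpyEncoder))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_config(config: SimulationConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["trait_specs"] = [dataclasses.asdict(t) for t in config.trait_specs]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def read_config(path: str | Path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    specs = [TraitSpec(**t) for t in d.pop("trait_specs", [])]
    d = _tupled(d, ("mqtl_r2_range", "maf_range", "sd_beta_range_hypo_hyper",
                    "sd_beta_range_intermediate", "age_r2_range",
                    "sex_r2_range"))
    cfg = SimulationConfig(trait_specs=specs, **d)
    cfg.validate()
    return cfg
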