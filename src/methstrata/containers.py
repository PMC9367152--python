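"""Shared in-memory containers for methylation matrices, phenotypes and probe sets.

All tabular data is held in pandas objects: a methylation matrix is a
samples x probes DataFrame of Beta-values (or residuals once adjusted),
phenotypes are a DataFrame with covariate columns plus one column per trait,
and probe annotations are a DataFrame indexed by probe id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: covariate columns every phenotype table carries
COVARIATE_COLUMNS = ("age", "sex", "height", "batch")

#: genomic feature categories used for annotation and enrichment
FEATURE_CATEGORIES = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1stExon",
    "Body",
    "3'UTR",
    "Intergenic",
)


class AlignmentError(ValueError):
    """Sample or probe identifiers of two objects do not line up."""


@dataclass
class MethylationMatrix:
    """Samples x probes matrix of methylation values.

    ``state`` is ``"raw"`` for Beta-values in [0, 1] and ``"residualized"``
    once probe values have been adjusted for covariates (then unbounded).
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "residualized"):
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr[~np.isnan(arr)])):
            raise ValueError("non-finite methylation values")
        if self.state == "raw":
            with np.errstate(invalid="ignore"):
                if np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0:
                    raise ValueError("raw Beta-values must lie in [0, 1]")

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylationMatrix":
        missing = [p for p in probe_ids if p not in self.values.columns]
        if missing:
            raise AlignmentError(f"probes absent from matrix: {missing[:5]}"
                                 + ("..." if len(missing) > 5 else ""))
        return MethylationMatrix(self.values.loc[:, list(probe_ids)], self.state)


@dataclass
class PhenotypeTable:
    """Sample-level table of trait values and covariates.

    ``data`` is indexed by sample id, with the covariate columns ``age``
    (years), ``sex`` (0/1 indicator), ``height`` (cm, may be absent) and
    ``batch`` (categorical label), plus one numeric column per trait.
    """

    data: pd.DataFrame
    traits: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def trait(self, name: str) -> pd.Series:
        if name not in self.traits and name != "age":
            raise KeyError(f"unknown trait {name!r}")
        return self.data[name] if name in self.data.columns else self.data["age"]

    def covariates(self) -> pd.DataFrame:
        cols = [c for c in COVARIATE_COLUMNS if c in self.data.columns]
        return self.data[cols]


@dataclass
class ProbeSet:
    """Named, ordered probe subset with machine-readable selection criteria."""

    name: str
    criteria: Mapping[str, object]
    probe_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError(f"probe set {self.name!r} contains duplicate ids")

    def __len__(self) -> int:
        return len(self.probe_ids)


#: columns a probe annotation table must provide
ANNOTATION_COLUMNS = (
    "on_450k",
    "on_epic",
    "cross_hybridising",
    "polymorphic_target",
    "mqtl",
    "ewas_catalog",
    "genomic_feature",
)


def check_annotation(annotation: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation lacks columns: {missing}")
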