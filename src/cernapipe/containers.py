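"""Core exchange object: an integer feature x sample count matrix with stage metadata."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Feature x sample counts plus per-sample (stage, replicate) metadata.

    ``counts``: DataFrame indexed by feature id, one column per sample id.
    ``samples``: DataFrame indexed by sample id with at least a ``stage``
    column; column order of ``counts`` and row order of ``samples`` agree and
    define the stage ordering used downstream.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count matrix columns and sample metadata disagree")
        if "stage" not in self.samples.columns or self.samples["stage"].isna().any():
            raise ValueError("every sample needs a stage label")
        if len(pd.unique(self.samples["stage"])) < 2:
            raise ValueError("at least two stages are required")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def stages(self) -> list[str]:
        """Stage labels in order of first appearance."""
        return list(pd.unique(self.samples["stage"]))

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in_stage(self, stage: str) -> list[str]:
        hits = [s for s in self.samples.index if self.samples.at[s, "stage"] == stage]
        if not hits:
            raise ValueError(f"stage {stage!r} absent from sample metadata")
        return hits

    def subset(self, features) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(features)], self.samples)

    def to_tsv(self, counts_path, meta_path) -> None:
        out = self.counts.copy()
        out.index.name = "feature"
        out.to_csv(counts_path, sep="\t")
        meta = self.samples.copy()
        meta.index.name = "sample"
        meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "CountMatrix":
        counts = pd.read_csv(Path(counts_path), sep="\t", index_col=0)
        meta = pd.read_csv(Path(meta_path), sep="\t", index_col=0, dtype={0: str})
        meta.index = meta.index.astype(str)
        counts.columns = counts.columns.astype(str)
        counts = counts[list(meta.index)].astype(np.int64)
        return cls(counts, meta)
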