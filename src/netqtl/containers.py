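"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "ModuleAssignment", "clr_transform", "log_relative"]


@dataclass
class AbundanceTable:
    """Samples x genera table of nonnegative counts with cohort metadata.

    ``counts`` has sample ids as the index and genus ids as columns.
    ``meta`` (optional) is indexed by sample id and may carry family id,
    affection group, covariates, etc.
    """

    counts: pd.DataFrame
    cohort: str | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise ValueError("abundance table must have >= 1 sample and >= 1 genus")
        if self.counts.columns.duplicated().any():
            raise ValueError("genus ids must be unique")
        if self.counts.index.duplicated().any():
            raise ValueError("sample ids must be unique")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("abundance counts must be nonnegative")
        if self.meta is not None:
            missing = self.counts.index.difference(self.meta.index)
            if len(missing):
                raise ValueError(f"meta missing {len(missing)} sample ids")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def genera(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def subset_genera(self, genera) -> "AbundanceTable":
        return AbundanceTable(self.counts.loc[:, list(genera)], self.cohort, self.meta)

    def subset_samples(self, samples) -> "AbundanceTable":
        meta = self.meta.loc[list(samples)] if self.meta is not None else None
        return AbundanceTable(self.counts.loc[list(samples)], self.cohort, meta)

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each genus is nonzero."""
        return (self.counts > 0).mean(axis=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path, cohort: str | None = None) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.round().astype(np.int64), cohort=cohort)


@dataclass
class ModuleAssignment:
    """Partition of genera into modules (label 0 = unassigned).

    Module labels are positive integers ordered by decreasing module size.
    ``params`` records the clustering provenance (beta, dissimilarity,
    min module size, deepSplit) so that downstream reports can state how
    the partition was obtained.
    """

    labels: pd.Series
    merge_heights: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        min_size = self.params.get("min_module_size")
        if min_size is not None:
            sizes = self.sizes()
            bad = {m: s for m, s in sizes.items() if s < min_size}
            if bad:
                raise ValueError(f"modules below min size {min_size}: {bad}")

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for genus, lab in self.labels.items():
            if lab > 0:
                out.setdefault(int(lab), []).append(genus)
        return {m: out[m] for m in sorted(out)}

    def sizes(self) -> dict[int, int]:
        return {m: len(g) for m, g in self.modules().items()}

    @property
    def n_modules(self) -> int:
        return len(self.modules())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"genus": self.labels.index, "module": self.labels.values})


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of a counts table (samples x genera).

    The CLR puts abundances on the same log-ratio scale on which the
    compositional correlations are estimated, and is invariant to
    per-sample sequencing depth.
    """
    logx = np.log(counts.to_numpy(dtype=float) + pseudocount)
    out = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def log_relative(counts: pd.DataFrame, scale: float = 1e4, pseudocount: float = 1.0) -> pd.DataFrame:
    """log(1 + relative abundance * scale): depth-normalised log counts."""
    vals = counts.to_numpy(dtype=float)
    depth = vals.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    return pd.DataFrame(
        np.log(pseudocount + vals / depth * scale),
        index=counts.index,
        columns=counts.columns,
    )
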