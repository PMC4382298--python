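"""Parametric Analysis of Gene set Enrichment (PAGE).

For a gene set with m measured members in a study, the PAGE statistic is

    Z = (Sm − μ) · √m / δ

where Sm is the mean log2 fold change over the m member genes, and μ and δ
are the mean and sample standard deviation (n−1 denominator) of the log2
fold changes over all measured genes in that study. Under a null in which
member genes are exchangeable with the rest of the transcriptome, Z is
approximately standard normal for moderate m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError
from .gsets import GeneSetCollection
from .probes import DifferentialResult


def page_zscore(diff: "DifferentialResult | pd.Series", members: Iterable[str]) -> float:
    """PAGE Z-score of one gene set in one study.

    ``diff`` may be a DifferentialResult or a Series of log2 fold changes
    indexed by gene. Only members measured in the study enter Sm; at least
    one member must be measured.
    """
    fc = diff.fold_changes if isinstance(diff, DifferentialResult) else diff
    fc = fc.dropna()
    if len(fc) < 2:
        raise ConfigError("need at least two measured genes")
    member_fc = fc.loc[fc.index.intersection(pd.Index(list(members)))]
    m = len(member_fc)
    if m < 1:
        raise ConfigError("no gene-set member measured in this study")
    mu = float(fc.mean())
    delta = float(fc.std(ddof=1))
    if delta == 0.0:
        raise DegenerateInputError("all fold changes identical; Z undefined")
    return float((member_fc.mean() - mu) * np.sqrt(m) / delta)


@dataclass
class ZScoreMatrix:
    """Terms × studies matrix of PAGE Z-scores with explicit missingness.

    A cell is missing (NaN) when the term's effective size in that study
    falls outside the configured bounds or no member is measured; 0 is a
    valid Z and is never used as a missing marker. ``effective_sizes``
    mirrors the matrix with the per-cell member counts, and
    ``universe_sizes`` records each study's measured-gene count.
    """

    z: pd.DataFrame  # terms × studies, NaN = missing
    effective_sizes: pd.DataFrame  # terms × studies, int counts
    universe_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if not np.isfinite(self.z.to_numpy()[~np.isnan(self.z.to_numpy())]).all():
            raise ConfigError("non-missing Z cells must be finite")
        all_missing = self.z.isna().all(axis=1)
        if all_missing.any():
            self.z = self.z.loc[~all_missing]
            self.effective_sizes = self.effective_sizes.loc[self.z.index]

    @property
    def terms(self) -> pd.Index:
        return self.z.index

    @property
    def studies(self) -> pd.Index:
        return self.z.columns

    def n_studies_per_term(self) -> pd.Series:
        return self.z.notna().sum(axis=1)


def page_matrix(
    diffs: Sequence[DifferentialResult],
    collection: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 1000,
    depth_range: tuple[int, int] = (3, 5),
) -> ZScoreMatrix:
    """PAGE Z-scores for every retained term in every study.

    Terms whose ontology depth falls outside ``depth_range`` are dropped
    entirely (non-specific shallow terms and over-specific deep ones).
    Within each study, a term is computed only when its effective size —
    members intersected with that study's measured genes — lies in
    [``min_size``, ``max_size``]; otherwise the cell is missing. The size
    filter is per study because platforms measure different gene subsets.
    """
    if len(diffs) < 1:
        raise ConfigError("need at least one study")
    if len(collection) == 0:
        raise ConfigError("empty gene-set collection")
    lo, hi = depth_range
    terms = [t for t in collection.term_ids if lo <= collection.depth.get(t, 0) <= hi]
    if not terms:
        raise ConfigError("all terms removed by the depth filter")

    study_ids = [d.study_id for d in diffs]
    z = np.full((len(terms), len(diffs)), np.nan)
    eff = np.zeros((len(terms), len(diffs)), dtype=int)
    universe: dict[str, int] = {}

    for j, diff in enumerate(diffs):
        fc = diff.fold_changes.dropna()
        universe[diff.study_id] = len(fc)
        fc_values = fc.to_numpy(dtype=float)
        mu = fc_values.mean()
        delta = fc_values.std(ddof=1)
        if delta == 0.0:
            raise DegenerateInputError(
                f"study {diff.study_id}: all fold changes identical; Z undefined"
            )
        pos = pd.Series(np.arange(len(fc)), index=fc.index)
        for i, term in enumerate(terms):
            idx = pos.reindex(list(collection.sets[term])).dropna().to_numpy(dtype=int)
            m = len(idx)
            eff[i, j] = m
            if m < min_size or m > max_size:
                continue
            z[i, j] = (fc_values[idx].mean() - mu) * np.sqrt(m) / delta

    zf = pd.DataFrame(z, index=pd.Index(terms, name="term_id"), columns=study_ids)
    if zf.isna().all(axis=1).all():
        raise ConfigError("size/depth filters removed every term in every study")
    ef = pd.DataFrame(eff, index=zf.index.copy(), columns=study_ids)
    return ZScoreMatrix(z=zf, effective_sizes=ef, universe_sizes=universe)
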