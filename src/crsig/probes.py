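"""Probe-level preprocessing and per-study differential statistics.

Microarray signal matrices arrive probe-level; the pipeline reduces them to
one row per gene (keeping, for multi-probe genes, the probe with the largest
mean intensity, and discarding unannotated or ambiguously annotated probes)
and then computes per-gene log2 fold changes and Welch t-tests between the
control and treated groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateInputError

GROUPS = ("control", "treated")


def _validate_groups(groups: pd.Series, columns: pd.Index, min_per_group: int = 2) -> pd.Series:
    groups = groups.reindex(columns)
    if groups.isna().any():
        raise ConfigError("every sample column needs a group label")
    bad = sorted(set(groups) - set(GROUPS))
    if bad:
        raise ConfigError(f"unknown group labels {bad}; expected {GROUPS}")
    for g in GROUPS:
        if (groups == g).sum() < min_per_group:
            raise ConfigError(f"group {g!r} has fewer than {min_per_group} samples")
    return groups


@dataclass
class ProbeTable:
    """Probe-level signal matrix plus probe→gene annotation.

    ``annotation`` is a two-column frame (probe_id, gene_id); a probe
    annotated to several genes appears on several rows, an unannotated
    probe on none.
    """

    signal: pd.DataFrame  # probes × samples, linear intensities
    groups: pd.Series  # sample -> control/treated
    annotation: pd.DataFrame  # columns probe_id, gene_id

    def __post_init__(self) -> None:
        if self.signal.index.has_duplicates:
            raise ConfigError("probe IDs must be unique")
        if (self.signal.to_numpy() <= 0).any():
            raise ConfigError("intensities must be positive (linear scale)")
        self.groups = _validate_groups(self.groups, self.signal.columns)
        self.annotation = self.annotation[["probe_id", "gene_id"]].astype(str)


@dataclass
class ExpressionStudy:
    """One study's gene-level signal matrix with group labels.

    The unit the source studies call a "tissue" or "dataset": a single
    two-group (control vs treated) experiment on one platform.
    """

    study_id: str
    signal: pd.DataFrame  # genes × samples, linear intensities
    groups: pd.Series  # sample -> control/treated
    label: str = ""  # species/tissue descriptor

    def __post_init__(self) -> None:
        if self.signal.index.has_duplicates:
            raise ConfigError(f"study {self.study_id}: gene IDs must be unique")
        self.groups = _validate_groups(self.groups, self.signal.columns, min_per_group=1)

    @property
    def genes(self) -> pd.Index:
        return self.signal.index

    def group_matrix(self, group: str) -> pd.DataFrame:
        return self.signal.loc[:, self.groups[self.groups == group].index]


@dataclass
class DifferentialResult:
    """Per-gene differential statistics for one study.

    ``table`` is indexed by gene and carries log2 fold change
    (treated − control on log2 signals), Welch t, two-sided p, the sign of
    the fold change, and a flag for degenerate (zero-spread) genes.
    """

    study_id: str
    table: pd.DataFrame  # columns: log2fc, t, p, direction, degenerate
    label: str = ""

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def fold_changes(self) -> pd.Series:
        return self.table["log2fc"]


def collapse_probes(probes: ProbeTable, study_id: str = "study", label: str = "") -> ExpressionStudy:
    """Reduce a probe-level matrix to one row per gene.

    Probes with no gene annotation are removed; probes annotated to more
    than one gene are removed; when a gene retains several probes, the one
    with the largest mean intensity across all samples in the study is
    kept (ties broken by lexicographically smallest probe_id).
    """
    ann = probes.annotation
    n_genes_per_probe = ann.groupby("probe_id")["gene_id"].nunique()
    unique_probes = n_genes_per_probe[n_genes_per_probe == 1].index
    keep = ann[ann["probe_id"].isin(unique_probes)].drop_duplicates()
    keep = keep[keep["probe_id"].isin(probes.signal.index)]
    if keep.empty:
        raise ConfigError("no annotatable probes after filtering")

    mean_int = probes.signal.mean(axis=1)
    keep = keep.assign(mean_intensity=keep["probe_id"].map(mean_int))
    # max mean intensity wins; ties go to the lexicographically smallest probe
    keep = keep.sort_values(
        ["gene_id", "mean_intensity", "probe_id"], ascending=[True, False, True]
    )
    best = keep.groupby("gene_id", sort=True).first()

    matrix = probes.signal.loc[best["probe_id"].to_numpy()]
    matrix.index = pd.Index(best.index, name="gene_id")
    return ExpressionStudy(study_id=study_id, signal=matrix, groups=probes.groups, label=label)


def differential_stats(study: ExpressionStudy) -> DifferentialResult:
    """Welch two-sample t-test on log2 signals, gene by gene.

    log2 fold change = mean(log2 treated) − mean(log2 control). Degenerate
    genes (zero within-group variance in both groups) get t = 0, p = 1 when
    the group means are equal and p = 0 (flagged) when they differ.
    """
    treated = np.log2(study.group_matrix("treated").to_numpy(dtype=float))
    control = np.log2(study.group_matrix("control").to_numpy(dtype=float))
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ConfigError("differential_stats needs >= 2 samples per group")

    log2fc = treated.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance rows handled below
        t, p = stats.ttest_ind(treated, control, axis=1, equal_var=False)

    var_t = treated.var(axis=1, ddof=1)
    var_c = control.var(axis=1, ddof=1)
    degenerate = (var_t == 0) & (var_c == 0)
    same = degenerate & (log2fc == 0)
    diff = degenerate & (log2fc != 0)
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    if diff.any():
        t[diff] = np.sign(log2fc[diff]) * np.inf
        p[diff] = 0.0

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "direction": np.sign(log2fc).astype(int),
            "degenerate": degenerate,
        },
        index=study.genes.copy(),
    )
    return DifferentialResult(study_id=study.study_id, table=table, label=study.label)


def gene_consensus(
    results: list[DifferentialResult],
    p_max: float = 0.05,
    min_studies: int | None = None,
) -> pd.DataFrame:
    """Genes consistently differentially expressed across studies.

    A gene is reported when it is significant (p < ``p_max``) in at least
    ``min_studies`` studies and its fold-change direction agrees across all
    studies where it is significant. Genes measured in fewer than
    ``min_studies`` studies are excluded. ``min_studies`` defaults to
    ceil(n_studies · 5/8), generalising a 5-of-8 majority rule.
    """
    if len(results) < 2:
        raise ConfigError("gene_consensus needs at least two studies")
    n_studies = len(results)
    if min_studies is None:
        min_studies = math.ceil(n_studies * 5 / 8)
    if min_studies > n_studies:
        raise ConfigError(f"min_studies={min_studies} exceeds the {n_studies} studies provided")

    p = pd.DataFrame({r.study_id: r.table["p"] for r in results})
    direction = pd.DataFrame({r.study_id: r.table["direction"] for r in results})

    measured = p.notna()
    sig = (p < p_max) & measured
    n_sig = sig.sum(axis=1)

    sig_dir = direction.where(sig)
    consistent = (sig_dir.nunique(axis=1, dropna=True) == 1) & (n_sig > 0)
    keep = (measured.sum(axis=1) >= min_studies) & (n_sig >= min_studies) & consistent

    if not keep.any():
        out = pd.DataFrame(columns=["n_significant", "consensus_direction"])
    else:
        shared = sig_dir[keep].apply(lambda row: int(row.dropna().iloc[0]), axis=1)
        out = pd.DataFrame(
            {"n_significant": n_sig[keep].astype(int), "consensus_direction": shared}
        )
    out.index.name = "gene_id"
    return out.sort_index()
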