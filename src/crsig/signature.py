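"""Cross-study consensus signature detection.

Each term's PAGE Z-scores across studies are tested against zero with a
two-sided one-sample t-test; Benjamini–Hochberg correction is applied over
all tested terms, and a term enters the signature when its adjusted p-value
falls below ``p_adj_max`` AND the median Z over studies clears
``z_median_min`` in magnitude. The median filter guarantees that at least
half of the studies individually show a strong effect on the term; the
default 2.58 is the conventional |Z| cutoff used by the screening
procedure, and 0.00285 the companion FDR cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .page import ZScoreMatrix


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ConfigError("bh_adjust expects a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_z(zmat: ZScoreMatrix, study_subset=None) -> pd.Series:
    """Per-term median Z over the non-missing cells of a study subset.

    Terms missing everywhere in the subset get NaN. The subset defaults to
    all studies. Even counts use the mean-of-middle-two convention.
    """
    cols = list(zmat.studies) if study_subset is None else list(study_subset)
    if not cols:
        raise ConfigError("study subset must be non-empty")
    missing = [c for c in cols if c not in zmat.studies]
    if missing:
        raise ConfigError(f"studies not in matrix: {missing}")
    med = zmat.z[cols].median(axis=1, skipna=True)
    med.name = "median_z"
    return med


def consensus_signature(
    zmat: ZScoreMatrix,
    p_adj_max: float = 0.00285,
    z_median_min: float = 2.58,
    min_studies: int = 2,
) -> pd.DataFrame:
    """Signature table of per-term consensus statistics.

    Terms with Z in fewer than ``min_studies`` studies are excluded before
    testing (so BH runs over exactly the tested set). Zero-variance rows
    with a non-zero mean are maximal evidence for a constant cross-study
    effect: they get p = 0 and are flagged degenerate rather than dropped.
    Zero-variance rows with zero mean carry no evidence and are excluded.

    Returns a frame indexed by term with columns median_z, n_studies, t, p,
    p_adj, passed, direction, degenerate, sorted by direction then
    median Z (descending).
    """
    if len(zmat.studies) < 2:
        raise ConfigError("consensus_signature needs at least two studies")
    if min_studies > len(zmat.studies):
        raise ConfigError(
            f"min_studies={min_studies} exceeds the {len(zmat.studies)} studies in the matrix"
        )

    n_per_term = zmat.n_studies_per_term()
    tested = zmat.z.loc[n_per_term >= min_studies]
    if tested.empty:
        raise ConfigError("no term has Z-scores in enough studies")

    values = tested.to_numpy(dtype=float)
    med = np.nanmedian(values, axis=1)
    n = (~np.isnan(values)).sum(axis=1)
    sd = np.array([np.nanstd(row, ddof=1) for row in values])

    constant = sd == 0
    drop = constant & (med == 0)
    tested = tested.loc[~drop]
    values, med, n, constant = values[~drop], med[~drop], n[~drop], constant[~drop]
    if tested.empty:
        raise ConfigError("no testable term rows remain")

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant rows handled below
        t, p = stats.ttest_1samp(values, popmean=0.0, axis=1, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    t[constant] = np.sign(med[constant]) * np.inf
    p[constant] = 0.0

    p_adj = bh_adjust(p)
    passed = (p_adj < p_adj_max) & (np.abs(med) >= z_median_min) & (n >= min_studies)
    direction = np.where(med > 0, "up", "down")

    out = pd.DataFrame(
        {
            "median_z": med,
            "n_studies": n.astype(int),
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "passed": passed,
            "direction": direction,
            "degenerate": constant,
        },
        index=tested.index.copy(),
    )
    # up block first, strongest terms at the top of each block
    out = out.sort_values(["direction", "median_z"], ascending=[False, False])
    return out
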