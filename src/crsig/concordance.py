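"""Concordance between two median-Z signature vectors.

The agreement between two groups of studies (e.g., mouse CR tissues versus
non-mouse CR datasets) is summarised by the Spearman correlation of their
per-term median PAGE Z-scores. Four resampling schemes attach uncertainty:

1. permutation — shuffle the pairing of terms; Monte Carlo p-value;
2. pair bootstrap — resample terms with replacement; percentile CI;
3. model-based permutation — simulate both vectors as zero-mean Gaussians
   whose term-by-term correlation is the overlap-induced null correlation
   overlap(i,j)/√(size_i·size_j), injected through a Cholesky factor;
4. model-based bootstrap — as 3, but centred on the componentwise average
   of the two observed vectors; percentile CI.

The model-based schemes exist because GO-style collections share genes
between terms: shared members correlate the Z-scores of otherwise null
terms, which widens the null spread of the correlation statistic relative
to a naive permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateInputError
from .gsets import GeneSetCollection

_EIG_CLIP = 1e-8


@dataclass
class OverlapCorrelationMatrix:
    """Predicted null correlation of gene-set Z-scores from member overlap.

    Entry (i, j) = overlap(i, j) / sqrt(size_i * size_j); unit diagonal.
    The raw matrix is not guaranteed positive semidefinite for arbitrary
    overlap patterns, so eigenvalues are clipped and the matrix rescaled to
    unit diagonal when needed; the repair is recorded.
    """

    matrix: pd.DataFrame
    clipped: bool = False
    min_eigenvalue: float = float("nan")

    @property
    def terms(self) -> pd.Index:
        return self.matrix.index

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def subset(self, terms) -> "OverlapCorrelationMatrix":
        sub = self.matrix.loc[terms, terms]
        return OverlapCorrelationMatrix(sub, self.clipped, self.min_eigenvalue)

    def cholesky(self) -> np.ndarray:
        c = self.values()
        try:
            return np.linalg.cholesky(c + _EIG_CLIP * np.eye(len(c)))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - post-repair failure
            raise DegenerateInputError(
                f"Cholesky failed after PSD repair (min eigenvalue {self.min_eigenvalue:g})"
            ) from exc


@dataclass
class ConcordanceResult:
    """Spearman r plus scheme-specific significance or CI, with provenance."""

    r: float
    scheme: str
    n_terms: int
    n_resamples: int
    seed: int
    p: float | None = None
    ci: tuple[float, float] | None = None
    level: float | None = None
    alternative: str = "greater"
    n_dropped: int = 0
    n_degenerate_redrawn: int = 0

    def to_dict(self) -> dict:
        d = {
            "r": self.r,
            "scheme": self.scheme,
            "n_terms": self.n_terms,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "alternative": self.alternative,
            "n_dropped": self.n_dropped,
        }
        if self.p is not None:
            d["p"] = self.p
        if self.ci is not None:
            d["ci"] = list(self.ci)
            d["level"] = self.level
        if self.n_degenerate_redrawn:
            d["n_degenerate_redrawn"] = self.n_degenerate_redrawn
        return d


def _align(a, b) -> tuple[np.ndarray, np.ndarray, pd.Index | None, int]:
    """Pairwise-complete alignment shared by all four schemes."""
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        common = a.index.intersection(b.index)
        dropped = len(a.index.union(b.index)) - len(common)
        a, b = a.loc[common], b.loc[common]
        mask = a.notna() & b.notna()
        dropped += int((~mask).sum())
        return (
            a[mask].to_numpy(dtype=float),
            b[mask].to_numpy(dtype=float),
            common[mask.to_numpy()],
            dropped,
        )
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ConfigError("vectors must have equal length")
    mask = ~(np.isnan(av) | np.isnan(bv))
    return av[mask], bv[mask], None, int((~mask).sum())


def _check_length(av: np.ndarray) -> None:
    if len(av) < 3:
        raise ConfigError("need at least 3 pairwise-complete term pairs")


def spearman(a, b) -> float:
    """Spearman rank correlation: Pearson on average (mid-) ranks.

    Entries missing in either vector are dropped pairwise; Series inputs
    are aligned on their term index first.
    """
    av, bv, _, _ = _align(a, b)
    _check_length(av)
    ra = stats.rankdata(av)
    rb = stats.rankdata(bv)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise DegenerateInputError("constant vector after rank transform")
    return float(np.corrcoef(ra, rb)[0, 1])


def _spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman for stacks of paired vectors (resampling loops)."""
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def permutation_test(a, b, n_perm: int = 999, seed: int = 0, alternative: str = "greater") -> ConcordanceResult:
    """Scheme 1: shuffle the term pairing of b against a fixed a.

    One-sided (positive concordance) by default; the add-one estimator
    p = (1 + #{r* ≥ r_obs}) / (n_perm + 1) never returns 0, with floor
    1/(n_perm+1) (0.001 at 999 permutations).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    av, bv, _, dropped = _align(a, b)
    _check_length(av)
    r_obs = spearman(av, bv)
    rng = np.random.default_rng(seed)
    rb = stats.rankdata(bv)
    perms = rng.permuted(np.tile(rb, (n_perm, 1)), axis=1)
    r_null = _spearman_rows(np.tile(stats.rankdata(av), (n_perm, 1)), perms)
    p = _mc_pvalue(r_obs, r_null, alternative)
    return ConcordanceResult(
        r=r_obs, scheme="permutation", n_terms=len(av), n_resamples=n_perm,
        seed=seed, p=p, alternative=alternative, n_dropped=dropped,
    )


def _mc_pvalue(r_obs: float, r_null: np.ndarray, alternative: str) -> float:
    if alternative == "greater":
        extreme = np.sum(r_null >= r_obs)
    elif alternative == "two-sided":
        extreme = np.sum(np.abs(r_null) >= abs(r_obs))
    else:
        raise ConfigError(f"unknown alternative {alternative!r}")
    return float((1 + extreme) / (len(r_null) + 1))


def pair_bootstrap(a, b, n_boot: int = 1000, seed: int = 0, level: float = 0.95) -> ConcordanceResult:
    """Scheme 2: resample terms with replacement; percentile CI for r.

    Resamples whose rank vectors are degenerate (a constant vector after
    resampling) are redrawn; the redraw count is recorded.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    av, bv, _, dropped = _align(a, b)
    _check_length(av)
    r_obs = spearman(av, bv)
    rng = np.random.default_rng(seed)
    n = len(av)

    r_boot = np.empty(n_boot)
    filled = 0
    redrawn = 0
    while filled < n_boot:
        todo = n_boot - filled
        idx = rng.integers(0, n, size=(todo, n))
        r = _spearman_rows(av[idx], bv[idx])
        ok = np.isfinite(r)
        redrawn += int((~ok).sum())
        k = int(ok.sum())
        r_boot[filled : filled + k] = r[ok]
        filled += k
    lo, hi = np.quantile(r_boot, [(1 - level) / 2, 1 - (1 - level) / 2])
    return ConcordanceResult(
        r=r_obs, scheme="pair_bootstrap", n_terms=n, n_resamples=n_boot, seed=seed,
        ci=(float(lo), float(hi)), level=level, n_dropped=dropped,
        n_degenerate_redrawn=redrawn,
    )


def overlap_correlation(collection: GeneSetCollection, term_list) -> OverlapCorrelationMatrix:
    """Overlap-induced null correlation matrix for a list of terms.

    Sizes are the nominal annotation sizes within the analysed universe
    (one matrix must serve both study groups). If the raw matrix is not
    PSD, eigenvalues are clipped at 1e-8 and the result rescaled back to
    unit diagonal.
    """
    terms = list(term_list)
    missing = [t for t in terms if t not in collection]
    if missing:
        raise ConfigError(f"terms not in collection: {missing[:5]}")
    k = len(terms)
    sizes = np.array([collection.size(t) for t in terms], dtype=float)
    c = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            c[i, j] = c[j, i] = collection.overlap(terms[i], terms[j]) / np.sqrt(
                sizes[i] * sizes[j]
            )
    eig = np.linalg.eigvalsh(c)
    min_eig = float(eig[0])
    clipped = min_eig < _EIG_CLIP
    if clipped:
        w, v = np.linalg.eigh(c)
        w = np.clip(w, _EIG_CLIP, None)
        c = (v * w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
    idx = pd.Index(terms, name="term_id")
    return OverlapCorrelationMatrix(
        matrix=pd.DataFrame(c, index=idx, columns=idx),
        clipped=clipped,
        min_eigenvalue=min_eig,
    )


def _aligned_corr(
    a, b, corr: OverlapCorrelationMatrix
) -> tuple[np.ndarray, np.ndarray, OverlapCorrelationMatrix, int]:
    av, bv, common, dropped = _align(a, b)
    _check_length(av)
    if common is not None:
        corr = corr.subset(common)
    if corr.matrix.shape[0] != len(av):
        raise ConfigError("correlation matrix dimension must equal the common term count")
    return av, bv, corr, dropped


def model_permutation(
    a, b, corr: OverlapCorrelationMatrix, n_sim: int = 999, seed: int = 0,
    alternative: str = "greater",
) -> ConcordanceResult:
    """Scheme 3: Gaussian null with overlap-induced term correlation.

    Each iteration draws two independent zero-mean Gaussian vectors, each
    with covariance equal to ``corr`` (via its Cholesky factor), and
    records their Spearman correlation; add-one Monte Carlo p of the
    observed r against this null sample.
    """
    if n_sim < 1:
        raise ConfigError("n_sim must be >= 1")
    av, bv, corr, dropped = _aligned_corr(a, b, corr)
    r_obs = spearman(av, bv)
    rng = np.random.default_rng(seed)
    L = corr.cholesky()
    k = len(av)
    draws = rng.standard_normal((n_sim, 2, k)) @ L.T
    r_null = _spearman_rows(draws[:, 0, :], draws[:, 1, :])
    p = _mc_pvalue(r_obs, r_null, alternative)
    return ConcordanceResult(
        r=r_obs, scheme="model_permutation", n_terms=k, n_resamples=n_sim, seed=seed,
        p=p, alternative=alternative, n_dropped=dropped,
    )


def model_bootstrap(
    a, b, corr: OverlapCorrelationMatrix, n_sim: int = 1000, seed: int = 0,
    level: float = 0.95,
) -> ConcordanceResult:
    """Scheme 4: as scheme 3 but centred on the componentwise mean (a+b)/2.

    Simulates the sampling distribution of r around the shared signal and
    returns a percentile CI. If both observed vectors are constant (all
    zeros, say) the observed r is undefined and recorded as NaN, but the
    mean vector is still well defined and the scheme degenerates to the
    scheme-3 null: the CI then spans the null spread.
    """
    if n_sim < 1:
        raise ConfigError("n_sim must be >= 1")
    av, bv, corr, dropped = _aligned_corr(a, b, corr)
    try:
        r_obs = spearman(av, bv)
    except DegenerateInputError:
        r_obs = float("nan")
    rng = np.random.default_rng(seed)
    L = corr.cholesky()
    k = len(av)
    mean = (av + bv) / 2.0
    draws = rng.standard_normal((n_sim, 2, k)) @ L.T + mean
    r_sim = _spearman_rows(draws[:, 0, :], draws[:, 1, :])
    lo, hi = np.quantile(r_sim, [(1 - level) / 2, 1 - (1 - level) / 2])
    return ConcordanceResult(
        r=r_obs, scheme="model_bootstrap", n_terms=k, n_resamples=n_sim, seed=seed,
        ci=(float(lo), float(hi)), level=level, n_dropped=dropped,
    )
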