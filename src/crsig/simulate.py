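"""Synthetic multi-study expression data with known signature truth.

Emulates the input side of a cross-tissue caloric-restriction compendium:
several two-group studies sharing one gene-set collection, log-normal-like
signal intensities, a subset of terms carrying coherent per-gene log2
shifts (up or down) realised in a configurable fraction of studies, and
pairwise-overlapping gene sets. Everything downstream of MAS5-style signal
summarisation is emulated; probe-level artifacts are not.

Signals are generated in log2 space (baseline + effect + noise) and
anti-logged, matching the linear-intensity input contract of the
differential module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .errors import ConfigError
from .gsets import GeneSetCollection
from .probes import ExpressionStudy


@dataclass
class SimulationConfig:
    """Parameters of the synthetic compendium.

    Gene-set structure: ``n_terms`` terms with sizes uniform in
    ``set_size_range``; consecutive terms form designated pairs that share
    round(overlap_fraction · min(size_i, size_j)) genes; all other term
    pairs are disjoint. Effects: a fraction ``signal_term_fraction`` of
    terms shift all their member genes by ±``effect_size`` log2 units in
    the treated group, in round(study_penetrance · n_studies) studies.
    """

    n_genes: int = 5000
    n_terms: int = 100
    set_size_range: tuple[int, int] = (10, 30)
    overlap_fraction: float = 0.25
    n_studies: int = 8
    n_control: int = 5
    n_treated: int = 5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.25
    effect_size: float = 0.5
    signal_term_fraction: float = 0.1
    study_penetrance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_terms": self.n_terms,
            "n_studies": self.n_studies, "n_control": self.n_control,
            "n_treated": self.n_treated,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        lo, hi = self.set_size_range
        if lo < 2 or hi < lo:
            raise ConfigError(f"set_size_range min must be >= 2 and <= max, got {self.set_size_range}")
        if not (0 <= self.overlap_fraction < 1):
            raise ConfigError("overlap_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not (0 <= self.signal_term_fraction <= 1):
            raise ConfigError("signal_term_fraction must lie in [0, 1]")
        if not (0 <= self.study_penetrance <= 1):
            raise ConfigError("study_penetrance must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated compendium.

    ``term_effects`` maps every term to (direction ∈ {+1, −1, 0}, per-gene
    log2 shift magnitude); ``gene_effects`` maps (study_id, gene_id) to the
    realised log2 shift in the treated group; null terms (direction 0)
    contain no shifted gene in any study.
    """

    term_effects: dict[str, tuple[int, float]]
    study_penetrance: float
    gene_effects: dict[tuple[str, str], float]
    seed: int

    def signal_terms(self) -> list[str]:
        return [t for t, (d, _) in self.term_effects.items() if d != 0]

    def direction_vector(self, terms=None) -> pd.Series:
        terms = list(self.term_effects) if terms is None else list(terms)
        return pd.Series({t: self.term_effects[t][0] for t in terms}, name="direction")

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "study_penetrance": self.study_penetrance,
            "term_effects": {t: [d, m] for t, (d, m) in self.term_effects.items()},
            "gene_effects": [
                {"study_id": s, "gene_id": g, "shift": v}
                for (s, g), v in sorted(self.gene_effects.items())
            ],
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SyntheticTruth":
        return cls(
            term_effects={t: (int(v[0]), float(v[1])) for t, v in d["term_effects"].items()},
            study_penetrance=float(d["study_penetrance"]),
            gene_effects={
                (r["study_id"], r["gene_id"]): float(r["shift"]) for r in d["gene_effects"]
            },
            seed=int(d["seed"]),
        )


def _gene_id(i: int) -> str:
    # Entrez-style numeric identifiers, treated as opaque strings downstream
    return str(100000 + i)


def simulate_collection(config: SimulationConfig) -> GeneSetCollection:
    """Build an overlapping gene-set collection from the shared gene pool.

    Consecutive terms (T0001,T0002), (T0003,T0004), ... are designated
    pairs sharing exactly round(overlap_fraction · min(size_i, size_j))
    genes; all other pairs are disjoint. Ontology depths are assigned
    uniformly in {3, 4, 5}. Raises a configuration error naming the first
    pair for which the gene pool cannot supply the requested sizes.
    """
    rng = stage_rng(config.seed, "collection")
    lo, hi = config.set_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_terms)
    depths = rng.choice([3, 4, 5], size=config.n_terms)

    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    depth: dict[str, int] = {}
    cursor = 0

    def take(n: int, pair: tuple[str, ...]) -> list[str]:
        nonlocal cursor
        if cursor + n > config.n_genes:
            raise ConfigError(
                f"gene pool exhausted while building terms {'/'.join(pair)}: "
                f"need {n} more genes but only {config.n_genes - cursor} remain; "
                "increase n_genes or reduce n_terms/set sizes"
            )
        out = [_gene_id(i) for i in range(cursor, cursor + n)]
        cursor += n
        return out

    term_ids = [f"T{i + 1:04d}" for i in range(config.n_terms)]
    i = 0
    while i < config.n_terms:
        if i + 1 < config.n_terms:
            ta, tb = term_ids[i], term_ids[i + 1]
            sa, sb = int(sizes[i]), int(sizes[i + 1])
            shared_n = int(round(config.overlap_fraction * min(sa, sb)))
            shared = take(shared_n, (ta, tb))
            sets[ta] = frozenset(shared + take(sa - shared_n, (ta, tb)))
            sets[tb] = frozenset(shared + take(sb - shared_n, (ta, tb)))
            i += 2
        else:
            t = term_ids[i]
            sets[t] = frozenset(take(int(sizes[i]), (t,)))
            i += 1
    for j, t in enumerate(term_ids):
        names[t] = f"synthetic term {t}"
        depth[t] = int(depths[j])
    return GeneSetCollection(sets=sets, names=names, depth=depth, seed=config.seed)


def _pick_signal_components(
    rng: np.random.Generator, config: SimulationConfig, term_ids: list[str]
) -> dict[str, int]:
    """Choose signal terms as whole overlap components with one direction.

    Overlapping pair partners share member genes, so signal status is
    assigned per pair: a null term may never contain a shifted gene. The
    number of signal terms is round(signal_term_fraction · n_terms),
    rounded to whole components.
    """
    n_signal = int(round(config.signal_term_fraction * config.n_terms))
    components: list[list[str]] = []
    i = 0
    while i < len(term_ids):
        if config.overlap_fraction > 0 and i + 1 < len(term_ids):
            components.append([term_ids[i], term_ids[i + 1]])
            i += 2
        else:
            components.append([term_ids[i]])
            i += 1
    order = rng.permutation(len(components))
    directions: dict[str, int] = {t: 0 for t in term_ids}
    count = 0
    for ci in order:
        if count >= n_signal:
            break
        d = int(rng.choice([-1, 1]))
        for t in components[ci]:
            directions[t] = d
            count += 1
    return directions


def simulate_studies(
    collection: GeneSetCollection, config: SimulationConfig
) -> tuple[list[ExpressionStudy], SyntheticTruth]:
    """Simulate the per-study signal matrices and record the truth.

    Per gene and study, log2 signal = baseline + group effect + noise;
    matrices are returned on the linear (anti-logged) scale. Every signal
    term realised in a study shifts all its member genes by
    direction × effect_size in the treated group; realisation happens in
    round(study_penetrance · n_studies) randomly chosen studies per signal
    component (pair partners are realised together).
    """
    genes = [_gene_id(i) for i in range(config.n_genes)]
    missing = collection.all_genes() - set(genes)
    if missing:
        raise ConfigError(f"collection genes outside the simulated universe: {sorted(missing)[:5]}")

    rng = stage_rng(config.seed, "studies")
    effect = config.effect_size
    directions = _pick_signal_components(rng, config, collection.term_ids)
    if config.effect_size == 0:
        directions = {t: 0 for t in directions}

    n_realized = int(round(config.study_penetrance * config.n_studies))
    study_ids = [f"S{j + 1:02d}" for j in range(config.n_studies)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    # realisation studies per signal component (pairs share one draw)
    realized_in: dict[str, set[str]] = {}
    seen_pairs: set[frozenset[str]] = set()
    term_list = collection.term_ids
    i = 0
    while i < len(term_list):
        if config.overlap_fraction > 0 and i + 1 < len(term_list):
            comp = [term_list[i], term_list[i + 1]]
            i += 2
        else:
            comp = [term_list[i]]
            i += 1
        chosen = set(rng.choice(study_ids, size=n_realized, replace=False)) if n_realized else set()
        for t in comp:
            realized_in[t] = chosen

    studies: list[ExpressionStudy] = []
    gene_effects: dict[tuple[str, str], float] = {}
    n_samples = config.n_control + config.n_treated
    sample_ids = [f"C{k + 1}" for k in range(config.n_control)] + [
        f"R{k + 1}" for k in range(config.n_treated)
    ]
    groups = pd.Series(
        ["control"] * config.n_control + ["treated"] * config.n_treated, index=sample_ids
    )

    for sid in study_ids:
        baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
        shift = np.zeros(config.n_genes)
        for t, d in directions.items():
            if d == 0 or sid not in realized_in[t]:
                continue
            for g in collection.sets[t]:
                shift[gene_pos[g]] = d * effect
        for gi in np.nonzero(shift)[0]:
            gene_effects[(sid, genes[gi])] = float(shift[gi])
        log2 = baseline[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, n_samples))
        log2[:, config.n_control :] += shift[:, None]
        studies.append(
            ExpressionStudy(
                study_id=sid,
                signal=pd.DataFrame(
                    np.exp2(log2), index=pd.Index(genes, name="gene_id"), columns=sample_ids
                ),
                groups=groups.copy(),
                label=f"synthetic tissue {sid}",
            )
        )

    term_effects = {
        t: (d, config.effect_size if d != 0 else 0.0) for t, d in directions.items()
    }
    truth = SyntheticTruth(
        term_effects=term_effects,
        study_penetrance=config.study_penetrance,
        gene_effects=gene_effects,
        seed=config.seed,
    )
    return studies, truth
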