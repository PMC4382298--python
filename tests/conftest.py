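import numpy as np
import pandas as pd
import pytest

from crsig import ExpressionStudy, GeneSetCollection, SimulationConfig


def make_study(control: np.ndarray, treated: np.ndarray, study_id: str = "S01",
               genes=None) -> ExpressionStudy:
    """Build a study from log2 control/treated matrices (genes x samples)."""
    control = np.atleast_2d(np.asarray(control, dtype=float))
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    n = control.shape[0]
    genes = [f"g{i}" for i in range(n)] if genes is None else list(genes)
    cols = [f"C{j}" for j in range(control.shape[1])] + [f"R{j}" for j in range(treated.shape[1])]
    signal = pd.DataFrame(np.exp2(np.hstack([control, treated])), index=genes, columns=cols)
    groups = pd.Series(["control"] * control.shape[1] + ["treated"] * treated.shape[1], index=cols)
    return ExpressionStudy(study_id=study_id, signal=signal, groups=groups)


@pytest.fixture
def small_collection() -> GeneSetCollection:
    return GeneSetCollection(
        sets={
            "T1": frozenset({"g1", "g2", "g3"}),
            "T2": frozenset({"g3", "g4", "g5", "g6"}),
            "T3": frozenset({"g7", "g8"}),
        },
        names={"T1": "alpha", "T2": "beta", "T3": "gamma"},
        depth={"T1": 3, "T2": 4, "T3": 5},
    )


@pytest.fixture
def null_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=3000, n_terms=80, set_size_range=(10, 20), overlap_fraction=0.25,
        n_studies=4, effect_size=0.0, noise_sd=0.25, signal_term_fraction=0.1, seed=11,
    )
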