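import numpy as np
import pandas as pd
import pytest

from gutliver.containers import TIMEPOINTS, CountMatrix
from gutliver.immune_library import ImmuneGeneLibrary


@pytest.fixture
def toy_library() -> ImmuneGeneLibrary:
    return ImmuneGeneLibrary(
        [
            ("g1", "complement system", "C3"),
            ("g2", "pattern recognition", "C-type lectin"),
            ("g3", "complement system", "C1q"),
        ]
    )


def make_count_matrix(
    feature_rows: dict[str, list[int]],
    n_reps: int = 2,
    tissue: str = "gut",
    n_ballast: int = 50,
    ballast_value: int = 1000,
) -> CountMatrix:
    """CountMatrix from per-time-point feature values, replicated exactly.

    ``feature_rows`` maps feature id -> one count per canonical time point;
    every replicate at a time point carries the identical value.  Ballast
    features constant across all samples pin the median-of-ratios size
    factors at exactly 1, so normalised counts equal raw counts.
    """
    rows = {}
    for fid, vals in feature_rows.items():
        assert len(vals) == len(TIMEPOINTS)
        rows[fid] = [v for v in vals for _ in range(n_reps)]
    for i in range(n_ballast):
        rows[f"ballast{i:03d}"] = [ballast_value] * (len(TIMEPOINTS) * n_reps)
    cols, sheet = [], []
    for tp in TIMEPOINTS:
        for r in range(1, n_reps + 1):
            cols.append(f"{tissue}_{tp}_r{r}")
            sheet.append(
                {"sample_id": f"{tissue}_{tp}_r{r}", "tissue": tissue,
                 "timepoint": tp, "replicate": r}
            )
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.columns = cols
    return CountMatrix(counts, pd.DataFrame(sheet))


def nb_sample(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Gamma-Poisson NB draws with Var = mu + dispersion * mu^2."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size) if size else np.asarray(mean, dtype=float)
    if dispersion <= 1e-8:
        return rng.poisson(mean)
    return rng.poisson(rng.gamma(1.0 / dispersion, mean * dispersion))
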