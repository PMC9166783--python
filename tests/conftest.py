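import numpy as np
import pandas as pd
import pytest

from immunobehav import cohort as ch
from immunobehav.preprocess import MinMaxLog, lod_filter


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared across read-only tests."""
    return ch.generate_cohort(ch.SimConfig(seed=20240917))


@pytest.fixture(scope="session")
def treated_blocks(default_cohort):
    """(CARS-change block, normalized cytokine-change block) of the
    treated arm, preprocessed the way the pipeline does."""
    coh = default_cohort
    info = ch.subject_info(coh)
    treated = info.index[info["arm"] == "drug"]
    kept, _ = lod_filter(coh[ch.analyte_names(coh)], ch.detection_ranges(coh))
    chg = ch.cytokine_change(coh, kept).loc[treated]
    norm = MinMaxLog().fit_transform(chg, info.loc[treated, "batch"])
    return ch.cars_change(coh).loc[treated], norm


def classical_cca_first(X, Y):
    """Independent closed-form oracle: leading canonical correlation via
    the generalized-eigenvalue formulation."""
    import scipy.linalg as sla
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    A = sla.solve(X.T @ X, X.T @ Y) @ sla.solve(Y.T @ Y, Y.T @ X)
    return float(np.sqrt(max(np.linalg.eigvals(A).real)))


@pytest.fixture(scope="session")
def cca_oracle():
    return classical_cca_first
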