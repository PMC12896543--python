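import numpy as np
import pandas as pd
import pytest

from triaxis import (
    CellConfig,
    SimulationConfig,
    generate_bulk_cohort,
    generate_cell_population,
)
from triaxis.deconvolution import build_reference, select_markers
from triaxis.synthetic import CD274_GENE, FOCAL_GENE, hot_gene_names


@pytest.fixture(scope="session")
def bulk_cohort():
    """Planted-signal discovery cohort (n=60)."""
    return generate_bulk_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects anywhere."""
    cfg = SimulationConfig(
        marker_effect=0.0, cd274_effect=0.0, hot_effect=0.0, survival_hr=1.0,
        seed=13,
    )
    return generate_bulk_cohort(cfg)


@pytest.fixture(scope="session")
def cells():
    """Planted-marker CD8 cell population."""
    return generate_cell_population(CellConfig(seed=7, n_cells=2000))


@pytest.fixture(scope="session")
def marker_set(cells):
    return select_markers(cells)


@pytest.fixture(scope="session")
def full_reference(cells, marker_set):
    return build_reference(cells, marker_set, "FULL")


@pytest.fixture(scope="session")
def panel_expression(bulk_cohort):
    """The 29-gene tri-axis panel slice of the discovery cohort."""
    genes = [FOCAL_GENE, CD274_GENE, *hot_gene_names()]
    return bulk_cohort.expression.loc[genes]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def brute_force_auc(probs, labels) -> float:
    """Exhaustive concordant-pair AUC (ties count half)."""
    p = np.asarray(probs, float)
    y = np.asarray(labels, int)
    pos, neg = p[y == 1], p[y == 0]
    wins = sum((xp > xn) + 0.5 * (xp == xn) for xp in pos for xn in neg)
    return wins / (len(pos) * len(neg))


def brute_force_bh(pvals) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        q[i] = prev
    return q
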