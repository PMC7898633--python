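import numpy as np
import pytest

from herbimeta import PipelineConfig, run_full_pipeline
from herbimeta.degmat import DEGMatrix
from herbimeta.io import DEGRecord, DEGTable


@pytest.fixture(scope="session")
def default_bundle():
    """One full pipeline run on the default synthetic scenario.

    B is reduced from the production default to keep the suite fast; the
    full-B run is exercised by the determinism check.
    """
    return run_full_pipeline(PipelineConfig(seed=11, B=2000))


def make_matrix(lfc, de=None, measured=None, genes=None, experiments=None):
    lfc = np.asarray(lfc, dtype=float)
    G, E = lfc.shape
    genes = genes or [f"g{i}" for i in range(G)]
    experiments = experiments or [f"e{j}" for j in range(E)]
    de = np.asarray(de, dtype=bool) if de is not None \
        else np.ones_like(lfc, dtype=bool)
    measured = np.asarray(measured, dtype=bool) if measured is not None \
        else np.ones_like(lfc, dtype=bool)
    return DEGMatrix(genes, experiments, lfc, de, measured)


def make_table(rows, experiment_id="exp1"):
    return DEGTable(experiment_id, {
        g: DEGRecord(g, lfc, padj) for g, lfc, padj in rows
    })


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
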