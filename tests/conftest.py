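"""Shared fixtures: one full synthetic pipeline run reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from ebatac.config import default_config
from ebatac.io import CountMatrix, GeneModel, PeakInterval
from ebatac.pipeline import run_all

#: the one seed used for the default-scale synthetic study
STUDY_SEED = 7

#: reduced cell numbers for fast end-to-end runs (structure unchanged)
SMALL_CELLS = {
    "D4": {"ESC": 10, "END": 4, "MES": 4, "ECT": 4,
           "EC_END": 8, "EC_MES": 8, "EC_ECT": 8},
    "D8": {"ESC": 2, "END": 8, "MES": 8, "ECT": 8,
           "EC_END": 4, "EC_MES": 4, "EC_ECT": 4},
}


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """A complete pipeline run at the default study design."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = default_config(seed=STUDY_SEED, outdir=str(outdir))
    run_all(cfg)
    return outdir


@pytest.fixture()
def small_config(tmp_path):
    cfg = default_config(
        seed=STUDY_SEED,
        outdir=str(tmp_path / "run"),
        simulate={"cells_per_type_per_stage": SMALL_CELLS},
    )
    return cfg


def toy_counts(rng: np.random.Generator, n_peaks: int, n_cells: int,
               lam: float = 3.0) -> CountMatrix:
    values = rng.poisson(lam, size=(n_peaks, n_cells))
    return CountMatrix(
        sp.csr_matrix(values),
        [f"p{i}" for i in range(n_peaks)],
        [f"c{j}" for j in range(n_cells)],
    )


def toy_peaks(n: int, spacing: int = 10_000, width: int = 400,
              contig: str = "chr1", gc: float = 0.5) -> list[PeakInterval]:
    return [
        PeakInterval(f"p{i}", contig, 1000 + i * spacing, 1000 + i * spacing + width, gc)
        for i in range(n)
    ]


def toy_genes(n: int, spacing: int = 10_000, contig: str = "chr1") -> list[GeneModel]:
    return [
        GeneModel(f"g{i}", contig, 1000 + i * spacing, "+", is_tf=False)
        for i in range(n)
    ]
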