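import numpy as np
import pandas as pd
import pytest

from ldanchor import (
    GenotypeMatrix,
    MarkerMap,
    SimConfig,
    simulate_panel,
)


@pytest.fixture(scope="session")
def sim_panel():
    """Mid-sized synthetic panel with misplacement, sweep and missingness."""
    cfg = SimConfig(n_individuals=200, n_year_annotated=150, n_markers=600, seed=11)
    return cfg, simulate_panel(cfg)


@pytest.fixture(scope="session")
def clean_panel():
    """Complete high-LD panel (no missingness/misplacement) for imputation."""
    cfg = SimConfig(
        n_individuals=150,
        n_year_annotated=110,
        n_markers=300,
        within_block_r2_target=0.9,
        missingness_rate=0.0,
        misplacement_fraction=0.0,
        seed=23,
    )
    return cfg, simulate_panel(cfg)


def make_gm(dosage, individuals=None, markers=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    individuals = individuals or [f"ind{i}" for i in range(n)]
    markers = markers or [f"mk{j}" for j in range(m)]
    return GenotypeMatrix(individuals, markers, dosage)


def make_map(records) -> MarkerMap:
    """records: iterable of (marker_id, chromosome, position_bp[, source])."""
    rows = []
    for rec in records:
        marker, chrom, pos = rec[:3]
        source = rec[3] if len(rec) > 3 else "other"
        rows.append((marker, chrom, int(pos), source))
    return MarkerMap(
        pd.DataFrame(
            rows, columns=["marker_id", "chromosome", "position_bp", "source_array"]
        )
    )
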