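import numpy as np
import pandas as pd
import pytest

from amtlfq import synthetic as syn


@pytest.fixture(scope="session")
def small_study():
    """A compact cohort reused across tests: 40 proteins, 8 neopterin-coupled."""
    cfg = syn.SimulationConfig(
        n_proteins=40, n_neopterin_coupled=8, n_nfl_coupled=4, n_overlap=2, seed=11
    )
    return syn.simulate_study(cfg)


@pytest.fixture(scope="session")
def noiseless_run():
    """Noiseless emitted cohort: exact masses/NETs, no dropout."""
    cfg = syn.SimulationConfig(
        n_proteins=50,
        n_neopterin_coupled=10,
        sigma_ppm=0.0,
        sigma_net=0.0,
        dropout_rate=0.0,
        seed=7,
    )
    study = syn.simulate_study(cfg)
    features, ids = syn.emit_runs(study)
    return study, features, ids


@pytest.fixture()
def id_table():
    """Twelve constructed identification records covering every filter branch.

    Hand-counted pass set: rows 1, 3, 5, 7, 9, 11 kept as targets; row 12 is
    the only decoy that passes.
    """
    rows = [
        # (charge, xcorr, spectra, prob, is_decoy)
        (1, 1.9, 1, 0.60, False),  # 1  kept: 1+ single-spectrum boundary
        (1, 1.8, 1, 0.90, False),  # 2  removed: below 1+ threshold
        (2, 2.2, 1, 0.60, False),  # 3  kept: 2+ single-spectrum boundary
        (2, 2.0, 1, 0.90, False),  # 4  removed: below 2+ threshold
        (2, 2.0, 2, 0.60, False),  # 5  kept: multi-spectrum relaxed 1.9
        (2, 1.8, 3, 0.90, False),  # 6  removed: below relaxed threshold
        (3, 3.5, 1, 0.50, False),  # 7  kept: >=3+ boundary, prob boundary
        (3, 3.4, 1, 0.90, False),  # 8  removed: below >=3+ threshold
        (4, 3.6, 1, 0.70, False),  # 9  kept: charge 4 shares the 3.5 cut
        (3, 3.6, 1, 0.40, False),  # 10 removed: prob < 0.5
        (1, 2.0, 2, 0.55, False),  # 11 kept: multi-spectrum, charge 1
        (2, 2.5, 1, 0.90, True),   # 12 kept but decoy
    ]
    return pd.DataFrame(
        {
            "peptide": [f"PEPTIDEK{i}".replace("0", "A") for i in range(1, 13)],
            "charge": [r[0] for r in rows],
            "xcorr": [r[1] for r in rows],
            "delta_cn": 0.2,
            "spectra_count": [r[2] for r in rows],
            "prob": [r[3] for r in rows],
            "is_decoy": [r[4] for r in rows],
            "protein_ids": "PROT1",
            "elution_net": np.linspace(0.1, 0.9, 12),
        }
    )
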