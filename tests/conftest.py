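import numpy as np
import pandas as pd
import pytest

from secep.io import LfqMatrix
from secep.simulate import SimConfig, simulate_cohort_pair, simulate_lfq


def make_lfq(values: np.ndarray, protein_ids=None) -> LfqMatrix:
    """Tiny five-line LFQ matrix (2 basal, 2 luminal, 1 control; 3 bio x 2 tech)."""
    lines = [
        ("BAS1", "basal"), ("BAS2", "basal"),
        ("LUM1", "luminal"), ("LUM2", "luminal"),
        ("CTRL", "control"),
    ]
    samples = []
    for name, subtype in lines:
        for b in (1, 2, 3):
            for t in (1, 2):
                samples.append(
                    {"sample_id": f"{name}_b{b}_t{t}", "cell_line": name,
                     "subtype": subtype, "bio_rep": b, "tech_rep": t}
                )
    sheet = pd.DataFrame(samples).set_index("sample_id")
    values = np.asarray(values, dtype=float)
    assert values.shape[1] == len(sheet)
    if protein_ids is None:
        protein_ids = [f"prot{i}" for i in range(values.shape[0])]
    return LfqMatrix(
        values=pd.DataFrame(values, index=protein_ids, columns=sheet.index),
        samples=sheet,
    )


def line_pattern(per_line: dict, noise_sd: float = 0.0, rng=None, base: float = 25.0) -> np.ndarray:
    """One protein row from per-cell-line target levels (6 replicates each)."""
    order = ["BAS1", "BAS2", "LUM1", "LUM2", "CTRL"]
    row = np.repeat([base + per_line.get(cl, 0.0) for cl in order], 6).astype(float)
    if noise_sd and rng is not None:
        row = row + rng.normal(0, noise_sd, row.size)
    return row


@pytest.fixture(scope="session")
def planted_lfq():
    """Seeded LFQ fixture: 500 proteins, 50 planted basal-up (shift 1.5, noise 0.4)."""
    config = SimConfig(seed=11)
    matrix, truth = simulate_lfq(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def cohort_pair():
    """Seeded cohort pair at the default study conditions (no planted combos)."""
    config = SimConfig(seed=5)
    discovery, validation, truth = simulate_cohort_pair(config)
    return config, discovery, validation, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
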