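import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from stilmap.lattice import PatchGrid, PatchLabel


def make_grid(spec: str, slide_id: str = "S1", patient_id: str = "P1") -> PatchGrid:
    """Build a PatchGrid from a compact string: 'P' pos, 'N' neg, 'X' necrotic,
    '.' background (absent). Rows separated by '/'."""
    mapping = {"P": PatchLabel.TIL_POS, "N": PatchLabel.TIL_NEG,
               "X": PatchLabel.NECROTIC_OTHER}
    patches = []
    rows = spec.split("/")
    for r, line in enumerate(rows):
        for c, ch in enumerate(line):
            if ch in mapping:
                patches.append((r, c, mapping[ch]))
    return PatchGrid.from_patches(slide_id, patient_id, patches,
                                  n_rows=len(rows), n_cols=len(rows[0]))


@pytest.fixture
def mixed_grid() -> PatchGrid:
    """3 TIL_POS, 5 TIL_NEG, 2 NECROTIC_OTHER on a 3x4 lattice."""
    return make_grid("PPNN/NXXN/PN..")


def random_masked_lattice(rng: np.random.Generator, max_side: int = 30):
    """A random connected-ish masked lattice with a binary field, for oracles."""
    nr = int(rng.integers(4, max_side + 1))
    nc = int(rng.integers(4, max_side + 1))
    mask = rng.random((nr, nc)) < rng.uniform(0.4, 0.9)
    if mask.sum() < 2:
        mask[0, 0] = mask[0, 1] = True
    rows, cols = np.nonzero(mask)
    x = (rng.random(mask.sum()) < rng.uniform(0.1, 0.6)).astype(float)
    if x.min() == x.max():  # keep the field non-degenerate
        x[0] = 1.0 - x[0]
    return rows, cols, x
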