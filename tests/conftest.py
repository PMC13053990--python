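import numpy as np
import pandas as pd
import pytest

from mipepkit import ProteinQuantTable


def make_table(bait, ctrl, bait_sc=None, ctrl_sc=None, ids=None):
    """Build a small bait/control ProteinQuantTable from row lists.

    ``bait``/``ctrl`` are lists (one entry per protein) of replicate values;
    use None/NaN for missing. Spectral counts default to 1 everywhere.
    """
    n = len(bait)
    ids = ids or [f"P{i + 1:03d}" for i in range(n)]
    nb, nc = len(bait[0]), len(ctrl[0])
    cols = [f"bait_{r + 1}" for r in range(nb)] + [f"control_{r + 1}" for r in range(nc)]
    samples = pd.DataFrame(
        {
            "condition": ["bait"] * nb + ["control"] * nc,
            "replicate": list(range(1, nb + 1)) + list(range(1, nc + 1)),
        },
        index=pd.Index(cols, name="sample"),
    )
    intens = pd.DataFrame(
        [list(b) + list(c) for b, c in zip(bait, ctrl)],
        index=pd.Index(ids, name="protein_id"),
        columns=cols,
        dtype=float,
    )
    if bait_sc is None:
        bait_sc = [[1] * nb] * n
    if ctrl_sc is None:
        ctrl_sc = [[1] * nc] * n
    sc = pd.DataFrame(
        [list(b) + list(c) for b, c in zip(bait_sc, ctrl_sc)],
        index=intens.index,
        columns=cols,
    )
    return ProteinQuantTable(intens, samples, sc, source="fixture")


def random_small_table(rng: np.random.Generator):
    """Random bait/control table (<=50 proteins, <=4 replicates per side) with
    missingness and spectral counts, guaranteed >=4 defined ratios."""
    while True:
        n = int(rng.integers(8, 51))
        nb = int(rng.integers(2, 5))
        nc = int(rng.integers(2, 5))
        bait, ctrl, bsc, csc = [], [], [], []
        for _ in range(n):
            base = float(rng.normal(20, 2))
            b = 2.0 ** (base + rng.normal(0, 1, nb))
            c = 2.0 ** (base + rng.normal(0, 1, nc))
            bm = rng.random(nb) < 0.2
            cm = rng.random(nc) < 0.25
            bait.append([None if m else v for v, m in zip(b, bm)])
            ctrl.append([None if m else v for v, m in zip(c, cm)])
            bsc.append([int(rng.poisson(3)) if not m else 0 for m in bm])
            csc.append([int(rng.poisson(3)) if not m else 0 for m in cm])
        defined = sum(
            1
            for b, c in zip(bait, ctrl)
            if any(v is not None for v in b) and any(v is not None for v in c)
        )
        if defined >= 4:
            return bait, ctrl, bsc, csc


@pytest.fixture
def small_table():
    return make_table(
        bait=[[80, 100, 120], [4, 4, 4], [50, None, 60]],
        ctrl=[[5, 8, 10], [4, 4, 4], [None, None, None]],
        bait_sc=[[4, 6, 5], [2, 2, 2], [3, 1, 2]],
        ctrl_sc=[[1, 1, 1], [2, 2, 2], [0, 0, 0]],
    )
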