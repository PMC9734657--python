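"""Shared test helpers (importable because tests/ is on sys.path)."""

import numpy as np
import pandas as pd

from scimet.matrix import WindowMatrix, WindowSet


def toy_window_matrix(sites, context="CH", window_size=100):
    """WindowMatrix from a raw site-count array on one chromosome."""
    n, m = sites.shape
    windows = pd.DataFrame(
        {"chrom": "c", "start": np.arange(m) * window_size,
         "end": (np.arange(m) + 1) * window_size}
    )
    frac = np.where(sites > 0, 0.5, np.nan)
    return WindowMatrix(
        np.array([f"cell{i}" for i in range(n)]),
        WindowSet(windows, window_size, context),
        frac.astype(float),
        np.asarray(sites, dtype=np.int64),
    )
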