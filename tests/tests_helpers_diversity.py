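"""Tiny shared helper: mean pairwise diversity per bp from haplotypes."""

import numpy as np


def window_pi(haps: np.ndarray, span_bp: int) -> float:
    H = np.asarray(haps, dtype=np.float64)
    n = H.shape[0]
    k = H.sum(axis=0)
    pair_diffs = k * (n - k) / (n * (n - 1) / 2.0)
    return float(pair_diffs.sum()) / span_bp
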