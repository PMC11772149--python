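import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_compactness(intensity, radius, mask):
    """Independent double-loop oracle for the neighbourhood-summed
    collagen intensity, on the same 1/255000 quantization grid."""
    from cordmetrics.histology import INTENSITY_SCALE

    q = np.rint(np.asarray(intensity, dtype=float) * INTENSITY_SCALE).astype(np.int64)
    q[~mask] = 0
    h, w = q.shape
    out = np.zeros((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            acc = 0
            for a in range(max(0, i - radius), min(h, i + radius + 1)):
                for b in range(max(0, j - radius), min(w, j + radius + 1)):
                    acc += q[a, b]
            out[i, j] = acc / INTENSITY_SCALE
    return out
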