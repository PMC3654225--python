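import numpy as np
import pytest
from scipy.stats import ks_2samp

from rrseg.core import CutCandidate


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def brute_force_scan(x, min_side=2):
    """Independent O(n^2) oracle for the maximal weighted KS cut.

    Evaluates scipy's two-sample KS statistic at every admissible cut and
    weights it by sqrt(n_L n_R / n); ties broken toward the smallest index.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    best = None
    for p in range(n - 1):
        nl, nr = p + 1, n - p - 1
        if nl < min_side or nr < min_side:
            continue
        d_ks = ks_2samp(x[: p + 1], x[p + 1:], method="asymp").statistic
        d = d_ks * np.sqrt(nl * nr / n)
        if best is None or d > best.d + 1e-12:
            best = CutCandidate(index=p, d_ks=float(d_ks), d=float(d),
                                n_left=nl, n_right=nr)
    return best


@pytest.fixture
def step_series(rng):
    """Two i.i.d. normal halves with a large mean step at index 500."""
    return np.r_[rng.normal(0.0, 1.0, 500), rng.normal(5.0, 1.0, 500)]
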