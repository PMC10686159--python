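import numpy as np
import pytest

from mdof_extremes.core import MergedVector


@pytest.fixture
def toy_csv(tmp_path):
    """Wide cause-of-death CSV: 2 entities x 3 years x 1 cause column."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "Entity,Code,Year,cvd\n"
        "Aland,ALA,1990,0.20\n"
        "Aland,ALA,1991,0.50\n"
        "Aland,ALA,1992,0.40\n"
        "Borduria,BOR,1990,0.30\n"
        "Borduria,BOR,1991,0.10\n"
        "Borduria,BOR,1992,0.60\n"
    )
    return path


def merged_from_values(values, limits=None, times=None) -> MergedVector:
    """Build a merged vector directly from arrays (single synthetic source)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if limits is None:
        limits = np.ones(n)
    if times is None:
        times = np.arange(n)
    return MergedVector(
        times=times, values=values, limits=limits, sources=["synthetic"] * n
    )


def brute_force_pk(values, limits, lam, k):
    """Independent naive re-count of the conditional exceedance rate.

    Written as the plainest possible loop so it can serve as an oracle for
    the vectorized estimator: for each index j (0-based, j >= k-1) check
    the k-1 preceding maxima against their scaled limits one by one.
    """
    values = np.asarray(values, dtype=float)
    limits = np.asarray(limits, dtype=float)
    n = len(values)
    n_cond = 0
    n_exc = 0
    for j in range(k - 1, n):
        ok = True
        for i in range(1, k):
            if not values[j - i] <= limits[j - i] * lam:
                ok = False
                break
        if ok:
            n_cond += 1
            if values[j] > limits[j] * lam:
                n_exc += 1
    p = n_exc / n_cond if n_cond > 0 else 0.0
    return p, n_cond, n_exc
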