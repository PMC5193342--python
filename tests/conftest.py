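import numpy as np
import pytest

from triocnv import simulate as sim


@pytest.fixture(scope="session")
def small_map():
    """2000 markers on two chromosomes, fixed seed."""
    return sim.generate_marker_map(
        2000, {"chr1": 50_000_000, "chr2": 30_000_000}, cnv_probe_fraction=0.1, seed=7
    )


@pytest.fixture(scope="session")
def small_trios():
    return sim.generate_trios(20, seed=11)


@pytest.fixture(scope="session")
def null_panel(small_map, small_trios):
    """Panel with no CNV events and no GC wave."""
    return sim.emit_intensities(
        small_trios, small_map, events=(), noise_sd=0.15, gc_lrr_coeff=0.0, seed=23
    )


def fisher_two_sided_enum(a, b, c, d):
    """Independent oracle: two-sided Fisher p by full hypergeometric
    enumeration (sum of tables with probability <= observed)."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = comb(r1, x) * comb(r2, c1 - x) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def hypergeom_upper_enum(N, K, n, k):
    """Independent oracle: P(X >= k) by direct summation of the pmf."""
    from math import comb

    denom = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x) / denom
        for x in range(k, min(K, n) + 1)
    )
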