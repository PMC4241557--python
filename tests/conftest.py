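import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibration():
    from ephysdev.synth import load_default_calibration

    return load_default_calibration()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def mid_shape():
    """A representative mature AP template parameter set."""
    from ephysdev.synth import APShapeParams

    return APShapeParams(threshold=-43.9, amplitude=62.6, half_width=1.50,
                         rise_slope=61.5, decay_slope=-44.1, ahp_depth=29.1,
                         baseline=-43.9 - 29.1 + 3.0)


def ward_oracle(X):
    """Exhaustive greedy Ward agglomeration (independent of scipy).

    Returns the merge history as a list of (partition_after_merge, height)
    where heights follow the convention height = sqrt(2 * merge cost) with
    cost = |A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2.
    """
    X = np.asarray(X, dtype=float)
    clusters = {i: [i] for i in range(X.shape[0])}
    history = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                ca = X[clusters[a]].mean(axis=0)
                cb = X[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                cost = na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, a, b)
        cost, a, b = best
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
        part = frozenset(frozenset(v) for v in clusters.values())
        history.append((part, np.sqrt(2.0 * cost)))
    return history


def scipy_ward_history(X):
    """Same merge-history representation extracted from scipy's linkage."""
    from scipy.cluster import hierarchy

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Z = hierarchy.linkage(X, method="ward")
    members = {i: frozenset([i]) for i in range(n)}
    live = set(range(n))
    history = []
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        members[n + k] = members[a] | members[b]
        live.discard(a)
        live.discard(b)
        live.add(n + k)
        part = frozenset(members[i] for i in live)
        history.append((part, float(h)))
    return history
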