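import numpy as np
import pytest

from ringdock.fixtures import ToyCageSpec, make_probe, make_toy_cage


@pytest.fixture(scope="session")
def cage():
    """Toy receptor cage (self-verification deferred to the dedicated
    grid-oracle test)."""
    return make_toy_cage(ToyCageSpec(), verify=False)


@pytest.fixture(scope="session")
def probe():
    return make_probe()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_clash(groups, scale, radii_fn):
    """All-pairs O(n²) steric-overlap oracle over molecule groups.

    ``groups`` is a list of (coords, elements); returns True iff any
    inter-group atom pair is closer than scale*(r_i + r_j).
    """
    for i in range(len(groups)):
        ci, ei = groups[i]
        ri = np.array([radii_fn(e) for e in ei])
        for j in range(i + 1, len(groups)):
            cj, ej = groups[j]
            rj = np.array([radii_fn(e) for e in ej])
            for a in range(len(ci)):
                for b in range(len(cj)):
                    cut = scale * (ri[a] + rj[b])
                    if np.linalg.norm(ci[a] - cj[b]) < cut:
                        return True
    return False
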