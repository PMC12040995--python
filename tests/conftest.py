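import numpy as np
import pytest

from ectonet.netcore import HostRecord, InteractionMatrix, NetworkBundle


def make_matrix(counts, host_ids=None, parasites=None) -> InteractionMatrix:
    counts = np.asarray(counts)
    n, s = counts.shape
    host_ids = host_ids or [f"h{i}" for i in range(n)]
    parasites = parasites or [f"p{j}" for j in range(s)]
    return InteractionMatrix(counts, host_ids, parasites)


def make_bundle(counts, sexes=None, species="sp", region="north",
                group="flea") -> NetworkBundle:
    m = make_matrix(counts)
    n = m.shape[0]
    sexes = sexes or ["F" if i < n // 2 else "M" for i in range(n)]
    hosts = [
        HostRecord(host_id=h, species=species, region=region, site="s1", sex=sx)
        for h, sx in zip(m.host_ids, sexes)
    ]
    return NetworkBundle(matrix=m, hosts=hosts, parasite_group=group,
                         id=f"{species}|{region}|{group}")


def random_matrix(rng, n=None, s=None, max_count=6) -> InteractionMatrix:
    """A random count matrix with no empty row or column."""
    n = n or rng.integers(3, 9)
    s = s or rng.integers(2, 7)
    while True:
        a = rng.integers(0, max_count + 1, size=(n, s))
        a[rng.random(a.shape) < 0.4] = 0
        if a.sum(axis=1).min() > 0 and a.sum(axis=0).min() > 0:
            return make_matrix(a)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_bundle():
    return make_bundle(
        [[5, 2, 0], [1, 0, 3], [0, 4, 2], [2, 1, 1]],
        sexes=["F", "F", "M", "M"],
    )
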