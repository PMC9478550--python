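import numpy as np
import pytest

from eareg import RegistrationConfig, register_pair
from eareg.geodesics import GridMetric
from eareg.synthetic import benchmark_crack_scene


def grid_graph_distances(barrier: np.ndarray, seed, connectivity: int = 8):
    """Independent shortest-path oracle: scipy csgraph Dijkstra on the
    explicit grid graph (barrier pixels excluded as nodes)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    H, W = barrier.shape
    N = H * W
    dr, dc, w = GridMetric(connectivity).offsets()
    rows, cols, vals = [], [], []
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    for e in range(dr.size):
        ur, uc = rr + dr[e], cc + dc[e]
        ok = (
            (ur >= 0) & (ur < H) & (uc >= 0) & (uc < W)
            & ~barrier
        )
        ok &= np.where(ok, ~barrier[np.clip(ur, 0, H - 1), np.clip(uc, 0, W - 1)], False)
        rows.append((rr[ok] * W + cc[ok]))
        cols.append((ur[ok] * W + uc[ok]))
        vals.append(np.full(ok.sum(), w[e]))
    g = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    out = dijkstra(g, indices=[seed[0] * W + seed[1]])[0].reshape(H, W)
    out[barrier] = np.inf
    return out


@pytest.fixture(scope="session")
def oracle_dijkstra():
    return grid_graph_distances


@pytest.fixture(scope="session")
def crack_run():
    """One registered benchmark crack scene, shared across tests."""
    scene = benchmark_crack_scene(0)
    cfg = RegistrationConfig(k_clusters=6)
    result = register_pair(scene.moving, scene.reference, scene.mask, cfg, seed=0)
    return scene, result
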