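import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Published per-type census composition, used as a planting target.
PAPER_TYPE_MIX = {
    "Coh1": 49, "Coh2": 15, "Coh3": 2, "Coh4": 26,
    "InCoh1": 87, "InCoh2": 8, "InCoh3": 1, "InCoh4": 14,
}


@pytest.fixture
def paper_mix():
    return dict(PAPER_TYPE_MIX)


def random_signed_network(seed: int, n_nodes: int = 25, edge_prob: float = 0.15):
    """Random signed digraph for oracle tests: node 0 is the master, the
    first half of the nodes are TFs.  Returns (interactions, master, tf_set)."""
    from crpffl.regnet import Effect, RegulatoryInteraction

    rng = np.random.default_rng(seed)
    names = [f"n{i:02d}" for i in range(n_nodes)]
    tf_set = set(names[: max(2, n_nodes // 2)])
    # guarantee the master is a node of the built network
    interactions = [RegulatoryInteraction(names[0], names[1], Effect.ACTIVATION)]
    for u in names:
        if u not in tf_set:
            continue
        for v in names:
            if u == v or rng.random() >= edge_prob:
                continue
            effect = Effect.ACTIVATION if rng.random() < 0.5 else Effect.REPRESSION
            interactions.append(RegulatoryInteraction(u, v, effect))
    return interactions, names[0], tf_set


def brute_force_ffls(net, master: str, tf_set: set[str]):
    """Independent oracle: test all (y, z) node pairs against the raw edge map
    and label the triangle from first principles (coherence = sign product;
    type number from the (X->Y, Y->Z) sign pattern)."""
    from crpffl.regnet import canonical

    m = canonical(master)
    tf_keys = {canonical(t) for t in tf_set}
    number = {(+1, +1): 1, (-1, +1): 2, (+1, -1): 3, (-1, -1): 4}
    incoh_number = {(+1, -1): 1, (-1, -1): 2, (+1, +1): 3, (-1, +1): 4}
    found = []
    for y in net.nodes:
        for z in net.nodes:
            if len({m, y, z}) != 3 or y not in tf_keys:
                continue
            try:
                s_xy = net.edges[(m, y)]
                s_yz = net.edges[(y, z)]
                s_xz = net.edges[(m, z)]
            except KeyError:
                continue
            if s_xz == s_xy * s_yz:
                label = f"Coh{number[(s_xy, s_yz)]}"
            else:
                label = f"InCoh{incoh_number[(s_xy, s_yz)]}"
            found.append((net.name_of(y), net.name_of(z), s_xy, s_yz, s_xz, label))
    return sorted(found)
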