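"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's own algorithms: the min-cut oracle
enumerates every source/sink partition, and the hypergeometric oracle
enumerates every possible draw of the target set.
"""

from itertools import combinations


def min_cut_enumeration(arcs: dict, source, sink) -> int:
    """Exact min-cut capacity by enumerating all 2^k interior partitions.

    ``arcs`` maps (u, v) to an integer capacity.  By max-flow/min-cut
    duality the returned value equals the maximum flow.
    """
    nodes = {u for u, _ in arcs} | {v for _, v in arcs} | {source, sink}
    interior = sorted(nodes - {source, sink})
    best = None
    for r in range(len(interior) + 1):
        for side in combinations(interior, r):
            s_side = {source, *side}
            cut = sum(
                cap for (u, v), cap in arcs.items()
                if u in s_side and v not in s_side
            )
            if best is None or cut < best:
                best = cut
    return best


def hypergeom_tail_enumeration(universe: frozenset, term: frozenset,
                               targets: frozenset) -> float:
    """P[overlap >= observed] by enumerating all size-n draws from the universe."""
    n = len(targets)
    observed = len(term & targets)
    hits = total = 0
    for draw in combinations(sorted(universe), n):
        total += 1
        if len(term & frozenset(draw)) >= observed:
            hits += 1
    return hits / total


def random_layered_network(rng, max_go=4, cap_grid=100):
    """A small random component-GO-effect network with rational capacities.

    Capacities are multiples of 1/cap_grid so integer scaling is exact.
    """
    from trimodenet import TriModeNetwork

    n_c = int(rng.integers(1, 3))
    n_g = int(rng.integers(1, max_go + 1))
    n_e = int(rng.integers(1, 3))
    comps = [f"c{i}" for i in range(n_c)]
    gos = [f"g{i}" for i in range(n_g)]
    effs = [f"e{i}" for i in range(n_e)]
    arcs = {}
    for c in comps:
        for g in gos:
            if rng.random() < 0.7:
                arcs[(c, g)] = int(rng.integers(0, cap_grid + 1)) / cap_grid
    for g in gos:
        for e in effs:
            if rng.random() < 0.7:
                arcs[(g, e)] = int(rng.integers(0, cap_grid + 1)) / cap_grid
    for i, ga in enumerate(gos):
        for gb in gos[i + 1:]:
            if rng.random() < 0.4:
                cap = int(rng.integers(1, cap_grid + 1)) / cap_grid
                arcs[(ga, gb)] = cap
                arcs[(gb, ga)] = cap
    return TriModeNetwork(
        components=tuple(comps), go_terms=tuple(gos), effects=tuple(effs),
        arcs=arcs,
    )


def isolated_int_arcs(net, component, effect, scale):
    """Integer-scaled arcs of the pair's isolated subnetwork."""
    excluded = (set(net.components) | set(net.effects)) - {component, effect}
    return {
        (u, v): int(round(cap * scale))
        for (u, v), cap in net.arcs.items()
        if u not in excluded and v not in excluded
    }
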