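import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vaftree as vt

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def chain3() -> vt.ClonalTree:
    """Linear hierarchy m1 -> m2 -> m3."""
    return vt.ClonalTree({"m1": None, "m2": "m1", "m3": "m2"})


@pytest.fixture
def star3() -> vt.ClonalTree:
    """Branched hierarchy m1 -> {m2, m3}."""
    return vt.ClonalTree({"m1": None, "m2": "m1", "m3": "m1"})


@pytest.fixture
def chain_gm(chain3) -> vt.GenotypeMatrix:
    return vt.tree_to_genotype_matrix(chain3)


@pytest.fixture
def star_gm(star3) -> vt.GenotypeMatrix:
    return vt.tree_to_genotype_matrix(star3)


def brute_force_rooted_trees(n: int, root: int | None = None) -> set:
    """Oracle: all rooted labeled trees on nodes 1..n by exhaustive parent
    assignment, independent of the Prüfer-based enumeration under test.

    Each tree is encoded as a frozenset of (child, parent) pairs plus root.
    """
    import itertools

    found = set()
    nodes = list(range(1, n + 1))
    roots = [root] if root is not None else nodes
    for r in roots:
        others = [v for v in nodes if v != r]
        if not others:
            found.add((r, frozenset()))
            continue
        for parents in itertools.product(nodes, repeat=len(others)):
            mapping = dict(zip(others, parents))
            # reject cyclic / disconnected assignments
            ok = True
            for v in others:
                seen = set()
                cur = v
                while cur != r:
                    if cur in seen or cur not in mapping:
                        ok = False
                        break
                    seen.add(cur)
                    cur = mapping[cur]
                if not ok:
                    break
            if ok:
                found.add((r, frozenset(mapping.items())))
    return found


def tree_key(tree: vt.ClonalTree):
    return (tree.root, frozenset((c, p) for c, p in tree.parent.items()
                                 if p is not None))
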