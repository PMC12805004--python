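"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own enumeration code
paths: partitions are enumerated as raw restricted-growth strings and
connectivity is checked with a hand-rolled depth-first search, so that
agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import warnings

import pytest

import catsym as cs

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


def brute_force_set_partitions(n: int):
    """All set partitions of 0..n-1 as canonical label tuples."""
    out = []
    assignment = [0] * n

    def rec(i: int, used: int) -> None:
        if i == n:
            out.append(tuple(assignment))
            return
        for lab in range(used + 1):
            assignment[i] = lab
            rec(i + 1, max(used, lab + 1))

    rec(0, 0)
    return out


def dfs_connected(block, edges) -> bool:
    block = set(block)
    start = next(iter(block))
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for a, b in edges:
            w = b if a == v else a if b == v else None
            if w in block and w not in seen:
                seen.add(w)
                stack.append(w)
    return seen == block


def brute_force_connected_partitions(structure, max_size=None):
    """Oracle: filter all set partitions by block connectivity."""
    n = structure.n
    if max_size is None:
        max_size = n
    edges = list(structure.space.adjacency)
    out = []
    for labels in brute_force_set_partitions(n):
        if len(set(labels)) > max_size:
            continue
        blocks = {}
        for i, lab in enumerate(labels):
            blocks.setdefault(lab, set()).add(i)
        if not edges or all(dfs_connected(b, edges) for b in blocks.values()):
            out.append(labels)
    return out


@pytest.fixture(scope="session")
def canonical_structures():
    """One instance of each canonical structure at a small resolution."""
    return {
        "linear": cs.make_structure("linear", 6),
        "bisected_linear": cs.make_structure("bisected_linear", 5),
        "bisected_circular": cs.make_structure("bisected_circular", 8),
        "binary_feature": cs.make_structure("binary_feature", 2),
    }
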