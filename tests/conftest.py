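"""Shared fixtures: tiny ontology files and exact-arithmetic oracles."""

from __future__ import annotations

import json
from fractions import Fraction
from math import comb

import pytest


def exact_binom_pmf(k: int, n: int, p_num: int, p_den: int) -> Fraction:
    """Binomial pmf as an exact rational: C(n,k) p^k (1-p)^(n-k)."""
    p = Fraction(p_num, p_den)
    return comb(n, k) * p**k * (1 - p) ** (n - k)


def exact_hypergeom_pmf(k: int, K: int, n: int, N: int) -> Fraction:
    """Hypergeometric pmf as an exact rational."""
    if k > min(K, n) or k < max(0, n - (N - K)):
        return Fraction(0)
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


CHAIN_OBO = """format-version: 1.2
data-version: chain/1

[Term]
id: HP:0000003
name: C root

[Term]
id: HP:0000002
name: B mid
is_a: HP:0000003 ! C root

[Term]
id: HP:0000001
name: A leaf
is_a: HP:0000002 ! B mid
"""

DIAMOND_OBO = """format-version: 1.2
data-version: diamond/1

[Term]
id: HP:000000A
name: top

[Term]
id: HP:000000B
name: left
is_a: HP:000000A ! top

[Term]
id: HP:000000C
name: right
is_a: HP:000000A ! top

[Term]
id: HP:000000D
name: bottom
is_a: HP:000000B ! left
is_a: HP:000000C ! right
"""

CYCLE_OBO = """format-version: 1.2

[Term]
id: HP:0000001
name: A
is_a: HP:0000002 ! B

[Term]
id: HP:0000002
name: B
is_a: HP:0000001 ! A
"""


@pytest.fixture
def chain_obo(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(CHAIN_OBO)
    return path


@pytest.fixture
def diamond_obo(tmp_path):
    path = tmp_path / "diamond.obo"
    path.write_text(DIAMOND_OBO)
    return path


@pytest.fixture
def cycle_obo(tmp_path):
    path = tmp_path / "cycle.obo"
    path.write_text(CYCLE_OBO)
    return path


@pytest.fixture
def diamond_obographs(tmp_path):
    """The diamond DAG as an obographs JSON document."""

    def iri(t):
        return f"http://purl.obolibrary.org/obo/{t.replace(':', '_')}"

    doc = {
        "graphs": [
            {
                "meta": {"version": "diamond-json/1"},
                "nodes": [
                    {"id": iri(t), "lbl": lbl, "type": "CLASS"}
                    for t, lbl in [
                        ("HP:000000A", "top"),
                        ("HP:000000B", "left"),
                        ("HP:000000C", "right"),
                        ("HP:000000D", "bottom"),
                    ]
                ],
                "edges": [
                    {"sub": iri("HP:000000B"), "pred": "is_a", "obj": iri("HP:000000A")},
                    {"sub": iri("HP:000000C"), "pred": "is_a", "obj": iri("HP:000000A")},
                    {"sub": iri("HP:000000D"), "pred": "is_a", "obj": iri("HP:000000B")},
                    {"sub": iri("HP:000000D"), "pred": "is_a", "obj": iri("HP:000000C")},
                ],
            }
        ]
    }
    path = tmp_path / "diamond.json"
    path.write_text(json.dumps(doc))
    return path
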