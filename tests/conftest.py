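"""Shared fixtures: one generated OBO/GAF/MITAB triple (seed 1) per session."""

from __future__ import annotations

import pytest

from godissim import db, fixtures


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fx")
    ledger = fixtures.generate(1, str(d))
    return d, ledger


@pytest.fixture(scope="session")
def ledger(fixture_dir):
    return fixture_dir[1]


@pytest.fixture(scope="session")
def store(fixture_dir):
    d, ledger = fixture_dir
    config = db.BuildConfig(taxon=ledger.taxon)
    return db.build(
        str(d / "fixture.obo"),
        str(d / "fixture.gaf"),
        str(d / "fixture.mitab"),
        str(d / "mapping.tsv"),
        config,
    )


@pytest.fixture(scope="session")
def graph(store):
    return store.graph


@pytest.fixture(scope="session")
def table(store):
    return store.table


@pytest.fixture(scope="session")
def network(store):
    return store.network


def brute_force_closure(edges, relations=("is_a", "part_of")):
    """Independent transitive-closure oracle from raw (child, parent, relation) rows."""
    parents: dict[str, set[str]] = {}
    for c, p, r in edges:
        if r in relations:
            parents.setdefault(c, set()).add(p)

    def closure(term: str) -> set[str]:
        out: set[str] = set()
        stack = [term]
        while stack:
            for p in parents.get(stack.pop(), ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    return closure
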