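"""Store build/query/summarize, persistence determinism and the CLI."""

import pytest
from click.testing import CliRunner

from godissim import cli, db
from godissim.cooccurrence import ap_counts, ip_counts, pair_result
from godissim.errors import ParseError


def _paths(d):
    return (str(d / "fixture.obo"), str(d / "fixture.gaf"),
            str(d / "fixture.mitab"), str(d / "mapping.tsv"))


def test_build_pool_sizes_match_ledger(store, ledger):
    assert store.meta["counts"]["pools"] == {
        ns: ledger.pool_sizes["AP"][ns]
        for ns in ("biological_process", "molecular_function", "cellular_component")
    }
    assert store.network.edges == {tuple(e) for e in ledger.edges}


def test_taxon_mismatch_is_hard_error(fixture_dir):
    d, _ledger = fixture_dir
    obo, gaf, mitab, mapping = _paths(d)
    with pytest.raises(ParseError, match="taxon"):
        db.build(obo, gaf, mitab, mapping, db.BuildConfig(taxon=7227))


def test_rebuild_writes_byte_identical_tables(fixture_dir, tmp_path):
    d, ledger = fixture_dir
    obo, gaf, mitab, mapping = _paths(d)
    cfg = db.BuildConfig(taxon=ledger.taxon)
    db.build(obo, gaf, mitab, mapping, cfg, out_dir=str(tmp_path / "s1"))
    db.build(obo, gaf, mitab, mapping, cfg, out_dir=str(tmp_path / "s2"))
    for name in ("terms.tsv", "ontology_edges.tsv", "annotations.tsv", "network.tsv"):
        assert (tmp_path / "s1" / name).read_bytes() == (tmp_path / "s2" / name).read_bytes()


def test_store_load_round_trip(fixture_dir, store, tmp_path, ledger):
    d, _ = fixture_dir
    db.save(store, str(tmp_path / "st"))
    loaded = db.load(str(tmp_path / "st"))
    pairs = [tuple(ledger.planted_dissimilar[0]), tuple(ledger.planted_similar[0])]
    orig = db.query(store, pairs, mode="both")
    back = db.query(loaded, pairs, mode="both")
    assert [(r.p_low, r.category, r.counts) for r in orig] == \
           [(r.p_low, r.category, r.counts) for r in back]


def test_query_rows_equal_direct_module_calls(store, ledger):
    (d1, d2), = ledger.planted_dissimilar
    rows = db.query(store, [(d1, d2)], mode="both")
    ap_ref = pair_result(d1, d2, ap_counts(d1, d2, store.table, store.graph))
    ip_ref = pair_result(d1, d2, ip_counts(d1, d2, store.table, store.network, store.graph))
    assert rows[0].p_low == ap_ref.p_low and rows[0].counts == ap_ref.counts
    assert rows[1].p_low == ip_ref.p_low and rows[1].counts == ip_ref.counts


def test_query_symmetric_in_pair_order(store, ledger):
    (s1, s2), = ledger.planted_similar
    a = db.query(store, [(s1, s2)], mode="both")
    b = db.query(store, [(s2, s1)], mode="both")
    for ra, rb in zip(a, b):
        assert (ra.p_low, ra.expected, ra.jaccard, ra.kappa, ra.category) == \
               (rb.p_low, rb.expected, rb.jaccard, rb.kappa, rb.category)


def test_query_na_for_unannotated_term(store, ledger):
    un = ledger.unannotated_terms[0]
    other = ledger.planted_dissimilar[0][0]
    for r in db.query(store, [(un, other)], mode="both"):
        assert r.category == "NA" and r.p_low is None


def test_query_invalid_id_gives_error_marker_not_crash(store):
    rows = db.query(store, [("BANANA", "GO:9000007"), ("GO:9000007", "GO:9000008")], mode="AP")
    assert rows[0].category == "Error" and rows[0].error
    assert rows[1].category in ("Dissimilar", "NotDissimilar")


def test_query_output_preserves_input_order(store, ledger):
    pairs = [tuple(ledger.planted_similar[0]), tuple(ledger.planted_dissimilar[0])]
    rows = db.query(store, pairs, mode="AP")
    assert [(r.go1, r.go2) for r in rows] == pairs


def test_query_tsv_columns(store, ledger, tmp_path):
    rows = db.query(store, [tuple(ledger.planted_dissimilar[0])], mode="both",
                    power_seed=17, power_sims=200)
    out = tmp_path / "q.tsv"
    db.write_query_tsv(rows, str(out))
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == list(db.QUERY_COLUMNS)
    first = dict(zip(db.QUERY_COLUMNS, lines[1].split("\t")))
    assert first["category"] == "Dissimilar"
    assert first["power"] != "NA" and first["power_seed"] != "NA"


def test_summarize_fractions(store):
    for mode in ("AP", "IP"):
        s = db.summarize(store, mode)
        assert 0 <= s["Dissimilar"] and 0 <= s["NotDissimilar"]
        assert s["Dissimilar"] + s["NotDissimilar"] <= 1.0 + 1e-12
        assert s["Dissimilar"] + s["NotDissimilar"] + s["NA"] == pytest.approx(1.0)


def test_summarize_all_na_store(store):
    # a store whose annotation table is empty after filtering: every pair NA
    empty = db.Store(config=store.config, graph=store.graph,
                     table=type(store.table)(taxon=store.config.taxon),
                     network=store.network)
    empty.table.propagated = {}
    s = db.summarize(empty, "AP")
    assert s["Dissimilar"] == 0.0 and s["NotDissimilar"] == 0.0


def test_cli_end_to_end(tmp_path):
    runner = CliRunner()
    fx = tmp_path / "fx"
    st = tmp_path / "st"
    r = runner.invoke(cli.main, ["fixtures", "--seed", "2", "--out", str(fx)])
    assert r.exit_code == 0, r.output
    r = runner.invoke(cli.main, [
        "build", "--obo", str(fx / "fixture.obo"), "--gaf", str(fx / "fixture.gaf"),
        "--mitab", str(fx / "fixture.mitab"), "--mapping", str(fx / "mapping.tsv"),
        "--taxon", "9999", "--out", str(st),
    ])
    assert r.exit_code == 0, r.output
    out = tmp_path / "res.tsv"
    r = runner.invoke(cli.main, [
        "query", "--store", str(st), "--pair", "GO:9000007,GO:9000008",
        "--mode", "both", "--out", str(out),
    ])
    assert r.exit_code == 0, r.output
    lines = out.read_text().splitlines()
    assert len(lines) == 3 and lines[1].split("\t")[2] == "AP"
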