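"""MeSH term extraction, query rendering and literature validation."""

import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

import pytest

from conftest import C1, C2, D1, G1, G2
from clingenmap.concept_mapping import CandidateRelation
from clingenmap.literature import (
    EntrezLiteratureBackend,
    MalformedResponseError,
    OfflineLiteratureIndex,
    TransientBackendError,
    ValidationAborted,
    build_query,
    count_hits,
    mesh_terms_for,
    validate_relations,
    write_validation_report,
)


class TestMeshTerms:
    def test_cui_without_mesh_atoms_is_empty(self, tiny_kb):
        assert not mesh_terms_for(C2, tiny_kb)

    def test_terms_collected_preferred_first(self, tiny_kb):
        terms = mesh_terms_for(C1, tiny_kb)
        assert terms.terms == ("Abdominal Pain",)
        g_terms = mesh_terms_for(G1, tiny_kb)
        assert g_terms.terms == ("Genes, alpha", "alpha gene synonym")

    def test_suppressed_mesh_atoms_excluded(self, tiny_kb):
        assert "old alpha name" not in mesh_terms_for(G1, tiny_kb).terms


class TestBuildQuery:
    def test_worked_example_template(self):
        query = build_query("Abdominal Pain", "Genes, fos",
                            "Colorectal neoplasms")
        assert query.rendered == ("Abdominal Pain[MeSH Terms] AND "
                                  "Genes, fos[MeSH Terms] AND "
                                  "Colorectal neoplasms[MeSH Terms]")

    def test_minimal_terms(self):
        assert build_query("a", "b", "c").rendered == (
            "a[MeSH Terms] AND b[MeSH Terms] AND c[MeSH Terms]")

    @pytest.mark.parametrize("x,y,ctx", [("", "b", "c"), ("a", "", "c"),
                                         ("a", "b", "")])
    def test_empty_term_rejected(self, x, y, ctx):
        with pytest.raises(ValueError, match="non-empty"):
            build_query(x, y, ctx)


class TestOfflineIndex:
    def test_empty_index_counts_zero(self):
        index = OfflineLiteratureIndex()
        assert count_hits(build_query("a", "b", "c"), index) == 0

    def test_counts_records_with_all_three_terms(self):
        index = OfflineLiteratureIndex([
            ("r1", ["Abdominal Pain", "Genes, fos", "Colorectal neoplasms"]),
            ("r2", ["abdominal pain", "genes, fos", "colorectal neoplasms",
                    "extra term"]),
            ("r3", ["Abdominal Pain", "Genes, fos"]),  # only two of three
            ("r4", ["Genes, fos", "Colorectal neoplasms"]),
            ("r5", ["unrelated", "terms", "here"]),
        ])
        query = build_query("Abdominal Pain", "Genes, fos",
                            "Colorectal neoplasms")
        assert index.count(query) == 2

    def test_file_roundtrip(self, tmp_path):
        index = OfflineLiteratureIndex([("r1", ["a", "b"]), ("r2", ["c"])])
        path = tmp_path / "index.tsv"
        index.to_file(path)
        reread = OfflineLiteratureIndex.from_file(path)
        assert len(reread) == 2
        assert reread.count(build_query("a", "b", "a")) == 1


def _candidate(g, c):
    return CandidateRelation(g, c, "direct", "genomic_to_clinic", ("e",))


class TestValidateRelations:
    def test_empty_candidates(self, tiny_kb):
        assert validate_relations([], tiny_kb, OfflineLiteratureIndex()) == []

    def test_supported_subset_passes(self, tiny_kb):
        index = OfflineLiteratureIndex([
            ("r1", ["Abdominal Pain", "Genes, alpha", "Colorectal neoplasms"]),
        ])
        candidates = [_candidate(G1, C1), _candidate(G2, C1)]
        validated = validate_relations(candidates, tiny_kb, index)
        assert [v.passed for v in validated] == [True, False]
        assert validated[0].hit_count == 1
        # candidate order is preserved
        assert [v.relation for v in validated] == candidates

    def test_synonym_combinations_tried_until_hit(self, tiny_kb):
        index = OfflineLiteratureIndex([
            ("r1", ["Abdominal Pain", "alpha gene synonym",
                    "Colorectal neoplasms"]),
        ])
        (validated,) = validate_relations([_candidate(G1, C1)], tiny_kb, index)
        assert validated.passed
        assert len(validated.queries) == 2  # preferred term pair missed first

    def test_missing_mesh_terms_fail_without_query(self, tiny_kb):
        (validated,) = validate_relations([_candidate(G1, C2)], tiny_kb,
                                          OfflineLiteratureIndex())
        assert not validated.passed
        assert validated.queries == ()

    def test_backend_error_aborts_with_validated_prefix(self, tiny_kb):
        class Exploding:
            def __init__(self):
                self.calls = 0

            def count(self, query):
                self.calls += 1
                if self.calls > 1:
                    raise TransientBackendError("down")
                return 1

        with pytest.raises(ValidationAborted) as info:
            validate_relations([_candidate(G1, C1), _candidate(G1, C1)],
                               tiny_kb, Exploding())
        assert len(info.value.validated) == 1
        assert info.value.validated[0].passed

    def test_report_writer(self, tiny_kb, tmp_path):
        index = OfflineLiteratureIndex([
            ("r1", ["Abdominal Pain", "Genes, alpha", "Colorectal neoplasms"]),
        ])
        validated = validate_relations([_candidate(G1, C1)], tiny_kb, index)
        path = tmp_path / "report.tsv"
        write_validation_report(validated, path, tiny_kb, provenance=("x",))
        lines = path.read_text(encoding="utf-8").splitlines()
        assert lines[0] == "# x"
        assert lines[1].split("\t")[-2:] == ["hit_count", "passed"]
        assert lines[2].split("\t")[-2:] == ["1", "true"]


# --- live endpoint behaviour against a local stub server -------------------

class _StubHandler(BaseHTTPRequestHandler):
    mode = "ok"

    def do_GET(self):
        if self.mode == "ok":
            body = b"<eSearchResult><Count>7</Count></eSearchResult>"
            self.send_response(200)
            self.send_header("Content-Type", "text/xml")
            self.end_headers()
            self.wfile.write(body)
        elif self.mode == "malformed":
            self.send_response(200)
            self.end_headers()
            self.wfile.write(b"<eSearchResult><NoCount/></eSearchResult>")
        else:
            self.send_response(500)
            self.end_headers()

    def log_message(self, *args):
        pass


@pytest.fixture()
def stub_server():
    server = ThreadingHTTPServer(("127.0.0.1", 0), _StubHandler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    yield f"http://127.0.0.1:{server.server_address[1]}/esearch"
    server.shutdown()


class TestEntrezBackend:
    def test_parses_count_field(self, stub_server):
        _StubHandler.mode = "ok"
        backend = EntrezLiteratureBackend(stub_server, min_interval=0.0)
        assert backend.count(build_query("a", "b", "c")) == 7

    def test_malformed_response_distinguished(self, stub_server):
        _StubHandler.mode = "malformed"
        backend = EntrezLiteratureBackend(stub_server, min_interval=0.0)
        with pytest.raises(MalformedResponseError):
            backend.count(build_query("a", "b", "c"))

    def test_server_errors_exhaust_retries(self, stub_server):
        _StubHandler.mode = "error"
        backend = EntrezLiteratureBackend(stub_server, min_interval=0.0,
                                          max_retries=2, backoff=0.01)
        with pytest.raises(TransientBackendError):
            backend.count(build_query("a", "b", "c"))
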