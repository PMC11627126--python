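"""Annotation search and structured editing."""

import copy
import json

import pytest
from hypothesis import given, settings, strategies as st

from vsegdb import editor, store
from vsegdb.errors import ConflictError, NotFoundError, ValidationFailure

from conftest import KEY_1273


@pytest.fixture()
def ann_doc(protocol_db):
    path = store.entry_dir(protocol_db, KEY_1273) / "annotations.json"
    return json.loads(path.read_text())


def _oracle_search(doc, query):
    """Exhaustive tree walk, written independently of the implementation."""
    kws = [k.lower() for k in query.split()]
    found = []

    def rec(node, ptr):
        if isinstance(node, dict):
            items = [(editor.escape_token(str(k)), k, v)
                     for k, v in node.items()]
            for esc, k, v in items:
                if all(w in str(k).lower() for w in kws):
                    found.append(f"{ptr}/{esc}")
                rec(v, f"{ptr}/{esc}")
        elif isinstance(node, list):
            for i, v in enumerate(node):
                rec(v, f"{ptr}/{i}")
        elif isinstance(node, str) and kws and all(
                w in node.lower() for w in kws):
            found.append(ptr)

    rec(doc, "")
    return sorted(set(found))


class TestSearch:
    def test_mask_id_found_in_description_and_segment_annotation(self,
                                                                 ann_doc):
        hits = editor.search_annotations(ann_doc, "emd_1273_msk_1")
        assert len(hits) >= 2
        assert any(h.startswith("/descriptions") for h in hits)
        assert any(h.startswith("/segment_annotations") for h in hits)

    def test_equals_tree_walk_oracle(self, ann_doc):
        for query in ("emd_1273_msk_1", "Segment", "segment 1", "lattice sa"):
            assert editor.search_annotations(ann_doc, query) == \
                _oracle_search(ann_doc, query)

    def test_two_keywords_require_both(self, ann_doc):
        both = editor.search_annotations(ann_doc, "msk_2 desc")
        assert both
        for ptr in both:
            leaf = editor.resolve_pointer(ann_doc, ptr)
            text = ptr.rsplit("/", 1)[-1] if not isinstance(leaf, str) else leaf
            assert "msk_2" in text.lower() and "desc" in text.lower()

    def test_empty_document_and_empty_query(self):
        assert editor.search_annotations({}, "anything") == []
        assert editor.search_annotations({"a": "b"}, "") == []

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.recursive(
        st.one_of(st.text(max_size=8), st.integers(), st.booleans()),
        lambda children: st.one_of(
            st.lists(children, max_size=3),
            st.dictionaries(st.text(max_size=6), children, max_size=3)),
        max_leaves=12),
        st.text(alphabet="abc 1", min_size=1, max_size=5))
    def test_oracle_equivalence_on_arbitrary_documents(self, doc, query):
        assert editor.search_annotations(doc, query) == \
            _oracle_search(doc, query)


class TestEdit:
    PTR = "/descriptions/desc-emd_1273_msk_1-1/name"

    def test_set_name_replaces_placeholder(self, ann_doc):
        new = editor.edit_at_pointer(
            ann_doc, self.PTR, "Microtubule (MT) network within the CTL")
        assert editor.resolve_pointer(new, self.PTR) == \
            "Microtubule (MT) network within the CTL"
        # original untouched (purity)
        assert editor.resolve_pointer(ann_doc, self.PTR) == "Segment 1"

    def test_set_then_set_back_is_identity(self, ann_doc):
        original = json.dumps(ann_doc, sort_keys=True)
        new = editor.edit_at_pointer(ann_doc, self.PTR, "temp")
        back = editor.edit_at_pointer(new, self.PTR, "Segment 1")
        assert json.dumps(back, sort_keys=True) == original

    def test_edit_equals_direct_document_surgery(self, ann_doc):
        new = editor.edit_at_pointer(ann_doc, self.PTR, "XYZ")
        manual = copy.deepcopy(ann_doc)
        manual["descriptions"]["desc-emd_1273_msk_1-1"]["name"] = "XYZ"
        assert new == manual

    def test_unresolvable_pointer(self, ann_doc):
        with pytest.raises(NotFoundError):
            editor.edit_at_pointer(ann_doc, "/descriptions/ghost/name", "x")

    def test_validation_regression_rejected(self, ann_doc):
        with pytest.raises(ValidationFailure):
            editor.edit_at_pointer(
                ann_doc, "/descriptions/desc-emd_1273_msk_1-1/target_kind",
                "not-a-kind")

    def test_retype_details_to_object_then_rebuild(self, ann_doc):
        ptr = "/descriptions/desc-emd_1273_msk_1-1/details"
        doc = editor.retype_at_pointer(ann_doc, ptr, "object")
        assert editor.resolve_pointer(doc, ptr) == {}
        doc = editor.append_field(doc, ptr, "format", "markdown")
        doc = editor.append_field(doc, ptr, "text",
                                  "# Biological context\nThe **MTs** ...")
        details = editor.resolve_pointer(doc, ptr)
        assert details == {"format": "markdown",
                           "text": "# Biological context\nThe **MTs** ..."}
        assert editor.search_annotations(doc, "biological context")

    def test_retype_to_same_kind_empties(self, ann_doc):
        ptr = "/descriptions/desc-emd_1273_msk_1-1/name"
        assert editor.resolve_pointer(
            editor.retype_at_pointer(ann_doc, ptr, "string"), ptr) == ""

    def test_append_duplicate_key_conflicts(self, ann_doc):
        ptr = "/descriptions/desc-emd_1273_msk_1-1"
        with pytest.raises(ConflictError):
            editor.append_field(ann_doc, ptr, "name", "again")


class TestCommit:
    @pytest.fixture()
    def editable_db(self, tmp_path, input_files):
        from vsegdb.preprocess import InputSpec, preprocess_entry

        db = tmp_path / "db"
        preprocess_entry(
            [InputSpec(input_files["map_1273"], "map")]
            + [InputSpec(input_files[f"mask_{i}"], "mask")
               for i in range(1, 6)],
            KEY_1273, tmp_path / "w", db)
        return db

    def test_commit_round_trip(self, editable_db):
        path = store.entry_dir(editable_db, KEY_1273) / "annotations.json"
        doc = json.loads(path.read_text())
        new = editor.edit_at_pointer(
            doc, "/descriptions/desc-emd_1273_msk_1-1/name", "edited")
        editor.commit_annotations(editable_db, KEY_1273, new)
        assert json.loads(path.read_text()) == new

    def test_invalid_document_leaves_store_untouched(self, editable_db):
        path = store.entry_dir(editable_db, KEY_1273) / "annotations.json"
        before = path.read_bytes()
        with pytest.raises(ValidationFailure):
            editor.commit_annotations(editable_db, KEY_1273, {"broken": True})
        assert path.read_bytes() == before

    def test_commit_is_atomic_replace(self, editable_db, monkeypatch):
        """No intermediate truncated file is ever visible at the target path."""
        import os

        path = store.entry_dir(editable_db, KEY_1273) / "annotations.json"
        doc = json.loads(path.read_text())
        observed = []
        real_replace = os.replace

        def spy(src, dst):
            # just before the swap, the target must still be the old document
            observed.append(json.loads(path.read_text()))
            return real_replace(src, dst)

        monkeypatch.setattr(os, "replace", spy)
        new = editor.edit_at_pointer(
            doc, "/descriptions/desc-emd_1273_msk_2-1/name", "swapped")
        editor.commit_annotations(editable_db, KEY_1273, new)
        assert observed == [doc]
        assert json.loads(path.read_text()) == new
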