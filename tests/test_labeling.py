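"""Labeling-function templates and label-matrix construction."""

import numpy as np
import pytest

from ontoweave.corpus import EntitySpan, tokenize, TokenizerConfig
from ontoweave.labeling import (
    ABSTAIN,
    LabelMatrix,
    LabelingFunction,
    build_label_matrix,
    context_window_lf,
    datetime_distance_lf,
    dict_lf,
    find_terminology_matches,
    fuzzy_bigram_lf,
    regex_lf,
    schwartz_hearst_pairs,
    section_header_lf,
    semantic_type_lf,
    synset_lf,
)
from ontoweave.ontology import SynsetCollection, Terminology, build_bigram_graph


def _term(name, term_to_vec, k=1):
    return Terminology(
        name=name, terms={t: np.asarray(v, dtype=float) for t, v in term_to_vec.items()}, k=k
    )


class TestSemanticTypeLF:
    def test_longest_match_disambiguates_nested_terms(self):
        t = _term("demo", {"lung": [1, 0], "lung cancer": [0, 1]})
        lf = semantic_type_lf(t)
        doc = tokenize("Patient has lung cancer today")
        votes = lf(doc)
        # 'lung cancer' wins over 'lung': both words vote the disease class
        assert votes.tolist() == [ABSTAIN, ABSTAIN, 1, 1, ABSTAIN]

    def test_shorter_match_used_when_longer_absent(self):
        t = _term("demo", {"lung": [1, 0]})
        votes = semantic_type_lf(t)(tokenize("the lung cancer"))
        assert votes.tolist() == [ABSTAIN, 0, ABSTAIN]

    def test_tied_vector_abstains(self):
        t = _term("demo", {"lung": [0.5, 0.5]})
        votes = semantic_type_lf(t)(tokenize("left lung"))
        assert votes.tolist() == [ABSTAIN, ABSTAIN]

    def test_case_sensitive_term_not_matched_lowercase(self):
        t = Terminology(
            "abbr", {"DMD": np.array([0.0, 1.0])}, k=1, case_sensitive_terms={"DMD"}
        )
        lf = semantic_type_lf(t)
        assert lf(tokenize("DMD confirmed")).tolist() == [1, ABSTAIN]
        assert lf(tokenize("dmd confirmed")).tolist() == [ABSTAIN, ABSTAIN]

    def test_slot_filled_paren_pattern(self):
        t = _term("drug", {"tylenol": [0, 1], "acetaminophen": [0, 1]})
        doc = tokenize("gave Tylenol (Acetaminophen) now")
        votes = semantic_type_lf(t, slot_patterns=["{*} ({*})"])(doc)
        # whole construction, including parens, voted as one match
        assert votes.tolist() == [ABSTAIN, 1, 1, 1, 1, ABSTAIN]

    def test_no_two_matches_overlap_and_maximality(self, rng):
        vocab = [f"w{i}" for i in range(10)]
        terms = {}
        for _ in range(15):
            L = int(rng.integers(1, 4))
            terms[" ".join(rng.choice(vocab, size=L))] = [0, 1]
        t = _term("rand", terms)
        doc = tokenize(" ".join(rng.choice(vocab, size=60)))
        matches = find_terminology_matches(doc, t)
        spans = sorted((m.start_word, m.end_word) for m in matches)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 <= a2  # no overlaps
        words = [w.lower() for w in doc.words()]
        for m in matches:  # not extendable to a longer in-dictionary match at same start
            for longer in range(m.end_word - m.start_word + 1, 4):
                cand = " ".join(words[m.start_word : m.start_word + longer])
                assert cand not in t.terms or len(cand.split()) < longer


class TestSynsetLF:
    def _synsets(self):
        return SynsetCollection.from_pairs(
            [("C1", "Duchenne muscular dystrophy"), ("C1", "DMD")]
        )

    def test_two_synonyms_license_all_mentions(self, disease_terminology):
        doc = tokenize("Duchenne muscular dystrophy ( DMD ) was noted. DMD progressing.")
        votes = synset_lf(self._synsets(), disease_terminology)(doc)
        words = doc.words()
        for i, w in enumerate(words):
            if w in ("Duchenne", "muscular", "dystrophy", "DMD"):
                assert votes[i] == 1, (i, w)
            else:
                assert votes[i] == ABSTAIN

    def test_single_synonym_abstains(self, disease_terminology):
        doc = tokenize("DMD progressing.")
        assert (synset_lf(self._synsets(), disease_terminology)(doc) == ABSTAIN).all()

    def test_matches_brute_force_co_occurrence_scan(self, rng):
        vocab = [f"w{i}" for i in range(8)]
        syn_pairs = [("C1", "alpha"), ("C1", "beta"), ("C2", "gamma"), ("C2", "delta")]
        source = _term("src", {"alpha": [0, 1], "beta": [0, 1], "gamma": [0, 1], "delta": [0, 1]})
        lf = synset_lf(SynsetCollection.from_pairs(syn_pairs), source)
        for _ in range(20):
            words = list(rng.choice(vocab + ["alpha", "beta", "gamma", "delta"], size=15))
            doc = tokenize(" ".join(words))
            votes = lf(doc)
            low = [w.lower() for w in doc.words()]
            for cid, syns in (("C1", {"alpha", "beta"}), ("C2", {"gamma", "delta"})):
                present = {s for s in syns if s in low}
                for i, w in enumerate(low):
                    if w in syns:
                        assert votes[i] == (1 if len(present) > 1 else ABSTAIN)


class TestSchwartzHearst:
    def test_canonical_pair(self):
        doc = tokenize("Duchenne muscular dystrophy ( DMD ) noted")
        (pair,) = schwartz_hearst_pairs(doc)
        assert pair.short_form == "DMD"
        assert pair.long_form == "Duchenne muscular dystrophy"

    def test_non_abbreviation_parenthetical_rejected(self):
        assert schwartz_hearst_pairs(tokenize("weight ( kg ) stable")) == []

    def test_alignment_on_generated_pairs(self, rng):
        # construct LONG (SHORT) instances whose short form is the initials
        words_pool = ["gamma", "delta", "omega", "sigma", "kappa"]
        for _ in range(15):
            n = int(rng.integers(2, 4))
            long_words = list(rng.choice(words_pool, size=n, replace=False))
            short = "".join(w[0].upper() for w in long_words)
            doc = tokenize(f"history of {' '.join(long_words)} ( {short} ) today")
            pairs = schwartz_hearst_pairs(doc)
            assert len(pairs) == 1
            assert pairs[0].short_form == short
            assert pairs[0].long_form == " ".join(long_words)

    def test_synset_lf_with_schwartz_hearst_licenses_short_form(self, disease_terminology):
        doc = tokenize("Duchenne muscular dystrophy ( DMD ) noted. DMD worse.")
        syn = SynsetCollection.from_pairs([("C9", "unrelated")])
        votes = synset_lf(syn, disease_terminology, use_schwartz_hearst=True)(doc)
        words = doc.words()
        assert all(votes[i] == 1 for i, w in enumerate(words) if w == "DMD")


class TestPatternLFs:
    def test_punctuation_dictionary_votes_negative(self):
        lf = dict_lf("punct", {",", ".", "(", ")"}, vote=0)
        doc = tokenize("fever , cough .")
        assert lf(doc).tolist() == [ABSTAIN, 0, ABSTAIN, 0]

    def test_dict_lf_equals_exhaustive_scan(self, rng):
        vocab = [f"w{i}" for i in range(10)]
        terms = set(rng.choice(vocab, size=4, replace=False))
        lf = dict_lf("rand", terms, vote=1)
        doc = tokenize(" ".join(rng.choice(vocab, size=50)))
        votes = lf(doc)
        for i, w in enumerate(doc.words()):
            assert votes[i] == (1 if w.lower() in terms else ABSTAIN)

    def test_regex_lf_votes_covered_words(self):
        lf = regex_lf("dose", [r"\d+ mg"], vote=1)
        doc = tokenize("gave 50 mg daily")
        assert lf(doc).tolist() == [ABSTAIN, 1, 1, ABSTAIN]

    def test_regex_no_match_all_abstain(self):
        lf = regex_lf("none", [r"zzz+"], vote=1)
        assert (lf(tokenize("no match here")) == ABSTAIN).all()

    def test_invalid_regex_raises_at_construction(self):
        with pytest.raises(ValueError, match="invalid regex"):
            regex_lf("bad", ["("], vote=1)


class TestFuzzyBigramLF:
    def _graph(self):
        return build_bigram_graph([_term("T", {"type 2 diabetes mellitus": [0, 1]})])

    def test_full_chain_voted(self):
        lf = fuzzy_bigram_lf(self._graph(), vote=1)
        doc = tokenize("has type 2 diabetes now")
        assert lf(doc).tolist() == [ABSTAIN, 1, 1, 1, ABSTAIN]

    def test_missing_edge_abstains(self):
        lf = fuzzy_bigram_lf(self._graph(), vote=1)
        assert (lf(tokenize("2 mellitus")) == ABSTAIN).all()

    def test_runs_equal_brute_force_chain_check(self, rng):
        vocab = [f"w{i}" for i in range(8)]
        pairs = {tuple(rng.choice(vocab, size=2, replace=False)) for _ in range(12)}
        from ontoweave.ontology import BigramGraph

        graph = BigramGraph(pairs=pairs, vocabulary={w for p in pairs for w in p})
        lf = fuzzy_bigram_lf(graph, vote=1, min_len=2)
        for _ in range(10):
            doc = tokenize(" ".join(rng.choice(vocab, size=20)))
            votes = lf(doc)
            low = [w.lower() for w in doc.words()]
            expected = np.full(len(low), ABSTAIN)
            i = 0
            while i < len(low):
                j = i
                while j + 1 < len(low) and (low[j], low[j + 1]) in pairs:
                    j += 1
                if j > i:
                    expected[i : j + 1] = 1
                i = j + 1
            assert votes.tolist() == expected.tolist()


class TestSpanScopeLFs:
    def test_negation_cue_within_window(self):
        doc = tokenize("Patient denies fever today")
        span = EntitySpan("doc", 2, 3, 1)
        lf = context_window_lf([("denies", "left", 3, 2)])
        assert lf(doc, [span]).tolist() == [2]

    def test_cue_beyond_max_distance_abstains(self):
        doc = tokenize("denies a b c d fever")
        span = EntitySpan("doc", 5, 6, 1)
        lf = context_window_lf([("denies", "left", 3, 2)])
        assert lf(doc, [span]).tolist() == [ABSTAIN]

    def test_cue_matches_brute_force_window_scan(self, rng):
        cue, max_dist = "denies", 2
        lf = context_window_lf([(cue, "left", max_dist, 2)])
        for _ in range(20):
            words = list(rng.choice(["a", "b", "c", cue], size=10))
            doc = tokenize(" ".join(words))
            pos = int(rng.integers(1, 9))
            span = EntitySpan("doc", pos, pos + 1, 1)
            got = lf(doc, [span])[0]
            low = [w.lower() for w in doc.words()]
            expect = 2 if any(
                low[c] == cue and 0 <= pos - (c + 1) <= max_dist for c in range(len(low))
            ) else ABSTAIN
            assert got == expect

    def test_packaged_negation_lexicon_loads_and_fires(self):
        from ontoweave.labeling import default_negation_cues

        cues = default_negation_cues()
        assert ("denies", "left", 5, 1) in cues
        doc = tokenize("Patient denies fever today")
        lf = context_window_lf(cues)
        assert lf(doc, [EntitySpan("doc", 2, 3, 1)]).tolist() == [1]

    def test_section_header_vote(self, note_doc):
        # an event inside PAST MEDICAL HISTORY is before the note time
        words = note_doc.words()
        i = words.index("Diabetes")
        span = EntitySpan("note1", i, i + 2, 1)
        lf = section_header_lf({"past medical history": 1})
        assert lf(note_doc, [span]).tolist() == [1]

    def test_datetime_before_document_timestamp(self, note_doc):
        words = note_doc.words()
        i = words.index("Diabetes")
        span = EntitySpan("note1", i, i + 2, 1)
        lf = datetime_distance_lf({"before": 1, "after": 2, "overlap": 3})
        assert lf(note_doc, [span]).tolist() == [1]  # nearest date 2019-01-02 < 2020-03-01

    def test_relative_phrase_resolves_after(self):
        doc = tokenize("surgery planned", doc_id="d", timestamp="2020-03-01T00:00:00")
        # no datetime mention at all -> abstain
        lf = datetime_distance_lf()
        assert lf(doc, [EntitySpan("d", 0, 1, 1)]).tolist() == [ABSTAIN]

    def test_equidistant_datetimes_abstain(self):
        doc = tokenize(
            "2019-01-02 surgery 2021-05-05", doc_id="d", timestamp="2020-03-01T00:00:00"
        )
        lf = datetime_distance_lf()
        assert lf(doc, [EntitySpan("d", 1, 2, 1)]).tolist() == [ABSTAIN]

    def test_unparseable_timestamp_abstains(self):
        doc = tokenize("2019-01-02 surgery", doc_id="d", timestamp="not-a-date")
        lf = datetime_distance_lf()
        assert lf(doc, [EntitySpan("d", 1, 2, 1)]).tolist() == [ABSTAIN]


class TestLabelMatrix:
    def _docs(self):
        return [tokenize("fever and cough", doc_id="a"), tokenize("no fever", doc_id="b")]

    def test_shape_and_row_index(self):
        docs = self._docs()
        lfs = [dict_lf("f", {"fever"}, 1), dict_lf("c", {"cough"}, 1)]
        L = build_label_matrix(lfs, docs, k=1)
        assert L.values.shape == (5, 2)
        assert L.word_index == [("a", 0), ("a", 1), ("a", 2), ("b", 0), ("b", 1)]

    def test_columns_equal_independent_application(self):
        docs = self._docs()
        lfs = [dict_lf("f", {"fever"}, 1), dict_lf("no", {"no"}, 0)]
        L = build_label_matrix(lfs, docs, k=1)
        for j, lf in enumerate(lfs):
            expected = np.concatenate([lf(d) for d in docs])
            assert (L.values[:, j] == expected).all()

    def test_crashing_lf_isolated_to_abstain_column(self, caplog):
        def boom(doc):
            raise RuntimeError("bad rule")

        lfs = [dict_lf("ok", {"fever"}, 1), LabelingFunction("bad", "word", boom)]
        L = build_label_matrix(lfs, self._docs(), k=1)
        assert (L.values[:, 1] == ABSTAIN).all()
        assert (L.values[:, 0] != ABSTAIN).any()

    def test_mixed_scopes_rejected(self):
        lfs = [dict_lf("w", {"fever"}, 1), context_window_lf([("denies", "left", 2, 0)])]
        with pytest.raises(ValueError, match="mix"):
            build_label_matrix(lfs, self._docs(), k=1)

    def test_span_mode_rows(self):
        docs = self._docs()
        spans = [EntitySpan("a", 0, 1, 1), EntitySpan("b", 1, 2, 1)]
        lf = context_window_lf([("no", "left", 2, 0)])
        L = build_label_matrix([lf], docs, k=1, spans=spans)
        assert L.mode == "span"
        assert L.values.shape == (2, 1)
        assert L.values[1, 0] == 0  # 'no fever' negated

    def test_determinism_identical_bytes(self, disease_terminology):
        docs = self._docs()
        lfs = [semantic_type_lf(disease_terminology), dict_lf("no", {"no"}, 0)]
        d1 = build_label_matrix(lfs, docs, k=1).digest()
        d2 = build_label_matrix(lfs, docs, k=1).digest()
        assert d1 == d2

    def test_save_load_round_trip(self, tmp_path):
        L = build_label_matrix([dict_lf("f", {"fever"}, 1)], self._docs(), k=1)
        L.save(tmp_path / "L.npz")
        got = LabelMatrix.load(tmp_path / "L.npz")
        assert (got.values == L.values).all()
        assert got.word_index == L.word_index
        assert got.source_names == L.source_names
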