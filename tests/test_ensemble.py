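import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from nner.ensemble import (
    PredictionSet,
    build_inter,
    build_intra,
    ensemble_from_spec,
    majority_vote,
)
from nner.standoff import CATEGORIES, Document, Entity, write_corpus_dir


def _member(member_id, entries):
    """entries: {doc_id: [(cat, start, end), ...]}"""
    return PredictionSet(member_id, {
        doc_id: {(cat, ((s, e),)) for cat, s, e in ents}
        for doc_id, ents in entries.items()
    })


def _random_members(seed: int, k: int) -> list[PredictionSet]:
    rng = np.random.default_rng(seed)
    members = []
    for m in range(k):
        docs = {}
        for d in range(int(rng.integers(1, 4))):
            ents = set()
            for _ in range(int(rng.integers(0, 8))):
                s = int(rng.integers(0, 40))
                e = s + int(rng.integers(1, 8))
                cat = CATEGORIES[int(rng.integers(len(CATEGORIES)))]
                ents.add((cat, ((s, e),)))
            docs[f"doc{d}"] = ents
        members.append(PredictionSet(f"m{m}", docs))
    return members


class TestMajorityVote:
    def test_single_member_identity(self):
        m = _member("a", {"d": [("Drug", 0, 5), ("ADE", 10, 15)]})
        out = majority_vote([m], min_votes=1)
        assert out.docs == m.docs

    def test_most_voted_category_wins(self):
        members = [
            _member("a", {"d": [("Drug", 10, 15)]}),
            _member("b", {"d": [("Drug", 10, 15)]}),
            _member("c", {"d": [("Reason", 10, 15)]}),
        ]
        out = majority_vote(members, min_votes=1)
        assert out.docs["d"] == {("Drug", ((10, 15),))}

    def test_threshold_drops_rare_spans(self):
        members = [
            _member("a", {"d": [("Drug", 0, 5), ("ADE", 10, 15)]}),
            _member("b", {"d": [("Drug", 0, 5)]}),
            _member("c", {"d": [("Drug", 0, 5)]}),
        ]
        out = majority_vote(members, min_votes=2)
        assert out.docs["d"] == {("Drug", ((0, 5),))}

    def test_default_is_strict_majority(self):
        members = [
            _member("a", {"d": [("Drug", 0, 5)]}),
            _member("b", {"d": [("Drug", 0, 5)]}),
            _member("c", {"d": []}),
            _member("e", {"d": []}),
        ]
        # 2 votes of 4: below floor(4/2)+1 = 3
        assert majority_vote(members).docs["d"] == set()
        assert majority_vote(members, min_votes=2).docs["d"] \
            == {("Drug", ((0, 5),))}

    def test_tied_categories_all_kept(self):
        # an even split is treated as a (possibly polysemous) tie, not
        # silently resolved — both categories survive
        members = [
            _member("a", {"d": [("ADE", 10, 15)]}),
            _member("b", {"d": [("Reason", 10, 15)]}),
        ]
        out = majority_vote(members, min_votes=1)
        assert out.docs["d"] == {("Reason", ((10, 15),)), ("ADE", ((10, 15),))}

    def test_polysemous_unanimous_span_survives_voting(self):
        poly = {"d": [("Reason", 0, 9), ("ADE", 0, 9)]}
        members = [_member(m, poly) for m in "abc"]
        out = majority_vote(members)
        assert out.docs["d"] == {("Reason", ((0, 9),)), ("ADE", ((0, 9),))}

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestEnsembleProperties:
    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=1, max_value=5))
    def test_idempotence_over_duplicated_member(self, seed, k):
        member = _random_members(seed, 1)[0]
        out = majority_vote([member] * k, min_votes=k // 2 + 1)
        assert out.docs == member.docs

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_permutation_invariance(self, seed):
        members = _random_members(seed, 4)
        rng = np.random.default_rng(seed + 1)
        shuffled = [members[i] for i in rng.permutation(4)]
        a = majority_vote(members, min_votes=2)
        b = majority_vote(shuffled, min_votes=2)
        assert a.docs == b.docs

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_min_votes_monotonicity(self, seed):
        members = _random_members(seed, 5)
        prev = None
        for mv in range(1, 6):
            out = majority_vote(members, min_votes=mv)
            n = sum(len(v) for v in out.docs.values())
            if prev is not None:
                assert n <= prev
            prev = n

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_unanimous_entities_survive(self, seed):
        members = _random_members(seed, 4)
        common = {
            doc_id: set.intersection(*(m.docs.get(doc_id, set())
                                       for m in members))
            for doc_id in members[0].docs
        }
        # unanimity on (category, span); drop spans where members also
        # voted other categories (those can out-compete only by priority)
        out = majority_vote(members, min_votes=4)
        for doc_id, ents in common.items():
            spans_single = {
                (cat, span) for cat, span in ents
                if all(
                    sum(1 for c2, s2 in m.docs.get(doc_id, set())
                        if s2 == span) == 1
                    for m in members
                )
            }
            assert spans_single <= out.docs.get(doc_id, set())


class TestEnsembleBuilders:
    def test_intra_and_inter_compose(self):
        vocabs = [300, 1000, 4000, 8000, 16000]
        members = [
            _member(f"wcsub@{v}", {"d": [("Drug", 0, 5)]}) for v in vocabs
        ]
        intra = build_intra(members, member_id="intra-wcsub")
        assert intra.docs["d"] == {("Drug", ((0, 5),))}
        crf = _member("inter-crf", {"d": [("ADE", 10, 12)]})
        inter = build_inter([intra, crf], min_votes=1, member_id="nn-crf")
        assert inter.docs["d"] == {("Drug", ((0, 5),)), ("ADE", ((10, 12),))}

    def test_inter_over_identical_members_is_identity(self):
        m = _member("x", {"d": [("Drug", 0, 5)]})
        assert build_inter([m, m, m]).docs == m.docs

    def test_spec_resolution_from_directories(self, tmp_path):
        text = "velomicin given today"
        doc_a = Document("n1", text, [Entity("T1", "Drug", ((0, 9),))])
        doc_b = Document("n1", text, [
            Entity("T1", "Drug", ((0, 9),)),
            Entity("T2", "ADE", ((10, 15),)),
        ])
        dir_a = tmp_path / "a"
        dir_b = tmp_path / "b"
        write_corpus_dir([doc_a], str(dir_a))
        write_corpus_dir([doc_b], str(dir_b))
        spec = yaml.safe_load(yaml.safe_dump({
            "member_id": "submission",
            "min_votes": 2,
            "members": [{"dir": str(dir_a)}, {"dir": str(dir_b)}],
        }))
        out = ensemble_from_spec(spec)
        assert out.docs["n1"] == {("Drug", ((0, 9),))}

    def test_missing_member_directory_fails_by_name(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ensemble_from_spec({"dir": str(tmp_path / "nope")})
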