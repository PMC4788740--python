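"""Keyword filter compilation, application and screening."""

from datetime import datetime, timezone

import pytest
from scipy.stats import binom

from retrievalqc import (
    Keyword,
    KeywordSearchFilter,
    Message,
    SearchFilter,
    apply_filter,
    compile_filter,
    screen_keywords,
)
from retrievalqc.filter_engine import FilterCompileError
from retrievalqc.synthetic import GroundTruthConfig, Vocabulary, generate_labeled_corpus


def msg(i, text, author="@someone", ts="2012-10-05T12:00:00+00:00"):
    return Message(id=f"m{i}", timestamp=ts, text=text, author=author)


@pytest.fixture
def ecig_filter() -> SearchFilter:
    """Small emulation of an e-cigarette-style filter: device, brand and
    behavior categories, a co-occurrence veto, and a promo-account handle
    rule. Synthetic; not the original study keyword list."""
    return SearchFilter(
        keywords=[
            Keyword("e-cig", "device"),
            Keyword("atomizer", "device"),
            Keyword("vape pen", "device", "phrase"),
            Keyword("blucig", "brand"),
            Keyword("#vaping", "behavior", "hashtag"),
            Keyword("vaping", "behavior"),
            Keyword("perfume", "exclusion-partner"),
            Keyword("@blupromo", "handle", "handle"),
        ],
        rule={
            "any": ["e-cig", "atomizer", "vape pen", "blucig", "#vaping", "vaping"]
        },
        exclusions=[("atomizer", "perfume")],
        name="ecig-demo",
    )


class TestCompile:
    def test_empty_include_set_retrieves_nothing(self):
        f = compile_filter(SearchFilter(keywords=[Keyword("x")], rule={"any": []}))
        assert not f(msg(1, "x marks the spot"))

    def test_undeclared_keyword_in_rule(self):
        with pytest.raises(FilterCompileError, match="undeclared"):
            compile_filter(SearchFilter(keywords=[Keyword("a")], rule="missing"))

    def test_undeclared_exclusion_member(self):
        with pytest.raises(FilterCompileError, match="undeclared"):
            compile_filter(
                SearchFilter(keywords=[Keyword("a")], exclusions=[("a", "ghost")])
            )

    def test_malformed_rule_nodes(self):
        with pytest.raises(FilterCompileError):
            compile_filter(SearchFilter(keywords=[Keyword("a")], rule={"xor": ["a"]}))
        with pytest.raises(FilterCompileError):
            compile_filter(SearchFilter(keywords=[Keyword("a")], rule=42))

    def test_boolean_operators(self):
        f = compile_filter(
            SearchFilter(
                keywords=[Keyword("smoke"), Keyword("square"), Keyword("barbeque")],
                rule={"all": ["smoke", {"not": "barbeque"}]},
            )
        )
        assert f(msg(1, "I smoke squares"))
        assert not f(msg(2, "smoke from the barbeque pit"))


class TestMatching:
    def test_cooccurrence_veto(self, ecig_filter):
        f = compile_filter(ecig_filter)
        assert f(msg(1, "new atomizer arrived today"))
        assert not f(msg(2, "this perfume atomizer sprays fine mist"))

    def test_handle_rule_overrides_terms(self, ecig_filter):
        f = compile_filter(ecig_filter)
        assert f(msg(1, "nothing topical here", author="@blupromo"))
        assert f(msg(2, "check out @blupromo deals"))
        assert not f(msg(3, "nothing topical here", author="@other"))

    def test_case_insensitive_word_boundaries(self, ecig_filter):
        f = compile_filter(ecig_filter)
        assert f(msg(1, "Loving my E-CIG!"))
        # no substring matches inside longer words
        assert not f(msg(2, "the vapers convention"))

    def test_phrase_requires_adjacency(self, ecig_filter):
        f = compile_filter(ecig_filter)
        assert f(msg(1, "got a vape pen yesterday"))
        assert not f(msg(2, "got a vape and a pen yesterday"))

    def test_hashtag_with_and_without_sigil(self, ecig_filter):
        f = compile_filter(ecig_filter)
        assert f(msg(1, "all about #vaping tonight"))
        assert f(msg(2, "all about vaping tonight"))


class TestApply:
    def test_hand_computed_partition(self, ecig_filter):
        f = compile_filter(ecig_filter)
        corpus = [
            msg(0, "my new e-cig is great"),            # retrieved: device term
            msg(1, "perfume atomizer for sale"),        # vetoed
            msg(2, "lovely weather today"),             # unretrieved
            msg(3, "big #vaping cloud"),                # retrieved: hashtag
            msg(4, "promo!", author="@blupromo"),       # retrieved: handle
            msg(5, "blucig starter kit"),               # retrieved: brand
            msg(6, "atomizer maintenance tips"),        # retrieved: no veto partner
            msg(7, "pen and paper"),                    # unretrieved
            msg(8, "vape pen juice"),                   # retrieved: phrase
            msg(9, "squares after lunch"),              # unretrieved
        ]
        retrieved, unretrieved, provenance, malformed = apply_filter(corpus, f)
        assert [m.id for m in retrieved] == ["m0", "m3", "m4", "m5", "m6", "m8"]
        assert [m.id for m in unretrieved] == ["m1", "m2", "m7", "m9"]
        assert malformed == 0
        assert provenance["m1"] == ["atomizer", "perfume"]
        assert provenance["m2"] == []

    def test_partition_exhaustive_and_disjoint(self, ecig_filter):
        f = compile_filter(ecig_filter)
        corpus = [msg(i, t) for i, t in enumerate(["e-cig", "tea", "vaping", "rain"])]
        corpus.append("not a message")  # malformed record
        retrieved, unretrieved, _, malformed = apply_filter(corpus, f)
        assert len(retrieved) + len(unretrieved) == len(corpus) - malformed
        assert malformed == 1
        assert not {m.id for m in retrieved} & {m.id for m in unretrieved}

    def test_zero_match_corpus(self, ecig_filter):
        f = compile_filter(ecig_filter)
        retrieved, unretrieved, _, _ = apply_filter(
            [msg(i, "plain talk") for i in range(5)], f
        )
        assert retrieved == [] and len(unretrieved) == 5

    def test_determinism(self, ecig_filter):
        f = compile_filter(ecig_filter)
        corpus = [msg(i, t) for i, t in enumerate(["e-cig now", "x", "vaping", "y"] * 5)]
        r1 = apply_filter(corpus, f)
        r2 = apply_filter(corpus, f)
        assert [m.id for m in r1[0]] == [m.id for m in r2[0]]
        assert r1[2] == r2[2]

    def test_adding_keyword_never_shrinks_retrieved(self, ecig_filter):
        corpus = [
            msg(i, t)
            for i, t in enumerate(
                ["e-cig talk", "cloud chasing", "vaping", "nothing", "cloud nine"]
            )
        ]
        base = compile_filter(ecig_filter)
        wider_def = SearchFilter(
            keywords=list(ecig_filter.keywords) + [Keyword("cloud", "behavior")],
            rule={"any": [
                "e-cig", "atomizer", "vape pen", "blucig", "#vaping", "vaping", "cloud"
            ]},
            exclusions=list(ecig_filter.exclusions),
        )
        wider = compile_filter(wider_def)
        base_ids = {m.id for m in apply_filter(corpus, base)[0]}
        wider_ids = {m.id for m in apply_filter(corpus, wider)[0]}
        assert base_ids <= wider_ids

    def test_planted_match_rate_within_binomial_bounds(self):
        """On a synthetic corpus the observed retrieval proportion sits
        inside 99% binomial bounds of the planted prevalence (decoys off,
        filter = exact relevant-term match)."""
        n = 20_000
        cfg = GroundTruthConfig(n_messages=n, prevalence=0.02, seed=3)
        corpus = generate_labeled_corpus(cfg, decoy_fraction=0.0)
        vocab = Vocabulary()
        filt = compile_filter(
            SearchFilter(keywords=[Keyword(t, "device") for t in vocab.relevant_terms])
        )
        retrieved, _, _, _ = apply_filter(corpus.messages, filt)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.02)
        assert lo <= len(retrieved) <= hi


class TestTransformer:
    def test_transform_frame(self, ecig_filter):
        t = KeywordSearchFilter(ecig_filter)
        frame = t.fit().transform([msg(0, "e-cig here"), msg(1, "nothing")])
        assert list(frame["retrieved"]) == [True, False]
        assert frame.loc[0, "matched"] == ["e-cig"]
        assert t.get_params()["definition"] is ecig_filter


class TestScreening:
    def make_corpus(self):
        # one calendar month of messages
        base = [
            ("popular term here", 12),     # 'popular': 12 matches, all relevant
            ("niche gadget", 8),           # 'niche': 8 matches -> low frequency
            ("noisy chatter", 20),         # 'noisy': 20 matches, 5 relevant
        ]
        corpus, labels = [], {}
        i = 0
        for text, reps in base:
            for _ in range(reps):
                m = msg(i, text, ts=datetime(2012, 10, 1 + i % 28, tzinfo=timezone.utc))
                corpus.append(m)
                labels[m.id] = ("popular" in text) or ("noisy" in text and i % 4 == 0)
                i += 1
        return corpus, labels

    def test_threshold_rules(self):
        corpus, labels = self.make_corpus()
        keywords = [Keyword("popular"), Keyword("niche"), Keyword("noisy"), Keyword("absent")]
        report = screen_keywords(corpus, keywords, coded_labels=labels).set_index("surface")
        assert not report.loc["popular", "discard"]
        assert report.loc["niche", "discard"]  # 8 < 10 per month
        assert "frequency" in report.loc["niche", "reason"]
        assert report.loc["noisy", "discard"]  # precision 0.25 < 0.30
        assert report.loc["noisy", "precision"] == pytest.approx(0.25)
        assert report.loc["absent", "matches"] == 0
        assert report.loc["absent", "discard"]

    def test_no_labels_frequency_rule_only(self):
        corpus, _ = self.make_corpus()
        report = screen_keywords(corpus, [Keyword("noisy")], coded_labels=None)
        row = report.iloc[0]
        assert row["precision"] != row["precision"]  # NaN
        assert not row["discard"]  # 20/month passes frequency; no precision veto
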