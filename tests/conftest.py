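import pytest

from claimcite.corpus import PRIMARY, REVIEW, CitationRecord, Paper
from claimcite.datasets import load_study_corpus
from claimcite.graph import build_graph


def make_paper(pid, ptype=REVIEW, classification="neutral", year=1975, **extra):
    return Paper(
        id=pid,
        paper_type=ptype,
        classification=classification,
        year=year,
        label=pid,
        extra=extra,
    )


def make_primary(pid, classification="supportive", year=1966):
    return make_paper(pid, ptype=PRIMARY, classification=classification, year=year)


@pytest.fixture(scope="session")
def study_corpus():
    """A corpus realising the published diet-heart study marginals."""
    return load_study_corpus(seed=1)


@pytest.fixture(scope="session")
def study_graph(study_corpus):
    papers, records = study_corpus
    return build_graph(papers, records)


def toy_corpus():
    """Two primaries of opposite stance, three reviews citing both."""
    papers = [
        make_primary("p-sup", "supportive"),
        make_primary("p-unsup", "unsupportive"),
        make_paper("r1", classification="supportive"),
        make_paper("r2", classification="neutral"),
        make_paper("r3", classification="unsupportive"),
    ]
    records = [
        CitationRecord(r, p)
        for r in ("r1", "r2", "r3")
        for p in ("p-sup", "p-unsup")
    ]
    return papers, records
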