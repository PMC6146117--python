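import numpy as np
import pytest

from humtag import Corpus, FeatureClass, TaggerConfig, train_tagger
from humtag.synthetic import GeneratorParams, generate

PUBMED_XML = """<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>12345678</PMID>
      <Article>
        <Journal>
          <JournalIssue><PubDate><Year>2015</Year></PubDate></JournalIssue>
          <Title>Journal of Testing</Title>
        </Journal>
        <ArticleTitle>Human T-cell responses in disease.</ArticleTitle>
        <Pagination><MedlinePgn>334-41</MedlinePgn></Pagination>
        <Abstract>
          <AbstractText Label="BACKGROUND">We studied cells.</AbstractText>
          <AbstractText Label="RESULTS">Cells responded.</AbstractText>
        </Abstract>
        <AuthorList>
          <Author><LastName>Smith</LastName><Initials>JA</Initials></Author>
          <Author><LastName>Jones</LastName><Initials>B</Initials></Author>
        </AuthorList>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName UI="D006801">Humans</DescriptorName></MeshHeading>
        <MeshHeading><DescriptorName UI="D005260">Female</DescriptorName></MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture
def pubmed_xml_path(tmp_path):
    p = tmp_path / "fixture.xml"
    p.write_text(PUBMED_XML, encoding="utf-8")
    return p


@pytest.fixture(scope="session")
def small_gen():
    """A 2000-record synthetic corpus with informative title+abstract."""
    return generate(GeneratorParams(n_records=2000, seed=42,
                                    abstract_length_mean=30))


@pytest.fixture(scope="session")
def small_corpus(small_gen):
    return small_gen.corpus


@pytest.fixture(scope="session")
def trained_tagger(small_corpus):
    classes = [FeatureClass.TITLE_UNIGRAM, FeatureClass.ABSTRACT_UNIGRAM,
               FeatureClass.JOURNAL_NAME]
    return train_tagger(small_corpus, classes, TaggerConfig(seed=7))


@pytest.fixture(scope="session")
def split_small(small_gen):
    """(train corpus, test corpus, test labels, test posteriors)."""
    recs = small_gen.corpus.records
    train_c = Corpus(recs[:1600])
    test_c = Corpus(recs[1600:])
    y = np.array([r.label for r in test_c], dtype=bool)
    return train_c, test_c, y, small_gen.posterior[1600:]
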