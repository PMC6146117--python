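"""Reading and writing citation corpora.

Citations come in as PubMed/MEDLINE XML (``PubmedArticleSet``) or as a
flat citation table (JSON-lines, or TSV with JSON-encoded list cells).
The reference label for supervised work is derived from the MeSH
descriptor list: a record is a positive iff its descriptors contain
"Humans".  Records without MeSH are retained but *unlabeled* — absence
of indexing is never treated as a negative.
"""

from __future__ import annotations

import json
import logging
import unicodedata
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

HUMANS_DESCRIPTOR = "Humans"
#: MeSH unique identifier of the Humans heading, accepted as an alias
#: when descriptor UIs (rather than names) are present.
HUMANS_MESH_UI = "D006801"

_TABLE_FIELDS = (
    "id", "title", "abstract", "authors", "journal",
    "pagination", "year", "mesh_terms", "label",
)


def _nfc(text: str | None) -> str | None:
    """Normalize to Unicode NFC so tokenization is stable across encodings."""
    if text is None:
        return None
    return unicodedata.normalize("NFC", text)


@dataclass(frozen=True)
class CitationRecord:
    """One publication's bibliographic metadata.

    ``label`` is the Humans reference standard: True/False when the
    record carried MeSH indexing (or a label was supplied directly,
    e.g. for synthetic corpora), None when unlabeled.
    """

    id: str
    title: str
    abstract: str | None = None
    authors: tuple[tuple[str, str], ...] = ()
    journal: str = ""
    pagination: str | None = None
    year: int | None = None
    mesh_terms: tuple[str, ...] | None = None
    label: bool | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("CitationRecord id must be non-empty")


def reference_label(record: CitationRecord) -> bool | None:
    """Humans reference standard from the MeSH descriptor list.

    True iff the descriptors contain the "Humans" heading (exact match
    after whitespace trim; the D006801 UI is accepted as an alias).
    None when the record carries no MeSH at all — unlabeled, not
    negative.  Qualifier terms are ignored.
    """
    if record.mesh_terms is None:
        return None
    for term in record.mesh_terms:
        t = term.strip()
        if t == HUMANS_DESCRIPTOR or t == HUMANS_MESH_UI:
            return True
    return False


@dataclass(frozen=True)
class StopwordList:
    """A set of lower-case stop tokens removed during tokenization."""

    tokens: frozenset[str] = frozenset()

    def __contains__(self, token: str) -> bool:
        return token in self.tokens

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    """An ordered collection of citation records with unique ids."""

    records: list[CitationRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes = sorted({r.id for r in self.records if r.id in seen or seen.add(r.id)})
        if dupes:
            raise ValueError(f"duplicate record ids in corpus: {dupes[:10]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CitationRecord]:
        return iter(self.records)

    def labeled(self) -> "Corpus":
        """Sub-corpus of records with a reference label."""
        return Corpus([r for r in self.records if r.label is not None],
                      provenance=self.provenance)

    def prevalence(self) -> float:
        """Fraction of labeled records that are positive."""
        labeled = [r for r in self.records if r.label is not None]
        if not labeled:
            raise ValueError("corpus has no labeled records")
        return sum(r.label for r in labeled) / len(labeled)

    def subset(self, ids: Iterable[str]) -> "Corpus":
        wanted = set(ids)
        return Corpus([r for r in self.records if r.id in wanted],
                      provenance=self.provenance)


# ---------------------------------------------------------------------------
# PubMed XML
# ---------------------------------------------------------------------------

def read_pubmed_xml(source: str | Path | IO) -> Corpus:
    """Read a ``PubmedArticleSet`` XML document into a Corpus.

    One record per ``PubmedArticle``; articles with no title are skipped
    with a warning.  Missing abstract / pagination / MeSH become absent
    fields (None), never empty strings.  Malformed XML raises
    ``ValueError`` and no partial corpus is returned.
    """
    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        raise ValueError(f"malformed PubMed XML: {exc}") from exc
    root = tree.getroot()

    records: list[CitationRecord] = []
    for ordinal, art in enumerate(root.iter("PubmedArticle"), start=1):
        cit = art.find("MedlineCitation")
        if cit is None:
            cit = art
        rec = _parse_article(cit, ordinal)
        if rec is not None:
            records.append(rec)
    name = getattr(source, "name", str(source))
    return Corpus(records, provenance=f"pubmed-xml:{name}")


def _parse_article(cit: ET.Element, ordinal: int) -> CitationRecord | None:
    pmid = _text(cit.find("PMID"))
    article = cit.find("Article")
    if article is None:
        logger.warning("article #%d has no Article element; skipped", ordinal)
        return None

    title = _text(article.find("ArticleTitle"))
    if not title:
        logger.warning("article #%d (PMID %s) has no title; skipped", ordinal, pmid)
        return None

    # Structured abstracts: concatenate the section bodies with one space
    # (section labels like "METHODS:" are not included).
    abstract_el = article.find("Abstract")
    abstract: str | None = None
    if abstract_el is not None:
        parts = [_text(t) for t in abstract_el.findall("AbstractText")]
        parts = [p for p in parts if p]
        if parts:
            abstract = " ".join(parts)

    authors: list[tuple[str, str]] = []
    author_list = article.find("AuthorList")
    if author_list is not None:
        for au in author_list.findall("Author"):
            last = _text(au.find("LastName"))
            initials = _text(au.find("Initials"))
            if last:
                authors.append((last, initials or ""))

    journal = _text(article.find("Journal/Title")) or ""

    pagination = (_text(article.find("Pagination/MedlinePgn"))
                  or _text(article.find("Pagination/MedlinePagination"))
                  or _text(article.find("MedlinePagination"))
                  or None)

    year_text = _text(article.find("Journal/JournalIssue/PubDate/Year"))
    year = int(year_text) if year_text and year_text.isdigit() else None

    mesh: tuple[str, ...] | None = None
    mesh_list = cit.find("MeshHeadingList")
    if mesh_list is not None:
        mesh = tuple(_text(d) or "" for d in mesh_list.iter("DescriptorName"))

    rec = CitationRecord(
        id=pmid or f"article-{ordinal}",
        title=_nfc(title),
        abstract=_nfc(abstract),
        authors=tuple((_nfc(a), _nfc(b)) for a, b in authors),
        journal=_nfc(journal),
        pagination=_nfc(pagination),
        year=year,
        mesh_terms=tuple(_nfc(m) for m in mesh) if mesh is not None else None,
    )
    return replace(rec, label=reference_label(rec))


def _text(el: ET.Element | None) -> str | None:
    if el is None:
        return None
    return "".join(el.itertext()).strip() or None


# ---------------------------------------------------------------------------
# Citation table (JSON-lines / TSV)
# ---------------------------------------------------------------------------

def read_citation_table(path: str | Path, format: str = "auto") -> Corpus:
    """Read a citation table.

    JSON-lines: one JSON object per line with keys from
    ``id,title,abstract,authors,journal,pagination,year,mesh_terms,label``.
    TSV: a header line with those column names; list-valued cells
    (authors, mesh_terms) are JSON-encoded; empty cells mean absent.
    A ``label`` supplied directly (without mesh_terms) is accepted so
    synthetic corpora can carry known labels.
    """
    path = Path(path)
    if format == "auto":
        format = "tsv" if path.suffix in (".tsv", ".tab") else "jsonl"
    with open(path, encoding="utf-8") as fh:
        if format == "jsonl":
            rows = [json.loads(line) for line in fh if line.strip()]
        elif format == "tsv":
            rows = list(_read_tsv_rows(fh))
        else:
            raise ValueError(f"unknown citation-table format: {format!r}")
    records = [_record_from_row(row, i) for i, row in enumerate(rows, start=1)]
    return Corpus(records, provenance=f"citation-table:{path}")


def _read_tsv_rows(fh: IO) -> Iterator[dict]:
    header: list[str] | None = None
    for line in fh:
        line = line.rstrip("\n")
        if not line:
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
            if "id" not in header:
                raise ValueError("citation table is missing the 'id' column")
            continue
        row: dict = {}
        for key, cell in zip(header, cells):
            if cell == "":
                continue
            if key in ("authors", "mesh_terms"):
                row[key] = json.loads(cell)
            elif key == "year":
                row[key] = int(cell)
            elif key == "label":
                row[key] = {"true": True, "false": False}[cell.lower()]
            else:
                row[key] = cell
        yield row


def _record_from_row(row: dict, ordinal: int) -> CitationRecord:
    if "id" not in row or row["id"] in (None, ""):
        raise ValueError(f"row #{ordinal} has no id")
    mesh = row.get("mesh_terms")
    mesh_t = tuple(_nfc(m) for m in mesh) if mesh is not None else None
    rec = CitationRecord(
        id=str(row["id"]),
        title=_nfc(row.get("title") or ""),
        abstract=_nfc(row.get("abstract")),
        authors=tuple((_nfc(a), _nfc(b)) for a, b in row.get("authors") or ()),
        journal=_nfc(row.get("journal") or ""),
        pagination=_nfc(row.get("pagination")),
        year=row.get("year"),
        mesh_terms=mesh_t,
        label=None,
    )
    if "label" in row and row["label"] is not None:
        return replace(rec, label=bool(row["label"]))
    return replace(rec, label=reference_label(rec))


def write_citation_table(corpus: Corpus, path: str | Path,
                         format: str = "auto") -> None:
    """Write a Corpus; round-trips field-identically with the reader."""
    path = Path(path)
    if format == "auto":
        format = "tsv" if path.suffix in (".tsv", ".tab") else "jsonl"
    with open(path, "w", encoding="utf-8") as fh:
        if format == "jsonl":
            for rec in corpus:
                fh.write(json.dumps(_row_from_record(rec), ensure_ascii=False))
                fh.write("\n")
        elif format == "tsv":
            fh.write("\t".join(_TABLE_FIELDS) + "\n")
            for rec in corpus:
                row = _row_from_record(rec)
                cells = []
                for key in _TABLE_FIELDS:
                    val = row.get(key)
                    if val is None:
                        cells.append("")
                    elif key in ("authors", "mesh_terms"):
                        cells.append(json.dumps(val, ensure_ascii=False))
                    elif key == "label":
                        cells.append("true" if val else "false")
                    else:
                        cells.append(str(val))
                fh.write("\t".join(cells) + "\n")
        else:
            raise ValueError(f"unknown citation-table format: {format!r}")


def _row_from_record(rec: CitationRecord) -> dict:
    row: dict = {"id": rec.id, "title": rec.title, "journal": rec.journal}
    if rec.abstract is not None:
        row["abstract"] = rec.abstract
    if rec.authors:
        row["authors"] = [list(a) for a in rec.authors]
    if rec.pagination is not None:
        row["pagination"] = rec.pagination
    if rec.year is not None:
        row["year"] = rec.year
    if rec.mesh_terms is not None:
        row["mesh_terms"] = list(rec.mesh_terms)
    if rec.label is not None:
        row["label"] = rec.label
    return row


# ---------------------------------------------------------------------------
# Stop words
# ---------------------------------------------------------------------------

def load_stopwords(source: str | Path | IO | Iterable[str]) -> StopwordList:
    """Load a stop-word list: one token per line, '#' comments allowed.

    Tokens are lower-cased and deduplicated.  An empty source yields an
    empty (valid but suspicious) list with a warning.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            lines = fh.readlines()
    elif hasattr(source, "read"):
        lines = source.readlines()
    else:
        lines = list(source)
    tokens = set()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens.add(line.lower())
    if not tokens:
        logger.warning("stop-word source yielded an empty list")
    return StopwordList(frozenset(tokens))


def default_stopwords() -> StopwordList:
    """The stop-word snapshot bundled with the package."""
    from importlib.resources import files
    text = files("humtag").joinpath("data/stopwords.txt").read_text("utf-8")
    return load_stopwords(text.splitlines())
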