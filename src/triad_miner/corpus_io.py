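"""Reading, writing and fetching bibliographic corpora.

A corpus is an ordered collection of records (id, title, abstract). Three
on-disk dialects are supported: MEDLINE tagged text (``PMID-``/``TI-``/``AB-``
fields with indented continuation lines), PubMed XML (``PubmedArticleSet``),
and JSONL (one object per line with keys ``doc_id``, ``title``, ``abstract``).
An optional online front end fetches records from NCBI E-utilities; every
discovery operation downstream takes a :class:`Corpus`, so nothing in the
pipeline requires network access.
"""

from __future__ import annotations

import io
import json
import logging
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence, TextIO

from Bio import Medline
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "Corpus",
    "BooleanQuery",
    "CorpusFormatError",
    "FetchConfig",
    "read_medline",
    "read_pubmed_xml",
    "read_jsonl",
    "write_jsonl",
    "build_boolean_query",
    "filter_with_abstract",
    "fetch_pubmed",
]


class CorpusFormatError(ValueError):
    """Malformed corpus input (bad record, duplicate id, broken XML/JSON)."""


@dataclass(frozen=True)
class Document:
    """One bibliographic record: a PMID (or synthetic id), title, abstract."""

    doc_id: str
    title: str = ""
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    @property
    def text(self) -> str:
        """Title and abstract joined — the unit of phrase extraction."""
        return f"{self.title} {self.abstract}".strip()


@dataclass
class Corpus:
    """Ordered, duplicate-free collection of documents."""

    documents: list[Document] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})
            raise CorpusFormatError(f"duplicate doc_id(s): {', '.join(dups)}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.documents == other.documents


@dataclass(frozen=True)
class BooleanQuery:
    """AND of OR-groups: terms within a group are OR'd, groups are AND'd."""

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("query needs at least one group")
        for g in self.groups:
            if not g:
                raise ValueError("empty term group")
            if any(not t for t in g):
                raise ValueError("empty term in group")


def build_boolean_query(groups: Sequence[Sequence[str]]) -> str:
    """Render OR-groups joined by AND in E-utilities syntax.

    Each term is double-quoted; each group is parenthesized.
    """
    q = BooleanQuery(tuple(tuple(g) for g in groups))
    rendered = ["(" + " OR ".join(f'"{t}"' for t in g) + ")" for g in q.groups]
    return " AND ".join(rendered)


# ---------------------------------------------------------------------------
# MEDLINE tagged format
# ---------------------------------------------------------------------------

def _medline_blocks(stream: TextIO) -> Iterator[tuple[int, str]]:
    """Yield (1-based starting line number, record block) per MEDLINE record."""
    block: list[str] = []
    start = 1
    for lineno, line in enumerate(stream, start=1):
        if line.strip() == "":
            if block:
                yield start, "".join(block)
                block = []
        else:
            if not block:
                start = lineno
            block.append(line)
    if block:
        yield start, "".join(block)


def read_medline(stream: TextIO) -> Corpus:
    """Parse MEDLINE tagged text into a corpus.

    Continuation lines are joined by a single space (Bio.Medline semantics).
    Records without an ``AB`` field get an empty abstract. A record without a
    PMID raises :class:`CorpusFormatError` naming the offending line.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    for start_line, block in _medline_blocks(stream):
        records = list(Medline.parse(io.StringIO(block)))
        for rec in records:
            pmid = rec.get("PMID")
            if not pmid:
                raise CorpusFormatError(
                    f"MEDLINE record starting at line {start_line} has no PMID"
                )
            if pmid in seen:
                raise CorpusFormatError(f"duplicate PMID: {pmid}")
            seen.add(pmid)
            docs.append(
                Document(
                    doc_id=pmid,
                    title=rec.get("TI", ""),
                    abstract=rec.get("AB", ""),
                )
            )
    return Corpus(docs, source_label="medline")


# ---------------------------------------------------------------------------
# PubMed XML
# ---------------------------------------------------------------------------

def _parse_pubmed_tree(root: etree._Element) -> list[Document]:
    docs: list[Document] = []
    for art in root.iter("PubmedArticle"):
        pmid_el = art.find(".//MedlineCitation/PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            raise CorpusFormatError(
                f"PubmedArticle at line {art.sourceline} has no PMID"
            )
        title = "".join(art.find(".//ArticleTitle").itertext()) if art.find(".//ArticleTitle") is not None else ""
        # Structured abstracts: concatenate AbstractText sections in document
        # order, single-space joined.
        sections = [
            " ".join("".join(el.itertext()).split())
            for el in art.findall(".//Abstract/AbstractText")
        ]
        abstract = " ".join(s for s in sections if s)
        docs.append(Document(pmid_el.text.strip(), " ".join(title.split()), abstract))
    return docs


def read_pubmed_xml(stream: TextIO | io.BytesIO) -> Corpus:
    """Parse a ``PubmedArticleSet`` XML document into a corpus."""
    data = stream.read()
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"malformed PubMed XML: {exc}") from exc
    return Corpus(_parse_pubmed_tree(root), source_label="pubmed-xml")


# ---------------------------------------------------------------------------
# JSONL
# ---------------------------------------------------------------------------

_JSONL_KEYS = {"doc_id", "title", "abstract"}


def read_jsonl(stream: TextIO) -> Corpus:
    """Read one document per JSON line; missing title/abstract become ''."""
    docs: list[Document] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"malformed JSON on line {lineno}: {exc}") from exc
        if not isinstance(obj, dict) or "doc_id" not in obj:
            raise CorpusFormatError(f"line {lineno}: object lacks doc_id")
        unknown = set(obj) - _JSONL_KEYS
        if unknown:
            logger.warning("line %d: ignoring unknown keys %s", lineno, sorted(unknown))
        docs.append(
            Document(str(obj["doc_id"]), obj.get("title", ""), obj.get("abstract", ""))
        )
    return Corpus(docs, source_label="jsonl")


def write_jsonl(corpus: Corpus, stream: TextIO) -> None:
    """Write a corpus as JSONL; round-trips exactly through :func:`read_jsonl`."""
    for doc in corpus:
        stream.write(
            json.dumps(
                {"doc_id": doc.doc_id, "title": doc.title, "abstract": doc.abstract},
                ensure_ascii=False,
                sort_keys=True,
            )
        )
        stream.write("\n")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_with_abstract(corpus: Corpus) -> Corpus:
    """Keep only documents whose abstract is non-empty after stripping."""
    kept = [d for d in corpus if d.abstract.strip()]
    return Corpus(kept, source_label=corpus.source_label)


# ---------------------------------------------------------------------------
# E-utilities fetch (online-only; transport injectable for tests)
# ---------------------------------------------------------------------------

EUTILS_BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"

Transport = Callable[[str, dict], bytes]


def _urllib_transport(url: str, params: dict) -> bytes:
    full = url + "?" + urllib.parse.urlencode(params)
    with urllib.request.urlopen(full, timeout=60) as resp:  # pragma: no cover
        return resp.read()


@dataclass
class FetchConfig:
    """Batching, throttling and retry policy for E-utilities downloads.

    NCBI allows 3 requests/second without an API key and 10 with one; those
    are the defaults here.
    """

    batch_size: int = 200
    api_key: str | None = None
    max_retries: int = 3
    retry_wait: float = 1.0
    requests_per_second: float | None = None
    transport: Transport = _urllib_transport
    sleep: Callable[[float], None] = time.sleep

    @property
    def min_interval(self) -> float:
        rps = self.requests_per_second or (10.0 if self.api_key else 3.0)
        return 1.0 / rps


def _throttled_request(cfg: FetchConfig, state: dict, url: str, params: dict) -> bytes:
    now = time.monotonic()
    wait = state.get("next_allowed", 0.0) - now
    if wait > 0:
        cfg.sleep(wait)
    state["next_allowed"] = max(now, state.get("next_allowed", 0.0)) + cfg.min_interval
    last_exc: Exception | None = None
    for attempt in range(cfg.max_retries + 1):
        try:
            return cfg.transport(url, params)
        except Exception as exc:  # noqa: BLE001 — transport errors are opaque
            last_exc = exc
            if attempt < cfg.max_retries:
                logger.warning("request failed (%s); retry %d", exc, attempt + 1)
                cfg.sleep(cfg.retry_wait)
    raise ConnectionError(f"E-utilities request failed after retries: {last_exc}")


def fetch_pubmed(query: str, config: FetchConfig | None = None) -> Corpus:
    """Download all records matching ``query`` via esearch + efetch.

    Online-only. Uses the web-environment history server to page through
    results in ``config.batch_size`` chunks; duplicate PMIDs across batches
    are dropped keeping the first occurrence (logged).
    """
    cfg = config or FetchConfig()
    state: dict = {}
    common = {"db": "pubmed", "retmode": "xml"}
    if cfg.api_key:
        common["api_key"] = cfg.api_key

    search = _throttled_request(
        cfg, state, f"{EUTILS_BASE}/esearch.fcgi",
        {**common, "term": query, "usehistory": "y", "retmax": 0},
    )
    sroot = etree.fromstring(search)
    count = int(sroot.findtext("Count", "0"))
    webenv = sroot.findtext("WebEnv", "")
    qkey = sroot.findtext("QueryKey", "")
    logger.info("esearch: %d records", count)

    docs: list[Document] = []
    seen: set[str] = set()
    fetched = 0
    while fetched < count:
        page = _throttled_request(
            cfg, state, f"{EUTILS_BASE}/efetch.fcgi",
            {**common, "WebEnv": webenv, "query_key": qkey,
             "retstart": fetched, "retmax": cfg.batch_size},
        )
        batch = read_pubmed_xml(io.BytesIO(page))
        if len(batch) == 0:
            break
        for doc in batch:
            if doc.doc_id in seen:
                logger.warning("duplicate PMID %s across batches; keeping first", doc.doc_id)
                continue
            seen.add(doc.doc_id)
            docs.append(doc)
        fetched += len(batch)
        logger.info("fetched %d/%d", fetched, count)
    return Corpus(docs, source_label=f"pubmed:{query}")
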