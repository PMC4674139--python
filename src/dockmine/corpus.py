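"""Abstract corpora: reading, tagging, filtering, and (optional) live fetch.

A corpus is a list of :class:`AbstractRecord`.  Each record carries
*retrieval tags* saying which query matched it: ``AND`` (both interactors
mentioned) and/or ``OR-1`` / ``OR-2`` (the per-interactor halves of the
OR-query).  An abstract matched by the AND-query necessarily mentions both
interactors, so it always carries both OR tags as well.

Two on-disk formats are supported: a documented fixture JSON (canonical for
testing) and read-only MEDLINE/PubMed XML (``PubmedArticleSet``).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable

from lxml import etree

__all__ = [
    "TAG_AND",
    "TAG_OR1",
    "TAG_OR2",
    "AbstractRecord",
    "read_corpus",
    "read_medline_xml",
    "write_corpus",
    "filter_corpus",
    "PubMedFetcher",
]

TAG_AND = "AND"
TAG_OR1 = "OR-1"
TAG_OR2 = "OR-2"
_VALID_TAGS = {TAG_AND, TAG_OR1, TAG_OR2}


@dataclass
class AbstractRecord:
    """One retrieved abstract.

    ``pub_date`` may be ``None`` when the source record carries no usable
    date; such records fail any active date window.  ``svm_label`` is
    filled by the relevance classifier ("positive" / "negative" /
    "unclassified") and is ``None`` before classification.
    """

    pmid: str
    title: str = ""
    body: str = ""
    pub_date: _dt.date | None = None
    retrieved_by: set[str] = field(default_factory=set)
    svm_label: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.retrieved_by) - _VALID_TAGS
        if bad:
            raise ValueError(f"unknown retrieval tags {sorted(bad)} on PMID {self.pmid}")
        if TAG_AND in self.retrieved_by:
            # AND implies both proteins occur, hence both OR halves match.
            self.retrieved_by |= {TAG_OR1, TAG_OR2}

    @property
    def text(self) -> str:
        """Title and body concatenated, as consumed by extraction."""
        return f"{self.title}\n{self.body}" if self.title else self.body

    @property
    def and_retrieved(self) -> bool:
        return TAG_AND in self.retrieved_by


def _parse_date(value) -> _dt.date | None:
    if value in (None, ""):
        return None
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def read_corpus(source: str | Path | IO[str]) -> list[AbstractRecord]:
    """Read a fixture-JSON corpus.

    The fixture format is a JSON array of objects with keys ``pmid``,
    ``title``, ``body``, ``pub_date`` (ISO date or null) and
    ``retrieved_by`` (array of tags).  See ``docs/methods.md``.
    """
    if hasattr(source, "read"):
        raw = source.read()
    else:
        raw = Path(source).read_text()
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed corpus JSON: {exc}") from exc
    records: list[AbstractRecord] = []
    seen: set[str] = set()
    for i, entry in enumerate(data):
        try:
            rec = AbstractRecord(
                pmid=str(entry["pmid"]),
                title=entry.get("title", ""),
                body=entry.get("body", ""),
                pub_date=_parse_date(entry.get("pub_date")),
                retrieved_by=set(entry.get("retrieved_by", [])),
                svm_label=entry.get("svm_label"),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed corpus record #{i}: {exc}") from exc
        if rec.pmid in seen:
            raise ValueError(f"duplicate PMID {rec.pmid} in corpus")
        seen.add(rec.pmid)
        records.append(rec)
    return records


def write_corpus(records: Iterable[AbstractRecord], path: str | Path) -> None:
    """Write records in the fixture-JSON format."""
    data = [
        {
            "pmid": r.pmid,
            "title": r.title,
            "body": r.body,
            "pub_date": r.pub_date.isoformat() if r.pub_date else None,
            "retrieved_by": sorted(r.retrieved_by),
            "svm_label": r.svm_label,
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(data, indent=1))


_MONTHS = {m: i + 1 for i, m in enumerate(
    ["Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"])}


def _medline_date(article: etree._Element) -> _dt.date | None:
    node = article.find(".//PubDate")
    if node is None:
        return None
    year = node.findtext("Year")
    if not year or not year.isdigit():
        return None
    month_txt = node.findtext("Month") or "Jan"
    month = _MONTHS.get(month_txt[:3], 1) if not month_txt.isdigit() else int(month_txt)
    day_txt = node.findtext("Day") or "1"
    day = int(day_txt) if day_txt.isdigit() else 1
    try:
        return _dt.date(int(year), month, day)
    except ValueError:
        return None


def read_medline_xml(source: str | Path | IO[bytes], retrieved_by: Iterable[str] = ()) -> list[AbstractRecord]:
    """Read a MEDLINE/PubMed ``PubmedArticleSet`` XML document.

    All records are tagged with ``retrieved_by`` (the caller knows which
    query produced the download).
    """
    tags = set(retrieved_by)
    try:
        tree = etree.parse(source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ValueError(f"malformed MEDLINE XML: {exc}") from exc
    records: list[AbstractRecord] = []
    for article in tree.iter("PubmedArticle"):
        pmid = article.findtext(".//PMID")
        if pmid is None:
            raise ValueError("malformed MEDLINE XML: PubmedArticle without PMID")
        title = article.findtext(".//ArticleTitle") or ""
        body = " ".join(
            (t.text or "") for t in article.findall(".//Abstract/AbstractText")
        ).strip()
        records.append(
            AbstractRecord(
                pmid=pmid.strip(),
                title=title.strip(),
                body=body,
                pub_date=_medline_date(article),
                retrieved_by=set(tags),
            )
        )
    return records


def filter_corpus(
    records: list[AbstractRecord],
    exclude_pmids: set[str] | None = None,
    date_window: tuple[_dt.date | None, _dt.date | None] | None = None,
    cap: int | None = None,
) -> list[AbstractRecord]:
    """Drop excluded PMIDs and out-of-window records, then cap the count.

    Order-preserving and idempotent.  A record with an unknown date is
    dropped whenever a window is active (conservative: it cannot be shown
    to precede the structure paper).  Typical uses: excluding the direct
    citation of the crystal structure, and the prior-to-structure-paper
    mode where the window end is the citation date minus one day.
    """
    out = []
    excl = exclude_pmids or set()
    for rec in records:
        if rec.pmid in excl:
            continue
        if date_window is not None:
            start, end = date_window
            if rec.pub_date is None:
                continue
            if start is not None and rec.pub_date < start:
                continue
            if end is not None and rec.pub_date > end:
                continue
        out.append(rec)
    if cap is not None:
        out = out[:cap]
    return out


class PubMedFetcher:
    """Optional live E-utilities adapter (ESearch + EFetch).

    Disabled by default; every offline workflow uses fixture corpora
    instead.  When enabled, the AND-query and the two OR-query halves are
    submitted separately and the returned records tagged accordingly.
    """

    ESEARCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
    EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

    def __init__(self, enabled: bool = False, retries: int = 2):
        self.enabled = enabled
        self.retries = retries

    def fetch(self, query, window=None, cap: int = 100_000, tag: str = TAG_AND) -> list[AbstractRecord]:
        """Fetch abstracts matching a serialized query; tag them with *tag*."""
        if not self.enabled:
            raise RuntimeError(
                "PubMed adapter is offline; enable it explicitly or use a fixture corpus"
            )
        import io
        import urllib.parse
        import urllib.request

        term = query.serialize() if hasattr(query, "serialize") else str(query)
        params = {"db": "pubmed", "term": term, "retmax": str(cap)}
        if window is not None and window[0] is not None:
            params["mindate"] = window[0].strftime("%Y/%m/%d")
        if window is not None and window[1] is not None:
            params["maxdate"] = window[1].strftime("%Y/%m/%d")
            params["datetype"] = "pdat"
        last_err: Exception | None = None
        for _ in range(self.retries + 1):
            try:
                with urllib.request.urlopen(
                    f"{self.ESEARCH}?{urllib.parse.urlencode(params)}", timeout=30
                ) as resp:
                    ids = [e.text for e in etree.parse(resp).iter("Id")]
                if not ids:
                    return []
                fetch_params = {"db": "pubmed", "id": ",".join(ids[:cap]), "retmode": "xml"}
                with urllib.request.urlopen(
                    self.EFETCH, data=urllib.parse.urlencode(fetch_params).encode(), timeout=60
                ) as resp:
                    payload = resp.read()
                return read_medline_xml(io.BytesIO(payload), retrieved_by={tag})[:cap]
            except OSError as exc:  # transport failure: retriable
                last_err = exc
        raise RuntimeError(f"PubMed fetch failed after {self.retries + 1} attempts: {last_err}")


def merge_retrievals(
    and_records: list[AbstractRecord],
    or1_records: list[AbstractRecord],
    or2_records: list[AbstractRecord],
) -> list[AbstractRecord]:
    """Merge the three per-query result lists into one tagged corpus.

    Records are keyed by PMID; tags are unioned.  Every AND record also
    appears in the OR union by construction.
    """
    merged: dict[str, AbstractRecord] = {}
    for tag, records in ((TAG_AND, and_records), (TAG_OR1, or1_records), (TAG_OR2, or2_records)):
        for rec in records:
            if rec.pmid in merged:
                merged[rec.pmid].retrieved_by |= rec.retrieved_by | {tag}
            else:
                merged[rec.pmid] = replace(rec, retrieved_by=rec.retrieved_by | {tag})
    # re-run tag closure (AND implies both OR halves)
    for rec in merged.values():
        if TAG_AND in rec.retrieved_by:
            rec.retrieved_by |= {TAG_OR1, TAG_OR2}
    return list(merged.values())
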