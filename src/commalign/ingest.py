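"""Reading, normalizing, routing and deduplicating short social-media posts.

The preprocessing pipeline mirrors common practice for topic modeling of
tweets: hashtags and @-mentions pass through verbatim, every other word is
lowercased, stop words / the retweet marker "rt" / purely numerical tokens
are removed, and the remainder is Porter-stemmed. URLs from generic
shortening services are dropped; full URLs contribute their registered
domain as a token. Posts left with fewer than ``min_tokens`` tokens are
routed to a reserved extra topic rather than entering topic inference, and
the remaining posts are deduplicated on their normalized token sequence so
the model sees each distinct token sequence once.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import urlparse

from .stem import porter_stem

__all__ = [
    "RawPost",
    "ProcessedDoc",
    "DEFAULT_SHORTENER_DOMAINS",
    "load_stopwords",
    "normalize_post",
    "process_posts",
    "route_short",
    "deduplicate",
    "read_posts",
    "write_processed",
    "read_processed",
]

#: Generic URL-shortener domains whose links carry no usable domain signal.
DEFAULT_SHORTENER_DOMAINS = frozenset(
    {"bit.ly", "t.co", "ow.ly", "goo.gl", "tinyurl.com", "buff.ly", "dlvr.it"}
)

# all-digit tokens, optionally with separators / percent signs
_NUMERIC_RE = re.compile(r"^[0-9][0-9.,%]*$|^[.,%]*[0-9][0-9.,%]*$")
_URL_RE = re.compile(r"^https?://", re.IGNORECASE)
_STRIP_CHARS = "".join(
    c for c in r""".,;:!?'"()[]{}<>…“”‘’-–—*&^%$+=|\/~`""" if c not in "#@"
)


@dataclass(frozen=True)
class RawPost:
    """One post as collected: identifier, author, raw text, expanded URLs."""

    post_id: str
    author_id: str
    text: str
    urls: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProcessedDoc:
    """A normalized post; ``is_short`` flags documents below the token floor."""

    post_id: str
    author_id: str
    tokens: tuple[str, ...]
    is_short: bool = field(default=False)


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """English stop words: a file with one word per line, or the standard
    built-in English list when no path is given."""
    if path is None:
        from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

        return frozenset(ENGLISH_STOP_WORDS)
    words = Path(path).read_text(encoding="utf-8").split()
    return frozenset(w.strip().lower() for w in words if w.strip())


def _registered_domain(url: str) -> str | None:
    netloc = urlparse(url if _URL_RE.match(url) else "http://" + url).netloc
    netloc = netloc.split("@")[-1].split(":")[0].lower()
    if netloc.startswith("www."):
        netloc = netloc[4:]
    return netloc or None


def normalize_post(
    text: str,
    urls: Sequence[str] = (),
    stopwords: frozenset[str] | set[str] | None = None,
    shortener_domains: frozenset[str] | set[str] = DEFAULT_SHORTENER_DOMAINS,
) -> list[str]:
    """Normalize one post into its token list.

    Hashtag (#) and mention (@) tokens are passed through verbatim. Other
    words are lowercased, stripped of surrounding punctuation, dropped when
    they are stop words, the token "rt", purely numerical, or in-text URLs,
    and Porter-stemmed otherwise. Each URL in ``urls`` contributes its
    registered domain (lowercased, "www." stripped) unless the domain is a
    known shortener. Empty output is legal.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    tokens: list[str] = []
    for raw in text.split():
        if raw.startswith(("#", "@")):
            if len(raw) > 1:
                tokens.append(raw)
            continue
        if _URL_RE.match(raw):
            continue
        word = raw.strip(_STRIP_CHARS).lower()
        if not word or word == "rt" or word in stopwords:
            continue
        if _NUMERIC_RE.match(word):
            continue
        tokens.append(porter_stem(word))
    for url in urls:
        domain = _registered_domain(url)
        if domain and domain not in shortener_domains:
            tokens.append(domain)
    return tokens


def process_posts(
    posts: Iterable[RawPost],
    stopwords: frozenset[str] | None = None,
    shortener_domains: frozenset[str] = DEFAULT_SHORTENER_DOMAINS,
    min_tokens: int = 3,
) -> list[ProcessedDoc]:
    """Normalize a batch of posts and flag the short ones."""
    if stopwords is None:
        stopwords = load_stopwords()
    docs = []
    for p in posts:
        toks = tuple(normalize_post(p.text, p.urls, stopwords, shortener_domains))
        docs.append(
            ProcessedDoc(p.post_id, p.author_id, toks, is_short=len(toks) < min_tokens)
        )
    return docs


def route_short(
    docs: Sequence[ProcessedDoc], min_tokens: int = 3
) -> tuple[list[ProcessedDoc], list[ProcessedDoc]]:
    """Split documents into (kept, short) at the token-count floor.

    Short documents bypass topic inference and are later assigned the
    reserved extra topic.
    """
    if min_tokens < 1:
        raise ValueError(f"min_tokens must be >= 1, got {min_tokens}")
    kept, short = [], []
    for d in docs:
        target = short if len(d.tokens) < min_tokens else kept
        target.append(d)
    return kept, short


def deduplicate(
    docs: Sequence[ProcessedDoc],
) -> tuple[list[ProcessedDoc], dict[tuple[str, ...], list[str]]]:
    """Collapse documents sharing a normalized token sequence.

    Returns one representative document per distinct token sequence plus a
    map from the token sequence to every post id sharing it, so inferred
    topics can be mapped back onto the full corpus.
    """
    unique: list[ProcessedDoc] = []
    dedup: dict[tuple[str, ...], list[str]] = {}
    for d in docs:
        key = tuple(d.tokens)
        if key not in dedup:
            dedup[key] = []
            unique.append(d)
        dedup[key].append(d.post_id)
    return unique, dedup


def read_posts(path: str | Path) -> list[RawPost]:
    """Read a post table: JSON-lines (``.jsonl``/``.json``) or CSV.

    Required fields/columns: post_id, author_id, text; optional urls
    (a JSON list, or whitespace-separated in CSV).
    """
    path = Path(path)
    posts: list[RawPost] = []
    if path.suffix.lower() in {".jsonl", ".json", ".ndjson"}:
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: invalid JSON") from exc
                posts.append(
                    RawPost(
                        str(rec["post_id"]),
                        str(rec["author_id"]),
                        rec.get("text", ""),
                        tuple(rec.get("urls", ()) or ()),
                    )
                )
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for rec in csv.DictReader(fh):
                urls = tuple((rec.get("urls") or "").split())
                posts.append(
                    RawPost(str(rec["post_id"]), str(rec["author_id"]), rec.get("text", ""), urls)
                )
    seen: set[str] = set()
    for p in posts:
        if p.post_id in seen:
            raise ValueError(f"duplicate post_id {p.post_id!r}")
        if not p.author_id:
            raise ValueError(f"post {p.post_id!r} has empty author_id")
        seen.add(p.post_id)
    return posts


def write_processed(docs: Iterable[ProcessedDoc], path: str | Path) -> None:
    """Write processed documents as TSV: post_id, author_id, tokens, is_short."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("post_id\tauthor_id\ttokens\tis_short\n")
        for d in docs:
            fh.write(f"{d.post_id}\t{d.author_id}\t{' '.join(d.tokens)}\t{int(d.is_short)}\n")


def read_processed(path: str | Path) -> list[ProcessedDoc]:
    docs = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("post_id"):
            raise ValueError(f"{path}: missing header line")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed line {line!r}")
            pid, aid, toks, short = parts
            docs.append(
                ProcessedDoc(pid, aid, tuple(toks.split()), is_short=bool(int(short)))
            )
    return docs
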