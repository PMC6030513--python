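"""Bibliographic citation data model, RIS I/O, tokenization and vocabulary.

A :class:`Citation` holds the fields the classifiers consume — title,
abstract, the MEDLINE publication-type (PT) status for "Randomized
Controlled Trial", and an optional gold label — plus every unparsed RIS
tag, so that files round-trip through :func:`read_ris` / :func:`write_ris`
without loss.

Tokenization lowercases, extracts maximal runs of letters/digits of length
at least two, and removes a pinned English stopword list shipped with the
package (``data/stopwords.txt``).
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PtTag",
    "Label",
    "Citation",
    "TokenizerConfig",
    "TokenizedDoc",
    "Vocabulary",
    "RISParseError",
    "read_ris",
    "write_ris",
    "tokenize",
    "build_vocabulary",
    "load_stopwords",
]

#: MEDLINE publication-type value marking a randomized controlled trial.
RCT_PT_PHRASE = "randomized controlled trial"

#: RIS tags that may carry publication-type information.
PT_BEARING_TAGS = ("PT", "M3")

PAD_INDEX = 0
OOV_INDEX = 1


class PtTag(Enum):
    """Tri-state publication-type status of a citation."""

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class Label(Enum):
    """Tri-state gold label."""

    RCT = "rct"
    NON_RCT = "non_rct"
    UNLABELED = "unlabeled"


@dataclass
class Citation:
    """One bibliographic record.

    Parameters
    ----------
    record_id : str
        Opaque identifier (RIS ``ID`` tag when present).
    title : str
        Non-empty article title.
    abstract : str
        Abstract text; may be empty.
    pt_rct_tag : PtTag
        Whether the record carries the RCT publication-type tag.
    label : Label
        Gold label if known.
    extra_fields : dict[str, list[str]]
        All RIS tags not mapped onto the fields above, preserved verbatim
        for round-trip fidelity.
    """

    record_id: str
    title: str
    abstract: str = ""
    pt_rct_tag: PtTag = PtTag.UNKNOWN
    label: Label = Label.UNLABELED
    extra_fields: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.title.strip():
            raise ValueError("Citation title must be non-empty")

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


def load_stopwords() -> frozenset[str]:
    """Load the pinned English stopword list shipped with the package."""
    text = resources.files("rctscreen.data").joinpath("stopwords.txt").read_text("utf-8")
    words = [ln.strip() for ln in text.splitlines()]
    return frozenset(w for w in words if w and not w.startswith("#"))


@dataclass(frozen=True)
class TokenizerConfig:
    """Token pattern and stopword list governing tokenization.

    The default pattern matches maximal runs of Unicode letters/digits of
    length >= 2 (underscores and punctuation are separators).
    """

    token_pattern: str = r"[^\W_]{2,}"
    stopwords: frozenset[str] = field(default_factory=load_stopwords)


@dataclass
class TokenizedDoc:
    """Ordered lowercase tokens with parallel title-origin flags."""

    tokens: list[str]
    in_title: list[bool]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.in_title):
            raise ValueError("tokens and in_title must have equal length")

    def __len__(self) -> int:
        return len(self.tokens)


class Vocabulary:
    """Frequency-ranked token index.

    Index 0 is reserved for padding and index 1 for out-of-vocabulary
    tokens; content tokens occupy contiguous indices starting at 2,
    ordered by descending corpus frequency with lexicographic tie-break.
    """

    pad_index = PAD_INDEX
    oov_index = OOV_INDEX

    def __init__(self, token_to_index: dict[str, int], max_size: int):
        self.token_to_index = token_to_index
        self.max_size = max_size

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    @property
    def n_indices(self) -> int:
        """Total index range including padding and OOV slots."""
        return len(self.token_to_index) + 2

    def index(self, token: str) -> int:
        """Index for *token*, or the OOV index if unknown."""
        return self.token_to_index.get(token, OOV_INDEX)

    def encode(self, tokens: Iterable[str]) -> list[int]:
        get = self.token_to_index.get
        return [get(t, OOV_INDEX) for t in tokens]


class RISParseError(ValueError):
    """Raised for structurally malformed RIS input."""


_TAG_RE = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def read_ris(path: str | Path) -> list[Citation]:
    """Parse an RIS file into citations.

    Accepts ``TI``/``T1`` for title and ``AB``/``N2`` for abstract. The PT
    status is ``PRESENT`` iff any publication-type-bearing field (``PT`` or
    ``M3``) contains the phrase "Randomized Controlled Trial"
    (case-insensitive), ``ABSENT`` if such fields exist without the phrase,
    and ``UNKNOWN`` if none exist. Records with an empty title are rejected
    with a warning. A record lacking its ``ER`` terminator raises
    :class:`RISParseError` naming the byte offset of the record start.
    """
    path = Path(path)
    raw = path.read_text("utf-8")
    citations: list[Citation] = []
    fields: dict[str, list[str]] | None = None
    current_tag: str | None = None
    record_offset = 0
    offset = 0
    n_rejected = 0

    def finish(fields: dict[str, list[str]]) -> None:
        nonlocal n_rejected
        cit = _citation_from_fields(fields, default_id=f"rec{len(citations) + 1}")
        if cit is None:
            n_rejected += 1
        else:
            citations.append(cit)

    for line in raw.splitlines(keepends=True):
        stripped = line.rstrip("\r\n")
        m = _TAG_RE.match(stripped)
        if m:
            tag, value = m.group(1), m.group(2)
            if tag == "TY":
                if fields is not None:
                    raise RISParseError(
                        f"record starting at byte {record_offset} has no ER terminator"
                    )
                fields = {}
                record_offset = offset
            if fields is not None:
                if tag == "ER":
                    finish(fields)
                    fields = None
                    current_tag = None
                else:
                    fields.setdefault(tag, []).append(value)
                    current_tag = tag
        elif fields is not None and current_tag is not None and stripped:
            # continuation line of a multi-line value
            fields[current_tag][-1] += "\n" + stripped
        offset += len(line.encode("utf-8"))

    if fields is not None:
        raise RISParseError(
            f"record starting at byte {record_offset} has no ER terminator"
        )
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} RIS record(s) with empty title", stacklevel=2
        )
    return citations


def _citation_from_fields(
    fields: dict[str, list[str]], default_id: str
) -> Citation | None:
    title = ""
    for tag in ("TI", "T1"):
        if fields.get(tag):
            title = fields[tag][0]
            break
    if not title.strip():
        return None
    abstract = ""
    for tag in ("AB", "N2"):
        if fields.get(tag):
            abstract = fields[tag][0]
            break

    pt_values = [v for tag in PT_BEARING_TAGS for v in fields.get(tag, [])]
    if not pt_values:
        pt = PtTag.UNKNOWN
    elif any(RCT_PT_PHRASE in v.lower() for v in pt_values):
        pt = PtTag.PRESENT
    else:
        pt = PtTag.ABSENT

    record_id = fields["ID"][0] if fields.get("ID") else default_id
    label = Label.UNLABELED
    if fields.get("LB"):
        try:
            label = Label(fields["LB"][0])
        except ValueError:
            pass

    consumed = {"TY", "ER", "ID", "LB"}
    for tag in ("TI", "T1"):
        if fields.get(tag):
            consumed.add(tag)
            break
    for tag in ("AB", "N2"):
        if fields.get(tag):
            consumed.add(tag)
            break
    extra = {t: list(v) for t, v in fields.items() if t not in consumed}
    return Citation(
        record_id=record_id,
        title=title,
        abstract=abstract,
        pt_rct_tag=pt,
        label=label,
        extra_fields=extra,
    )


def _emit(tag: str, value: str) -> str:
    lines = value.split("\n")
    out = [f"{tag}  - {lines[0]}"]
    out.extend(lines[1:])
    return "\n".join(out)


def write_ris(citations: Sequence[Citation], path: str | Path) -> None:
    """Write citations to *path* in RIS format.

    Emits ``TI``/``AB`` for title/abstract and preserves
    ``extra_fields``. The PT status survives a round trip: a ``PRESENT``
    record without a stored PT field gains ``PT  - Randomized Controlled
    Trial``; an ``ABSENT`` one gains ``PT  - Journal Article``.
    """
    path = Path(path)
    chunks: list[str] = []
    for cit in citations:
        lines = [f"TY  - JOUR", f"ID  - {cit.record_id}", _emit("TI", cit.title)]
        if cit.abstract:
            lines.append(_emit("AB", cit.abstract))
        has_pt_field = any(t in cit.extra_fields for t in PT_BEARING_TAGS)
        if cit.pt_rct_tag is PtTag.PRESENT and not (
            has_pt_field
            and any(
                RCT_PT_PHRASE in v.lower()
                for t in PT_BEARING_TAGS
                for v in cit.extra_fields.get(t, [])
            )
        ):
            lines.append("PT  - Randomized Controlled Trial")
        elif cit.pt_rct_tag is PtTag.ABSENT and not has_pt_field:
            lines.append("PT  - Journal Article")
        if cit.label is not Label.UNLABELED:
            lines.append(f"LB  - {cit.label.value}")
        for tag, values in cit.extra_fields.items():
            for v in values:
                lines.append(_emit(tag, v))
        lines.append("ER  - ")
        chunks.append("\n".join(lines))
    path.write_text("\n".join(chunks) + ("\n" if chunks else ""), "utf-8")


_DEFAULT_CONFIG: TokenizerConfig | None = None


def default_tokenizer_config() -> TokenizerConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = TokenizerConfig()
    return _DEFAULT_CONFIG


def tokenize(citation: Citation, config: TokenizerConfig | None = None) -> TokenizedDoc:
    """Tokenize title then abstract, lowercased, stopwords removed.

    ``in_title`` flags mark tokens originating from the title. Deterministic
    for a fixed config; an empty abstract yields title tokens only.
    """
    config = config or default_tokenizer_config()
    pattern = re.compile(config.token_pattern, re.UNICODE)
    tokens: list[str] = []
    in_title: list[bool] = []
    for text, flag in ((citation.title, True), (citation.abstract, False)):
        for tok in pattern.findall(text.lower()):
            if tok not in config.stopwords:
                tokens.append(tok)
                in_title.append(flag)
    return TokenizedDoc(tokens=tokens, in_title=in_title)


def build_vocabulary(docs: Sequence[TokenizedDoc], max_size: int) -> Vocabulary:
    """Build a vocabulary of the ``max_size`` most frequent tokens.

    Tokens are ranked by descending corpus frequency; ties at any rank are
    broken lexicographically (smaller token first). Content indices start
    at 2 (0 = padding, 1 = OOV).
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    counts: Counter[str] = Counter()
    for doc in docs:
        counts.update(doc.tokens)
    if not counts:
        raise ValueError("cannot build a vocabulary from empty documents")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:max_size]
    token_to_index = {tok: i + 2 for i, (tok, _) in enumerate(ranked)}
    return Vocabulary(token_to_index, max_size=max_size)
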