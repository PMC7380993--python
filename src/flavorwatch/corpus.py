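"""Post corpus I/O (JSON-lines) and calendar-month bucketing.

One post per line, fields ``id``, ``platform``, ``author``, ``created_utc``
(epoch seconds or ISO-8601) and ``text``. All timestamps are interpreted as
UTC — both major platform archives deliver UTC epochs — so monthly bucketing
is independent of machine locale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

log = logging.getLogger(__name__)

__all__ = ["Post", "MonthKey", "CorpusError", "read_posts", "write_posts", "month_of", "month_range"]

PLATFORMS = ("reddit", "twitter", "other")


class CorpusError(ValueError):
    """Raised when a corpus file is unusable (mostly malformed)."""


class MonthKey(NamedTuple):
    year: int
    month: int

    @classmethod
    def parse(cls, text: str) -> "MonthKey":
        """Parse 'YYYY-MM'."""
        year, month = text.split("-")
        key = cls(int(year), int(month))
        if not 1 <= key.month <= 12:
            raise ValueError(f"invalid month: {text!r}")
        return key

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


@dataclass(frozen=True)
class Post:
    """One social-media message."""

    id: str
    platform: str
    author: str
    timestamp: datetime  # tz-aware, UTC
    text: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("post id must be non-empty")
        if self.timestamp.tzinfo is None:
            raise ValueError("post timestamp must be timezone-aware")


def _parse_timestamp(value: object) -> datetime:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return datetime.fromtimestamp(float(value), tz=timezone.utc)
    if isinstance(value, str):
        text = value.strip()
        if text.replace(".", "", 1).lstrip("-").isdigit():
            return datetime.fromtimestamp(float(text), tz=timezone.utc)
        dt = datetime.fromisoformat(text.replace("Z", "+00:00"))
        if dt.tzinfo is None:
            dt = dt.replace(tzinfo=timezone.utc)
        return dt.astimezone(timezone.utc)
    raise ValueError(f"unparseable timestamp: {value!r}")


def _post_from_obj(obj: dict) -> Post:
    platform = str(obj["platform"]).lower()
    if platform not in PLATFORMS:
        platform = "other"
    return Post(
        id=str(obj["id"]),
        platform=platform,
        author=str(obj.get("author", "")),
        timestamp=_parse_timestamp(obj["created_utc"]),
        text=str(obj.get("text", "")),
    )


def read_posts(path: str | Path) -> Iterator[Post]:
    """Stream posts from a JSON-lines file.

    Malformed lines are skipped with a logged warning; if more than half of
    the non-empty lines are malformed the stream ends with a
    :class:`CorpusError` (the file is presumed not to be a post corpus).
    """
    path = Path(path)
    n_ok = 0
    n_bad = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                post = _post_from_obj(obj)
            except (ValueError, KeyError, TypeError) as exc:
                n_bad += 1
                log.warning("%s:%d: skipping malformed line (%s)", path.name, lineno, exc)
                continue
            n_ok += 1
            yield post
    if n_bad > n_ok:
        raise CorpusError(
            f"{path.name}: {n_bad} of {n_ok + n_bad} lines malformed; not a post corpus"
        )


def write_posts(posts: Iterable[Post], path: str | Path) -> int:
    """Write posts as JSON-lines (ISO-8601 UTC timestamps); returns the count."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for post in posts:
            obj = {
                "id": post.id,
                "platform": post.platform,
                "author": post.author,
                "created_utc": post.timestamp.astimezone(timezone.utc).strftime(
                    "%Y-%m-%dT%H:%M:%SZ"
                ),
                "text": post.text,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
            n += 1
    return n


def month_of(post: Post) -> MonthKey:
    """UTC calendar month of a post's timestamp."""
    dt = post.timestamp.astimezone(timezone.utc)
    return MonthKey(dt.year, dt.month)


def month_range(start: MonthKey | str, end: MonthKey | str) -> list[MonthKey]:
    """All calendar months from start to end inclusive."""
    if isinstance(start, str):
        start = MonthKey.parse(start)
    if isinstance(end, str):
        end = MonthKey.parse(end)
    if (start.year, start.month) > (end.year, end.month):
        raise ValueError(f"month range reversed: {start} > {end}")
    months = []
    year, month = start
    while (year, month) <= (end.year, end.month):
        months.append(MonthKey(year, month))
        month += 1
        if month == 13:
            year, month = year + 1, 1
    return months
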