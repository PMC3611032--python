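"""RSS 2.0 notification feeds for new results and diagnoses.

Feeds let patients and doctors subscribe to updates without polling the
web interface.  Items deliberately carry no numeric scores or analyte
values — feeds are an unauthenticated channel, so titles say only that
results are ready or that the doctor should be contacted; full detail
stays behind the record store.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from email.utils import format_datetime

from lxml import etree

from .engine import NotificationEvent
from .errors import ConfigError

__all__ = ["FeedConfig", "build_feed", "event_title"]


@dataclass(frozen=True)
class FeedConfig:
    title: str
    link: str
    description: str
    max_items: int = 20

    def __post_init__(self):
        if self.max_items < 1:
            raise ConfigError("max_items must be at least 1")


_TITLES = {
    "new_result": "New lab results are ready",
    "diagnosis": "A diagnosis update is available",
    "critical": "Important: please contact your doctor",
}


def event_title(event: NotificationEvent) -> str:
    return _TITLES.get(event.kind, "Notification")


def build_feed(config: FeedConfig, events) -> str:
    """Render events as an RSS 2.0 document.

    Items are newest-first and truncated to ``config.max_items``; each
    carries a title, an RFC-822 pubDate in UTC, and a stable guid derived
    from the event's identifiers, so rebuilding from the same events is
    idempotent.  An empty event list yields a valid empty channel.
    """
    rss = etree.Element("rss", version="2.0")
    channel = etree.SubElement(rss, "channel")
    etree.SubElement(channel, "title").text = config.title
    etree.SubElement(channel, "link").text = config.link
    etree.SubElement(channel, "description").text = config.description

    ordered = sorted(events, key=lambda e: e.timestamp, reverse=True)
    for event in ordered[: config.max_items]:
        item = etree.SubElement(channel, "item")
        etree.SubElement(item, "title").text = event_title(event)
        etree.SubElement(item, "description").text = event.summary
        guid = etree.SubElement(item, "guid", isPermaLink="false")
        guid.text = event.guid()
        ts = event.timestamp
        if ts.tzinfo is None:  # naive timestamps are taken as UTC
            ts = ts.replace(tzinfo=dt.timezone.utc)
        etree.SubElement(item, "pubDate").text = format_datetime(ts, usegmt=True)
    return etree.tostring(
        rss, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode()
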