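#!/usr/bin/env python
"""Catalog alternative-splicing events from the simulated annotation and
summarize the category composition."""

from pathlib import Path

from spliceprio.events import (
    enumerate_events,
    parse_annotation,
    summarize_event_categories,
    write_catalog,
)

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "results" / "bundle"
OUT = ROOT / "results" / "event_catalog.tsv"


def main():
    transcripts = parse_annotation(BUNDLE / "annotation.gtf")
    events = enumerate_events(transcripts)
    write_catalog(events, OUT)
    print(f"{len(events)} events from {len(transcripts)} transcripts -> {OUT}")
    print(summarize_event_categories(events).to_string())
    in_cds = sum(e.in_cds for e in events)
    in_window = sum(30 <= e.alt_length <= 300 for e in events)
    print(f"coding-region events: {in_cds}; length 30-300 bp: {in_window}")


if __name__ == "__main__":
    main()
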