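"""Shared test utilities: greedy event-to-truth matching."""

from __future__ import annotations


def match_events(events, truths, key=lambda ev: ev.start,
                 truth_key=lambda tr: tr.start, tolerance: float = 0.5) -> int:
    """Greedy one-to-one matching by onset distance; returns true positives."""
    used: set[int] = set()
    tp = 0
    for ev in sorted(events, key=key):
        candidates = [(abs(key(ev) - truth_key(tr)), i)
                      for i, tr in enumerate(truths) if i not in used]
        if not candidates:
            break
        dist, best = min(candidates)
        if dist <= tolerance:
            used.add(best)
            tp += 1
    return tp


def recall_precision(events, truths, **kwargs) -> tuple[float, float]:
    tp = match_events(events, truths, **kwargs)
    recall = tp / len(truths) if truths else float("nan")
    precision = tp / len(events) if events else float("nan")
    return recall, precision
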