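"""Topic assignment and per-period topic strengths.

Detected modules are mapped to named topics through a configurable lexicon
(topic id -> keyword set); a module gets the topic with the largest Jaccard
overlap between its keywords and the topic's lexicon.

Strength of topic u in period m:

    AStrength(u, m) = n_um / M_m
    RStrength(u, m) = AStrength(u, m) / sum_u' AStrength(u', m)

where M_m is the number of reports in period m and n_um the number of those
reports related to topic u.  A report is related to a topic when it contains
at least one of the topic's keywords (so one report may count toward several
topics); a stricter plurality mode assigns each report only to the topic
with the most keyword hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .communities import OMITTED, ModulePartition

__all__ = ["TopicLexicon", "StrengthSeries", "assign_topics", "topic_strengths"]

UNASSIGNED = -1


@dataclass
class TopicLexicon:
    """topic id -> keyword set, with display labels."""

    topics: dict[int, set]
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.topics:
            raise ValueError("lexicon must contain at least one topic")
        for tid, kws in self.topics.items():
            if not kws:
                raise ValueError(f"topic {tid} has an empty keyword set")
            self.topics[tid] = set(kws)
        for tid in self.topics:
            self.labels.setdefault(tid, f"topic {tid}")

    @classmethod
    def default(cls) -> "TopicLexicon":
        """The bundled four-topic lexicon (industry development, health
        care, financial market, industry management)."""
        from importlib.resources import files

        raw = yaml.safe_load((files("tgnet.data") / "default_topics.yaml").read_text())
        return cls._from_mapping(raw)

    @classmethod
    def from_yaml(cls, path) -> "TopicLexicon":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw) -> "TopicLexicon":
        topics, labels = {}, {}
        for tid, entry in raw.items():
            tid = int(tid)
            if isinstance(entry, dict):
                topics[tid] = set(entry["keywords"])
                if "label" in entry:
                    labels[tid] = str(entry["label"])
            else:
                topics[tid] = set(entry)
        return cls(topics, labels)


@dataclass
class StrengthSeries:
    """Long-format table of (period, topic, a_strength, r_strength) plus the
    raw counts behind them."""

    table: pd.DataFrame  # columns: period, topic, n, total, a_strength, r_strength


def assign_topics(partition: ModulePartition, lexicon: TopicLexicon) -> dict[int, int]:
    """Map each non-omitted module to the topic of maximal Jaccard overlap.

    Ties go to the lowest topic id; a module sharing no keyword with any
    topic maps to UNASSIGNED (-1).
    """
    if not partition.assignment:
        raise ValueError("empty partition")
    members: dict[int, set] = {}
    for node, mod in partition.assignment.items():
        if mod == OMITTED:
            continue
        members.setdefault(mod, set()).add(node)
    mapping: dict[int, int] = {}
    for mod, words in sorted(members.items()):
        best_tid, best_j = UNASSIGNED, 0.0
        for tid in sorted(lexicon.topics):
            kws = lexicon.topics[tid]
            inter = len(words & kws)
            if inter == 0:
                continue
            j = inter / len(words | kws)
            if j > best_j:
                best_tid, best_j = tid, j
        mapping[mod] = best_tid
    return mapping


def topic_strengths(reports_by_period, topic_word_sets, *, mode: str = "any") -> StrengthSeries:
    """Compute absolute and relative topic strengths.

    Parameters
    ----------
    reports_by_period : mapping period -> list of reports, each report an
        iterable of tokens (or a set of keywords present).
    topic_word_sets : mapping topic id -> keyword set.
    mode : "any" counts a report toward every topic it shares a keyword
        with; "plurality" toward only the topic with the most hits.
    """
    if mode not in ("any", "plurality"):
        raise ValueError("mode must be 'any' or 'plurality'")
    topic_ids = sorted(topic_word_sets)
    rows = []
    for period, reports in reports_by_period.items():
        M_m = len(reports)
        if M_m == 0:
            raise ValueError(f"period {period!r} has no reports")
        counts = {tid: 0 for tid in topic_ids}
        for rep in reports:
            toks = set(rep)
            hits = {tid: len(toks & set(topic_word_sets[tid])) for tid in topic_ids}
            if mode == "any":
                for tid, h in hits.items():
                    if h > 0:
                        counts[tid] += 1
            else:
                best = max(hits.values())
                if best > 0:
                    winner = min(t for t, h in hits.items() if h == best)
                    counts[winner] += 1
        a = {tid: counts[tid] / M_m for tid in topic_ids}
        denom = sum(a.values())
        for tid in topic_ids:
            r = a[tid] / denom if denom > 0 else 0.0
            rows.append(
                {"period": period, "topic": tid, "n": counts[tid], "total": M_m,
                 "a_strength": a[tid], "r_strength": r}
            )
    return StrengthSeries(pd.DataFrame(rows))
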