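"""From raw documents to a per-period keyword panel.

The pipeline is: tokenize (pluggable callable; default lowercase whitespace
splitting), drop stopwords and punctuation-only tokens, rank terms by
TF-IDF, merge synonyms into canonical keywords, and build one non-negative
observation matrix per period, where the entry for keyword j in report i is
the *adjusted term frequency*

    scale * count(j, i) / total_tokens(i),

a length-normalized relative frequency (scale defaults to 1000).  Rows are
reports, grouped by calendar period (default: quarters) in chronological
order.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "KeywordSet",
    "PanelData",
    "default_tokenizer",
    "count_terms",
    "tfidf_rank",
    "merge_synonyms",
    "build_panel",
    "quarter_of",
    "read_jsonl_corpus",
    "read_merge_map",
]

_PUNCT_ONLY = re.compile(r"^[\W_]+$", re.UNICODE)


def default_tokenizer(text: str) -> list[str]:
    return text.lower().split()


@dataclass
class Document:
    id: str
    date: date
    tokens: list[str]

    def __post_init__(self) -> None:
        if isinstance(self.date, str):
            self.date = datetime.fromisoformat(self.date).date()
        elif isinstance(self.date, datetime):
            self.date = self.date.date()
        if not self.tokens:
            logger.warning("document %s has no tokens", self.id)


@dataclass
class KeywordSet:
    """Ordered canonical keywords plus the raw-term -> canonical merge map."""

    keywords: list[str]
    merge_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.keywords)) != len(self.keywords):
            raise ValueError("keywords contain duplicates")
        bad = [t for t in self.merge_map.values() if t not in self.keywords]
        if bad:
            raise ValueError(f"merge_map targets missing from keywords: {bad[:5]}")


@dataclass
class PanelData:
    """Ordered per-period observation matrices over one keyword vocabulary."""

    periods: list[str]
    matrices: list[np.ndarray]
    keywords: KeywordSet
    scale: float = 1000.0

    def __post_init__(self) -> None:
        if len(self.periods) != len(self.matrices):
            raise ValueError("one matrix per period required")
        p = len(self.keywords.keywords)
        for lbl, m in zip(self.periods, self.matrices):
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[1] != p:
                raise ValueError(f"period {lbl}: matrix must have {p} columns")
            if not np.isfinite(m).all() or (m < 0).any():
                raise ValueError(f"period {lbl}: entries must be finite and non-negative")
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        if any(a >= b for a, b in zip(self.periods, self.periods[1:])):
            raise ValueError("periods must be strictly increasing")

    @property
    def M(self) -> int:
        return len(self.periods)

    @property
    def p(self) -> int:
        return len(self.keywords.keywords)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lbl, m in zip(self.periods, self.matrices):
            pd.DataFrame(m, columns=self.keywords.keywords).to_csv(
                outdir / f"panel_{lbl}.csv", index=False
            )
        manifest = {
            "periods": list(self.periods),
            "keywords": list(self.keywords.keywords),
            "merge_map": dict(self.keywords.merge_map),
            "scale": self.scale,
        }
        (outdir / "panel_manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, indir) -> "PanelData":
        indir = Path(indir)
        manifest = json.loads((indir / "panel_manifest.json").read_text())
        kws = KeywordSet(manifest["keywords"], manifest.get("merge_map", {}))
        mats = [
            pd.read_csv(indir / f"panel_{lbl}.csv")[manifest["keywords"]].to_numpy(dtype=float)
            for lbl in manifest["periods"]
        ]
        return cls(manifest["periods"], mats, kws, manifest.get("scale", 1000.0))


def count_terms(documents, stopwords=frozenset()) -> pd.DataFrame:
    """Per-document term counts, stopwords and punctuation-only tokens dropped.

    Returns a documents x terms count table (index = document ids).
    """
    documents = list(documents)
    if not documents:
        raise ValueError("empty corpus")
    stopwords = set(stopwords)
    counters = {}
    for doc in documents:
        kept = [t for t in doc.tokens if t not in stopwords and not _PUNCT_ONLY.match(t)]
        if not kept:
            logger.warning("document %s has no surviving tokens", doc.id)
        counters[doc.id] = Counter(kept)
    table = pd.DataFrame.from_dict(counters, orient="index").fillna(0.0)
    table = table.reindex([doc.id for doc in documents])
    table = table.reindex(sorted(table.columns), axis=1)
    return table.astype(float)


def tfidf_rank(
    count_table: pd.DataFrame,
    K: int,
    *,
    aggregate: str = "max",
    smooth: bool = False,
) -> pd.Series:
    """Top-K terms by TF-IDF.

    Per-document score(t, d) = f_td * ln(N / df_t) (optionally smoothed to
    ln(1 + N/df_t)); a term's corpus-level score aggregates per-document
    scores (default: max, favouring terms highly salient somewhere).  Ties
    break lexicographically.
    """
    N = count_table.shape[0]
    if N < 1:
        raise ValueError("empty corpus")
    df = (count_table > 0).sum(axis=0)
    idf = np.log(1.0 + N / df) if smooth else np.log(N / df)
    scores = count_table * idf
    if aggregate == "max":
        corpus_score = scores.max(axis=0)
    elif aggregate == "mean":
        corpus_score = scores.mean(axis=0)
    elif aggregate == "sum":
        corpus_score = scores.sum(axis=0)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if K > len(corpus_score):
        logger.warning("K=%d exceeds %d distinct terms; returning all", K, len(corpus_score))
        K = len(corpus_score)
    ranked = corpus_score.sort_index().sort_values(ascending=False, kind="stable")
    return ranked.iloc[:K]


def merge_synonyms(count_table: pd.DataFrame, merge_map: dict[str, str]) -> pd.DataFrame:
    """Sum counts of raw terms into their canonical term (one-hop map only)."""
    for raw, canon in merge_map.items():
        if canon in merge_map and merge_map[canon] != canon:
            raise ValueError(f"chained mapping {raw} -> {canon} -> {merge_map[canon]}")
    renamed = count_table.rename(columns=lambda c: merge_map.get(c, c))
    merged = renamed.T.groupby(level=0).sum().T
    return merged.reindex(sorted(merged.columns), axis=1)


def quarter_of(d: date) -> str:
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


def build_panel(
    documents,
    keyword_set: KeywordSet,
    period_rule=quarter_of,
    scale: float = 1000.0,
    stopwords=frozenset(),
) -> PanelData:
    """Assemble the per-period adjusted-term-frequency panel.

    Entry (i, j) = scale * count of keyword j in report i / total surviving
    tokens of report i.  Raw terms are routed through the merge map before
    matching keywords.  A period with zero reports raises; a zero-length
    report becomes an all-zero row with a warning.
    """
    documents = list(documents)
    if not documents:
        raise ValueError("empty corpus")
    stopwords = set(stopwords)
    kw_index = {k: j for j, k in enumerate(keyword_set.keywords)}
    mm = keyword_set.merge_map
    by_period: dict[str, list[np.ndarray]] = {}
    for doc in documents:
        kept = [t for t in doc.tokens if t not in stopwords and not _PUNCT_ONLY.match(t)]
        row = np.zeros(len(kw_index))
        total = len(kept)
        if total == 0:
            logger.warning("document %s has zero surviving tokens; zero row", doc.id)
        else:
            for t in kept:
                canon = mm.get(t, t)
                j = kw_index.get(canon)
                if j is not None:
                    row[j] += 1.0
            row = scale * row / total
        by_period.setdefault(period_rule(doc.date), []).append(row)
    periods = sorted(by_period)
    empty = [lbl for lbl in periods if not by_period[lbl]]
    if empty:
        raise ValueError(f"periods with zero reports: {empty}")
    mats = [np.vstack(by_period[lbl]) for lbl in periods]
    return PanelData(periods, mats, keyword_set, scale)


def read_jsonl_corpus(path, tokenizer=default_tokenizer) -> list[Document]:
    """Read a JSON-lines corpus (objects with id, date, text)."""
    docs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            docs.append(Document(str(obj["id"]), obj["date"], tokenizer(obj["text"])))
    return docs


def read_merge_map(path) -> dict[str, str]:
    """Two-column CSV raw,canonical -> merge map."""
    df = pd.read_csv(path, header=None, names=["raw", "canonical"], skipinitialspace=True)
    if df.iloc[0]["raw"] in ("raw", "term"):
        df = df.iloc[1:]
    return dict(zip(df["raw"], df["canonical"]))
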