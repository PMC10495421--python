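"""Lexicon-based emotion labeling and daily aggregation.

Documents (pre-lemmatized token lists) are tagged with any number of
emotions by exact matching against per-emotion unigram/bigram
dictionaries; daily relative frequencies are the share of that day's
documents carrying each label. Labels are multi-label by construction,
so per-day frequencies need not sum to one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import MissingDataError
from .types import EmotionDictionaries, EmotionPanel, LabeledCorpus


def label_document(tokens: list[str], dicts: EmotionDictionaries) -> np.ndarray:
    """Binary indicator per emotion: 1 iff a unigram of that emotion occurs
    among the tokens or one of its bigrams occurs as an adjacent ordered
    pair. Matching is exact string equality after case-folding; an empty
    token list yields the all-zero vector.
    """
    toks = [t.casefold() for t in tokens]
    tok_set = set(toks)
    pairs = set(zip(toks, toks[1:])) if len(toks) > 1 else set()
    labels = np.zeros(len(dicts.emotions), dtype=int)
    for i, emo in enumerate(dicts.emotions):
        if tok_set & dicts.unigrams[emo] or pairs & dicts.bigrams[emo]:
            labels[i] = 1
    return labels


def label_corpus(corpus: LabeledCorpus, dicts: EmotionDictionaries) -> pd.DataFrame:
    """Label every record; returns a documents x emotions indicator frame
    with the record date as a column."""
    rows = [label_document(rec.tokens, dicts) for rec in corpus.records]
    df = pd.DataFrame(rows, columns=dicts.emotions)
    df.insert(0, "date", [rec.date for rec in corpus.records])
    return df


def aggregate_daily(labeled: pd.DataFrame) -> EmotionPanel:
    """Daily relative frequencies from per-document labels.

    E_it = (# documents on day t labeled with emotion i) / (# documents
    on day t). The date span must be gap-free: a calendar day with zero
    documents inside the span raises :class:`MissingDataError` naming
    the first missing date.
    """
    if labeled.empty:
        raise MissingDataError("no documents to aggregate")
    dates = pd.to_datetime(labeled["date"]).dt.normalize()
    emo_cols = [c for c in labeled.columns if c != "date"]
    daily = labeled[emo_cols].groupby(dates).mean()
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    missing = full.difference(daily.index)
    if len(missing):
        raise MissingDataError(
            f"no documents on {missing[0].strftime('%Y-%m-%d')} inside the panel span"
        )
    return EmotionPanel(freq=daily.reindex(full))


def corpus_to_panel(corpus: LabeledCorpus, dicts: EmotionDictionaries) -> EmotionPanel:
    """Convenience: label then aggregate in one step."""
    return aggregate_daily(label_corpus(corpus, dicts))
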