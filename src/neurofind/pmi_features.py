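"""Pointwise mutual information ranking of n-grams against sentence labels.

Used to prototype and audit the keyword lexicons: high-PMI n-grams for a
label are candidate keywords for human curation. The co-occurrence unit is
the sentence (presence counts, not token frequencies); a document's label is
inherited by its sentences upstream of this module.

PMI is base-2:  pmi = log2( count_joint * n_total / (count_token * count_label) ).
With ``smoothing="add_one"`` (the default) one is added to the joint count so
n-grams never co-occurring with a label score finitely instead of -inf;
``smoothing="none"`` uses raw counts and yields -inf for zero joints.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

from neurofind.errors import DegenerateInputError


@dataclass(frozen=True)
class PmiScore:
    token_or_ngram: str
    label: Hashable
    pmi: float
    count_joint: int
    count_token: int
    count_label: int
    n_total: int


def ngrams_of(tokens: Sequence[str], ngram_max: int) -> set[str]:
    """All distinct n-grams of a token sequence, n = 1..ngram_max,
    joined with single spaces."""
    out: set[str] = set()
    for n in range(1, ngram_max + 1):
        for i in range(len(tokens) - n + 1):
            out.add(" ".join(tokens[i : i + n]))
    return out


def compute_pmi(
    labeled_sentences: Iterable[tuple[Sequence[str], Hashable]],
    ngram_max: int = 3,
    min_count: int = 1,
    smoothing: str = "add_one",
) -> list[PmiScore]:
    """Score every (n-gram, label) pair by PMI over sentence presence counts.

    Results are grouped by label and sorted descending by PMI within each
    label, ties broken lexicographically by n-gram. ``min_count`` filters on
    the n-gram's sentence count. Raises :class:`DegenerateInputError` when
    fewer than 2 distinct labels are present.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if smoothing not in ("add_one", "none"):
        raise ValueError(f"unknown smoothing mode {smoothing!r}")

    sentences = [(list(toks), label) for toks, label in labeled_sentences]
    labels = sorted({label for _, label in sentences}, key=str)
    if len(labels) < 2:
        raise DegenerateInputError("PMI requires at least 2 distinct labels")

    n_total = len(sentences)
    count_label: Counter = Counter(label for _, label in sentences)
    count_token: Counter = Counter()
    count_joint: Counter = Counter()
    for toks, label in sentences:
        grams = ngrams_of(toks, ngram_max)
        count_token.update(grams)
        count_joint.update((g, label) for g in grams)

    scores: list[PmiScore] = []
    for label in labels:
        for gram, c_tok in count_token.items():
            if c_tok < min_count:
                continue
            c_joint = count_joint.get((gram, label), 0)
            numerator = c_joint + 1 if smoothing == "add_one" else c_joint
            if numerator == 0:
                pmi = float("-inf")
            else:
                pmi = math.log2(numerator * n_total / (c_tok * count_label[label]))
            scores.append(
                PmiScore(
                    token_or_ngram=gram,
                    label=label,
                    pmi=pmi,
                    count_joint=c_joint,
                    count_token=c_tok,
                    count_label=count_label[label],
                    n_total=n_total,
                )
            )
    scores.sort(key=lambda s: (str(s.label), -s.pmi, s.token_or_ngram))
    return scores


def write_pmi_tsv(scores: Iterable[PmiScore], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ngram\tlabel\tpmi\tcount_joint\tcount_token\tcount_label\tn_total\n")
        for s in scores:
            fh.write(
                f"{s.token_or_ngram}\t{s.label}\t{s.pmi:.6f}\t{s.count_joint}\t"
                f"{s.count_token}\t{s.count_label}\t{s.n_total}\n"
            )
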