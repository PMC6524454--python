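"""Synthetic neuroimaging-report generator and embedding stand-ins.

Generates labeled reports with the structural properties the classifiers
are exposed to in practice: two documentation styles (a free-form site
drawing negative-infarct phrasings from a large compositional paraphrase
pool, and a template-based site with a small fixed pool), low SBI
prevalence vs high WMD prevalence, hedged / negated / historical mentions,
location-only confounder sentences, and coreference-split findings whose
document label no single sentence supports.

Every generated positive is lexicon-consistent, so on a corpus with
``coreference_rate=0`` the rule engine recovers the gold labels. Also
provides a skip-gram (SGNS, NumPy) or seeded-random embedding table and an
oversampling utility for rebalancing training data.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from neurofind._tokenize import tokenize
from neurofind.corpus_io import GoldAnnotation, Label, Report, ScanType, Site
from neurofind.embedding_cnn import EmbeddingTable
from neurofind.errors import ConfigurationError, DegenerateInputError


def _grammar() -> dict:
    text = resources.files("neurofind.data").joinpath("generator_grammar.json")
    return json.loads(text.read_text("utf-8"))


@dataclass(frozen=True)
class GeneratorConfig:
    n_reports: int = 1000
    sbi_prevalence: float = 0.12  # stand-in: the source corpora print no rate
    wmd_prevalence: float = 0.60
    site_a_fraction: float = 0.5
    richness_site_a: int = 212  # distinct negative-infarct phrasings
    richness_site_b: int = 12
    hedge_rate: float = 0.08
    historical_rate: float = 0.08
    confounder_rate: float = 0.20
    coreference_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sbi_prevalence", "wmd_prevalence", "site_a_fraction",
            "hedge_rate", "historical_rate", "confounder_rate", "coreference_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be >= 1")
        if self.richness_site_a < 1 or self.richness_site_b < 1:
            raise ConfigurationError("phrasing richness must be >= 1")


@dataclass(frozen=True)
class SentenceLabel:
    text: str
    sbi: int  # 1 iff the sentence alone supports a positive SBI call
    wmd: int
    provenance: str


@dataclass(frozen=True)
class SyntheticReportBundle:
    report: Report
    gold: GoldAnnotation
    sentence_labels: tuple[SentenceLabel, ...] = field(default=())

    @property
    def provenance(self) -> tuple[str, ...]:
        return tuple(s.provenance for s in self.sentence_labels)


def negative_phrasing_pool(richness: int, grammar: dict | None = None) -> list[str]:
    """Deterministic compositional pool of distinct negative-infarct
    phrasings (cue x modifier x finding x tail), truncated to ``richness``."""
    g = grammar or _grammar()
    spec = g["negative_sbi"]
    pool: list[str] = []
    seen: set[str] = set()
    for cue in spec["cues"]:
        for mod in spec["modifiers"]:
            for finding in spec["findings"]:
                for tail in spec["tails"]:
                    sentence = f"{cue} {mod} {finding}"
                    if tail:
                        sentence += f" {tail}"
                    sentence += "."
                    if sentence not in seen:
                        seen.add(sentence)
                        pool.append(sentence)
    if richness > len(pool):
        raise ConfigurationError(
            f"requested richness {richness} exceeds compositional pool ({len(pool)})"
        )
    return pool[:richness]


def site_b_phrasing_pool(richness: int, grammar: dict | None = None) -> list[str]:
    g = grammar or _grammar()
    templates = g["negative_sbi"]["site_b_templates"]
    if richness <= len(templates):
        return templates[:richness]
    extra = [s for s in negative_phrasing_pool(len(templates) + richness, g)
             if s not in templates]
    return (templates + extra)[:richness]


def _positive_sbi_sentence(rng: random.Random, g: dict, site: Site) -> str:
    # the template-based site reuses a small fixed phrasing subset; the
    # free-form site draws from the full compositional space
    spec = g["positive_sbi"]
    templated = site is Site.SITE_B_TEMPLATE
    anatomies = spec["anatomies"][:3] if templated else spec["anatomies"]
    anatomy = rng.choice(anatomies)
    if not templated and rng.random() < 0.2:
        return rng.choice(spec["unmodified_frames"]).format(anatomy=anatomy)
    mod = rng.choice(spec["modifiers"][:1] if templated else spec["modifiers"])
    frame = rng.choice(spec["frames"][:1] if templated else spec["frames"])
    finding = rng.choice(spec["findings"][:1] if templated else spec["findings"])
    return frame.format(mod=mod, mod_lower=mod.lower(), finding=finding, anatomy=anatomy)


def _hedged_sbi_sentence(rng: random.Random, g: dict) -> str:
    spec = g["positive_sbi"]
    return (
        f"{rng.choice(g['hedge_cues'])} {rng.choice(spec['modifiers']).lower()} "
        f"{rng.choice(spec['findings'])} in the {rng.choice(spec['anatomies'])}."
    )


def generate_corpus(config: GeneratorConfig) -> list[SyntheticReportBundle]:
    """Generate a labeled synthetic corpus, byte-identical under a seed.

    Gold document labels are consistent with the rule-engine summarization
    semantics except for coreference-split reports, which are POSITIVE at
    document level while no single sentence qualifies (the engineered rule-
    engine failure mode).
    """
    g = _grammar()
    rng = random.Random(config.seed)
    pool_a = negative_phrasing_pool(config.richness_site_a, g)
    pool_b = site_b_phrasing_pool(config.richness_site_b, g)
    bundles: list[SyntheticReportBundle] = []

    for i in range(config.n_reports):
        site = (
            Site.SITE_A_FREEFORM
            if rng.random() < config.site_a_fraction
            else Site.SITE_B_TEMPLATE
        )
        scan = ScanType.MRI if rng.random() < 0.6 else ScanType.CT
        content: list[SentenceLabel] = []

        # --- SBI strand -------------------------------------------------
        if rng.random() < config.sbi_prevalence:
            sbi_gold = Label.POSITIVE
            if rng.random() < config.coreference_rate:
                pair = rng.choice(g["coreference_sbi"])
                anatomy = rng.choice(g["positive_sbi"]["anatomies"])
                content.append(
                    SentenceLabel(pair[0].format(anatomy=anatomy), 0, 0, "coref_antecedent")
                )
                content.append(SentenceLabel(pair[1], 1, 0, "coref_conclusion"))
            else:
                content.append(
                    SentenceLabel(_positive_sbi_sentence(rng, g, site), 1, 0, "sbi_positive")
                )
        else:
            u = rng.random()
            if u < config.hedge_rate:
                sbi_gold = Label.INDETERMINATE
                content.append(
                    SentenceLabel(_hedged_sbi_sentence(rng, g), 0, 0, "sbi_hedged")
                )
            elif u < config.hedge_rate + config.historical_rate:
                sbi_gold = Label.NEGATIVE
                template = rng.choice(g["historical_sbi"])
                sentence = template.format(
                    anatomy=rng.choice(g["positive_sbi"]["anatomies"])
                )
                content.append(SentenceLabel(sentence, 0, 0, "sbi_historical"))
            else:
                sbi_gold = Label.NEGATIVE
                pool = pool_a if site is Site.SITE_A_FREEFORM else pool_b
                content.append(SentenceLabel(rng.choice(pool), 0, 0, "sbi_negated"))

        if rng.random() < config.confounder_rate:
            content.append(
                SentenceLabel(rng.choice(g["confounder_sbi"]), 0, 0, "sbi_confounder")
            )

        # --- WMD strand -------------------------------------------------
        if rng.random() < config.wmd_prevalence:
            wmd_gold = Label.POSITIVE
            spec = g["positive_wmd"]
            sentence = rng.choice(spec["frames"]).format(sev=rng.choice(spec["severities"]))
            content.append(SentenceLabel(sentence, 0, 1, "wmd_positive"))
        else:
            wmd_gold = Label.NEGATIVE
            u = rng.random()
            if u < 0.4:
                content.append(
                    SentenceLabel(rng.choice(g["negative_wmd"]), 0, 0, "wmd_negated")
                )
            elif u < 0.6:
                content.append(
                    SentenceLabel(rng.choice(g["exclusion_wmd"]), 0, 0, "wmd_exclusion")
                )
            # else: WMD simply not mentioned

        for _ in range(rng.randint(1, 2)):
            content.append(
                SentenceLabel(rng.choice(g["neutral_findings"]), 0, 0, "neutral")
            )
        rng.shuffle(content)

        header = [
            SentenceLabel(f"EXAM: {scan.value.upper()} HEAD.", 0, 0, "boilerplate"),
            SentenceLabel(f"INDICATION: {rng.choice(g['indications'])}.", 0, 0, "boilerplate"),
            SentenceLabel("FINDINGS:", 0, 0, "boilerplate"),
        ]
        footer = [
            SentenceLabel("IMPRESSION:", 0, 0, "boilerplate"),
            SentenceLabel(rng.choice(g["impressions_neutral"]), 0, 0, "boilerplate"),
        ]
        lines = header + content + footer
        report = Report(
            report_id=f"synth-{config.seed}-{i:05d}",
            site=site,
            scan_type=scan,
            text="\n".join(s.text for s in lines),
        )
        gold = GoldAnnotation(
            report_id=report.report_id, sbi_label=sbi_gold, wmd_label=wmd_gold
        )
        bundles.append(
            SyntheticReportBundle(report=report, gold=gold, sentence_labels=tuple(lines))
        )
    return bundles


def sentences_for_ml(
    bundles: Iterable[SyntheticReportBundle], concept: str = "sbi"
) -> list[tuple[list[str], int]]:
    """Flatten bundles into (tokens, 0/1) sentence examples for training."""
    if concept not in ("sbi", "wmd"):
        raise ValueError("concept must be 'sbi' or 'wmd'")
    out = []
    for b in bundles:
        for s in b.sentence_labels:
            toks = tokenize(s.text)
            if toks:
                out.append((toks, s.sbi if concept == "sbi" else s.wmd))
    return out


def write_corpus(bundles: Sequence[SyntheticReportBundle], outdir: str | Path) -> None:
    """Write reports.jsonl, gold.jsonl and sentence_labels.jsonl."""
    from neurofind.corpus_io import write_annotations, write_reports

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_reports([b.report for b in bundles], outdir / "reports.jsonl")
    write_annotations([b.gold for b in bundles], outdir / "gold.jsonl")
    with open(outdir / "sentence_labels.jsonl", "w", encoding="utf-8") as fh:
        for b in bundles:
            for s in b.sentence_labels:
                fh.write(
                    json.dumps(
                        {
                            "report_id": b.report.report_id,
                            "text": s.text,
                            "sbi": s.sbi,
                            "wmd": s.wmd,
                            "provenance": s.provenance,
                        }
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Embedding stand-ins
# ---------------------------------------------------------------------------

def _token_rng(seed: int, token: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}|{token}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def seeded_random_table(vocabulary: Sequence[str], d: int, seed: int) -> EmbeddingTable:
    """Unit-norm random vector per token, a pure function of (seed, token)."""
    tokens = sorted(set(vocabulary))
    matrix = np.zeros((len(tokens), d))
    for i, tok in enumerate(tokens):
        v = _token_rng(seed, tok).standard_normal(d)
        matrix[i] = v / np.linalg.norm(v)
    return EmbeddingTable.from_vectors(tokens, matrix)


def train_skipgram(
    sentences: Sequence[Sequence[str]],
    d: int = 100,
    window: int = 3,
    negatives: int = 5,
    epochs: int = 5,
    learning_rate: float = 0.05,
    seed: int = 0,
) -> EmbeddingTable:
    """Skip-gram with negative sampling (SGNS), plain NumPy.

    Unigram^0.75 negative distribution, linearly decaying learning rate,
    deterministic under ``seed``. Adequate for the small synthetic corpora
    this package trains on; not a general-purpose word2vec replacement.
    """
    tokens_flat = [t for s in sentences for t in s]
    if not tokens_flat:
        raise DegenerateInputError("cannot train an embedding on an empty corpus")
    vocab = sorted(set(tokens_flat))
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)
    counts = np.zeros(V)
    for t in tokens_flat:
        counts[index[t]] += 1
    noise = counts**0.75
    noise /= noise.sum()

    pairs: list[tuple[int, int]] = []
    for s in sentences:
        ids = [index[t] for t in s]
        for i, c in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    pairs.append((c, ids[j]))
    if not pairs:
        raise DegenerateInputError("corpus has no co-occurring token pairs")

    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))
    pairs_arr = np.array(pairs)
    n_pairs = len(pairs_arr)
    total_steps = epochs * n_pairs
    step = 0
    batch = 512
    for _epoch in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            idx = order[start : start + batch]
            centers = pairs_arr[idx, 0]
            contexts = pairs_arr[idx, 1]
            lr = learning_rate * max(1e-4, 1.0 - step / total_steps)
            step += len(idx)
            negs = rng.choice(V, size=(len(idx), negatives), p=noise)
            targets = np.concatenate([contexts[:, None], negs], axis=1)  # (B, 1+neg)
            labels = np.zeros((len(idx), 1 + negatives))
            labels[:, 0] = 1.0
            vc = w_in[centers]  # (B, d)
            vo = w_out[targets]  # (B, 1+neg, d)
            scores = np.einsum("bd,bnd->bn", vc, vo)
            sig = 1.0 / (1.0 + np.exp(-np.clip(scores, -30, 30)))
            err = sig - labels  # (B, 1+neg)
            grad_c = np.einsum("bn,bnd->bd", err, vo)
            grad_o = err[:, :, None] * vc[:, None, :]
            np.add.at(w_in, centers, -lr * grad_c)
            np.add.at(w_out, targets.ravel(), -lr * grad_o.reshape(-1, d))
    return EmbeddingTable.from_vectors(vocab, w_in)


def build_embedding_table(
    sentences: Sequence[Sequence[str]],
    d: int = 100,
    mode: str = "skipgram",
    seed: int = 0,
    **kwargs,
) -> EmbeddingTable:
    """Stand-in embedding table covering the full corpus vocabulary.

    ``mode`` is ``"skipgram"`` (trained on the given corpus) or
    ``"seeded_random"`` (deterministic unit-norm vectors per token).
    """
    if d < 2:
        raise ConfigurationError("embedding dimensionality must be >= 2")
    sentences = [list(s) for s in sentences if s]
    if not sentences:
        raise DegenerateInputError("cannot build an embedding from an empty corpus")
    if mode == "seeded_random":
        vocab = sorted({t for s in sentences for t in s})
        return seeded_random_table(vocab, d, seed)
    if mode == "skipgram":
        return train_skipgram(sentences, d=d, seed=seed, **kwargs)
    raise ConfigurationError(f"unknown embedding mode {mode!r}")


# ---------------------------------------------------------------------------
# Oversampling
# ---------------------------------------------------------------------------

def oversample(
    items: Sequence[tuple], target_ratio: float, seed: int = 0
) -> list[tuple]:
    """Duplicate minority-class items (with replacement, seeded) until the
    minority fraction reaches ``target_ratio``; never removes items.

    ``items`` are (example, label) pairs with exactly two label values.
    A target at or below the current minority fraction is a no-op.
    """
    if not (0.0 < target_ratio < 1.0):
        raise ConfigurationError("target_ratio must lie in (0, 1)")
    labels = [lab for _, lab in items]
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise DegenerateInputError("oversample requires exactly 2 label classes")
    counts = {c: labels.count(c) for c in classes}
    minority = min(classes, key=lambda c: (counts[c], str(c)))
    n_min = counts[minority]
    n_maj = len(items) - n_min
    if n_min / len(items) >= target_ratio:
        return list(items)
    import math

    needed_total = math.ceil(target_ratio * n_maj / (1.0 - target_ratio))
    minority_items = [it for it in items if it[1] == minority]
    rng = random.Random(seed)
    extra = [rng.choice(minority_items) for _ in range(needed_total - n_min)]
    return list(items) + extra
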