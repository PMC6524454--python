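"""Corpus I/O: reports, gold annotations, predictions, and the 3-way split.

Canonical on-disk format is JSONL, one record per line:

* report:      ``{"report_id": str, "site": "site_a"|"site_b",
  "scan_type": "ct"|"mri", "text": str}``
* annotation:  ``{"report_id": str, "sbi": label, "wmd": label,
  "annotator": str|null}`` with labels in
  ``positive|indeterminate|negative`` (case-insensitive on read).
* prediction:  ``{"report_id": str, "sbi": label, "wmd": label}``

A plain-directory reader (one ``.txt`` per report plus a ``metadata.json``
sidecar keyed by report id) is provided for convenience. Text is NFC
normalized on read so lexicon matching is stable.
"""

from __future__ import annotations

import enum
import json
import random
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from neurofind.errors import CorpusError, FormatError, SizeError


class Site(enum.Enum):
    """Documentation style of the originating site."""

    SITE_A_FREEFORM = "site_a"
    SITE_B_TEMPLATE = "site_b"


class ScanType(enum.Enum):
    CT = "ct"
    MRI = "mri"


class Label(enum.Enum):
    """Three-way document label for SBI and for WMD."""

    POSITIVE = "positive"
    INDETERMINATE = "indeterminate"
    NEGATIVE = "negative"


def _parse_enum(cls, raw: str, what: str, where: str):
    try:
        return cls(str(raw).strip().lower())
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise FormatError(f"{where}: unknown {what} {raw!r} (expected one of: {valid})")


@dataclass(frozen=True)
class Report:
    """One neuroimaging document; the unit of classification."""

    report_id: str
    site: Site
    scan_type: ScanType
    text: str

    def __post_init__(self) -> None:
        if not self.report_id:
            raise FormatError("report_id must be non-empty")
        if not self.text or not self.text.strip():
            raise FormatError(f"report {self.report_id!r}: text is empty")


@dataclass(frozen=True)
class GoldAnnotation:
    """Reference 3-way labels for one report, optionally per annotator."""

    report_id: str
    sbi_label: Label
    wmd_label: Label
    annotator_id: str | None = None


@dataclass(frozen=True)
class Prediction:
    """Serialized document-level decision of any classifier."""

    report_id: str
    sbi_label: Label
    wmd_label: Label


@dataclass(frozen=True)
class CorpusSplit:
    """Three-way partition of report ids. Remainder goes to ``train``."""

    train: tuple[str, ...]
    dev: tuple[str, ...]
    test: tuple[str, ...]
    seed: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "train": list(self.train),
            "dev": list(self.dev),
            "test": list(self.test),
            "seed": self.seed,
        }


def _nfc(text: str) -> str:
    return unicodedata.normalize("NFC", text)


def _jsonl_records(path: Path) -> Iterable[tuple[int, dict]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON ({exc})")
            if not isinstance(rec, dict):
                raise FormatError(f"{path}:{lineno}: record is not an object")
            yield lineno, rec


def _report_from_record(rec: dict, where: str) -> Report:
    for key in ("report_id", "site", "scan_type", "text"):
        if key not in rec:
            raise FormatError(f"{where}: missing required field {key!r}")
    text = _nfc(str(rec["text"]))
    if not text.strip():
        raise FormatError(f"{where}: text is empty after whitespace normalization")
    return Report(
        report_id=str(rec["report_id"]),
        site=_parse_enum(Site, rec["site"], "site", where),
        scan_type=_parse_enum(ScanType, rec["scan_type"], "scan_type", where),
        text=text,
    )


def read_reports(path: str | Path, format: str = "jsonl") -> list[Report]:
    """Read a corpus of reports.

    ``format`` is ``"jsonl"`` (canonical) or ``"plain_dir"`` (one ``.txt``
    per report, metadata in ``metadata.json``). Reports are returned in
    input order; duplicate ids raise :class:`CorpusError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "jsonl":
        reports = [
            _report_from_record(rec, f"{path}:{lineno}")
            for lineno, rec in _jsonl_records(path)
        ]
    elif fmt == "plain_dir":
        meta_path = path / "metadata.json"
        if not meta_path.exists():
            raise FormatError(f"{path}: plain_dir corpus requires metadata.json")
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        reports = []
        for txt in sorted(path.glob("*.txt")):
            rid = txt.stem
            if rid not in meta:
                raise FormatError(f"{txt}: no metadata entry for report {rid!r}")
            rec = dict(meta[rid])
            rec.setdefault("report_id", rid)
            rec["text"] = txt.read_text(encoding="utf-8")
            reports.append(_report_from_record(rec, str(txt)))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    seen: set[str] = set()
    for report in reports:
        if report.report_id in seen:
            raise CorpusError(f"duplicate report_id {report.report_id!r}")
        seen.add(report.report_id)
    return reports


def write_reports(reports: Iterable[Report], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {
                        "report_id": r.report_id,
                        "site": r.site.value,
                        "scan_type": r.scan_type.value,
                        "text": r.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_annotations(path: str | Path) -> list[GoldAnnotation]:
    """Read gold annotations; labels are matched case-insensitively against
    the closed 3-value vocabulary. Annotations for unknown reports are
    permitted here and validated at join time."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    annotations = []
    per_report_annotators: dict[str, set[str | None]] = {}
    for lineno, rec in _jsonl_records(path):
        where = f"{path}:{lineno}"
        for key in ("report_id", "sbi", "wmd"):
            if key not in rec:
                raise FormatError(f"{where}: missing required field {key!r}")
        ann = GoldAnnotation(
            report_id=str(rec["report_id"]),
            sbi_label=_parse_enum(Label, rec["sbi"], "label", where),
            wmd_label=_parse_enum(Label, rec["wmd"], "label", where),
            annotator_id=rec.get("annotator"),
        )
        readers = per_report_annotators.setdefault(ann.report_id, set())
        readers.add(ann.annotator_id)
        if len(readers) > 2:
            raise CorpusError(
                f"{where}: more than 2 annotators for report {ann.report_id!r}"
            )
        annotations.append(ann)
    return annotations


def write_annotations(annotations: Iterable[GoldAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            fh.write(
                json.dumps(
                    {
                        "report_id": a.report_id,
                        "sbi": a.sbi_label.value,
                        "wmd": a.wmd_label.value,
                        "annotator": a.annotator_id,
                    }
                )
                + "\n"
            )


def split_corpus(reports: Sequence[Report], seed: int) -> CorpusSplit:
    """Uniform random three-way split with any remainder assigned to train.

    1000 reports -> 334/333/333; 1001 -> 335/333/333. Deterministic under
    ``seed``; raises :class:`SizeError` below 3 reports.
    """
    ids = [r.report_id for r in reports]
    n = len(ids)
    if n < 3:
        raise SizeError(f"need at least 3 reports to split, got {n}")
    if len(set(ids)) != n:
        raise CorpusError("duplicate report_id in corpus")
    rng = random.Random(seed)
    order = sorted(ids)  # membership depends on ids+seed, not input order
    rng.shuffle(order)
    base, rem = divmod(n, 3)
    n_train = base + rem
    return CorpusSplit(
        train=tuple(order[:n_train]),
        dev=tuple(order[n_train : n_train + base]),
        test=tuple(order[n_train + base :]),
        seed=seed,
    )


def write_predictions(classifications: Iterable, path: str | Path) -> None:
    """Write document-level decisions as JSONL.

    Accepts anything exposing ``report_id``, ``sbi_label`` and ``wmd_label``
    (:class:`Prediction` or ``rule_engine.DocumentClassification``). Labels
    serialize as lower-case strings.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for c in classifications:
            fh.write(
                json.dumps(
                    {
                        "report_id": c.report_id,
                        "sbi": Label(c.sbi_label).value,
                        "wmd": Label(c.wmd_label).value,
                    }
                )
                + "\n"
            )


def read_predictions(path: str | Path) -> list[Prediction]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for lineno, rec in _jsonl_records(path):
        where = f"{path}:{lineno}"
        for key in ("report_id", "sbi", "wmd"):
            if key not in rec:
                raise FormatError(f"{where}: missing required field {key!r}")
        out.append(
            Prediction(
                report_id=str(rec["report_id"]),
                sbi_label=_parse_enum(Label, rec["sbi"], "label", where),
                wmd_label=_parse_enum(Label, rec["wmd"], "label", where),
            )
        )
    return out
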