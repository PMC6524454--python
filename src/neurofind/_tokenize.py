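"""Shared lowercase word tokenizer used by the ML and PMI paths."""

import re

_WORD = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens; punctuation is discarded."""
    return _WORD.findall(text.lower())
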