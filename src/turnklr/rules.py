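"""Ordered state-changing rules that smooth raw per-residue predictions.

β-turns occur in runs of at least four adjacent residues, so isolated
predictions are physically implausible.  Four rewrite rules, applied in
this fixed order, make a raw ``t``/``n`` string "more β-turn like":

1. isolated non-turn inside turns → turn              (tnt → ttt)
2. isolated turn → non-turn                           (ntn → nnn)
3. neighbours of an isolated turn pair → turn         (nttn → tttt)
4. for an isolated turn triplet, the flanking non-turn with the higher
   predicted turn probability → turn                  (ntttn → ttttn or ntttt)

Within each pass all matches are located on the pass-input string and all
flips applied simultaneously; patterns must lie fully inside the chain (no
virtual residues beyond the termini).  Rule 4 breaks probability ties to
the left flank.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .formats import TURN_ALPHABET

# (pattern, offsets flipped, replacement character)
_SIMPLE_PASSES = (
    ("tnt", (1,), "t"),
    ("ntn", (1,), "n"),
    ("nttn", (0, 3), "t"),
)


def _validate(labels: str, probs: Sequence[float]) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if len(labels) != len(probs):
        raise ValueError(
            f"labels length {len(labels)} != probabilities length {len(probs)}"
        )
    for i, ch in enumerate(labels):
        if ch not in TURN_ALPHABET:
            raise ValueError(f"illegal label {ch!r} at position {i}")
    return probs


def apply_state_rules(labels: str, probs: Sequence[float]) -> str:
    """Apply the four ordered smoothing rules to one chain's predictions.

    ``probs`` are the per-residue turn probabilities from the classifier;
    they are consulted only by rule 4's flank comparison.
    """
    probs = _validate(labels, probs)
    chars = list(labels)

    for pattern, offsets, repl in _SIMPLE_PASSES:
        cur = "".join(chars)
        flips = set()
        for i in range(len(cur) - len(pattern) + 1):
            if cur[i : i + len(pattern)] == pattern:
                flips.update(i + off for off in offsets)
        for i in flips:
            chars[i] = repl

    # rule 4: ntttn → flip the flanking n with the higher probability
    cur = "".join(chars)
    flips = set()
    for i in range(len(cur) - 4):
        if cur[i : i + 5] == "ntttn":
            left, right = i, i + 4
            flips.add(left if probs[left] >= probs[right] else right)
    for i in flips:
        chars[i] = "t"

    return "".join(chars)
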