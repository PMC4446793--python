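"""Sequence alphabets.

The likelihood core is alphabet-size-agnostic: the 20 amino acids are
the default, but a two-state alphabet is used throughout the test suite
because it admits closed-form transition probabilities and distance
estimators. Missing data ('-', '?', 'X' on input) is one internal state
code equal to ``n_states``; in likelihoods it marginalises over all
states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Residue order of the shipped empirical matrices (PAML convention).
AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"

MISSING_INPUT_CHARS = frozenset("-?X")


@dataclass(frozen=True)
class Alphabet:
    letters: str
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be unique")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.letters)})

    @property
    def n_states(self) -> int:
        return len(self.letters)

    @property
    def missing_code(self) -> int:
        return len(self.letters)

    def encode(self, seq: str) -> np.ndarray:
        """Encode a sequence string to uint8 state codes (missing -> n_states)."""
        out = np.empty(len(seq), dtype=np.uint8)
        idx = self._index
        miss = self.missing_code
        for i, c in enumerate(seq):
            if c in idx:
                out[i] = idx[c]
            elif c.upper() in idx:
                out[i] = idx[c.upper()]
            elif c in MISSING_INPUT_CHARS or c.upper() in MISSING_INPUT_CHARS:
                out[i] = miss
            else:
                raise ValueError(f"unknown state {c!r} for alphabet {self.letters!r}")
        return out

    def decode(self, codes: np.ndarray, missing_char: str = "-") -> str:
        lut = np.array(list(self.letters + missing_char), dtype="U1")
        return "".join(lut[np.asarray(codes, dtype=np.intp)])


AMINO_ACIDS = Alphabet(AA_LETTERS)
TWO_STATE = Alphabet("01")
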