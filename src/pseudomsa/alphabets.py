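"""Sequence alphabets and validated sequence containers.

Two 20-letter alphabets are used throughout: the canonical amino-acid
alphabet and the 3Di structural alphabet, which tokenizes each residue's
tertiary interaction with its nearest spatial neighbour.  Both happen to
use the same 20 uppercase letters, so validation is by declared kind, not
by character set alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Canonical amino-acid one-letter codes, alphabetical.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: The 20-state 3Di structural alphabet (Foldseek's state ordering is
#: irrelevant here; only membership matters, stored uppercase).
TDI_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

GAP = "-"

_AA_SET = frozenset(AA_ALPHABET)
_TDI_SET = frozenset(TDI_ALPHABET)


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


@dataclass(frozen=True)
class AminoSequence:
    """A validated amino-acid sequence with a free-text identifier."""

    residues: str
    id: str = "query"

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError("amino-acid sequence must be non-empty")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise AlphabetError(
                f"invalid amino-acid characters {sorted(bad)} in '{self.id}'"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class StructuralString:
    """A 3Di token string, optionally tied to the fragment it abstracts."""

    tokens: str
    source_fragment: Optional[object] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.tokens:
            raise AlphabetError("3Di string must be non-empty")
        up = self.tokens.upper()
        if up != self.tokens:
            object.__setattr__(self, "tokens", up)
        bad = set(up) - _TDI_SET
        if bad:
            raise AlphabetError(f"invalid 3Di tokens {sorted(bad)}")
        if self.source_fragment is not None:
            frag_len = getattr(self.source_fragment, "length", None)
            if frag_len is not None and frag_len != len(up):
                raise AlphabetError(
                    f"3Di length {len(up)} != fragment length {frag_len}"
                )

    def __len__(self) -> int:
        return len(self.tokens)


def validate_aligned_row(row: str, width: int) -> None:
    """Check an aligned row: exact width, amino alphabet plus gaps."""
    if len(row) != width:
        raise AlphabetError(f"aligned row width {len(row)} != {width}")
    bad = set(row) - _AA_SET - {GAP}
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)} in aligned row")
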