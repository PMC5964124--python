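"""Small sequence helpers used throughout the package.

Only plain A/C/G/T strings are accepted: the assay relies on exact sequence
identity, so IUPAC ambiguity codes are rejected rather than skipped.
"""

from __future__ import annotations

from .errors import ValidationError

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def validate_dna(sequence: str, *, name: str = "sequence", length: int | None = None,
                 min_length: int = 1) -> str:
    """Return ``sequence`` uppercased, or raise :class:`ValidationError`.

    ``length`` pins an exact length; ``min_length`` a lower bound.
    """
    if not isinstance(sequence, str):
        raise ValidationError(f"{name} must be a string, got {type(sequence).__name__}")
    seq = sequence.upper()
    if length is not None and len(seq) != length:
        raise ValidationError(f"{name} must be exactly {length} nt, got {len(seq)}")
    if len(seq) < min_length:
        raise ValidationError(f"{name} must be at least {min_length} nt, got {len(seq)}")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValidationError(
            f"{name} contains non-ACGT characters {sorted(bad)}; "
            "ambiguity codes are not allowed in exact-match panels"
        )
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]
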