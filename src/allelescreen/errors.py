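"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented invariant (bad allele, flank length, negative count...)."""


class CollisionError(ValidationError):
    """Two templates share a sequence (same or opposite strand).

    Carries the offending (snp_id, allele) pairs so panels can be repaired.
    """

    def __init__(self, pairs):
        self.pairs = list(pairs)
        detail = "; ".join(f"{a} <-> {b}" for a, b in self.pairs)
        super().__init__(f"template sequence collision(s): {detail}")


class ParseError(ValueError):
    """Malformed input file; message carries the file and record/line number."""
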