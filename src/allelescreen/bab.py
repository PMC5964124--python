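"""Biased allelic binding (BAB) scores.

The BAB score contrasts the variant/reference read-count ratio in a
protein-bound (test) sample against the same ratio in the input oligo pool:

    BAB = log2 [ (RC_variant / RC_reference)_test /
                 (RC_variant / RC_reference)_input ]

A positive score means the variant allele is preferentially retained by the
bound protein; |BAB| ≥ 0.58 corresponds to a 1.5-fold allelic difference and
is the default significance cutoff.  The identical formula applied to
mRNA-vs-plasmid STARR-seq counts is the BAE score (see :mod:`.bae`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .counting import AlleleCountTable
from .errors import ValidationError

DEFAULT_BAB_CUTOFF = 0.58  # log2(1.5) to two decimals
DEFAULT_EQTL_CUTOFF = 1e-5


def _score(test_var: float, test_ref: float, input_var: float, input_ref: float,
           pseudocount: float = 1.0) -> tuple[float, bool]:
    """(score, pseudocounted).  NaN when all four counts are zero."""
    counts = (test_var, test_ref, input_var, input_ref)
    if any(c < 0 for c in counts):
        raise ValidationError("read counts must be non-negative")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if all(c == 0 for c in counts):
        return math.nan, False
    pseudocounted = any(c == 0 for c in counts)
    if pseudocounted:
        test_var, test_ref, input_var, input_ref = (c + pseudocount for c in counts)
    # grouped so that swapping (var, ref) negates the score bit-exactly
    numerator = math.log2(test_var) + math.log2(input_ref)
    denominator = math.log2(test_ref) + math.log2(input_var)
    return numerator - denominator, pseudocounted


def bab_score(test_var: float, test_ref: float, input_var: float, input_ref: float,
              pseudocount: float = 1.0) -> float:
    """BAB score from four read counts; see module docstring for the formula.

    A pseudocount is added to *all four* counts whenever any of them is zero,
    keeping the score finite and the variant/reference swap antisymmetric.
    All four zero yields NaN (no information).
    """
    return _score(test_var, test_ref, input_var, input_ref, pseudocount)[0]


@dataclass
class ImbalanceResult:
    """Score and provenance for one (SNP, variant allele, condition)."""

    snp_id: str
    variant_allele: str
    reference_allele: str
    condition: str
    test_var: float
    test_ref: float
    input_var: float
    input_ref: float
    score: float
    pseudocounted: bool = False
    replicate_scores: list[float] = field(default_factory=list)
    significant: bool | None = None
    eqtl_p: float | None = None
    missing_reason: str | None = None

    @property
    def fold_change(self) -> float:
        """Linear-scale allelic fold change, 2**score."""
        return 2.0 ** self.score


def infer_roles(roles: Mapping[tuple[str, str], str]) -> dict[str, tuple[str, list[str]]]:
    """Collapse a (snp, allele) -> role map into snp -> (reference, [variants])."""
    out: dict[str, tuple[str | None, list[str]]] = {}
    for (snp, allele), role in roles.items():
        ref, variants = out.setdefault(snp, (None, []))
        if role == "reference":
            if ref is not None:
                raise ValidationError(f"{snp}: multiple reference alleles declared")
            out[snp] = (allele, variants)
        else:
            variants.append(allele)
    for snp, (ref, variants) in out.items():
        if ref is None or not variants:
            raise ValidationError(f"{snp}: needs one reference and ≥1 variant allele")
        variants.sort()
    return {snp: (ref, variants) for snp, (ref, variants) in out.items()}


def _sum_counts(tables: Sequence[AlleleCountTable], key) -> float:
    return sum(t.counts.get(key, 0) for t in tables)


def score_panel(test_tables: Sequence[AlleleCountTable],
                input_tables: Sequence[AlleleCountTable],
                roles: Mapping[tuple[str, str], str] | None = None,
                pseudocount: float = 1.0,
                eqtl_p: Mapping[str, float] | None = None) -> list[ImbalanceResult]:
    """Score every SNP (one result per variant allele per test condition).

    Technical replicates are pooled by summing counts — the maximum-likelihood
    treatment for multinomial sampling — while per-replicate scores are kept
    for dispersion QC.  Test tables are grouped by their ``condition`` label;
    all input tables are pooled as the common baseline.
    """
    if not test_tables or not input_tables:
        raise ValidationError("need at least one test and one input count table")
    if roles is None:
        roles = test_tables[0].roles
    snp_roles = infer_roles(roles)

    by_condition: dict[str, list[AlleleCountTable]] = {}
    for t in test_tables:
        by_condition.setdefault(t.condition, []).append(t)

    input_keys = set().union(*(set(t.counts) for t in input_tables))
    results = []
    for condition in sorted(by_condition):
        tests = by_condition[condition]
        for snp in sorted(snp_roles):
            ref, variants = snp_roles[snp]
            for variant in variants:
                kv, kr = (snp, variant), (snp, ref)
                res = ImbalanceResult(
                    snp_id=snp, variant_allele=variant, reference_allele=ref,
                    condition=condition,
                    test_var=_sum_counts(tests, kv), test_ref=_sum_counts(tests, kr),
                    input_var=_sum_counts(input_tables, kv),
                    input_ref=_sum_counts(input_tables, kr),
                    score=math.nan,
                    eqtl_p=None if eqtl_p is None else eqtl_p.get(snp),
                )
                if kv not in input_keys or kr not in input_keys:
                    res.missing_reason = "SNP absent from input tables"
                    results.append(res)
                    continue
                res.score, res.pseudocounted = _score(
                    res.test_var, res.test_ref, res.input_var, res.input_ref,
                    pseudocount)
                res.replicate_scores = [
                    _score(t.counts.get(kv, 0), t.counts.get(kr, 0),
                           res.input_var, res.input_ref, pseudocount)[0]
                    for t in tests]
                if math.isnan(res.score):
                    res.missing_reason = "all counts zero"
                results.append(res)
    return results


def classify(results: Iterable[ImbalanceResult],
             bab_cutoff: float = DEFAULT_BAB_CUTOFF,
             eqtl_cutoff: float | None = DEFAULT_EQTL_CUTOFF) -> list[ImbalanceResult]:
    """Mark significant results and return those of selected SNPs.

    A result is significant when |score| ≥ ``bab_cutoff`` (inclusive) and,
    if an eQTL P value is attached, eqtl_p ≤ ``eqtl_cutoff``.  A SNP is
    selected when any of its variant alleles is significant in any condition;
    the returned subset contains the qualifying results.
    """
    results = list(results)
    for r in results:
        ok = not math.isnan(r.score) and abs(r.score) >= bab_cutoff
        if ok and r.eqtl_p is not None and eqtl_cutoff is not None:
            ok = r.eqtl_p <= eqtl_cutoff
        r.significant = ok
    selected_snps = {r.snp_id for r in results if r.significant}
    return [r for r in results if r.snp_id in selected_snps and r.significant]
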