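"""STARR-seq allelic enhancer analysis.

Targeted-amplicon STARR-seq couples a candidate sequence to its own
transcription: mRNA read abundance measures enhancer activity, with the
transfected plasmid pool as input.  This module provides

* RPM normalization of allele count tables,
* the test-vs-input enhancer enrichment filter (default 1.5-fold, two-sided),
* the BAE score — the same log2 double-ratio as the BAB score, applied to
  mRNA (test) vs plasmid (input) allelic counts,
* haplotype-resolved counting and scoring from single reads that span all
  SNPs of a clustered region.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .bab import bab_score, _score
from .counting import AlleleCountTable
from .errors import ValidationError
from .sequtil import reverse_complement, validate_dna

RPM_SCALE = 1e6
DEFAULT_ENRICHMENT_FOLD = 1.5

Haplotype = tuple[str, ...]


@dataclass(frozen=True)
class SnpOffset:
    """One SNP's location within an amplicon (1-based offset)."""

    snp_id: str
    offset: int
    ref_allele: str
    variant_alleles: tuple[str, ...]

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.variant_alleles


@dataclass(frozen=True)
class AmpliconRecord:
    """A cloned candidate fragment and the SNPs it carries."""

    amplicon_id: str
    sequence: str
    snps: tuple[SnpOffset, ...]

    def __post_init__(self):
        object.__setattr__(self, "sequence",
                           validate_dna(self.sequence, name="amplicon sequence",
                                        min_length=1))
        offsets = [s.offset for s in self.snps]
        if offsets != sorted(offsets) or len(set(offsets)) != len(offsets):
            raise ValidationError(
                f"{self.amplicon_id}: SNP offsets must be strictly increasing")
        for s in self.snps:
            if not 1 <= s.offset <= len(self.sequence):
                raise ValidationError(
                    f"{self.amplicon_id}:{s.snp_id}: offset {s.offset} out of bounds")
            base = self.sequence[s.offset - 1]
            if base not in s.alleles:
                raise ValidationError(
                    f"{self.amplicon_id}:{s.snp_id}: amplicon base {base} at offset "
                    f"{s.offset} matches neither reference nor variant allele")

    def haplotype_space(self) -> list[Haplotype]:
        """All allele combinations across the covered SNPs, reference-first."""
        return list(itertools.product(*(s.alleles for s in self.snps)))

    def substituted_sequence(self, haplotype: Haplotype) -> str:
        seq = list(self.sequence)
        for snp, allele in zip(self.snps, haplotype):
            seq[snp.offset - 1] = allele
        return "".join(seq)


@dataclass(frozen=True)
class RpmTable:
    """Reads-per-million normalized allele counts for one sample."""

    sample_id: str
    condition: str
    rpm: dict
    denominator: int  # template-assigned read observations

    def __post_init__(self):
        if self.denominator <= 0:
            raise ValidationError("RPM denominator must be positive")


def rpm_normalize(table: AlleleCountTable) -> RpmTable:
    """count × 1e6 / (total template-assigned observations).

    The denominator is the sum of per-allele assignments, so RPM values
    always sum to 1e6 regardless of the multi-SNP counting policy.
    """
    denom = sum(table.counts.values())
    if denom == 0:
        raise ValidationError(f"{table.sample_id}: no assigned reads to normalize")
    return RpmTable(sample_id=table.sample_id, condition=table.condition,
                    rpm={k: c * RPM_SCALE / denom for k, c in table.counts.items()},
                    denominator=denom)


def enhancer_filter(test_rpm: RpmTable, input_rpm: RpmTable,
                    fold: float = DEFAULT_ENRICHMENT_FOLD,
                    pseudocount: float = 1.0,
                    two_sided: bool = True) -> list[str]:
    """SNPs with at least one allele ≥ ``fold`` different between test and input.

    The threshold is inclusive; ``two_sided`` (default) keeps both enriched
    (enhancer-like) and depleted (silencer-like) alleles, one-sided keeps
    enrichment only.  RPM values get a small pseudocount so zero-input
    alleles stay finite.
    """
    if fold < 1:
        raise ValidationError("fold must be ≥ 1")
    shared = set(test_rpm.rpm) & set(input_rpm.rpm)
    if not shared:
        raise ValidationError("test and input RPM tables share no alleles")
    kept = set()
    for key in shared:
        ratio = (test_rpm.rpm[key] + pseudocount) / (input_rpm.rpm[key] + pseudocount)
        if ratio >= fold or (two_sided and ratio <= 1.0 / fold):
            kept.add(key[0])
    return sorted(kept)


def bae_score(test_var: float, test_ref: float, input_var: float, input_ref: float,
              pseudocount: float = 1.0) -> float:
    """Biased allelic enhancer score: the BAB formula on mRNA vs plasmid counts.

    Inputs may be raw counts or RPM values — the double ratio cancels the
    per-sample depth either way.
    """
    return bab_score(test_var, test_ref, input_var, input_ref, pseudocount)


@dataclass
class HaplotypeCountTable:
    """Per-amplicon counts of allele combinations read off spanning reads."""

    amplicon_id: str
    counts: dict  # Haplotype -> int
    other_count: int = 0
    spanning_reads: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()) or self.other_count < 0:
            raise ValidationError("haplotype counts must be non-negative")


def haplotype_counts(reads: Iterable[str], amplicon: AmpliconRecord,
                     declared_haplotypes: Sequence[Haplotype] | None = None,
                     ) -> HaplotypeCountTable:
    """Count haplotypes from reads that cover *all* SNPs of the amplicon.

    A read contributes iff it matches a window of one allele-substituted
    amplicon variant perfectly (either strand; mismatches are allowed only at
    the declared SNP offsets, via the substitution) and that window spans
    every SNP offset.  The allele tuple at the offsets is the haplotype;
    tuples outside ``declared_haplotypes`` (default: the full combination
    space) land in ``other_count``.  Reads spanning only a subset of the
    SNPs are excluded entirely.
    """
    if not amplicon.snps:
        raise ValidationError(f"{amplicon.amplicon_id}: no SNPs declared")
    space = amplicon.haplotype_space()
    declared = set(space if declared_haplotypes is None
                   else (tuple(h) for h in declared_haplotypes))
    unknown = declared - set(space)
    if unknown:
        raise ValidationError(
            f"{amplicon.amplicon_id}: declared haplotypes {sorted(unknown)} use "
            "alleles outside the amplicon's SNP definitions")
    variants = [(hap, amplicon.substituted_sequence(hap)) for hap in space]
    first = amplicon.snps[0].offset - 1        # 0-based index of first SNP
    last = amplicon.snps[-1].offset - 1        # 0-based index of last SNP

    counts = {hap: 0 for hap in declared}
    other = spanning = 0
    for read in reads:
        read = read.upper()
        if len(read) > len(amplicon.sequence):
            raise ValidationError(
                f"{amplicon.amplicon_id}: read longer than amplicon sequence")
        hit: Haplotype | None = None
        for oriented in (read, reverse_complement(read)):
            for hap, variant_seq in variants:
                start = variant_seq.find(oriented)
                while start != -1:
                    if start <= first and start + len(oriented) > last:
                        hit = hap
                        break
                    start = variant_seq.find(oriented, start + 1)
                if hit:
                    break
            if hit:
                break
        if hit is None:
            continue
        spanning += 1
        if hit in declared:
            counts[hit] += 1
        else:
            other += 1
    return HaplotypeCountTable(amplicon_id=amplicon.amplicon_id, counts=counts,
                               other_count=other, spanning_reads=spanning)


class HaplotypeBaeSummary(NamedTuple):
    per_amplicon: dict            # amplicon_id -> score (NaN if undefined)
    mean: float
    min: float
    max: float


def haplotype_bae(counts_test: Mapping[str, HaplotypeCountTable],
                  counts_input: Mapping[str, HaplotypeCountTable],
                  variant_hap: Haplotype, reference_hap: Haplotype,
                  pseudocount: float = 1.0) -> HaplotypeBaeSummary:
    """Per-amplicon haplotype BAE scores plus their unweighted mean and range.

    Each amplicon spanning the SNP cluster yields
    ``log2[(test hap_var/hap_ref) / (input hap_var/hap_ref)]``; the summary
    is the plain mean and min–max range across amplicons (per-amplicon depths
    are available in the count tables for weighted reanalysis).
    """
    variant_hap, reference_hap = tuple(variant_hap), tuple(reference_hap)
    shared = sorted(set(counts_test) & set(counts_input))
    if not shared:
        raise ValidationError("test and input haplotype tables share no amplicons")
    per = {}
    for amp in shared:
        t, i = counts_test[amp], counts_input[amp]
        for table in (t, i):
            for hap in (variant_hap, reference_hap):
                if hap not in table.counts:
                    raise ValidationError(
                        f"{amp}: haplotype {'-'.join(hap)} not in declared set")
        per[amp], _ = _score(t.counts[variant_hap], t.counts[reference_hap],
                             i.counts[variant_hap], i.counts[reference_hap],
                             pseudocount)
    finite = [s for s in per.values() if not math.isnan(s)]
    if not finite:
        return HaplotypeBaeSummary(per, math.nan, math.nan, math.nan)
    return HaplotypeBaeSummary(per, sum(finite) / len(finite), min(finite), max(finite))
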