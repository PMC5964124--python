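"""Design and QC of allele-specific oligo panels.

Each SNP is rendered as one 21-nt template per allele with the polymorphic
base at the 11th (central) position, flanked by 10 nt of genomic context on
each side.  Templates are annotated with the sequence-composition and
thermodynamic properties known to drive read-count bias in pooled-oligo
sequencing libraries: GC fraction, nearest-neighbor Tm and ΔG°37, and the
terminal mono-/dinucleotide classes (A/T-rich 5′/3′ ends yield fewer reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from Bio.SeqUtils import gc_fraction as _bio_gc_fraction

from . import thermo
from .errors import ValidationError
from .sequtil import validate_dna

#: Template geometry: 21-nt oligo, SNP at the 11th base (0-based offset 10).
TEMPLATE_LENGTH = 21
SNP_OFFSET = 10  # 0-based; reported 1-based as position 11 in outputs
FLANK_LENGTH = 10

#: Adaptor bases added during library preparation, per fragment.
ADAPTOR_BP = 140

#: Terminal dinucleotides associated with the lowest read counts.
LOW_YIELD_DINUCLEOTIDES = frozenset({"AA", "AT", "TA", "TT"})

#: Average molecular weight of one double-stranded base pair, g/mol.
DEFAULT_MW_PER_BP = 660.0


@dataclass(frozen=True)
class SnpPanelEntry:
    """One SNP with its alleles and ±10-nt plus-strand flanking context."""

    snp_id: str
    chrom: str
    pos: int  # 1-based genomic position
    ref_allele: str
    variant_alleles: tuple[str, ...]
    left_flank: str
    right_flank: str

    def __post_init__(self):
        object.__setattr__(self, "ref_allele",
                           validate_dna(self.ref_allele, name="ref_allele", length=1))
        variants = tuple(validate_dna(a, name="variant allele", length=1)
                         for a in self.variant_alleles)
        if not 1 <= len(variants) <= 3:
            raise ValidationError(
                f"{self.snp_id}: expected 1..3 variant alleles, got {len(variants)}")
        alleles = (self.ref_allele,) + variants
        if len(set(alleles)) != len(alleles):
            raise ValidationError(f"{self.snp_id}: alleles must be mutually distinct")
        object.__setattr__(self, "variant_alleles", variants)
        object.__setattr__(
            self, "left_flank",
            validate_dna(self.left_flank, name="left_flank", length=FLANK_LENGTH))
        object.__setattr__(
            self, "right_flank",
            validate_dna(self.right_flank, name="right_flank", length=FLANK_LENGTH))
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos must be a 1-based positive position")

    @property
    def alleles(self) -> tuple[str, ...]:
        """Reference allele first, then variants in declared order."""
        return (self.ref_allele,) + self.variant_alleles


@dataclass(frozen=True)
class AlleleTemplate:
    """A 21-nt allele-specific template with its QC annotations."""

    snp_id: str
    allele: str
    role: str  # "reference" | "variant"
    sequence: str
    gc_fraction: float
    tm_celsius: float
    delta_g_kcal: float
    end5_mono: str
    end3_mono: str
    end5_di: str
    end3_di: str


class EndClasses(NamedTuple):
    end5_mono: str
    end3_mono: str
    end5_di: str
    end3_di: str


class UniqueSequenceReport(NamedTuple):
    n_unique: int
    collision: bool
    colliding_sequences: tuple[str, ...]


@dataclass(frozen=True)
class PoolSpec:
    """Arithmetic description of an equimolar oligo pool."""

    n_oligos: int
    per_oligo_conc_nM: float
    total_mass_ng: float
    duplex_length_bp: int = TEMPLATE_LENGTH
    avg_mw_per_bp: float = DEFAULT_MW_PER_BP

    def __post_init__(self):
        for name in ("n_oligos", "per_oligo_conc_nM", "total_mass_ng",
                     "duplex_length_bp", "avg_mw_per_bp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"PoolSpec.{name} must be positive")


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length for an ACGT sequence."""
    seq = validate_dna(sequence, name="sequence", min_length=1)
    return _bio_gc_fraction(seq)


def end_nucleotide_classes(sequence: str) -> EndClasses:
    """Terminal mono- and dinucleotides at the 5′ and 3′ ends (plus strand)."""
    seq = validate_dna(sequence, name="sequence", min_length=2)
    return EndClasses(end5_mono=seq[0], end3_mono=seq[-1],
                      end5_di=seq[:2], end3_di=seq[-2:])


def build_allele_templates(entry: SnpPanelEntry, *, salt_mM: float = 50.0,
                           conc_nM: float = 5.05) -> list[AlleleTemplate]:
    """All templates for one SNP, reference first, annotated for QC.

    Every template of the SNP shares the flanks and differs only at the
    central (11th) base.
    """
    templates = []
    for allele in entry.alleles:
        seq = entry.left_flank + allele + entry.right_flank
        ends = end_nucleotide_classes(seq)
        templates.append(AlleleTemplate(
            snp_id=entry.snp_id,
            allele=allele,
            role="reference" if allele == entry.ref_allele else "variant",
            sequence=seq,
            gc_fraction=gc_fraction(seq),
            tm_celsius=thermo.melting_temperature(seq, salt_mM=salt_mM,
                                                  oligo_conc_nM=conc_nM),
            delta_g_kcal=thermo.duplex_delta_g(seq),
            **ends._asdict(),
        ))
    return templates


def count_unique_sequences(panel: Sequence[SnpPanelEntry]) -> UniqueSequenceReport:
    """Number of distinct template sequences across the panel.

    Equals Σ(1 + n_variants) unless two SNPs happen to share a template
    sequence, in which case the collision flag is set and the offending
    sequences reported.
    """
    seen: dict[str, str] = {}
    collisions: list[str] = []
    for entry in panel:
        for allele in entry.alleles:
            seq = entry.left_flank + allele + entry.right_flank
            if seq in seen and seen[seq] != entry.snp_id:
                collisions.append(seq)
            seen[seq] = entry.snp_id
    return UniqueSequenceReport(n_unique=len(seen), collision=bool(collisions),
                                colliding_sequences=tuple(collisions))


def flag_low_yield(template: AlleleTemplate, gc_cutoff: float = 0.25,
                   weak_delta_g: float = -20.0) -> list[str]:
    """QC flags predicting low read counts for one template.

    LOW_GC       gc_fraction strictly below ``gc_cutoff``
    AT_END5/3    terminal dinucleotide in {AA, AT, TA, TT}
    WEAK_DUPLEX  ΔG°37 above (less stable than) ``weak_delta_g`` kcal/mol
    """
    flags = []
    if template.gc_fraction < gc_cutoff:
        flags.append("LOW_GC")
    if template.end5_di in LOW_YIELD_DINUCLEOTIDES:
        flags.append("AT_END5")
    if template.end3_di in LOW_YIELD_DINUCLEOTIDES:
        flags.append("AT_END3")
    if template.delta_g_kcal > weak_delta_g:
        flags.append("WEAK_DUPLEX")
    return flags


def pool_mass_to_fmol(spec: PoolSpec) -> float:
    """Femtomoles of each oligo in an equimolar pool of ``total_mass_ng``.

    per-oligo amount = (total_mass_ng / n_oligos) / (length × MW per bp).
    """
    per_oligo_ng = spec.total_mass_ng / spec.n_oligos
    mw = spec.duplex_length_bp * spec.avg_mw_per_bp  # g/mol
    return per_oligo_ng * 1e-9 / mw * 1e15


def expected_library_size(insert_length: int = TEMPLATE_LENGTH,
                          adaptor_bp: int = ADAPTOR_BP) -> int:
    """Expected sequencing-library fragment size: insert plus adaptor bases."""
    if insert_length <= 0 or adaptor_bp < 0:
        raise ValidationError("insert_length must be positive, adaptor_bp non-negative")
    return insert_length + adaptor_bp


class HeterozygositySummary(NamedTuple):
    n_heterozygous: int
    n_total: int
    percent: float


def heterozygosity_summary(het_flags: Iterable[bool]) -> HeterozygositySummary:
    """Count and percentage of panel SNPs heterozygous in a given cell line.

    Relevant as QC context: only heterozygous sites are informative for
    read-count-based allelic analyses in that line.
    """
    flags = list(het_flags)
    if not flags:
        raise ValidationError("empty heterozygosity flag list")
    n_het = sum(bool(f) for f in flags)
    return HeterozygositySummary(n_het, len(flags), 100.0 * n_het / len(flags))
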