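"""Perfect-match assignment of sequencing reads to allele-specific templates.

A read is assigned to a template if and only if the template's full-length
sequence occurs as an exact substring of the read, on either strand.  No
mismatches, no quality filtering: because all templates are unique even at a
single-nucleotide difference, the perfect-match rule cleanly separates the
two alleles of every SNP, and sequencing errors simply push reads off-target
rather than to the wrong allele.

Ambiguity policy: a read containing full templates of two or more distinct
SNPs is excluded from counts (tallied as ambiguous).  For long reads over
clustered SNPs — e.g. 100-bp fragments spanning several nearby SNPs of one
amplicon — pass ``multi_snp="count_each"`` to credit each covered SNP once.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .errors import CollisionError, ValidationError
from .panel import AlleleTemplate
from .sequtil import reverse_complement

log = logging.getLogger(__name__)

Key = tuple[str, str]  # (snp_id, allele)


@dataclass
class TemplateLibrary:
    """Exact-lookup index over template sequences and their reverse complements."""

    templates: list[AlleleTemplate]
    index: dict[str, Key] = field(repr=False)
    lengths: tuple[int, ...]

    @property
    def keys(self) -> list[Key]:
        return [(t.snp_id, t.allele) for t in self.templates]

    @property
    def roles(self) -> dict[Key, str]:
        return {(t.snp_id, t.allele): t.role for t in self.templates}


def build_index(templates: Sequence[AlleleTemplate]) -> TemplateLibrary:
    """Index templates on both strands, failing loudly on any collision.

    A collision is two templates sharing a sequence directly or through
    reverse complement; either would make perfect-match counts ambiguous.
    """
    index: dict[str, Key] = {}
    collisions: list[tuple[str, str]] = []
    for t in templates:
        key = (t.snp_id, t.allele)
        for seq in {t.sequence, reverse_complement(t.sequence)}:
            prior = index.get(seq)
            if prior is not None and prior != key:
                collisions.append((f"{prior[0]}|{prior[1]}", f"{t.snp_id}|{t.allele}"))
            else:
                index[seq] = key
    if collisions:
        raise CollisionError(collisions)
    lengths = tuple(sorted({len(t.sequence) for t in templates}))
    return TemplateLibrary(templates=list(templates), index=index, lengths=lengths)


@dataclass
class AlleleCountTable:
    """Per-sample, per-allele exact-match read counts plus assignment totals."""

    sample_id: str
    condition: str
    counts: dict[Key, int]
    roles: dict[Key, str]
    total_reads: int
    assigned_reads: int
    ambiguous_reads: int

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("counts must be non-negative")
        if self.assigned_reads + self.ambiguous_reads > self.total_reads:
            raise ValidationError("assigned + ambiguous reads exceed total reads")

    @property
    def off_target_reads(self) -> int:
        return self.total_reads - self.assigned_reads - self.ambiguous_reads


@dataclass(frozen=True)
class MappingStats:
    on_target_fraction: float
    median_depth: float
    min_depth: int
    max_depth: int


def _match_keys(read: str, index: dict[str, Key], lengths: tuple[int, ...]) -> set[Key]:
    """Distinct (snp_id, allele) whose template occurs exactly in ``read``."""
    hits: set[Key] = set()
    get = index.get
    for k in lengths:
        if k > len(read):
            continue
        for i in range(len(read) - k + 1):
            key = get(read[i:i + k])
            if key is not None:
                hits.add(key)
    return hits


def _iter_fastq(path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzip detected by magic bytes)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    from .io import ParseError, open_maybe_gzip

    with open_maybe_gzip(path) as handle:
        record_no = 0
        try:
            for _, seq, _ in FastqGeneralIterator(handle):
                record_no += 1
                yield seq.upper()
        except ValueError as exc:
            raise ParseError(f"{path}: malformed FASTQ near record "
                             f"{record_no + 1}: {exc}") from exc


def count_reads(fastq, library: TemplateLibrary, *, fastq2=None,
                sample_id: str = "sample", condition: str = "test",
                multi_snp: str = "ambiguous",
                ) -> tuple[AlleleCountTable, MappingStats]:
    """Count perfect-match template occurrences in one sample's reads.

    Parameters
    ----------
    fastq : path (or list of paths) to FASTQ/FASTQ.gz; ``fastq2`` gives the
        mate files for paired-end data.  Mates are counted per read, but a
        pair supporting two different alleles of one SNP is excluded.
    multi_snp : ``"ambiguous"`` (default) excludes reads matching templates
        of ≥2 distinct SNPs; ``"count_each"`` credits every covered SNP once.
    """
    if multi_snp not in ("ambiguous", "count_each"):
        raise ValidationError(f"unknown multi_snp policy {multi_snp!r}")
    paths1 = [fastq] if isinstance(fastq, (str, bytes)) or hasattr(fastq, "__fspath__") \
        else list(fastq)
    paths2 = None
    if fastq2 is not None:
        paths2 = [fastq2] if isinstance(fastq2, (str, bytes)) or hasattr(fastq2, "__fspath__") \
            else list(fastq2)
        if len(paths2) != len(paths1):
            raise ValidationError("fastq and fastq2 must list the same number of files")

    counts: dict[Key, int] = {key: 0 for key in library.keys}
    total = assigned = ambiguous = 0

    def _consume(read_hit_sets: list[set[Key]]):
        nonlocal assigned, ambiguous
        # pair-level conflict: two alleles of one SNP across (or within) mates
        union: set[Key] = set().union(*read_hit_sets)
        snps = {snp for snp, _ in union}
        conflict = len(union) != len(snps)
        for hits in read_hit_sets:
            if not hits:
                continue
            if conflict or (multi_snp == "ambiguous" and len({s for s, _ in hits}) > 1):
                ambiguous += 1
                continue
            assigned += 1
            for key in hits:
                counts[key] += 1

    if paths2 is None:
        for path in paths1:
            for n, read in enumerate(_iter_fastq(path), 1):
                total += 1
                _consume([_match_keys(read, library.index, library.lengths)])
                if n % 1_000_000 == 0:
                    log.info("%s: processed %d reads", path, n)
    else:
        for p1, p2 in zip(paths1, paths2):
            it1, it2 = _iter_fastq(p1), _iter_fastq(p2)
            for r1, r2 in zip(it1, it2):
                total += 2
                _consume([_match_keys(r1, library.index, library.lengths),
                          _match_keys(r2, library.index, library.lengths)])
            if next(it1, None) is not None or next(it2, None) is not None:
                raise ValidationError(f"paired files {p1}/{p2} differ in read count")

    if total == 0:
        log.warning("%s: no reads in input; emitting empty count table", sample_id)
    table = AlleleCountTable(sample_id=sample_id, condition=condition, counts=counts,
                             roles=library.roles, total_reads=total,
                             assigned_reads=assigned, ambiguous_reads=ambiguous)
    depths = sorted(counts.values())
    stats = MappingStats(
        on_target_fraction=assigned / total if total else 0.0,
        median_depth=float(statistics.median(depths)) if depths else 0.0,
        min_depth=depths[0] if depths else 0,
        max_depth=depths[-1] if depths else 0,
    )
    return table, stats


def replicate_concordance(table_a: AlleleCountTable, table_b: AlleleCountTable,
                          pseudocount: float = 1.0) -> float:
    """Pearson R² of log2(count + pseudocount) between two replicates."""
    keys_a, keys_b = set(table_a.counts), set(table_b.counts)
    shared = sorted(keys_a & keys_b)
    if not shared:
        raise ValidationError("replicate tables share no (snp_id, allele) entries")
    x = np.log2(np.array([table_a.counts[k] for k in shared], dtype=float) + pseudocount)
    y = np.log2(np.array([table_b.counts[k] for k in shared], dtype=float) + pseudocount)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("replicate concordance undefined: zero variance in counts")
    r = _scipy_stats.pearsonr(x, y).statistic
    return float(r * r)


@dataclass(frozen=True)
class CompositionBiasReport:
    """Associations between template composition and observed read counts."""

    r_squared: dict  # factor -> R² of log2(count+1) vs factor
    end_group_quartiles: "object"  # DataFrame: end, class, n, q25, q50, q75
    per_template: "object"  # DataFrame with counts and annotations


def composition_bias_report(table: AlleleCountTable,
                            library: TemplateLibrary,
                            pseudocount: float = 1.0) -> CompositionBiasReport:
    """Quantify how GC%, Tm, ΔG and end-nucleotide classes drive read counts.

    R² values are squared Pearson correlations of log2(count + pseudocount)
    against each continuous factor; end classes get grouped count quartiles.
    """
    import pandas as pd

    if len(library.templates) < 3:
        raise ValidationError("composition bias report needs at least 3 templates")
    rows = [{
        "snp_id": t.snp_id, "allele": t.allele,
        "log2_count": float(np.log2(table.counts[(t.snp_id, t.allele)] + pseudocount)),
        "gc_fraction": t.gc_fraction, "tm_celsius": t.tm_celsius,
        "delta_g_kcal": t.delta_g_kcal,
        "end5_mono": t.end5_mono, "end3_mono": t.end3_mono,
        "end5_di": t.end5_di, "end3_di": t.end3_di,
    } for t in library.templates]
    df = pd.DataFrame(rows)

    r2 = {}
    for factor in ("gc_fraction", "tm_celsius", "delta_g_kcal"):
        x, y = df[factor].to_numpy(), df["log2_count"].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r2[factor] = float("nan")
        else:
            r2[factor] = float(_scipy_stats.pearsonr(x, y).statistic ** 2)

    groups = []
    for end in ("end5_mono", "end3_mono", "end5_di", "end3_di"):
        g = df.groupby(end)["log2_count"].quantile([0.25, 0.5, 0.75]).unstack()
        g.columns = ["q25", "q50", "q75"]
        g["n"] = df.groupby(end)["log2_count"].size()
        g = g.reset_index().rename(columns={end: "klass"})
        g.insert(0, "end", end)
        groups.append(g)
    quartiles = pd.concat(groups, ignore_index=True)
    return CompositionBiasReport(r_squared=r2, end_group_quartiles=quartiles,
                                 per_template=df)
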