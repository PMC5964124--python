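"""Synthetic SNPs-seq and STARR-seq read simulators with known ground truth.

The simulators emulate the two library types of the screening workflow:

* **SNPs-seq** — 50-bp single-end reads over a pool of 21-nt allele-specific
  ds-oligos.  Input-control samples draw templates near-uniformly (optionally
  with a GC-dependent yield bias); protein-bound test samples reweight each
  variant allele by its true binding ratio *r* (variant/reference retention
  odds).  A configurable fraction of reads is background "naked DNA"
  (uniform random sequence), reproducing the observed on-target regimes of
  roughly 57–94%.  Per-base substitution errors push reads off-target under
  the perfect-match counting rule.
* **STARR-seq** — 100-bp paired-end reads from 100–150-bp fragments sheared
  uniformly from ~600-bp amplicons.  Plasmid-input samples follow the
  declared haplotype frequencies; mRNA samples reweight haplotypes by their
  enhancer activity, so the expected haplotype BAE equals
  log2(activity_variant / activity_reference).

All randomness flows from a single integer seed through numpy's PCG64
generator (:data:`PRNG_ID`); the same seed gives byte-identical FASTQ files.
Ground-truth tables are written next to the reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bae import AmpliconRecord, Haplotype, SnpOffset
from .errors import ValidationError
from .panel import (FLANK_LENGTH, TEMPLATE_LENGTH, SnpPanelEntry,
                    build_allele_templates, count_unique_sequences)
from .sequtil import reverse_complement

#: PRNG algorithm identity, recorded so summary statistics are reproducible
#: across reimplementations even where byte-identity is not promised.
PRNG_ID = "numpy-pcg64"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _apply_errors(codes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """In-place uniform substitution errors on a (n_reads, read_len) code array."""
    if rate <= 0:
        return
    mask = rng.random(codes.shape) < rate
    n = int(mask.sum())
    if n:
        codes[mask] = (codes[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4


def _write_fastq(path: Path, codes: np.ndarray, prefix: str) -> None:
    qual = "I" * codes.shape[1]
    ascii_rows = _BASES[codes]
    with open(path, "w") as out:
        for i in range(codes.shape[0]):
            out.write(f"@{prefix}:{i}\n{ascii_rows[i].tobytes().decode()}\n+\n{qual}\n")


def _check_prob(value: float, name: str, upper_inclusive: bool = False) -> None:
    hi_ok = value <= 1 if upper_inclusive else value < 1
    if not (0 <= value and hi_ok):
        raise ValidationError(f"{name} must be in [0, 1{']' if upper_inclusive else ')'}")


# --------------------------------------------------------------------------
# panel / amplicon generators

def make_panel(seed: int, n_biallelic: int = 369, n_triallelic: int = 3,
               n_quadallelic: int = 2, chrom: str = "chrS") -> list[SnpPanelEntry]:
    """Random SNP panel with the study's allele-multiplicity composition.

    Defaults give 369 SNPs with one variant, 3 with two and 2 with three —
    i.e. 755 unique 21-nt templates.  Flanks are uniform random sequence;
    cross-SNP template collisions are vanishingly unlikely at this scale and
    are asserted against.
    """
    rng = np.random.default_rng(seed)
    entries = []
    spec = [(1, n_biallelic), (2, n_triallelic), (3, n_quadallelic)]
    idx = 0
    for n_variants, n_snps in spec:
        for _ in range(n_snps):
            idx += 1
            alleles = rng.permutation(4)[:n_variants + 1]
            left = "".join("ACGT"[b] for b in rng.integers(0, 4, FLANK_LENGTH))
            right = "".join("ACGT"[b] for b in rng.integers(0, 4, FLANK_LENGTH))
            entries.append(SnpPanelEntry(
                snp_id=f"rs{900000 + idx}", chrom=chrom, pos=1000 * idx,
                ref_allele="ACGT"[alleles[0]],
                variant_alleles=tuple("ACGT"[a] for a in alleles[1:]),
                left_flank=left, right_flank=right))
    report = count_unique_sequences(entries)
    if report.collision:  # pragma: no cover - probability ~ n²/4^21
        raise ValidationError("random panel produced a template collision; retry "
                              "with a different seed")
    return entries


def make_haplotype_locus(seed: int, n_amplicons: int = 3, amplicon_length: int = 600,
                         cluster_span: int = 68, n_snps: int = 3,
                         stagger: int = 60) -> list[AmpliconRecord]:
    """Overlapping amplicons sharing one cluster of nearby SNPs.

    Emulates a haplotype region: ``n_snps`` SNPs spread over ``cluster_span``
    bases of a common locus, covered by ``n_amplicons`` staggered windows of
    ``amplicon_length``.  Every amplicon spans the full cluster, so reads can
    phase complete haplotypes.
    """
    if n_snps < 2:
        raise ValidationError("a haplotype locus needs at least 2 SNPs")
    rng = np.random.default_rng(seed)
    locus_len = amplicon_length + (n_amplicons - 1) * stagger
    locus = "".join("ACGT"[b] for b in rng.integers(0, 4, locus_len))
    # cluster centered in the region shared by all amplicon windows
    shared_start = (n_amplicons - 1) * stagger
    center = (shared_start + amplicon_length) // 2
    positions = sorted(int(p) for p in np.linspace(center - cluster_span // 2,
                                                   center + cluster_span // 2, n_snps))
    snp_defs = []
    for j, pos in enumerate(positions):
        ref = locus[pos]
        alt = "ACGT"[(_CODE[ord(ref)] + 1 + rng.integers(0, 3)) % 4]
        if alt == ref:
            alt = "ACGT"[(_CODE[ord(ref)] + 1) % 4]
        snp_defs.append((f"rsH{j + 1}", pos, ref, (alt,)))
    amplicons = []
    for k in range(n_amplicons):
        start = k * stagger
        snps = tuple(SnpOffset(snp_id=sid, offset=pos - start + 1, ref_allele=ref,
                               variant_alleles=alts)
                     for sid, pos, ref, alts in snp_defs)
        amplicons.append(AmpliconRecord(
            amplicon_id=f"amp{k + 1}",
            sequence=locus[start:start + amplicon_length], snps=snps))
    return amplicons


# --------------------------------------------------------------------------
# SNPs-seq

@dataclass
class SnpsSeqConfig:
    """Conditions of a simulated SNPs-seq experiment.

    ``binding_ratio`` is the true variant/reference retention odds, given
    either per SNP (dict) or as one scalar for the whole panel; 1.0 is the
    null.  Background fractions default to the observed regimes: ~40% naked
    DNA in protein-bound test samples (~60% on-target) and ~5% in input
    controls (~95% on-target).
    """

    seed: int
    panel: Sequence[SnpPanelEntry]
    binding_ratio: Mapping[str, float] | float = 1.0
    depth: int = 100_000
    read_length: int = 50
    test_background_fraction: float = 0.40
    input_background_fraction: float = 0.05
    error_rate: float = 0.001
    replicates: int = 2
    gc_bias: float = 0.0
    condition: str = "DHT"

    def __post_init__(self):
        if not self.panel:
            raise ValidationError("panel must be non-empty")
        _check_prob(self.test_background_fraction, "test_background_fraction")
        _check_prob(self.input_background_fraction, "input_background_fraction")
        _check_prob(self.error_rate, "error_rate", upper_inclusive=False)
        if self.depth <= 0 or self.replicates <= 0:
            raise ValidationError("depth and replicates must be positive")
        if self.read_length < TEMPLATE_LENGTH:
            raise ValidationError("read_length must fit a full template")

    def ratio_for(self, snp_id: str) -> float:
        if isinstance(self.binding_ratio, Mapping):
            return float(self.binding_ratio.get(snp_id, 1.0))
        return float(self.binding_ratio)


@dataclass
class SimResult:
    fastq: dict           # sample name -> path(s)
    truth: pd.DataFrame
    truth_path: Path
    prng: str = PRNG_ID


def simulate_snpsseq(config: SnpsSeqConfig, outdir) -> SimResult:
    """Write test/input replicate FASTQs plus a ground-truth table.

    Samples: ``test_rep1..n`` (allele-reweighted, high background) and
    ``input_rep1..n`` (near-uniform, low background).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    templates = [t for e in config.panel for t in build_allele_templates(e)]
    tcodes = np.stack([_encode(t.sequence) for t in templates])
    gc = np.array([t.gc_fraction for t in templates])
    yield_w = np.exp(config.gc_bias * gc)
    ratio = np.array([config.ratio_for(t.snp_id) if t.role == "variant" else 1.0
                      for t in templates])
    weights = {"input": yield_w / yield_w.sum(),
               "test": yield_w * ratio / (yield_w * ratio).sum()}
    background = {"input": config.input_background_fraction,
                  "test": config.test_background_fraction}

    fastq = {}
    samples = [(f"{kind}_rep{r + 1}", kind)
               for kind in ("test", "input") for r in range(config.replicates)]
    for s_idx, (name, kind) in enumerate(samples):
        rng = np.random.default_rng([config.seed, s_idx])
        n_bg = rng.binomial(config.depth, background[kind])
        n_on = config.depth - n_bg
        codes = rng.integers(0, 4, (config.depth, config.read_length), dtype=np.uint8)
        chosen = rng.choice(len(templates), size=n_on, p=weights[kind])
        offsets = rng.integers(0, config.read_length - TEMPLATE_LENGTH + 1, n_on)
        for i in range(n_on):
            codes[i, offsets[i]:offsets[i] + TEMPLATE_LENGTH] = tcodes[chosen[i]]
        codes = codes[rng.permutation(config.depth)]
        _apply_errors(codes, config.error_rate, rng)
        path = outdir / f"{name}.fastq"
        _write_fastq(path, codes, prefix=name)
        fastq[name] = path

    rows = []
    for j, t in enumerate(templates):
        r = config.ratio_for(t.snp_id)
        rows.append({
            "snp_id": t.snp_id, "allele": t.allele, "role": t.role,
            "binding_ratio": r if t.role == "variant" else 1.0,
            "input_weight": weights["input"][j], "test_weight": weights["test"][j],
            "expected_bab": math.log2(r) if t.role == "variant" else 0.0,
        })
    truth = pd.DataFrame(rows)
    truth_path = outdir / "truth_snpsseq.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimResult(fastq=fastq, truth=truth, truth_path=truth_path)


# --------------------------------------------------------------------------
# STARR-seq

@dataclass
class StarrSeqConfig:
    """Conditions of a simulated targeted-amplicon STARR-seq experiment.

    ``haplotype_frequencies`` gives the plasmid-pool composition per
    amplicon; ``activities`` maps each condition to per-amplicon haplotype
    enhancer activities (mRNA abundance multipliers, 1.0 = inert).  Depth is
    fragments (read pairs) per sample.
    """

    seed: int
    amplicons: Sequence[AmpliconRecord]
    haplotype_frequencies: Mapping[str, Mapping[Haplotype, float]]
    activities: Mapping[str, Mapping[str, Mapping[Haplotype, float]]] = field(
        default_factory=lambda: {"DHT": {}})
    depth: int = 50_000
    read_length: int = 100
    fragment_length: tuple[int, int] = (100, 150)
    background_fraction: float = 0.2
    error_rate: float = 0.001
    replicates: int = 2

    def __post_init__(self):
        if not self.amplicons:
            raise ValidationError("amplicons must be non-empty")
        _check_prob(self.background_fraction, "background_fraction")
        _check_prob(self.error_rate, "error_rate")
        lo, hi = self.fragment_length
        if not 1 <= lo <= hi:
            raise ValidationError("fragment_length must be a (lo, hi) range with lo ≥ 1")
        if self.read_length > lo:
            raise ValidationError("read_length must not exceed the minimum fragment length")
        for amp in self.amplicons:
            if hi > len(amp.sequence):
                raise ValidationError(
                    f"{amp.amplicon_id}: fragment length {hi} exceeds amplicon length")
            freqs = self.haplotype_frequencies.get(amp.amplicon_id)
            if not freqs:
                raise ValidationError(f"{amp.amplicon_id}: no haplotype frequencies")
            space = set(amp.haplotype_space())
            if any(tuple(h) not in space for h in freqs):
                raise ValidationError(
                    f"{amp.amplicon_id}: haplotype frequency for unknown haplotype")
            if abs(sum(freqs.values()) - 1.0) > 1e-8:
                raise ValidationError(
                    f"{amp.amplicon_id}: haplotype frequencies must sum to 1")

    def activity_for(self, condition: str, amplicon_id: str, hap: Haplotype) -> float:
        return float(self.activities.get(condition, {}).get(amplicon_id, {})
                     .get(tuple(hap), 1.0))


def simulate_starrseq(config: StarrSeqConfig, outdir) -> SimResult:
    """Write paired mRNA/plasmid FASTQs plus ground-truth tables.

    Samples: ``plasmid_rep1..n`` and ``{condition}_rep1..n`` for each
    condition in ``config.activities``; each sample is an (R1, R2) pair.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # flatten (amplicon, haplotype) units with plasmid weights
    units = []
    plasmid_w = []
    for amp in config.amplicons:
        freqs = config.haplotype_frequencies[amp.amplicon_id]
        for hap, freq in sorted(freqs.items()):
            units.append((amp, tuple(hap), amp.substituted_sequence(tuple(hap))))
            plasmid_w.append(freq)
    plasmid_w = np.array(plasmid_w) / np.sum(plasmid_w)

    def sample_weights(condition: str | None) -> np.ndarray:
        if condition is None:
            return plasmid_w
        w = plasmid_w * np.array([config.activity_for(condition, amp.amplicon_id, hap)
                                  for amp, hap, _ in units])
        return w / w.sum()

    lo, hi = config.fragment_length
    samples = [("plasmid", None, r) for r in range(config.replicates)]
    for condition in config.activities:
        samples += [(condition, condition, r) for r in range(config.replicates)]

    fastq = {}
    for s_idx, (label, condition, rep) in enumerate(samples):
        name = f"{label}_rep{rep + 1}"
        rng = np.random.default_rng([config.seed, 7, s_idx])
        n_bg = rng.binomial(config.depth, config.background_fraction)
        n_real = config.depth - n_bg
        w = sample_weights(condition)
        chosen = rng.choice(len(units), size=n_real, p=w)
        flens = rng.integers(lo, hi + 1, n_real)
        r1 = np.empty((config.depth, config.read_length), dtype=np.uint8)
        r2 = np.empty_like(r1)
        for i in range(n_real):
            _, _, seq = units[chosen[i]]
            start = rng.integers(0, len(seq) - flens[i] + 1)
            frag = seq[start:start + flens[i]]
            r1[i] = _encode(frag[:config.read_length])
            r2[i] = _encode(reverse_complement(frag)[:config.read_length])
        if n_bg:
            r1[n_real:] = rng.integers(0, 4, (n_bg, config.read_length), dtype=np.uint8)
            r2[n_real:] = rng.integers(0, 4, (n_bg, config.read_length), dtype=np.uint8)
        order = rng.permutation(config.depth)
        r1, r2 = r1[order], r2[order]
        _apply_errors(r1, config.error_rate, rng)
        _apply_errors(r2, config.error_rate, rng)
        p1, p2 = outdir / f"{name}_R1.fastq", outdir / f"{name}_R2.fastq"
        _write_fastq(p1, r1, prefix=f"{name}/1")
        _write_fastq(p2, r2, prefix=f"{name}/2")
        fastq[name] = (p1, p2)

    rows = []
    for amp, hap, _ in units:
        ref_hap = tuple(s.ref_allele for s in amp.snps)
        row = {"amplicon_id": amp.amplicon_id, "haplotype": "-".join(hap),
               "frequency": config.haplotype_frequencies[amp.amplicon_id][hap]}
        for condition in config.activities:
            act = config.activity_for(condition, amp.amplicon_id, hap)
            ref_act = config.activity_for(condition, amp.amplicon_id, ref_hap)
            row[f"activity_{condition}"] = act
            row[f"expected_bae_{condition}"] = (math.log2(act / ref_act)
                                                if ref_act > 0 else math.nan)
        rows.append(row)
    truth = pd.DataFrame(rows)
    truth_path = outdir / "truth_starrseq.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimResult(fastq=fastq, truth=truth, truth_path=truth_path)
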