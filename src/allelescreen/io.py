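"""Readers and writers for the package's tabular and sequence formats.

Canonical tabular dialect: tab-separated, header row, UTF-8, '.' decimal.
All writers sort deterministically (snp_id, allele) so file diffs are
meaningful.  Gzip is detected by magic bytes, never by file extension.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__ as _version
from .bab import ImbalanceResult
from .bae import AmpliconRecord, HaplotypeCountTable, SnpOffset
from .counting import AlleleCountTable
from .errors import ParseError, ValidationError
from .panel import AlleleTemplate, SnpPanelEntry, build_allele_templates

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "left_flank", "right_flank"]
COUNT_COLUMNS = ["sample_id", "condition", "snp_id", "allele", "role", "count"]
RESULT_COLUMNS = ["snp_id", "variant_allele", "reference_allele", "condition",
                  "test_var", "test_ref", "input_var", "input_ref",
                  "score", "fold_change", "pseudocounted", "significant", "eqtl_p"]


def open_maybe_gzip(path, mode: str = "rt"):
    """Open a possibly-gzipped text file, sniffing the gzip magic bytes."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


# --------------------------------------------------------------------------
# panel

def read_panel(path) -> list[SnpPanelEntry]:
    """Parse a panel TSV (snp_id, chrom, pos, ref, alt, left_flank, right_flank).

    ``alt`` may hold several comma-separated variant alleles.  Validation
    failures name the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing panel columns {sorted(missing)}")
    entries = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            entries.append(SnpPanelEntry(
                snp_id=row.snp_id, chrom=row.chrom, pos=int(row.pos),
                ref_allele=row.ref,
                variant_alleles=tuple(row.alt.split(",")),
                left_flank=row.left_flank, right_flank=row.right_flank))
        except (ValidationError, ValueError, AttributeError) as exc:
            raise ParseError(f"{path}: line {row_no}: {exc}") from exc
    return entries


def write_panel(panel: Sequence[SnpPanelEntry], path) -> None:
    rows = [{"snp_id": e.snp_id, "chrom": e.chrom, "pos": e.pos, "ref": e.ref_allele,
             "alt": ",".join(e.variant_alleles), "left_flank": e.left_flank,
             "right_flank": e.right_flank} for e in panel]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).sort_values("snp_id").to_csv(
        path, sep="\t", index=False)


# --------------------------------------------------------------------------
# templates

def write_templates_fasta(templates: Sequence[AlleleTemplate], path) -> None:
    """FASTA with record ids ``snp_id|allele|role``."""
    records = [SeqRecord(Seq(t.sequence), id=f"{t.snp_id}|{t.allele}|{t.role}",
                         description="")
               for t in sorted(templates, key=lambda t: (t.snp_id, t.allele))]
    SeqIO.write(records, path, "fasta")


def read_templates_fasta(path) -> list[AlleleTemplate]:
    """Rebuild annotated templates from a ``snp_id|allele|role`` FASTA."""
    from . import panel as _panel
    from . import thermo

    templates = []
    for n, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        parts = record.id.split("|")
        if len(parts) != 3:
            raise ParseError(f"{path}: record {n}: id {record.id!r} is not "
                             "snp_id|allele|role")
        snp_id, allele, role = parts
        seq = str(record.seq).upper()
        ends = _panel.end_nucleotide_classes(seq)
        templates.append(AlleleTemplate(
            snp_id=snp_id, allele=allele, role=role, sequence=seq,
            gc_fraction=_panel.gc_fraction(seq),
            tm_celsius=thermo.melting_temperature(seq),
            delta_g_kcal=thermo.duplex_delta_g(seq), **ends._asdict()))
    return templates


def write_template_qc(templates: Sequence[AlleleTemplate], path,
                      gc_cutoff: float = 0.25) -> None:
    from .panel import flag_low_yield

    rows = [{
        "snp_id": t.snp_id, "allele": t.allele, "role": t.role, "sequence": t.sequence,
        "gc_fraction": t.gc_fraction, "tm_celsius": t.tm_celsius,
        "delta_g_kcal": t.delta_g_kcal, "end5_mono": t.end5_mono,
        "end3_mono": t.end3_mono, "end5_di": t.end5_di, "end3_di": t.end3_di,
        "flags": ";".join(flag_low_yield(t, gc_cutoff=gc_cutoff)),
    } for t in sorted(templates, key=lambda t: (t.snp_id, t.allele))]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# counts

def write_counts(table: AlleleCountTable, path) -> None:
    """Counts TSV with the assignment totals carried in '#key=value' headers."""
    with open(path, "w") as out:
        out.write(f"#total_reads={table.total_reads}\n")
        out.write(f"#assigned_reads={table.assigned_reads}\n")
        out.write(f"#ambiguous_reads={table.ambiguous_reads}\n")
        out.write("\t".join(COUNT_COLUMNS) + "\n")
        for (snp, allele) in sorted(table.counts):
            role = table.roles.get((snp, allele), "")
            out.write(f"{table.sample_id}\t{table.condition}\t{snp}\t{allele}\t"
                      f"{role}\t{table.counts[(snp, allele)]}\n")


def read_counts(path) -> AlleleCountTable:
    meta = {}
    with open_maybe_gzip(path) as handle:
        lines = handle.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, value = line[1:].strip().partition("=")
        meta[key] = int(value)
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t", dtype=str)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing count columns {sorted(missing)}")
    counts, roles = {}, {}
    sample_id = condition = None
    for row_no, row in enumerate(df.to_dict("records"), start=body_start + 2):
        try:
            count = int(row["count"])
        except ValueError as exc:
            raise ParseError(f"{path}: line {row_no}: count {row['count']!r} "
                             "is not an integer") from exc
        if count < 0:
            raise ParseError(f"{path}: line {row_no}: negative count {count}")
        counts[(row["snp_id"], row["allele"])] = count
        roles[(row["snp_id"], row["allele"])] = (row["role"]
                                                 if isinstance(row["role"], str) else "")
        sample_id, condition = row["sample_id"], row["condition"]
    try:
        return AlleleCountTable(
            sample_id=sample_id or "", condition=condition or "",
            counts=counts, roles=roles,
            total_reads=meta.get("total_reads", sum(counts.values())),
            assigned_reads=meta.get("assigned_reads", sum(counts.values())),
            ambiguous_reads=meta.get("ambiguous_reads", 0))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# results

def write_results(results: Iterable[ImbalanceResult], path) -> None:
    """Machine-readable results TSV (full precision; summaries round to 2 dp)."""
    rows = []
    for r in sorted(results, key=lambda r: (r.snp_id, r.variant_allele, r.condition)):
        rows.append({
            "snp_id": r.snp_id, "variant_allele": r.variant_allele,
            "reference_allele": r.reference_allele, "condition": r.condition,
            "test_var": r.test_var, "test_ref": r.test_ref,
            "input_var": r.input_var, "input_ref": r.input_ref,
            "score": r.score,
            "fold_change": r.fold_change if not math.isnan(r.score) else math.nan,
            "pseudocounted": r.pseudocounted, "significant": r.significant,
            "eqtl_p": r.eqtl_p,
        })
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# amplicons / haplotypes

def read_amplicons(path) -> list[AmpliconRecord]:
    """Amplicon TSV: amplicon_id, sequence, snps as ``snp:offset:ref:alts;...``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"amplicon_id", "sequence", "snps"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing amplicon columns {sorted(missing)}")
    amplicons = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        snps = []
        try:
            for token in row.snps.split(";"):
                snp_id, offset, ref, alts = token.split(":")
                snps.append(SnpOffset(snp_id=snp_id, offset=int(offset),
                                      ref_allele=ref,
                                      variant_alleles=tuple(alts.split(","))))
            amplicons.append(AmpliconRecord(amplicon_id=row.amplicon_id,
                                            sequence=row.sequence, snps=tuple(snps)))
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path}: line {row_no}: {exc}") from exc
    return amplicons


def write_amplicons(amplicons: Sequence[AmpliconRecord], path) -> None:
    rows = [{"amplicon_id": a.amplicon_id, "sequence": a.sequence,
             "snps": ";".join(f"{s.snp_id}:{s.offset}:{s.ref_allele}:"
                              f"{','.join(s.variant_alleles)}" for s in a.snps)}
            for a in sorted(amplicons, key=lambda a: a.amplicon_id)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_haplotype_tables(test: Mapping[str, HaplotypeCountTable],
                           input_: Mapping[str, HaplotypeCountTable],
                           scores: Mapping[str, float], path) -> None:
    rows = []
    for amp in sorted(set(test) & set(input_)):
        for hap in sorted(test[amp].counts):
            rows.append({"amplicon_id": amp, "haplotype": "-".join(hap),
                         "test_count": test[amp].counts[hap],
                         "input_count": input_[amp].counts.get(hap, 0),
                         "score": scores.get(amp, math.nan)})
    pd.DataFrame(rows, columns=["amplicon_id", "haplotype", "test_count",
                                "input_count", "score"]).to_csv(path, sep="\t",
                                                                index=False)


# --------------------------------------------------------------------------
# run manifest

@dataclass(frozen=True)
class RunManifest:
    """Provenance of one CLI run: version, parameters, input checksums."""

    tool: str
    version: str
    command: str
    parameters: dict
    inputs: dict  # path -> sha256
    timestamp: str


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(path, command: str, parameters: Mapping,
                   inputs: Sequence) -> RunManifest:
    manifest = RunManifest(
        tool="allelescreen", version=_version, command=command,
        parameters=dict(parameters),
        inputs={str(p): _sha256(p) for p in inputs if p is not None},
        timestamp=datetime.now(timezone.utc).isoformat())
    with open(path, "w") as out:
        json.dump(manifest.__dict__, out, indent=2, sort_keys=True)
        out.write("\n")
    return manifest
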