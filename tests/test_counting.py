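"""Perfect-match read counting: indexing, assignment, QC statistics."""

import gzip

import numpy as np
import pytest

from allelescreen import (AlleleCountTable, CollisionError, ParseError,
                          ValidationError, build_allele_templates, build_index,
                          composition_bias_report, count_reads,
                          replicate_concordance)
from allelescreen.counting import _match_keys
from allelescreen.panel import AlleleTemplate, end_nucleotide_classes
from allelescreen.sequtil import reverse_complement


def _template(snp_id, sequence, allele=None, role="reference"):
    ends = end_nucleotide_classes(sequence)
    return AlleleTemplate(snp_id=snp_id, allele=allele or sequence[10], role=role,
                          sequence=sequence, gc_fraction=0.5, tm_celsius=50.0,
                          delta_g_kcal=-25.0, **ends._asdict())


def _write_fastq(path, reads):
    with open(path, "w") as out:
        for i, read in enumerate(reads):
            out.write(f"@r{i}\n{read}\n+\n{'I' * len(read)}\n")


def _embed(rng, template, read_len=50):
    offset = rng.integers(0, read_len - len(template) + 1)
    flank = "".join("ACGT"[b] for b in rng.integers(0, 4, read_len))
    return flank[:offset] + template + flank[offset + len(template):]


class TestBuildIndex:
    def test_both_strands_indexed(self, small_library):
        n = len(small_library.templates)
        assert len(small_library.index) == 2 * n  # odd length: no palindromes
        t = small_library.templates[0]
        key = (t.snp_id, t.allele)
        assert small_library.index[t.sequence] == key
        assert small_library.index[reverse_complement(t.sequence)] == key

    def test_alleles_of_one_snp_coexist(self):
        a = _template("rs1", "ACGTACGTACATTGCATGCAA")
        b = _template("rs1", "ACGTACGTACGTTGCATGCAA", role="variant")
        assert len(build_index([a, b]).index) == 4

    def test_reverse_complement_collision_detected(self):
        a = _template("rs1", "ACGTACGTACATTGCATGCAA")
        b = _template("rs2", reverse_complement(a.sequence))
        with pytest.raises(CollisionError) as err:
            build_index([a, b])
        assert "rs1" in str(err.value) and "rs2" in str(err.value)


class TestCountReads:
    def test_pure_embedded_library(self, small_library, tmp_path):
        rng = np.random.default_rng(0)
        expected = {}
        reads = []
        for j, t in enumerate(small_library.templates):
            n = 50 + 10 * j
            expected[(t.snp_id, t.allele)] = n
            reads += [_embed(rng, t.sequence) for _ in range(n)]
        path = tmp_path / "pure.fastq"
        _write_fastq(path, reads)
        table, stats = count_reads(path, small_library)
        assert stats.on_target_fraction == 1.0
        assert table.counts == expected
        assert table.assigned_reads == sum(expected.values()) == table.total_reads

    def test_single_mismatch_is_off_target(self, small_library, tmp_path):
        t = small_library.templates[0]
        mutated = list(t.sequence)
        mutated[5] = {"A": "C"}.get(mutated[5], "A")
        path = tmp_path / "mm.fastq"
        _write_fastq(path, ["".join(mutated) + "ACGTACGTACGTACGTACGTACGTACGTA"])
        table, stats = count_reads(path, small_library)
        assert table.assigned_reads == 0 and table.off_target_reads == 1

    def test_multi_snp_read_policies(self, small_library, tmp_path):
        t1, t2 = small_library.templates[0], small_library.templates[2]
        assert t1.snp_id != t2.snp_id
        read = t1.sequence + "ACGTACG" + t2.sequence  # 49 bp, two SNPs
        path = tmp_path / "multi.fastq"
        _write_fastq(path, [read])
        table, _ = count_reads(path, small_library)
        assert table.ambiguous_reads == 1 and table.assigned_reads == 0
        table2, _ = count_reads(path, small_library, multi_snp="count_each")
        assert table2.assigned_reads == 1
        assert table2.counts[(t1.snp_id, t1.allele)] == 1
        assert table2.counts[(t2.snp_id, t2.allele)] == 1

    def test_conservation_and_strand_symmetry(self, small_library, tmp_path):
        rng = np.random.default_rng(1)
        reads = [_embed(rng, t.sequence) for t in small_library.templates
                 for _ in range(20)]
        reads += ["".join("ACGT"[b] for b in rng.integers(0, 4, 50))
                  for _ in range(60)]
        fwd, rev = tmp_path / "f.fastq", tmp_path / "r.fastq"
        _write_fastq(fwd, reads)
        _write_fastq(rev, [reverse_complement(r) for r in reads])
        tf, sf = count_reads(fwd, small_library)
        tr, _ = count_reads(rev, small_library)
        assert tf.assigned_reads + tf.ambiguous_reads + tf.off_target_reads \
            == tf.total_reads
        assert tf.counts == tr.counts

    def test_read_order_irrelevant(self, small_library, tmp_path):
        rng = np.random.default_rng(2)
        reads = [_embed(rng, t.sequence) for t in small_library.templates]
        a, b = tmp_path / "a.fastq", tmp_path / "b.fastq"
        _write_fastq(a, reads)
        _write_fastq(b, reads[::-1])
        assert count_reads(a, small_library)[0].counts \
            == count_reads(b, small_library)[0].counts

    def test_matches_brute_force_scan(self, small_library, tmp_path):
        """Oracle: naive substring scan over every template on both strands."""
        rng = np.random.default_rng(3)
        reads = []
        for _ in range(1500):
            kind = rng.random()
            if kind < 0.6:
                t = small_library.templates[rng.integers(len(small_library.templates))]
                seq = t.sequence if rng.random() < 0.5 \
                    else reverse_complement(t.sequence)
                reads.append(_embed(rng, seq))
            else:
                reads.append("".join("ACGT"[b] for b in rng.integers(0, 4, 50)))
        path = tmp_path / "mix.fastq"
        _write_fastq(path, reads)
        table, _ = count_reads(path, small_library)

        brute = {key: 0 for key in small_library.keys}
        n_assigned = n_ambig = 0
        for read in reads:
            hits = set()
            for t in small_library.templates:
                if t.sequence in read or reverse_complement(t.sequence) in read:
                    hits.add((t.snp_id, t.allele))
            snps = {s for s, _ in hits}
            if len(snps) == 1 and len(hits) == 1:
                brute[hits.pop()] += 1
                n_assigned += 1
            elif hits:
                n_ambig += 1
        assert table.counts == brute
        assert table.assigned_reads == n_assigned
        assert table.ambiguous_reads == n_ambig

    def test_gzip_detected_by_magic(self, small_library, tmp_path):
        t = small_library.templates[0]
        path = tmp_path / "reads.weirdext"
        with gzip.open(path, "wt") as out:
            out.write(f"@r0\n{t.sequence}AAACCCGGGTTTAAACCCGGGTTTAAACC\n+\n{'I'*50}\n")
        table, _ = count_reads(path, small_library)
        assert table.counts[(t.snp_id, t.allele)] == 1

    def test_paired_conflicting_alleles_excluded(self, small_panel, tmp_path):
        templates = build_allele_templates(small_panel[0])
        lib = build_index(templates)
        ref, var = templates
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        # pair 1 supports both alleles of one SNP (conflict); pair 2 is clean
        _write_fastq(r1, [ref.sequence + "A" * 29, ref.sequence + "A" * 29])
        _write_fastq(r2, [var.sequence + "A" * 29, ref.sequence + "A" * 29])
        table, _ = count_reads(r1, lib, fastq2=r2)
        assert table.total_reads == 4
        assert table.ambiguous_reads == 2
        assert table.counts[(ref.snp_id, ref.allele)] == 2
        assert table.counts[(var.snp_id, var.allele)] == 0

    def test_malformed_fastq(self, small_library, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\nplus-line-missing\n")
        with pytest.raises(ParseError, match="record"):
            count_reads(path, small_library)

    def test_empty_input_yields_empty_table(self, small_library, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        table, stats = count_reads(path, small_library)
        assert table.total_reads == 0 and stats.on_target_fraction == 0.0


def _table(counts, roles=None, **kw):
    total = sum(counts.values())
    defaults = dict(sample_id="s", condition="test", counts=counts,
                    roles=roles or {}, total_reads=total, assigned_reads=total,
                    ambiguous_reads=0)
    defaults.update(kw)
    return AlleleCountTable(**defaults)


class TestReplicateConcordance:
    def test_identical_tables_give_unity(self):
        counts = {("rs1", "A"): 10, ("rs1", "G"): 25, ("rs2", "C"): 4}
        assert replicate_concordance(_table(counts), _table(dict(counts))) \
            == pytest.approx(1.0)

    def test_multinomial_replicates_highly_concordant(self):
        """Replicates of one heterogeneous pool at depth 1e6 exceed R² 0.95."""
        rng = np.random.default_rng(42)
        weights = rng.lognormal(sigma=1.0, size=755)
        p = weights / weights.sum()
        keys = [(f"rs{i}", "A") for i in range(755)]
        a = dict(zip(keys, rng.multinomial(1_000_000, p)))
        b = dict(zip(keys, rng.multinomial(1_000_000, p)))
        assert replicate_concordance(_table(a), _table(b)) > 0.95

    def test_zero_variance_is_degenerate(self):
        counts = {("rs1", "A"): 0, ("rs1", "G"): 0}
        with pytest.raises(ValidationError, match="variance"):
            replicate_concordance(_table(counts), _table(dict(counts)))

    def test_disjoint_panels_rejected(self):
        with pytest.raises(ValidationError):
            replicate_concordance(_table({("rs1", "A"): 1}),
                                  _table({("rs2", "C"): 1}))


class TestCompositionBias:
    def test_deterministic_gc_dependence(self, small_library):
        counts = {(t.snp_id, t.allele): int(round(2 ** (10 * t.gc_fraction)))
                  for t in small_library.templates}
        table = _table(counts)
        report = composition_bias_report(table, small_library)
        assert report.r_squared["gc_fraction"] > 0.99

    def test_permuted_counts_uncorrelated(self, small_library):
        rng = np.random.default_rng(5)
        values = [int(round(2 ** (10 * t.gc_fraction)))
                  for t in small_library.templates]
        rng.shuffle(values)
        counts = dict(zip([(t.snp_id, t.allele) for t in small_library.templates],
                          values))
        report = composition_bias_report(_table(counts), small_library)
        assert report.r_squared["gc_fraction"] < 0.5

    def test_end_groups_cover_observed_classes(self, small_library):
        counts = {(t.snp_id, t.allele): 10 for t in small_library.templates}
        report = composition_bias_report(_table(counts), small_library)
        observed_di5 = {t.end5_di for t in small_library.templates}
        listed = set(report.end_group_quartiles.query("end == 'end5_di'")["klass"])
        assert listed == observed_di5

    def test_too_few_templates_rejected(self, small_library):
        tiny = build_index(small_library.templates[:2])
        with pytest.raises(ValidationError):
            composition_bias_report(_table({}), tiny)
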