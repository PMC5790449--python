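"""Phase-2 genome aligner (with brute-force oracle), size selection,
annotation assignment with homolog sharing, and the sncRNA matrix."""

import numpy as np
import pandas as pd
import pytest

from rnacensus.io import Annotation
from rnacensus.preprocess import RawRead, preprocess_reads
from rnacensus.simulate import (
    SimulationConfig,
    build_reference,
    parse_read_id,
    reverse_complement,
    simulate_cohort,
)
from rnacensus.sncrna import (
    AnnotationIndex,
    GenomeAligner,
    GenomicHit,
    align_to_genome,
    assign_to_annotations,
    build_sncrna_counts,
    expand_homologs,
    select_quantifiable_annotations,
)


def brute_force_genome(sequence, genome, max_mismatches):
    """Independent both-strand full-scan oracle."""
    found = []
    for strand, query in (("+", sequence), ("-", reverse_complement(sequence))):
        for contig, ref in genome.items():
            for start in range(len(ref) - len(query) + 1):
                window = ref[start : start + len(query)]
                mism = sum(1 for a, b in zip(query, window) if a != b)
                if mism <= max_mismatches:
                    found.append((contig, start, strand, mism))
    if not found:
        return []
    best = min(m for *_, m in found)
    return sorted(t for t in found if t[3] == best)


def _hit_tuples(hits):
    return sorted((h.contig, h.start, h.strand, h.n_mismatches) for h in hits)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(31)
    bases = np.array(list("ACGT"))
    return {
        "chrA": "".join(rng.choice(bases, size=1500)),
        "chrB": "".join(rng.choice(bases, size=900)),
    }


class TestGenomeAligner:
    def test_exact_forward_hit(self, genome):
        seq = genome["chrA"][100:140]
        hits = align_to_genome(("r", seq), genome)
        assert _hit_tuples(hits) == [("chrA", 100, "+", 0)]

    def test_reverse_complement_hit(self, genome):
        seq = reverse_complement(genome["chrB"][200:240])
        hits = align_to_genome(("r", seq), genome)
        assert _hit_tuples(hits) == [("chrB", 200, "-", 0)]

    def test_random_read_no_hit(self, genome):
        rng = np.random.default_rng(99)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
        expected = brute_force_genome(seq, genome, 2)
        assert _hit_tuples(align_to_genome(("r", seq), genome)) == expected

    def test_short_read_fallback_path(self, genome):
        seq = genome["chrA"][50:68]  # 18 nt: below the seeding threshold
        hits = align_to_genome(("r", seq), genome)
        assert ("chrA", 50, "+", 0) in _hit_tuples(hits)

    def test_oracle_equivalence_500_random_instances(self, genome):
        rng = np.random.default_rng(61)
        bases = np.array(list("ACGT"))
        aligner = GenomeAligner(genome, 2)
        for _ in range(500):
            contig = "chrA" if rng.random() < 0.6 else "chrB"
            ref = genome[contig]
            length = int(rng.integers(24, 61))
            if rng.random() < 0.7:
                start = int(rng.integers(0, len(ref) - length + 1))
                seq = list(ref[start : start + length])
                for _ in range(int(rng.integers(0, 4))):
                    seq[int(rng.integers(0, length))] = str(rng.choice(bases))
                seq = "".join(seq)
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
            else:
                seq = "".join(rng.choice(bases, size=length))
            assert _hit_tuples(aligner.align("r", seq)) == brute_force_genome(seq, genome, 2)


class TestSizeSelection:
    def _ann(self, id, cls, src, length):
        return Annotation(id, cls, src, "chr1", 0, length, "+")

    def test_gencode_boundary_70_kept(self):
        kept = select_quantifiable_annotations([self._ann("x", "snoRNA", "GENCODE", 70)])
        assert [a.id for a in kept] == ["x"]

    def test_gencode_75_dropped(self):
        assert select_quantifiable_annotations([self._ann("x", "misc_RNA", "GENCODE", 75)]) == []

    def test_dashr_trna_81_exempt(self):
        kept = select_quantifiable_annotations([self._ann("t", "tRNA", "DASHR", 81)])
        assert [a.id for a in kept] == ["t"]

    def test_dashr_non_pirna_trna_dropped(self):
        assert select_quantifiable_annotations([self._ann("x", "snoRNA", "DASHR", 60)]) == []


class TestAssignment:
    annotations = [
        Annotation("pi1", "piRNA", "DASHR", "chr1", 100, 131, "+"),
        Annotation("t1", "tRNA", "DASHR", "chr1", 300, 374, "+"),
        Annotation("pi2", "piRNA", "DASHR", "chr1", 500, 531, "-"),
    ]

    def test_fully_contained_read(self):
        hit = GenomicHit("r", "chr1", 100, 130, "+", 0)
        assert assign_to_annotations(hit, self.annotations) == ["pi1"]

    def test_half_overlap_unassigned_at_090(self):
        hit = GenomicHit("r", "chr1", 285, 315, "+", 0)  # 15/30 inside t1
        assert assign_to_annotations(hit, self.annotations) == []
        assert assign_to_annotations(hit, self.annotations, min_overlap_fraction=0.5) == ["t1"]

    def test_strand_discipline(self):
        hit = GenomicHit("r", "chr1", 505, 525, "+", 0)
        assert assign_to_annotations(hit, self.annotations) == []
        minus = GenomicHit("r", "chr1", 505, 525, "-", 0)
        assert assign_to_annotations(minus, self.annotations) == ["pi2"]

    def test_homolog_expansion(self):
        groups = {"g": ("L1", "L2")}
        locus_to_group = {"L1": "g", "L2": "g"}
        assert expand_homologs(["L1"], locus_to_group, groups) == ["L1", "L2"]
        assert expand_homologs(["x"], locus_to_group, groups) == ["x"]


class TestBuildCounts:
    def _sheet(self, samples, specimen="urine"):
        return pd.DataFrame(
            {
                "sample_id": samples,
                "specimen": [specimen] * len(samples),
                "batch": ["study2"] * len(samples),
                "subject_id": [f"s{i}" for i in range(len(samples))],
            }
        )

    def test_single_trna_cohort(self, small_bundle):
        ann = next(a for a in small_bundle.sncrna_annotations if a.rna_class == "tRNA")
        seq = small_bundle.annotation_sequence(ann)[:40]
        reads = [RawRead(f"r{i}", seq, "F" * 40) for i in range(50)]
        result = build_sncrna_counts({"u1": reads}, small_bundle, self._sheet(["u1"]))
        counts = result.matrix.counts["u1"]
        assert counts[ann.id] == 50
        assert counts.drop(ann.id).sum() == 0

    def test_partition_identity(self, small_bundle, small_cohort):
        sid = "urine01"
        clean, _ = preprocess_reads(small_cohort.reads[sid][:1500])
        result = build_sncrna_counts({sid: clean}, small_bundle, self._sheet([sid]))
        row = result.report.loc[sid]
        assert (
            row["n_assigned"] + row["n_unassigned_mapped"] + row["n_genome_unmapped"]
            == row["n_pool"]
            == len(clean)
        )

    def test_homolog_equality_exact(self, small_bundle, small_cohort):
        members = small_bundle.sncrna_groups["piR-0001"]
        pools = {}
        for sid in list(small_cohort.reads)[:6]:
            pools[sid], _ = preprocess_reads(small_cohort.reads[sid][:1500])
        sheet = self._sheet(list(pools))
        result = build_sncrna_counts(pools, small_bundle, sheet)
        rows = result.matrix.counts.loc[list(members)]
        for other in members[1:]:
            assert (rows.loc[members[0]] == rows.loc[other]).all()

    def test_antisense_not_counted(self, small_bundle):
        ann = next(a for a in small_bundle.sncrna_annotations if a.rna_class == "tRNA")
        sense = small_bundle.annotation_sequence(ann)[:40]
        antisense = reverse_complement(sense)
        reads = [RawRead("r0", antisense, "F" * 40)]
        result = build_sncrna_counts({"u1": reads}, small_bundle, self._sheet(["u1"]))
        assert result.matrix.counts.loc[ann.id, "u1"] == 0
        # the read still maps to the genome, just on the opposite strand
        assert result.report.loc["u1", "n_genome_mapped"] == 1

    def test_empty_sample_is_zero_column(self, small_bundle):
        result = build_sncrna_counts({"u1": []}, small_bundle, self._sheet(["u1"]))
        assert (result.matrix.counts["u1"] == 0).all()

    def test_microbiome_fraction_reflected_in_alignment_rate(self):
        cfg = SimulationConfig(
            seed=13,
            depth=4000,
            n_samples_per_specimen={"plasma": 2, "stool": 3, "urine": 2, "cervical": 2},
            noise_fraction={"stool": 0.5},
        )
        bundle = build_reference(cfg)
        cohort = simulate_cohort(cfg, bundle)
        stool_ids = [s for s in cohort.reads if s.startswith("stool")]
        pools = {}
        for sid in stool_ids:
            clean, _ = preprocess_reads(cohort.reads[sid])
            # phase-2 pool: reads that are not miRNA-derived
            matures = {m.name for m in bundle.mature_annotations}
            pools[sid] = [
                r for r in clean if parse_read_id(r.id)["f"] not in matures
            ]
        sheet = self._sheet(stool_ids, "stool")
        result = build_sncrna_counts(pools, bundle, sheet)
        for sid in stool_ids:
            rate = result.report.loc[sid, "genome_alignment_rate"]
            # noise is ~50% of all reads; the phase-2 pool is noise + sncRNA
            expected = 1.0 - 0.5 / (0.5 + 0.5 * (1 - cfg.mirna_mass))
            assert abs(rate - expected) < 0.1
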