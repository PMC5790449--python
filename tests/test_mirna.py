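"""Phase-1 aligner (with exhaustive-scan oracle), mature assignment,
counting-matrix construction and isomiR calling."""

import numpy as np
import pandas as pd
import pytest

from rnacensus.mirna import (
    AlignedRead,
    PrecursorAligner,
    PrecursorHit,
    align_to_precursors,
    assign_mature,
    build_mirna_counts,
    call_isomirs,
    classify_variant,
)
from rnacensus.preprocess import RawRead
from rnacensus.simulate import MatureAnnotation, parse_read_id


def brute_force_align(sequence, precursors, max_mismatches):
    """Independent O(reads x precursors x offsets) oracle."""
    found = []
    for name, prec in precursors.items():
        for off in range(len(prec) - len(sequence) + 1):
            window = prec[off : off + len(sequence)]
            mism = sum(1 for a, b in zip(sequence, window) if a != b)
            if mism <= max_mismatches:
                found.append((name, off, mism))
    if not found:
        return []
    best = min(m for _, _, m in found)
    return sorted((n, o, m) for n, o, m in found if m == best)


def _hits_as_tuples(hits):
    return sorted((h.precursor, h.offset, h.n_mismatches) for h in hits)


@pytest.fixture(scope="module")
def precursors():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    return {
        f"prec{i}": "".join(rng.choice(bases, size=int(rng.integers(60, 91))))
        for i in range(6)
    }


class TestAligner:
    def test_exact_substring_single_hit(self, precursors):
        seq = precursors["prec0"][10:32]
        hits = align_to_precursors(("r", seq), precursors)
        assert any(h.precursor == "prec0" and h.offset == 10 and h.n_mismatches == 0 for h in hits)
        assert all(h.n_mismatches == 0 for h in hits)

    def test_four_mismatches_rejected(self, precursors):
        seq = list(precursors["prec0"][10:32])
        for i in (0, 5, 10, 15):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        mutated = "".join(seq)
        if brute_force_align(mutated, precursors, 3):
            pytest.skip("random sequence happened to match elsewhere")
        assert align_to_precursors(("r", mutated), precursors, max_mismatches=3) == []

    def test_tie_between_two_precursors(self, precursors):
        shared = precursors["prec1"][5:27]
        doubled = dict(precursors)
        doubled["clone"] = "ACGTA" + shared + "GGCCA"
        hits = align_to_precursors(("r", shared), doubled)
        names = {h.precursor for h in hits}
        assert {"prec1", "clone"} <= names
        scores = {h.score for h in hits}
        assert len(scores) == 1  # equal score for tied hits

    def test_n_heavy_read_skipped(self, precursors):
        seq = precursors["prec0"][10:30]
        noisy = "NNN" + seq[3:]  # 15% N
        assert align_to_precursors(("r", noisy), precursors) == []

    def test_oracle_equivalence_500_random_instances(self, precursors):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        aligner = PrecursorAligner(precursors, 3)
        for _ in range(500):
            prec = list(precursors.values())[int(rng.integers(0, len(precursors)))]
            length = int(rng.integers(15, 36))
            if rng.random() < 0.7:
                off = int(rng.integers(0, len(prec) - length + 1))
                seq = list(prec[off : off + length])
                for _ in range(int(rng.integers(0, 5))):
                    i = int(rng.integers(0, length))
                    seq[i] = str(rng.choice(bases))
                seq = "".join(seq)
            else:
                seq = "".join(rng.choice(bases, size=length))
            expected = brute_force_align(seq, precursors, 3)
            assert _hits_as_tuples(aligner.align("r", seq)) == expected

    def test_monotone_in_mismatch_cap(self, precursors):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            prec = precursors["prec2"]
            off = int(rng.integers(0, len(prec) - 22))
            seq = list(prec[off : off + 22])
            for _ in range(int(rng.integers(0, 4))):
                seq[int(rng.integers(0, 22))] = str(rng.choice(bases))
            seq = "".join(seq)
            counts = [
                len(align_to_precursors(("r", seq), precursors, max_mismatches=k))
                for k in range(4)
            ]
            hit_flags = [c > 0 for c in counts]
            assert hit_flags == sorted(hit_flags)  # once aligned, stays aligned


class TestAssignMature:
    matures = [
        MatureAnnotation("m-5p", "prec", 8, 30),
        MatureAnnotation("m-3p", "prec", 42, 64),
    ]

    def _hit(self, offset, length=22):
        return PrecursorHit("r", "prec", offset, length, 0)

    def test_identity_interval(self):
        assert assign_mature(self._hit(8), self.matures) == "m-5p"

    def test_shift_plus_two_still_5p(self):
        # overlap 20/22 >= 50%
        assert assign_mature(self._hit(10), self.matures) == "m-5p"

    def test_loop_read_unassigned(self):
        # centered on the loop: overlaps both arms < 50%
        assert assign_mature(self._hit(26, 20), self.matures) is None

    def test_no_annotations(self):
        assert assign_mature(self._hit(8), []) is None

    def test_tie_prefers_5p(self):
        matures = [
            MatureAnnotation("x-3p", "prec", 0, 22),
            MatureAnnotation("x-5p", "prec", 0, 22),
        ]
        assert assign_mature(self._hit(0), matures) == "x-5p"


class _Bundle:
    """Minimal duck-typed bundle for phase-1 counting tests."""

    def __init__(self, precursors, matures):
        self.precursors = precursors
        self.mature_annotations = matures

    def mature_by_precursor(self):
        out = {}
        for m in self.mature_annotations:
            out.setdefault(m.precursor, []).append(m)
        return out


def _sheet(samples, specimen="plasma"):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "specimen": [specimen] * len(samples),
            "batch": ["study1"] * len(samples),
            "subject_id": [f"s{i}" for i in range(len(samples))],
        }
    )


class TestBuildCounts:
    def test_single_feature_cohort(self):
        prec = "GGGGG" + "ACGTACGTACGTACGTACGTAC" + "TTTTTTTTTTTT" + "CATCATCATCATCATCATCATC" + "AAAAA"
        matures = [
            MatureAnnotation("mi-5p", "p1", 5, 27),
            MatureAnnotation("mi-3p", "p1", 39, 61),
        ]
        bundle = _Bundle({"p1": prec}, matures)
        reads = [RawRead(f"r{i}", prec[5:27], "F" * 22) for i in range(100)]
        result = build_mirna_counts({"s1": reads}, bundle, _sheet(["s1"]))
        counts = result.matrix.counts["s1"]
        assert counts["mi-5p"] == 100
        assert (counts.drop("mi-5p") == 0).all()
        assert result.report.loc["s1", "n_aligned"] == 100
        assert result.unmapped["s1"] == []

    def test_homologous_precursors_both_incremented(self):
        core = "ACGTACGTACGTACGTACGTAC"
        bundle = _Bundle(
            {"pA": "GGGGG" + core + "TTTTT", "pB": "CCCCC" + core + "AAAAA"},
            [
                MatureAnnotation("mA-5p", "pA", 5, 27),
                MatureAnnotation("mB-5p", "pB", 5, 27),
            ],
        )
        reads = [RawRead("r0", core, "F" * 22)]
        result = build_mirna_counts({"s1": reads}, bundle, _sheet(["s1"]))
        assert result.matrix.counts.loc["mA-5p", "s1"] == 1
        assert result.matrix.counts.loc["mB-5p", "s1"] == 1

    def test_partition_identity(self, small_bundle, small_cohort):
        sid = "plasma01"
        reads = [RawRead(r, s, q) for r, s, q in small_cohort.reads[sid][:2000]]
        result = build_mirna_counts({sid: reads}, small_bundle, _sheet([sid]))
        row = result.report.loc[sid]
        assert row["n_aligned"] + row["n_unmapped"] == row["n_input"] == len(reads)

    def test_unknown_sample_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="absent from sample sheet"):
            build_mirna_counts({"ghost": []}, small_bundle, _sheet(["s1"]))

    def test_assignment_accuracy_against_truth(self, small_config, small_bundle, small_cohort):
        """Per-read assignment accuracy >= 99% at the default error rate."""
        assert small_config.insert_error_rate <= 0.005
        matures = {m.name for m in small_bundle.mature_annotations}
        total = correct = 0
        for sid in list(small_cohort.reads)[:4]:
            raw = small_cohort.reads[sid]
            from rnacensus.preprocess import preprocess_reads

            clean, _ = preprocess_reads(raw)
            result = build_mirna_counts({sid: clean}, small_bundle, _sheet([sid]))
            for entry in result.aligned[sid]:
                truth_feature = parse_read_id(entry.read_id)["f"]
                if truth_feature not in matures:
                    continue
                total += 1
                if truth_feature in entry.matures:
                    correct += 1
        assert total > 1000
        assert correct / total >= 0.99


class TestIsomiRs:
    def test_variant_classes(self):
        assert classify_variant(0, 0, 0) == "canonical"
        assert classify_variant(-1, 0, 0) == "5p_shift"
        assert classify_variant(0, 2, 0) == "3p_shift"
        assert classify_variant(0, 0, 2) == "internal_mismatch"
        assert classify_variant(1, 0, 1) == "combined"
        assert classify_variant(1, -1, 0) == "combined"

    @staticmethod
    def _bundle():
        prec = "GGGGGAAA" + "ACGTTGCAACGTTGCAACGTTG" + "TTTTTTTTTTTT" + "CATGGATCCATGGATCCATGGA" + "CCCAAAAA"
        return _Bundle(
            {"p1": prec},
            [
                MatureAnnotation("mi-5p", "p1", 8, 30),
                MatureAnnotation("mi-3p", "p1", 42, 64),
            ],
        )

    def _run(self, per_sample_counts, insert_fn, support_threshold=20):
        bundle = self._bundle()
        prec = bundle.precursors["p1"]
        samples = {}
        specimens = {}
        for i, count in enumerate(per_sample_counts):
            sid = f"stool{i + 1:02d}"
            samples[sid] = [
                RawRead(f"{sid}:{j}", insert_fn(prec), "F" * len(insert_fn(prec)))
                for j in range(count)
            ]
            specimens[sid] = "stool"
        sheet = _sheet(list(samples), "stool")
        result = build_mirna_counts(samples, bundle, sheet)
        return call_isomirs(result.aligned, bundle, specimens, support_threshold)

    def test_canonical_reads_never_reported(self):
        calls = self._run([30, 30, 30], lambda p: p[8:30])
        assert calls == []

    def test_5p_shift_called(self):
        calls = self._run([30, 30, 30], lambda p: p[7:30])
        assert len(calls) == 1
        call = calls[0]
        assert call.mature == "mi-5p"
        assert call.variant_class == "5p_shift"
        assert call.delta5 == -1 and call.delta3 == 0

    def test_strict_support_boundary(self):
        # median exactly 20 in every specimen -> excluded; 21 -> included
        assert self._run([20, 20, 20], lambda p: p[7:30]) == []
        assert len(self._run([21, 21, 21], lambda p: p[7:30])) == 1

    def test_internal_mismatch_signature(self):
        def mutated(p):
            seq = list(p[8:30])
            seq[5] = "A" if seq[5] != "A" else "C"
            return "".join(seq)

        calls = self._run([30, 30, 30], mutated)
        assert len(calls) == 1
        assert calls[0].variant_class == "internal_mismatch"
        assert calls[0].n_mismatches == 1
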