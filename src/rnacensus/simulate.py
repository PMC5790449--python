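"""Synthetic cohort generator with planted ground truth.

Builds a fully specified toy reference (genome, miRNA precursors with mature
arms, sncRNA loci including homologous identical-sequence piRNA groups) and a
multi-specimen, multi-batch read cohort in which every downstream signal is
planted and therefore exactly recoverable:

* ``n_common_mirnas`` miRNAs abundant in every specimen group;
* specimen-specific miRNAs abundant in exactly one group;
* low-dispersion "stable" features (reference-gene candidates);
* paired-correlated features sharing a per-subject latent factor across
  specimen types at a target correlation ``rho``;
* per-study batch offsets on plasma samples;
* adapter-contaminated reads with per-base substitution errors, a configurable
  low-quality read fraction and unmappable noise reads.

Every read id encodes its true source feature (and isomiR shift), so
assignment accuracy downstream is computable exactly. All randomness flows
from ``SimulationConfig.seed``; a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .io import Annotation, write_fasta, write_fastq, write_gtf, write_json, write_tsv

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NOISE_FEATURE = "_noise"
GENCODE_CLASSES = ("snoRNA", "snRNA", "misc_RNA", "rRNA", "Mt_tRNA", "sRNA")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


# ---------------------------------------------------------------------------
# configuration


def _default_samples() -> dict[str, int]:
    return {"plasma": 12, "stool": 12, "urine": 12, "cervical": 12}


def _default_specific() -> dict[str, int]:
    return {"plasma": 8, "stool": 5, "urine": 3, "cervical": 1}


def _default_snc_specific() -> dict[str, int]:
    return {"plasma": 2, "stool": 2, "urine": 4, "cervical": 0}


def _default_batch_offsets() -> dict[str, float]:
    return {"study1": 0.0, "study2": 0.3, "study3": -0.2}


def _default_noise() -> dict[str, float]:
    return {"stool": 0.3}


@dataclass
class SimulationConfig:
    """Knobs for the toy reference and the read cohort.

    Defaults reproduce the standard scenario: 4 specimen groups x 12 samples,
    50k reads per sample, 11 common miRNAs and specimen-specific sets of
    sizes {8, 5, 3, 1}.
    """

    seed: int = 0
    specimens: tuple[str, ...] = ("plasma", "stool", "urine", "cervical")
    n_samples_per_specimen: Mapping[str, int] = field(default_factory=_default_samples)
    depth: int = 50_000
    read_length: int = 50
    adapter: str = "AGATCGGAAGAGC"  # NEBNext small-RNA 3' adapter motif
    insert_error_rate: float = 0.005
    low_quality_fraction: float = 0.02
    # planted miRNA structure
    n_common_mirnas: int = 11
    n_specific_per_specimen: Mapping[str, int] = field(default_factory=_default_specific)
    n_shared_mirnas: int = 4
    n_stable_per_specimen: int = 1
    n_paired_correlated: int = 2
    rho: float = 0.6
    latent_sigma: float = 0.4
    dispersion_sigma: float = 0.25
    common_sigma: float = 0.1  # common features are the uniformly expressed ones
    stable_sigma: float = 0.02
    isomir_fraction: float = 0.15
    # batches
    batch_log_offsets: Mapping[str, float] = field(default_factory=_default_batch_offsets)
    plasma_batches: tuple[str, ...] = ("study1", "study2", "study3")
    noise_fraction: Mapping[str, float] = field(default_factory=_default_noise)
    default_noise_fraction: float = 0.02
    mirna_mass: float = 0.55
    # reference sizing
    n_pirna_loci: int = 20
    n_homolog_loci: int = 2
    n_trna_loci: int = 10
    n_gencode_small: int = 8
    n_gencode_large: int = 5
    # planted sncRNA structure
    n_snc_common: int = 6
    n_snc_specific_per_specimen: Mapping[str, int] = field(default_factory=_default_snc_specific)
    specimen_profiles: Mapping[str, Mapping[str, float]] | None = None

    def validate(self) -> None:
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if not self.specimens:
            raise ConfigError("at least one specimen group is required")
        if not self.adapter or set(self.adapter) - set("ACGT"):
            raise ConfigError("adapter must be a non-empty ACGT string")
        for name, value in (
            ("insert_error_rate", self.insert_error_rate),
            ("low_quality_fraction", self.low_quality_fraction),
            ("isomir_fraction", self.isomir_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not -1.0 < self.rho < 1.0:
            raise ConfigError("rho must be in (-1, 1)")
        if self.read_length < 20:
            raise ConfigError("read_length must be at least 20")
        for sp in self.specimens:
            if self.n_samples_per_specimen.get(sp, 0) <= 0:
                raise ConfigError(f"no samples configured for specimen {sp!r}")
        unknown = set(self.n_samples_per_specimen) - set(self.specimens)
        if unknown:
            raise ConfigError(f"unknown specimen(s) in sample map: {sorted(unknown)}")
        if self.n_homolog_loci < 2:
            raise ConfigError("homolog group needs at least 2 loci")
        if self.n_homolog_loci > self.n_pirna_loci:
            raise ConfigError("homolog loci exceed configured piRNA loci")
        n_groups = (self.n_pirna_loci - self.n_homolog_loci + 1) + self.n_trna_loci + self.n_gencode_small
        wanted = self.n_snc_common + sum(
            self.n_snc_specific_per_specimen.get(sp, 0) for sp in self.specimens
        )
        if wanted > n_groups:
            raise ConfigError(
                "requested planted sncRNA feature counts exceed configured reference size"
            )
        if self.n_stable_per_specimen < 0 or self.n_paired_correlated < 0:
            raise ConfigError("planted feature counts must be non-negative")

    def specimen_noise(self, specimen: str) -> float:
        return float(self.noise_fraction.get(specimen, self.default_noise_fraction))


# ---------------------------------------------------------------------------
# reference


@dataclass(frozen=True)
class MatureAnnotation:
    """Mature arm interval, 0-based half-open on its precursor."""

    name: str
    precursor: str
    start: int
    end: int


@dataclass
class ReferenceBundle:
    """Toy genome + precursor/mature miRNA + sncRNA annotations."""

    genome: dict[str, str]
    precursors: dict[str, str]
    mature_annotations: list[MatureAnnotation]
    sncrna_annotations: list[Annotation]
    # quantification group -> member locus ids; homologous identical-sequence
    # loci share one group, everything else is a singleton
    sncrna_groups: dict[str, tuple[str, ...]]

    def mature_by_precursor(self) -> dict[str, list[MatureAnnotation]]:
        out: dict[str, list[MatureAnnotation]] = {}
        for ann in self.mature_annotations:
            out.setdefault(ann.precursor, []).append(ann)
        return out

    def annotation_by_id(self) -> dict[str, Annotation]:
        return {ann.id: ann for ann in self.sncrna_annotations}

    def annotation_sequence(self, ann: Annotation) -> str:
        chunk = self.genome[ann.contig][ann.start : ann.end]
        return reverse_complement(chunk) if ann.strand == "-" else chunk

    def group_of_locus(self) -> dict[str, str]:
        return {
            locus: group
            for group, members in self.sncrna_groups.items()
            for locus in members
        }

    def validate(self) -> None:
        for ann in self.mature_annotations:
            prec = self.precursors.get(ann.precursor)
            if prec is None:
                raise ValueError(f"mature {ann.name}: unknown precursor")
            if not (0 <= ann.start < ann.end <= len(prec)):
                raise ValueError(f"mature {ann.name}: interval outside precursor")
        by_id = self.annotation_by_id()
        for ann in self.sncrna_annotations:
            if ann.contig not in self.genome:
                raise ValueError(f"annotation {ann.id}: unknown contig")
            if ann.end > len(self.genome[ann.contig]):
                raise ValueError(f"annotation {ann.id}: beyond contig end")
        for group, members in self.sncrna_groups.items():
            seqs = {self.annotation_sequence(by_id[m]) for m in members}
            if len(seqs) != 1:
                raise ValueError(f"homolog group {group}: member sequences differ")


def build_reference(config: SimulationConfig) -> ReferenceBundle:
    """Construct the deterministic toy reference for ``config``.

    Precursors are laid out as 5' flank + mature-5p + loop + mature-3p +
    3' flank (total 60-90 nt), guaranteeing >=2 nt of slack around each
    mature arm for isomiR shifts. The genome carries the sncRNA loci on
    alternating strands separated by random spacers; the homologous piRNA
    group is planted as byte-identical sequences at distinct coordinates.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    precursors: dict[str, str] = {}
    matures: list[MatureAnnotation] = []

    def add_precursor(stem: str) -> None:
        f5 = int(rng.integers(5, 10))
        m5 = int(rng.integers(21, 24))
        loop = int(rng.integers(10, 16))
        m3 = int(rng.integers(21, 24))
        f3 = int(rng.integers(5, 10))
        seq = _random_bases(rng, f5 + m5 + loop + m3 + f3)
        precursors[stem] = seq
        matures.append(MatureAnnotation(f"{stem}-5p", stem, f5, f5 + m5))
        matures.append(
            MatureAnnotation(f"{stem}-3p", stem, f5 + m5 + loop, f5 + m5 + loop + m3)
        )

    for i in range(config.n_common_mirnas):
        add_precursor(f"mir-com{i + 1:02d}")
    for sp in config.specimens:
        for i in range(config.n_specific_per_specimen.get(sp, 0)):
            add_precursor(f"mir-{sp[:3]}{i + 1:02d}")
    for i in range(config.n_shared_mirnas):
        add_precursor(f"mir-shr{i + 1:02d}")
    for i in range(config.n_paired_correlated):
        add_precursor(f"mir-cor{i + 1:02d}")

    # --- sncRNA loci ---------------------------------------------------
    loci: list[tuple[str, str, str, str]] = []  # (locus id, class, source, sequence)
    groups: dict[str, tuple[str, ...]] = {}

    homolog_seq = _random_bases(rng, int(rng.integers(30, 33)))
    members = tuple(f"piR-0001-L{j + 1}" for j in range(config.n_homolog_loci))
    groups["piR-0001"] = members
    for member in members:
        loci.append((member, "piRNA", "DASHR", homolog_seq))
    for i in range(config.n_pirna_loci - config.n_homolog_loci):
        lid = f"piR-{i + 2:04d}"
        loci.append((lid, "piRNA", "DASHR", _random_bases(rng, int(rng.integers(30, 33)))))
        groups[lid] = (lid,)
    for i in range(config.n_trna_loci):
        lid = f"tRNA-{i + 1:02d}"
        loci.append((lid, "tRNA", "DASHR", _random_bases(rng, int(rng.integers(67, 82)))))
        groups[lid] = (lid,)
    for i in range(config.n_gencode_small):
        cls = GENCODE_CLASSES[i % len(GENCODE_CLASSES)]
        lid = f"{cls}-{i + 1:02d}"
        loci.append((lid, cls, "GENCODE", _random_bases(rng, int(rng.integers(40, 71)))))
        groups[lid] = (lid,)
    for i in range(config.n_gencode_large):
        cls = GENCODE_CLASSES[i % len(GENCODE_CLASSES)]
        lid = f"{cls}-L{i + 1:02d}"
        loci.append((lid, cls, "GENCODE", _random_bases(rng, int(rng.integers(71, 91)))))
        groups[lid] = (lid,)

    # --- place loci on two contigs -------------------------------------
    contig_parts: dict[str, list[str]] = {"chr1": [], "chr2": []}
    contig_len: dict[str, int] = {"chr1": 0, "chr2": 0}
    annotations: list[Annotation] = []
    for idx, (lid, cls, src, seq) in enumerate(loci):
        contig = "chr1" if idx % 2 == 0 else "chr2"
        strand = "+" if (idx // 2) % 2 == 0 else "-"
        spacer = _random_bases(rng, int(rng.integers(50, 81)))
        contig_parts[contig].append(spacer)
        contig_len[contig] += len(spacer)
        start = contig_len[contig]
        planted = seq if strand == "+" else reverse_complement(seq)
        contig_parts[contig].append(planted)
        contig_len[contig] += len(seq)
        annotations.append(
            Annotation(id=lid, rna_class=cls, source=src, contig=contig,
                       start=start, end=start + len(seq), strand=strand)
        )
    for contig in contig_parts:
        tail = _random_bases(rng, int(rng.integers(50, 81)))
        contig_parts[contig].append(tail)
    genome = {c: "".join(parts) for c, parts in contig_parts.items()}

    bundle = ReferenceBundle(
        genome=genome,
        precursors=precursors,
        mature_annotations=matures,
        sncrna_annotations=annotations,
        sncrna_groups=groups,
    )
    bundle.validate()
    return bundle


def write_reference(bundle: ReferenceBundle, out_dir: str | Path) -> None:
    """Export the bundle as FASTA/GTF/BED/TSV files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "precursors.fasta", bundle.precursors)
    write_fasta(out / "genome.fasta", bundle.genome)
    mature = pd.DataFrame(
        [(m.name, m.precursor, m.start, m.end) for m in bundle.mature_annotations],
        columns=["mature", "precursor", "start", "end"],
    )
    write_tsv(out / "mature.tsv", mature)
    write_gtf(out / "sncrna.gtf", bundle.sncrna_annotations)
    from .io import write_bed6

    write_bed6(out / "sncrna.bed", bundle.sncrna_annotations)
    write_json(out / "sncrna_groups.json", {g: list(m) for g, m in bundle.sncrna_groups.items()})


# ---------------------------------------------------------------------------
# planted structure


@dataclass
class PlantedSets:
    """Which features carry which planted signal."""

    common: list[str]
    specific: dict[str, list[str]]
    shared: dict[str, tuple[str, str]]  # feature -> specimen pair
    correlated: list[str]
    stable: dict[str, list[str]]  # specimen -> stable miRNAs (subset of specific)
    snc_common: list[str]
    snc_specific: dict[str, list[str]]
    snc_stable: dict[str, list[str]]

    def all_stable(self) -> set[str]:
        out: set[str] = set()
        for feats in self.stable.values():
            out.update(feats)
        for feats in self.snc_stable.values():
            out.update(feats)
        return out


def planted_sets(config: SimulationConfig, bundle: ReferenceBundle) -> PlantedSets:
    """Deterministic assignment of reference features to planted roles."""
    specimens = list(config.specimens)
    common = [f"mir-com{i + 1:02d}-5p" for i in range(config.n_common_mirnas)]
    specific = {
        sp: [
            f"mir-{sp[:3]}{i + 1:02d}-5p"
            for i in range(config.n_specific_per_specimen.get(sp, 0))
        ]
        for sp in specimens
    }
    pair_cycle = list(itertools.combinations(specimens, 2)) or [(specimens[0], specimens[0])]
    shared = {
        f"mir-shr{i + 1:02d}-5p": pair_cycle[i % len(pair_cycle)]
        for i in range(config.n_shared_mirnas)
    }
    corr_specimens = [sp for sp in specimens if sp in ("plasma", "stool", "urine")]
    correlated = (
        [f"mir-cor{i + 1:02d}-5p" for i in range(config.n_paired_correlated)]
        if len(corr_specimens) >= 2
        else []
    )
    stable = {
        sp: specific[sp][: config.n_stable_per_specimen] for sp in specimens if specific[sp]
    }

    group_order = list(bundle.sncrna_groups)
    # only groups that survive size selection can carry planted signal
    by_id = bundle.annotation_by_id()
    quantifiable = []
    for g in group_order:
        ann = by_id[bundle.sncrna_groups[g][0]]
        if ann.source == "GENCODE" and ann.length > 70:
            continue
        quantifiable.append(g)
    cursor = 0
    snc_common = quantifiable[cursor : cursor + config.n_snc_common]
    cursor += config.n_snc_common
    snc_specific: dict[str, list[str]] = {}
    for sp in specimens:
        k = config.n_snc_specific_per_specimen.get(sp, 0)
        snc_specific[sp] = quantifiable[cursor : cursor + k]
        cursor += k
    snc_stable = {sp: feats[:1] for sp, feats in snc_specific.items() if feats}
    return PlantedSets(
        common=common,
        specific=specific,
        shared=shared,
        correlated=correlated,
        stable=stable,
        snc_common=snc_common,
        snc_specific=snc_specific,
        snc_stable=snc_stable,
    )


def derive_profiles(
    config: SimulationConfig, bundle: ReferenceBundle, planted: PlantedSets
) -> dict[str, dict[str, float]]:
    """Per-specimen expected relative abundances (summing to 1).

    Mass layout per specimen: a noise slice (unmappable reads), then
    ``mirna_mass`` of the mappable slice on miRNA features (with a tiny
    allowance on each planted precursor's 3p arm, kept far below the
    detection threshold) and the remainder on sncRNA groups.
    """
    if config.specimen_profiles is not None:
        profiles = {sp: dict(p) for sp, p in config.specimen_profiles.items()}
        for sp, prof in profiles.items():
            if abs(sum(prof.values()) - 1.0) > 1e-9:
                raise ConfigError(f"profile for {sp!r} does not sum to 1")
        return profiles
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    profiles: dict[str, dict[str, float]] = {}
    for sp in config.specimens:
        mirnas = list(planted.common) + list(planted.specific.get(sp, []))
        mirnas += [f for f, pair in planted.shared.items() if sp in pair]
        if sp in ("plasma", "stool", "urine"):
            mirnas += planted.correlated
        sncs = list(planted.snc_common) + list(planted.snc_specific.get(sp, []))
        noise = config.specimen_noise(sp)
        mappable = 1.0 - noise
        three_p = [m.replace("-5p", "-3p") for m in mirnas if m.endswith("-5p")]
        three_p_each = 5e-5
        mirna_total = config.mirna_mass * mappable - three_p_each * len(three_p)
        snc_total = mappable - config.mirna_mass * mappable
        prof: dict[str, float] = {}
        w = rng.uniform(0.5, 1.5, size=len(mirnas))
        w = w / w.sum() * mirna_total
        prof.update(zip(mirnas, w.tolist()))
        for arm in three_p:
            prof[arm] = three_p_each
        if sncs:
            v = rng.uniform(0.5, 1.5, size=len(sncs))
            v = v / v.sum() * snc_total
            prof.update(zip(sncs, v.tolist()))
        else:
            noise += snc_total
        prof[NOISE_FEATURE] = 1.0 - sum(prof.values())
        profiles[sp] = prof
    return profiles


# ---------------------------------------------------------------------------
# cohort


@dataclass
class GroundTruth:
    """Planted truth: exact counts, labels, batches and subject pairing."""

    counts: pd.DataFrame  # features x samples, integer; columns sum to depth
    sample_sheet: pd.DataFrame  # sample_id, specimen, batch, subject_id
    planted: PlantedSets

    def pairs(self, specimen_a: str, specimen_b: str) -> list[tuple[str, str]]:
        """Sample-id pairs sharing a subject across the two specimen types."""
        sheet = self.sample_sheet.set_index("sample_id")
        a = sheet[sheet["specimen"] == specimen_a]
        b = sheet[sheet["specimen"] == specimen_b]
        by_subject = dict(zip(b["subject_id"], b.index))
        return [
            (sid, by_subject[subj])
            for sid, subj in zip(a.index, a["subject_id"])
            if subj in by_subject
        ]


@dataclass
class Cohort:
    sample_sheet: pd.DataFrame
    truth: GroundTruth
    reads: dict[str, list[tuple[str, str, str]]] | None = None
    fastq_paths: dict[str, Path] | None = None


def make_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Sample ids, specimen groups, batch labels and subject pairing.

    Plasma samples rotate through the configured plasma batches; sample *i*
    of stool/urine shares its subject with plasma sample *i* where one
    exists, which is what makes cross-specimen paired analyses possible.
    """
    rows = []
    n_plasma = config.n_samples_per_specimen.get("plasma", 0)
    for sp in config.specimens:
        n = config.n_samples_per_specimen[sp]
        for i in range(n):
            sid = f"{sp}{i + 1:02d}"
            if sp == "plasma":
                batch = config.plasma_batches[i % len(config.plasma_batches)]
                subject = f"subj{i + 1:03d}"
            elif sp in ("stool", "urine") and i < n_plasma:
                batch = "study1" if sp == "stool" else "study2"
                subject = f"subj{i + 1:03d}"
            else:
                batch = {"stool": "study1", "urine": "study2"}.get(sp, "ntcc")
                subject = f"{sp[:3]}sub{i + 1:03d}"
            rows.append((sid, sp, batch, subject))
    return pd.DataFrame(rows, columns=["sample_id", "specimen", "batch", "subject_id"])


def simulate_truth_counts(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    planted: PlantedSets | None = None,
    profiles: dict[str, dict[str, float]] | None = None,
    sheet: pd.DataFrame | None = None,
) -> GroundTruth:
    """Draw per-sample true counts (multinomial at ``depth``; exact sums).

    Applies, in order: the batch log-offset (on a deterministic half of the
    features, then renormalised), per-feature lognormal dispersion (narrow
    for stable features), and the shared per-subject latent factor for
    paired-correlated features.
    """
    config.validate()
    planted = planted or planted_sets(config, bundle)
    profiles = profiles or derive_profiles(config, bundle, planted)
    sheet = sheet if sheet is not None else make_sample_sheet(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    features = sorted({f for prof in profiles.values() for f in prof} - {NOISE_FEATURE})
    all_rows = features + [NOISE_FEATURE]
    batch_affected = set(features[::2])  # offset half the features, see ledger
    stable_feats = planted.all_stable()
    common_feats = set(planted.common) | set(planted.snc_common)
    corr_feats = [f for f in planted.correlated if f in features]

    subjects = sorted(sheet["subject_id"].unique())
    latent = {
        (subj, f): float(z)
        for subj, zs in zip(subjects, rng.standard_normal((len(subjects), len(corr_feats))))
        for f, z in zip(corr_feats, zs)
    }

    counts = np.zeros((len(all_rows), len(sheet)), dtype=np.int64)
    row_index = {f: i for i, f in enumerate(all_rows)}
    sqrho = np.sqrt(config.rho)
    sqres = np.sqrt(1.0 - config.rho)
    for j, (sid, sp, batch, subject) in enumerate(
        sheet[["sample_id", "specimen", "batch", "subject_id"]].itertuples(index=False)
    ):
        prof = profiles[sp]
        names = list(prof)
        p = np.array([prof[f] for f in names], dtype=float)
        offset = float(config.batch_log_offsets.get(batch, 0.0)) if sp == "plasma" else 0.0
        if offset:
            mask = np.array([f in batch_affected for f in names])
            p[mask] *= 10.0**offset
        for i, f in enumerate(names):
            if f == NOISE_FEATURE:
                continue
            if f in corr_feats:
                z = latent[(subject, f)]
                eps = rng.standard_normal()
                p[i] *= 10.0 ** (config.latent_sigma * (sqrho * z + sqres * eps))
            else:
                if f in stable_feats:
                    sigma = config.stable_sigma
                elif f in common_feats:
                    sigma = config.common_sigma
                else:
                    sigma = config.dispersion_sigma
                p[i] *= 10.0 ** (sigma * rng.standard_normal())
        p /= p.sum()
        draw = rng.multinomial(config.depth, p)
        for f, c in zip(names, draw):
            counts[row_index[f], j] = c
    frame = pd.DataFrame(counts, index=all_rows, columns=sheet["sample_id"].tolist())
    return GroundTruth(counts=frame, sample_sheet=sheet, planted=planted)


_ISOMIR_SHIFTS = [
    (d5, d3) for d5 in (-2, -1, 0, 1, 2) for d3 in (-2, -1, 0, 1, 2) if (d5, d3) != (0, 0)
]


def _sample_reads(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    sample_id: str,
    feature_counts: pd.Series,
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """Materialise one sample's reads from its true feature counts."""
    mature = {m.name: m for m in bundle.mature_annotations}
    by_id = bundle.annotation_by_id()
    adapter = config.adapter
    rl = config.read_length

    entries: list[tuple[str, str]] = []  # (id suffix, insert)
    for feat, count in feature_counts.items():
        count = int(count)
        if count == 0:
            continue
        if feat == NOISE_FEATURE:
            for _ in range(count):
                entries.append((f"f={feat};d5=0;d3=0", _random_bases(rng, rl)))
        elif feat in mature:
            ann = mature[feat]
            prec = bundle.precursors[ann.precursor]
            iso = rng.random(count) < config.isomir_fraction
            picks = rng.integers(0, len(_ISOMIR_SHIFTS), size=count)
            for k in range(count):
                d5, d3 = _ISOMIR_SHIFTS[picks[k]] if iso[k] else (0, 0)
                insert = prec[ann.start + d5 : ann.end + d3]
                entries.append((f"f={feat};d5={d5};d3={d3}", insert))
        elif feat in bundle.sncrna_groups:
            locus = by_id[bundle.sncrna_groups[feat][0]]
            seq = bundle.annotation_sequence(locus)
            max_len = min(70, len(seq))
            lengths = rng.integers(30, max_len + 1, size=count)
            starts = rng.integers(0, len(seq) - lengths + 1)
            for L, s in zip(lengths, starts):
                entries.append((f"f={feat};d5=0;d3=0", seq[s : s + L]))
        else:
            raise ConfigError(f"planted feature {feat!r} not present in the reference")

    n = len(entries)
    order = rng.permutation(n)
    err_counts = rng.binomial(rl, config.insert_error_rate, size=n)
    low_q = rng.random(n) < config.low_quality_fraction
    good_qual = "F" * rl  # Q37
    bad_qual = "5" * rl  # Q20 -> mean Phred < 30
    reads: list[tuple[str, str, str]] = []
    for out_i, k in enumerate(order):
        suffix, insert = entries[k]
        seq = insert + adapter
        if len(seq) < rl:
            seq += _random_bases(rng, rl - len(seq))
        else:
            seq = seq[:rl]
        ne = err_counts[k]
        if ne:
            chars = list(seq)
            for pos in rng.choice(rl, size=ne, replace=False):
                old = chars[pos]
                choices = [b for b in "ACGT" if b != old]
                chars[pos] = choices[rng.integers(0, 3)]
            seq = "".join(chars)
        rid = f"{sample_id}:{out_i:06d}|{suffix}"
        reads.append((rid, seq, bad_qual if low_q[k] else good_qual))
    return reads


def parse_read_id(read_id: str) -> dict[str, str]:
    """Recover the planted truth encoded in a simulated read id."""
    _, _, payload = read_id.partition("|")
    out: dict[str, str] = {}
    for item in payload.split(";"):
        key, _, value = item.partition("=")
        out[key] = value
    return out


def iter_sample_reads(
    config: SimulationConfig, bundle: ReferenceBundle, truth: GroundTruth
) -> Iterator[tuple[str, list[tuple[str, str, str]]]]:
    """Yield (sample_id, reads) one sample at a time (bounded memory)."""
    seq = np.random.SeedSequence([config.seed, 4])
    children = seq.spawn(len(truth.sample_sheet))
    for child, sid in zip(children, truth.sample_sheet["sample_id"]):
        rng = np.random.default_rng(child)
        yield sid, _sample_reads(config, bundle, sid, truth.counts[sid], rng)


def simulate_cohort(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate the full cohort: FASTQ per sample, sample sheet, ground truth.

    With ``out_dir`` set, FASTQ/TSV artifacts are written and reads are not
    retained in memory; otherwise reads are returned in ``Cohort.reads``.
    """
    truth = simulate_truth_counts(config, bundle)
    reads: dict[str, list[tuple[str, str, str]]] | None = None
    paths: dict[str, Path] | None = None
    if out_dir is None:
        reads = {sid: recs for sid, recs in iter_sample_reads(config, bundle, truth)}
    else:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sid, recs in iter_sample_reads(config, bundle, truth):
            path = out / f"{sid}.fastq"
            write_fastq(path, recs)
            paths[sid] = path
        write_tsv(out / "sample_sheet.tsv", truth.sample_sheet)
        write_tsv(out / "truth_counts.tsv", truth.counts, index_label="feature")
        write_json(
            out / "truth_labels.json",
            {
                "common": truth.planted.common,
                "specific": truth.planted.specific,
                "shared": {f: list(p) for f, p in truth.planted.shared.items()},
                "correlated": truth.planted.correlated,
                "stable": truth.planted.stable,
                "snc_common": truth.planted.snc_common,
                "snc_specific": truth.planted.snc_specific,
                "snc_stable": truth.planted.snc_stable,
            },
        )
    return Cohort(sample_sheet=truth.sample_sheet, truth=truth, reads=reads, fastq_paths=paths)
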