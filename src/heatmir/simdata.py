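"""Synthetic sRNA-seq data with planted ground truth.

Generates a small genome carrying planted miRNA hairpin loci, a matching
reference-mature catalog and contaminant set, and simulates the 16-library
design (stamen/pistil x control/heat-stress x 2d/12d x 2 replicates) as
FASTQ with known per-library expression and fold-change truth, so every
downstream stage of the pipeline can be exercised and scored without any
external download.

Reads are insert + 3' adapter truncated to the read length, with fixed
Phred+33 quality 'I'.  miRNA read counts are Poisson around
expected TPM x depth / 1e6 (negative-binomial overdispersion available);
star reads are a fixed fraction of mature abundance; contaminants are
random windows of the contaminant set; the remaining depth is filled with
random genomic degradation fragments of 15-40 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._util import revcomp, spawn_rng, to_dna, to_rna, write_fasta

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"  # common small-RNA kit 3' adapter
DEFAULT_READ_LEN = 51
DEFAULT_STAR_FRACTION = 0.05
DEFAULT_HS_FOLD_CHANGE = 0.25

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedHairpin:
    """A planted miRNA locus: a perfect stem-loop whose one arm carries the
    mature sequence, with the star placed with canonical 2-nt 3' overhangs."""

    locus_id: str
    chrom: str
    start0: int  # precursor start, 0-based, on the forward strand
    strand: str  # '+' or '-'
    mature_seq: str  # DNA T-form
    star_seq: str
    loop_seq: str
    arm: str  # '5p' or '3p'
    precursor_seq: str  # strand-oriented (reads 5'->3' on its own strand)
    mature_offset: int  # offset of mature within precursor

    def __post_init__(self):
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")
        if not 18 <= len(self.mature_seq) <= 26:
            raise ValueError("mature length must be 18-26 nt")
        if len(self.loop_seq) < 8:
            raise ValueError("loop must be >= 8 nt")
        if not 61 <= len(self.precursor_seq) <= 218:
            raise ValueError("precursor length must be within 61-218 nt")

    @property
    def end0(self) -> int:
        return self.start0 + len(self.precursor_seq)


@dataclass(frozen=True)
class LibraryDesign:
    library_id: str
    tissue: str  # stamen | pistil
    condition: str  # CK | HS
    timepoint: str  # 2d | 12d
    replicate: int
    depth: int = 200_000
    adapter3: str = DEFAULT_ADAPTER3
    contaminant_fraction: float = 0.05
    background_fraction: float = 0.90  # nominal; fills remaining depth

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.contaminant_fraction + self.background_fraction > 1 + 1e-9:
            raise ValueError("contaminant + background fractions exceed 1")


@dataclass
class ExpressionTruth:
    """Per-locus, per-library expected TPM plus per-contrast true HS/CK fold
    change; the ground-truth table downstream recovery is scored against."""

    expected_tpm: dict[tuple[str, str], float]  # (locus_id, library_id) -> TPM
    true_fc: dict[tuple[str, str, str], float]  # (locus, tissue, timepoint) -> HS/CK

    def __post_init__(self):
        for key, tpm in self.expected_tpm.items():
            if tpm < 0:
                raise ValueError(f"negative expected TPM for {key}")
        for key, fc in self.true_fc.items():
            if not np.isfinite(fc) or fc <= 0:
                raise ValueError(f"true fold change must be finite positive: {key}")


def simulate_genome(length: int, gc: float, seed: int) -> tuple[str, str]:
    """Random genome sequence of the requested length and GC fraction.

    Returns (sequence, chromosome_id); deterministic for a fixed seed.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000 bp")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode(), "chr1"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def build_precursor(
    mature_dna: str,
    arm: str,
    rng: np.random.Generator,
    loop_len: int | None = None,
    upper_stem: int | None = None,
    lower_stem: int | None = None,
) -> tuple[str, int, str, str]:
    """Construct a perfect stem-loop around a mature sequence.

    Layout (5p arm): lower5 + mature + upper5 + loop + revcomp(arm5).
    The star is the m-nt interval pairing mature[0:m-2] whose two
    3'-terminal bases pair the lower stem, i.e. the canonical duplex with
    2-nt 3' overhangs on both strands.

    Returns (precursor, mature_offset, star_seq, loop_seq).
    """
    m = len(mature_dna)
    l = int(lower_stem if lower_stem is not None else rng.integers(3, 9))
    u = int(upper_stem if upper_stem is not None else rng.integers(6, 25))
    loop = int(loop_len if loop_len is not None else rng.integers(8, 25))
    loop_seq = _random_seq(rng, loop)
    if arm == "5p":
        arm5 = _random_seq(rng, l) + mature_dna + _random_seq(rng, u)
        offset = l
    elif arm == "3p":
        arm3 = _random_seq(rng, u) + mature_dna + _random_seq(rng, l)
        arm5 = revcomp(arm3)
        offset = len(arm5) + loop + u
    else:
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    precursor = arm5 + loop_seq + revcomp(arm5)
    n = len(precursor)
    # perfect-stem partner function: partner(x) = n - 1 - x
    b = offset + m
    star_start = (n - 1 - (b - 1)) + 2
    star_seq = precursor[star_start : star_start + m]
    return precursor, offset, star_seq, loop_seq


def plant_hairpin(
    genome: str,
    mature_seq: str,
    position: int,
    arm: str,
    seed: int,
    *,
    chrom: str = "chr1",
    strand: str = "+",
    locus_id: str | None = None,
    existing: tuple[PlantedHairpin, ...] | list[PlantedHairpin] = (),
    loop_len: int | None = None,
    upper_stem: int | None = None,
    lower_stem: int | None = None,
    validate: bool = True,
) -> tuple[str, PlantedHairpin]:
    """Overwrite the genome at ``position`` with a hairpin precursor whose
    ``arm`` carries ``mature_seq``.  Returns (modified genome, record).

    Raises ValueError if the precursor would overlap a previously planted
    locus (pass them via ``existing``) or run past the genome end.
    """
    mature_dna = to_dna(mature_seq)
    if not 18 <= len(mature_dna) <= 26:
        raise ValueError("mature length must be 18-26 nt")
    rng = np.random.default_rng(seed)
    precursor, offset, star_seq, loop_seq = build_precursor(
        mature_dna, arm, rng, loop_len=loop_len, upper_stem=upper_stem, lower_stem=lower_stem
    )
    end = position + len(precursor)
    if end > len(genome):
        raise ValueError("precursor does not fit in the genome at this position")
    for prev in existing:
        if prev.chrom == chrom and position < prev.end0 and prev.start0 < end:
            raise ValueError(
                f"placement overlaps previously planted locus {prev.locus_id}"
            )
    inserted = precursor if strand == "+" else revcomp(precursor)
    new_genome = genome[:position] + inserted + genome[end:]
    record = PlantedHairpin(
        locus_id=locus_id or f"locus_{position}",
        chrom=chrom,
        start0=position,
        strand=strand,
        mature_seq=mature_dna,
        star_seq=star_seq,
        loop_seq=loop_seq,
        arm=arm,
        precursor_seq=precursor,
        mature_offset=offset,
    )
    if validate:
        _validate_hairpin(record)
    return new_genome, record


def _validate_hairpin(record: PlantedHairpin) -> None:
    """Generator-side check that the planted precursor satisfies the
    discovery module's structural criteria at default settings."""
    from .discovery import HairpinCriteria, evaluate_hairpin_structure

    from .fold import fold_rna

    db, mfe = fold_rna(to_rna(record.precursor_seq))
    verdict = evaluate_hairpin_structure(
        db, record.mature_offset, len(record.mature_seq), HairpinCriteria()
    )
    if not verdict.passed:
        raise ValueError(
            f"planted locus {record.locus_id} fails hairpin criteria: {verdict.reasons}"
        )
    if mfe > -16.0:
        raise ValueError(
            f"planted locus {record.locus_id} folds with mfe {mfe:.2f} > -16"
        )


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------


def _draw_counts(rng, lam: float, nb_size: float | None) -> int:
    if lam <= 0:
        return 0
    if nb_size:
        # gamma-poisson mixture: mean lam, dispersion 1/size
        lam = rng.gamma(nb_size, lam / nb_size)
    return int(rng.poisson(lam))


def simulate_libraries(
    genome: str,
    hairpins: list[PlantedHairpin],
    truth: ExpressionTruth,
    designs: list[LibraryDesign],
    seed: int,
    outdir: str | Path,
    *,
    contaminants: dict[str, str] | None = None,
    read_len: int = DEFAULT_READ_LEN,
    star_fraction: float = DEFAULT_STAR_FRACTION,
    nb_size: float | None = None,
) -> dict[str, Path]:
    """Simulate FASTQ for every library design plus a truth table TSV.

    Each record is insert + 3' adapter truncated to ``read_len``; read
    headers carry an ``origin=`` tag (mirna:<locus>, star:<locus>,
    contaminant:<class>, background) usable for simulation-side accounting.
    Deterministic for fixed (inputs, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_locus = {h.locus_id: h for h in hairpins}
    for locus_id, _lib in truth.expected_tpm:
        if locus_id not in by_locus:
            raise ValueError(f"truth references unknown locus {locus_id!r}")
    cont_items = sorted((contaminants or {}).items())
    paths: dict[str, Path] = {}
    glen = len(genome)
    for design in designs:
        rng = spawn_rng(seed, "library", design.library_id)
        inserts: list[str] = []
        origins: list[str] = []
        for h in hairpins:
            tpm = truth.expected_tpm.get((h.locus_id, design.library_id), 0.0)
            lam = tpm * design.depth / 1e6
            n_mat = _draw_counts(rng, lam, nb_size)
            n_star = _draw_counts(rng, star_fraction * lam, nb_size)
            inserts.extend([h.mature_seq] * n_mat)
            origins.extend([f"mirna:{h.locus_id}"] * n_mat)
            inserts.extend([h.star_seq] * n_star)
            origins.extend([f"star:{h.locus_id}"] * n_star)
        n_mirna = len(inserts)
        if n_mirna > design.depth:
            raise ValueError(
                f"{design.library_id}: planted expression exceeds library depth"
            )
        n_cont = (
            int(rng.binomial(design.depth, design.contaminant_fraction))
            if cont_items
            else 0
        )
        n_cont = min(n_cont, design.depth - n_mirna)
        for _ in range(n_cont):
            name, seq = cont_items[int(rng.integers(0, len(cont_items)))]
            flen = int(rng.integers(15, min(41, len(seq) + 1)))
            start = int(rng.integers(0, len(seq) - flen + 1))
            inserts.append(seq[start : start + flen])
            origins.append(f"contaminant:{name.split('_')[0].split()[0]}")
        n_bg = design.depth - n_mirna - n_cont
        # degradation fragments: distinct (start, length, strand) combos so
        # that individual fragments stay below abundance filters, as they
        # would against a realistically sized genome
        n_len = 26  # lengths 15..40
        combos = glen * n_len * 2
        picks = rng.choice(combos, size=n_bg, replace=False)
        for p in picks:
            p = int(p)
            rc = p % 2
            flen = (p // 2) % n_len + 15
            start = p // (2 * n_len)
            if start + flen > glen:
                start = glen - flen
            frag = genome[start : start + flen]
            if "N" in frag:
                frag = frag.replace("N", "A")
            inserts.append(revcomp(frag) if rc else frag)
            origins.append("background")
        order = rng.permutation(len(inserts))
        fq = outdir / f"{design.library_id}.fastq"
        with open(fq, "w") as fh:
            for i, k in enumerate(order):
                read = (inserts[k] + design.adapter3)[:read_len]
                fh.write(
                    f"@{design.library_id}_{i} origin={origins[k]}\n"
                    f"{read}\n+\n{'I' * len(read)}\n"
                )
        paths[design.library_id] = fq
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("locus_id\tlibrary_id\texpected_tpm\ttrue_fc\n")
        for (locus_id, lib), tpm in sorted(truth.expected_tpm.items()):
            design = next(d for d in designs if d.library_id == lib)
            fc = truth.true_fc.get((locus_id, design.tissue, design.timepoint), 1.0)
            fh.write(f"{locus_id}\t{lib}\t{tpm:.6g}\t{fc:.6g}\n")
    paths["truth"] = truth_path
    return paths


def write_loci_gff3(hairpins: list[PlantedHairpin], path: str | Path) -> None:
    """Planted loci as GFF3 (1-based, inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hairpins:
            fh.write(
                f"{h.chrom}\theatmir_sim\tmiRNA_primary_transcript\t"
                f"{h.start0 + 1}\t{h.end0}\t.\t{h.strand}\t.\t"
                f"ID={h.locus_id};arm={h.arm};mature={h.mature_seq}\n"
            )


# ---------------------------------------------------------------------------
# bundled demo dataset
# ---------------------------------------------------------------------------

_KNOWN_FAMILIES = [
    "miR156", "miR159", "miR160", "miR162", "miR164", "miR166", "miR167",
    "miR168", "miR169", "miR171", "miR172", "miR319", "miR393", "miR394",
    "miR395", "miR396", "miR397", "miR398", "miR399", "miR482",
]

_TISSUES = ("stamen", "pistil")
_CONDITIONS = ("CK", "HS")
_TIMEPOINTS = ("2d", "12d")


def default_designs(
    depth: int = 200_000,
    adapter3: str = DEFAULT_ADAPTER3,
    contaminant_fraction: float = 0.05,
) -> list[LibraryDesign]:
    """The 16-library design: stamen/pistil x CK/HS x 2d/12d x 2 replicates."""
    designs = []
    for tissue in _TISSUES:
        for cond in _CONDITIONS:
            for tp in _TIMEPOINTS:
                for rep in (1, 2):
                    designs.append(
                        LibraryDesign(
                            library_id=f"{tissue}_{cond}_{tp}_r{rep}",
                            tissue=tissue,
                            condition=cond,
                            timepoint=tp,
                            replicate=rep,
                            depth=depth,
                            adapter3=adapter3,
                            contaminant_fraction=contaminant_fraction,
                        )
                    )
    return designs


def _hamming_min(seq: str, others: list[str]) -> int:
    best = 10**9
    for o in others:
        if len(o) == len(seq):
            d = sum(a != b for a, b in zip(seq, o))
            best = min(best, d)
    return best


@dataclass
class SyntheticDataset:
    genome: str
    chrom: str
    hairpins: list[PlantedHairpin]
    truth: ExpressionTruth
    designs: list[LibraryDesign]
    reference: dict[str, str]  # reference mature catalog (header -> DNA seq)
    contaminants: dict[str, str]
    known_loci: list[str]
    novel_loci: list[str]
    responsive_loci: list[str]
    transcripts: dict[str, str]
    planted_sites: list[dict]  # locus_id, transcript_id, site_start0


def build_dataset(
    seed: int,
    *,
    genome_length: int = 100_000,
    gc: float = 0.36,
    n_known: int = 20,
    n_novel: int = 10,
    n_responsive: int = 10,
    n_stamen_specific: int = 2,
    depth: int = 200_000,
    hs_fold_change: float = DEFAULT_HS_FOLD_CHANGE,
    tpm_range: tuple[float, float] = (50.0, 2000.0),
) -> SyntheticDataset:
    """Assemble the default synthetic study.

    Plants ``n_known`` loci seeded from a generated reference catalog (three
    of them with 1-2 substitutions versus their reference entry) and
    ``n_novel`` reference-free loci (including one pair within 2 mismatches,
    forming a novel family); ``n_responsive`` loci are down-regulated by
    ``hs_fold_change`` under heat stress in both tissues and timepoints.
    """
    rng = np.random.default_rng(seed)
    genome, chrom = simulate_genome(genome_length, gc, seed)

    n_loci = n_known + n_novel
    # mature sequences: mutually distant (>=4 mismatches) random 20-22mers
    matures: list[str] = []
    while len(matures) < n_loci:
        m = _random_seq(rng, int(rng.integers(20, 23)))
        if m.count("A") / len(m) >= 0.7:
            continue
        if _hamming_min(m, matures) < 4:
            continue
        if genome.find(m) >= 0 or genome.find(revcomp(m)) >= 0:
            continue
        matures.append(m)
    # one novel family pair: replace the last novel mature with a 2-mismatch
    # variant of the preceding one
    fam_src = matures[n_known + 0]
    variant = list(fam_src)
    pos = rng.choice(len(fam_src) - 4, size=2, replace=False) + 2
    for p in pos:
        old = variant[p]
        choices = [b for b in "ACGT" if b != old]
        variant[p] = choices[int(rng.integers(0, 3))]
    matures[n_loci - 1] = "".join(variant)

    # reference catalog: the known matures (with decoys) under miRBase-style
    # names; three planted matures deviate from their reference by 1-2 nt
    reference: dict[str, str] = {}
    known_planted: list[str] = []
    for i in range(n_known):
        fam = _KNOWN_FAMILIES[i % len(_KNOWN_FAMILIES)]
        name = f"sly-{fam}{'abcdef'[i // len(_KNOWN_FAMILIES)]} {fam}"
        ref_seq = matures[i]
        planted = ref_seq
        if i < 3:  # mismatched known members exercise the <=2-mismatch rule
            planted = list(ref_seq)
            for p in rng.choice(len(ref_seq) - 2, size=min(i + 1, 2), replace=False) + 1:
                choices = [b for b in "ACGT" if b != planted[p]]
                planted[p] = choices[int(rng.integers(0, 3))]
            planted = "".join(planted)
        reference[name] = ref_seq
        known_planted.append(planted)
        matures[i] = planted
    for j in range(10):  # decoy reference entries not planted anywhere
        while True:
            d = _random_seq(rng, 21)
            if _hamming_min(d, matures) >= 4 and genome.find(d) < 0:
                break
        reference[f"sly-miR{7000 + j}a miR{7000 + j}"] = d

    # plant hairpins at spaced positions, a few on the minus strand
    positions = np.sort(rng.choice(genome_length // 700 - 2, size=n_loci, replace=False))
    hairpins: list[PlantedHairpin] = []
    known_loci, novel_loci = [], []
    for i, m in enumerate(matures):
        pos = int(positions[i]) * 700 + 400
        arm = "5p" if i % 2 == 0 else "3p"
        strand = "-" if i % 7 == 3 else "+"
        lid = f"known_{i:02d}" if i < n_known else f"novel_{i - n_known:02d}"
        genome, hp = plant_hairpin(
            genome,
            m,
            pos,
            arm,
            int(rng.integers(0, 2**31)),
            chrom=chrom,
            strand=strand,
            locus_id=lid,
            existing=hairpins,
        )
        hairpins.append(hp)
        (known_loci if i < n_known else novel_loci).append(lid)

    contaminants = _default_contaminants(rng)

    designs = default_designs(depth=depth)
    truth = build_truth(
        hairpins,
        designs,
        seed=int(rng.integers(0, 2**31)),
        n_responsive=n_responsive,
        n_stamen_specific=n_stamen_specific,
        hs_fold_change=hs_fold_change,
        tpm_range=tpm_range,
    )
    responsive = sorted({k[0] for k, fc in truth.true_fc.items() if fc != 1.0})

    # target transcripts: perfect complementary sites for a few planted
    # miRNAs, plus site-free decoys
    transcripts: dict[str, str] = {}
    planted_sites: list[dict] = []
    targeted = hairpins[:4] + hairpins[n_known : n_known + 2]
    for i, hp in enumerate(targeted):
        body = _random_seq(rng, 400)
        pos = 150 + 7 * i
        site = revcomp(hp.mature_seq)
        tseq = body[:pos] + site + body[pos:]
        tid = f"transcript_{i + 1:02d}"
        transcripts[tid] = tseq
        planted_sites.append(
            {"locus_id": hp.locus_id, "transcript_id": tid, "site_start0": pos}
        )
    for j in range(2):
        transcripts[f"decoy_{j + 1:02d}"] = _random_seq(rng, 420)

    return SyntheticDataset(
        genome=genome,
        chrom=chrom,
        hairpins=hairpins,
        truth=truth,
        designs=designs,
        reference=reference,
        contaminants=contaminants,
        known_loci=known_loci,
        novel_loci=novel_loci,
        responsive_loci=responsive,
        transcripts=transcripts,
        planted_sites=planted_sites,
    )


def _default_contaminants(rng: np.random.Generator) -> dict[str, str]:
    """Synthetic stand-ins for the Rfam-style contaminant classes."""
    cont = {}
    for i in range(2):
        cont[f"rRNA_{i + 1} synthetic ribosomal RNA"] = _random_seq(rng, 1800)
    for i in range(4):
        cont[f"tRNA_{i + 1} synthetic transfer RNA"] = _random_seq(rng, 82)
    for i in range(2):
        cont[f"snoRNA_{i + 1} synthetic snoRNA"] = _random_seq(rng, 130)
    cont["snRNA_1 synthetic snRNA"] = _random_seq(rng, 160)
    return cont


def build_truth(
    hairpins: list[PlantedHairpin],
    designs: list[LibraryDesign],
    seed: int,
    *,
    n_responsive: int = 10,
    n_stamen_specific: int = 2,
    hs_fold_change: float = DEFAULT_HS_FOLD_CHANGE,
    tpm_range: tuple[float, float] = (50.0, 2000.0),
) -> ExpressionTruth:
    """Draw per-locus baseline TPM (log-uniform) and apply the heat-stress
    down-regulation to the responsive loci in every HS library."""
    rng = np.random.default_rng(seed)
    lo, hi = tpm_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(hairpins)))
    order = rng.permutation(len(hairpins))
    responsive = set(order[:n_responsive])
    specific = set(order[n_responsive : n_responsive + n_stamen_specific])
    expected: dict[tuple[str, str], float] = {}
    true_fc: dict[tuple[str, str, str], float] = {}
    for i, h in enumerate(hairpins):
        for d in designs:
            tpm = float(base[i])
            if i in specific and d.tissue == "pistil":
                tpm = 0.0
            if i in responsive and d.condition == "HS":
                tpm *= hs_fold_change
            expected[(h.locus_id, d.library_id)] = tpm
        for tissue in _TISSUES:
            for tp in _TIMEPOINTS:
                fc = hs_fold_change if i in responsive else 1.0
                true_fc[(h.locus_id, tissue, tp)] = fc
    return ExpressionTruth(expected_tpm=expected, true_fc=true_fc)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path, seed: int) -> dict[str, Path]:
    """Write genome/reference/contaminants FASTA, loci GFF3, per-library
    FASTQ and the truth table under ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = simulate_libraries(
        dataset.genome,
        dataset.hairpins,
        dataset.truth,
        dataset.designs,
        seed,
        outdir,
        contaminants=dataset.contaminants,
    )
    genome_fa = outdir / "genome.fasta"
    write_fasta(genome_fa, {dataset.chrom: dataset.genome})
    paths["genome"] = genome_fa
    ref_fa = outdir / "reference_mirnas.fasta"
    write_fasta(ref_fa, dataset.reference)
    paths["reference"] = ref_fa
    cont_fa = outdir / "contaminants.fasta"
    write_fasta(cont_fa, dataset.contaminants)
    paths["contaminants"] = cont_fa
    gff = outdir / "planted_loci.gff3"
    write_loci_gff3(dataset.hairpins, gff)
    paths["loci"] = gff
    tx_fa = outdir / "transcripts.fasta"
    write_fasta(tx_fa, dataset.transcripts)
    paths["transcripts"] = tx_fa
    return paths
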