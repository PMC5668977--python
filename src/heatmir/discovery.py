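"""miRNA discovery: exact genome mapping, precursor excision and folding,
stem-loop criteria, known/novel classification and family grouping.

Mapping is native exact search (k-mer seeded); the perfect-match
constraint makes an aligner unnecessary and keeps the mapper checkable
against a naive full-scan.  Hairpin thresholds follow canonical plant
miRNA annotation practice (mature on one arm outside the terminal loop,
<= 4 unpaired mature bases in the duplex, no asymmetric bulge > 2 nt) and
are all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import read_fasta, revcomp, to_dna, to_rna
from .fold import fold_rna, pair_table

DEFAULT_FLANK = 200
DEFAULT_MIN_TPM = 10.0
DEFAULT_LEN_RANGE = (18, 30)
DEFAULT_MAX_HITS = 20
DEFAULT_MFE_MAX = -16.0  # kcal/mol; just above the least stable precursors
                         # reported for plant pre-miRNAs


@dataclass(frozen=True, order=True)
class GenomeHit:
    chrom: str
    start0: int
    end0: int
    strand: str


@dataclass
class PrecursorCandidate:
    """An excised genomic window with its fold and mature/star placement."""

    hit: GenomeHit
    wstart0: int
    wend0: int
    sequence: str  # RNA, strand-oriented
    dotbracket: str
    mfe: float
    mature_offset: int
    mature_len: int
    star_offset: int | None = None


@dataclass
class MiRNARecord:
    name: str
    mature_seq: str  # DNA T-form
    status: str  # known | novel
    family: str | None
    mismatches_to_ref: int | None
    precursor: PrecursorCandidate
    expression: dict[str, float] = field(default_factory=dict)
    star_seq: str | None = None
    star_supported: bool = False


@dataclass
class HairpinCriteria:
    max_unpaired_mature: int = 4
    max_bulge: int = 2
    require_arm_ge_mature: bool = True


@dataclass
class Verdict:
    passed: bool
    reasons: list[str]


# ---------------------------------------------------------------------------
# exact mapping
# ---------------------------------------------------------------------------


class KmerIndex:
    """Exact-match index over a genome: k-mer seeds verified by extension."""

    def __init__(self, chroms: dict[str, str], k: int = 12):
        self.k = k
        self.chroms = {name: seq.upper() for name, seq in chroms.items()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(self.chroms):
            seq = self.chroms[name]
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((name, i))

    def find(self, tag: str) -> list[GenomeHit]:
        tag = tag.upper()
        if len(tag) < self.k:
            raise ValueError(f"tag shorter than index k={self.k}")
        hits = []
        for query, strand in ((tag, "+"), (revcomp(tag), "-")):
            for chrom, pos in self._index.get(query[: self.k], ()):
                if self.chroms[chrom][pos : pos + len(query)] == query:
                    hits.append(GenomeHit(chrom, pos, pos + len(query), strand))
        hits.sort(key=lambda h: (h.chrom, h.start0, h.strand))
        return hits


def map_exact(
    tags, genome: dict[str, str] | str, k: int = 12
) -> dict[str, list[GenomeHit]]:
    """Map each tag (both strands) to all its perfect-match genome positions.

    ``genome`` is a chrom->sequence dict or a single sequence (named chr1).
    Hit order is deterministic: (chrom, start, strand).
    """
    chroms = genome if isinstance(genome, dict) else {"chr1": genome}
    index = KmerIndex(chroms, k=k)
    return {tag: index.find(tag) for tag in tags}


def select_candidates(
    tpm: pd.DataFrame,
    hit_map: dict[str, list[GenomeHit]],
    min_tpm: float = DEFAULT_MIN_TPM,
    len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
    max_hits: int = DEFAULT_MAX_HITS,
) -> list[str]:
    """Tags kept for discovery: peak TPM >= min_tpm in at least one library,
    length within range, and 1..max_hits unique genome hits."""
    lo, hi = len_range
    kept = []
    peak = tpm.max(axis=1)
    for tag in tpm.index:
        if not lo <= len(tag) <= hi:
            continue
        if peak[tag] < min_tpm:
            continue
        hits = hit_map.get(tag, [])
        if 1 <= len(hits) <= max_hits:
            kept.append(tag)
    return kept


def prefilter_tags(
    tpm: pd.DataFrame,
    min_tpm: float = DEFAULT_MIN_TPM,
    len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
) -> list[str]:
    """Cheap abundance/length screen applied before genome mapping."""
    lo, hi = len_range
    lens = tpm.index.str.len()
    mask = (lens >= lo) & (lens <= hi) & (tpm.max(axis=1) >= min_tpm)
    return list(tpm.index[mask])


# ---------------------------------------------------------------------------
# precursor excision and folding
# ---------------------------------------------------------------------------


def extract_precursor(
    hit: GenomeHit, chroms: dict[str, str], flank: int = DEFAULT_FLANK
) -> tuple[str, int, int, int]:
    """Excise the window [start-flank, end+flank) around a hit, clipped at
    chromosome ends; minus-strand windows are reverse-complemented.

    Returns (window RNA sequence, wstart0, wend0, mature offset in the
    strand-oriented window).
    """
    seq = chroms[hit.chrom]
    ws = max(0, hit.start0 - flank)
    we = min(len(seq), hit.end0 + flank)
    window = seq[ws:we].upper()
    if hit.strand == "-":
        window = revcomp(window)
        offset = we - hit.end0
    else:
        offset = hit.start0 - ws
    return to_rna(window), ws, we, offset


def make_candidate(
    hit: GenomeHit,
    chroms: dict[str, str],
    flank: int = DEFAULT_FLANK,
    engine: str = "builtin",
) -> PrecursorCandidate:
    window, ws, we, offset = extract_precursor(hit, chroms, flank)
    db, mfe = fold_rna(window, engine=engine)
    cand = PrecursorCandidate(
        hit=hit,
        wstart0=ws,
        wend0=we,
        sequence=window,
        dotbracket=db,
        mfe=mfe,
        mature_offset=offset,
        mature_len=hit.end0 - hit.start0,
    )
    cand.star_offset = infer_star(db, offset, cand.mature_len)
    return cand


# ---------------------------------------------------------------------------
# hairpin criteria
# ---------------------------------------------------------------------------


def _hairpin_loops(pt: np.ndarray) -> list[tuple[int, int]]:
    """(x, y) pairs that enclose no other pair: the terminal loops."""
    loops = []
    for x in range(len(pt)):
        y = pt[x]
        if y > x and all(pt[z] < 0 for z in range(x + 1, y)):
            loops.append((x, y))
    return loops


def evaluate_hairpin_structure(
    dotbracket: str,
    mature_offset: int,
    mature_len: int,
    criteria: HairpinCriteria | None = None,
) -> Verdict:
    """Apply the stem-loop criteria to a folded window.

    Failure reasons: ``mature_in_loop`` (mature pairs with itself, pairs to
    both sides, or overlaps a terminal loop), ``too_many_mispairs``,
    ``asymmetric_bulge``, ``short_arm``.
    """
    criteria = criteria or HairpinCriteria()
    pt = pair_table(dotbracket)
    a, b = mature_offset, mature_offset + mature_len
    mature = range(a, b)
    reasons: list[str] = []

    paired = [i for i in mature if pt[i] >= 0]
    unpaired = mature_len - len(paired)
    if unpaired > criteria.max_unpaired_mature:
        reasons.append("too_many_mispairs")
    if not paired:
        reasons.append("mature_in_loop")
        return Verdict(False, reasons)

    partners = [int(pt[i]) for i in paired]
    if any(a <= p < b for p in partners):
        reasons.append("mature_in_loop")
    elif min(partners) < a and max(partners) >= b:
        reasons.append("mature_in_loop")
    else:
        for x, y in _hairpin_loops(pt):
            if x + 1 < b and a < y:  # mature overlaps (x, y) exclusive
                if max(a, x + 1) < min(b, y):
                    reasons.append("mature_in_loop")
                    break

    for (i1, i2) in zip(paired, paired[1:]):
        g_m = i2 - i1 - 1
        g_s = abs(int(pt[i1]) - int(pt[i2])) - 1
        if abs(g_m - g_s) > criteria.max_bulge:
            reasons.append("asymmetric_bulge")
            break

    if criteria.require_arm_ge_mature and "mature_in_loop" not in reasons:
        arm5 = partners[0] > paired[0]  # partners downstream => mature on 5' arm
        if arm5:
            i_star, p_star = paired[-1], int(pt[paired[-1]])
            xs = [x for x in range(0, i_star + 1) if pt[x] >= p_star]
            arm_len = i_star - min(xs) + 1 if xs else 0
        else:
            i_star, p_star = paired[0], int(pt[paired[0]])
            ys = [y for y in range(i_star, len(pt)) if 0 <= pt[y] <= p_star]
            arm_len = max(ys) - i_star + 1 if ys else 0
        if arm_len < mature_len:
            reasons.append("short_arm")

    return Verdict(not reasons, reasons)


def evaluate_hairpin(
    candidate: PrecursorCandidate, criteria: HairpinCriteria | None = None
) -> Verdict:
    return evaluate_hairpin_structure(
        candidate.dotbracket, candidate.mature_offset, candidate.mature_len, criteria
    )


def infer_star(
    dotbracket: str,
    mature_offset: int,
    mature_len: int,
    min_paired_to_mature: float = 0.5,
) -> int | None:
    """Locate the star: the mature-length interval on the opposite arm
    offset so that both duplex ends carry 2-nt 3' overhangs.

    Extrapolates from the 3'-most paired mature base along the duplex
    antidiagonal; returns the star offset or None when no credible star
    placement exists.
    """
    pt = pair_table(dotbracket)
    a, b = mature_offset, mature_offset + mature_len
    paired = [i for i in range(a, b) if pt[i] >= 0 and not a <= pt[i] < b]
    if not paired:
        return None
    x = paired[-1]  # paired mature base closest to the mature 3' end
    star_start = int(pt[x]) - ((b - 1) - x) + 2
    if star_start < 0 or star_start + mature_len > len(pt):
        return None
    star = range(star_start, star_start + mature_len)
    if max(a, star_start) < min(b, star_start + mature_len):
        return None  # overlaps the mature itself
    n_to_mature = sum(1 for s in star if pt[s] >= 0 and a <= pt[s] < b)
    if n_to_mature < min_paired_to_mature * mature_len:
        return None
    return star_start


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _sliding_mismatches(query: str, ref: str, max_shift: int = 2) -> int:
    """Ungapped distance: substitutions in the best overlap plus overhang
    bases, minimised over slides of up to max_shift positions."""
    best = 10**9
    for shift in range(-max_shift, max_shift + 1):
        # query[i] aligns ref[i + shift]
        lo = max(0, -shift)
        hi = min(len(query), len(ref) - shift)
        if hi - lo <= 0:
            continue
        subs = sum(1 for i in range(lo, hi) if query[i] != ref[i + shift])
        overhang = (len(query) - (hi - lo)) + (len(ref) - (hi - lo))
        best = min(best, subs + overhang)
    return best


def classify_known(
    mature_seq: str,
    reference: dict[str, str] | str,
    max_mismatches: int = 2,
) -> tuple[str, str | None, int] | None:
    """Best reference match within ``max_mismatches`` or None.

    ``reference`` maps FASTA headers ("name [family]") to mature sequences;
    comparison is ungapped with up to 2-nt slide, overhangs counted as
    mismatches.  Ties break on fewest mismatches then lexicographic name.
    """
    if isinstance(reference, str):
        reference = read_fasta(reference)
    if not reference:
        raise ValueError("reference mature catalog is empty")
    query = to_dna(mature_seq)
    best: tuple[int, str, str | None] | None = None
    for header in sorted(reference):
        ref_seq = to_dna(reference[header])
        if abs(len(ref_seq) - len(query)) > 2:
            continue
        mm = _sliding_mismatches(query, ref_seq)
        if mm > max_mismatches:
            continue
        tokens = header.split()
        name, family = tokens[0], tokens[1] if len(tokens) > 1 else None
        key = (mm, name, family)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    mm, name, family = best
    return name, family, mm


@dataclass
class NovelVerdict:
    is_novel: bool
    reasons: list[str]
    star_seq: str | None = None
    star_supported: bool = False


def validate_novel(
    candidate: PrecursorCandidate,
    tag_sequences=(),
    mfe_max: float = DEFAULT_MFE_MAX,
) -> NovelVerdict:
    """Novel iff the precursor is stable enough (mfe <= mfe_max) and a star
    placement with 2-nt 3' overhangs exists on the opposite arm;
    star_supported is set when a sequenced tag matches the star exactly."""
    reasons = []
    if candidate.mfe > mfe_max:
        reasons.append("mfe_above_threshold")
    star_off = candidate.star_offset
    if star_off is None:
        star_off = infer_star(
            candidate.dotbracket, candidate.mature_offset, candidate.mature_len
        )
    star_seq = None
    if star_off is None:
        reasons.append("no_star_placement")
    else:
        star_seq = to_dna(
            candidate.sequence[star_off : star_off + candidate.mature_len]
        )
    supported = star_seq is not None and star_seq in set(tag_sequences)
    return NovelVerdict(
        is_novel=not reasons,
        reasons=reasons,
        star_seq=star_seq,
        star_supported=supported,
    )


def group_families(
    records: list[MiRNARecord], max_mismatch: int = 3
) -> dict[str, list[MiRNARecord]]:
    """Single-linkage grouping of novel matures by sliding ungapped distance.

    Multi-member groups get deterministic ids (fam-01, ...) assigned by the
    lexicographically first member name and written onto the records'
    ``family``; singletons keep family None.
    """
    if not records:
        raise ValueError("no records to group")
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = _sliding_mismatches(
                records[i].mature_seq, records[j].mature_seq, max_shift=2
            )
            if d <= max_mismatch:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[MiRNARecord]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(records[i])
    multi = [c for c in clusters.values() if len(c) > 1]
    multi.sort(key=lambda c: min(r.name for r in c))
    groups: dict[str, list[MiRNARecord]] = {}
    for gi, cluster in enumerate(multi, 1):
        fam = f"fam-{gi:02d}"
        for r in cluster:
            r.family = fam
        groups[fam] = cluster
    return groups


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class DiscoveryResult:
    records: list[MiRNARecord]
    n_prefiltered: int
    n_candidates: int
    n_hairpin_pass: int
    n_absorbed: int
    families: dict[str, list[MiRNARecord]]

    @property
    def known(self) -> list[MiRNARecord]:
        return [r for r in self.records if r.status == "known"]

    @property
    def novel(self) -> list[MiRNARecord]:
        return [r for r in self.records if r.status == "novel"]


def discover_mirnas(
    tpm: pd.DataFrame,
    genome: dict[str, str] | str,
    reference: dict[str, str] | str,
    *,
    min_tpm: float = DEFAULT_MIN_TPM,
    len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
    max_hits: int = DEFAULT_MAX_HITS,
    flank: int = DEFAULT_FLANK,
    mfe_max: float = DEFAULT_MFE_MAX,
    criteria: HairpinCriteria | None = None,
    engine: str = "builtin",
    locus_margin: int = 220,
) -> DiscoveryResult:
    """Run the discovery stage over a tag TPM matrix.

    Precedence: a candidate within 2 mismatches of the reference catalog is
    always classified known and never enters the novel path.

    Dominant-read rule: candidates are processed in descending peak-TPM
    order, and a candidate whose only hits fall within the hairpin locus of
    an already-accepted record (its mature position +/- ``locus_margin``)
    is absorbed as a fragment of that locus — this is what keeps star-arm
    and loop degradation reads from being annotated as separate miRNAs.
    """
    chroms = genome if isinstance(genome, dict) else {"chr1": genome}
    if isinstance(reference, str):
        reference = read_fasta(reference)
    criteria = criteria or HairpinCriteria()

    pre = prefilter_tags(tpm, min_tpm=min_tpm, len_range=len_range)
    hit_map = map_exact(pre, chroms)
    candidates = select_candidates(
        tpm, hit_map, min_tpm=min_tpm, len_range=len_range, max_hits=max_hits
    )
    all_tags = set(tpm.index)
    peak_tpm = tpm.max(axis=1)
    candidates.sort(key=lambda t: (-peak_tpm[t], t))

    accepted: list[MiRNARecord] = []
    seen_precursors: set[str] = set()
    n_pass = 0
    n_absorbed = 0
    for tag in candidates:
        free_hits = [
            hit
            for hit in hit_map[tag]
            if not any(
                _same_locus(kept.precursor.hit, hit, locus_margin)
                for kept in accepted
            )
        ]
        if not free_hits:
            n_absorbed += 1
            continue
        best_cand: PrecursorCandidate | None = None
        for hit in free_hits:
            cand = make_candidate(hit, chroms, flank=flank, engine=engine)
            if not evaluate_hairpin(cand, criteria).passed:
                continue
            if cand.sequence in seen_precursors:
                continue  # duplicate precursor; keep the first coordinate
            seen_precursors.add(cand.sequence)
            if best_cand is None or cand.mfe < best_cand.mfe:
                best_cand = cand
        if best_cand is None:
            continue
        n_pass += 1
        match = classify_known(tag, reference)
        expr = {lib: float(v) for lib, v in tpm.loc[tag].items()}
        nv = validate_novel(best_cand, all_tags, mfe_max=mfe_max)
        if match is not None:
            name, family, mm = match
            record = MiRNARecord(
                name=name,
                mature_seq=tag,
                status="known",
                family=family,
                mismatches_to_ref=mm,
                precursor=best_cand,
                expression=expr,
                star_seq=nv.star_seq,
                star_supported=nv.star_supported,
            )
        else:
            if not nv.is_novel:
                continue
            record = MiRNARecord(
                name="",  # assigned below, in coordinate order
                mature_seq=tag,
                status="novel",
                family=None,
                mismatches_to_ref=None,
                precursor=best_cand,
                expression=expr,
                star_seq=nv.star_seq,
                star_supported=nv.star_supported,
            )
        accepted.append(record)

    accepted.sort(key=lambda r: r.precursor.hit)
    novel = [r for r in accepted if r.status == "novel"]
    for i, r in enumerate(novel, 1):
        r.name = f"pc-{i}"
    seen: dict[str, int] = {}
    for r in accepted:  # distinct loci may share a reference name
        n = seen.get(r.name, 0) + 1
        seen[r.name] = n
        if n > 1:
            r.name = f"{r.name}-{n}"
    families = group_families(novel) if novel else {}
    return DiscoveryResult(
        records=accepted,
        n_prefiltered=len(pre),
        n_candidates=len(candidates),
        n_hairpin_pass=n_pass,
        n_absorbed=n_absorbed,
        families=families,
    )


def _same_locus(kept: GenomeHit, hit: GenomeHit, margin: int) -> bool:
    """Does ``hit`` fall within the hairpin locus around an accepted mature?
    ``margin`` bounds the stem extent on each side of the mature position."""
    return (
        kept.chrom == hit.chrom
        and hit.start0 < kept.end0 + margin
        and kept.start0 - margin < hit.end0
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def catalog_table(records: list[MiRNARecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        h = r.precursor.hit
        row = {
            "name": r.name,
            "status": r.status,
            "family": r.family or "",
            "mature_seq": r.mature_seq,
            "mismatches_to_ref": "" if r.mismatches_to_ref is None else r.mismatches_to_ref,
            "chrom": h.chrom,
            "start0": h.start0,
            "end0": h.end0,
            "strand": h.strand,
            "mfe": round(r.precursor.mfe, 2),
            "star_seq": r.star_seq or "",
            "star_supported": r.star_supported,
        }
        row.update({f"tpm_{lib}": round(v, 3) for lib, v in r.expression.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_precursor_gff3(records: list[MiRNARecord], path) -> None:
    """Precursor windows and mature positions, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            p = r.precursor
            fh.write(
                f"{p.hit.chrom}\theatmir\tmiRNA_primary_transcript\t"
                f"{p.wstart0 + 1}\t{p.wend0}\t.\t{p.hit.strand}\t.\t"
                f"ID={r.name};status={r.status}\n"
            )
            fh.write(
                f"{p.hit.chrom}\theatmir\tmiRNA\t{p.hit.start0 + 1}\t{p.hit.end0}"
                f"\t.\t{p.hit.strand}\t.\tID={r.name}.mature;Parent={r.name}\n"
            )


def write_precursor_fasta(records: list[MiRNARecord], path) -> None:
    """Precursor sequences with the dot-bracket and mfe in the description."""
    with open(path, "w") as fh:
        for r in records:
            p = r.precursor
            fh.write(f">{r.name} {p.dotbracket} mfe={p.mfe:.2f}\n{p.sequence}\n")
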