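"""Raw FASTQ -> distinct clean tags with per-library counts and TPM.

Stages: 3' adapter trimming, length/N/poly(A) filtering, per-library tag
collapsing, contaminant (rRNA/tRNA/sno/snRNA) removal by exact substring
match, and TPM normalisation against per-library clean totals.  Read
accounting is exact at every stage: raw = kept + discarded by reason.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import read_fasta, revcomp

#: leading bases of the 3' adapter that must match exactly inside a read
ADAPTER_SEED_K = 8
#: minimum adapter prefix accepted at the extreme 3' end of a read
ADAPTER_MIN_TERMINAL = 5
#: fraction of A residues above which an insert is discarded as poly(A)
POLYA_FRACTION = 0.8


@dataclass
class CleanTag:
    """A distinct clean sRNA sequence with per-library counts and TPM."""

    sequence: str
    counts: dict[str, int]
    tpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.counts and not any(c > 0 for c in self.counts.values()):
            raise ValueError(f"tag {self.sequence} has no positive count")


@dataclass
class LibraryStats:
    library_id: str
    raw_reads: int = 0
    after_trim_filter: int = 0
    contaminant_reads: int = 0
    clean_reads: int = 0
    unique_tags: int = 0
    discarded: dict[str, int] = field(default_factory=dict)


def trim_read(
    read: str,
    adapter3: str,
    seed_k: int = ADAPTER_SEED_K,
    min_terminal: int = ADAPTER_MIN_TERMINAL,
) -> str | None:
    """Insert before the leftmost adapter occurrence, or None if no adapter.

    A match is the exact first ``seed_k`` adapter bases anywhere in the
    read, or a terminal adapter prefix of at least ``min_terminal`` bases
    flush with the 3' end.
    """
    seed = adapter3[: min(seed_k, len(adapter3))]
    i = read.find(seed)
    if i >= 0:
        return read[:i]
    for L in range(min(len(adapter3), len(read), seed_k - 1), min_terminal - 1, -1):
        if read.endswith(adapter3[:L]):
            return read[: len(read) - L]
    return None


def trim_and_filter(
    reads,
    adapter3: str,
    min_len: int = 15,
    max_len: int = 40,
    polya_filter: bool = True,
) -> tuple[list[str], dict[str, int]]:
    """Trim the 3' adapter and apply length/N/poly(A) filters.

    Returns (clean insert sequences, counts of discarded reads by reason:
    no_adapter, too_short, too_long, contains_n, poly_a).
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    adapter = adapter3.upper()
    seed = adapter[:ADAPTER_SEED_K]
    kept: list[str] = []
    discarded: Counter[str] = Counter()
    polya_cut = POLYA_FRACTION
    for read in reads:
        read = read.upper()
        i = read.find(seed)  # fast path: full seed occurs in the read
        if i < 0:
            insert = trim_read(read, adapter)
            if insert is None:
                discarded["no_adapter"] += 1
                continue
        else:
            insert = read[:i]
        n = len(insert)
        if n < min_len:
            discarded["too_short"] += 1
            continue
        if n > max_len:
            discarded["too_long"] += 1
            continue
        if "N" in insert:
            discarded["contains_n"] += 1
            continue
        if polya_filter and insert.count("A") >= polya_cut * n:
            discarded["poly_a"] += 1
            continue
        kept.append(insert)
    return kept, dict(discarded)


def collapse_tags(reads_by_library: dict[str, list[str] | Counter]) -> pd.DataFrame:
    """Collapse clean reads to distinct tags.

    Returns a counts DataFrame indexed by tag sequence with one column per
    library; column sums equal the per-library clean read counts.
    """
    columns = {}
    for lib, reads in reads_by_library.items():
        counter = reads if isinstance(reads, Counter) else Counter(reads)
        columns[lib] = pd.Series(counter, dtype="int64")
    df = pd.DataFrame(columns).fillna(0).astype("int64")
    df.index.name = "sequence"
    return df.sort_index()


def filter_contaminants(
    counts: pd.DataFrame, contaminant_fasta: str | Path | dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Remove tags occurring as exact substrings of any contaminant
    sequence or its reverse complement.

    The contaminant class of a removed tag is the first token prefix of the
    matching FASTA header (e.g. ``tRNA_3`` -> class ``tRNA``).

    Returns (kept counts, removed counts, per-class removed read counts
    with classes as rows and libraries as columns).
    """
    if isinstance(contaminant_fasta, (str, Path)):
        contaminants = read_fasta(contaminant_fasta)
    else:
        contaminants = contaminant_fasta
    lengths = sorted({len(t) for t in counts.index})
    # enumerate every contaminant window (both strands) of a tag length once;
    # exact-substring matching then reduces to hash lookups
    window_class: dict[str, str] = {}
    for name in contaminants:
        cls = name.split("_")[0].split()[0]
        seq = contaminants[name].upper()
        for strand_seq in (seq, revcomp(seq)):
            for L in lengths:
                for i in range(0, len(strand_seq) - L + 1):
                    window_class.setdefault(strand_seq[i : i + L], cls)
    hit = counts.index.map(window_class.get)
    removed_mask = hit.notna()
    kept = counts.loc[~removed_mask]
    removed = counts.loc[removed_mask]
    by_class = (
        removed.groupby(pd.Index(hit[removed_mask], name="class")).sum()
        if removed_mask.any()
        else pd.DataFrame(columns=counts.columns)
    )
    return kept, removed, by_class


def tpm_normalize(counts: pd.DataFrame, clean_totals: pd.Series) -> pd.DataFrame:
    """counts / clean_total x 1e6 per library; totals must be positive."""
    for lib in counts.columns:
        total = clean_totals.get(lib, 0)
        if total <= 0:
            raise ZeroDivisionError(f"library {lib!r} has zero clean total")
    return counts.div(clean_totals[counts.columns], axis=1) * 1e6


@dataclass
class PreprocessResult:
    counts: pd.DataFrame  # kept tags x libraries, raw counts
    tpm: pd.DataFrame
    stats: list[LibraryStats]
    removed_by_class: pd.DataFrame
    clean_totals: pd.Series


def read_fastq_sequences(path: str | Path):
    """Yield read sequences from a FASTQ file."""
    with open(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq


def _read_fastq_bulk(path: str | Path) -> list[str]:
    """Sequence lines of a FASTQ file, loaded in one pass."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ (line count not divisible by 4)")
    return lines[1::4]


def preprocess_libraries(
    fastq_map: dict[str, str | Path],
    adapter3: str,
    contaminant_fasta: str | Path | dict[str, str] | None = None,
    min_len: int = 15,
    max_len: int = 40,
    polya_filter: bool = True,
) -> PreprocessResult:
    """Run the full preprocessing stage for a set of libraries."""
    reads_by_library: dict[str, Counter] = {}
    stats: list[LibraryStats] = []
    for lib, path in fastq_map.items():
        seqs = _read_fastq_bulk(path)
        raw = len(seqs)
        kept, discarded = trim_and_filter(
            seqs, adapter3, min_len=min_len, max_len=max_len,
            polya_filter=polya_filter,
        )
        reads_by_library[lib] = Counter(kept)
        stats.append(
            LibraryStats(
                library_id=lib,
                raw_reads=raw,
                after_trim_filter=len(kept),
                discarded=discarded,
            )
        )
    counts = collapse_tags(reads_by_library)
    if contaminant_fasta is not None:
        kept_counts, removed_counts, by_class = filter_contaminants(
            counts, contaminant_fasta
        )
    else:
        kept_counts = counts
        removed_counts = counts.iloc[0:0]
        by_class = pd.DataFrame(columns=counts.columns)
    clean_totals = kept_counts.sum(axis=0)
    removed_totals = removed_counts.sum(axis=0)
    for st in stats:
        st.contaminant_reads = int(removed_totals.get(st.library_id, 0))
        st.clean_reads = int(clean_totals.get(st.library_id, 0))
        st.unique_tags = int((kept_counts[st.library_id] > 0).sum())
    tpm = tpm_normalize(kept_counts, clean_totals)
    return PreprocessResult(
        counts=kept_counts,
        tpm=tpm,
        stats=stats,
        removed_by_class=by_class,
        clean_totals=clean_totals,
    )


def stats_table(stats: list[LibraryStats]) -> pd.DataFrame:
    """Per-library read accounting, one row per statistic (library columns),
    mirroring the usual sequencing-statistics table layout."""
    rows = {
        "Raw reads": {s.library_id: s.raw_reads for s in stats},
        "Adapter & length filter": {s.library_id: s.after_trim_filter for s in stats},
        "Contaminant reads": {s.library_id: s.contaminant_reads for s in stats},
        "Clean reads": {s.library_id: s.clean_reads for s in stats},
        "Unique tags": {s.library_id: s.unique_tags for s in stats},
    }
    return pd.DataFrame(rows).T
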