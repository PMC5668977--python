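"""miRNA target prediction with a plant-style expectation penalty, cleavage
position mapping, and RACE clone tallying.

The scoring scheme is the Allen-style scheme used throughout plant target
prediction: per miRNA position (counted from the miRNA 5' end) a mismatch
costs 1.0, a G:U wobble 0.5 and a gap 2.0, and every penalty is doubled in
the seed region (miRNA positions 2-13).  Sites at or below the expectation
cutoff (default 3.0) are reported.  A site whose positions 9-11 pair
cleanly is a cleavage site; the guided cut falls opposite the miRNA 10/11
bond and is recorded as the 0-based transcript index of the base opposite
miRNA position 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import read_fasta, to_rna

DEFAULT_CUTOFF = 3.0
SEED_START, SEED_END = 2, 13  # miRNA positions with doubled penalties
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass
class TargetSite:
    """A scored miRNA-transcript duplex."""

    mirna: str  # miRNA name or sequence label
    mirna_seq: str  # RNA, 5'->3'
    transcript_id: str
    start0: int  # target span on the transcript, 0-based half-open
    end0: int
    expectation: float
    alignment: str  # three rows: target 5'->3', pairing, miRNA 3'->5'
    mode: str  # cleavage | translational
    cleavage_pos0: int | None = None
    # miRNA position (1-based) -> transcript index, for paired positions
    pairing: dict[int, int] = field(default_factory=dict, repr=False)


@dataclass
class RaceTally:
    site: TargetSite
    n_clones: int
    positions: list[int]
    at_site: int
    secondary_peaks: dict[int, int] = field(default_factory=dict)


def _penalty(mi_base: str, t_base: str) -> tuple[float, str]:
    """(penalty, pairing symbol) for one opposed base pair."""
    key = (mi_base, t_base)
    if key in _WC:
        return 0.0, "|"
    if key in _WOBBLE:
        return WOBBLE_PENALTY, "o"
    return MISMATCH_PENALTY, " "


def _seed_factor(pos: int) -> float:
    return 2.0 if SEED_START <= pos <= SEED_END else 1.0


_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}
# penalty lookup [mirna_base, target_base]; column 4 = unknown base (mismatch)
_PENTAB = np.full((4, 5), MISMATCH_PENALTY)
for (_mi, _t) in _WC:
    _PENTAB[_ENC[_mi], _ENC[_t]] = 0.0
for (_mi, _t) in _WOBBLE:
    _PENTAB[_ENC[_mi], _ENC[_t]] = WOBBLE_PENALTY


def _encode_rna(seq: str, strict: bool) -> np.ndarray:
    out = np.fromiter((_ENC.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))
    if strict and (out == 4).any():
        raise ValueError("invalid RNA base in miRNA sequence")
    return out


def _variant_mapping(m: int, wlen: int, bulge: tuple[str, int] | None) -> dict[int, int]:
    """miRNA position (1-based) -> window index, mirroring _score_alignment."""
    mapping: dict[int, int] = {}
    if bulge is None:
        for q in range(1, m + 1):
            mapping[q] = wlen - q
    elif bulge[0] == "target":
        g = bulge[1]
        for q in range(1, m + 1):
            mapping[q] = (wlen - q) if q <= g else (wlen - 1 - q)
    else:
        g = bulge[1]
        for q in range(1, m + 1):
            if q != g:
                mapping[q] = (wlen - q) if q < g else (wlen - q + 1)
    return mapping


def _score_alignment(mirna: str, window: str, bulge: tuple[str, int] | None):
    """Score one candidate duplex.

    ``window`` is the transcript slice (5'->3'); the miRNA runs antiparallel
    so miRNA position q (1-based from its 5' end) faces the window from the
    right.  ``bulge`` is None for the gapless case, ("target", g) for an
    unopposed target base between miRNA positions g and g+1, or
    ("mirna", g) for an unopposed miRNA base at position g.

    Returns (expectation, pairing map q->window index, rows) or None when
    the geometry is inconsistent.
    """
    m = len(mirna)
    w = len(window)
    pairing: dict[int, int] = {}
    score = 0.0

    if bulge is None:
        if w != m:
            return None
        for q in range(1, m + 1):
            pairing[q] = w - q
    elif bulge[0] == "target":
        g = bulge[1]
        if w != m + 1 or not 1 <= g <= m - 1:
            return None
        score += GAP_PENALTY * _seed_factor(g)
        for q in range(1, m + 1):
            pairing[q] = (w - q) if q <= g else (w - 1 - q)
    elif bulge[0] == "mirna":
        g = bulge[1]
        if w != m - 1 or not 2 <= g <= m - 1:
            return None
        score += GAP_PENALTY * _seed_factor(g)
        for q in range(1, m + 1):
            if q == g:
                continue
            pairing[q] = (w - q) if q < g else (w - q + 1)
    else:
        return None

    for q, ti in pairing.items():
        pen, _ = _penalty(mirna[q - 1], window[ti])
        score += pen * _seed_factor(q)

    # three-row text: target 5'->3' left to right, miRNA 3'->5' beneath it
    by_ti = {ti: q for q, ti in pairing.items()}
    cols = []
    for ti in range(w):
        if ti in by_ti:
            q = by_ti[ti]
            _, sym = _penalty(mirna[q - 1], window[ti])
            cols.append((window[ti], sym, mirna[q - 1]))
        else:  # unopposed target base
            cols.append((window[ti], " ", "-"))
    if bulge is not None and bulge[0] == "mirna":
        g = bulge[1]
        cols.insert(w - g + 1, ("-", " ", mirna[g - 1]))
    rows = (
        "5' " + "".join(c[0] for c in cols) + " 3' (target)\n"
        "   " + "".join(c[1] for c in cols) + "\n"
        "3' " + "".join(c[2] for c in cols) + " 5' (miRNA)"
    )
    return score, pairing, rows


def _site_mode(mirna: str, window: str, pairing: dict[int, int]) -> str:
    """Cleavage unless any of miRNA positions 9-11 is mismatched or gapped
    (a G:U wobble still counts as paired)."""
    for q in (9, 10, 11):
        if q > len(mirna):
            return "translational"
        ti = pairing.get(q)
        if ti is None:
            return "translational"
        key = (mirna[q - 1], window[ti])
        if key not in _WC and key not in _WOBBLE:
            return "translational"
    return "cleavage"


def score_targets(
    mirna_seq: str,
    transcripts: dict[str, str] | str | Path,
    cutoff: float = DEFAULT_CUTOFF,
    mirna_name: str | None = None,
    allow_bulge: bool = True,
) -> list[TargetSite]:
    """Scan transcripts for target sites of one miRNA.

    Ungapped windows plus (optionally) single 1-nt bulge variants are
    scored; sites with expectation <= cutoff are returned sorted by
    (expectation, transcript, position).  Overlapping sites on the same
    transcript are deduplicated keeping the lowest expectation.
    """
    if isinstance(transcripts, (str, Path)):
        transcripts = read_fasta(transcripts)
    if not transcripts:
        raise ValueError("transcript set is empty")
    mirna = to_rna(mirna_seq)
    if not 18 <= len(mirna) <= 26:
        raise ValueError("miRNA length must be 18-26 nt")
    m = len(mirna)
    label = mirna_name or mirna
    variants: list[tuple[int, tuple[str, int] | None]] = [(m, None)]
    if allow_bulge:
        variants += [(m + 1, ("target", g)) for g in range(1, m)]
        variants += [(m - 1, ("mirna", g)) for g in range(2, m)]
    mi_code = _encode_rna(mirna, strict=True)
    sites: list[TargetSite] = []
    for tid in sorted(transcripts):
        seq = to_rna(transcripts[tid])
        t_code = _encode_rna(seq, strict=False)
        for wlen, bulge in variants:
            ns = len(seq) - wlen + 1
            if ns <= 0:
                continue
            # vectorised prescreen over all windows of this variant
            scores = np.zeros(ns)
            if bulge is not None:
                scores += GAP_PENALTY * _seed_factor(bulge[1])
            for q, ti in _variant_mapping(m, wlen, bulge).items():
                scores += _seed_factor(q) * _PENTAB[mi_code[q - 1], t_code[ti : ti + ns]]
            for s in np.nonzero(scores <= cutoff + 1e-9)[0]:
                s = int(s)
                window = seq[s : s + wlen]
                scored = _score_alignment(mirna, window, bulge)
                if scored is None:
                    continue
                expectation, pairing, rows = scored
                if expectation > cutoff:
                    continue
                mode = _site_mode(mirna, window, pairing)
                abs_pairing = {q: s + ti for q, ti in pairing.items()}
                cleave = None
                if mode == "cleavage":
                    cleave = abs_pairing[10]
                sites.append(
                    TargetSite(
                        mirna=label,
                        mirna_seq=mirna,
                        transcript_id=tid,
                        start0=s,
                        end0=s + wlen,
                        expectation=expectation,
                        alignment=rows,
                        mode=mode,
                        cleavage_pos0=cleave,
                        pairing=abs_pairing,
                    )
                )
    sites = _dedupe_overlaps(sites)
    sites.sort(key=lambda x: (x.expectation, x.transcript_id, x.start0))
    return sites


def _dedupe_overlaps(sites: list[TargetSite]) -> list[TargetSite]:
    kept: list[TargetSite] = []
    for site in sorted(sites, key=lambda x: (x.expectation, x.transcript_id, x.start0)):
        clash = any(
            k.transcript_id == site.transcript_id
            and k.start0 < site.end0
            and site.start0 < k.end0
            for k in kept
        )
        if not clash:
            kept.append(site)
    return kept


def locate_cleavage(site: TargetSite) -> int:
    """Transcript coordinate of the guided cut: the 0-based index of the
    target base opposite miRNA position 10 (the base 3' of the cut bond)."""
    if site.mode != "cleavage":
        raise ValueError("cleavage position is undefined for a translational site")
    assert site.cleavage_pos0 is not None
    return site.cleavage_pos0


def tally_race(site: TargetSite, clone_positions) -> RaceTally:
    """Count RACE clone 5' ends at the predicted cleavage position.

    ``clone_positions`` are 0-based transcript indices of clone 5' ends in
    the same convention as ``cleavage_pos0``.  Any position observed in
    at least 2 clones is reported as a secondary peak.
    """
    positions = [int(p) for p in clone_positions]
    if not positions:
        raise ValueError("no RACE clones supplied")
    predicted = locate_cleavage(site)
    at_site = sum(1 for p in positions if p == predicted)
    peaks: dict[int, int] = {}
    for p in positions:
        peaks[p] = peaks.get(p, 0) + 1
    secondary = {p: c for p, c in sorted(peaks.items()) if c >= 2}
    return RaceTally(
        site=site,
        n_clones=len(positions),
        positions=positions,
        at_site=at_site,
        secondary_peaks=secondary,
    )


def target_table(sites: list[TargetSite]):
    """Target report rows (1-based inclusive span) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "mirna": s.mirna,
                "transcript": s.transcript_id,
                "start": s.start0 + 1,
                "end": s.end0,
                "expectation": s.expectation,
                "mode": s.mode,
                "cleavage_pos0": "" if s.cleavage_pos0 is None else s.cleavage_pos0,
            }
            for s in sites
        ]
    )
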