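"""RNA secondary-structure prediction for precursor screening.

The built-in engine is a Nussinov-style interval dynamic program over
nested structures (minimum hairpin loop of 3 nt) that maximises a
stacking-aware pairing score:

    G:C = 3, A:U = 2, G:U = 1, +1 for every stacked pair
    (a pair (i, j) directly enclosing a pair (i+1, j-1)).

The maximal score is reported as a pseudo minimum free energy,
``mfe = -0.5 * score`` (kcal/mol-like units).  Hairpin topology, not the
exact thermodynamics, is what the downstream structural criteria consume;
for publication-grade energies the ViennaRNA thermodynamic engine can be
selected with ``engine="vienna"`` when its python bindings are installed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: pseudo-kcal/mol per score unit of the built-in engine
ENERGY_SCALE = 0.5

#: minimum number of unpaired bases enclosed by a hairpin-closing pair
MIN_LOOP = 3

_NEG = -1e9

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}

# pair score lookup, indexed [base_i, base_j]
_PAIR = np.zeros((4, 4), dtype=np.float64)
_PAIR[_ENC["G"], _ENC["C"]] = _PAIR[_ENC["C"], _ENC["G"]] = 3.0
_PAIR[_ENC["A"], _ENC["U"]] = _PAIR[_ENC["U"], _ENC["A"]] = 2.0
_PAIR[_ENC["G"], _ENC["U"]] = _PAIR[_ENC["U"], _ENC["G"]] = 1.0

PAIR_SCORES = {"GC": 3.0, "CG": 3.0, "AU": 2.0, "UA": 2.0, "GU": 1.0, "UG": 1.0}
STACK_BONUS = 1.0


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper().replace("T", "U")
    try:
        return np.array([_ENC[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid RNA base {exc.args[0]!r} in sequence") from None


@njit(cache=True)
def _fill(code, pair_tab):  # pragma: no cover - numba kernel
    n = code.shape[0]
    P = np.full((n, n), _NEG)
    F = np.zeros((n, n))
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            s = pair_tab[code[i], code[j]]
            if s > 0.0:
                best = F[i + 1, j - 1]
                if j - i - 2 > MIN_LOOP and P[i + 1, j - 1] > _NEG / 2:
                    alt = P[i + 1, j - 1] + 1.0
                    if alt > best:
                        best = alt
                P[i, j] = s + best
            best = F[i, j - 1]
            for k in range(i, j - MIN_LOOP):
                if P[k, j] > _NEG / 2:
                    left = F[i, k - 1] if k > i else 0.0
                    v = left + P[k, j]
                    if v > best:
                        best = v
            F[i, j] = best
    return P, F


def _traceback(P, F, code, pairs, i, j, paired):
    """Recover one optimal structure; deterministic tie-break prefers the
    3' base unpaired, then the smallest bifurcation point."""
    while True:
        if paired:
            pairs.append((i, j))
            target = P[i, j] - _PAIR[code[i], code[j]]  # interior contribution
            stacked = (
                j - i - 2 > MIN_LOOP
                and P[i + 1, j - 1] > _NEG / 2
                and abs(target - (P[i + 1, j - 1] + 1.0)) < 1e-9
            )
            if stacked:
                i, j = i + 1, j - 1
                continue
            i, j, paired = i + 1, j - 1, False
            continue
        if j - i <= MIN_LOOP or F[i, j] <= 0.0:
            return
        if abs(F[i, j] - F[i, j - 1]) < 1e-9:
            j -= 1
            continue
        for k in range(i, j - MIN_LOOP):
            if P[k, j] <= _NEG / 2:
                continue
            left = F[i, k - 1] if k > i else 0.0
            if abs(F[i, j] - (left + P[k, j])) < 1e-9:
                if k > i:
                    _traceback(P, F, code, pairs, i, k - 1, False)
                i, j, paired = k, j, True
                break
        else:  # numerical safety net; should not happen
            return


def fold_builtin(sequence: str) -> tuple[str, float]:
    """Fold with the built-in stacking-aware Nussinov engine."""
    code = _encode(sequence)
    n = code.shape[0]
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    if n <= MIN_LOOP + 1:
        return "." * n, 0.0
    P, F = _fill(code, _PAIR)
    score = float(F[0, n - 1])
    pairs: list[tuple[int, int]] = []
    if score > 0:
        _traceback(P, F, code, pairs, 0, n - 1, False)
    db = ["."] * n
    for a, b in pairs:
        db[a], db[b] = "(", ")"
    return "".join(db), -ENERGY_SCALE * score


def fold_vienna(sequence: str) -> tuple[str, float]:
    """Fold with the ViennaRNA thermodynamic engine (optional dependency)."""
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "ViennaRNA python bindings are not installed; use engine='builtin'"
        ) from exc
    _encode(sequence)  # alphabet validation, same contract as builtin
    db, mfe = RNA.fold(sequence.upper().replace("T", "U"))
    return db, float(mfe)


_ENGINES = {"builtin": fold_builtin, "vienna": fold_vienna}


def fold_rna(sequence: str, engine: str = "builtin") -> tuple[str, float]:
    """Fold an RNA sequence into (dot-bracket, mfe).

    Parameters
    ----------
    sequence:
        RNA over {A, C, G, U} (T accepted and treated as U).
    engine:
        "builtin" (default) or "vienna".

    Returns
    -------
    (dotbracket, mfe) with mfe ≤ 0 in (pseudo-)kcal/mol.
    """
    try:
        fn = _ENGINES[engine]
    except KeyError:
        raise ValueError(f"unknown folding engine {engine!r}") from None
    return fn(sequence)


def pair_table(dotbracket: str) -> np.ndarray:
    """Partner index per position (-1 for unpaired); raises on unbalanced input."""
    pt = np.full(len(dotbracket), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt


def structure_score(sequence: str, pairs: list[tuple[int, int]]) -> float:
    """Score an explicit structure under the built-in model (pair scores plus
    stacking bonuses).  Used for cross-checks against the DP engine."""
    seq = sequence.upper().replace("T", "U")
    pairset = set(pairs)
    total = 0.0
    for i, j in pairs:
        total += PAIR_SCORES.get(seq[i] + seq[j], 0.0)
        if (i + 1, j - 1) in pairset:
            total += STACK_BONUS
    return total
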