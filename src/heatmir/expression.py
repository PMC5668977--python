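"""Expression quantification, chi-square differential expression, and the
composition / validation statistics.

Differential calls follow the count-based recipe: replicate counts are
pooled per condition, a 2x2 Pearson chi-square (no continuity correction)
tests each miRNA's count against the library totals, and a miRNA is called
up/down when |log2(HS/CK)| >= 1 and raw p <= 0.05.  Benjamini-Hochberg q
values are reported alongside but do not drive the calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DE_LOG2FC_MIN = 1.0
DE_P_MAX = 0.05


@dataclass
class ExpressionMatrix:
    """miRNA x library raw counts and TPM, with per-library clean totals."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    totals: pd.Series

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")


def build_matrix(records, counts: pd.DataFrame, totals: pd.Series) -> ExpressionMatrix:
    """Expression matrix for a miRNA catalog from the clean-tag counts."""
    names = [r.name for r in records]
    seqs = [r.mature_seq for r in records]
    sub = counts.reindex(seqs).fillna(0).astype("int64")
    sub.index = pd.Index(names, name="mirna")
    tpm = sub.div(totals[sub.columns], axis=1) * 1e6
    return ExpressionMatrix(counts=sub, tpm=tpm, totals=totals)


@dataclass
class DEResult:
    mirna: str
    contrast: str
    tpm_a: float  # HS (numerator) side
    tpm_b: float  # CK side
    log2fc: float
    chi2: float
    p: float
    q: float
    call: str  # up | down | ns

    def __post_init__(self):
        if self.call != "ns" and (abs(self.log2fc) < DE_LOG2FC_MIN or self.p > DE_P_MAX):
            raise ValueError("non-ns call violates the DE thresholds")


@dataclass(frozen=True)
class Contrast:
    """A named comparison: libraries of the numerator condition (e.g. HS)
    against libraries of the denominator condition (e.g. CK)."""

    name: str
    libs_a: tuple[str, ...]
    libs_b: tuple[str, ...]


def chisq_test(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2 table
    [[count_a, total_a - count_a], [count_b, total_b - count_b]]."""
    for c, t in ((count_a, total_a), (count_b, total_b)):
        if c < 0 or t <= 0 or c > t:
            raise ValueError("need 0 <= count <= total and total > 0")
    a, b = count_a, total_a - count_a
    c, d = count_b, total_b - count_b
    if a + c == 0 or b + d == 0:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(chi2), float(p)


def call_differential(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    log2fc_min: float = DE_LOG2FC_MIN,
    p_max: float = DE_P_MAX,
    replicate_policy: str = "pool",
) -> list[DEResult]:
    """Differential expression for one contrast.

    Counts are pooled across replicates per condition (default policy);
    log2fc = log2((TPM_a + eps_a) / (TPM_b + eps_b)) where eps is the TPM
    equivalent of a single pooled read, so zero counts stay finite.
    With policy "per_replicate", matched replicate pairs are tested
    separately and combined with Fisher's method (fold change still pooled).
    """
    for lib in contrast.libs_a + contrast.libs_b:
        if lib not in matrix.counts.columns:
            raise ValueError(f"contrast library {lib!r} missing from the matrix")
    if not contrast.libs_a or not contrast.libs_b:
        raise ValueError("both conditions must have at least one library")
    ca = matrix.counts[list(contrast.libs_a)].sum(axis=1)
    cb = matrix.counts[list(contrast.libs_b)].sum(axis=1)
    ta = int(matrix.totals[list(contrast.libs_a)].sum())
    tb = int(matrix.totals[list(contrast.libs_b)].sum())
    eps_a, eps_b = 1e6 / ta, 1e6 / tb
    results: list[DEResult] = []
    ps = []
    for name in matrix.counts.index:
        a, b = int(ca[name]), int(cb[name])
        tpm_a, tpm_b = a / ta * 1e6, b / tb * 1e6
        log2fc = math.log2((tpm_a + eps_a) / (tpm_b + eps_b))
        if replicate_policy == "pool":
            chi2, p = chisq_test(a, ta, b, tb)
        elif replicate_policy == "per_replicate":
            pvals = []
            chi2 = 0.0
            for la, lb in zip(contrast.libs_a, contrast.libs_b):
                x2, pv = chisq_test(
                    int(matrix.counts.loc[name, la]),
                    int(matrix.totals[la]),
                    int(matrix.counts.loc[name, lb]),
                    int(matrix.totals[lb]),
                )
                chi2 += x2
                pvals.append(pv)
            _, p = stats.combine_pvalues(pvals, method="fisher")
            p = float(p)
        else:
            raise ValueError(f"unknown replicate_policy {replicate_policy!r}")
        ps.append(p)
        results.append(
            DEResult(
                mirna=str(name),
                contrast=contrast.name,
                tpm_a=tpm_a,
                tpm_b=tpm_b,
                log2fc=log2fc,
                chi2=chi2,
                p=p,
                q=1.0,  # filled below
                call="ns",
            )
        )
    if results:
        qs = stats.false_discovery_control(np.array(ps), method="bh")
        for r, q in zip(results, qs):
            r.q = float(min(1.0, q))
            if abs(r.log2fc) >= log2fc_min and r.p <= p_max:
                r.call = "up" if r.log2fc > 0 else "down"
    return results


def de_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna,
                "contrast": r.contrast,
                "tpm_hs": round(r.tpm_a, 3),
                "tpm_ck": round(r.tpm_b, 3),
                "log2fc": round(r.log2fc, 4),
                "chi2": round(r.chi2, 4),
                "p": r.p,
                "q": r.q,
                "call": r.call,
            }
            for r in results
        ]
    )


def replicate_correlation(
    tpm: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r on log2(TPM+1) for each replicate pair, over miRNAs
    expressed (TPM > 0) in at least one member of the pair.  Zero-variance
    vectors yield r = NaN with the ``undefined`` flag set."""
    rows = []
    for lib1, lib2 in pairs:
        sub = tpm[[lib1, lib2]]
        sub = sub[(sub > 0).any(axis=1)]
        x = np.log2(sub[lib1].to_numpy() + 1)
        y = np.log2(sub[lib2].to_numpy() + 1)
        undefined = len(x) < 2 or np.std(x) == 0 or np.std(y) == 0
        r = float("nan") if undefined else float(stats.pearsonr(x, y)[0])
        rows.append(
            {"lib1": lib1, "lib2": lib2, "n": len(x), "r": r, "undefined": undefined}
        )
    return pd.DataFrame(rows)


def tissue_specificity(
    matrix: ExpressionMatrix,
    libs_by_tissue: dict[str, tuple[str, ...]],
    min_tpm: float = 10.0,
    log2fc_min: float = DE_LOG2FC_MIN,
    p_max: float = DE_P_MAX,
) -> pd.DataFrame:
    """Label each miRNA by tissue bias at control conditions.

    "<tissue>-specific": TPM >= min_tpm in that tissue and 0 in the other;
    "<tissue>-preferential": the DE criteria met between tissues;
    otherwise "shared".  Expects exactly two tissues.
    """
    (t1, libs1), (t2, libs2) = sorted(libs_by_tissue.items())
    c1 = matrix.counts[list(libs1)].sum(axis=1)
    c2 = matrix.counts[list(libs2)].sum(axis=1)
    n1 = int(matrix.totals[list(libs1)].sum())
    n2 = int(matrix.totals[list(libs2)].sum())
    eps1, eps2 = 1e6 / n1, 1e6 / n2
    labels = {}
    for name in matrix.counts.index:
        a, b = int(c1[name]), int(c2[name])
        tpm1, tpm2 = a / n1 * 1e6, b / n2 * 1e6
        if tpm1 >= min_tpm and b == 0:
            labels[name] = f"{t1}-specific"
            continue
        if tpm2 >= min_tpm and a == 0:
            labels[name] = f"{t2}-specific"
            continue
        log2fc = math.log2((tpm1 + eps1) / (tpm2 + eps2))
        _, p = chisq_test(a, n1, b, n2)
        if abs(log2fc) >= log2fc_min and p <= p_max:
            labels[name] = f"{t1}-preferential" if log2fc > 0 else f"{t2}-preferential"
        else:
            labels[name] = "shared"
    out = pd.DataFrame({"label": pd.Series(labels)})
    out.index.name = "mirna"
    return out


@dataclass
class CompositionStats:
    length_dist: pd.DataFrame  # length x library, fractions summing to 1
    first_nt: pd.DataFrame  # base x library, 5'-nucleotide fractions
    positional: pd.DataFrame  # base x position (1..24), fractions per position


def composition_stats(counts: pd.DataFrame, max_pos: int = 24) -> CompositionStats:
    """Length distribution and (U-form) base composition of tags, weighted
    by read counts; fractions sum to 1 per library / per position."""
    seqs = counts.index.to_numpy()
    lens = np.array([len(s) for s in seqs])
    length_dist = counts.groupby(lens).sum()
    length_dist = length_dist / length_dist.sum(axis=0)
    length_dist.index.name = "length"

    first = pd.Index([s[0].replace("T", "U") for s in seqs])
    first_nt = counts.groupby(first).sum()
    first_nt = first_nt / first_nt.sum(axis=0)
    first_nt.index.name = "base"

    total = counts.sum(axis=1).to_numpy()
    pos_counts = {b: np.zeros(max_pos) for b in "ACGU"}
    pos_total = np.zeros(max_pos)
    for seq, w in zip(seqs, total):
        u = seq.replace("T", "U")
        for i, base in enumerate(u[:max_pos]):
            if base in pos_counts:
                pos_counts[base][i] += w
                pos_total[i] += w
    with np.errstate(invalid="ignore"):
        positional = pd.DataFrame(
            {b: pos_counts[b] / pos_total for b in "ACGU"},
            index=pd.RangeIndex(1, max_pos + 1, name="position"),
        ).T
    return CompositionStats(length_dist=length_dist, first_nt=first_nt, positional=positional)


@dataclass
class DdctResult:
    fold_change: float
    ddct: float
    se_ddct: float
    n: int


def ddct_fold_change(ct_target_t, ct_ref_t, ct_target_c, ct_ref_c):
    """Relative qPCR quantification, fold change = 2^-ddCt.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control).

    Scalars give a float; replicate vectors give a DdctResult with the mean
    fold change and the standard error propagated on ddCt.
    """
    arrs = [np.atleast_1d(np.asarray(x, dtype=float)) for x in
            (ct_target_t, ct_ref_t, ct_target_c, ct_ref_c)]
    if any(not np.isfinite(a).all() for a in arrs):
        raise ValueError("Ct values must be finite")
    n = max(a.size for a in arrs)
    tt, rt, tc, rc = (np.broadcast_to(a, (n,)) for a in arrs)
    ddct = (tt - rt) - (tc - rc)
    mean = float(np.mean(ddct))
    if n == 1:
        return float(2.0 ** -mean)
    se = float(np.std(ddct, ddof=1) / np.sqrt(n))
    return DdctResult(fold_change=float(2.0 ** -mean), ddct=mean, se_ddct=se, n=n)


@dataclass
class DValueResult:
    d: float  # mean stamen length - mean pistil length (mm)
    se: float
    p: float
    undefined_variance: bool = False


def dvalue_summary(stamen_lengths, pistil_lengths) -> DValueResult:
    """Stigma-exsertion D-value: mean(stamen) - mean(pistil) with its SE and
    a two-sided Welch t-test p-value.  Negative D means the stigma protrudes
    beyond the anther cone."""
    s = np.asarray(stamen_lengths, dtype=float)
    p = np.asarray(pistil_lengths, dtype=float)
    if s.size < 3 or p.size < 3:
        raise ValueError("need at least 3 measurements per organ")
    d = float(s.mean() - p.mean())
    var_s, var_p = s.var(ddof=1), p.var(ddof=1)
    se = float(np.sqrt(var_s / s.size + var_p / p.size))
    if var_s == 0 and var_p == 0:
        return DValueResult(d=d, se=0.0, p=1.0 if d == 0 else 0.0, undefined_variance=True)
    t = stats.ttest_ind(s, p, equal_var=False)
    return DValueResult(d=d, se=se, p=float(t.pvalue))


def de_overlap_table(results_by_contrast: dict[str, list[DEResult]]) -> pd.DataFrame:
    """Set-overlap (Venn) membership of DE miRNAs across contrasts: one row
    per miRNA significant anywhere, one boolean column per contrast."""
    sig = {
        cname: {r.mirna for r in results if r.call != "ns"}
        for cname, results in results_by_contrast.items()
    }
    universe = sorted(set().union(*sig.values())) if sig else []
    table = pd.DataFrame(
        {cname: [m in members for m in universe] for cname, members in sig.items()},
        index=pd.Index(universe, name="mirna"),
    )
    table["n_contrasts"] = table.sum(axis=1) if len(table.columns) else 0
    return table
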