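"""Scoring a pipeline run against the synthetic dataset's planted truth.

Used by the test suite and the acceptance script to measure parameter
recovery: how many planted matures that survive the abundance filters are
re-discovered, whether known/novel precedence is ever violated, and the
sensitivity / false-positive rate of the differential-expression calls
against the planted fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discovery import classify_known, map_exact, select_candidates
from .expression import chisq_test
from .simdata import SyntheticDataset


@dataclass
class RecoveryMetrics:
    n_planted: int
    n_eligible: int  # planted matures passing the abundance/length filters
    n_recovered: int
    n_status_correct: int
    precedence_violations: int
    de_true_cases: int
    de_true_called_down: int
    de_null_cases: int
    de_null_called: int

    @property
    def recovery_pct(self) -> float:
        return 100.0 * self.n_recovered / self.n_eligible if self.n_eligible else 0.0

    @property
    def de_sensitivity_pct(self) -> float:
        return (
            100.0 * self.de_true_called_down / self.de_true_cases
            if self.de_true_cases
            else 0.0
        )

    @property
    def de_false_positive_pct(self) -> float:
        return (
            100.0 * self.de_null_called / self.de_null_cases
            if self.de_null_cases
            else 0.0
        )


def score_run(dataset: SyntheticDataset, results) -> RecoveryMetrics:
    """Compare a PipelineResults object against the dataset's truth."""
    cfg = results.config
    pre = results.preprocess
    planted = {h.mature_seq: h.locus_id for h in dataset.hairpins}

    # which planted matures pass the selection filters
    present = [seq for seq in planted if seq in pre.tpm.index]
    hit_map = map_exact(present, dataset.genome)
    eligible = set(
        select_candidates(
            pre.tpm.loc[present],
            hit_map,
            min_tpm=cfg.min_tpm,
            len_range=cfg.len_range,
            max_hits=cfg.max_hits,
        )
    )

    catalog = {r.mature_seq: r for r in results.discovery.records}
    recovered = [seq for seq in eligible if seq in catalog]
    status_correct = sum(
        1
        for seq in recovered
        if catalog[seq].status
        == ("known" if planted[seq].startswith("known") else "novel")
    )

    reference = dataset.reference
    violations = 0
    for rec in results.discovery.records:
        if rec.status == "novel" and classify_known(rec.mature_seq, reference):
            violations += 1

    responsive = set(dataset.responsive_loci)
    name_to_locus = {
        rec.name: planted[rec.mature_seq]
        for rec in results.discovery.records
        if rec.mature_seq in planted
    }
    de_true = de_down = de_null = de_null_called = 0
    for rs in results.de_results.values():
        for r in rs:
            locus = name_to_locus.get(r.mirna)
            if locus is None:
                continue
            if locus in responsive:
                de_true += 1
                de_down += r.call == "down"
            else:
                de_null += 1
                de_null_called += r.call != "ns"

    return RecoveryMetrics(
        n_planted=len(planted),
        n_eligible=len(eligible),
        n_recovered=len(recovered),
        n_status_correct=status_correct,
        precedence_violations=violations,
        de_true_cases=de_true,
        de_true_called_down=de_down,
        de_null_cases=de_null,
        de_null_called=de_null_called,
    )


def type1_error_rate(
    n_reps: int = 2000,
    expected_tpm: float = 100.0,
    depth: int = 200_000,
    n_rep_libs: int = 2,
    seed: int = 0,
) -> float:
    """Empirical type-I rate of the pooled chi-square DE test under the
    null: both conditions share the same expected TPM and pooled counts are
    Poisson around expected TPM x pooled depth / 1e6."""
    rng = np.random.default_rng(seed)
    lam = expected_tpm * depth / 1e6 * n_rep_libs
    total = depth * n_rep_libs
    a = rng.poisson(lam, n_reps)
    b = rng.poisson(lam, n_reps)
    hits = 0
    for ai, bi in zip(a, b):
        _, p = chisq_test(int(ai), total, int(bi), total)
        hits += p <= 0.05
    return hits / n_reps
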