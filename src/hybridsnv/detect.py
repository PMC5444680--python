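"""Hypothesis testing for the presence of each candidate mutation.

For every candidate, the vertical distances of its mutation-set probes are
compared against the reference-branch distances with a one-sided Wilcoxon
rank-sum (Mann-Whitney) test, alternative "mutation distances stochastically
greater".  Because p-values can be extremely small, significance is reported
as p' = -ln(p), computed in log space via the normal log-survival function
whenever the asymptotic approximation is used.

Significance alone cannot distinguish between the three base hypotheses at
one position: when a mutant is present, the side branches (same position,
different base) are also genuinely shifted above the reference branch, so
their tests also reject.  The branch geometry does the base identification: a
hypothesis is accepted only when its branch is both significant and the most
deviating one (largest rho).  A pure wild-type sample yields no call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .branchfit import (
    BranchResult,
    ReferenceLine,
    ScatterData,
    branch_distances,
)
from .probeset import MutationHypothesis, Probeset

#: above this product n1*n2 the exact null distribution is replaced by the
#: tie-corrected normal approximation with continuity correction; the exact
#: tail matters here because a fully separated small subset saturates the
#: normal approximation far below its true significance
EXACT_LIMIT = 10_000

MIN_MUTATION_PROBES = 2
MIN_REFERENCE_PROBES = 10


def rank_sum_greater(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum of x stochastically greater than y.

    Returns ``(p, p_prime)`` with ``p_prime = -ln(p)``.  Small untied samples
    use the exact distribution; otherwise the normal approximation with
    continuity and tie correction, evaluated through the log survival
    function so that extreme significance does not underflow.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank-sum test needs non-empty samples")

    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2

    if n1 * n2 <= EXACT_LIMIT and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="greater", method="exact")
        p = float(res.pvalue)
        return p, -math.log(p)

    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:  # all observations identical
        return 1.0, 0.0
    z = (u1 - 0.5 - mean_u) / math.sqrt(var_u)  # continuity corrected
    log_p = stats.norm.logsf(z)
    return float(np.exp(log_p)), float(-log_p)


@dataclass(frozen=True)
class HypothesisResult:
    """Outcome of testing one candidate mutation."""

    hypothesis: MutationHypothesis
    rho: float
    p: float | None
    p_prime: float
    n_mutation_probes: int
    n_reference_probes: int
    significant: bool
    valid: bool = True

    def as_dict(self) -> dict:
        return {
            "label": self.hypothesis.label,
            "aa_label": self.hypothesis.aa_label,
            "rho": self.rho,
            "p": self.p,
            "p_prime": self.p_prime,
            "n_mutation_probes": self.n_mutation_probes,
            "n_reference_probes": self.n_reference_probes,
            "significant": self.significant,
            "valid": self.valid,
        }


def test_hypothesis(branches: BranchResult, alpha: float = 0.01) -> HypothesisResult:
    """Rank-sum test of the mutation-set distances against the reference pool.

    The reference pool is every retained probe with no mismatch at the
    hypothesis position.  Hypotheses whose retained mutation set is smaller
    than two probes (or reference pool below ten) are flagged invalid rather
    than tested.
    """
    mut = branches.pool("mutation")
    ref = branches.pool("reference")
    if len(mut) < MIN_MUTATION_PROBES or len(ref) < MIN_REFERENCE_PROBES:
        return HypothesisResult(
            hypothesis=branches.hypothesis,
            rho=branches.rho,
            p=None,
            p_prime=float("nan"),
            n_mutation_probes=len(mut),
            n_reference_probes=len(ref),
            significant=False,
            valid=False,
        )
    p, p_prime = rank_sum_greater(mut, ref)
    return HypothesisResult(
        hypothesis=branches.hypothesis,
        rho=branches.rho,
        p=p,
        p_prime=p_prime,
        n_mutation_probes=len(mut),
        n_reference_probes=len(ref),
        significant=p < alpha,
    )


@dataclass
class SampleCall:
    """All per-hypothesis results for one sample plus the final verdict.

    ``called`` is the accepted hypothesis (most deviating significant branch),
    or None (wild type).  ``gap`` is p'(called position's best) minus the best
    p' among hypotheses at *other* positions — the margin separating the true
    position from the false ones (hypotheses at the same position share the
    physical signal and are separated by rho, not by p').
    """

    results: list[HypothesisResult]
    called: MutationHypothesis | None
    gap: float
    alpha: float
    notes: list[str] = field(default_factory=list)

    @property
    def called_label(self) -> str:
        return self.called.label if self.called else "wild type"

    def as_dict(self) -> dict:
        return {
            "call": self.called_label,
            "aa_call": self.called.aa_label if self.called else None,
            "alpha": self.alpha,
            "p_prime_gap": self.gap,
            "notes": self.notes,
            "hypotheses": [r.as_dict() for r in self.results],
        }


def call_sample(
    scatter: ScatterData,
    line: ReferenceLine,
    probeset: Probeset,
    hypotheses: list[MutationHypothesis],
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> SampleCall:
    """Test every candidate mutation and call the sample.

    The panel mutations are mutually exclusive, so at most one is called: the
    significant hypothesis whose branch is the most deviating (largest rho).
    Significance identifies the mutated *position*; among the three base
    hypotheses there, the side branches are also shifted and also reject, so
    the base is read off the branch geometry.  When hypotheses at several
    *different* positions are simultaneously significant (e.g. an
    out-of-panel multi-mutant mixture) the most deviating one is still
    returned, with a note — the single-mutant model is outside its domain
    there.  ``bonferroni`` divides alpha by the number of hypotheses (off by
    default; the framework reports per-hypothesis significance).
    """
    if not hypotheses:
        raise ValueError("need at least one hypothesis")
    level = alpha / len(hypotheses) if bonferroni else alpha
    results = [
        test_hypothesis(branch_distances(scatter, line, probeset, h), alpha=level)
        for h in hypotheses
    ]
    valid = [r for r in results if r.valid]
    notes: list[str] = []
    if not valid:
        notes.append("no hypothesis had enough retained probes to test")
        return SampleCall(results=results, called=None, gap=float("nan"), alpha=level, notes=notes)

    significant = [r for r in valid if r.significant]
    best = max(significant, key=lambda r: r.rho) if significant else None
    called = best.hypothesis if best else None

    if best is not None:
        others = [
            r.p_prime for r in valid if r.hypothesis.position != best.hypothesis.position
        ]
        own = max(
            r.p_prime for r in valid if r.hypothesis.position == best.hypothesis.position
        )
        gap = own - max(others) if others else float("inf")
    else:
        gap = float("nan")

    significant_positions = {r.hypothesis.position for r in significant}
    if len(significant_positions) > 1:
        notes.append(
            "significant hypotheses at multiple positions; sample may contain "
            "more than one mutant — reporting the most deviating only"
        )
    return SampleCall(results=results, called=called, gap=gap, alpha=level, notes=notes)
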