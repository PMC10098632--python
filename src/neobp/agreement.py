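"""Agreement analysis for BP device validation.

Bland-Altman bias/precision statistics (both pooled over all points and
averaged per individual first, which weights every patient equally
regardless of recording length), the FDA accuracy gate (|bias| <= 5
mmHg and SD <= 8 mmHg), the three regression fits used to visualize
predicted-vs-true agreement (unconstrained, zero-intercept, identity),
and Tukey-Kramer all-pairs subgroup comparison with a compact letter
display.

Terminology note: following clinical device-validation convention, the
"MAE" reported everywhere here is the *signed* mean difference (bias),
not the mean absolute error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.stats import studentized_range

__all__ = ["ComponentAgreement", "AgreementReport", "RegressionFits",
           "GroupResult", "SubgroupComparison", "bland_altman", "fda_check",
           "regression_fits", "tukey_kramer_letters",
           "FDA_MAE_LIMIT", "FDA_SD_LIMIT"]

FDA_MAE_LIMIT = 5.0  # mmHg, on the signed mean difference
FDA_SD_LIMIT = 8.0   # mmHg, on the SD of differences

COMPONENTS = ("sbp", "dbp", "map")


class EmptyInputError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class ComponentAgreement:
    mae: float           # signed mean difference, mmHg
    sd: float            # SD of differences, mmHg
    loa_low: float       # mae - 2*sd
    loa_high: float      # mae + 2*sd
    n: int
    fda_pass: bool


@dataclass
class AgreementReport:
    mode: str  # "pooled" | "per_individual"
    components: dict[str, ComponentAgreement] = field(default_factory=dict)

    def all_pass(self) -> bool:
        return all(c.fda_pass for c in self.components.values())


@dataclass(frozen=True)
class RegressionFits:
    """Predicted-vs-true fits: unconstrained OLS, zero-intercept LS, and
    the identity line, each with its RMS residual."""

    slope: float
    intercept: float
    r2: float
    rms: float
    zero_intercept_slope: float
    zero_intercept_rms: float
    identity_rms: float


@dataclass(frozen=True)
class GroupResult:
    label: str
    n: int
    mean: float
    sd: float
    letters: str


@dataclass
class SubgroupComparison:
    groups: list[GroupResult]
    alpha: float
    #: pairwise significance matrix: True where significantly different
    significant: np.ndarray
    q_critical: float


def _gate(mae: float, sd: float) -> bool:
    # inclusive boundary: a device reported at exactly 5.0 / 8.0 passes
    return abs(mae) <= FDA_MAE_LIMIT and sd <= FDA_SD_LIMIT


def bland_altman(pred: np.ndarray, truth: np.ndarray,
                 patient_ids: Optional[Sequence[str]] = None,
                 mode: str = "pooled") -> AgreementReport:
    """Bland-Altman bias and precision of predicted vs reference BP.

    ``pred`` and ``truth`` are (n, 3) arrays ordered (SBP, DBP, MAP).
    In ``pooled`` mode the statistics are over all point differences; in
    ``per_individual`` mode each patient's differences are averaged
    first and the statistics are over the patient means, which removes
    the imbalance from patients contributing different numbers of
    points.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape or pred.shape[0] == 0:
        raise EmptyInputError("pred and truth must be non-empty and congruent")
    d = pred - truth
    if mode == "per_individual":
        if patient_ids is None:
            raise ValueError("per_individual mode needs patient_ids")
        pids = np.asarray(patient_ids)
        uniq = list(dict.fromkeys(pids))
        if len(uniq) < 2:
            raise ValueError("per_individual SD undefined with one patient")
        d = np.stack([d[pids == p].mean(axis=0) for p in uniq])
    elif mode != "pooled":
        raise ValueError(f"unknown mode {mode!r}")
    report = AgreementReport(mode=mode)
    for j, name in enumerate(COMPONENTS):
        mae = float(np.mean(d[:, j]))
        sd = float(np.std(d[:, j], ddof=1)) if d.shape[0] > 1 else 0.0
        report.components[name] = ComponentAgreement(
            mae=mae, sd=sd, loa_low=mae - 2 * sd, loa_high=mae + 2 * sd,
            n=d.shape[0], fda_pass=_gate(mae, sd))
    return report


def fda_check(report: AgreementReport) -> dict[str, bool]:
    """Per-component FDA accuracy verdict: |bias| <= 5 and SD <= 8 mmHg."""
    return {name: _gate(c.mae, c.sd) for name, c in report.components.items()}


def regression_fits(pred: np.ndarray, truth: np.ndarray) -> RegressionFits:
    """The three agreement fits of predicted on true values."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if len(pred) < 3:
        raise EmptyInputError("need >= 3 points")
    if np.std(truth) == 0:
        raise DegenerateFitError("constant truth; regression undefined")
    slope, intercept, r, _, _ = stats.linregress(truth, pred)
    rms = float(np.sqrt(np.mean((pred - (slope * truth + intercept)) ** 2)))
    zi_slope = float(np.sum(truth * pred) / np.sum(truth**2))
    zi_rms = float(np.sqrt(np.mean((pred - zi_slope * truth) ** 2)))
    id_rms = float(np.sqrt(np.mean((pred - truth) ** 2)))
    return RegressionFits(slope=float(slope), intercept=float(intercept),
                          r2=float(r**2), rms=rms,
                          zero_intercept_slope=zi_slope,
                          zero_intercept_rms=zi_rms, identity_rms=id_rms)


# --------------------------------------------------------------------------
# Tukey-Kramer with compact letter display
# --------------------------------------------------------------------------

def _tukey_kramer_matrix(samples: Sequence[np.ndarray], alpha: float
                         ) -> tuple[np.ndarray, float]:
    """All-pairs significance via the studentized-range distribution.

    Uses the Tukey-Kramer unequal-n standard error
    ``sqrt(MSW/2 * (1/n_i + 1/n_j))`` with the pooled within-group mean
    square; with equal group sizes this reduces to classic Tukey HSD.
    """
    k = len(samples)
    ns = np.array([len(s) for s in samples])
    means = np.array([np.mean(s) for s in samples])
    df = int(np.sum(ns - 1))
    msw = float(sum(np.sum((s - m) ** 2) for s, m in zip(samples, means)) / df)
    q_crit = float(studentized_range.ppf(1 - alpha, k, df))
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se if se > 0 else np.inf
            sig[i, j] = sig[j, i] = q >= q_crit
    return sig, q_crit


def _max_cliques(adj: list[set[int]]) -> list[set[int]]:
    """Maximal cliques by Bron-Kerbosch with pivoting (k is tiny here)."""
    cliques: list[set[int]] = []

    def expand(r: set[int], p: set[int], x: set[int]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        pivot = max(p | x, key=lambda v: len(adj[v] & p))
        for v in sorted(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(range(len(adj))), set())
    return cliques


def _letter_display(sig: np.ndarray) -> list[str]:
    """Compact letter display: one letter per maximal clique of the
    non-significance graph, so two groups share a letter iff they are
    not significantly different."""
    k = sig.shape[0]
    adj = [{j for j in range(k) if j != i and not sig[i, j]} for i in range(k)]
    sets = sorted(_max_cliques(adj), key=lambda s: (min(s), -len(s)))
    letters = ["" for _ in range(k)]
    for li, s in enumerate(sets):
        ch = chr(ord("A") + li)
        for g in s:
            letters[g] += ch
    # sanity: soundness of the display
    for i in range(k):
        for j in range(i + 1, k):
            share = bool(set(letters[i]) & set(letters[j]))
            assert share != bool(sig[i, j]), "letter display inconsistent"
    return letters


def tukey_kramer_letters(groups: dict[str, np.ndarray],
                         alpha: float = 0.05) -> SubgroupComparison:
    """All-pairs Tukey-Kramer comparison of per-group error samples.

    Groups sharing a compact-display letter are not significantly
    different at level ``alpha``; valid for unequal group sizes.
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    for lab, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {lab!r} needs >= 2 observations")
    sig, q_crit = _tukey_kramer_matrix(samples, alpha)
    letters = _letter_display(sig)
    results = [GroupResult(label=lab, n=len(s), mean=float(np.mean(s)),
                           sd=float(np.std(s, ddof=1)), letters=lt)
               for lab, s, lt in zip(labels, samples, letters)]
    return SubgroupComparison(groups=results, alpha=alpha, significant=sig,
                              q_critical=q_crit)
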