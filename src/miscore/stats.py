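"""Case-control inference for score vectors.

Two-sample statistics (Welch t, Mann-Whitney U, Kolmogorov-Smirnov) are
tested by permuting the case-control labels.  When the number of
distinct label arrangements is small the permutation null is enumerated
exhaustively and the p-value is exact; otherwise Monte-Carlo permutation
is used with the add-one estimator ``p = (b + 1) / (B + 1)``.  Families
of hypotheses computed on the same individuals are adjusted for
family-wise error by the single-step max(T) procedure: one shared
permutation stream, adjusted ``p_h`` from the permutation distribution
of the maximum |statistic| across hypotheses.

Permutations can be stratified within race-ethnicity groups, preserving
each stratum's case/control ratio — the default for pooled analyses.

Single-variant association uses maximum-likelihood logistic regression
of status on dosage (log-additive model, optional stratum adjustment),
falling back to a Firth-penalized fit when separation makes the ML
estimate diverge.  Dichotomized odds ratios come from 2×2 tables with
Woolf log-interval confidence limits and the Haldane-Anscombe 0.5
correction when a cell is empty.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .datatypes import DataValidationError, case_mask

METHODS = ("t", "mannwhitney", "ks")

#: Label arrangements at or below this count trigger exhaustive enumeration.
EXHAUSTIVE_CAP = 1_000_000


# ---------------------------------------------------------------------------
# observed statistics


def two_sample_stat(scores, labels, method: str = "t") -> float:
    """Observed case-vs-control statistic.

    ``t`` is the Welch (unequal-variance) t statistic on group means;
    ``mannwhitney`` is the U statistic of the case group; ``ks`` is the
    sup-distance between the two empirical CDFs.  A zero pooled variance
    under ``t`` is an error — use the Mann-Whitney or KS statistic for
    degenerate score distributions.
    """
    _check_method(method)
    scores = np.asarray(scores, dtype=float)
    case = case_mask(labels)
    x, y = scores[case], scores[~case]
    if x.size == 0 or y.size == 0:
        raise DataValidationError("both groups must be non-empty")
    if method == "t":
        if np.ptp(scores) == 0 or (np.ptp(x) == 0 and np.ptp(y) == 0):
            raise DataValidationError(
                "zero pooled variance: the t statistic is undefined; use "
                "method='mannwhitney' or 'ks'"
            )
        return float(sps.ttest_ind(x, y, equal_var=False).statistic)
    if method == "mannwhitney":
        return float(sps.mannwhitneyu(x, y, alternative="two-sided").statistic)
    return float(sps.ks_2samp(x, y).statistic)


def _check_method(method: str) -> None:
    if method not in METHODS:
        raise DataValidationError(f"method must be one of {METHODS}, got {method!r}")


# ---------------------------------------------------------------------------
# batch (vectorised) statistics over many label arrangements
#
# X is (n_individuals, n_hypotheses); masks is (B, n) boolean case
# indicators.  All statistics are returned on a *centered* effect scale
# so that |stat| is a two-sided exceedance measure: Welch t as-is, U
# shifted by its null mean n1*n2/2, KS as-is (non-negative).  Degenerate
# hypothesis columns yield statistic 0.


def _batch_stats(X: np.ndarray, masks: np.ndarray, method: str) -> np.ndarray:
    n, n_hyp = X.shape
    M = masks.astype(float)
    n1 = M.sum(axis=1)
    n2 = n - n1
    if (n1 == 0).any() or (n2 == 0).any():
        raise DataValidationError("a permutation produced an empty group")
    if method == "t":
        s_all = X.sum(axis=0)
        q_all = (X * X).sum(axis=0)
        s1 = M @ X
        q1 = M @ (X * X)
        m1 = s1 / n1[:, None]
        m2 = (s_all - s1) / n2[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            v1 = (q1 - n1[:, None] * m1 * m1) / (n1[:, None] - 1)
            v2 = ((q_all - q1) - n2[:, None] * m2 * m2) / (n2[:, None] - 1)
            t = (m1 - m2) / np.sqrt(v1 / n1[:, None] + v2 / n2[:, None])
        return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    if method == "mannwhitney":
        ranks = sps.rankdata(X, axis=0, method="average")
        r1 = M @ ranks
        u1 = r1 - n1[:, None] * (n1[:, None] + 1) / 2.0
        return u1 - n1[:, None] * n2[:, None] / 2.0
    # Kolmogorov-Smirnov, one hypothesis column at a time
    out = np.empty((masks.shape[0], n_hyp))
    idx = np.arange(1, n + 1, dtype=float)
    for h in range(n_hyp):
        order = np.argsort(X[:, h], kind="stable")
        xs = X[order, h]
        if xs[0] == xs[-1]:
            out[:, h] = 0.0
            continue
        boundary = np.flatnonzero(np.append(xs[1:] != xs[:-1], True))
        cum = np.cumsum(masks[:, order], axis=1, dtype=float)
        f1 = cum[:, boundary] / n1[:, None]
        f2 = (idx[boundary][None, :] - cum[:, boundary]) / n2[:, None]
        out[:, h] = np.abs(f1 - f2).max(axis=1)
    return out


def _observed_effect(X: np.ndarray, case: np.ndarray, method: str) -> np.ndarray:
    return _batch_stats(X, case[None, :], method)[0]


# ---------------------------------------------------------------------------
# permutation streams


def _strata_codes(strata, n: int) -> np.ndarray:
    if strata is None:
        return np.zeros(n, dtype=int)
    arr = np.asarray(strata)
    if arr.shape[0] != n:
        raise DataValidationError("strata must align with labels")
    return pd.factorize(arr)[0]


def count_arrangements(case: np.ndarray, codes: np.ndarray) -> int:
    """Number of distinct case-label placements respecting strata."""
    total = 1
    for code in np.unique(codes):
        rows = codes == code
        total *= math.comb(int(rows.sum()), int(case[rows].sum()))
        if total > 10 * EXHAUSTIVE_CAP:
            break
    return total


def _exhaustive_masks(case: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """All distinct stratified case-label arrangements as a (B, n) array."""
    n = case.size
    per_stratum = []
    for code in np.unique(codes):
        rows = np.flatnonzero(codes == code)
        k = int(case[rows].sum())
        per_stratum.append([rows[list(c)] for c in itertools.combinations(range(rows.size), k)])
    masks = []
    for combo in itertools.product(*per_stratum):
        mask = np.zeros(n, dtype=bool)
        for chosen in combo:
            mask[chosen] = True
        masks.append(mask)
    return np.array(masks, dtype=bool)


def _montecarlo_masks(
    case: np.ndarray, codes: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    masks = np.tile(case, (n_permutations, 1))
    for code in np.unique(codes):
        rows = codes == code
        masks[:, rows] = rng.permuted(masks[:, rows], axis=1)
    return masks


@dataclass(frozen=True)
class PermutationResult:
    """A label-permutation test of one score vector."""

    observed: float
    method: str
    n_permutations: int
    exceedance: int
    p_value: float
    seed: int | None
    exhaustive: bool
    sided: str = "two"
    degenerate: bool = False


def permutation_pvalue(
    scores,
    labels,
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int = 0,
    sided: str = "two",
    strata=None,
    mode: str = "auto",
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> PermutationResult:
    """Permutation p-value for a case-control score comparison.

    ``mode='auto'`` enumerates all label arrangements exactly when their
    count is at most ``exhaustive_cap`` (exact p = b / B_total, the
    observed arrangement counted), otherwise draws ``n_permutations``
    Monte-Carlo label shuffles and reports ``p = (b + 1) / (B + 1)``.
    ``strata`` restricts shuffles to within-stratum swaps.  A degenerate
    score vector (all values equal) returns p = 1 by convention.
    """
    _check_method(method)
    if sided not in ("two", "greater", "less"):
        raise DataValidationError("sided must be 'two', 'greater' or 'less'")
    if n_permutations < 1:
        raise DataValidationError("n_permutations must be >= 1")
    scores = np.asarray(scores, dtype=float)
    case = case_mask(labels)
    if scores.shape[0] != case.shape[0]:
        raise DataValidationError("scores and labels must align")
    if case.all() or not case.any():
        raise DataValidationError("both groups must be non-empty")
    codes = _strata_codes(strata, scores.size)

    if np.ptp(scores) == 0:
        return PermutationResult(
            observed=0.0, method=method, n_permutations=0, exceedance=0,
            p_value=1.0, seed=seed, exhaustive=False, sided=sided,
            degenerate=True,
        )

    X = scores[:, None]
    obs_eff = _observed_effect(X, case, method)[0]
    observed = two_sample_stat(scores, labels, method)

    n_arrangements = count_arrangements(case, codes)
    exhaustive = mode == "exhaustive" or (
        mode == "auto" and n_arrangements <= exhaustive_cap
    )
    if mode not in ("auto", "exhaustive", "montecarlo"):
        raise DataValidationError(f"unknown mode {mode!r}")
    if exhaustive:
        masks = _exhaustive_masks(case, codes)
        effs = _batch_stats(X, masks, method)[:, 0]
        b = int(_count_exceedance(effs, obs_eff, sided))
        return PermutationResult(
            observed=observed, method=method, n_permutations=masks.shape[0],
            exceedance=b, p_value=b / masks.shape[0], seed=None,
            exhaustive=True, sided=sided,
        )
    rng = np.random.default_rng(seed)
    masks = _montecarlo_masks(case, codes, n_permutations, rng)
    effs = _batch_stats(X, masks, method)[:, 0]
    b = int(_count_exceedance(effs, obs_eff, sided))
    return PermutationResult(
        observed=observed, method=method, n_permutations=n_permutations,
        exceedance=b, p_value=(b + 1) / (n_permutations + 1), seed=seed,
        exhaustive=False, sided=sided,
    )


def _count_exceedance(effs: np.ndarray, obs: float, sided: str) -> np.ndarray:
    tol = 1e-12  # guard against float jitter in tie comparisons
    if sided == "two":
        return (np.abs(effs) >= abs(obs) - tol).sum(axis=0)
    if sided == "greater":
        return (effs >= obs - tol).sum(axis=0)
    return (effs <= obs + tol).sum(axis=0)


@dataclass(frozen=True)
class MaxTResult:
    """Single-step max(T) adjustment over a hypothesis family."""

    table: pd.DataFrame  # observed, raw_p, adjusted_p per hypothesis
    method: str
    n_permutations: int
    seed: int | None
    exhaustive: bool

    @property
    def raw_p(self) -> pd.Series:
        return self.table["raw_p"]

    @property
    def adjusted_p(self) -> pd.Series:
        return self.table["adjusted_p"]


def maxt_adjust(
    score_matrix,
    labels,
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int = 0,
    strata=None,
    mode: str = "auto",
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> MaxTResult:
    """Family-wise adjusted p-values by single-step max(T) permutation.

    ``score_matrix`` is hypotheses × individuals (DataFrame rows are
    hypothesis names).  All hypotheses share one permutation stream; for
    each permutation the maximum |statistic| over hypotheses is recorded
    and ``adjusted_p_h`` is the exceedance fraction of those maxima over
    the observed |statistic| of hypothesis *h*.  Raw per-hypothesis
    p-values come from the same stream, so ``adjusted >= raw`` pointwise.
    Degenerate hypothesis rows (constant scores) carry statistic 0.
    """
    _check_method(method)
    if isinstance(score_matrix, pd.DataFrame):
        names = list(score_matrix.index)
        X = score_matrix.to_numpy(dtype=float).T
    else:
        X = np.asarray(score_matrix, dtype=float).T
        names = [f"h{i}" for i in range(X.shape[1])]
    case = case_mask(labels)
    if X.shape[0] != case.size:
        raise DataValidationError("score matrix columns must align with labels")
    codes = _strata_codes(strata, case.size)

    obs = np.abs(_observed_effect(X, case, method))
    n_arrangements = count_arrangements(case, codes)
    exhaustive = mode == "exhaustive" or (
        mode == "auto" and n_arrangements <= exhaustive_cap
    )
    if exhaustive:
        masks = _exhaustive_masks(case, codes)
        used_seed = None
    else:
        rng = np.random.default_rng(seed)
        masks = _montecarlo_masks(case, codes, n_permutations, rng)
        used_seed = seed
    effs = np.abs(_batch_stats(X, masks, method))
    maxima = effs.max(axis=1)
    tol = 1e-12
    raw_b = (effs >= obs[None, :] - tol).sum(axis=0)
    adj_b = (maxima[:, None] >= obs[None, :] - tol).sum(axis=0)
    B = masks.shape[0]
    if exhaustive:
        raw_p, adj_p = raw_b / B, adj_b / B
    else:
        raw_p, adj_p = (raw_b + 1) / (B + 1), (adj_b + 1) / (B + 1)
    table = pd.DataFrame(
        {
            "observed": np.where(
                np.ptp(X, axis=0) == 0, 0.0,
                _observed_effect(X, case, method),
            ),
            "raw_p": raw_p,
            "adjusted_p": adj_p,
        },
        index=pd.Index(names, name="hypothesis"),
    )
    return MaxTResult(
        table=table, method=method, n_permutations=B, seed=used_seed,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# single-variant log-additive association


@dataclass(frozen=True)
class SingleVariantResult:
    """Per-allele odds ratio from a log-additive logistic model."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    fit: str  # "ml", "firth", or "monomorphic"
    n: int

    @property
    def estimable(self) -> bool:
        return self.fit != "monomorphic"


def _firth_penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    loglik = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = expit(eta)
    w = np.clip(p * (1 - p), 1e-10, None)
    sign, logdet = np.linalg.slogdet((X.T * w) @ X)
    return loglik + 0.5 * logdet


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200):
    """Firth-penalized logistic regression (Jeffreys-prior score correction).

    Newton iterations with a step-size cap and step-halving on the
    penalized log-likelihood, so the fit stays finite under separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll = _firth_penalized_loglik(X, y, beta)
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        info = (X.T * w) @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        biggest = np.max(np.abs(step))
        if biggest > 5.0:  # cap the Newton step
            step = step * (5.0 / biggest)
        candidate = beta + step
        ll_new = _firth_penalized_loglik(X, y, candidate)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 25:
            step = step / 2.0
            candidate = beta + step
            ll_new = _firth_penalized_loglik(X, y, candidate)
            halvings += 1
        beta, converged = candidate, np.max(np.abs(step)) < 1e-8
        ll = ll_new
        if converged:
            break
    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-10, None)
    cov = np.linalg.pinv((X.T * w) @ X)
    return beta, np.sqrt(np.diag(cov))


def single_variant_assoc(
    dosage,
    labels,
    stratum_covariate=None,
) -> SingleVariantResult:
    """Log-additive logistic association of status on a dosage vector.

    Fits ``logit Pr(case) = a + beta * dosage (+ stratum indicators)``
    by maximum likelihood; the per-allele odds ratio is ``exp(beta)``
    with a Wald 95% CI.  On separation (non-finite or diverging ML fit)
    the model is refit with Firth's penalty and flagged.  Missing
    dosages are dropped; a monomorphic dosage yields no estimate.
    """
    import statsmodels.api as sm

    dosage = np.asarray(dosage, dtype=float)
    y = case_mask(labels).astype(float)
    keep = ~np.isnan(dosage)
    dosage, y = dosage[keep], y[keep]
    columns = [np.ones_like(dosage), dosage]
    if stratum_covariate is not None:
        strat = np.asarray(stratum_covariate)[keep]
        codes, levels = pd.factorize(strat)
        for level in range(1, len(levels)):
            columns.append((codes == level).astype(float))
    X = np.column_stack(columns)
    n = int(y.size)
    if np.ptp(dosage) == 0:
        return SingleVariantResult(
            odds_ratio=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            p_value=float("nan"), beta=float("nan"), se=float("nan"),
            fit="monomorphic", n=n,
        )

    beta = se = None
    fit = "ml"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if (
            res.mle_retvals.get("converged", False)
            and np.all(np.isfinite(res.bse))
            and np.max(np.abs(res.params)) < 15
        ):
            beta, se = res.params[1], res.bse[1]
    except Exception:
        beta = None
    if beta is None or not np.isfinite(se) or se > 50:
        params, bse = _firth_logistic(X, y)
        beta, se = params[1], bse[1]
        fit = "firth"
    z = beta / se
    p = 2 * sps.norm.sf(abs(z))
    half = 1.959963984540054 * se
    return SingleVariantResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - half)),
        ci_high=float(np.exp(beta + half)),
        p_value=float(p),
        beta=float(beta),
        se=float(se),
        fit=fit,
        n=n,
    )


# ---------------------------------------------------------------------------
# dichotomized odds ratios


@dataclass(frozen=True)
class OddsRatioResult:
    """2×2 odds ratio for score-above vs score-below a cutpoint.

    Table layout: rows = (above, below), columns = (case, control);
    ``OR = (case_above * control_below) / (control_above * case_below)``.
    """

    table: np.ndarray
    odds_ratio: float
    ci_low: float
    ci_high: float
    rule: str
    cutpoint: float | tuple[float, float]
    haldane_corrected: bool
    n_excluded: int


def dichotomized_or(
    scores,
    labels,
    rule="median_of_controls",
    ties: str | None = None,
) -> OddsRatioResult:
    """Case-control odds ratio after dichotomizing a score vector.

    Rules:

    * ``"median_of_controls"`` — cut at the control median; scores
      strictly above the cut form the "above" arm, ties go below.
    * ``("fixed_cut", c)`` — cut at ``c``; by default individuals whose
      score equals the cut are excluded (``ties="exclude"``), or pass
      ``ties="below"`` to pool them with the below arm.
    * ``("extremes", lo, hi)`` — keep only scores <= lo (below arm) or
      >= hi (above arm); everyone strictly between is dropped.

    A zero cell triggers the Haldane-Anscombe 0.5 correction (flagged);
    the CI is the Woolf log interval.  An empty arm is an error.
    """
    scores = np.asarray(scores, dtype=float)
    case = case_mask(labels)

    if rule == "median_of_controls":
        if (~case).sum() == 0:
            raise DataValidationError("no controls to take the median of")
        cut = float(np.median(scores[~case]))
        above = scores > cut
        keep = np.ones_like(above)
        rule_name, cutpoint = "median_of_controls", cut
    elif isinstance(rule, (tuple, list)) and rule[0] == "fixed_cut":
        cut = float(rule[1])
        ties = "exclude" if ties is None else ties
        if ties not in ("exclude", "below"):
            raise DataValidationError("ties must be 'exclude' or 'below'")
        above = scores > cut
        keep = (scores != cut) if ties == "exclude" else np.ones_like(above)
        rule_name, cutpoint = "fixed_cut", cut
    elif isinstance(rule, (tuple, list)) and rule[0] == "extremes":
        lo, hi = float(rule[1]), float(rule[2])
        if lo >= hi:
            raise DataValidationError("extremes rule needs lo < hi")
        above = scores >= hi
        keep = (scores <= lo) | (scores >= hi)
        rule_name, cutpoint = "extremes", (lo, hi)
    else:
        raise DataValidationError(f"unknown dichotomization rule {rule!r}")

    case_k, above_k = case[keep], above[keep]
    a = int((above_k & case_k).sum())       # cases above
    b = int((above_k & ~case_k).sum())      # controls above
    c = int((~above_k & case_k).sum())      # cases below
    d = int((~above_k & ~case_k).sum())     # controls below
    if a + b == 0 or c + d == 0:
        raise DataValidationError("an arm is empty after dichotomization")
    if a + c == 0 or b + d == 0:
        raise DataValidationError("a label group is empty after dichotomization")
    table = np.array([[a, b], [c, d]], dtype=float)
    corrected = (table == 0).any()
    work = table + 0.5 if corrected else table
    odds_ratio = (work[0, 0] * work[1, 1]) / (work[0, 1] * work[1, 0])
    se = math.sqrt((1.0 / work).sum())
    half = 1.959963984540054 * se
    return OddsRatioResult(
        table=table.astype(int),
        odds_ratio=float(odds_ratio),
        ci_low=float(odds_ratio * math.exp(-half)),
        ci_high=float(odds_ratio * math.exp(half)),
        rule=rule_name,
        cutpoint=cutpoint,
        haldane_corrected=bool(corrected),
        n_excluded=int((~keep).sum()),
    )
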