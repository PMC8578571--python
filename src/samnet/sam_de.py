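"""Significance Analysis of Microarrays (SAM) for two-group designs.

For each gene the regularised statistic

    d = r / (s + s0)

is computed, where r is the difference of group means on the log2 scale,
s the pooled standard error, and s0 a small positive "fudge factor" that
stabilises d for low-variance genes.  Significance comes from a
permutation null: every relabelling of the samples into two groups of the
original sizes is enumerated when the number of distinct assignments is
small enough (C(12,6) = 924 for the 6 vs 6 design), otherwise a seeded
sample of distinct assignments is drawn.  Null d values are pooled across
genes and permutations; p-values are two-sided empirical tail
probabilities with an add-one correction, and q-values come from
SAM-style discretised rejection regions.

Differentially expressed genes (DEGs) are called at q < 0.05 together
with a signed linear fold change beyond +/-1.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, GroupDesign, signed_fold_change_from_diff

logger = logging.getLogger(__name__)

CV_MINIMISATION = "cv_minimisation"
PERCENTILE = "percentile"
FIXED = "fixed"

REG_UP = "up"
REG_DOWN = "down"
REG_NONE = "none"


@dataclass
class SamParams:
    """Tunable parameters of a SAM run.

    n_permutations caps the size of the permutation null (the full set of
    label assignments is enumerated whenever it fits under the cap);
    q_threshold / fc_threshold are the DEG gates.
    """

    n_permutations: int = 1000
    s0_strategy: str = CV_MINIMISATION
    s0_value: float = 0.0          # used when s0_strategy == "fixed"
    s0_percentile: float = 50.0    # used when s0_strategy == "percentile"
    seed: int = 0
    q_threshold: float = 0.05
    fc_threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.q_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.s0_strategy not in (CV_MINIMISATION, PERCENTILE, FIXED):
            raise ValueError(f"unknown s0 strategy {self.s0_strategy!r}")


def _group_indices(m: ExpressionMatrix, design: GroupDesign) -> tuple[np.ndarray, np.ndarray]:
    cols = {s: i for i, s in enumerate(m.sample_ids)}
    ctrl = np.array([cols[s] for s in design.control_samples], dtype=int)
    expt = np.array([cols[s] for s in design.experimental_samples], dtype=int)
    if len(ctrl) < 2 or len(expt) < 2:
        raise ValueError("each group needs at least 2 samples")
    return ctrl, expt


def _r_s_for_assignments(X: np.ndarray, ctrl_mask: np.ndarray, exp_mask: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised r and pooled-SE s for a batch of label assignments.

    X is genes x samples; ctrl_mask / exp_mask are assignments x samples
    0/1 floats.  Returns (r, s), each genes x assignments.
    """
    n1 = ctrl_mask.sum(axis=1)
    n2 = exp_mask.sum(axis=1)
    sum1 = X @ ctrl_mask.T
    sum2 = X @ exp_mask.T
    sq = X * X
    ss1 = sq @ ctrl_mask.T
    ss2 = sq @ exp_mask.T
    mean1 = sum1 / n1
    mean2 = sum2 / n2
    r = mean2 - mean1
    within = (ss1 - n1 * mean1 ** 2) + (ss2 - n2 * mean2 ** 2)
    within = np.maximum(within, 0.0)  # guard tiny negative rounding
    dof = n1 + n2 - 2
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * within / dof)
    return r, s


def compute_d_scores(m: ExpressionMatrix, design: GroupDesign, s0: float) -> pd.DataFrame:
    """Per-gene r, s and d = r/(s + s0) for the observed labels.

    r = mean(experimental) - mean(control) in log2 units;
    s = sqrt((1/n1 + 1/n2) * pooled within-group sum of squares / (n1+n2-2)).
    """
    if m.scale != "log2":
        raise ValueError("SAM statistics require a log2-scale matrix")
    ctrl, expt = _group_indices(m, design)
    X = m.values.to_numpy(dtype=float)
    S = X.shape[1]
    ctrl_mask = np.zeros((1, S))
    exp_mask = np.zeros((1, S))
    ctrl_mask[0, ctrl] = 1.0
    exp_mask[0, expt] = 1.0
    r, s = _r_s_for_assignments(X, ctrl_mask, exp_mask)
    r = r[:, 0]
    s = s[:, 0]
    if s0 == 0.0 and np.any(s == 0.0):
        bad = m.feature_ids[int(np.argmax(s == 0.0))]
        raise ValueError(
            f"gene {bad!r} has zero variance in both groups; d is undefined with "
            "s0 = 0 — use a positive s0 (e.g. the cv_minimisation estimate)"
        )
    d = r / (s + s0)
    return pd.DataFrame({"gene": m.feature_ids, "r": r, "s": s, "d": d}).set_index("gene")


def estimate_s0(
    s_values: np.ndarray,
    d_numerators: np.ndarray,
    strategy: str = CV_MINIMISATION,
    percentile: float = 50.0,
    n_bins: int = 10,
) -> float:
    """Choose the fudge factor s0 from the per-gene s and r values.

    ``cv_minimisation`` scans the percentiles {0, 5, ..., 100} of s and
    picks the candidate minimising the coefficient of variation of the
    spread (median absolute deviation) of d across s-quantile bins, so
    that the magnitude of d does not depend systematically on s — the
    canonical SAM tuning.  ``percentile`` simply returns the requested
    percentile of s (median by default).
    """
    s = np.asarray(s_values, dtype=float)
    r = np.asarray(d_numerators, dtype=float)
    if s.size == 0:
        raise ValueError("no s values")
    if np.all(s == s[0]):
        return float(s[0])  # any s0 rescales d uniformly
    if strategy == PERCENTILE:
        return float(np.percentile(s, percentile))
    if strategy != CV_MINIMISATION:
        raise ValueError(f"unknown s0 strategy {strategy!r}")

    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    n_bins = max(2, min(n_bins, s.size // 5)) if s.size >= 10 else 2
    bins = np.array_split(order, n_bins)
    s_min = s.min()
    best_s0, best_cv = float(candidates[candidates + s_min > 0][0]), math.inf
    for cand in candidates:
        if s_min + cand == 0:
            continue  # d undefined for zero-variance genes at this candidate
        d = r / (s + cand)
        spreads = []
        for b in bins:
            db = d[b]
            spreads.append(np.median(np.abs(db - np.median(db))))
        spreads = np.asarray(spreads)
        mu = spreads.mean()
        if mu == 0:
            continue
        cv = spreads.std() / mu
        if cv < best_cv - 1e-15:
            best_cv = cv
            best_s0 = float(cand)
    return best_s0


def n_distinct_assignments(n_control: int, n_experimental: int) -> int:
    """Number of distinct two-group relabellings of the pooled samples."""
    return math.comb(n_control + n_experimental, n_experimental)


def _assignment_combos(m: ExpressionMatrix, design: GroupDesign, params: SamParams
                       ) -> tuple[list[tuple[int, ...]], np.ndarray, bool]:
    """Experimental-index assignments for the permutation null.

    Full enumeration (itertools order, deterministic) when the number of
    distinct assignments fits under n_permutations, otherwise a seeded
    sample of distinct assignments.  Returns (combos, pooled sample
    indices, enumerated).
    """
    ctrl, expt = _group_indices(m, design)
    pool = np.concatenate([ctrl, expt])
    pool.sort()
    n2 = len(expt)
    total = math.comb(len(pool), n2)
    if total <= params.n_permutations:
        combos = list(combinations(pool.tolist(), n2))
        enumerated = True
    else:
        rng = np.random.default_rng(params.seed)
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < params.n_permutations:
            pick = tuple(sorted(rng.choice(pool, size=n2, replace=False).tolist()))
            chosen.add(pick)
        combos = sorted(chosen)
        enumerated = False
    return combos, pool, enumerated


def _d_for_combos(X: np.ndarray, combos: list[tuple[int, ...]], pool: np.ndarray,
                  s0: float) -> np.ndarray:
    """d matrix (assignments x genes) for experimental-index combos."""
    S = X.shape[1]
    P = len(combos)
    exp_masks = np.zeros((P, S))
    for i, combo in enumerate(combos):
        exp_masks[i, list(combo)] = 1.0
    pool_mask = np.zeros(S)
    pool_mask[pool] = 1.0
    ctrl_masks = pool_mask[None, :] - exp_masks
    r, s = _r_s_for_assignments(X, ctrl_masks, exp_masks)
    return (r / (s + s0)).T


def observed_and_null(m: ExpressionMatrix, design: GroupDesign, params: SamParams,
                      s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Observed d vector plus the null d matrix, in one batched pass.

    The observed labelling is evaluated inside the same batch as the
    permutations, so its d values are bitwise identical to the
    corresponding null row: the pooled-tail p then counts the observed
    assignment (and its complement) as exact ties, with no dependence on
    floating-point batching effects.  Under full enumeration the observed
    assignment is one of the enumerated rows; under sampling it is
    appended for the computation and excluded from the returned null.
    """
    combos, pool, enumerated = _assignment_combos(m, design, params)
    _, expt = _group_indices(m, design)
    obs_combo = tuple(sorted(expt.tolist()))
    X = m.values.to_numpy(dtype=float)
    if enumerated:
        null = _d_for_combos(X, combos, pool, s0)
        d_obs = null[combos.index(obs_combo)].copy()
        return d_obs, null
    logger.info(
        "sampled %d of %d possible assignments (seed=%d)",
        len(combos),
        n_distinct_assignments(len(design.control_samples), len(design.experimental_samples)),
        params.seed,
    )
    d_all = _d_for_combos(X, combos + [obs_combo], pool, s0)
    return d_all[-1].copy(), d_all[:-1]


def permutation_null(m: ExpressionMatrix, design: GroupDesign, params: SamParams,
                     s0: float) -> np.ndarray:
    """Null d-score matrix (assignments x genes) under group relabelling.

    s0 is the value fixed on the observed data and is reused unchanged for
    every permutation.  For the 6 vs 6 design all C(12,6) = 924 label
    assignments are enumerated exactly once (the observed assignment and
    every complement included), giving a fully deterministic null.
    """
    return observed_and_null(m, design, params, s0)[1]

def permutation_p(observed_d: np.ndarray | float, null_d: np.ndarray) -> np.ndarray | float:
    """Two-sided pooled-permutation p: (1 + #{|null| >= |d|}) / (1 + N).

    The null pool is flattened across genes and permutations (the SAM
    convention — per-gene nulls would rest on too few permutations).  The
    add-one keeps p strictly positive.
    """
    pool = np.sort(np.abs(np.asarray(null_d, dtype=float)), axis=None)
    n = pool.size
    if n == 0:
        raise ValueError("empty null pool")
    obs = np.abs(np.asarray(observed_d, dtype=float))
    scalar = obs.ndim == 0
    n_ge = n - np.searchsorted(pool, np.atleast_1d(obs), side="left")
    p = (1.0 + n_ge) / (1.0 + n)
    return float(p[0]) if scalar else p


def pi0_estimate(observed_d: np.ndarray, null_d: np.ndarray) -> float:
    """Fraction of genes estimated null: 2 * share of |d| below the null
    median of |d|, capped at 1."""
    med = np.median(np.abs(null_d))
    return float(min(1.0, 2.0 * np.mean(np.abs(observed_d) <= med)))


def q_values(observed_d: np.ndarray, null_d: np.ndarray) -> np.ndarray:
    """SAM-style q-values from discretised rejection regions.

    For each candidate threshold Delta (the sorted observed |d| values):
    observed positives O(Delta) = #{|d| >= Delta}; expected false
    positives F(Delta) = median over permutations of #{|d_null| >= Delta};
    FDR(Delta) = pi0 * F(Delta) / max(O(Delta), 1), clipped to [0, 1].  A
    gene's q is the minimum FDR over all thresholds it clears
    (Delta <= |d_gene|), which makes q non-increasing in |d|.
    """
    obs = np.abs(np.asarray(observed_d, dtype=float))
    null_abs = np.abs(np.asarray(null_d, dtype=float))
    if null_abs.ndim != 2:
        raise ValueError("null_d must be assignments x genes")
    G = obs.size
    order = np.argsort(obs, kind="stable")
    thresholds = obs[order]

    obs_sorted = np.sort(obs)
    O = G - np.searchsorted(obs_sorted, thresholds, side="left")

    null_sorted = np.sort(null_abs, axis=1)
    P, Gn = null_sorted.shape
    counts = np.empty((P, thresholds.size), dtype=np.int64)
    for i in range(P):
        counts[i] = Gn - np.searchsorted(null_sorted[i], thresholds, side="left")
    # permutation nulls carry Gn genes each; rescale the median count to the
    # observed gene universe when they differ (they agree in this pipeline)
    F = np.median(counts, axis=0) * (G / Gn)

    pi0 = pi0_estimate(obs, null_abs)
    fdr = np.clip(pi0 * F / np.maximum(O, 1), 0.0, 1.0)
    q_at_thr = np.minimum.accumulate(fdr)
    q = np.empty(G)
    q[order] = q_at_thr
    return q


def call_degs(results: pd.DataFrame, params: SamParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition called genes into (up, down) tables.

    up: q < q_threshold and fold_change > fc_threshold;
    down: q < q_threshold and fold_change < -fc_threshold.
    Both tables are ranked by increasing p, then q, then gene id.
    """
    req = {"q", "fold_change", "p"}
    if not req.issubset(results.columns):
        raise ValueError(f"results must contain columns {sorted(req)}")
    called = results[results["q"] < params.q_threshold]
    up = called[called["fold_change"] > params.fc_threshold].copy()
    down = called[called["fold_change"] < -params.fc_threshold].copy()
    for part in (up, down):
        # stable sort: gene id is the final tie-break after p then q
        part.sort_index(kind="stable", inplace=True)
        part.sort_values(["p", "q"], kind="stable", inplace=True)
        part["rank"] = np.arange(1, len(part) + 1)
    return up, down


def sam_analysis(m: ExpressionMatrix, design: GroupDesign, params: SamParams | None = None
                 ) -> pd.DataFrame:
    """Full SAM run: d scores, fold changes, permutation p, q, DEG calls.

    Returns a DataFrame indexed by gene with columns r, s, d, fold_change,
    p, q, regulation ('up'/'down'/'none') and rank (1..n over called genes
    in increasing-p order; <NA> for uncalled genes), sorted by increasing p.
    """
    params = params or SamParams()
    ctrl, expt = _group_indices(m, design)

    # r and s first (s0-independent), then s0, then d
    X = m.values.to_numpy(dtype=float)
    S = X.shape[1]
    ctrl_mask = np.zeros((1, S)); ctrl_mask[0, ctrl] = 1.0
    exp_mask = np.zeros((1, S)); exp_mask[0, expt] = 1.0
    r, s = _r_s_for_assignments(X, ctrl_mask, exp_mask)
    r, s = r[:, 0], s[:, 0]

    if params.s0_strategy == FIXED:
        s0 = params.s0_value
    else:
        s0 = estimate_s0(s, r, strategy=params.s0_strategy,
                         percentile=params.s0_percentile)
    if s0 == 0.0 and np.any(s == 0.0):
        raise ValueError("estimated s0 is 0 while some genes have zero variance; "
                         "set a positive s0")

    # observed d extracted from the same batch as the null, so the pooled
    # tail counts the observed assignment and its complement as exact ties
    d, null = observed_and_null(m, design, params, s0)
    p = permutation_p(d, null)
    q = q_values(d, null)
    fc = signed_fold_change_from_diff(r)

    out = pd.DataFrame(
        {"r": r, "s": s, "d": d, "fold_change": fc, "p": p, "q": q},
        index=pd.Index(m.feature_ids, name="gene"),
    )
    out.attrs["s0"] = s0
    out.attrs["n_null_assignments"] = null.shape[0]

    reg = np.full(len(out), REG_NONE, dtype=object)
    called = out["q"] < params.q_threshold
    reg[(called & (out["fold_change"] > params.fc_threshold)).to_numpy()] = REG_UP
    reg[(called & (out["fold_change"] < -params.fc_threshold)).to_numpy()] = REG_DOWN
    out["regulation"] = reg

    out = out.sort_index(kind="stable").sort_values(["p", "q"], kind="stable")
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    called_mask = out["regulation"] != REG_NONE
    out.loc[called_mask, "rank"] = np.arange(1, int(called_mask.sum()) + 1)
    return out


def write_sam_table(results: pd.DataFrame, path, header_lines=()) -> None:
    """Write the SAM result table as TSV (d score, fold change, p, q,
    regulation, rank), with optional ``#`` header comments."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        results.to_csv(fh, sep="\t", index_label="gene")
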