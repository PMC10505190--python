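"""Staircase ordering and scoring of cleaved/not-cleaved matrices.

A variant x target call matrix that obeys the cleavage rule is a Guttman
scalogram: once variants are sorted by how many targets they cleave and
targets by how many variants cleave them, the cleaved cells form a
staircase.  This module computes those orderings, fits the per-variant
staircase boundary, counts outlier cells, and scores the fit (pooled
G-mean, per-variant rank ROC/AUC).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .activity import ActivityMatrix, CallMatrix

# internal cell encoding: 1 = cleaved, 0 = not cleaved, -1 = missing
_CLEAVED, _NOT, _MISSING = 1, 0, -1


class RuleError(ValueError):
    pass


def _encode(calls: pd.DataFrame) -> np.ndarray:
    arr = np.full(calls.shape, _MISSING, dtype=np.int8)
    defined = calls.notna().to_numpy()
    truth = calls.fillna(False).to_numpy(dtype=bool)
    arr[defined & truth] = _CLEAVED
    arr[defined & ~truth] = _NOT
    return arr


def _misclass_table(m: np.ndarray) -> np.ndarray:
    """Per-row misclassification counts for every cutoff b = 0..T.

    For a row over ordered targets, predicting the first ``b`` targets
    cleaved misclassifies the not-cleaved cells among them plus the cleaved
    cells after them; missing cells never count.  Returns shape (V, T+1).
    """
    t = (m == _CLEAVED).astype(np.int32)
    f = (m == _NOT).astype(np.int32)
    zeros = np.zeros((m.shape[0], 1), dtype=np.int32)
    tc = np.concatenate([zeros, np.cumsum(t, axis=1)], axis=1)
    fc = np.concatenate([zeros, np.cumsum(f, axis=1)], axis=1)
    return fc + (tc[:, -1:] - tc)


def _total_outliers(m: np.ndarray) -> int:
    """Minimal total outliers of ``m`` under per-row optimal cutoffs."""
    return int(_misclass_table(m).min(axis=1).sum())


@dataclass
class RankedCleavageMap:
    """Orderings, staircase boundary and outliers of a call matrix."""

    variant_order: list
    target_order: list
    boundary: np.ndarray  # per ordered variant: number of top targets predicted cleaved
    outliers: list  # (variant_id, target_id, observed_call, predicted_call)
    calls: pd.DataFrame  # reordered calls (nullable boolean)
    theta: float
    monotone_boundary: bool = False

    @property
    def n_outliers(self) -> int:
        return len(self.outliers)

    def predicted(self) -> pd.DataFrame:
        """Predicted calls: for each variant, top ``b_v`` ranked targets cleaved."""
        n_t = len(self.target_order)
        pred = np.zeros((len(self.variant_order), n_t), dtype=bool)
        for i, b in enumerate(self.boundary):
            pred[i, :b] = True
        return pd.DataFrame(pred, index=self.variant_order, columns=self.target_order)

    def to_tsv(self, path) -> None:
        body = self.calls.map(lambda x: "" if pd.isna(x) else int(bool(x)))
        body.insert(0, "boundary", self.boundary)
        body.to_csv(path, sep="\t", index_label="variant_id")


@dataclass
class RuleFit:
    """Pooled confusion matrix of the staircase prediction vs observation."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan

    @property
    def gmean(self) -> float:
        """sqrt(sensitivity * specificity); NaN when either class is absent."""
        s, p = self.sensitivity, self.specificity
        return math.sqrt(s * p) if math.isfinite(s) and math.isfinite(p) else math.nan

    @property
    def defined(self) -> bool:
        return math.isfinite(self.sensitivity) and math.isfinite(self.specificity)

    @property
    def n_outliers(self) -> int:
        return self.fp + self.fn

    @property
    def n_cells(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class VariantROC:
    """Rank-based ROC of one variant's calls against the target order."""

    variant_id: str
    points: list  # (fpr, tpr), starts (0,0), ends (1,1)
    auc: float  # NaN when the column is single-class

    @property
    def defined(self) -> bool:
        return math.isfinite(self.auc)


def order_variants(calls: CallMatrix, activities: ActivityMatrix) -> list:
    """Order variants by descending cleaved-target count.

    Ties are broken by descending mean normalized activity, residual ties
    lexicographically by variant id.
    """
    if list(calls.calls.index) != list(activities.values.index) or list(
        calls.calls.columns
    ) != list(activities.values.columns):
        raise RuleError("calls and activities have mismatching axes")
    m = _encode(calls.calls)
    counts = (m == _CLEAVED).sum(axis=1)
    means = activities.values.mean(axis=1, skipna=True).to_numpy(dtype=float)
    keyed = sorted(
        zip(calls.variant_ids, counts, means),
        key=lambda r: (-r[1], -(r[2] if np.isfinite(r[2]) else -np.inf), str(r[0])),
    )
    return [vid for vid, _, _ in keyed]


def _exhaustive_block(
    m: np.ndarray, start: int, size: int
) -> tuple:
    """Best permutation of columns [start, start+size) minimizing total outliers.

    Evaluates every permutation of the tie block, vectorized via the
    decomposition of the cutoff scan into a fixed outside part and a
    block-local cumulative part.  Returns (best permutation of local
    indices, outliers achieved).  First (lexicographic) permutation wins
    ties.
    """
    v, t = m.shape
    end = start + size
    tbl = _misclass_table(m)
    t_tot = (m == _CLEAVED).sum(axis=1).astype(np.int32)
    # cutoffs outside the block are invariant under block permutation
    outside = np.concatenate([tbl[:, : start + 1], tbl[:, end:]], axis=1)
    fixed_min = outside.min(axis=1)
    pre_t = np.cumsum(m[:, :start] == _CLEAVED, axis=1)[:, -1] if start else np.zeros(v, np.int32)
    pre_f = np.cumsum(m[:, :start] == _NOT, axis=1)[:, -1] if start else np.zeros(v, np.int32)

    perms = np.array(list(itertools.permutations(range(size))), dtype=np.intp)
    block = m[:, start:end]  # (V, k)
    bt = (block == _CLEAVED).astype(np.int32)
    bf = (block == _NOT).astype(np.int32)
    # (V, P, k) cumulative counts within each permuted block
    btp = np.cumsum(bt[:, perms], axis=2)
    bfp = np.cumsum(bf[:, perms], axis=2)
    inside = (pre_f[:, None, None] + bfp) + (t_tot[:, None, None] - pre_t[:, None, None] - btp)
    row_min = np.minimum(fixed_min[:, None], inside.min(axis=2))
    totals = row_min.sum(axis=0)
    best = int(np.argmin(totals))  # first minimum = lexicographically smallest perm
    return tuple(perms[best]), int(totals[best])


def _hillclimb_block(m: np.ndarray, start: int, size: int) -> tuple:
    """Deterministic pairwise-swap descent within a tie block."""
    order = list(range(size))
    cur = _apply_block(m, start, order)
    best_out = _total_outliers(cur)
    improved = True
    while improved:
        improved = False
        for i in range(size - 1):
            for j in range(i + 1, size):
                cand = order.copy()
                cand[i], cand[j] = cand[j], cand[i]
                out = _total_outliers(_apply_block(m, start, cand))
                if out < best_out:
                    order, best_out = cand, out
                    improved = True
    return tuple(order), best_out


def _apply_block(m: np.ndarray, start: int, local_order) -> np.ndarray:
    cols = np.arange(m.shape[1])
    cols[start : start + len(local_order)] = start + np.asarray(local_order)
    return m[:, cols]


def _inversions(seq) -> int:
    seq = list(seq)
    return sum(
        1 for i in range(len(seq)) for j in range(i + 1, len(seq)) if seq[i] > seq[j]
    )


def _exhaustive_full(m: np.ndarray) -> list:
    """Globally optimal target order over all permutations (small maps).

    Among permutations with minimal total outliers, prefers the one
    closest to the descending cleaved-by-count order (fewest inversions
    against it), then the lexicographically smallest.  ``m`` columns must
    already be in the count-descending lexicographic order.
    """
    n_t = m.shape[1]
    perms = np.array(list(itertools.permutations(range(n_t))), dtype=np.intp)
    t = (m == _CLEAVED).astype(np.int32)
    f = (m == _NOT).astype(np.int32)
    totals = np.empty(len(perms), dtype=np.int64)
    chunk = 5040
    for s in range(0, len(perms), chunk):
        pc = perms[s : s + chunk]
        tc = np.cumsum(t[:, pc], axis=2)  # (V, P, T)
        fc = np.cumsum(f[:, pc], axis=2)
        t_tot = tc[:, :, -1:]
        # cutoff b = 0 gives t_tot; b = 1..T given by the cumsums
        mis = np.concatenate([t_tot, fc + (t_tot - tc)], axis=2)
        totals[s : s + chunk] = mis.min(axis=2).sum(axis=0)
    best = totals.min()
    candidates = np.nonzero(totals == best)[0]
    # enumeration is lexicographic, so the first minimal-inversion hit wins
    return list(perms[min(candidates, key=lambda i: _inversions(perms[i]))])


def order_targets(
    calls: CallMatrix,
    variant_order: list,
    *,
    exhaustive_limit: int = 8,
) -> list:
    """Order targets by cleavability to minimize staircase outliers.

    The guiding key is the descending cleaved-by count.  Maps with up to
    ``exhaustive_limit`` targets are solved exactly over every target
    permutation (count order preferred among outlier ties, then
    lexicographic).  Larger maps keep the count order as the primary key
    and optimize within count-tie blocks — exhaustively for blocks up to
    ``exhaustive_limit`` targets, by deterministic pairwise-swap descent
    beyond — followed by a global swap-descent pass; everything is
    deterministic and randomness-free.
    """
    df = calls.calls.loc[variant_order]
    m_full = _encode(df)
    cleaved_by = (m_full == _CLEAVED).sum(axis=0)
    # guiding key: descending count; provisional tie order: lexicographic
    target_ids = list(df.columns)
    order = sorted(range(len(target_ids)), key=lambda j: (-cleaved_by[j], str(target_ids[j])))
    m = m_full[:, order]

    if len(order) <= exhaustive_limit:
        best = _exhaustive_full(m)
        return [target_ids[order[j]] for j in best]

    # tie blocks over the ordered counts
    blocks = []
    sorted_counts = [cleaved_by[j] for j in order]
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and sorted_counts[j] == sorted_counts[i]:
            j += 1
        if j - i > 1:
            blocks.append((i, j - i))
        i = j

    # Coordinate descent over blocks until a fixed point.  Both searchers
    # return the identity whenever it ties the optimum (identity is first in
    # lexicographic enumeration), so any non-identity result is a strict
    # improvement and the loop terminates.
    changed = True
    while changed:
        changed = False
        for start, size in blocks:
            if size <= exhaustive_limit:
                local, _ = _exhaustive_block(m, start, size)
            else:
                local, _ = _hillclimb_block(m, start, size)
            if local != tuple(range(size)):
                m = _apply_block(m, start, local)
                seg = order[start : start + size]
                order[start : start + size] = [seg[k] for k in local]
                changed = True

    # global pairwise-swap descent: lets the count order bend where that
    # strictly reduces outliers (deterministic scan, strict improvements only)
    n_t = len(order)
    improved = True
    while improved:
        improved = False
        best_out = _total_outliers(m)
        for i in range(n_t - 1):
            for j in range(i + 1, n_t):
                cols = np.arange(n_t)
                cols[i], cols[j] = j, i
                out = _total_outliers(m[:, cols])
                if out < best_out:
                    m = m[:, cols]
                    order[i], order[j] = order[j], order[i]
                    best_out = out
                    improved = True
    return [target_ids[j] for j in order]


def fit_boundary(
    ordered_calls: CallMatrix,
    *,
    monotone: bool = False,
    count_matched: bool = False,
) -> RankedCleavageMap:
    """Fit the per-variant staircase cutoff on an already-ordered matrix.

    Default mode picks, per variant, the cutoff ``b`` minimizing that
    variant's misclassified cells (ties -> smaller ``b``).
    ``count_matched=True`` instead fixes ``b`` at the variant's observed
    cleaved count.  ``monotone=True`` additionally forces ``b`` to be
    non-increasing down the fidelity ranking via a constrained pass.
    """
    df = ordered_calls.calls
    m = _encode(df)
    tbl = _misclass_table(m)
    if count_matched:
        boundary = (m == _CLEAVED).sum(axis=1)
    else:
        boundary = tbl.argmin(axis=1)  # first minimum -> smallest b
    if monotone:
        cap = m.shape[1]
        mono = []
        for i in range(m.shape[0]):
            row = tbl[i, : cap + 1]
            b = int(np.argmin(row))
            mono.append(b)
            cap = b
        boundary = np.asarray(mono)
    boundary = np.asarray(boundary, dtype=int)

    outliers = []
    for i, vid in enumerate(df.index):
        for j, tid in enumerate(df.columns):
            if m[i, j] == _MISSING:
                continue
            observed = m[i, j] == _CLEAVED
            predicted = j < boundary[i]
            if observed != predicted:
                outliers.append((vid, tid, bool(observed), bool(predicted)))
    return RankedCleavageMap(
        variant_order=list(df.index),
        target_order=list(df.columns),
        boundary=boundary,
        outliers=outliers,
        calls=df,
        theta=ordered_calls.theta,
        monotone_boundary=monotone,
    )


def boundary_is_monotone(rmap: RankedCleavageMap) -> bool:
    """Whether the fitted boundary is non-increasing down the variant order."""
    b = rmap.boundary
    return bool(np.all(b[1:] <= b[:-1]))


def score_rule_fit(rmap: RankedCleavageMap) -> RuleFit:
    """Pool the confusion matrix of staircase prediction vs observed calls."""
    m = _encode(rmap.calls)
    pred = np.zeros(m.shape, dtype=bool)
    for i, b in enumerate(rmap.boundary):
        pred[i, :b] = True
    defined = m != _MISSING
    obs = m == _CLEAVED
    tp = int(np.sum(defined & obs & pred))
    fp = int(np.sum(defined & ~obs & pred))
    tn = int(np.sum(defined & ~obs & ~pred))
    fn = int(np.sum(defined & obs & ~pred))
    return RuleFit(tp=tp, fp=fp, tn=tn, fn=fn)


def variant_roc(target_order: list, calls_for_variant: pd.Series, variant_id: str = "") -> VariantROC:
    """Rank ROC for one variant's calls against the target cleavability order.

    The score of a target is its cleavability rank (targets earlier in
    ``target_order`` score higher, predicting cleaved).  The AUC is the
    tie-aware rank (Mann-Whitney) statistic; the trapezoidal area under
    the swept curve is computed independently and must agree to 1e-12.
    """
    labels = calls_for_variant.reindex(target_order)
    if labels.isna().any():
        raise RuleError(f"calls undefined for some ordered targets ({variant_id!r})")
    y = labels.to_numpy(dtype=bool)
    n = len(y)
    scores = np.arange(n, 0, -1, dtype=float)  # rank 1 (most cleavable) -> highest score

    n_pos = int(y.sum())
    n_neg = n - n_pos
    # curve: sweep thresholds over descending unique scores
    points = [(0.0, 0.0)]
    tp = fp = 0
    for s in np.unique(scores)[::-1]:
        sel = scores == s
        tp += int((y & sel).sum())
        fp += int((~y & sel).sum())
        points.append(
            (fp / n_neg if n_neg else math.nan, tp / n_pos if n_pos else math.nan)
        )
    if n_pos == 0 or n_neg == 0:
        return VariantROC(variant_id=variant_id, points=points, auc=math.nan)

    ranks = rankdata(scores)  # mid-ranks on ties
    auc_rank = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc_trap = float(np.trapezoid(tpr, fpr))
    if abs(auc_rank - auc_trap) > 1e-12:
        raise RuleError("rank AUC and trapezoidal AUC disagree beyond 1e-12")
    return VariantROC(variant_id=variant_id, points=points, auc=float(auc_rank))


def all_variant_rocs(rmap: RankedCleavageMap) -> dict:
    return {
        vid: variant_roc(rmap.target_order, rmap.calls.loc[vid], vid)
        for vid in rmap.variant_order
    }


def build_map(
    activities: ActivityMatrix,
    theta: float | None = None,
    *,
    exhaustive_limit: int = 8,
    monotone: bool = False,
    count_matched: bool = False,
) -> RankedCleavageMap:
    """Full ordering pipeline: call -> order variants -> order targets -> fit."""
    from .activity import call_cleavage

    cm = call_cleavage(activities, theta if theta is not None else activities.theta)
    vorder = order_variants(cm, activities)
    torder = order_targets(cm, vorder, exhaustive_limit=exhaustive_limit)
    ordered = CallMatrix(calls=cm.calls.loc[vorder, torder], theta=cm.theta)
    return fit_boundary(ordered, monotone=monotone, count_matched=count_matched)


def brute_force_best_order(calls: CallMatrix, max_cells: int = 24) -> tuple:
    """Global-optimum outlier count over every target permutation (test oracle).

    Variants keep their given row order (callers normally pre-order them);
    every permutation of targets is scored by summing per-variant minimal
    misclassification counts.  Refuses instances larger than ``max_cells``
    cells.  Returns (best target order, minimal outliers); ties resolve to
    the lexicographically smallest target-id permutation.
    """
    df = calls.calls
    n_v, n_t = df.shape
    if n_v * n_t > max_cells:
        raise RuleError(f"instance with {n_v * n_t} cells exceeds max_cells={max_cells}")
    m = _encode(df)
    ids = list(df.columns)
    best_order, best_out = None, None
    for perm in itertools.permutations(sorted(range(n_t), key=lambda j: str(ids[j]))):
        out = _total_outliers(m[:, perm])
        if best_out is None or out < best_out:
            best_order, best_out = perm, out
    return [ids[j] for j in best_order], int(best_out)
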