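"""Hypothesis-testing layer.

PERMANOVA partitions the squared dissimilarities between group labels and
tests the pseudo-F statistic by free label permutation; distance-based RDA
regresses the positive-eigenvalue PCoA axes on standardized explanatory
variables and tests the constrained fraction the same way; forward selection
steps through candidates by smallest marginal permutation p behind a global
gate. One-way ANOVA + Tukey HSD (raw data or summary statistics) yields a
compact letter display; Spearman/Pearson correlation and Benjamini-Hochberg
adjustment round out the utilities.

All permutation p-values use the add-one convention
p = (1 + #{stat_perm >= stat_obs}) / (1 + n_permutations), which cannot
return zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ordination import pcoa
from .types import DbRdaResult, DistanceMatrix, PermanovaResult, TukeyLetters, ValidationError

__all__ = [
    "permanova",
    "dbrda",
    "forward_select",
    "ForwardSelectionStep",
    "anova_tukey",
    "correlate",
    "bh_adjust",
]


# ---------------------------------------------------------------------------
# PERMANOVA

def _ss_within(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    return sum(d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx)) for idx in groups)


def _distinct_label_permutations(codes: np.ndarray):
    """All distinct arrangements of a label multiset (for exact enumeration)."""
    seen = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


def permanova(
    dist: DistanceMatrix,
    labels,
    n_permutations: int | str = 999,
    seed: int | None = None,
    factor: str = "group",
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within pools within-group pair sums
    scaled by group size; pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a));
    R^2 = SS_between/SS_total. ``n_permutations="exact"`` enumerates every
    distinct labeling (p = #{F_perm >= F_obs} / #labelings); otherwise the
    given number of free random permutations is drawn.
    """
    labels = np.asarray(pd.Series(list(labels)).astype(str))
    n = dist.n
    if len(labels) != n:
        raise ValidationError("labels length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = uniq[np.argmin(sizes)]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")

    d = dist.values
    off = d[np.triu_indices(n, 1)]
    if np.allclose(off, off[0]):
        raise ValidationError("constant distance matrix: pseudo-F undefined")
    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)

    def f_of(code_vec: np.ndarray) -> float:
        groups = [np.where(code_vec == g)[0] for g in range(a)]
        ssw = _ss_within(d2, groups)
        ssb = ss_total - ssw
        if ssw <= 0:
            return np.inf
        return (ssb / (a - 1)) / (ssw / (n - a))

    groups = [np.where(codes == g)[0] for g in range(a)]
    ssw = _ss_within(d2, groups)
    ssb = ss_total - ssw
    r2 = ssb / ss_total
    f_obs = f_of(codes)

    if n_permutations == "exact":
        count = total = 0
        for perm_codes in _distinct_label_permutations(codes):
            total += 1
            if f_of(perm_codes) >= f_obs - 1e-12:
                count += 1
        p = count / total
        n_perm_out = total
    else:
        rng = np.random.default_rng(seed)
        n_perm = int(n_permutations)
        exceed = 0
        for _ in range(n_perm):
            exceed += f_of(codes[rng.permutation(n)]) >= f_obs - 1e-12
        p = (1 + exceed) / (1 + n_perm)
        n_perm_out = n_perm
    return PermanovaResult(
        factor=factor,
        pseudo_F=float(f_obs),
        R2=float(r2),
        p_value=float(p),
        n_permutations=n_perm_out,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# db-RDA

def _standardize(x: pd.DataFrame, no_scale: set[str]) -> np.ndarray:
    out = np.empty(x.shape, dtype=float)
    for j, col in enumerate(x.columns):
        v = x[col].to_numpy(dtype=float)
        v = v - v.mean()
        if col not in no_scale:
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValidationError(f"explanatory variable {col!r} has zero variance")
            v = v / sd
        elif np.allclose(v, 0):
            raise ValidationError(f"explanatory variable {col!r} has zero variance")
        out[:, j] = v
    return out


def _collinear_columns(x: np.ndarray, columns) -> list[str]:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    return [str(columns[j]) for j in np.where(bad)[0]]


def _constrained_trace(x: np.ndarray, y: np.ndarray) -> float:
    """trace(Yhat' Yhat) for the least-squares projection of y on x."""
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    yhat = x @ coef
    return float(np.sum(yhat**2))


def dbrda(
    dist: DistanceMatrix,
    explanatory: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
    no_scale: set[str] | frozenset[str] = frozenset({"pH"}),
) -> DbRdaResult:
    """Distance-based redundancy analysis.

    The response matrix is the positive-eigenvalue PCoA embedding of
    ``dist`` (negative axes dropped, keeping the constrained proportion
    interpretable). Explanatory columns are centered and z-scaled except
    those in ``no_scale`` (soil pH is conventionally left on its own scale,
    centered only). The permutation test shuffles explanatory rows.
    """
    ord_res = pcoa(dist)
    y = ord_res.coordinates.to_numpy()
    n, q = y.shape
    if explanatory.shape[0] != n:
        raise ValidationError("explanatory rows do not match distance matrix")
    x = _standardize(explanatory, set(no_scale))
    k = x.shape[1]
    if np.linalg.matrix_rank(x) < k:
        bad = _collinear_columns(x, explanatory.columns)
        raise ValidationError(f"explanatory matrix is rank-deficient; collinear columns: {bad}")
    if k >= n:
        raise ValidationError("more explanatory variables than samples")

    total = float(np.sum(y**2))
    constrained = _constrained_trace(x, y)
    proportion = constrained / total
    resid_df = n - k - 1
    f_obs = (constrained / k) / max(total - constrained, 1e-300) * resid_df

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        xp = x[rng.permutation(n)]
        c = _constrained_trace(xp, y)
        f_perm = (c / k) / max(total - c, 1e-300) * resid_df
        exceed += f_perm >= f_obs - 1e-12
    p = (1 + exceed) / (1 + n_permutations)

    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    yhat = x @ coef
    # constrained axes: eigen-structure of the fitted values
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    lam_c = (s**2)[s**2 > 1e-10]
    resid = y - yhat
    _, s_r, _ = np.linalg.svd(resid, full_matrices=False)
    lam_u = (s_r**2)[s_r**2 > 1e-10]
    n_axes = min(len(lam_c), k)
    coords = pd.DataFrame(
        (u * s)[:, :n_axes],
        index=explanatory.index,
        columns=[f"dbRDA{i + 1}" for i in range(n_axes)],
    )
    return DbRdaResult(
        constrained_proportion=float(proportion),
        constrained_eigenvalues=lam_c,
        unconstrained_eigenvalues=lam_u,
        pseudo_F=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        variables=[str(c) for c in explanatory.columns],
        coordinates=coords,
    )


@dataclass
class ForwardSelectionStep:
    variable: str
    pseudo_F: float
    p_value: float


def _partial_f(x_sel: np.ndarray | None, x_new: np.ndarray, y: np.ndarray, total: float) -> float:
    """Partial pseudo-F for adding one variable to the selected set."""
    n = y.shape[0]
    if x_sel is None or x_sel.shape[1] == 0:
        base = 0.0
        x_full = x_new
    else:
        base = _constrained_trace(x_sel, y)
        x_full = np.hstack([x_sel, x_new])
    k_full = x_full.shape[1]
    tr_full = _constrained_trace(x_full, y)
    resid = max(total - tr_full, 1e-300)
    return (tr_full - base) / (resid / (n - k_full - 1))


def forward_select(
    dist: DistanceMatrix,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_permutations: int = 499,
    seed: int | None = None,
    no_scale: set[str] | frozenset[str] = frozenset({"pH"}),
) -> list[ForwardSelectionStep]:
    """Permutation forward selection of explanatory variables for db-RDA.

    A global permutation test of the full candidate set gates the procedure
    (double stopping: without a significant global model no variable enters,
    which keeps the family-wise false-selection rate near ``alpha`` under
    the null). Steps then add the candidate with the smallest marginal
    permutation p (ties broken toward the larger partial pseudo-F) until the
    best remaining p is >= ``alpha``. Candidates made collinear by earlier
    picks are skipped.
    """
    if candidates.shape[1] < 1:
        raise ValidationError("forward selection needs at least 1 candidate")
    rng = np.random.default_rng(seed)
    y = pcoa(dist).coordinates.to_numpy()
    total = float(np.sum(y**2))
    n = y.shape[0]
    x_all = _standardize(candidates, set(no_scale))
    names = [str(c) for c in candidates.columns]

    # global gate over all candidates (drop exactly collinear duplicates first)
    keep = []
    for j in range(x_all.shape[1]):
        trial = x_all[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    xg = x_all[:, keep]
    kg = xg.shape[1]
    if kg < n - 1:
        tr = _constrained_trace(xg, y)
        f_obs = (tr / kg) / max(total - tr, 1e-300) * (n - kg - 1)
        exceed = 0
        for _ in range(n_permutations):
            xp = xg[rng.permutation(n)]
            c = _constrained_trace(xp, y)
            exceed += (c / kg) / max(total - c, 1e-300) * (n - kg - 1) >= f_obs - 1e-12
        p_global = (1 + exceed) / (1 + n_permutations)
        if p_global >= alpha:
            return []

    selected: list[ForwardSelectionStep] = []
    sel_idx: list[int] = []
    remaining = list(range(x_all.shape[1]))
    while remaining:
        x_sel = x_all[:, sel_idx] if sel_idx else None
        best = None  # (p, -F, idx)
        for j in remaining:
            x_new = x_all[:, [j]]
            if x_sel is not None:
                trial = np.hstack([x_sel, x_new])
                if np.linalg.matrix_rank(trial) <= len(sel_idx):
                    continue  # collinear with current selection
            if len(sel_idx) + 2 >= n:
                continue  # no residual degrees of freedom left
            f_obs = _partial_f(x_sel, x_new, y, total)
            exceed = 0
            for _ in range(n_permutations):
                f_perm = _partial_f(x_sel, x_new[rng.permutation(n)], y, total)
                exceed += f_perm >= f_obs - 1e-12
            p = (1 + exceed) / (1 + n_permutations)
            key = (p, -f_obs, j)
            if best is None or key < best:
                best = key
                best_step = ForwardSelectionStep(names[j], float(f_obs), float(p))
        if best is None or best[0] >= alpha:
            break
        selected.append(best_step)
        sel_idx.append(best[2])
        remaining.remove(best[2])
    return selected


# ---------------------------------------------------------------------------
# ANOVA + Tukey compact letters

def _compact_letters(groups: list[str], means: dict[str, float],
                     significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Start from one column holding every group; for each significant pair
    sharing a column, split the column; absorb columns that became subsets.
    Letters are assigned in descending-mean order of first appearance.
    """
    columns: list[set[str]] = [set(groups)]
    for g1, g2 in sorted(significant):
        for col in list(columns):
            if g1 in col and g2 in col:
                c1 = col - {g2}
                c2 = col - {g1}
                columns.remove(col)
                columns.extend([c1, c2])
        # absorb subsets
        pruned: list[set[str]] = []
        for col in columns:
            if not any(col < other for other in columns if other is not col):
                if col not in pruned:
                    pruned.append(col)
        columns = pruned
    order = sorted(groups, key=lambda g: -means[g])
    # order columns by the highest-mean group they contain
    columns.sort(key=lambda col: min(order.index(g) for g in col) if col else len(order))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for li, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[li % len(alphabet)]
    return letters


def anova_tukey(
    values=None,
    groups=None,
    *,
    summaries: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> TukeyLetters:
    """One-way ANOVA followed by Tukey HSD with a compact letter display.

    Either raw ``values``/``groups`` or ``summaries`` (DataFrame indexed by
    group with columns ``mean``, ``sd``, ``n``) may be given; with summaries
    the pooled mean square error is computed from the per-group variances.
    Groups sharing a letter are not separable by Tukey's test at ``alpha``.
    Zero pooled variance with unequal means makes every unequal pair
    significant (all-distinct letters), not an error.
    """
    if summaries is not None:
        summaries = summaries.copy()
        if (summaries["n"] < 2).any():
            raise ValidationError("summary input needs n >= 2 per group")
        names = [str(g) for g in summaries.index]
        means = {g: float(summaries.loc[g, "mean"]) for g in names}
        ns = {g: int(summaries.loc[g, "n"]) for g in names}
        sse = float(sum((ns[g] - 1) * summaries.loc[g, "sd"] ** 2 for g in names))
        df_err = sum(ns[g] - 1 for g in names)
        grand = sum(means[g] * ns[g] for g in names) / sum(ns.values())
        ssb = float(sum(ns[g] * (means[g] - grand) ** 2 for g in names))
    else:
        s = pd.Series(np.asarray(values, dtype=float), name="value")
        g = pd.Series([str(x) for x in groups], name="group")
        if len(s) != len(g):
            raise ValidationError("values and groups must have equal length")
        by = s.groupby(g.values)
        names = sorted(by.groups)
        counts = by.count()
        if (counts < 2).any():
            raise ValidationError("each group needs >= 2 observations")
        means = by.mean().to_dict()
        ns = counts.astype(int).to_dict()
        sse = float(((s - g.map(by.mean()).values) ** 2).sum())
        df_err = int(len(s) - len(names))
        grand = float(s.mean())
        ssb = float(sum(ns[k] * (means[k] - grand) ** 2 for k in names))
    a = len(names)
    if a < 2:
        raise ValidationError("need at least 2 groups")

    mse = sse / df_err if df_err > 0 else 0.0
    if mse > 0:
        f_stat = (ssb / (a - 1)) / mse
        anova_p = float(sps.f.sf(f_stat, a - 1, df_err))
    else:
        f_stat, anova_p = math.inf, 0.0

    significant: set[tuple[str, str]] = set()
    if mse == 0:
        for g1, g2 in itertools.combinations(names, 2):
            if means[g1] != means[g2]:
                significant.add((g1, g2))
    else:
        q_crit = sps.studentized_range.ppf(1 - alpha, a, df_err)
        for g1, g2 in itertools.combinations(names, 2):
            se = math.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            if abs(means[g1] - means[g2]) / se > q_crit:
                significant.add((g1, g2))
    letters = _compact_letters(names, means, significant)
    return TukeyLetters(letters=letters, alpha=alpha, anova_F=float(f_stat), anova_p=anova_p)


# ---------------------------------------------------------------------------
# correlation and multiplicity

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    return float(x @ y / math.sqrt((x @ x) * (y @ y)))


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient with p-value.

    Pearson p comes from the t-distribution with n-2 df. Spearman is
    Pearson on average ranks; its p is exact (full enumeration of rank
    permutations, two-sided) for n <= 9 and the t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or n < 4:
        raise ValidationError("correlate needs equal-length inputs with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("correlate requires finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance input: correlation undefined")

    if method == "pearson":
        r = _pearson(x, y)
        t = r * math.sqrt((n - 2) / max(1 - r**2, 1e-300))
        p = 2 * sps.t.sf(abs(t), n - 2)
        return r, float(min(p, 1.0))
    if method == "spearman":
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        r = _pearson(rx, ry)
        if n <= 9:
            rxc = rx - rx.mean()
            ryc = ry - ry.mean()
            denom = math.sqrt((rxc @ rxc) * (ryc @ ryc))
            perms = np.array(list(itertools.permutations(range(n))))
            r_perm = (rxc[perms] @ ryc) / denom
            p = float(np.mean(np.abs(r_perm) >= abs(r) - 1e-12))
        else:
            t = r * math.sqrt((n - 2) / max(1 - r**2, 1e-300))
            p = float(min(2 * sps.t.sf(abs(t), n - 2), 1.0))
        return r, p
    raise ValueError(f"unknown method {method!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
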