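"""Distance-based multivariate comparisons of diet composition.

Everything here is implemented from first principles on numpy arrays:
Bray-Curtis dissimilarity on (typically fourth-root transformed) gravimetric
prey matrices, group-average (UPGMA) agglomerative clustering with Newick
export, one-way and additive two-way PERMANOVA with permutation p-values,
and the univariate Kruskal-Wallis / Dunn's post-hoc pair.  scipy supplies
only reference distributions (chi-square, normal).

The PERMANOVA pseudo-F reduces to the classical ANOVA F when the distance is
squared-Euclidean on univariate data; that identity is the main correctness
oracle for the implementation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .data_model import DietMatrix
from .errors import NoDataError, ValidationError

# ---------------------------------------------------------------------------
# transforms and distances
# ---------------------------------------------------------------------------


def fourth_root(x):
    """Elementwise fourth-root transform; a strong down-weighting of dominant
    prey so that rare groups contribute to the dissimilarity structure."""
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValidationError("fourth-root transform requires non-negative entries")
    out = arr ** 0.25
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample identifiers."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("distance matrix must be square and match ids")
        if np.isnan(v).any():
            raise ValidationError("distance matrix contains NaN")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric (tol 1e-12)")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(dtype=float))


def bray_curtis(X, ids: list[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x - y| / sum(x + y).

    Rows are samples (stomachs or pooled strata), columns prey groups.  A
    pair in which both rows are all-zero has an undefined ratio; it is
    defined as 0 here (identical emptiness) with a warning.
    """
    if isinstance(X, pd.DataFrame):
        if ids is None:
            ids = [str(i) for i in X.index]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least two samples")
    if (X < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative entries")
    if ids is None:
        ids = [str(i) for i in range(X.shape[0])]
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    zero_pairs = den == 0
    if zero_pairs.sum() > len(X):  # off-diagonal all-zero pairs exist
        warnings.warn(
            "all-zero sample pair(s): Bray-Curtis undefined, set to 0", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(zero_pairs, 0.0, num / np.where(zero_pairs, 1.0, den))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry
    return DistanceMatrix(ids=list(ids), values=d)


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------


@dataclass
class MergeTree:
    """Agglomerative clustering result in scipy-like encoding.

    ``merges`` is an (n-1) x 4 array: child id a, child id b, merge height,
    merged size.  Leaves are ids 0..n-1 in ``leaf_labels`` order; merge k
    creates id n + k.  Group-average linkage guarantees non-decreasing merge
    heights.
    """

    leaf_labels: list[str]
    merges: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def similarity_percent(self) -> list[float]:
        """Percent similarity (100 * (1 - height)) at each merge, for reports."""
        return [100.0 * (1.0 - h) for h in self.merges[:, 2]]


def upgma(D: DistanceMatrix) -> MergeTree:
    """Group-average hierarchical clustering.

    Inter-cluster distance is the size-weighted mean of all member pairwise
    distances (Lance-Williams update).  Ties are broken deterministically by
    the smallest label-sorted pair: each cluster is represented by its
    lexicographically smallest leaf label, and among equidistant pairs the
    smallest (rep_a, rep_b) pair merges first.
    """
    n = D.n
    if n < 2:
        raise ValidationError("need at least two samples to cluster")
    # active clusters: id -> (size, representative label)
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D.values[i, j]
    size = {i: 1 for i in range(n)}
    rep = {i: D.ids[i] for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            d = dist[(i, j) if i < j else (j, i)]
            key = (d, *sorted((rep[i], rep[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, a, b = best
        h = dist[(a, b) if a < b else (b, a)]
        merges.append([a, b, h, size[a] + size[b]])
        for k in active - {a, b}:
            dak = dist[(a, k) if a < k else (k, a)]
            dbk = dist[(b, k) if b < k else (k, b)]
            dist[(k, next_id)] = (size[a] * dak + size[b] * dbk) / (
                size[a] + size[b]
            )
        size[next_id] = size[a] + size[b]
        rep[next_id] = min(rep[a], rep[b])
        active -= {a, b}
        active.add(next_id)
        next_id += 1
    return MergeTree(leaf_labels=list(D.ids), merges=np.asarray(merges, dtype=float))


_NEWICK_RESERVED = set("(),:;'[] \t\n")


def _quote_label(label: str) -> str:
    if any(c in _NEWICK_RESERVED for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: MergeTree) -> str:
    """Serialise a merge tree as an ultrametric Newick string.

    Each merge at height h places its node at ultrametric depth h/2, so leaf
    branch lengths are half the first merge height and internal branch
    lengths are differences of successive half-heights.
    """
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    text = {i: _quote_label(lab) for i, lab in enumerate(tree.leaf_labels)}
    rep = {i: lab for i, lab in enumerate(tree.leaf_labels)}
    for k, (a, b, h, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        if rep[b] < rep[a]:  # children ordered by smallest leaf label
            a, b = b, a
        node_h = h / 2.0
        la = node_h - height[a]
        lb = node_h - height[b]
        nid = n + k
        text[nid] = f"({text[a]}:{float(la)!r},{text[b]}:{float(lb)!r})"
        height[nid] = node_h
        rep[nid] = min(rep[a], rep[b])
    root = n + len(tree.merges) - 1
    return text[root] + ";"


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Partitioned sums of squared dissimilarities with permutation p-values."""

    table: pd.DataFrame  # Source, df, SS, MS, pseudo_F, p
    n_permutations: int
    scheme: str
    seed: int | None
    degenerate: bool = False

    def to_json(self) -> str:
        payload = {
            "table": self.table.to_dict(orient="records"),
            "n_permutations": self.n_permutations,
            "scheme": self.scheme,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }
        import json

        return json.dumps(payload, indent=2)


def _check_groups(groups) -> np.ndarray:
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    singletons = labels[counts < 2]
    if len(singletons):
        raise ValidationError(
            f"group(s) of size one: {', '.join(map(str, singletons))}"
        )
    return g


def _oneway_ss(D2: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Total / within / between SS from squared dissimilarities and labels."""
    n = len(g)
    iu = np.triu_indices(n, 1)
    ss_total = D2[iu].sum() / n
    ss_within = 0.0
    for lab in np.unique(g):
        idx = np.flatnonzero(g == lab)
        sub = D2[np.ix_(idx, idx)]
        ss_within += np.triu(sub, 1).sum() / len(idx)
    return ss_total, ss_within, ss_total - ss_within


def _n_distinct_relabellings(counts: np.ndarray) -> float:
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova_oneway(
    D: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F on squared dissimilarities, permutation p.

    SS_total = (1/N) * sum_{i<j} d_ij^2, SS_within analogously per group;
    pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)).  The p-value counts
    relabellings with F_perm >= F_obs, with the +1 correction for Monte-Carlo
    sampling.  When the number of distinct relabellings is at most ``n_perm``
    the full enumeration is used instead and p is exact.
    """
    g = _check_groups(groups)
    if len(g) != D.n:
        raise ValidationError("group labels do not match distance matrix size")
    if n_perm < 1:
        raise ValidationError("need at least one permutation")
    D2 = D.values**2
    labels, counts = np.unique(g, return_counts=True)
    a = len(labels)
    N = D.n
    df_b, df_w = a - 1, N - a
    ss_total, ss_within, ss_between = _oneway_ss(D2, g)

    if ss_total <= 1e-300:
        table = pd.DataFrame(
            {
                "Source": ["Between", "Within", "Total"],
                "df": [df_b, df_w, N - 1],
                "SS": [0.0, 0.0, 0.0],
                "MS": [np.nan, np.nan, np.nan],
                "pseudo_F": [np.nan, np.nan, np.nan],
                "p": [np.nan, np.nan, np.nan],
            }
        )
        return PermanovaResult(table, 0, "degenerate", seed, degenerate=True)

    f_obs = (ss_between / df_b) / (ss_within / df_w)

    n_distinct = _n_distinct_relabellings(counts)
    if n_distinct <= n_perm:
        # exact: every distinct assignment of labels to positions
        from sympy.utilities.iterables import multiset_permutations

        count_ge = 0
        total = 0
        for perm in multiset_permutations(list(g)):
            _, ssw, ssb = _oneway_ss(D2, np.asarray(perm))
            f_p = (ssb / df_b) / (ssw / df_w) if ssw > 0 else np.inf
            if f_p >= f_obs - 1e-12:
                count_ge += 1
            total += 1
        p = count_ge / total
        n_done, scheme = total, "exact enumeration"
    else:
        rng = np.random.default_rng(seed)
        count_ge = 0
        for _ in range(n_perm):
            gp = rng.permutation(g)
            _, ssw, ssb = _oneway_ss(D2, gp)
            f_p = (ssb / df_b) / (ssw / df_w) if ssw > 0 else np.inf
            if f_p >= f_obs - 1e-12:
                count_ge += 1
        p = (count_ge + 1) / (n_perm + 1)
        n_done, scheme = n_perm, "free permutation of labels"

    table = pd.DataFrame(
        {
            "Source": ["Between", "Within", "Total"],
            "df": [df_b, df_w, N - 1],
            "SS": [ss_between, ss_within, ss_total],
            "MS": [ss_between / df_b, ss_within / df_w, np.nan],
            "pseudo_F": [f_obs, np.nan, np.nan],
            "p": [p, np.nan, np.nan],
        }
    )
    return PermanovaResult(table, n_done, scheme, seed)


def _gower_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def _hat(X: np.ndarray) -> np.ndarray:
    # pseudo-inverse hat matrix; tolerant to dummy-variable redundancy
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _dummies(f) -> np.ndarray:
    f = np.asarray(f)
    levels = pd.unique(pd.Series(f))
    return np.column_stack([(f == lv).astype(float) for lv in levels])


def permanova_twoway(
    D: DistanceMatrix,
    factor_a,
    factor_b,
    n_perm: int = 9999,
    seed: int | None = None,
    names: tuple[str, str] = ("A", "B"),
    scheme: str = "unrestricted",
) -> PermanovaResult:
    """Additive two-way PERMANOVA (main effects only, no interaction).

    The squared-dissimilarity matrix is Gower-centred to G and sums of
    squares are partitioned sequentially (type-I) through hat matrices of the
    expanding design [1], [1 A], [1 A B]:  SS_term = tr((H_k - H_{k-1}) G).
    The term order matters in unbalanced designs and is reported.  pseudo-F
    per term = MS_term / MS_residual; p by permutation of raw observations
    (rows and columns of G together), either unrestricted (default) or
    restricted within the levels of the other factor (``scheme="within-b"``
    permutes within factor-B blocks for the A test and vice versa).
    """
    fa, fb = np.asarray(factor_a), np.asarray(factor_b)
    if len(fa) != D.n or len(fb) != D.n:
        raise ValidationError("factor lengths do not match distance matrix")
    if n_perm < 1:
        raise ValidationError("need at least one permutation")
    cells = pd.crosstab(pd.Series(fa), pd.Series(fb))
    if (cells == 0).any().any():
        warnings.warn(
            "empty cells in the two-way design; sequential SS depends on term "
            f"order ({names[0]} before {names[1]})",
            stacklevel=2,
        )

    n = D.n
    G = _gower_center(D.values**2)
    A_dum, B_dum = _dummies(fa), _dummies(fb)
    if A_dum.shape[1] < 2:
        raise ValidationError(f"factor {names[0]} is constant")
    if B_dum.shape[1] < 2:
        # constant second factor: the design degenerates to the one-way case
        res = permanova_oneway(D, fa, n_perm=n_perm, seed=seed)
        tab = res.table.copy()
        tab.loc[0, "Source"] = names[0]
        return PermanovaResult(tab, res.n_permutations, res.scheme, seed,
                               degenerate=res.degenerate)
    ones = np.ones((n, 1))
    H0 = _hat(ones)
    H1 = _hat(np.hstack([ones, A_dum]))
    H2 = _hat(np.hstack([ones, A_dum, B_dum]))
    df_a = A_dum.shape[1] - 1
    df_b = B_dum.shape[1] - 1
    df_res = n - 1 - df_a - df_b

    def partition(Gm):
        ss_a = np.trace((H1 - H0) @ Gm)
        ss_b = np.trace((H2 - H1) @ Gm)
        ss_res = np.trace((np.eye(n) - H2) @ Gm)
        return ss_a, ss_b, ss_res

    ss_a, ss_b, ss_res = partition(G)
    ss_total = np.trace((np.eye(n) - H0) @ G)
    if ss_total <= 1e-300:
        table = pd.DataFrame(
            {
                "Source": [names[0], names[1], "Residual", "Total"],
                "df": [df_a, df_b, df_res, n - 1],
                "SS": [0.0] * 4,
                "MS": [np.nan] * 4,
                "pseudo_F": [np.nan] * 4,
                "p": [np.nan] * 4,
            }
        )
        return PermanovaResult(table, 0, "degenerate", seed, degenerate=True)

    ms_res = ss_res / df_res
    f_a = (ss_a / df_a) / ms_res
    f_b = (ss_b / df_b) / ms_res

    rng = np.random.default_rng(seed)
    count_a = count_b = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        if scheme == "unrestricted":
            pa = rng.permutation(idx)
            pb = pa
        elif scheme == "within-b":
            pa = _permute_within(rng, idx, fb)
            pb = _permute_within(rng, idx, fa)
        else:
            raise ValidationError(f"unknown permutation scheme {scheme!r}")
        Gp = G[np.ix_(pa, pa)]
        sa, _, sr = partition(Gp)
        if (sa / df_a) / (sr / df_res) >= f_a - 1e-12:
            count_a += 1
        if scheme == "unrestricted":
            _, sb, sr2 = partition(Gp)
            if (sb / df_b) / (sr2 / df_res) >= f_b - 1e-12:
                count_b += 1
        else:
            Gpb = G[np.ix_(pb, pb)]
            _, sb, sr2 = partition(Gpb)
            if (sb / df_b) / (sr2 / df_res) >= f_b - 1e-12:
                count_b += 1
    p_a = (count_a + 1) / (n_perm + 1)
    p_b = (count_b + 1) / (n_perm + 1)

    table = pd.DataFrame(
        {
            "Source": [names[0], names[1], "Residual", "Total"],
            "df": [df_a, df_b, df_res, n - 1],
            "SS": [ss_a, ss_b, ss_res, ss_a + ss_b + ss_res],
            "MS": [ss_a / df_a, ss_b / df_b, ms_res, np.nan],
            "pseudo_F": [f_a, f_b, np.nan, np.nan],
            "p": [p_a, p_b, np.nan, np.nan],
        }
    )
    return PermanovaResult(table, n_perm, scheme, seed)


def _permute_within(rng, idx, blocks):
    out = idx.copy()
    for lv in pd.unique(pd.Series(np.asarray(blocks))):
        sel = np.flatnonzero(np.asarray(blocks) == lv)
        out[sel] = rng.permutation(idx[sel])
    return out


def permanova_pairwise(
    D: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
    adjust: str = "none",
) -> pd.DataFrame:
    """One-way PERMANOVA restricted to every pair of groups.

    Returns one row per pair with pseudo-F and p; ``adjust="bonferroni"``
    multiplies p by the number of pairs (capped at 1).  Unadjusted by
    default, matching how pairwise tables are conventionally reported with
    raw significance bands.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    g = _check_groups(groups)
    labels = list(pd.unique(pd.Series(g)))
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for k, (la, lb) in enumerate(pairs):
        sel = np.flatnonzero((g == la) | (g == lb))
        sub = DistanceMatrix(
            ids=[D.ids[i] for i in sel], values=D.values[np.ix_(sel, sel)]
        )
        res = permanova_oneway(
            sub, g[sel], n_perm=n_perm, seed=None if seed is None else seed + k
        )
        p = res.table.loc[0, "p"]
        if adjust == "bonferroni" and not math.isnan(p):
            p = min(1.0, p * len(pairs))
        rows.append(
            {
                "group_a": la,
                "group_b": lb,
                "pseudo_F": res.table.loc[0, "pseudo_F"],
                "p": p,
                "n_permutations": res.n_permutations,
                "scheme": res.scheme,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# univariate nonparametric tests
# ---------------------------------------------------------------------------


def _ranks_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks and the tie-group sizes."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    tie_sizes = []
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        tie_sizes.append(j - i + 1)
        i = j + 1
    return ranks, np.asarray(tie_sizes)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square with k-1 df."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) < 2 or len(v) < 2:
        raise ValidationError("need at least two groups and two observations")
    N = len(v)
    ranks, ties = _ranks_with_ties(v)
    h = 0.0
    for lab in labels:
        sel = g == lab
        h += ranks[sel].sum() ** 2 / sel.sum()
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    tie_corr = 1.0 - (ties**3 - ties).sum() / (N**3 - N)
    if tie_corr <= 0:  # all values identical
        return 0.0, 1.0
    h /= tie_corr
    p = float(_stats.chi2.sf(h, len(labels) - 1))
    return float(h), p


def dunns_posthoc(values, groups, adjust: str = "none") -> pd.DataFrame:
    """Dunn's pairwise z tests on mean ranks, with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) where
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups.  Two-sided p from the
    standard normal; unadjusted by default, optional Bonferroni.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = sorted(pd.unique(pd.Series(g)))  # sorted: z sign is well defined
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    N = len(v)
    ranks, ties = _ranks_with_ties(v)
    tie_term = (ties**3 - ties).sum() / (12.0 * (N - 1))
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for la, lb in pairs:
        na, nb = (g == la).sum(), (g == lb).sum()
        ra, rb = ranks[g == la].mean(), ranks[g == lb].mean()
        se2 = (N * (N + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
        z = 0.0 if se2 <= 0 else (ra - rb) / math.sqrt(se2)
        p = 2.0 * float(_stats.norm.sf(abs(z)))
        if adjust == "bonferroni":
            p = min(1.0, p * len(pairs))
        rows.append({"group_a": la, "group_b": lb, "z": z, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pooling helper
# ---------------------------------------------------------------------------


def pool_matrix(matrix: DietMatrix, by: str | list[str]) -> pd.DataFrame:
    """Sum stomach-level gravimetric rows into pooled samples (e.g. per area).

    Returns a samples x prey-groups DataFrame, the unit used when clustering
    sub-areas or running PERMANOVA on pooled strata rather than individual
    stomachs.
    """
    if isinstance(by, str):
        by = [by]
    missing = [b for b in by if b not in matrix.labels.columns]
    if missing:
        raise ValidationError(f"unknown label column(s): {missing}")
    joined = matrix.weight.join(matrix.labels[by])
    pooled = joined.groupby(by, observed=True).sum()
    if len(pooled) < 2:
        raise NoDataError("pooling left fewer than two samples")
    pooled.index = [
        "_".join(map(str, i)) if isinstance(i, tuple) else str(i)
        for i in pooled.index
    ]
    return pooled
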