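"""Phylogenetic-signal diagnostics: Moran's I, Blomberg's K and K*, and
phylogenetic autocorrelograms with bootstrap confidence bands.

These tests ask whether a per-sample statistic (E-score, ambiguity count, IR
mismatch count) is structured by shared evolutionary history.  Symbols, with
``x`` the tip trait vector, ``C`` the phylogenetic covariance matrix (shared
root-to-MRCA branch length) and ``D`` the patristic distance matrix:

* Moran's I with proximity weights ``w_ij = 1 / D_ij`` (row-normalized,
  zero diagonal):  ``I = (n / S0) * z'Wz / z'z`` with ``z = x - mean(x)``.
  Null expectation ``E[I] = -1/(n-1)``.
* Blomberg's K: observed ``MSE0/MSE`` divided by its Brownian-motion
  expectation.  Here ``MSE0`` centers on the ordinary mean and its BM
  expectation is ``[tr(C) - 1'C1/n]/(n-1)``; the starred variant K* centers
  the numerator on the generalized-least-squares ancestral estimate
  ``a = (1'C^-1 x)/(1'C^-1 1)`` with expectation
  ``[tr(C) - n/(1'C^-1 1)]/(n-1)``.  ``MSE`` is the GLS mean squared error
  ``(x-a)'C^-1(x-a)/(n-1)`` in both.  K = K* = 1 under Brownian motion;
  values near 0 indicate no signal.

Permutation p-values shuffle trait values across tips (999 permutations,
p = (r+1)/1000): two-tailed on ``|I - E[I]|`` for Moran's I, upper-tailed for
K and K* (signal inflates both).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd


@dataclass
class TraitVector:
    """Tip-indexed trait; NaN marks missing.  ``kind`` records provenance:
    empirical / randomized / enforced_bm."""

    values: pd.Series
    kind: str = "empirical"

    def non_missing(self) -> pd.Series:
        return self.values[self.values.notna()]

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate tip labels in trait")


@dataclass
class SignalIndices:
    I: float
    K: float
    K_star: float
    p_I: float
    p_K: float
    p_K_star: float
    n: int


@dataclass
class CorrelogramResult:
    class_mid: np.ndarray
    I: np.ndarray                 # NaN for classes with too few pairs
    ci_low: np.ndarray
    ci_high: np.ndarray
    flag: list[str]               # '+', '-', 'ns', or 'na'
    null_expectation: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"class_mid": self.class_mid, "I": self.I,
                             "ci_low": self.ci_low, "ci_high": self.ci_high,
                             "flag": self.flag})


# ---------------------------------------------------------------------------
# tree algebra

def read_tree(path_or_string, schema: str = "newick") -> dendropy.Tree:
    if isinstance(path_or_string, str) and path_or_string.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=path_or_string, schema=schema)
    else:
        tree = dendropy.Tree.get(path=str(path_or_string), schema=schema)
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip-to-tip path-length matrix, rows/cols ordered by sorted tip label."""
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise ValueError("negative branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            D[i, j] = D[j, i] = d
    return labels, D


def vcv_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Phylogenetic covariance: C[i,j] = root-to-MRCA(i,j) path length.

    Derived from root distances r and patristic distances D via
    C_ij = (r_i + r_j - D_ij) / 2.
    """
    labels, D = patristic_matrix(tree)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    r = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
    rv = np.array([r[lab] for lab in labels])
    C = (rv[:, None] + rv[None, :] - D) / 2.0
    return labels, C


def _align(trait: TraitVector, labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Trait vector aligned to tree labels; returns (values, keep mask)."""
    missing = set(trait.values.index) - set(labels)
    if missing:
        raise ValueError(f"trait tips not in tree: {sorted(missing)}")
    x = np.array([trait.values.get(lab, np.nan) for lab in labels])
    return x, np.isfinite(x)


# ---------------------------------------------------------------------------
# global indices

def morans_I(trait: TraitVector, tree: dendropy.Tree, n_perm: int = 999,
             seed: int | None = None) -> tuple[float, float]:
    """Global Moran's I with row-normalized inverse-patristic weights and a
    two-tailed permutation p-value.  Missing tips are pruned pairwise."""
    labels, D = patristic_matrix(tree)
    x, keep = _align(trait, labels)
    x, D = x[keep], D[np.ix_(keep, keep)]
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 non-missing tips")
    if np.ptp(x) == 0:
        raise ValueError("zero trait variance")
    W = _row_normalized_inverse(D)
    I_obs = _moran_stat(x, W)
    if n_perm <= 0:
        return I_obs, float("nan")
    rng = np.random.default_rng(seed)
    e0 = -1.0 / (n - 1)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)]).T  # n x P
    I_perm = _moran_stat_many(perms, W)
    r = int(np.sum(np.abs(I_perm - e0) >= np.abs(I_obs - e0) - 1e-12))
    return I_obs, (r + 1) / (n_perm + 1)


def _row_normalized_inverse(D: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        W = 1.0 / D
    np.fill_diagonal(W, 0.0)
    W[~np.isfinite(W)] = 0.0
    rs = W.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return W / rs


def _moran_stat(x: np.ndarray, W: np.ndarray) -> float:
    z = x - x.mean()
    s0 = W.sum()
    return float(len(x) / s0 * (z @ W @ z) / (z @ z))


def _moran_stat_many(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    Z = X - X.mean(axis=0, keepdims=True)
    s0 = W.sum()
    num = np.einsum("ip,ip->p", Z, W @ Z)
    den = np.einsum("ip,ip->p", Z, Z)
    return X.shape[0] / s0 * num / den


def blomberg_K(trait: TraitVector, tree: dendropy.Tree, n_perm: int = 999,
               seed: int | None = None) -> SignalIndices:
    """Blomberg's K and K* with upper-tailed permutation p-values (and
    Moran's I bundled for convenience, sharing the permutation scheme)."""
    labels, C = vcv_matrix(tree)
    x, keep = _align(trait, labels)
    x = x[keep]
    C = C[np.ix_(keep, keep)]
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 non-missing tips")
    if np.ptp(x) == 0:
        raise ValueError("zero trait variance")
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular phylogenetic covariance") from err

    K_obs, Ks_obs = _K_stats(x[:, None], C, Ci)
    K_obs, Ks_obs = float(K_obs[0]), float(Ks_obs[0])

    _, D = patristic_matrix(tree)  # same sorted-label order as vcv_matrix
    keep_idx = np.where(keep)[0]
    W = _row_normalized_inverse(D[np.ix_(keep_idx, keep_idx)])
    I_obs = _moran_stat(x, W)

    if n_perm <= 0:
        return SignalIndices(I_obs, K_obs, Ks_obs,
                             float("nan"), float("nan"), float("nan"), n)
    rng = np.random.default_rng(seed)
    X = np.array([rng.permutation(x) for _ in range(n_perm)]).T
    K_perm, Ks_perm = _K_stats(X, C, Ci)
    I_perm = _moran_stat_many(X, W)
    e0 = -1.0 / (n - 1)
    p_I = (np.sum(np.abs(I_perm - e0) >= np.abs(I_obs - e0) - 1e-12) + 1) / (n_perm + 1)
    p_K = (np.sum(K_perm >= K_obs - 1e-12) + 1) / (n_perm + 1)
    p_Ks = (np.sum(Ks_perm >= Ks_obs - 1e-12) + 1) / (n_perm + 1)
    return SignalIndices(I_obs, K_obs, Ks_obs, float(p_I), float(p_K), float(p_Ks), n)


def _K_stats(X: np.ndarray, C: np.ndarray, Ci: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """K (mean-centered numerator) and K* (GLS-centered numerator) for each
    column of X."""
    n = X.shape[0]
    one = np.ones(n)
    w = Ci @ one
    denom_gls = one @ w
    ahat = (w @ X) / denom_gls                       # per-column GLS mean
    R = X - ahat[None, :]
    MSE = np.einsum("ip,ip->p", R, Ci @ R) / (n - 1)
    MSE0_star = np.einsum("ip,ip->p", R, R) / (n - 1)
    Z = X - X.mean(axis=0, keepdims=True)
    MSE0 = np.einsum("ip,ip->p", Z, Z) / (n - 1)
    trC = np.trace(C)
    e_mean = (trC - (one @ C @ one) / n) / (n - 1)
    e_gls = (trC - n / denom_gls) / (n - 1)
    K = (MSE0 / MSE) / e_mean
    K_star = (MSE0_star / MSE) / e_gls
    return K, K_star


# ---------------------------------------------------------------------------
# correlogram

def correlogram(trait: TraitVector, tree: dendropy.Tree, n_classes: int = 30,
                n_boot: int = 100, seed: int | None = None,
                min_pairs: int = 10) -> CorrelogramResult:
    """Moran's I per patristic-distance class with percentile bootstrap CIs.

    Classes are equal-width over (0, max distance]; weights are binary
    within-class.  The bootstrap resamples tips with replacement (duplicate
    pairs have distance 0 and fall outside every class).  A class with fewer
    than ``min_pairs`` unordered tip pairs is reported NA.
    """
    labels, D = patristic_matrix(tree)
    x, keep = _align(trait, labels)
    x, D = x[keep], D[np.ix_(keep, keep)]
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 non-missing tips")
    dmax = D.max()
    edges = np.linspace(0, dmax, n_classes + 1)
    mids = (edges[:-1] + edges[1:]) / 2
    e0 = -1.0 / (n - 1)

    I_point = _class_morans(x, D, edges, min_pairs)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.full((n_boot, n_classes), np.nan)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b] = _class_morans(x[idx], D[np.ix_(idx, idx)], edges, min_pairs)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN classes
            ci_low = np.nanpercentile(boots, 2.5, axis=0)
            ci_high = np.nanpercentile(boots, 97.5, axis=0)
    else:
        ci_low = np.full(n_classes, np.nan)
        ci_high = np.full(n_classes, np.nan)

    flags = []
    for i in range(n_classes):
        if not np.isfinite(I_point[i]):
            flags.append("na")
        elif np.isfinite(ci_low[i]) and ci_low[i] > e0:
            flags.append("+")
        elif np.isfinite(ci_high[i]) and ci_high[i] < e0:
            flags.append("-")
        else:
            flags.append("ns")
    return CorrelogramResult(mids, I_point, ci_low, ci_high, flags, e0)


def _class_morans(x: np.ndarray, D: np.ndarray, edges: np.ndarray,
                  min_pairs: int) -> np.ndarray:
    n = len(x)
    z = x - x.mean()
    zz = z @ z
    out = np.full(len(edges) - 1, np.nan)
    if zz == 0:
        return out
    iu = np.triu_indices(n, k=1)
    d_up = D[iu]
    zprod = (z[:, None] * z[None, :])[iu]
    valid = d_up > 0
    cls = np.searchsorted(edges, d_up[valid], side="left") - 1
    cls = np.clip(cls, 0, len(edges) - 2)
    zp = zprod[valid]
    for c in range(len(edges) - 1):
        in_c = cls == c
        npairs = int(in_c.sum())
        if npairs < min_pairs:
            continue
        s0 = 2.0 * npairs              # symmetric binary weights
        out[c] = n / s0 * 2.0 * zp[in_c].sum() / zz
    return out


# ---------------------------------------------------------------------------
# controlled trait distributions

def randomize_trait(trait: TraitVector, seed: int | None = None) -> TraitVector:
    """Permute non-missing values across the same non-missing tips; missing
    pattern and value multiset (hence mean and dispersion) are preserved."""
    rng = np.random.default_rng(seed)
    vals = trait.values.copy()
    idx = vals.index[vals.notna()]
    vals.loc[idx] = rng.permutation(vals.loc[idx].to_numpy())
    return TraitVector(vals, kind="randomized")


def simulate_bm_trait(tree: dendropy.Tree, seed: int | None = None,
                      match: TraitVector | None = None,
                      sigma2: float = 1.0) -> TraitVector:
    """Brownian-motion trait: root value 0, independent normal increments
    with variance sigma2 * branch length.  If ``match`` is given, the result
    is affinely rescaled to the empirical mean/SD and the empirical missing
    pattern is re-imposed."""
    depth = max((leaf.distance_from_root() for leaf in tree.leaf_node_iter()),
                default=0.0)
    if depth <= 0:
        raise ValueError("zero-depth tree")
    rng = np.random.default_rng(seed)
    value: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            value[id(node)] = 0.0
        else:
            bl = node.edge.length or 0.0
            value[id(node)] = value[id(node.parent_node)] + \
                rng.normal(0.0, np.sqrt(sigma2 * bl))
    tips = {leaf.taxon.label: value[id(leaf)] for leaf in tree.leaf_node_iter()}
    s = pd.Series(tips, dtype=float)
    if match is not None:
        emp = match.non_missing()
        s = (s - s.mean()) / (s.std(ddof=1) if s.std(ddof=1) > 0 else 1.0)
        s = s * emp.std(ddof=1) + emp.mean()
        out = pd.Series(np.nan, index=match.values.index, dtype=float)
        common = [t for t in match.values.index
                  if t in s.index and np.isfinite(match.values[t])]
        out.loc[common] = s.loc[common]
        return TraitVector(out, kind="enforced_bm")
    return TraitVector(s, kind="enforced_bm")
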