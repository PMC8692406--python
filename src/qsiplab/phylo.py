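"""Phylogenetic signal of isotope-assimilation traits: Blomberg's K and
Pagel's lambda.

Both statistics ask whether a continuous trait (here, per-OTU excess atom
fraction 13C within a treatment) is distributed on the 16S phylogeny as
expected under Brownian-motion (BM) evolution.

* Blomberg's K compares the observed ratio of the trait's total variance to
  its phylogenetically corrected (GLS) variance against the ratio expected
  under BM on the same tree.  K ~ 1 under BM, K ~ 0 for tree-independent
  traits.  Significance comes from permuting trait values across tips.
* Pagel's lambda multiplies the off-diagonal entries of the BM covariance
  matrix by a factor in [0, lambda_max] and estimates it by maximum
  likelihood (mean and variance profiled out analytically); the p-value is a
  boundary-corrected likelihood-ratio test of lambda = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize, stats

from .tables import ValidationError

__all__ = [
    "SignalResult",
    "load_tree",
    "tree_vcv",
    "blomberg_k",
    "pagels_lambda",
    "simulate_bm_traits",
]


@dataclass
class SignalResult:
    statistic: str            # "K" or "lambda"
    estimate: float
    p_value: float
    n_tips: int
    detail: dict
    identifiable: bool = True


def load_tree(source) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths from a path or string."""
    if isinstance(source, dendropy.Tree):
        return source
    text = str(source)
    if "(" not in text:  # path, not newick
        with open(text) as fh:
            text = fh.read()
    return dendropy.Tree.get(data=text, schema="newick")


def tree_vcv(tree, tip_order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion variance-covariance matrix of a rooted tree.

    C[i, j] is the root-to-MRCA path length shared by tips i and j;
    C[i, i] is the root-to-tip length.  Terminal zero-length branches are
    perturbed by 1e-8 of the tree depth (C would be singular otherwise).
    """
    tree = load_tree(tree)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(taxa)) != len(taxa):
        raise ValidationError("duplicate tip labels")
    order = tip_order if tip_order is not None else taxa
    missing = set(order) - set(taxa)
    if missing:
        raise ValidationError(f"tips not in tree: {sorted(missing)[:5]}")
    idx = {label: i for i, label in enumerate(order)}
    n = len(order)
    C = np.zeros((n, n))

    # root distance per node, then MRCA depths by combining child tip sets
    root_dist: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length
        if edge is None and parent is not None:
            raise ValidationError("tree has branches without lengths")
        if edge is not None and edge < 0:
            raise ValidationError("negative branch length")
        root_dist[id(node)] = (root_dist[id(parent)] if parent is not None else 0.0) + (edge or 0.0)

    depth = max(root_dist.values())
    if depth <= 0:
        raise ValidationError("zero-depth tree")

    tipsets: dict[int, list[int]] = {}
    zero_terminals = False
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if (node.edge.length or 0.0) == 0.0 and node.parent_node is not None:
                zero_terminals = True
            if label in idx:
                i = idx[label]
                C[i, i] = root_dist[id(node)]
                tipsets[id(node)] = [i]
            else:
                tipsets[id(node)] = []
        else:
            d = root_dist[id(node)]
            children = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
            merged: list[int] = []
            for k, tips_a in enumerate(children):
                for tips_b in children[k + 1:]:
                    for i in tips_a:
                        for j in tips_b:
                            C[i, j] = C[j, i] = d
                merged.extend(tips_a)
            tipsets[id(node)] = merged

    if zero_terminals:
        warnings.warn("zero-length terminal branches perturbed by 1e-8 of tree depth",
                      stacklevel=2)
        C[np.diag_indices(n)] += 1e-8 * depth
    return C, list(order)


def _align_trait(C: np.ndarray, tips: list[str], trait) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Subset C and the trait to their shared tips (missing tips dropped)."""
    if isinstance(trait, dict):
        items = trait
    else:
        items = dict(trait)  # pandas Series or iterable of pairs
    keep = [i for i, t in enumerate(tips) if t in items and np.isfinite(items[t])]
    if not keep:
        raise ValidationError("no tips with finite trait values")
    sel = np.asarray(keep)
    x = np.array([items[tips[i]] for i in keep], float)
    return C[np.ix_(sel, sel)], x, [tips[i] for i in keep]


def blomberg_k(
    tree,
    trait,
    n_perm: int = 999,
    seed: int | None = None,
    tip_order: list[str] | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-permutation test.

    K = (MSE0/MSE)_obs / (MSE0/MSE)_BM, where MSE0 is the mean squared
    deviation from the phylogenetically corrected mean and MSE the GLS error
    under the BM covariance C.  The expected ratio under BM is
    (tr(C) - n / sum(C^-1)) / (n - 1).  p is the fraction of permutations
    (observed included) whose MSE0/MSE is at least the observed one.
    """
    if isinstance(tree, np.ndarray):
        C, tips = tree, tip_order
    else:
        C, tips = tree_vcv(tree, tip_order)
    C, x, tips = _align_trait(C, tips, trait)
    n = len(x)
    if n < 4:
        raise ValidationError(f"need >= 4 tips for Blomberg's K, got {n}")
    if np.allclose(x, x[0]):
        raise ValidationError("constant trait: K undefined (MSE = 0)")
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        raise ValidationError("singular phylogenetic covariance matrix") from None
    w = Ci.sum(axis=1) / Ci.sum()  # GLS weights for the phylogenetic mean

    def ratio(vals: np.ndarray) -> np.ndarray:
        # vals: (m, n) rows of trait vectors
        a = vals @ w
        dev = vals - a[:, None]
        mse0 = (dev ** 2).sum(axis=1)
        mse = np.einsum("mi,ij,mj->m", dev, Ci, dev)
        return mse0 / mse

    obs = float(ratio(x[None, :])[0])
    expected = (np.trace(C) - n / Ci.sum()) / (n - 1)
    k = obs / expected

    rng = np.random.default_rng(seed)
    if n_perm > 0:
        perms = np.array([rng.permutation(x) for _ in range(n_perm)])
        exceed = int((ratio(perms) >= obs - 1e-12).sum())
        p = (1 + exceed) / (1 + n_perm)
    else:
        p = np.nan
    return SignalResult("K", float(k), float(p), n, {"n_perm": n_perm, "mse_ratio": obs})


def _lambda_profile(C: np.ndarray, x: np.ndarray):
    """Eigendecomposition-based profile log-likelihood for Pagel's lambda.

    V(lam) = lam*(C - D) + D with D = diag(C).  With
    A = D^-1/2 (C - D) D^-1/2 = Q L Q', the likelihood at any lam costs
    O(n) after a single O(n^3) decomposition.  Returns (loglik(lam),
    lambda_max) where lambda_max keeps V positive-definite.
    """
    d = np.diag(C).copy()
    if (d <= 0).any():
        raise ValidationError("non-positive diagonal in covariance matrix")
    s = 1.0 / np.sqrt(d)
    A = (C - np.diag(d)) * s[:, None] * s[None, :]
    evals, Q = np.linalg.eigh(A)
    z = Q.T @ (s * x)
    u = Q.T @ s  # transform of the ones vector
    n = len(x)
    logdet_d = np.log(d).sum()
    lam_min_eig = evals.min()
    lam_max = (1.0 - 1e-8) / (-lam_min_eig) if lam_min_eig < 0 else 10.0

    def loglik(lam: float) -> float:
        dd = 1.0 + lam * evals
        if (dd <= 0).any():
            return -np.inf
        mu = (u * z / dd).sum() / (u * u / dd).sum()
        r = z - mu * u
        quad = (r * r / dd).sum()
        sigma2 = quad / n
        if sigma2 <= 0 or not np.isfinite(sigma2):
            return -np.inf
        return -0.5 * (n * np.log(2 * np.pi * sigma2) + np.log(dd).sum() + logdet_d + n)

    return loglik, lam_max


def pagels_lambda(
    tree,
    trait,
    tip_order: list[str] | None = None,
    tol: float = 1e-8,
) -> SignalResult:
    """ML estimate of Pagel's lambda with a boundary-corrected LRT vs 0.

    On a star tree the off-diagonal covariance is identically zero, so lambda
    is non-identifiable; the result is flagged and the estimate is NaN.
    """
    if isinstance(tree, np.ndarray):
        C, tips = tree, tip_order
    else:
        C, tips = tree_vcv(tree, tip_order)
    C, x, tips = _align_trait(C, tips, trait)
    n = len(x)
    if n < 4:
        raise ValidationError(f"need >= 4 tips for Pagel's lambda, got {n}")
    if np.allclose(x, x[0]):
        raise ValidationError("constant trait: lambda undefined")
    off = C - np.diag(np.diag(C))
    if np.allclose(off, 0.0):
        return SignalResult("lambda", np.nan, np.nan, n,
                            {"note": "star tree: lambda non-identifiable"},
                            identifiable=False)
    loglik, lam_max = _lambda_profile(C, x)
    # coarse scan brackets the global maximum (the profile can be flat or
    # weakly multimodal); bounded minimization then refines within the bracket
    grid = np.linspace(0.0, lam_max, 201)
    vals = np.array([loglik(l) for l in grid])
    if not np.isfinite(vals).any():
        raise ValidationError("lambda likelihood optimization failed")
    j = int(np.nanargmax(np.where(np.isfinite(vals), vals, -np.inf)))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda lam: -loglik(lam), bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    if not np.isfinite(res.fun):
        raise ValidationError("lambda likelihood optimization failed")
    lam_hat = float(res.x)
    ll_hat = float(-res.fun)
    # bounded optimizer never lands exactly on the boundary; snap if flat
    for cand in (0.0, min(1.0, lam_max)):
        if loglik(cand) >= ll_hat - 1e-10:
            lam_hat, ll_hat = cand, float(loglik(cand))
    ll0 = float(loglik(0.0))
    lrt = 2.0 * (ll_hat - ll0)
    p = 1.0 if lrt <= 0 else 0.5 * float(stats.chi2.sf(lrt, df=1))
    return SignalResult(
        "lambda", lam_hat, p, n,
        {"loglik_hat": ll_hat, "loglik_0": ll0, "lrt": lrt, "lambda_max": lam_max},
    )


def simulate_bm_traits(
    C: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
    lam: float = 1.0,
    sigma2: float = 1.0,
    mean: float = 0.0,
) -> np.ndarray:
    """Draw trait vectors under BM with covariance sigma2 * C(lam).

    Returns an (n_reps, n_tips) array.  lam < 1 shrinks the off-diagonal
    covariance (the Pagel transform); lam = 0 gives independent tips with
    variances diag(C)."""
    D = np.diag(np.diag(C))
    V = lam * (C - D) + D
    L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(len(C)))
    z = rng.standard_normal((n_reps, len(C)))
    return mean + z @ L.T
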