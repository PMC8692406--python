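"""Treatment- and group-level summaries of qSIP results, plus the community
statistics used to compare sample types (Chao1 richness, Welch t-test,
Bray-Curtis ANOSIM).

Percentages follow reporting conventions: fraction labeled to one decimal,
percent change with H2 to the nearest integer.  Full precision is retained
internally; rounding happens only in rendered output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .tables import ValidationError

__all__ = [
    "TreatmentSummary",
    "H2Effect",
    "fraction_labeled",
    "percent_change",
    "treatment_summaries",
    "h2_effect",
    "group_eaf_table",
    "chao1",
    "compare_richness",
    "bray_curtis",
    "anosim",
]

TAXONOMY_RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]


@dataclass
class TreatmentSummary:
    treatment: str
    n_labeled: int
    n_unlabeled: int
    mean_eaf: float
    sd_eaf: float

    @property
    def percent_labeled(self) -> float:
        return fraction_labeled(self.n_labeled, self.n_unlabeled)


@dataclass
class H2Effect:
    substrate: str
    mean_eaf_noh2: float
    mean_eaf_h2: float
    percent_change: float
    uncertainty: float  # bootstrap SD of percent_change over OTUs


def fraction_labeled(n_labeled: int, n_unlabeled: int) -> float:
    """Percent of evaluated OTUs called 13C-labeled, 100*l/(l+u)."""
    total = n_labeled + n_unlabeled
    if total <= 0:
        raise ValidationError("no evaluated OTUs")
    if min(n_labeled, n_unlabeled) < 0:
        raise ValidationError("negative counts")
    return 100.0 * n_labeled / total


def percent_change(mean_noh2: float, mean_h2: float) -> float:
    """Percent change of the mean EAF when H2 is added: 100*(b-a)/a."""
    if mean_noh2 == 0:
        raise ValidationError("zero baseline mean EAF")
    return 100.0 * (mean_h2 - mean_noh2) / mean_noh2


def treatment_summaries(results: pd.DataFrame, labeled_only: bool = False) -> pd.DataFrame:
    """Per-treatment labeled/unlabeled counts and mean EAF.

    ``labeled_only`` restricts the mean to labeled OTUs (sensitivity mode);
    by default the mean runs over all evaluable OTUs.
    """
    rows = []
    for treatment, sub in results[results["evaluable"].astype(bool)].groupby("treatment"):
        n_lab = int(sub["labeled"].sum())
        n_unlab = int(len(sub) - n_lab)
        vals = sub.loc[sub["labeled"], "eaf"] if labeled_only else sub["eaf"]
        rows.append({
            "treatment": treatment,
            "n_labeled": n_lab,
            "n_unlabeled": n_unlab,
            "percent_labeled": round(fraction_labeled(n_lab, n_unlab), 1) if n_lab + n_unlab else np.nan,
            "mean_eaf": float(vals.mean()) if len(vals) else np.nan,
            "sd_eaf": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def h2_effect(
    results: pd.DataFrame,
    substrate: str,
    *,
    n_boot: int = 1000,
    seed: int | None = None,
    labeled_only: bool = False,
) -> H2Effect:
    """Percent change in mean EAF with H2 for one substrate.

    Uncertainty is the bootstrap (over OTUs) standard deviation of the percent
    change, resampling the two treatment arms independently.
    """
    ev = results[results["evaluable"].astype(bool)]
    if labeled_only:
        ev = ev[ev["labeled"].astype(bool)]
    a = ev.loc[ev["treatment"] == substrate, "eaf"].to_numpy(float)
    b = ev.loc[ev["treatment"] == f"{substrate}+H2", "eaf"].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError(f"missing treatment arm for substrate {substrate!r}")
    pc = percent_change(a.mean(), b.mean())
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        am = a[rng.integers(0, len(a), len(a))].mean()
        bm = b[rng.integers(0, len(b), len(b))].mean()
        if am != 0:
            boots.append(100.0 * (bm - am) / am)
    return H2Effect(
        substrate=substrate,
        mean_eaf_noh2=float(a.mean()),
        mean_eaf_h2=float(b.mean()),
        percent_change=pc,
        uncertainty=float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan,
    )


def _rank_of(lineage: str, rank: str) -> str:
    idx = TAXONOMY_RANKS.index(rank)
    parts = [p.strip() for p in str(lineage).split(";")]
    if idx < len(parts) and parts[idx] and not parts[idx].endswith("__"):
        name = parts[idx]
        return name.split("__", 1)[1] if "__" in name else name
    return "unassigned"


def group_eaf_table(
    results: pd.DataFrame,
    taxonomy: dict[str, str] | None,
    rank: str = "genus",
) -> pd.DataFrame:
    """Mean EAF per taxonomic group per treatment, with a flag marking
    whether any member OTU was called labeled.  OTUs without a classified
    name at ``rank`` fall into "unassigned"."""
    if rank not in TAXONOMY_RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {TAXONOMY_RANKS}")
    taxonomy = taxonomy or {}
    ev = results[results["evaluable"].astype(bool)].copy()
    ev["group"] = [_rank_of(taxonomy.get(o, ""), rank) for o in ev["otu_id"]]
    out = (
        ev.groupby(["group", "treatment"])
        .agg(mean_eaf=("eaf", "mean"), n_otus=("eaf", "size"), any_labeled=("labeled", "any"))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# community statistics


def chao1(counts) -> float:
    """Chao1 richness: S_obs + f1^2/(2 f2), bias-corrected when f2 = 0."""
    counts = np.asarray(counts)
    if counts.size == 0 or (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    s_obs = int((counts > 0).sum())
    if s_obs == 0:
        raise ValidationError("all-zero sample")
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def compare_richness(group_a, group_b) -> tuple[float, float]:
    """Welch two-sample t-test on per-sample Chao1 richness values."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least two samples per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bray_curtis(counts: np.ndarray) -> np.ndarray:
    """Bray-Curtis distance matrix over samples (rows) from a counts matrix,
    computed on relative abundances."""
    counts = np.asarray(counts, float)
    tot = counts.sum(axis=1, keepdims=True)
    rel = np.divide(counts, np.where(tot > 0, tot, 1.0))
    return squareform(pdist(rel, metric="braycurtis"))


def anosim(
    distances: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    ranks over all pairwise distances with average ties.  p is estimated by
    permuting group labels (observed configuration included in numerator and
    denominator).
    """
    d = np.asarray(distances, float)
    groups = np.asarray(groups)
    n = len(groups)
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValidationError("distances must be a symmetric n x n matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValidationError("need >= 2 groups with >= 2 members each")
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d[iu])
    denom = n * (n - 1) / 4.0

    def r_stat(g):
        within = g[iu[0]] == g[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(groups)
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_perm):
        if r_stat(rng.permutation(groups)) >= r_obs:
            count += 1
    return float(r_obs), count / (n_perm + 1)
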