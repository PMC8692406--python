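"""Per-taxon density profiles, WADs, EAF estimation and bootstrap labeling calls.

Workflow, per substrate x H2 comparison:

1. Convert read counts to absolute 16S copy numbers per fraction:
   copies_ik = qPCR total of fraction k x relative abundance of taxon i in k.
2. For every replicate incubation, compute the taxon's weighted average
   density (WAD): W = sum_k x_k * y_ik with y_ik the taxon's copy portions
   across that replicate's fractions.
3. The light (unlabeled) density W_light is the mean of the control-replicate
   WADs; the density shift of each labeled replicate relative to W_light is
   converted to excess atom fraction 13C via the isotope model.
4. Uncertainty: labeled and control replicate WADs are resampled with
   replacement, independently, n_boot times; the percentile interval of the
   recomputed EAFs gives the CI.  A taxon is called a 13C-assimilator iff the
   lower CI bound exceeds 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .isotope import DEFAULT_PARAMS, IsotopeModelParams, eaf_point
from .tables import FractionMetadata, OTUTable, ValidationError

__all__ = [
    "TaxonDensityProfile",
    "EAFResult",
    "taxon_copies",
    "weighted_average_density",
    "replicate_wads",
    "bootstrap_eaf",
    "run_qsip",
]

RESULT_COLUMNS = [
    "otu_id", "treatment", "eaf", "ci_low", "ci_high", "labeled",
    "evaluable", "n_labeled_reps", "n_control_reps", "W_light", "G",
    "delta_W",
]


@dataclass
class TaxonDensityProfile:
    """Copy-weighted density distribution of one OTU in one replicate."""

    otu_id: str
    replicate_id: str
    densities: np.ndarray   # x_k, g/ml
    copies: np.ndarray      # copies_ik per fraction

    @property
    def portions(self) -> np.ndarray:
        total = self.copies.sum()
        if total <= 0:
            raise ValidationError(f"OTU {self.otu_id!r} has no copies in {self.replicate_id!r}")
        return self.copies / total

    @property
    def wad(self) -> float:
        return weighted_average_density(self.densities, self.copies)


@dataclass
class EAFResult:
    otu_id: str
    treatment: str
    eaf: float
    ci_low: float
    ci_high: float
    labeled: bool
    evaluable: bool
    n_labeled_reps: int
    n_control_reps: int
    w_light: float
    gc: float
    delta_w: float


def taxon_copies(table: OTUTable, metadata: FractionMetadata) -> pd.DataFrame:
    """Absolute 16S copies per (OTU, fraction sample).

    copies_ik = f_k * count_ik / sum_i count_ik, where f_k is the fraction's
    total qPCR copy number.  Fractions with zero sequencing depth contribute
    zero copies for every OTU.
    """
    metadata.require_samples(table.sample_ids)
    qpcr = metadata.frame.loc[table.sample_ids, "qpcr_copies"].to_numpy(float)
    if (qpcr < 0).any():
        raise ValidationError("negative qpcr_copies")
    counts = table.counts.astype(float)
    depth = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(depth > 0, counts / np.where(depth > 0, depth, 1.0), 0.0)
    return pd.DataFrame(rel * qpcr, index=table.otu_ids, columns=table.sample_ids)


def weighted_average_density(densities, copies) -> float:
    """WAD: copy-weighted mean buoyant density, W = sum_k x_k y_ik."""
    densities = np.asarray(densities, float)
    copies = np.asarray(copies, float)
    total = copies.sum()
    if total <= 0:
        raise ValidationError("all-zero copies: WAD undefined")
    return float((densities * copies).sum() / total)


def replicate_wads(
    copies: pd.DataFrame, metadata: FractionMetadata, comparison: str, label: str
) -> pd.DataFrame:
    """Per-OTU WADs for every replicate of one arm of a comparison.

    Returns a DataFrame (OTU x replicate id); NaN where the OTU has no copies
    in that replicate (absent, not zero enrichment).
    """
    md = metadata.frame
    sel = md[(md["comparison"] == comparison) & (md["label"].astype(str) == label)]
    if sel.empty:
        return pd.DataFrame(index=copies.index)
    out = {}
    for rep, sub in sel.groupby("replicate"):
        samples = [s for s in sub["sample_id"] if s in copies.columns]
        if not samples:
            continue
        c = copies[samples].to_numpy(float)
        x = md.loc[samples, "density_g_ml"].to_numpy(float)
        tot = c.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = (c * x).sum(axis=1) / tot
        out[f"rep{rep}"] = np.where(tot > 0, w, np.nan)
    return pd.DataFrame(out, index=copies.index)


def _percentile_ci(samples: np.ndarray, ci: float) -> tuple[float, float]:
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bootstrap_eaf(
    labeled_wads,
    control_wads,
    *,
    otu_id: str = "",
    treatment: str = "",
    n_boot: int = 1000,
    ci: float = 0.90,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    params: IsotopeModelParams = DEFAULT_PARAMS,
) -> EAFResult:
    """Point EAF and percentile bootstrap CI from replicate WADs.

    The resampling unit is the biological replicate WAD; the labeled and
    control arms are resampled independently with replacement.
    """
    labeled = np.asarray([w for w in np.atleast_1d(labeled_wads) if np.isfinite(w)], float)
    control = np.asarray([w for w in np.atleast_1d(control_wads) if np.isfinite(w)], float)
    if len(labeled) < 1 or len(control) < 1:
        raise ValidationError("need at least one labeled and one control replicate WAD")
    if rng is None:
        rng = np.random.default_rng(seed)
    point = eaf_point(control.mean(), labeled.mean(), params)
    il = rng.integers(0, len(labeled), size=(n_boot, len(labeled)))
    ic = rng.integers(0, len(control), size=(n_boot, len(control)))
    boots = eaf_point(control[ic].mean(axis=1), labeled[il].mean(axis=1), params)
    lo, hi = _percentile_ci(boots, ci)
    w_light = control.mean()
    from .isotope import gc_from_density

    return EAFResult(
        otu_id=otu_id,
        treatment=treatment,
        eaf=float(point),
        ci_low=lo,
        ci_high=hi,
        labeled=bool(lo > 0.0),
        evaluable=True,
        n_labeled_reps=len(labeled),
        n_control_reps=len(control),
        w_light=float(w_light),
        gc=float(gc_from_density(w_light, params, warn=False)),
        delta_w=float(labeled.mean() - w_light),
    )


def run_qsip(
    table: OTUTable,
    metadata: FractionMetadata,
    *,
    n_boot: int = 1000,
    ci: float = 0.90,
    seed: int | None = None,
    params: IsotopeModelParams = DEFAULT_PARAMS,
    labeled_tag: str = "13C",
    control_tag: str = "control",
    kept_by_treatment: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """EAF with bootstrap CI and labeling call for every OTU x comparison.

    OTUs absent from all control replicates of a comparison have no density
    baseline and are reported with ``evaluable=False`` (distinct from
    unlabeled).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    copies = taxon_copies(table, metadata)
    md = metadata.frame
    rows: list[dict] = []
    for comparison in metadata.comparisons():
        labels = set(md.loc[md["comparison"] == comparison, "label"].astype(str))
        if labeled_tag not in labels or control_tag not in labels:
            raise ValidationError(
                f"treatment {comparison!r} lacks "
                f"{'control' if labeled_tag in labels else 'labeled'} samples"
            )
        wl = replicate_wads(copies, metadata, comparison, labeled_tag)
        wc = replicate_wads(copies, metadata, comparison, control_tag)
        otus = table.otu_ids
        if kept_by_treatment is not None:
            allowed = set(kept_by_treatment.get(comparison, otus))
            otus = [o for o in otus if o in allowed]
        for otu in otus:
            lab = wl.loc[otu].dropna().to_numpy() if len(wl.columns) else np.array([])
            con = wc.loc[otu].dropna().to_numpy() if len(wc.columns) else np.array([])
            if len(con) == 0 or len(lab) == 0:
                rows.append(dict(
                    otu_id=otu, treatment=comparison, eaf=np.nan, ci_low=np.nan,
                    ci_high=np.nan, labeled=False, evaluable=False,
                    n_labeled_reps=len(lab), n_control_reps=len(con),
                    W_light=np.nan, G=np.nan, delta_W=np.nan,
                ))
                continue
            res = bootstrap_eaf(
                lab, con, otu_id=otu, treatment=comparison,
                n_boot=n_boot, ci=ci, rng=rng, params=params,
            )
            rows.append(dict(
                otu_id=res.otu_id, treatment=res.treatment, eaf=res.eaf,
                ci_low=res.ci_low, ci_high=res.ci_high, labeled=res.labeled,
                evaluable=True, n_labeled_reps=res.n_labeled_reps,
                n_control_reps=res.n_control_reps, W_light=res.w_light,
                G=res.gc, delta_W=res.delta_w,
            ))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
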