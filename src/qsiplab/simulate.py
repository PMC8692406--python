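"""Ground-truthed synthetic qSIP experiments.

The generator emulates the statistical structure of a 13C qSIP study on a
CsCl density gradient: a lognormal community whose members band as Gaussian
peaks in density (center set by GC content and true 13C enrichment through
the isotope model), fractionated on a fixed density grid, with qPCR totals
per fraction (multiplicative lognormal noise) and multinomial sequencing
counts at a configured depth.  Every pipeline stage can be tested against the
stored truth: per-taxon GC, abundance, per-treatment true EAF, the tree the
traits evolved on, and the expected (noise-free) WAD of every incubation arm.

Study design defaults: three substrates (bicarbonate, acetate, formate) with
and without added H2, each comparison with 3 labeled (13C) and 3 unlabeled
control replicates, ~20 fractions spanning 1.640-1.780 g/ml, band sigma
0.006 g/ml so roughly ten fractions carry signal.  Default mean true EAFs per
treatment follow the magnitudes observed in rock-hosted incubations (0.13 to
0.42), which put peak-density shifts in the 0.002-0.028 g/ml range.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .isotope import DEFAULT_PARAMS, IsotopeModelParams, expected_band_center
from .tables import ContaminantProfile, FractionMetadata, OTUTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimBundle",
    "band_weights",
    "simulate_gradient_replicate",
    "simulate_experiment",
    "true_peak_shifts",
    "write_experiment",
    "tiny_config",
    "paper_like_config",
]

DEFAULT_MEAN_EAF = {
    "bicarbonate": 0.13,
    "bicarbonate+H2": 0.32,
    "acetate": 0.27,
    "acetate+H2": 0.42,
    "formate": 0.32,
    "formate+H2": 0.14,
}


@dataclass
class SimConfig:
    """Knobs of the synthetic experiment; defaults are the study conditions."""

    n_taxa: int = 100
    seed: int = 0
    # community
    abundance_sigma: float = 1.5          # lognormal sd of relative abundances
    gc_alpha: float = 5.0                 # GC ~ Beta(a, b) scaled to gc_range
    gc_beta: float = 5.0
    gc_range: tuple[float, float] = (0.3, 0.7)
    # design
    substrates: tuple[str, ...] = ("bicarbonate", "acetate", "formate")
    h2_levels: tuple[bool, ...] = (False, True)
    n_replicates: int = 3
    # truth
    mean_eaf: dict = field(default_factory=lambda: dict(DEFAULT_MEAN_EAF))
    p_labeled: float = 0.5
    eaf_sd_frac: float = 0.3              # sd of labeled EAF as fraction of mean
    tree_structured: bool = False         # evolve EAF on the tree instead
    trait_lambda: float = 1.0
    trait_sigma: float = 0.08             # BM trait sd at the tips
    # gradient
    grid_min: float = 1.640
    grid_max: float = 1.780
    n_fractions: int = 20
    band_sigma: float = 0.006             # g/ml, isopycnic band width
    band_profile: str = "gaussian"        # or "delta" (noise-free lever rule)
    top_k_fractions: int | None = None    # keep only k highest-qPCR fractions
    # measurement
    reads_per_fraction: int = 20_000
    counts_mode: str = "multinomial"      # or "expected" (noise-free)
    qpcr_cv: float = 0.2                  # lognormal CV of fraction totals
    qpcr_scale: float = 1e8               # copies per unit community mass
    # contamination
    n_contaminants: int = 5
    contaminant_leakage: float = 5e-4     # contaminant share of community mass
    contaminant_profile_reads: int = 5000

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.grid_min >= self.grid_max or self.n_fractions < 2:
            raise ValueError("gradient grid must be strictly increasing")
        for name in ("band_sigma", "qpcr_cv", "contaminant_leakage", "p_labeled"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.band_profile not in {"gaussian", "delta"}:
            raise ValueError("band_profile must be 'gaussian' or 'delta'")
        if self.counts_mode not in {"multinomial", "expected"}:
            raise ValueError("counts_mode must be 'multinomial' or 'expected'")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.n_fractions)

    def comparisons(self) -> list[str]:
        return [s + ("+H2" if h2 else "") for s in self.substrates for h2 in self.h2_levels]


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    taxa: list[str]
    contaminant_taxa: list[str]
    gc: np.ndarray                     # per taxon
    abundance: np.ndarray              # relative, sums to 1 over taxa
    eaf: pd.DataFrame                  # taxa x comparison, true EAF in [0, 1-nat]
    tree_newick: str
    expected_wads: pd.DataFrame        # taxa x incubation arm, noise-free WAD

    def to_json(self, path):
        payload = {
            "taxa": self.taxa,
            "contaminant_taxa": self.contaminant_taxa,
            "gc": self.gc.tolist(),
            "abundance": self.abundance.tolist(),
            "eaf": {c: self.eaf[c].tolist() for c in self.eaf.columns},
            "tree_newick": self.tree_newick,
            "expected_wads": {c: self.expected_wads[c].tolist() for c in self.expected_wads.columns},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SimBundle:
    table: OTUTable
    metadata: FractionMetadata
    contaminants: ContaminantProfile
    tree_newick: str
    truth: SimTruth
    config: SimConfig


def band_weights(centers: np.ndarray, grid: np.ndarray, sigma: float,
                 profile: str = "gaussian") -> np.ndarray:
    """Mass of each taxon's DNA band in each fraction (rows taxa, cols grid).

    gaussian: integrate N(center, sigma) over fraction bins (edges midway
    between grid points), renormalized over the grid.  delta: lever-rule split
    of a point band between the two flanking fractions, so the discretized
    mean equals the band center exactly.
    """
    from scipy.stats import norm

    centers = np.atleast_1d(np.asarray(centers, float))
    n, k = len(centers), len(grid)
    if profile == "gaussian" and sigma > 0:
        mids = (grid[:-1] + grid[1:]) / 2.0
        edges = np.concatenate(([-np.inf], mids, [np.inf]))
        cdf = norm.cdf((edges[None, :] - centers[:, None]) / sigma)
        w = np.diff(cdf, axis=1)
    else:
        w = np.zeros((n, k))
        j = np.clip(np.searchsorted(grid, centers), 1, k - 1)
        lo, hi = grid[j - 1], grid[j]
        frac = np.clip((centers - lo) / (hi - lo), 0.0, 1.0)
        w[np.arange(n), j - 1] = 1.0 - frac
        w[np.arange(n), j] = frac
    return w / w.sum(axis=1, keepdims=True)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


def simulate_gradient_replicate(
    centers: np.ndarray,
    masses: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gradient: (counts (taxa x fractions), qPCR totals per fraction).

    Each taxon's DNA mass is spread over the fractions according to its band;
    fraction qPCR totals are the summed masses with lognormal noise; read
    counts are multinomial draws at the configured depth from the fraction's
    mass proportions.
    """
    grid = config.grid
    w = band_weights(centers, grid, config.band_sigma, config.band_profile)
    mass = masses[:, None] * w                      # taxa x fractions
    totals = mass.sum(axis=0)
    qpcr = config.qpcr_scale * totals * _lognormal_factor(rng, config.qpcr_cv, len(grid))
    counts = np.zeros_like(mass, dtype=np.int64)
    for k in range(len(grid)):
        if totals[k] <= 0:
            continue
        p = mass[:, k] / totals[k]
        if config.counts_mode == "multinomial":
            counts[:, k] = rng.multinomial(config.reads_per_fraction, p)
        else:
            counts[:, k] = np.round(p * 1e9).astype(np.int64)
    return counts, qpcr


def _simulate_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth tree over the community taxa, rescaled to unit depth.

    Terminal branches are extended by 5% of the tree depth past the last
    speciation event (the birth process stops exactly at a split, which would
    otherwise leave zero-length terminal branches and a singular trait
    covariance)."""
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace([f"OTU_{i:04d}" for i in range(1, n_tips + 1)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=random.Random(seed),
    )
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.05 * depth
    depth *= 1.05
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree


def _draw_true_eaf(config: SimConfig, tree: dendropy.Tree, taxa: list[str],
                   rng: np.random.Generator,
                   params: IsotopeModelParams) -> pd.DataFrame:
    emax = params.max_eaf
    comps = config.comparisons()
    out = pd.DataFrame(0.0, index=taxa, columns=comps)
    if config.tree_structured:
        from .phylo import simulate_bm_traits, tree_vcv

        C, tips = tree_vcv(tree, tip_order=taxa)
        for comp in comps:
            mean = config.mean_eaf.get(comp, 0.2)
            z = simulate_bm_traits(C, 1, rng, lam=config.trait_lambda,
                                   sigma2=config.trait_sigma ** 2)[0]
            out[comp] = np.clip(mean + z, 0.0, emax)
        return out
    for comp in comps:
        mean = config.mean_eaf.get(comp, 0.2)
        labeled = rng.random(len(taxa)) < config.p_labeled
        vals = rng.normal(mean, config.eaf_sd_frac * mean, len(taxa))
        out[comp] = np.where(labeled, np.clip(vals, 0.005, emax), 0.0)
    return out


def simulate_experiment(
    config: SimConfig,
    params: IsotopeModelParams = DEFAULT_PARAMS,
) -> SimBundle:
    """Full study bundle: counts, metadata, contaminant profile, tree, truth.

    Deterministic given ``config.seed``: all randomness (community, traits,
    tree, gradients, contaminants) flows from one seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    taxa = [f"OTU_{i:04d}" for i in range(1, config.n_taxa + 1)]
    cont_taxa = [f"CONT_{i:03d}" for i in range(1, config.n_contaminants + 1)]

    # community composition and genome GC
    raw = rng.lognormal(0.0, config.abundance_sigma, config.n_taxa)
    abundance = raw / raw.sum()
    lo, hi = config.gc_range
    gc = lo + (hi - lo) * rng.beta(config.gc_alpha, config.gc_beta, config.n_taxa)
    gc_cont = lo + (hi - lo) * rng.beta(config.gc_alpha, config.gc_beta, config.n_contaminants)

    tree = _simulate_tree(config.n_taxa, int(rng.integers(2**31 - 1)))
    eaf = _draw_true_eaf(config, tree, taxa, rng, params)

    # per-arm expected band centers (contaminants are never labeled)
    all_ids = taxa + cont_taxa
    all_gc = np.concatenate([gc, gc_cont])
    leak = config.contaminant_leakage
    all_abund = np.concatenate([abundance * (1.0 - leak * config.n_contaminants),
                                np.full(config.n_contaminants, leak)])

    grid = config.grid
    meta_rows: list[dict] = []
    count_cols: dict[str, np.ndarray] = {}
    expected_wads: dict[str, np.ndarray] = {}
    for substrate in config.substrates:
        for h2 in config.h2_levels:
            comp = substrate + ("+H2" if h2 else "")
            for label in ("13C", "control"):
                a_true = eaf[comp].to_numpy() if label == "13C" else np.zeros(config.n_taxa)
                centers = expected_band_center(all_gc,
                                               np.concatenate([a_true, np.zeros(config.n_contaminants)]),
                                               params)
                w = band_weights(centers, grid, config.band_sigma, config.band_profile)
                expected_wads[f"{comp}|{label}"] = (w * grid[None, :]).sum(axis=1)
                for rep in range(1, config.n_replicates + 1):
                    counts, qpcr = simulate_gradient_replicate(centers, all_abund, config, rng)
                    keep = np.arange(len(grid))
                    if config.top_k_fractions is not None:
                        keep = np.sort(np.argsort(qpcr)[-config.top_k_fractions:])
                    for k in keep:
                        sid = f"{comp}_{label}_r{rep}_f{k:02d}"
                        meta_rows.append(dict(
                            sample_id=sid, treatment=f"{comp}_{label}",
                            substrate=substrate, h2=h2, label=label,
                            replicate=rep, fraction=int(k),
                            density_g_ml=float(grid[k]), qpcr_copies=float(qpcr[k]),
                        ))
                        count_cols[sid] = counts[:, k]

    sample_ids = list(count_cols)
    counts_mat = np.column_stack([count_cols[s] for s in sample_ids]) if sample_ids \
        else np.zeros((len(all_ids), 0), int)
    table = OTUTable(all_ids, sample_ids, counts_mat)
    metadata = FractionMetadata(pd.DataFrame(meta_rows))
    contaminants = ContaminantProfile(
        {c: config.contaminant_profile_reads for c in cont_taxa})
    truth = SimTruth(
        taxa=taxa, contaminant_taxa=cont_taxa, gc=gc, abundance=abundance,
        eaf=eaf, tree_newick=tree.as_string(schema="newick").strip(),
        expected_wads=pd.DataFrame(expected_wads, index=all_ids),
    )
    return SimBundle(table, metadata, contaminants, truth.tree_newick, truth, config)


def true_peak_shifts(truth: SimTruth,
                     params: IsotopeModelParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Noise-free peak buoyant-density shift per taxon per comparison:
    band center at the true EAF minus the light band center (g/ml)."""
    light = expected_band_center(truth.gc, 0.0, params)
    out = {}
    for comp in truth.eaf.columns:
        out[comp] = expected_band_center(truth.gc, truth.eaf[comp].to_numpy(), params) - light
    return pd.DataFrame(out, index=truth.taxa)


def write_experiment(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Write the exact input formats the pipeline reads, plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": outdir / "otu_table.tsv",
        "metadata": outdir / "metadata.csv",
        "contaminants": outdir / "contaminants.tsv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    bundle.table.write_tsv(paths["otu_table"])
    bundle.metadata.frame.drop(columns=["comparison"]).to_csv(paths["metadata"], index=False)
    with open(paths["contaminants"], "w") as fh:
        fh.write("otu_id\tcount\n")
        for otu, c in bundle.contaminants.counts.items():
            fh.write(f"{otu}\t{c}\n")
    paths["tree"].write_text(bundle.tree_newick + "\n")
    bundle.truth.to_json(paths["truth"])
    return paths


def tiny_config(seed: int = 0, **overrides) -> SimConfig:
    """Eight taxa, one substrate pair; runs in seconds."""
    base = dict(
        n_taxa=8, seed=seed, substrates=("bicarbonate",),
        reads_per_fraction=5_000, n_contaminants=2,
    )
    base.update(overrides)
    return SimConfig(**base)


def paper_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Six-hundred-taxon community, three substrates with and without H2."""
    base = dict(n_taxa=600, seed=seed, n_contaminants=30)
    base.update(overrides)
    return SimConfig(**base)
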