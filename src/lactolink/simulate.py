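"""Truth-known synthetic milk single-cell + HMO datasets.

The generator emulates the statistical structure of a longitudinal milk
single-cell study with matched HMO quantitation:

* negative-binomial UMI counts (variance mu + alpha*mu^2) with
  cell-type-specific per-gene expression programs;
* optional planted co-expressed gene pairs driven by a latent per-cell
  Bernoulli "program" state that multiplies both genes' means, so the pair
  is detected together more often than independence predicts;
* per-sample HMO concentrations following donor-random-intercept linear
  trajectories in time postpartum, truncated at zero by resampling the
  residual; and
* optional gene-HMO links whose pseudobulk means scale as
  2**(lfc * z(concentration)).

Defaults mirror a 10-donor cohort sampled roughly three times each across
days 4-272 postpartum, with concentrations in nmol/mL declining over
lactation for most HMOs (3FL rising), which is the regime the downstream
statistics are designed for. Gene names are synthetic placeholders
(G0001...) with a few milk-relevant aliases available for readable reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import (
    TYPE_I_HMOS,
    TYPE_II_HMOS,
    GeneSetLibrary,
    validate_cell_data,
    validate_hmo_panel,
    write_cell_data,
    write_gmt,
)


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


#: real gene symbols usable as aliases for the first synthetic genes
GENE_ALIASES = (
    "LALBA", "B4GALT1", "FUT2", "ST6GAL1", "ST3GAL1", "B3GNT3", "B3GNT7",
    "B3GALT4", "B3GALT5", "FUT3", "FUT6", "B4GALT2", "B4GALT3", "CSN2",
    "FASN", "FABP3", "PLIN2", "BTN1A1", "XDH", "CIDEA",
)


@dataclasses.dataclass(frozen=True)
class HMOSpec:
    """Donor-random-intercept linear trajectory for one HMO (nmol/mL)."""

    intercept: float
    time_slope: float  # nmol/mL per day postpartum
    donor_sd: float
    resid_sd: float

    def __post_init__(self):
        if self.donor_sd < 0 or self.resid_sd <= 0:
            raise ConfigError("donor_sd must be >= 0 and resid_sd > 0")


def default_hmo_specs() -> dict[str, HMOSpec]:
    """Trajectories for a representative HMO panel.

    Intercepts and slopes are on the scale of HPLC-FL absolute
    concentrations: most HMOs decline over lactation, 3FL rises. The panel
    covers all declared type-I and type-II members so aggregate columns are
    exercised.
    """
    return {
        "2'FL": HMOSpec(5000.0, -7.0, 800.0, 400.0),
        "3FL": HMOSpec(500.0, 3.0, 150.0, 100.0),
        "LNT": HMOSpec(1500.0, -3.0, 250.0, 150.0),
        "LNFPI": HMOSpec(1200.0, -2.5, 250.0, 150.0),
        "LNFPII": HMOSpec(350.0, -0.7, 70.0, 50.0),
        "LSTb": HMOSpec(150.0, -0.3, 30.0, 20.0),
        "DSLNT": HMOSpec(400.0, -0.8, 80.0, 50.0),
        "LNnT": HMOSpec(600.0, -1.5, 120.0, 80.0),
        "LNFPIII": HMOSpec(300.0, -0.5, 60.0, 40.0),
        "LSTc": HMOSpec(250.0, -0.5, 50.0, 35.0),
    }


@dataclasses.dataclass
class SimConfig:
    """Configuration for :func:`simulate_dataset`. ``seed`` is mandatory."""

    seed: int
    n_donors: int = 10
    samples_per_donor: int = 3
    cells_per_sample_range: tuple[int, int] = (300, 600)
    n_genes: int = 120
    cell_type_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"LC1": 0.45, "LC2": 0.45, "immune": 0.10}
    )
    baseline_mean: float = 0.5
    dispersion_alpha: float = 0.3
    #: (gene_a, gene_b, cell_type, odds_enrichment >= 1): mean multiplier
    #: applied to both genes in cells where the latent program is on
    planted_pairs: list[tuple[str, str, str, float]] = dataclasses.field(default_factory=list)
    program_prob: float = 0.5
    hmo_specs: dict[str, HMOSpec] = dataclasses.field(default_factory=default_hmo_specs)
    #: (gene, hmo, log2-fold-change per SD of concentration, cell_type)
    gene_hmo_links: list[tuple[str, str, float, str]] = dataclasses.field(default_factory=list)
    time_range_days: tuple[float, float] = (4.0, 272.0)
    gene_mean_log_sd: float = 1.0
    #: (gene, cell_type, mean) — pin specific genes' baseline means, e.g. to
    #: put a planted pair in the informative detection regime
    mean_overrides: list[tuple[str, str, float]] = dataclasses.field(default_factory=list)
    use_gene_aliases: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if abs(sum(self.cell_type_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("cell_type_mix fractions must sum to 1")
        if min(self.cell_type_mix.values()) < 0:
            raise ConfigError("cell_type_mix fractions must be non-negative")
        if self.baseline_mean <= 0 or self.dispersion_alpha <= 0:
            raise ConfigError("baseline_mean and dispersion_alpha must be positive")
        if not (0 < self.program_prob < 1):
            raise ConfigError("program_prob must be in (0, 1)")
        lo, hi = self.cells_per_sample_range
        if not (1 <= lo <= hi):
            raise ConfigError("invalid cells_per_sample_range")
        for _, _, ct, odds in self.planted_pairs:
            if odds < 1:
                raise ConfigError("odds_enrichment must be >= 1")
            if ct not in self.cell_type_mix:
                raise ConfigError(f"planted pair cell type {ct!r} not in mix")
        t_lo, t_hi = self.time_range_days
        for name, spec in self.hmo_specs.items():
            for t in (t_lo, t_hi):
                if spec.intercept + spec.time_slope * t < 0:
                    raise ConfigError(
                        f"HMO {name!r} implies a negative mean concentration at t={t}"
                    )

    def gene_names(self) -> list[str]:
        names = [f"G{i + 1:04d}" for i in range(self.n_genes)]
        if self.use_gene_aliases:
            for i, alias in enumerate(GENE_ALIASES[: self.n_genes]):
                names[i] = alias
        return names


@dataclasses.dataclass
class SimulatedDataset:
    cells: ad.AnnData
    hmo_panel: pd.DataFrame
    truth: dict


def _substreams(seed: int, names):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _nb_counts(rng, mean, alpha):
    """Negative binomial via gamma-Poisson: variance mean + alpha*mean^2."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean)
    return rng.poisson(lam)


def _draw_samples(cfg: SimConfig, rng) -> tuple[pd.DataFrame, np.ndarray]:
    donors = [f"D{d + 1:02d}" for d in range(cfg.n_donors)]
    sample_rows = []
    for d in donors:
        for s in range(cfg.samples_per_donor):
            t = rng.uniform(*cfg.time_range_days)
            sample_rows.append((f"{d}_S{s + 1}", d, float(t)))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "donor_id", "time"])
    samples["study_id"] = "SIM1"
    n_cells = rng.integers(
        cfg.cells_per_sample_range[0], cfg.cells_per_sample_range[1] + 1, len(samples)
    )
    return samples, n_cells


def _draw_panel(cfg: SimConfig, samples: pd.DataFrame, rng) -> pd.DataFrame:
    donors = samples["donor_id"].unique()
    donor_effects = {
        name: {d: rng.normal(0.0, spec.donor_sd) for d in donors}
        for name, spec in cfg.hmo_specs.items()
    }
    panel = pd.DataFrame(index=samples["sample_id"])
    for name, spec in cfg.hmo_specs.items():
        vals = np.empty(len(samples))
        for i, row in samples.iterrows():
            mu = spec.intercept + spec.time_slope * row["time"] + donor_effects[name][row["donor_id"]]
            y = mu + rng.normal(0.0, spec.resid_sd)
            tries = 0
            while y < 0:  # truncate at zero by resampling the residual
                y = mu + rng.normal(0.0, spec.resid_sd)
                tries += 1
                if tries > 1000:
                    raise ConfigError(
                        f"HMO {name!r} cannot produce a non-negative draw at t={row['time']:.1f}"
                    )
            vals[i] = y
        panel[name] = vals
    present_I = [m for m in TYPE_I_HMOS if m in panel.columns]
    present_II = [m for m in TYPE_II_HMOS if m in panel.columns]
    panel["typeI_total"] = panel[present_I].sum(axis=1)
    panel["typeII_total"] = panel[present_II].sum(axis=1)
    panel["donor_id"] = samples.set_index("sample_id")["donor_id"]
    panel["time_postpartum_days"] = samples.set_index("sample_id")["time"].round(1)
    panel["secretor"] = True
    panel.index.name = "sample_id"
    return panel


def simulate_hmo_panel(cfg: SimConfig) -> pd.DataFrame:
    """Generate only the HMO panel (donor-random-intercept trajectories).

    Shares the generator's structure and hmo substreams, so the panel of a
    full :func:`simulate_dataset` run with the same config is identical.
    """
    rngs = _substreams(cfg.seed, ("structure", "means", "hmo", "program", "counts"))
    samples, _ = _draw_samples(cfg, rngs["structure"])
    panel = _draw_panel(cfg, samples, rngs["hmo"])
    return validate_hmo_panel(panel, hmo_columns=list(cfg.hmo_specs))


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate an annotated cell matrix, HMO panel, and truth record."""
    rngs = _substreams(cfg.seed, ("structure", "means", "hmo", "program", "counts"))
    genes = cfg.gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    for a, b, _, _ in cfg.planted_pairs:
        for g in (a, b):
            if g not in gene_index:
                raise ConfigError(f"planted gene {g!r} not among simulated genes")
    for g, hmo, _, ct in cfg.gene_hmo_links:
        if g not in gene_index:
            raise ConfigError(f"linked gene {g!r} not among simulated genes")
        if hmo not in cfg.hmo_specs:
            raise ConfigError(f"linked HMO {hmo!r} not in hmo_specs")
        if ct not in cfg.cell_type_mix:
            raise ConfigError(f"linked cell type {ct!r} not in mix")

    # --- study structure: donors, samples, times
    samples, n_cells_per_sample = _draw_samples(cfg, rngs["structure"])

    # --- per-cell-type gene mean programs
    cell_types = list(cfg.cell_type_mix)
    mean_rng = rngs["means"]
    base_means = {
        ct: cfg.baseline_mean
        * np.exp(mean_rng.normal(0.0, cfg.gene_mean_log_sd, cfg.n_genes))
        for ct in cell_types
    }
    for g, ct, mean in cfg.mean_overrides:
        if g not in gene_index:
            raise ConfigError(f"mean override for unknown gene {g!r}")
        if ct not in base_means:
            raise ConfigError(f"mean override for unknown cell type {ct!r}")
        if mean <= 0:
            raise ConfigError("overridden means must be positive")
        base_means[ct][gene_index[g]] = mean

    # --- HMO trajectories with donor random intercepts
    panel = _draw_panel(cfg, samples, rngs["hmo"])

    # z-scored concentrations drive the gene-HMO links
    hmo_z = {
        name: (panel[name] - panel[name].mean()) / panel[name].std(ddof=1)
        for name in cfg.hmo_specs
    }

    # --- cells
    program_rng = rngs["program"]
    count_rng = rngs["counts"]
    obs_blocks, count_blocks = [], []
    for (_, srow), n_cells in zip(samples.iterrows(), n_cells_per_sample):
        ct_labels = program_rng.choice(
            cell_types, size=n_cells, p=[cfg.cell_type_mix[ct] for ct in cell_types]
        )
        mu = np.empty((n_cells, cfg.n_genes))
        for ct in cell_types:
            mask = ct_labels == ct
            mu[mask] = base_means[ct]
        # gene-HMO links scale the whole cell-type program for this sample
        for g, hmo, lfc, ct in cfg.gene_hmo_links:
            mask = ct_labels == ct
            mu[mask, gene_index[g]] *= 2.0 ** (lfc * hmo_z[hmo].loc[srow["sample_id"]])
        # planted pairs: latent program multiplies both genes' means
        for a, b, ct, odds in cfg.planted_pairs:
            mask = ct_labels == ct
            on = program_rng.random(int(mask.sum())) < cfg.program_prob
            boost = np.where(on, odds, 1.0)
            mu[mask, gene_index[a]] *= boost
            mu[mask, gene_index[b]] *= boost
        counts = _nb_counts(count_rng, mu, cfg.dispersion_alpha)
        count_blocks.append(sp.csr_matrix(counts))
        obs_blocks.append(
            pd.DataFrame(
                {
                    "sample_id": srow["sample_id"],
                    "donor_id": srow["donor_id"],
                    "study_id": srow["study_id"],
                    "cell_type": ct_labels,
                    "time_postpartum_days": round(float(srow["time"]), 1),
                }
            )
        )

    obs = pd.concat(obs_blocks, ignore_index=True)
    obs.index = [f"cell{i + 1:06d}" for i in range(len(obs))]
    X = sp.vstack(count_blocks).tocsr()
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    validate_cell_data(adata)
    validate_hmo_panel(panel, hmo_columns=list(cfg.hmo_specs))

    truth = {
        "seed": cfg.seed,
        "planted_pairs": [list(p) for p in cfg.planted_pairs],
        "gene_hmo_links": [list(l) for l in cfg.gene_hmo_links],
        "hmo_specs": {
            name: dataclasses.asdict(spec) for name, spec in cfg.hmo_specs.items()
        },
        "cell_type_mix": dict(cfg.cell_type_mix),
        "dispersion_alpha": cfg.dispersion_alpha,
        "n_cells_per_sample": {
            s: int(n) for s, n in zip(samples["sample_id"], n_cells_per_sample)
        },
        "realized_proportions": (
            obs.groupby("sample_id")["cell_type"].value_counts(normalize=True).unstack(fill_value=0.0)
        ).to_dict(),
        "base_means": {ct: base_means[ct].tolist() for ct in cell_types},
    }
    return SimulatedDataset(cells=adata, hmo_panel=panel, truth=truth)


def simulate_de_pseudobulk(
    seed: int,
    n_samples_per_study: int = 10,
    n_studies: int = 2,
    n_genes: int = 200,
    base_mean: float = 100.0,
    dispersion_alpha: float = 0.1,
    lfc: np.ndarray | float = 0.0,
    depth_sd: float = 0.3,
) -> "PseudobulkTable":
    """Pseudobulk counts for calibrating the LC1-vs-LC2 Wald contrast.

    Each sample contributes an LC1 and an LC2 row; LC2 means are scaled by
    2**lfc (scalar or per-gene). Per-row sequencing depth varies
    lognormally, exercising size-factor normalization. Counts are NB with
    variance mu + alpha*mu^2 at the pseudobulk level.
    """
    from .pseudobulk import PseudobulkTable

    rng = np.random.default_rng(seed)
    lfc = np.broadcast_to(np.asarray(lfc, dtype=float), (n_genes,))
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    gene_base = base_mean * np.exp(rng.normal(0.0, 0.5, n_genes))
    rows, meta_rows, index = [], [], []
    for st in range(n_studies):
        study = f"ST{st + 1}"
        study_shift = np.exp(rng.normal(0.0, 0.2, n_genes))
        for s in range(n_samples_per_study):
            sample = f"{study}_S{s + 1}"
            for ct, scale in (("LC1", np.ones(n_genes)), ("LC2", 2.0**lfc)):
                depth = np.exp(rng.normal(0.0, depth_sd))
                mu = gene_base * study_shift * scale * depth
                rows.append(_nb_counts(rng, mu, dispersion_alpha))
                meta_rows.append((sample, study, float(30 * (s + 1)), 100))
                index.append((sample, ct))
    idx = pd.MultiIndex.from_tuples(index, names=["sample_id", "cell_type"])
    counts = pd.DataFrame(np.asarray(rows), index=idx, columns=genes)
    meta = pd.DataFrame(
        meta_rows,
        index=idx,
        columns=["donor_id", "study_id", "time_postpartum_days", "n_cells_aggregated"],
    )
    meta["donor_id"] = [s.split("_")[0] + "D" + s.split("_S")[1] for s, _ in index]
    return PseudobulkTable(counts=counts, meta=meta)


def simulate_hmo_linked_pseudobulk(
    seed: int,
    n_donors: int = 10,
    samples_per_donor: int = 2,
    n_genes: int = 100,
    base_mean: float = 100.0,
    dispersion_alpha: float = 0.1,
    linked_lfc: dict[int, float] | None = None,
    hmo_name: str = "LNT",
    donor_sd_log: float = 0.2,
    depth_sd: float = 0.3,
) -> tuple["PseudobulkTable", pd.DataFrame]:
    """Pseudobulk + HMO panel for calibrating the concentration LRT.

    ``linked_lfc`` maps gene indices to log2 fold change per SD of the HMO
    concentration: those genes' means scale as 2**(lfc * z(conc)). Donor
    multipliers and per-row depth variation exercise the nuisance
    covariates.
    """
    from .pseudobulk import PseudobulkTable

    rng = np.random.default_rng(seed)
    linked_lfc = linked_lfc or {}
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    gene_base = base_mean * np.exp(rng.normal(0.0, 0.5, n_genes))
    # within-donor residual variation dominates: the LRT design projects out
    # donor and time, so only this component of the concentration is testable
    spec = HMOSpec(intercept=1500.0, time_slope=-1.5, donor_sd=150.0, resid_sd=300.0)

    cfg = SimConfig(seed=seed, n_donors=n_donors, samples_per_donor=samples_per_donor,
                    hmo_specs={hmo_name: spec}, n_genes=1)
    samples, _ = _draw_samples(cfg, np.random.default_rng(rng.integers(2**31)))
    panel = _draw_panel(cfg, samples, np.random.default_rng(rng.integers(2**31)))
    z = (panel[hmo_name] - panel[hmo_name].mean()) / panel[hmo_name].std(ddof=1)

    donor_mult = {
        d: np.exp(rng.normal(0.0, donor_sd_log, n_genes))
        for d in samples["donor_id"].unique()
    }
    rows, meta_rows, index = [], [], []
    for _, srow in samples.iterrows():
        sample = srow["sample_id"]
        mu = gene_base * donor_mult[srow["donor_id"]]
        mu = mu * np.exp(rng.normal(0.0, depth_sd))
        mu = mu.copy()
        for gi, lfc in linked_lfc.items():
            mu[gi] *= 2.0 ** (lfc * z.loc[sample])
        rows.append(_nb_counts(rng, mu, dispersion_alpha))
        meta_rows.append((srow["donor_id"], srow["study_id"], float(srow["time"]), 100))
        index.append((sample, "LC2"))
    idx = pd.MultiIndex.from_tuples(index, names=["sample_id", "cell_type"])
    counts = pd.DataFrame(np.asarray(rows), index=idx, columns=genes)
    meta = pd.DataFrame(
        meta_rows, index=idx,
        columns=["donor_id", "study_id", "time_postpartum_days", "n_cells_aggregated"],
    )
    return PseudobulkTable(counts=counts, meta=meta), panel


def default_gene_sets(dataset: SimulatedDataset, n_random: int = 3, seed: int = 0) -> GeneSetLibrary:
    """A small library derived from the simulation truth: one set per linked
    HMO plus random filler sets."""
    rng = np.random.default_rng(seed)
    genes = list(dataset.cells.var_names)
    sets: dict[str, list[str]] = {}
    links = dataset.truth["gene_hmo_links"]
    by_hmo: dict[str, list[str]] = {}
    for g, hmo, _, _ in links:
        by_hmo.setdefault(hmo, []).append(g)
    for hmo, members in by_hmo.items():
        sets[f"linked_{hmo}"] = sorted(set(members))
    for i in range(n_random):
        sets[f"random_{i + 1}"] = sorted(rng.choice(genes, size=min(10, len(genes)), replace=False))
    return GeneSetLibrary(name="simulated_sets", sets=sets)


def write_fixture(dataset: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Serialize a simulated dataset as MTX/TSV/CSV/GMT/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_cell_data(dataset.cells, out)
    paths["hmo_panel"] = out / "hmo_panel.csv"
    dataset.hmo_panel.reset_index().to_csv(paths["hmo_panel"], index=False)
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
    paths["gene_sets"] = write_gmt(default_gene_sets(dataset), out / "gene_sets.gmt")
    return paths
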