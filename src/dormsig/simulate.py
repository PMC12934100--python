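"""Seeded synthetic two-phenotype melanoma cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: a small cohort of dormant vs proliferative samples, eight planted
signature genes (four up- and four down-regulated in the dormant state on
the log2 scale), one planted co-expression module with a designated hub,
uncorrelated background genes, exponential survival worse in the dormant
arm, a lower responder rate in the dormant arm, paired DNA/RNA variant
calls with RNA VAF usually higher, and per-sample single-cell expression
in which the hub gene marks a rare (< 20 % by default) cell fraction.

Expression is log-normal: Gaussian on the log2 scale, exponentiated to
non-negative TPM-like values via ``2**x - 1``.  The planted module is
induced by one latent factor per cohort whose *realized* sample correlation
with the standardized phenotype indicator equals ``module_trait_r``
exactly (Gram-Schmidt construction); per-gene loadings are chosen so the
expected pairwise correlation of plain members is ``module_correlation``
and the hub's is ``module_correlation + hub_boost``, which guarantees the
hub has the highest expected intramodular connectivity.

One integer seed drives independent, hierarchically spawned streams per
generator, so each output is a pure function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

DORMANT = "dormant"
PROLIFERATIVE = "proliferative"

_DEFAULT_UP = ("TACSTD2", "EREG", "SOX9", "LPPR4")
_DEFAULT_DOWN = ("LAMA1", "TMEM27", "AMIGO2", "MGAT5B")

# per-gene protein-change vocabularies for the simulated variant tables
_CHANGES = {
    "BRAF": ("V600E", "V600K", "L597S", "D594N"),
    "NRAS": ("Q61K", "Q61R", "Q61L", "G13D"),
}

# stream indices for hierarchical seed spawning
_STREAM_EXPRESSION = 0
_STREAM_CLINICAL = 1
_STREAM_VARIANTS = 2
_STREAM_SINGLE_CELL = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of the emulated study; defaults mirror the 22-sample discovery cohort."""

    n_dormant: int = 11
    n_proliferative: int = 11
    n_background_genes: int = 200
    up_genes: tuple[str, ...] = _DEFAULT_UP
    down_genes: tuple[str, ...] = _DEFAULT_DOWN
    effect_size: float = 2.0          # log2-scale mean shift dormant vs proliferative
    module_genes: int = 12            # planted module size, hub included
    module_hub: str = "TACSTD2"
    module_correlation: float = 0.7   # target pairwise correlation of plain members
    hub_boost: float = 0.2            # extra expected correlation of the hub
    module_trait_r: float = 0.6       # planted eigengene-phenotype correlation
    noise_sd: float = 0.5             # log2-scale residual SD
    hazard_ratio: float = 3.0         # dormant vs proliferative hazard
    baseline_median_months: float = 24.0
    censor_rate: float = 0.2
    responder_prob_dormant: float = 0.15
    responder_prob_proliferative: float = 0.50
    rna_higher_prob: float = 12 / 14  # P(RNA VAF > DNA VAF) among comparable pairs
    dna_missing_prob: float = 0.1
    rna_wt_prob: float = 0.1
    different_site_prob: float = 0.08
    n_cells_per_sample: int = 200
    rare_pos_fraction_max: float = 0.20
    rare_pos_fraction_min: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_dormant": self.n_dormant,
            "n_proliferative": self.n_proliferative,
            "n_background_genes": self.n_background_genes,
            "module_genes": self.module_genes,
            "n_cells_per_sample": self.n_cells_per_sample,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        probs = {
            "censor_rate": self.censor_rate,
            "responder_prob_dormant": self.responder_prob_dormant,
            "responder_prob_proliferative": self.responder_prob_proliferative,
            "rna_higher_prob": self.rna_higher_prob,
            "dna_missing_prob": self.dna_missing_prob,
            "rna_wt_prob": self.rna_wt_prob,
            "different_site_prob": self.different_site_prob,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value!r}")
        if not 0.0 < self.rare_pos_fraction_max <= 1.0:
            raise ValueError("rare_pos_fraction_max must be in (0, 1]")
        if not 0.0 < self.rare_pos_fraction_min <= self.rare_pos_fraction_max:
            raise ValueError("rare_pos_fraction_min must be in (0, rare_pos_fraction_max]")
        if not 0.0 <= self.module_correlation < 1.0:
            raise ValueError("module_correlation must be in [0, 1)")
        if self.module_correlation + self.hub_boost >= 1.0 + 1e-12:
            raise ValueError("module_correlation + hub_boost must be < 1")
        if not -1.0 <= self.module_trait_r <= 1.0:
            raise ValueError("module_trait_r must be in [-1, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.baseline_median_months <= 0:
            raise ValueError("baseline_median_months must be positive")
        up, down = set(self.up_genes), set(self.down_genes)
        if up & down:
            raise ValueError(f"up and down gene sets overlap: {sorted(up & down)}")
        if self.module_hub in down:
            raise ValueError("module_hub may coincide with an up gene but not a down gene")
        signature = up | down
        if signature & set(self.module_member_ids()) - {self.module_hub}:
            raise ValueError("planted module members collide with signature genes")
        if signature & set(self.background_gene_ids()):
            raise ValueError("background genes collide with signature genes")

    # --- deterministic identifier layout -------------------------------------

    def sample_ids(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_dormant)] + [
            f"P{i + 1:02d}" for i in range(self.n_proliferative)
        ]

    def labels(self) -> pd.Series:
        values = [DORMANT] * self.n_dormant + [PROLIFERATIVE] * self.n_proliferative
        return pd.Series(values, index=self.sample_ids(), name="phenotype")

    def module_member_ids(self) -> list[str]:
        if self.module_genes == 0:
            return []
        extra = [f"MOD{i + 1:02d}" for i in range(self.module_genes - 1)]
        return [self.module_hub] + extra

    def background_gene_ids(self) -> list[str]:
        return [f"BG{i + 1:04d}" for i in range(self.n_background_genes)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["up_genes"] = list(self.up_genes)
        d["down_genes"] = list(self.down_genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("up_genes", "down_genes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _standardized_indicator(labels: pd.Series) -> np.ndarray:
    ind = (labels.to_numpy() == DORMANT).astype(float)
    centered = ind - ind.mean()
    norm = np.linalg.norm(centered)
    if norm == 0:
        raise ValueError("both phenotypes must be present")
    return centered / norm  # unit-norm, zero-mean


def _latent_factor(rng: np.random.Generator, c_unit: np.ndarray, r: float) -> np.ndarray:
    """Unit-norm latent factor whose realized correlation with ``c_unit`` is exactly r."""
    n = c_unit.shape[0]
    g = rng.standard_normal(n)
    g = g - g.mean()
    g = g - (g @ c_unit) * c_unit
    norm = np.linalg.norm(g)
    if norm < 1e-12:  # pathological draw; fall back to the indicator itself
        return c_unit.copy()
    g /= norm
    return r * c_unit + np.sqrt(max(0.0, 1.0 - r * r)) * g


def simulate_expression(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a genes x samples TPM matrix plus phenotype labels.

    Returns
    -------
    (matrix, labels)
        ``matrix`` is a non-negative DataFrame indexed by gene id with one
        column per sample; ``labels`` maps sample id to phenotype.
    """
    if config.n_dormant == 0 or config.n_proliferative == 0:
        raise ValueError("both phenotypes need at least one sample")
    rng = _rng(config, _STREAM_EXPRESSION)
    labels = config.labels()
    n = len(labels)
    sign = np.where(labels.to_numpy() == DORMANT, 1.0, -1.0)

    genes = (
        list(config.up_genes)
        + list(config.down_genes)
        + [g for g in config.module_member_ids() if g != config.module_hub]
        + config.background_gene_ids()
    )
    module_members = config.module_member_ids()

    mu = rng.uniform(3.0, 8.0, size=len(genes))
    shift = np.zeros(len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    for g in config.up_genes:
        shift[idx[g]] = config.effect_size / 2.0
    for g in config.down_genes:
        shift[idx[g]] = -config.effect_size / 2.0

    # module latent factor scaled to unit sample variance
    c_unit = _standardized_indicator(labels)
    f = _latent_factor(rng, c_unit, config.module_trait_r) * np.sqrt(max(n - 1, 1))

    loadings = np.zeros(len(genes))
    rho = config.module_correlation
    rho_hub = min(rho + config.hub_boost, 0.95)
    if module_members and rho > 0:
        lam = config.noise_sd * np.sqrt(rho / (1.0 - rho))
        lam_hub = config.noise_sd * np.sqrt(rho_hub / (1.0 - rho_hub))
        for g in module_members:
            loadings[idx[g]] = lam_hub if g == config.module_hub else lam

    log2x = (
        mu[:, None]
        + shift[:, None] * sign[None, :]
        + loadings[:, None] * f[None, :]
        + config.noise_sd * rng.standard_normal((len(genes), n))
    )
    tpm = np.clip(np.exp2(log2x) - 1.0, 0.0, None)
    matrix = pd.DataFrame(tpm, index=pd.Index(genes, name="gene_id"), columns=labels.index)
    return matrix, labels


def simulate_clinical(config: SimulationConfig, labels: pd.Series) -> pd.DataFrame:
    """Exponential survival and Bernoulli response per sample.

    Dormant samples have hazard ``hazard_ratio`` x baseline; censoring is an
    independent coin flip at ``censor_rate`` with the censoring time drawn
    uniformly before the latent event time.
    """
    if config.hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if labels.empty:
        raise ValueError("labels must cover at least one sample")
    rng = _rng(config, _STREAM_CLINICAL)
    base_rate = np.log(2.0) / config.baseline_median_months
    is_dormant = labels.to_numpy() == DORMANT
    rate = np.where(is_dormant, base_rate * config.hazard_ratio, base_rate)
    event_time = rng.exponential(1.0 / rate)
    censored = rng.random(len(labels)) < config.censor_rate
    observed = np.where(censored, event_time * rng.random(len(labels)), event_time)
    p_resp = np.where(is_dormant, config.responder_prob_dormant, config.responder_prob_proliferative)
    responder = rng.random(len(labels)) < p_resp
    return pd.DataFrame(
        {
            "sample_id": labels.index,
            "phenotype": labels.to_numpy(),
            "time": observed,
            "event": (~censored).astype(int),
            "response": np.where(responder, "responder", "non_responder"),
        }
    ).set_index("sample_id")


def simulate_variant_table(config: SimulationConfig) -> pd.DataFrame:
    """Per-sample DNA/RNA variant pairs shaped like the cohort mutation table.

    Each sample carries one driver call in BRAF or NRAS; the RNA-level call
    confirms the same site, reports a different site, or comes back wild
    type, and among comparable pairs the RNA VAF exceeds the DNA VAF with
    probability ``rna_higher_prob`` (copy-number gains at the mutant locus
    inflate mutant transcript fractions).
    """
    rng = _rng(config, _STREAM_VARIANTS)
    rows = []
    for sample in config.sample_ids():
        gene = "BRAF" if rng.random() < 0.7 else "NRAS"
        changes = _CHANGES[gene]
        dna_change = changes[rng.integers(len(changes))]
        dna_vaf: float | None = float(rng.integers(10, 91))  # [10, 90]
        if rng.random() < config.dna_missing_prob:
            dna_vaf = None
        u = rng.random()
        if u < config.rna_wt_prob:
            rna_change, rna_vaf = "WT", None
        elif u < config.rna_wt_prob + config.different_site_prob:
            rna_change = changes[rng.integers(len(changes))]
            while rna_change == dna_change:
                rna_change = changes[rng.integers(len(changes))]
            rna_vaf = float(rng.integers(5, 96))
        else:
            rna_change = dna_change
            anchor = dna_vaf if dna_vaf is not None else float(rng.integers(10, 91))
            if rng.random() < config.rna_higher_prob:
                rna_vaf = float(rng.integers(int(anchor) + 1, 96))
            else:
                rna_vaf = float(rng.integers(5, int(anchor)))
        rows.append(
            {
                "sample_id": sample,
                "gene": gene,
                "dna_variant": dna_change,
                "dna_vaf": dna_vaf,
                "rna_variant": rna_change,
                "rna_vaf": rna_vaf,
            }
        )
    return pd.DataFrame(rows)


def simulate_single_cell(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Cell x gene expression with a cell-to-sample map.

    The hub gene is expressed in a rare fraction of cells per sample, drawn
    in ``[rare_pos_fraction_min, rare_pos_fraction_max]``; the remaining
    signature genes are expressed in broad fractions (30-90 % of cells).
    Expressed cells get log-normal TPM-like values, others exact zeros.
    """
    if config.n_cells_per_sample < 1:
        raise ValueError("n_cells_per_sample must be >= 1")
    rng = _rng(config, _STREAM_SINGLE_CELL)
    genes = list(config.up_genes) + list(config.down_genes)
    n_cells = config.n_cells_per_sample
    blocks, cell_ids, cell_samples = [], [], []
    for sample in config.sample_ids():
        values = np.zeros((n_cells, len(genes)))
        for j, gene in enumerate(genes):
            if gene == config.module_hub:
                frac = rng.uniform(config.rare_pos_fraction_min, config.rare_pos_fraction_max)
            else:
                frac = rng.uniform(0.3, 0.9)
            n_pos = int(np.floor(frac * n_cells))
            n_pos = max(n_pos, 1) if frac > 0 else 0
            n_pos = min(n_pos, int(np.floor(config.rare_pos_fraction_max * n_cells))
                        if gene == config.module_hub else n_cells)
            pos = rng.choice(n_cells, size=n_pos, replace=False)
            values[pos, j] = np.exp2(rng.normal(2.0, 1.0, size=n_pos))
        blocks.append(values)
        cell_ids.extend(f"{sample}_c{i + 1:04d}" for i in range(n_cells))
        cell_samples.extend([sample] * n_cells)
    cells = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(cell_ids, name="cell_id"), columns=genes
    )
    cell_map = pd.Series(cell_samples, index=cells.index, name="sample_id")
    return cells, cell_map
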