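"""Synthetic data generator with planted ground truth.

Every pipeline input is emulated: a cell-line panel whose per-drug AUCs
depend on a latent glycolysis/OXPHOS program, two patient cohorts sharing
that program but shifted by a batch offset, drug metadata, a PPI edge list
with planted hubs, perturbation pre/post profiles, and survival driven by a
marker gene. Fixed seed gives bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import GeneSetCollection

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "PerturbationSet",
    "generate_gene_sets",
    "generate_ccl_panel",
    "generate_patient_cohort",
    "generate_ppi_edges",
    "generate_perturbation_profiles",
]

COHORT_IDS = ("EC-like", "WC-like")

# substream keys so each artifact has an independent, reproducible stream
_STREAMS = {
    "gene_sets": 0,
    "baseline": 1,
    "ccl": 2,
    "EC-like": 3,
    "WC-like": 4,
    "ppi": 5,
    "perturb": 6,
    "drugs": 7,
    "background": 8,
}


@dataclass
class SynthConfig:
    n_genes: int = 2000
    n_ccl: int = 300
    n_patients_per_cohort: int = 120
    n_drugs: int = 60
    n_planted_hg: int = 8
    n_planted_de: int = 4
    geneset_sizes: dict[str, int] = field(
        default_factory=lambda: {"glycolysis": 40, "oxphos": 200, "ar": 20}
    )
    effect_size_gamma: float = -0.5
    noise_sd: float = 0.15
    expr_noise_sd: float = 0.5
    batch_shift: float = 2.0
    prog_corr: float = 0.5
    survival_beta: float = 0.8
    censor_rate: float = 0.2
    age_oxphos_coef: float = 0.0
    # background latent factors give off-signature genes correlated structure;
    # without them the metabolic program is the only structured direction and
    # every random prediction vector aligns with it, inflating null hits
    n_background_factors: int = 30
    background_loading: float = 0.7
    n_planted_hubs: int = 3
    hub_partners: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_ccl", "n_patients_per_cohort", "n_drugs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_hg < 0 or self.n_planted_de < 0:
            raise ValueError("planted drug counts must be nonnegative")
        if self.n_planted_hg + self.n_planted_de > self.n_drugs:
            raise ValueError("n_planted_hg + n_planted_de exceeds n_drugs")
        total = sum(self.geneset_sizes.values())
        if total > self.n_genes:
            raise ValueError("gene set sizes exceed the gene universe")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if abs(self.prog_corr) > 1:
            raise ValueError("|prog_corr| must be <= 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def drug_ids(self) -> list[str]:
        width = len(str(self.n_drugs))
        return [f"D{i:0{width}d}" for i in range(1, self.n_drugs + 1)]


@dataclass
class GroundTruth:
    latent_glycolysis: pd.Series
    latent_oxphos: pd.Series
    planted_hg_drugs: set[str]
    planted_de_drugs: set[str]
    true_auc: pd.DataFrame  # cell line x drug, noiseless
    marker_gene: str
    planted_hub_genes: set[str] = field(default_factory=set)
    gamma: dict[str, float] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)


@dataclass
class PerturbationSet:
    """Pre/post treatment replicate profiles per drug (genes x replicates)."""

    profiles: dict[str, tuple[pd.DataFrame, pd.DataFrame]]

    def drugs(self) -> list[str]:
        return list(self.profiles)


def generate_gene_sets(config: SynthConfig) -> GeneSetCollection:
    """Disjoint signature gene sets drawn without replacement from the universe."""
    rng = config.rng("gene_sets")
    perm = rng.permutation(config.gene_ids)
    sets: dict[str, list[str]] = {}
    cursor = 0
    for name in sorted(config.geneset_sizes):
        size = config.geneset_sizes[name]
        if size > config.n_genes:
            raise ValueError(f"gene set {name!r} size {size} exceeds universe")
        if size == 0:
            warnings.warn(f"gene set {name!r} is empty (degenerate)", stacklevel=2)
            sets[name] = []
            continue
        sets[name] = sorted(perm[cursor : cursor + size])
        cursor += size
    return GeneSetCollection(sets, {name: "synthetic signature" for name in sets})


def _baseline(config: SynthConfig) -> np.ndarray:
    return config.rng("baseline").uniform(2.0, 10.0, size=config.n_genes)


def _signature_loadings(config: SynthConfig, sets: GeneSetCollection) -> dict[str, np.ndarray]:
    gene_index = pd.Index(config.gene_ids)
    return {
        name: gene_index.isin(members).astype(float)
        for name, members in sets.sets.items()
    }


def _background_assignment(config: SynthConfig, sets: GeneSetCollection) -> np.ndarray:
    """Factor index per gene (-1 for signature genes), fixed across populations."""
    signature = {g for members in sets.sets.values() for g in members}
    fidx = np.full(config.n_genes, -1, dtype=int)
    if config.n_background_factors <= 0:
        return fidx
    rng = config.rng("background")
    off = [i for i, g in enumerate(config.gene_ids) if g not in signature]
    assignment = rng.integers(0, config.n_background_factors, size=len(off))
    fidx[off] = assignment
    return fidx


def _latents(rng: np.random.Generator, n: int, corr: float) -> np.ndarray:
    cov = np.array([[1.0, corr], [corr, 1.0]])
    return rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")


def _expression(
    config: SynthConfig,
    rng: np.random.Generator,
    latents: np.ndarray,
    sets: GeneSetCollection,
    sample_ids: list[str],
    shift: float = 0.0,
) -> pd.DataFrame:
    """baseline + loading * latent + noise, on a log-like scale."""
    loadings = _signature_loadings(config, sets)
    n = len(sample_ids)
    expr = _baseline(config)[:, None] + rng.normal(
        0.0, config.expr_noise_sd, size=(config.n_genes, n)
    )
    expr += np.outer(loadings["glycolysis"], latents[:, 0])
    expr += np.outer(loadings["oxphos"], latents[:, 1])
    if "ar" in loadings:
        ar_latent = rng.standard_normal(n)
        expr += np.outer(loadings["ar"], ar_latent)
    fidx = _background_assignment(config, sets)
    if config.n_background_factors > 0:
        factors = rng.standard_normal((n, config.n_background_factors))
        structured = fidx >= 0
        expr[structured] += config.background_loading * factors[:, fidx[structured]].T
    expr += shift
    return pd.DataFrame(expr, index=config.gene_ids, columns=sample_ids)


def _drug_effects(config: SynthConfig) -> tuple[dict[str, float], dict[str, float]]:
    drugs = config.drug_ids
    gamma = {d: 0.0 for d in drugs}
    delta = {d: 0.0 for d in drugs}
    for d in drugs[: config.n_planted_hg]:
        gamma[d] = config.effect_size_gamma
    for d in drugs[config.n_planted_hg : config.n_planted_hg + config.n_planted_de]:
        gamma[d] = config.effect_size_gamma
        delta[d] = config.effect_size_gamma
    return gamma, delta


def generate_ccl_panel(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Cell-line expression, measured AUC table, drug metadata and truth."""
    rng = config.rng("ccl")
    ids = [f"CCL{i:04d}" for i in range(1, config.n_ccl + 1)]
    latents = _latents(rng, config.n_ccl, config.prog_corr)
    sets = generate_gene_sets(config)
    expr = _expression(config, rng, latents, sets, ids)

    gamma, delta = _drug_effects(config)
    drug_rng = config.rng("drugs")
    alpha = drug_rng.uniform(8.0, 14.0, size=config.n_drugs)
    drugs = config.drug_ids
    true_auc = pd.DataFrame(
        {
            d: alpha[k] + gamma[d] * latents[:, 0] + delta[d] * latents[:, 1]
            for k, d in enumerate(drugs)
        },
        index=ids,
    )
    measured = true_auc + rng.normal(0.0, config.noise_sd, size=true_auc.shape)

    moas = [
        "CDK inhibitor",
        "HSP inhibitor",
        "aurora kinase inhibitor",
        "EGFR inhibitor",
        "mTOR inhibitor",
        "topoisomerase inhibitor",
        "HDAC inhibitor",
        "proteasome inhibitor",
    ]
    statuses = []
    n_planted = config.n_planted_hg + config.n_planted_de
    for k in range(config.n_drugs):
        if k < n_planted:
            statuses.append(["approved", "clinical"][k % 2])
        else:
            statuses.append(["approved", "clinical", "preclinical"][k % 3])
    metadata = pd.DataFrame(
        {
            "drug_id": drugs,
            "moa": [moas[k % len(moas)] for k in range(config.n_drugs)],
            "status": statuses,
        }
    )

    signature_genes = {g for members in sets.sets.values() for g in members}
    marker = next(g for g in config.gene_ids if g not in signature_genes)
    truth = GroundTruth(
        latent_glycolysis=pd.Series(latents[:, 0], index=ids),
        latent_oxphos=pd.Series(latents[:, 1], index=ids),
        planted_hg_drugs=set(drugs[: config.n_planted_hg]),
        planted_de_drugs=set(
            drugs[config.n_planted_hg : config.n_planted_hg + config.n_planted_de]
        ),
        true_auc=true_auc,
        marker_gene=marker,
        gamma=gamma,
        delta=delta,
    )
    return expr, measured, metadata, truth


def generate_patient_cohort(
    config: SynthConfig, truth: GroundTruth, cohort_id: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient expression (batch-shifted) and clinical table for one cohort."""
    if cohort_id not in COHORT_IDS:
        raise ValueError(f"unknown cohort_id {cohort_id!r}; expected one of {COHORT_IDS}")
    rng = config.rng(cohort_id)
    n = config.n_patients_per_cohort
    prefix = cohort_id.split("-")[0]
    ids = [f"{prefix}{i:04d}" for i in range(1, n + 1)]
    latents = _latents(rng, n, config.prog_corr)
    sets = generate_gene_sets(config)
    expr = _expression(config, rng, latents, sets, ids, shift=config.batch_shift)

    age = rng.uniform(45.0, 85.0, size=n) + config.age_oxphos_coef * latents[:, 1]
    marker = expr.loc[truth.marker_gene].to_numpy()
    z = (marker - marker.mean()) / marker.std(ddof=0)
    base_rate = np.log(2.0) / 24.0  # median ~24 months at beta=0
    rate = base_rate * np.exp(config.survival_beta * z)
    event_time = rng.exponential(1.0 / rate)
    censored = rng.uniform(size=n) < config.censor_rate
    frac = rng.uniform(size=n)
    time = np.where(censored, np.maximum(event_time * frac, 1e-6), event_time)
    clinical = pd.DataFrame(
        {
            "sample_id": ids,
            "age_at_procurement": age,
            "os_months": time,
            "os_event": (~censored).astype(int),
        }
    )
    return expr, clinical


def generate_ppi_edges(config: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """STRING-style undirected edge list with planted high-confidence hubs."""
    rng = config.rng("ppi")
    genes = config.gene_ids
    hubs = sorted(rng.choice(genes, size=config.n_planted_hubs, replace=False))
    truth.planted_hub_genes = set(hubs)

    edges: dict[tuple[str, str], int] = {}

    def add(a: str, b: str, score: int) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        edges[key] = max(edges.get(key, 0), score)

    for hub in hubs:
        pool = [g for g in genes if g != hub]
        partners = rng.choice(pool, size=config.hub_partners, replace=False)
        for p in partners:
            add(hub, p, int(rng.integers(700, 1000)))
    n_background = config.n_genes * 2
    a_idx = rng.integers(0, config.n_genes, size=n_background)
    b_idx = rng.integers(0, config.n_genes, size=n_background)
    scores = rng.integers(150, 1000, size=n_background)
    for ai, bi, sc in zip(a_idx, b_idx, scores):
        add(genes[ai], genes[bi], int(sc))

    rows = sorted(edges.items())
    return pd.DataFrame(
        {
            "protein1": [k[0] for k, _ in rows],
            "protein2": [k[1] for k, _ in rows],
            "combined_score": [v for _, v in rows],
        }
    )


def generate_perturbation_profiles(
    config: SynthConfig,
    truth: GroundTruth,
    drug_effects: dict[str, dict[str, float]],
    n_replicates: int = 5,
) -> PerturbationSet:
    """Pre/post replicate profiles; post shifts signature-gene means per drug.

    ``drug_effects`` maps drug id -> {signature name: mean shift}.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition for the Welch test")
    unknown = set(drug_effects) - set(config.drug_ids)
    if unknown:
        raise ValueError(f"drug_effects contains unknown drugs: {sorted(unknown)}")
    rng = config.rng("perturb")
    sets = generate_gene_sets(config)
    loadings = _signature_loadings(config, sets)
    baseline = _baseline(config)
    profiles = {}
    for drug, shifts in drug_effects.items():
        unknown_sigs = set(shifts) - set(loadings)
        if unknown_sigs:
            raise ValueError(f"unknown signatures for {drug}: {sorted(unknown_sigs)}")
        pre = baseline[:, None] + rng.normal(
            0.0, config.expr_noise_sd, size=(config.n_genes, n_replicates)
        )
        post = baseline[:, None] + rng.normal(
            0.0, config.expr_noise_sd, size=(config.n_genes, n_replicates)
        )
        for sig, shift in shifts.items():
            post += shift * loadings[sig][:, None]
        cols_pre = [f"{drug}_pre_{i}" for i in range(1, n_replicates + 1)]
        cols_post = [f"{drug}_post_{i}" for i in range(1, n_replicates + 1)]
        profiles[drug] = (
            pd.DataFrame(pre, index=config.gene_ids, columns=cols_pre),
            pd.DataFrame(post, index=config.gene_ids, columns=cols_post),
        )
    return PerturbationSet(profiles)
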