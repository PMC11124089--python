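"""End-to-end orchestration of the synthetic analysis.

Stage order: simulate -> signature scoring -> harmonization + imputation
(per cohort, as each cohort defines its own batch pairing with the
cell-line panel) -> association/nomination -> MOA summary -> filter
cascade -> network biomarker discovery -> survival stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import imputation, io, network, nomination, scoring, survival, synth
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "simulate_universe", "run_all"]


@dataclass
class SyntheticUniverse:
    config: synth.SynthConfig
    gene_sets: scoring.GeneSetCollection
    ccl_expr: pd.DataFrame
    measured: pd.DataFrame
    metadata: pd.DataFrame
    truth: synth.GroundTruth
    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    ppi_edges: pd.DataFrame
    perturb: synth.PerturbationSet
    activation_drug: str
    suppression_drug: str


@dataclass
class PipelineResult:
    universe: SyntheticUniverse
    scores: dict[str, scoring.ScoreTable]
    ar_scores: dict[str, scoring.ScoreTable]
    strata: dict[str, pd.Series]
    bundles: dict[str, imputation.RidgeModelBundle]
    imputed: dict[str, pd.DataFrame]
    assoc: pd.DataFrame
    sets: nomination.NominationSets
    moa: pd.DataFrame
    trail: nomination.FilterTrail
    biomarkers: dict = field(default_factory=dict)
    survival_results: dict = field(default_factory=dict)


def simulate_universe(config: PipelineConfig) -> SyntheticUniverse:
    """Generate every pipeline input with planted ground truth."""
    synth_cfg = synth.SynthConfig(seed=config.seed, **config.synth)
    gene_sets = synth.generate_gene_sets(synth_cfg)
    ccl_expr, measured, metadata, truth = synth.generate_ccl_panel(synth_cfg)
    cohorts = {
        cid: synth.generate_patient_cohort(synth_cfg, truth, cid)
        for cid in config.cohorts
    }
    ppi = synth.generate_ppi_edges(synth_cfg, truth)
    planted = sorted(truth.planted_hg_drugs)
    suppression_drug = planted[0]
    activation_drug = planted[1] if len(planted) > 1 else planted[0]
    effects = {
        suppression_drug: {"glycolysis": -0.8, "oxphos": -0.8},
        activation_drug: {"glycolysis": 1.0},
    }
    perturb = synth.generate_perturbation_profiles(synth_cfg, truth, effects)
    return SyntheticUniverse(
        config=synth_cfg,
        gene_sets=gene_sets,
        ccl_expr=ccl_expr,
        measured=measured,
        metadata=metadata,
        truth=truth,
        cohorts=cohorts,
        ppi_edges=ppi,
        perturb=perturb,
        activation_drug=activation_drug,
        suppression_drug=suppression_drug,
    )


def _score_cohort(expr: pd.DataFrame, gene_sets: scoring.GeneSetCollection):
    metabolic = scoring.GeneSetCollection(
        {k: v for k, v in gene_sets.sets.items() if k in ("glycolysis", "oxphos")}
    )
    raw = scoring.gsva_enrichment(expr, metabolic)
    return scoring.rescale_scores(raw)


def run_all(config: PipelineConfig, universe: SyntheticUniverse | None = None) -> PipelineResult:
    """Execute every stage on the synthetic universe and persist artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if universe is None:
        universe = simulate_universe(config)
    if universe.measured.shape[1] == 0:
        raise ValueError("drug library is empty; nothing to impute")
    source = config.sources[0]

    # stage 1: signature scoring per cohort
    scores, ar_scores, strata = {}, {}, {}
    for cid, (expr, _clin) in universe.cohorts.items():
        scores[cid] = _score_cohort(expr, universe.gene_sets)
        ar_scores[cid] = scoring.ar_activity(expr, universe.gene_sets["ar"])
        strata[cid] = scoring.stratify_ar_gly(ar_scores[cid], scores[cid], "glycolysis")
        scores[cid].scores.to_csv(out / f"scores_{cid}.csv")

    # stage 2: harmonize + train + impute per cohort
    bundles, imputed = {}, {}
    for cid, (expr, _clin) in universe.cohorts.items():
        train_h, target_h = imputation.harmonize_expression(universe.ccl_expr, expr)
        bundle = imputation.train_drug_models(
            train_h,
            universe.measured,
            feature_fraction=config.feature_fraction,
            seed=config.seed,
        )
        bundles[cid] = bundle
        imputed[cid] = imputation.impute(bundle, target_h)
        imputed[cid].to_csv(out / f"imputed_{cid}.csv")

    # stage 3: association + nomination
    assoc_frames = []
    for cid, (expr, clin) in universe.cohorts.items():
        for score_type in ("glycolysis", "oxphos"):
            assoc_frames.append(
                nomination.score_response_association(
                    scores[cid], imputed[cid], clin, score_type,
                    cohort=cid, source=source,
                )
            )
    assoc = pd.concat(assoc_frames, ignore_index=True)
    sets, assoc = nomination.nominate_drug_sets(assoc, alpha=config.alpha)
    assoc.to_csv(out / "associations.csv", index=False)
    io.write_json(sets.summary_counts(), out / "nomination_counts.json")

    # stage 4: MOA summary + filter cascade
    candidates = sets.cross_cohort_hg[source]
    moa = nomination.primary_moa_summary(candidates, universe.metadata, assoc)
    moa.to_csv(out / "moa_summary.csv", index=False)
    if candidates:
        trail = nomination.run_filter_cascade(
            candidates,
            universe.metadata,
            assoc,
            universe.ccl_expr,
            universe.measured,
            universe.perturb,
            universe.gene_sets,
            alpha=config.alpha,
            enabled=config.filters,
        )
    else:
        trail = nomination.FilterTrail()
    trail.to_frame().to_csv(out / "filter_trail.csv", index=False)

    result = PipelineResult(
        universe=universe,
        scores=scores,
        ar_scores=ar_scores,
        strata=strata,
        bundles=bundles,
        imputed=imputed,
        assoc=assoc,
        sets=sets,
        moa=moa,
        trail=trail,
    )

    # stage 5: biomarker discovery for the lead surviving candidate
    lead = sorted(trail.final)[0] if trail.final else None
    first_cohort = config.cohorts[0]
    expr0, clin0 = universe.cohorts[first_cohort]
    if lead is not None:
        genes = network.preselect_correlated_genes(
            expr0, imputed[first_cohort][lead], threshold=config.preselect_threshold
        )
        if genes:
            graph = network.build_ppi_subnetwork(
                universe.ppi_edges, genes, min_conf=config.min_conf
            )
            table = network.centrality_table(
                graph, seed=config.seed, n_reps=config.epc_reps
            )
            counts, hubs = network.consensus_hubs(
                table, k=config.top_k, min_methods=config.min_methods
            )
            biomarker_table = network.spearman_biomarker_filter(
                universe.ccl_expr, universe.measured[lead], hubs, alpha=config.alpha
            )
            stratum = network.stratum_response_test(
                imputed[first_cohort][lead], strata[first_cohort]
            )
            result.biomarkers = {
                "drug": lead,
                "preselected": genes,
                "consensus_counts": counts,
                "hubs": hubs,
                "biomarker_table": biomarker_table,
                "stratum_test": stratum,
            }
            table.to_csv(out / "centrality.csv")
            biomarker_table.to_csv(out / "biomarkers.csv", index=False)

    # stage 6: survival stratification on the planted marker gene
    low, high, lr, labels = survival.median_split_survival(
        expr0, universe.truth.marker_gene, clin0
    )
    result.survival_results = {
        "gene": universe.truth.marker_gene,
        "low_curve": low,
        "high_curve": high,
        "log_rank": lr,
    }
    low.table.to_csv(out / "km_low.csv", index=False)
    high.table.to_csv(out / "km_high.csv", index=False)
    io.write_json(lr, out / "log_rank.json")

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_drugs": universe.measured.shape[1],
        "cohorts": list(config.cohorts),
        "final_candidates": sorted(trail.final),
    }
    io.write_json(manifest, out / "manifest.json")
    io.write_json(
        {
            "nomination": sets.summary_counts(),
            "filter_survivors": [sorted(s) for s in trail.survivors],
        },
        out / "summary.json",
    )
    return result
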