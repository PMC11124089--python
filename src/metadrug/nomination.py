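"""Score-response association screening, FDR control, drug-set nomination,
MOA summaries and the four-filter candidate cascade.

Per drug, the signature score is regressed on the predicted response
(score = b0 + b1 * response, plus an age covariate for OXPHOS models when
age is available); drugs with significantly negative b1 after BH adjustment
in every cohort are nominated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scoring import GeneSetCollection, ScoreTable, gsva_enrichment
from .synth import PerturbationSet

logger = logging.getLogger(__name__)

__all__ = [
    "score_response_association",
    "bh_adjust",
    "nominate_drug_sets",
    "NominationSets",
    "primary_moa_summary",
    "FilterTrail",
    "run_filter_cascade",
]

ASSOC_COLUMNS = [
    "drug_id", "score_type", "cohort", "source",
    "beta0", "beta1", "beta2", "p_value", "fdr", "n",
]


def score_response_association(
    scores: ScoreTable,
    imputed: pd.DataFrame,
    clinical: pd.DataFrame | None,
    score_type: str,
    cohort: str = "cohort",
    source: str = "source",
    adjust_age: bool = True,
) -> pd.DataFrame:
    """OLS of signature score on predicted response, one model per drug.

    For ``score_type == "oxphos"`` the age at procurement is added as a
    covariate when present in ``clinical``. Complete-case per model.
    """
    y_all = scores.scores[score_type] if score_type in scores.scores else scores.scores.iloc[:, 0]
    shared = [s for s in imputed.index if s in y_all.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    age = None
    if score_type == "oxphos" and adjust_age and clinical is not None \
            and "age_at_procurement" in clinical.columns:
        age = clinical.set_index("sample_id")["age_at_procurement"].reindex(shared)
        if age.notna().sum() < 3:
            age = None

    records = []
    for drug in imputed.columns:
        x = imputed.loc[shared, drug].astype(float)
        y = y_all.loc[shared].astype(float)
        cols = {"response": x}
        if age is not None:
            cols["age"] = age
        design = pd.DataFrame(cols).dropna()
        y = y.loc[design.index]
        n = len(design)
        if design["response"].nunique() <= 1:
            warnings.warn(f"drug {drug}: constant predicted response", stacklevel=2)
            records.append((drug, score_type, cohort, source,
                            y.mean(), 0.0, np.nan, 1.0, np.nan, n))
            continue
        x_mat = sm.add_constant(design)
        fit = sm.OLS(y, x_mat).fit()
        beta2 = fit.params.get("age", np.nan)
        records.append((
            drug, score_type, cohort, source,
            fit.params["const"], fit.params["response"], beta2,
            fit.pvalues["response"], np.nan, n,
        ))
    return pd.DataFrame(records, columns=ASSOC_COLUMNS)


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((arr < 0) | (arr > 1)) or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(arr)
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class NominationSets:
    """Per-(cohort, source) drug sets and their cross-cohort intersections."""

    drug_hg: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    drug_ox: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    drug_de: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    cross_cohort_hg: dict[str, set[str]] = field(default_factory=dict)
    cross_cohort_ox: dict[str, set[str]] = field(default_factory=dict)
    cross_cohort_de: dict[str, set[str]] = field(default_factory=dict)

    def summary_counts(self) -> dict:
        return {
            "drug_hg": {f"{c}|{s}": len(v) for (c, s), v in self.drug_hg.items()},
            "drug_ox": {f"{c}|{s}": len(v) for (c, s), v in self.drug_ox.items()},
            "drug_de": {f"{c}|{s}": len(v) for (c, s), v in self.drug_de.items()},
            "cross_cohort_hg": {s: len(v) for s, v in self.cross_cohort_hg.items()},
            "cross_cohort_ox": {s: len(v) for s, v in self.cross_cohort_ox.items()},
            "cross_cohort_de": {s: len(v) for s, v in self.cross_cohort_de.items()},
        }


def nominate_drug_sets(assoc: pd.DataFrame, alpha: float = 0.05) -> tuple[NominationSets, pd.DataFrame]:
    """BH-adjust per (cohort, source, score_type) family, then form
    Drug_HG / Drug_OX / Drug_DE sets and their cross-cohort intersections.

    Returns the sets and the association table with the ``fdr`` column filled.
    """
    assoc = assoc.copy()
    for _, idx in assoc.groupby(["cohort", "source", "score_type"]).groups.items():
        assoc.loc[idx, "fdr"] = bh_adjust(assoc.loc[idx, "p_value"].to_numpy())

    sets = NominationSets()
    cohorts = sorted(assoc["cohort"].unique())
    sources = sorted(assoc["source"].unique())
    for source in sources:
        for cohort in cohorts:
            sub = assoc[(assoc["cohort"] == cohort) & (assoc["source"] == source)]
            gly = sub[sub["score_type"] == "glycolysis"]
            oxp = sub[sub["score_type"] == "oxphos"]
            hg = set(gly.loc[(gly["beta1"] < 0) & (gly["fdr"] < alpha), "drug_id"])
            ox = set(oxp.loc[(oxp["beta1"] < 0) & (oxp["fdr"] < alpha), "drug_id"])
            sets.drug_hg[(cohort, source)] = hg
            sets.drug_ox[(cohort, source)] = ox
            sets.drug_de[(cohort, source)] = hg & ox
        per_cohort_hg = [sets.drug_hg[(c, source)] for c in cohorts]
        per_cohort_ox = [sets.drug_ox[(c, source)] for c in cohorts]
        per_cohort_de = [sets.drug_de[(c, source)] for c in cohorts]
        sets.cross_cohort_hg[source] = set.intersection(*per_cohort_hg) if per_cohort_hg else set()
        sets.cross_cohort_ox[source] = set.intersection(*per_cohort_ox) if per_cohort_ox else set()
        sets.cross_cohort_de[source] = set.intersection(*per_cohort_de) if per_cohort_de else set()
    return sets, assoc


def primary_moa_summary(
    cross_cohort_hg: set[str],
    metadata: pd.DataFrame,
    assoc: pd.DataFrame,
    score_type: str = "glycolysis",
) -> pd.DataFrame:
    """MOA counts among drugs in the top 50% most significant half of every
    cohort; MOAs appearing at least twice are flagged primary.
    """
    meta = metadata.set_index("drug_id")
    sub = assoc[(assoc["score_type"] == score_type) & assoc["drug_id"].isin(cross_cohort_hg)]
    halves = []
    for _, cohort_sub in sub.groupby("cohort"):
        ranked = cohort_sub.sort_values(["p_value", "drug_id"])
        k = int(np.ceil(len(ranked) / 2))
        halves.append(set(ranked["drug_id"].head(k)))
    survivors = set.intersection(*halves) if halves else set()
    moas = [
        meta.loc[d, "moa"] if d in meta.index and pd.notna(meta.loc[d, "moa"]) else "unknown"
        for d in sorted(survivors)
    ]
    counts = pd.Series(moas, dtype=object).value_counts()
    return pd.DataFrame(
        {"moa": counts.index, "count": counts.values, "primary": counts.values >= 2}
    ).reset_index(drop=True)


@dataclass
class FilterTrail:
    """Ordered record of the candidate cascade; survivor sets are nested."""

    filter_names: list[str] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)
    survivors: list[set[str]] = field(default_factory=list)

    @property
    def final(self) -> set[str]:
        return self.survivors[-1] if self.survivors else set()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _welch_increase_p(pre: np.ndarray, post: np.ndarray) -> float:
    """One-sided Welch p for mean(post) > mean(pre)."""
    res = stats.ttest_ind(post, pre, equal_var=False, alternative="greater")
    return float(res.pvalue)


def run_filter_cascade(
    candidates: set[str],
    metadata: pd.DataFrame,
    assoc: pd.DataFrame,
    ccl_expr: pd.DataFrame,
    ccl_measured: pd.DataFrame,
    perturb: PerturbationSet | None,
    gene_sets: GeneSetCollection,
    alpha: float = 0.05,
    enabled: tuple[bool, bool, bool, bool] = (True, True, True, True),
) -> FilterTrail:
    """Four-stage cascade:

    1. development status in {approved, clinical};
    2. no significantly opposing association (beta1 > 0 with FDR < alpha)
       in any (cohort, source, score) record;
    3. both CCL signature-score-on-measured-AUC slopes negative;
    4. no significant post-treatment increase of either signature score
       (one-sided Welch on replicate scores); drugs without perturbation
       data pass with reason "no data".
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    trail = FilterTrail()
    meta = metadata.set_index("drug_id")
    current = set(candidates)
    score_sets = GeneSetCollection(
        {k: v for k, v in gene_sets.sets.items() if k in ("glycolysis", "oxphos")}
    )

    def record(stage: str, drug: str, passed: bool, reason: str) -> None:
        trail.records.append(
            {"filter": stage, "drug_id": drug, "passed": passed, "reason": reason}
        )

    # -- filter 1: development status ------------------------------------
    if enabled[0]:
        stage = "development_status"
        trail.filter_names.append(stage)
        nxt = set()
        for drug in sorted(current):
            status = meta.loc[drug, "status"] if drug in meta.index else "unknown"
            ok = status in ("approved", "clinical")
            record(stage, drug, ok, f"status={status}")
            if ok:
                nxt.add(drug)
        current = nxt
        trail.survivors.append(set(current))

    # -- filter 2: cross-dataset consistency -----------------------------
    if enabled[1]:
        stage = "cross_dataset_consistency"
        trail.filter_names.append(stage)
        nxt = set()
        for drug in sorted(current):
            sub = assoc[assoc["drug_id"] == drug]
            opposing = sub[(sub["beta1"] > 0) & (sub["fdr"] < alpha)]
            ok = opposing.empty
            reason = "consistent" if ok else (
                "opposing association in "
                + ";".join(f"{r.cohort}|{r.source}|{r.score_type}" for r in opposing.itertuples())
            )
            record(stage, drug, ok, reason)
            if ok:
                nxt.add(drug)
        current = nxt
        trail.survivors.append(set(current))

    # -- filter 3: measured-response sign check in CCLs -------------------
    if enabled[2]:
        stage = "measured_response_sign"
        trail.filter_names.append(stage)
        ccl_scores = gsva_enrichment(ccl_expr, score_sets)
        nxt = set()
        for drug in sorted(current):
            if drug not in ccl_measured.columns:
                record(stage, drug, False, "no measured data")
                continue
            auc = ccl_measured[drug].dropna()
            shared = [s for s in auc.index if s in ccl_scores.scores.index]
            if len(shared) < 3:
                record(stage, drug, False, "no measured data")
                continue
            slopes = {}
            for sig in ("glycolysis", "oxphos"):
                y = ccl_scores.scores.loc[shared, sig]
                x = sm.add_constant(auc.loc[shared].rename("auc"))
                fit = sm.OLS(y, x).fit()
                slopes[sig] = fit.params["auc"]
            ok = all(v < 0 for v in slopes.values())
            record(
                stage, drug, ok,
                f"slope_gly={slopes['glycolysis']:.4g},slope_ox={slopes['oxphos']:.4g}",
            )
            if ok:
                nxt.add(drug)
        current = nxt
        trail.survivors.append(set(current))

    # -- filter 4: post-treatment metabolic activation --------------------
    if enabled[3]:
        stage = "perturbation_activation"
        trail.filter_names.append(stage)
        nxt = set()
        for drug in sorted(current):
            if perturb is None or drug not in perturb.profiles:
                record(stage, drug, True, "no data")
                nxt.add(drug)
                continue
            pre, post = perturb.profiles[drug]
            combined = pd.concat([pre, post], axis=1)
            rep_scores = gsva_enrichment(combined, score_sets).scores
            p_up = {}
            for sig in ("glycolysis", "oxphos"):
                p_up[sig] = _welch_increase_p(
                    rep_scores.loc[pre.columns, sig].to_numpy(),
                    rep_scores.loc[post.columns, sig].to_numpy(),
                )
            ok = all(p >= alpha for p in p_up.values())
            record(
                stage, drug, ok,
                f"p_gly_up={p_up['glycolysis']:.4g},p_ox_up={p_up['oxphos']:.4g}",
            )
            if ok:
                nxt.add(drug)
        current = nxt
        trail.survivors.append(set(current))

    return trail
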