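"""End-to-end orchestration: simulate -> overlap -> CTS -> differential binding
-> annotation -> DE -> integration, with a flat summary of counts,
percentages and p-values.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from ctsdimer.annotation import assign_peaks_to_genes, promoter_bound_flags
from ctsdimer.coverage_profiles import normalize_to_10M, occupancy_reduction
from ctsdimer.expression_integration import (
    differential_expression,
    fisher_association,
    gsea_lite,
    percent_lost,
)
from ctsdimer.motif_cts import classify_cts
from ctsdimer.peak_classes import (
    WT_EQ_CM,
    WT_GT_CM,
    WT_LT_CM,
    build_composite,
    categorize_differential,
    classify_overlap,
)
from ctsdimer.synthetic_data import SimulatedStudy, SimulationConfig, simulate_study


def run_study(config: SimulationConfig) -> tuple[SimulatedStudy, dict]:
    """Simulate a study and run the full analysis; returns (study, summary)."""
    study = simulate_study(config)
    summary = analyze_study(study, gsea_seed=config.seed)
    return study, summary


def analyze_study(study: SimulatedStudy, gsea_seed: int = 0) -> dict:
    """Run the complete binding + expression analysis of a simulated study."""
    wt_ctcf = study.peaks["wt_ctcf"]
    wt_boris = study.peaks["wt_boris"]
    cm_ctcf = study.peaks["cm_ctcf"]
    cov_wt = normalize_to_10M(study.coverage["wt"])
    cov_cm = normalize_to_10M(study.coverage["cm"])
    genes = study.genes

    summary: dict = {}

    # 1. co-occupancy classes (CTCF/BORIS vs CTCF-only vs BORIS-only)
    ov = classify_overlap(wt_ctcf, wt_boris)
    summary["overlap"] = ov.summary

    # 2. motif classification around summits of shared vs exclusive peaks
    shared_cts = classify_cts(ov.a_shared, study.genome, study.pwm)
    only_cts = classify_cts(ov.a_only, study.genome, study.pwm)
    frac2x = lambda cs: (
        sum(c.label == "2x_or_more" for c in cs) / len(cs) if cs else float("nan")
    )
    summary["cts"] = {
        "frac_2x_shared": frac2x(shared_cts),
        "frac_2x_ctcf_only": frac2x(only_cts),
    }

    # 3. composite differential-binding categories
    composite = build_composite(wt_ctcf, cm_ctcf)
    cat = categorize_differential(composite, cov_wt, cov_cm)
    counts = cat["label"].value_counts().to_dict()
    summary["differential"] = {
        "n_composite": len(composite),
        "n_wt_gt_cm": int(counts.get(WT_GT_CM, 0)),
        "n_wt_eq_cm": int(counts.get(WT_EQ_CM, 0)),
        "n_wt_lt_cm": int(counts.get(WT_LT_CM, 0)),
    }

    # 4. occupancy reduction at co-occupied vs CTCF-only site classes
    red_shared = occupancy_reduction(cov_wt, cov_cm, ov.a_shared)
    red_only = occupancy_reduction(cov_wt, cov_cm, ov.a_only)
    summary["reduction"] = {
        "ctcf_boris_pct": red_shared.mean_reduction_pct,
        "ctcf_boris_p": red_shared.rank_sum_p,
        "ctcf_only_pct": red_only.mean_reduction_pct,
        "ctcf_only_p": red_only.rank_sum_p,
    }

    # 5. differential expression (condition B = mutant vs A = wild type)
    de = differential_expression(study.counts)
    degs = set(de.index[de["deg"]])
    summary["de"] = {
        "n_deg": len(degs),
        "n_up": int((de["direction"] == "up").sum()),
        "n_down": int((de["direction"] == "down").sum()),
    }

    # 6. binding-expression integration
    all_wt_peaks = wt_ctcf + [p for p in wt_boris if p.name.startswith("boris")]
    gene_to_peaks, _ = assign_peaks_to_genes(all_wt_peaks, genes, flank=2000)
    bound = {g for g, ps in gene_to_peaks.items() if ps}
    universe = {g.gene_id for g in genes}
    assoc = fisher_association(degs, bound, universe) if degs else None
    summary["association"] = (
        {
            "bound_fraction_pct": assoc.bound_fraction_pct,
            "odds_ratio": assoc.odds_ratio,
            "exact_p": assoc.exact_p,
            "n_deg_bound": int(assoc.table[0, 0]),
        }
        if assoc
        else None
    )

    # 7. promoter-bound DEGs and loss of binding in the mutant
    wt_flags = promoter_bound_flags(wt_ctcf, genes, tss_flank=2000)
    cm_flags = promoter_bound_flags(cm_ctcf, genes, tss_flank=2000)
    bound_degs = {g for g in degs if wt_flags.get(g, False)}
    lost_degs = {g for g in bound_degs if not cm_flags.get(g, False)}
    summary["promoter"] = {
        "n_deg_promoter_bound": len(bound_degs),
        "pct_lost": percent_lost(bound_degs, lost_degs) if bound_degs else None,
    }

    # 8. gene-set enrichment on the t-statistic ranking
    summary["gsea"] = {}
    for gs in study.gene_sets:
        res = gsea_lite(de["t"], gs, n_perm=1000, seed=gsea_seed)
        summary["gsea"][gs.set_id] = {
            "es": res.es,
            "nes": res.nes,
            "perm_p": res.perm_p,
        }

    return summary


def recovery_metrics(study: SimulatedStudy, summary: Mapping | None = None) -> dict:
    """Compare pipeline output against the planted ground truth.

    Returns occupancy-reduction recovery per motif class, categorizer accuracy
    on truly twofold-reduced and unchanged sites, DE sensitivity/FDR, and the
    bound-DEG fraction.
    """
    cov_wt = normalize_to_10M(study.coverage["wt"])
    cov_cm = normalize_to_10M(study.coverage["cm"])
    truth_sites = study.truth.sites
    truth_genes = study.truth.genes
    wt_by_name = {p.name: p for p in study.peaks["wt_ctcf"]}

    out: dict = {}
    for cls in ("1x", "2x"):
        names = truth_sites.index[truth_sites["cls"] == cls]
        sites = [wt_by_name[n] for n in names]
        rep = occupancy_reduction(cov_wt, cov_cm, sites)
        out[f"reduction_{cls}_pct"] = rep.mean_reduction_pct
        out[f"reduction_{cls}_p"] = rep.rank_sum_p

    composite = build_composite(study.peaks["wt_ctcf"], study.peaks["cm_ctcf"])
    cat = categorize_differential(composite, cov_wt, cov_cm)
    # composite peaks keep planted names only when unmerged; map by summit overlap
    label_of_site: dict[str, str] = {}
    by_pos = {(p.chrom, p.summit): p.name for p in composite}
    for name, p in wt_by_name.items():
        comp_name = by_pos.get((p.chrom, p.summit))
        if comp_name is not None:
            label_of_site[name] = cat.loc[comp_name, "label"]

    twofold = truth_sites[
        (truth_sites["cls"] == "2x")
        & (truth_sites["amplitude"] > 2.0 * truth_sites["cm_amplitude"])
    ]
    labels = [label_of_site[n] for n in twofold.index if n in label_of_site]
    out["frac_twofold_reduced_wt_gt_cm"] = (
        float(np.mean([l == WT_GT_CM for l in labels])) if labels else float("nan")
    )
    decoys = truth_sites.index[truth_sites["cls"] == "decoy"]
    dlabels = [label_of_site[n] for n in decoys if n in label_of_site]
    out["frac_decoy_wt_eq_cm"] = (
        float(np.mean([l == WT_EQ_CM for l in dlabels])) if dlabels else float("nan")
    )

    de = differential_expression(study.counts)
    called = set(de.index[de["deg"]])
    true_degs = set(truth_genes.index[truth_genes["true_deg"]])
    tp = len(called & true_degs)
    out["de_sensitivity"] = tp / len(true_degs) if true_degs else float("nan")
    out["de_fdr"] = (len(called) - tp) / len(called) if called else 0.0
    out["n_deg_called"] = len(called)

    return out
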