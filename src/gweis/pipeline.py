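"""End-to-end synthetic study: simulate -> scan -> score -> evaluate.

One seeded configuration produces a cohort, splits it into discovery and
target halves, runs the additive GWAS and the robust GWEIS on discovery,
builds clumped + thresholded polygenic scores under the three weighting
schemes, scores the target half, and evaluates incremental prediction —
including the joint-versus-combined comparison: because scoring is linear,
a joint-weighted score built on a SNP set equals the sum of the additive-
and interaction-weighted scores on that same set, so the model with
PRS_joint is the equal-coefficient constraint of the model with both
components and the two can be compared by an exact nested LRT.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import GwasScan, GweisScan, genomic_inflation
from .evaluate import ModelComparison, fit_comparison, improvement_report, permutation_empirical_p
from .panel import GenotypePanel
from .prs import PrsScorer, build_weights, clump, score
from .simulate import (
    SimConfig,
    simulate_covariates,
    simulate_exposure,
    simulate_genotypes,
    simulate_phenotype,
    write_fixture,
)

log = logging.getLogger("gweis")

_ALLOWED_TOP = {"seed", "out_prefix", "simulate", "gweis", "prs", "evaluate", "log_level"}
_ALLOWED_GWEIS = {"robust_variant", "standardize", "add_covariate_interactions"}
_ALLOWED_PRS = {"p_threshold", "clump_r2", "clump_window_kb", "clump_p1"}
_ALLOWED_EVAL = {"n_perm", "discovery_fraction"}


def validate_config(config: dict) -> dict:
    """Reject unknown keys; fill defaults; return a normalised config dict."""
    unknown = set(config) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_kwargs = dict(config.get("simulate", {}))
    valid_sim = set(SimConfig.__dataclass_fields__)
    unknown = set(sim_kwargs) - valid_sim
    if unknown:
        raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
    if "maf_range" in sim_kwargs:
        sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
    for block, allowed in (("gweis", _ALLOWED_GWEIS), ("prs", _ALLOWED_PRS), ("evaluate", _ALLOWED_EVAL)):
        unknown = set(config.get(block, {})) - allowed
        if unknown:
            raise ValueError(f"unknown {block} keys: {sorted(unknown)}")
    return {
        "seed": int(config.get("seed", 0)),
        "out_prefix": str(config.get("out_prefix", "gweis_run")),
        "simulate": sim_kwargs,
        "gweis": dict(config.get("gweis", {})),
        "prs": dict(config.get("prs", {})),
        "evaluate": {
            "n_perm": int(config.get("evaluate", {}).get("n_perm", 0)),
            "discovery_fraction": float(config.get("evaluate", {}).get("discovery_fraction", 0.5)),
        },
    }


def split_panel(panel: GenotypePanel, n_first: int):
    idx = np.arange(panel.n_samples)
    return panel.subset_samples(idx[:n_first]), panel.subset_samples(idx[n_first:])


def joint_vs_combined(
    gweis_results: pd.DataFrame,
    reference: GenotypePanel,
    target: GenotypePanel,
    phenotype,
    covariates=None,
    p_threshold: float = 1.0,
    clump_r2: float = 0.1,
    clump_window_kb: float = 250.0,
) -> ModelComparison:
    """LRT of (PRS_D + PRS_GxE) against PRS_joint on the joint-selected SNP set.

    All three scores are built on the SNP set clumped and thresholded by
    the 2-df joint p-value, which makes PRS_joint = PRS_D + PRS_GxE hold
    exactly and the comparison a 1-df nested LRT.
    """
    kept = clump(
        gweis_results, reference, r2_threshold=clump_r2,
        window_kb=clump_window_kb, p_col="P_JOINT",
    )
    records = gweis_results[gweis_results["SNP"].isin(kept)]
    w_joint = build_weights(records, "joint")
    w_d = build_weights(records.assign(BETA=records["BETA_G"], P=records["P_JOINT"]), "additive")
    w_gxe = build_weights(records.assign(P_GXE=records["P_JOINT"]), "gxe")

    s_joint = score(target, w_joint, p_threshold)["SCORE"].to_numpy()
    s_d = score(target, w_d, p_threshold)["SCORE"].to_numpy()
    s_gxe = score(target, w_gxe, p_threshold)["SCORE"].to_numpy()

    return fit_comparison(
        phenotype,
        pd.DataFrame({"PRS_joint": s_joint}),
        pd.DataFrame({"PRS_D": s_d, "PRS_GxE": s_gxe}),
        covariates=covariates,
        trait_id="joint_vs_combined",
    )


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the full synthetic study; write all declared outputs; return results."""
    cfg = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / cfg["out_prefix"]

    sim = SimConfig(seed=cfg["seed"], **cfg["simulate"])
    panel = simulate_genotypes(sim)
    exposure = simulate_exposure(panel, sim)
    covariates = simulate_covariates(sim)
    truth = simulate_phenotype(panel, exposure.counts, covariates, sim)
    write_fixture(panel, exposure.counts, truth.y, covariates, prefix)

    n_disc = int(round(cfg["evaluate"]["discovery_fraction"] * sim.n_samples))
    disc, targ = split_panel(panel, n_disc)
    e_disc, e_targ = exposure.counts[:n_disc], exposure.counts[n_disc:]
    y_disc, y_targ = truth.y[:n_disc], truth.y[n_disc:]
    c_disc, c_targ = covariates.iloc[:n_disc], covariates.iloc[n_disc:].reset_index(drop=True)

    gwas = GwasScan().fit(disc, y_disc, c_disc).results_
    gweis = GweisScan(**cfg["gweis"]).fit(disc, y_disc, e_disc, c_disc).results_
    gwas.to_csv(f"{prefix}.gwas.tsv", sep="\t", index=False, float_format="%.6g")
    gweis.to_csv(f"{prefix}.gweis.tsv", sep="\t", index=False, float_format="%.6g")

    inflation = {
        "gwas": vars(genomic_inflation(gwas["P"].dropna(), n=disc.n_samples)),
        "gweis_gxe": vars(genomic_inflation(gweis["P_GXE"].dropna(), n=disc.n_samples)),
        "gweis_joint": vars(genomic_inflation(gweis["P_JOINT"].dropna(), n=disc.n_samples)),
    }

    prs_cfg = cfg["prs"]
    thr = prs_cfg.get("p_threshold", 1.0)
    scorer_kwargs = dict(
        p_threshold=thr,
        clump_r2=prs_cfg.get("clump_r2", 0.1),
        clump_window_kb=prs_cfg.get("clump_window_kb", 250.0),
        clump_p1=prs_cfg.get("clump_p1", 1.0),
    )
    profiles = {}
    for scheme, sumstats in (("additive", gwas), ("gxe", gweis), ("joint", gweis)):
        scorer = PrsScorer(scheme=scheme, **scorer_kwargs).fit(sumstats, reference=disc)
        scorer.weights_.to_csv(
            f"{prefix}.weights_{scheme}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        prof = scorer.transform(targ)
        prof.to_csv(f"{prefix}.profile_{scheme}.tsv", sep="\t", index=False, float_format="%.6g")
        profiles[scheme] = prof["SCORE"].to_numpy()

    comparisons = [
        fit_comparison(
            y_targ,
            pd.DataFrame({"PRS_D": profiles["additive"]}),
            pd.DataFrame({"PRS_D": profiles["additive"], "PRS_GxE": profiles["gxe"]}),
            covariates=c_targ,
            trait_id="combined_over_additive",
        ),
        joint_vs_combined(
            gweis, disc, targ, y_targ, covariates=c_targ,
            p_threshold=thr,
            clump_r2=scorer_kwargs["clump_r2"],
            clump_window_kb=scorer_kwargs["clump_window_kb"],
        ),
    ]
    n_perm = cfg["evaluate"]["n_perm"]
    if n_perm >= 100:
        for comp, scheme in zip(comparisons, ("gxe", "joint")):
            comp.empirical_p = permutation_empirical_p(
                y_targ, profiles[scheme], covariates=c_targ, n_perm=n_perm, seed=cfg["seed"]
            )
    report = improvement_report(comparisons)
    report.to_csv(f"{prefix}.comparisons.csv", index=False, float_format="%.6g")

    provenance = {
        "package": "gweis",
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg["seed"],
        "config": {**cfg, "simulate": asdict(sim)},
        "inflation": inflation,
    }
    with open(f"{prefix}.provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)

    return {
        "prefix": prefix,
        "gwas": gwas,
        "gweis": gweis,
        "profiles": profiles,
        "comparisons": comparisons,
        "report": report,
        "inflation": inflation,
        "truth": truth,
    }
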