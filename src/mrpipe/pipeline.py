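"""End-to-end analysis orchestration from a single YAML config.

Runs the full design: per blood-pressure exposure, instrument selection →
harmonization → all causal estimators → heterogeneity/pleiotropy
diagnostics → multivariable MR across exposures; and per antihypertensive
drug class × LD threshold, proxy selection → harmonization → estimators
scaled per 10 mmHg SBP decrease → diagnostics. Every threshold lives in the
config with the standard values as defaults, every random step is seeded,
and re-running a config+seed reproduces the report byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import drug_targets, mvmr, selection, sensitivity
from .estimators import estimate_all, significance_threshold
from .harmonize import harmonize
from .io import (
    ConfounderTable,
    read_confounder_table,
    read_gene_regions,
    read_ld_reference,
    read_summary_stats,
)

logger = logging.getLogger("mrpipe")

#: default analysis thresholds (the standard conventions for each stage)
DEFAULT_THRESHOLDS = {
    "p_gws": 5e-8,
    "clump_kb": 10_000,
    "clump_r2": 0.001,
    "drug_r2": [0.4, 0.2],
    "f_min": 10.0,
    "af_window": 0.08,
}


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(cfg.get("thresholds", {}))
    cfg["thresholds"] = thresholds
    cfg.setdefault("n_boot", 1000)
    cfg.setdefault("presso_nsim", 1000)
    cfg.setdefault("seed", 0)
    return cfg


def _child_seed(seed: int, *tags: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = int(seed)
    for tag in tags:
        for ch in tag:
            h = (h * 1000003 + ord(ch)) & 0xFFFFFFFFFFFF
    return h % (2**31 - 1)


def _diagnostics(instruments, presso_nsim: int, seed: int) -> dict:
    out: dict = {"n_snps": len(instruments)}
    if len(instruments) >= 2:
        q = sensitivity.cochran_q(instruments, "ivw")
        out["q_ivw"] = {"q": q.q, "df": q.df, "pval": q.pval}
    if len(instruments) >= 3:
        q = sensitivity.cochran_q(instruments, "egger")
        out["q_egger"] = {"q": q.q, "df": q.df, "pval": q.pval}
        icpt = sensitivity.egger_intercept_test(instruments)
        out["egger_intercept"] = {"intercept": icpt.intercept, "se": icpt.se, "pval": icpt.pval}
    if len(instruments) >= 4:
        pr = sensitivity.mr_presso(instruments, n_sim=presso_nsim, seed=seed)
        out["presso"] = {
            "global_pval": pr.global_rss_pval,
            "n_outliers": len(pr.outlier_indices),
            "outlier_snps": instruments.data["snp_id"].iloc[pr.outlier_indices].tolist(),
            "distortion_pval": pr.distortion_pval,
            "estimate_after_outlier_removal": (
                pr.estimate_after.as_dict() if pr.estimate_after else None
            ),
        }
    return out


def run_bp_analysis(config: dict) -> dict:
    """The blood-pressure arm: univariable MR per exposure plus joint MVMR."""
    th = config["thresholds"]
    seed = config["seed"]
    ld = read_ld_reference(config["ld"]["pairs"], config["ld"].get("variants"))
    confounders = (
        read_confounder_table(config["confounder_table"])
        if config.get("confounder_table")
        else ConfounderTable.empty()
    )
    out_cfg = config["outcome"]
    outcome = read_summary_stats(
        out_cfg["stats"],
        dialect=out_cfg.get("dialect"),
        trait_label=out_cfg.get("label", "outcome"),
        trait_sd=out_cfg.get("trait_sd", 1.0),
    )

    exposures = config["exposures"]
    alpha = significance_threshold(len(exposures))
    report: dict = {"analysis": "blood_pressure", "alpha": alpha, "exposures": {}}
    full_sets, instrument_ids, scale_factors = {}, {}, {}

    for label, ecfg in exposures.items():
        stats = read_summary_stats(
            ecfg["stats"], dialect=ecfg.get("dialect"), trait_label=label, trait_sd=ecfg["trait_sd"]
        )
        full_sets[label] = stats
        scale = float(ecfg.get("scale_mmhg", 10))
        scale_factors[label] = scale
        selected, sel_report = selection.select_instruments(
            stats, ld, confounders,
            p_thresh=th["p_gws"], window_kb=th["clump_kb"], r2_max=th["clump_r2"], f_min=th["f_min"],
        )
        instruments = harmonize(selected, outcome, af_window=th["af_window"])
        instrument_ids[label] = instruments.data["snp_id"].tolist()
        r2_sum = float(
            np.sum(
                selection.variance_explained(
                    instruments.beta_exp, instruments.data["eaf_exp"].to_numpy(), stats.trait_sd
                )
            )
        ) if len(instruments) else 0.0
        ests = estimate_all(
            instruments, scale_factor=scale,
            n_boot=config["n_boot"], seed=_child_seed(seed, label, "boot"),
        )
        block = {
            "scale_mmhg": scale,
            "selection": {
                "stage_counts": sel_report.stage_counts,
                "exclusions": [list(e) for e in sel_report.exclusions],
            },
            "harmonization": {
                "n_intersection": instruments.audit.n_intersection,
                "n_retained": instruments.audit.n_retained,
                "n_palindromic_dropped": instruments.audit.n_palindromic_dropped,
                "n_irreconcilable": instruments.audit.n_irreconcilable,
            },
            "variance_explained": r2_sum,
            "estimates": [e.as_dict() for e in ests],
            "diagnostics": _diagnostics(instruments, config["presso_nsim"], _child_seed(seed, label, "presso")),
        }
        ivw_row = next((e for e in ests if e.method == "ivw"), ests[0])
        block["significant_at_alpha"] = bool(ivw_row.pval < alpha)
        report["exposures"][label] = block

    if len(exposures) >= 2:
        union = sorted(set().union(*instrument_ids.values()))
        multi = mvmr.build_multi_set(
            list(full_sets.values()), outcome, instrument_ids=union, af_window=th["af_window"]
        )
        mv_ests = mvmr.mvmr_ivw(multi, scale_factors=scale_factors)
        report["mvmr"] = {
            "n_snps": len(multi),
            "estimates": [e.as_dict() for e in mv_ests],
            "conditional_f": mvmr.conditional_f(multi),
        }
    return report


def run_drug_analysis(config: dict) -> dict:
    """The drug-target arm: ACEI/BB/CCB proxies at both LD thresholds."""
    th = config["thresholds"]
    seed = config["seed"]
    ld = read_ld_reference(config["ld"]["pairs"], config["ld"].get("variants"))
    regions = read_gene_regions(config["regions"])
    out_cfg = config["outcome"]
    outcome = read_summary_stats(
        out_cfg["stats"], dialect=out_cfg.get("dialect"),
        trait_label=out_cfg.get("label", "outcome"), trait_sd=out_cfg.get("trait_sd", 1.0),
    )
    ecfg = config["exposures"]["SBP"] if "SBP" in config.get("exposures", {}) else list(config["exposures"].values())[0]
    sbp = read_summary_stats(ecfg["stats"], dialect=ecfg.get("dialect"), trait_label="SBP", trait_sd=ecfg["trait_sd"])

    classes = sorted({r.drug_class for r in regions})
    alpha = significance_threshold(len(classes) if classes else 1)
    report: dict = {"analysis": "drug_target", "alpha": alpha, "classes": {}}
    for klass in classes:
        report["classes"][klass] = {}
        for r2_max in th["drug_r2"]:
            proxies = drug_targets.select_drug_instruments(
                sbp, regions, klass, ld, p_thresh=th["p_gws"], r2_max=r2_max
            )
            key = f"r2<{r2_max}"
            if len(proxies) == 0:
                report["classes"][klass][key] = {"n_proxies": 0, "warning": "no significant variant in target regions"}
                continue
            instruments = harmonize(proxies, outcome, af_window=th["af_window"])
            if len(instruments) == 0:
                report["classes"][klass][key] = {"n_proxies": 0, "warning": "no proxy survived harmonization"}
                continue
            ests = estimate_all(
                instruments, scale_factor=drug_targets.DRUG_SCALE_FACTOR,
                n_boot=config["n_boot"], seed=_child_seed(seed, klass, key, "boot"),
            )
            ivw_row = next((e for e in ests if e.method == "ivw"), ests[0])
            max_r2 = 0.0
            ids = instruments.data["snp_id"].tolist()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    max_r2 = max(max_r2, ld.r2(ids[i], ids[j]))
            report["classes"][klass][key] = {
                "n_proxies": len(instruments),
                "max_pairwise_r2": max_r2,
                "estimates": [e.as_dict() for e in ests],
                "diagnostics": _diagnostics(instruments, config["presso_nsim"], _child_seed(seed, klass, key, "presso")),
                "significant_at_alpha": bool(ivw_row.pval < alpha),
                "single_proxy_wald_fallback": len(instruments) == 1,
            }
    return report


def run_all(config: dict) -> dict:
    report = {"seed": config["seed"], "thresholds": config["thresholds"]}
    report["blood_pressure"] = run_bp_analysis(config)
    if config.get("regions"):
        report["drug_target"] = run_drug_analysis(config)
    return report


def report_estimate_table(report: dict) -> pd.DataFrame:
    """Flatten all estimate rows into one table (the text form of the
    forest-plot figures)."""
    rows = []
    bp = report.get("blood_pressure", report)
    for label, block in bp.get("exposures", {}).items():
        for e in block.get("estimates", []):
            rows.append({"analysis": "bp", "group": label, **e})
    for e in bp.get("mvmr", {}).get("estimates", []):
        rows.append({"analysis": "mvmr", "group": e["method"], **e})
    for klass, thr in report.get("drug_target", {}).get("classes", {}).items():
        for key, block in thr.items():
            for e in block.get("estimates", []):
                rows.append({"analysis": f"drug {key}", "group": klass, **e})
    return pd.DataFrame(rows)


def write_report(report: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    table = report_estimate_table(report)
    table.to_csv(out_dir / "report.tsv", sep="\t", index=False)
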