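"""End-to-end workflow: filter -> 1D scan -> CV -> 2D scan -> SWVg ->
consensus K-means -> signature.

Every stage writes its artifact (TSV or JSON) into the output directory as
soon as it completes, so a failing stage leaves all upstream results on
disk; the machine-readable ``summary.json`` lists the counts at each
stage.  All randomness derives from the single mandatory ``seed``, and a
re-run with the same configuration produces byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as consensus_mod
from . import core_data, ddss, preprocess, signature as signature_mod, swvg
from .errors import ConfigError
from .synthetic import default_truth, generate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int | None = None
    out_dir: str = "survstrat-out"
    # inputs: either a synthetic cohort or a pair of TSV paths
    synthetic: bool = True
    n_samples: int = 486  # synthetic cohort size
    expression_path: str | None = None
    clinical_path: str | None = None
    # preprocessing
    min_expr: float = 4.1
    min_variance: float = 0.0
    mixture_subsample: int = 5000
    # scans
    min_group_frac: float = 0.10
    top_n: int = 100
    p_max: float = 0.05
    cv_repeats: int = 10
    cv_folds: int = 10
    pair_top: int = 100
    n_quantiles: int = 49
    pair_refine: int = 128
    synergy_p: float = 0.05
    min_pairs: int = 50
    # grouping acceptance thresholds
    logrank_threshold: float = 0.005
    pairwise_threshold: float = 0.05
    # consensus clustering
    kmeans_runs: int = 1000
    kmeans_k: int = 2
    feature_threshold: float = 0.90

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory (stochastic stages enabled)")
        if not self.synthetic and not (self.expression_path and self.clinical_path):
            raise ConfigError("non-synthetic runs need expression_path and clinical_path")
        if not 0 < self.min_group_frac < 0.5:
            raise ConfigError("min_group_frac must lie in (0, 0.5)")
        for name in ("p_max", "synergy_p", "logrank_threshold", "pairwise_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must lie in (0, 1]")
        for name in ("top_n", "cv_repeats", "cv_folds", "pair_top",
                     "n_quantiles", "kmeans_runs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": 1, "seed": config.seed, "stages": {}}
    _write_json({k: v for k, v in asdict(config).items()}, out / "run_config.json")

    def stage(name):
        log.info("stage %s ...", name)
        return _StageTimer(name, summary)

    # ------------------------------------------------------------------ input
    with stage("input"):
        if config.synthetic:
            truth = default_truth(seed=config.seed)
            truth.n_samples = config.n_samples
            expr, surv, record = generate(truth)
            core_data.write_expression(expr, out / "expression.tsv")
            core_data.write_clinical(surv, out / "clinical.tsv")
            _write_json(record, out / "truth.json")
        else:
            expr = core_data.read_expression(config.expression_path)
            surv = core_data.read_clinical(config.clinical_path)
        expr, surv, discarded = core_data.align(expr, surv)
        summary["stages"]["input"] = {
            "n_features": expr.n_features,
            "n_samples": expr.n_samples,
            "n_discarded_samples": discarded,
            "n_excluded_no_followup": surv.n_excluded,
            "event_fraction": float(np.mean(surv.event)),
        }

    # ---------------------------------------------------------------- mixture
    with stage("mixture"):
        pool = expr.values.ravel()
        rng = np.random.default_rng(config.seed + 1)
        if pool.size > config.mixture_subsample:
            pool = rng.choice(pool, config.mixture_subsample, replace=False)
        mix = preprocess.fit_noise_mixture(pool, seed=config.seed + 1)
        mix_doc = {
            "schema_version": 1,
            "signal_cutoff": mix.signal_cutoff,
            "precision_at_cutoff": mix.precision_at_cutoff,
            "signal_weight": mix.signal_weight,
            "noise_rate": mix.noise_rate,
            "gpd_location": mix.gpd_location,
            "gpd_scale": mix.gpd_scale,
            "gpd_shape": mix.gpd_shape,
            "degenerate": mix.degenerate,
        }
        _write_json(mix_doc, out / "mixture.json")
        summary["stages"]["mixture"] = {
            "signal_cutoff": mix.signal_cutoff,
            "precision_at_cutoff": mix.precision_at_cutoff,
            "signal_weight": mix.signal_weight,
        }

    # ----------------------------------------------------------------- filter
    with stage("filter"):
        filtered = preprocess.filter_features(expr, config.min_expr,
                                              config.min_variance)
        core_data.write_expression(filtered, out / "filtered_expression.tsv")
        summary["stages"]["filter"] = {
            "kept": filtered.n_features,
            "removed": expr.n_features - filtered.n_features,
            "min_expr": config.min_expr,
        }

    # ----------------------------------------------------------------- ddss1d
    with stage("ddss1d"):
        models = {}
        rows = []
        for fid in filtered.feature_ids:
            try:
                m = ddss.scan_1d(filtered.feature(fid), surv,
                                 config.min_group_frac, feature_id=fid,
                                 keep_profile=False)
            except Exception as e:  # feature unusable for a scan
                log.info("ddss1d: %s skipped (%s)", fid, e)
                continue
            models[fid] = m
            rows.append({
                "feature_id": fid, "cutoff": m.cutoff, "p": m.wald.p,
                "hr": m.wald.hr, "phenotype": m.phenotype,
                "n_low": m.n_low, "n_high": m.n_high,
            })
        ddss1d_df = pd.DataFrame(rows)
        ddss1d_df.to_csv(out / "ddss1d.tsv", sep="\t", index=False)
        top_set = signature_mod.rank_top(models.values(), config.top_n,
                                         config.p_max)
        summary["stages"]["ddss1d"] = {
            "fitted": len(models),
            "top_set": len(top_set),
            "pro_oncogenic": int(sum(m.phenotype == ddss.PRO_ONCOGENIC
                                     for m in models.values())),
            "tumor_suppressor_like": int(sum(m.phenotype == ddss.TUMOR_SUPPRESSOR
                                             for m in models.values())),
        }

    # --------------------------------------------------------------------- cv
    with stage("cv"):
        cv_rows = []
        for i, fid in enumerate(top_set):
            res = swvg.cv_stability(
                filtered.feature(fid), surv, repeats=config.cv_repeats,
                folds=config.cv_folds, seed=config.seed + 2 + i,
                min_group_frac=config.min_group_frac, feature_id=fid,
            )
            cv_rows.append({
                "feature_id": fid, "confidence": res.confidence,
                "cutoff_cv_pct": res.cutoff_cv,
                "pass_confidence": res.pass_confidence,
                "pass_cutoff_cv": res.pass_cutoff_cv,
            })
        cv_df = pd.DataFrame(cv_rows)
        cv_df.to_csv(out / "cv_stability.tsv", sep="\t", index=False)
        cv_set = [r["feature_id"] for r in cv_rows if r["pass_confidence"]]
        summary["stages"]["cv"] = {
            "evaluated": len(cv_rows),
            "pass_confidence": len(cv_set),
            "pass_both": int(sum(r["pass_confidence"] and r["pass_cutoff_cv"]
                                 for r in cv_rows)),
        }

    # ----------------------------------------------------------------- ddss2d
    with stage("ddss2d"):
        pair_universe = top_set[: config.pair_top]
        scanner = ddss.PairScanner(surv, config.min_group_frac,
                                   config.n_quantiles, config.pair_refine,
                                   keep_grouping=False)
        for fid in pair_universe:
            scanner.add_feature(fid, filtered.feature(fid))
        pair_models = []
        prow = []
        for i, f1 in enumerate(pair_universe):
            for f2 in pair_universe[i + 1:]:
                pm = scanner.scan(f1, f2)
                pair_models.append(pm)
                prow.append({
                    "feature_a": f1, "feature_b": f2,
                    "cutoff_a": pm.cutoffs[0], "cutoff_b": pm.cutoffs[1],
                    "design_id": pm.design.id, "p": pm.wald.p,
                    "synergistic": pm.synergistic,
                })
        pd.DataFrame(prow).to_csv(out / "pairs.tsv", sep="\t", index=False)
        syn_counts = ddss.synergy_frequency(pair_models, config.synergy_p)
        pd.DataFrame(sorted(syn_counts.items()),
                     columns=["feature_id", "synergistic_pairs"]).to_csv(
            out / "synergy.tsv", sep="\t", index=False)
        synergy_set = [f for f in pair_universe
                       if syn_counts.get(f, 0) >= config.min_pairs]
        summary["stages"]["ddss2d"] = {
            "pairs": len(pair_models),
            "pairs_p01": int(sum(pm.wald.p < 0.01 for pm in pair_models)),
            "synergistic_pairs": int(sum(
                pm.synergistic and pm.wald.p < config.synergy_p
                for pm in pair_models)),
            "synergy_set": len(synergy_set),
        }

    # ------------------------------------------------------------------- swvg
    with stage("swvg"):
        top_models = [models[f] for f in top_set]
        vm2 = swvg.select(top_models, surv, k=2,
                          min_group_frac=config.min_group_frac)
        _write_json(vm2.to_dict(), out / "swvg_k2.json")
        try:
            vm3 = swvg.select(top_models, surv, k=3,
                              min_group_frac=config.min_group_frac)
            _write_json(vm3.to_dict(), out / "swvg_k3.json")
            k3 = {"selected": len(vm3.selected_features),
                  "logrank_p": vm3.overall_logrank_p}
        except Exception as e:
            vm3 = None
            k3 = {"error": str(e)}
        summary["stages"]["swvg"] = {
            "k2_selected": len(vm2.selected_features),
            "k2_logrank_p": vm2.overall_logrank_p,
            "k3": k3,
        }

    # ----------------------------------------------------------------- kmeans
    with stage("kmeans"):
        cons = consensus_mod.robust_kmeans(
            filtered, k=config.kmeans_k, runs=config.kmeans_runs,
            feature_threshold=config.feature_threshold, seed=config.seed + 3,
        )
        cores_p = None
        n_differential = None
        try:
            _, cores_p = consensus_mod.compare_cores(cons, surv)
            grouping = consensus_mod.cores_to_grouping(cons, surv)
            core_ids = [s for s in filtered.sample_ids if s in grouping.labels]
            de = preprocess.differential_features(
                filtered.subset_samples(core_ids), grouping)
            de.to_frame().to_csv(out / "core_differential.tsv", sep="\t",
                                 index=False)
            n_differential = int(de.passes.sum())
        except Exception as e:
            log.info("kmeans: core comparison unavailable (%s)", e)
        cons_doc = {
            "schema_version": 1,
            "runs_completed": cons.runs,
            "core_sizes": [len(c) for c in cons.robust_sample_cores],
            "core_fraction": cons.core_fraction,
            "feature_cluster_sizes": [len(c) for c in cons.robust_feature_clusters],
            "cores": cons.robust_sample_cores[:2],
            "logrank_p_two_cores": cores_p,
        }
        _write_json(cons_doc, out / "consensus.json")
        summary["stages"]["kmeans"] = {
            "runs_completed": cons.runs,
            "core_fraction": cons.core_fraction,
            "n_cores": len(cons.robust_sample_cores),
            "logrank_p_two_cores": cores_p,
            "core_differential_features": n_differential,
        }

    # -------------------------------------------------------------- signature
    with stage("signature"):
        sig = signature_mod.intersect_signature(top_set, cv_set, synergy_set)
        sig_summary = {"members": len(sig.member_features)}
        if len(sig.member_features) >= 2:
            sig_models = [models[f] for f in sig.member_features]
            try:
                svm = swvg.select(sig_models, surv, k=3,
                                  min_group_frac=config.min_group_frac)
            except Exception:
                svm = swvg.select(sig_models, surv, k=2,
                                  min_group_frac=config.min_group_frac)
            sig.grouping = svm.grouping
            sig_summary["k"] = svm.k
            sig_summary["logrank_p"] = svm.overall_logrank_p
            _write_json(svm.to_dict(), out / "signature_voting.json")
            if surv.clinical is not None and not surv.clinical.empty:
                assoc = signature_mod.associate_clinical(svm.grouping,
                                                         surv.clinical)
                assoc.to_csv(out / "clinical_association.tsv", sep="\t",
                             index=False)
                sig_summary["clinical"] = {
                    r["category"]: r["chi2_p"] for _, r in assoc.iterrows()
                }
        _write_json(sig.to_dict(), out / "signature.json")
        summary["stages"]["signature"] = sig_summary

    _write_json(summary, out / "summary.json")
    return summary


class _StageTimer:
    def __init__(self, name, summary):
        self.name = name
        self.summary = summary

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s done in %.1fs", self.name, dt)
        else:
            log.error("stage %s FAILED after %.1fs: %s", self.name, dt, exc)
            self.summary["failed_stage"] = self.name
        return False
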