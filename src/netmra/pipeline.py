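"""End-to-end orchestration of the master-regulator workflow.

One JSON config drives: network inference on two disease cohorts (plus an
optional control-tissue cohort), the differential-expression signature,
master regulator analysis of each network, the cross-network consensus
with control-tissue and proliferation specificity filters, the
cross-network regulon overlap table, and — when sequence/motif or survival
inputs are supplied — motif enrichment and survival analysis for every
surviving master regulator.

One global seed deterministically derives a seed per stage (by hashing the
stage name), so any stage can be re-run in isolation and reproduce its
part of the bundle exactly. The bundle checksum covers everything except
wall-clock metadata: identical config + seed means identical checksum.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from . import io as nio
from .core import GeneSet, ValidationError
from .mra import (
    consensus_mrs,
    mra_enrichment,
    regulon_overlap_table,
    results_to_frame,
    significant_mrs,
    specificity_filter,
)
from .motif import (
    background_from_sequences,
    build_pwm,
    genes_with_motif,
    resampling_enrichment,
    score_threshold_from_pvalue,
)
from .network import extract_regulons, infer_network
from .signature import compute_de_signature
from .survival import cox_fit, km_estimate, optimal_cutoff_scan

logger = logging.getLogger("netmra")

DEFAULT_PARAMS = {
    "alpha": 0.05,
    "n_perm": 1000,
    "bins": None,
    "dpi_epsilon": 0.0,
    "signature_alpha": 0.05,
    "lfc_min": 1.0,
    "mra_alpha": 0.05,
    "min_regulon_size": 1,
    "scan_p": 1e-4,
    "pseudocount": 0.1,
    "motif_n_samples": 100_000,
    "cutoff_n_permutations": 1000,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2**31)."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, set):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "to_dict") and not isinstance(obj, (str, bytes)):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def bundle_checksum(bundle: dict) -> str:
    """SHA-256 over the canonical JSON of the bundle, excluding wall-clock
    metadata, so re-runs can be compared byte-for-byte."""
    payload = {k: v for k, v in bundle.items() if k != "meta"}
    if "meta" in bundle:
        meta = {k: v for k, v in bundle["meta"].items() if k != "timestamp"}
        payload["meta"] = meta
    blob = json.dumps(_jsonable(payload), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def validate_config(config: dict) -> dict:
    cfg = dict(config)
    if "seed" not in cfg:
        raise ValidationError("pipeline config needs a global 'seed'")
    required = ["expr_disease_a", "expr_disease_b", "tf_list"]
    for key in required:
        if key not in cfg:
            raise ValidationError(f"pipeline config missing required key {key!r}")
    has_contrast = "contrast_a" in cfg and "contrast_b" in cfg
    if not has_contrast and "signature_gmt" not in cfg:
        raise ValidationError("need either contrast_a/contrast_b or signature_gmt")
    for key, value in cfg.items():
        if key.startswith(("expr_", "contrast_", "signature_", "proliferation_")) or key in (
            "tf_list", "pfm", "flanks_fasta"
        ):
            if value is not None and not Path(value).exists():
                raise ValidationError(f"config path {key} = {value!r} does not exist")
    for t in cfg.get("survival_tables", []):
        if not Path(t).exists():
            raise ValidationError(f"survival table {t!r} does not exist")
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    cfg["params"] = params
    return cfg


def run_full_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the full workflow and persist every stage output under
    ``out_dir``. Returns the results bundle (also written as bundle.json).
    Any stage failure aborts with the stage name; outputs of completed
    stages remain on disk."""
    cfg = validate_config(config)
    params = cfg["params"]
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "config"
    try:
        tf_list = nio.read_gene_list(cfg["tf_list"])

        stage = "network_inference"
        networks = {}
        regulons = {}
        universes = {}
        cohorts = {"a": cfg["expr_disease_a"], "b": cfg["expr_disease_b"]}
        if cfg.get("expr_control"):
            cohorts["control"] = cfg["expr_control"]
        for name, path in cohorts.items():
            expr = nio.read_expression_matrix(path)
            net = infer_network(
                expr,
                tf_list,
                alpha=params["alpha"],
                n_perm=params["n_perm"],
                bins=params["bins"],
                dpi_epsilon=params["dpi_epsilon"],
                seed=stage_seed(seed, f"infer:{name}"),
            )
            networks[name] = net
            regulons[name] = extract_regulons(net, min_size=params["min_regulon_size"])
            universes[name] = set(expr.gene_ids)
            nio.write_edge_list(net, out / f"network_{name}.tsv")
            if regulons[name]:
                nio.write_gene_sets_gmt(regulons[name], out / f"regulons_{name}.gmt")

        stage = "signature"
        if cfg.get("signature_gmt"):
            signature_set = nio.read_gene_sets_gmt(cfg["signature_gmt"])[0]
            signature_stats = None
        else:
            expr_a = nio.read_expression_matrix(cfg["contrast_a"])
            expr_b = nio.read_expression_matrix(cfg["contrast_b"])
            sig = compute_de_signature(
                expr_a, expr_b,
                alpha=params["signature_alpha"], lfc_min=params["lfc_min"],
            )
            signature_set = sig.gene_set("signature")
            sig.table.to_csv(out / "signature_stats.tsv", sep="\t")
            signature_stats = {"n_members": len(signature_set)}
        nio.write_gene_sets_gmt([signature_set], out / "signature.gmt")

        stage = "mra"
        mra_results = {}
        for name in networks:
            mra_results[name] = mra_enrichment(
                regulons[name], signature_set, universes[name], alpha=params["mra_alpha"]
            )
            results_to_frame(mra_results[name]).to_csv(
                out / f"mra_{name}.tsv", sep="\t", index=False
            )

        stage = "proliferation_mra"
        prolif_results = {"a": [], "b": []}
        if cfg.get("proliferation_signature_gmt"):
            prolif_sig = nio.read_gene_sets_gmt(cfg["proliferation_signature_gmt"])[0]
            for name in ("a", "b"):
                prolif_results[name] = mra_enrichment(
                    regulons[name], prolif_sig, universes[name], alpha=params["mra_alpha"]
                )
        else:
            logger.warning("no proliferation signature: proliferation filter is a no-op")

        stage = "consensus"
        alpha = params["mra_alpha"]
        mrs_a = significant_mrs(mra_results["a"], alpha)
        mrs_b = significant_mrs(mra_results["b"], alpha)
        consensus = consensus_mrs(mra_results["a"], mra_results["b"], alpha)
        if "control" in mra_results:
            report = specificity_filter(
                consensus,
                mra_results["control"],
                prolif_results["a"],
                prolif_results["b"],
                alpha=alpha,
                mrs_network1=mrs_a,
                mrs_network2=mrs_b,
            )
        else:
            logger.warning("no control network: specificity filter skipped")
            report = specificity_filter(
                consensus, [], prolif_results["a"], prolif_results["b"],
                alpha=alpha, mrs_network1=mrs_a, mrs_network2=mrs_b,
            )
            report.provenance.insert(0, "control network missing: control filter skipped")

        stage = "regulon_overlap"
        overlap = regulon_overlap_table(regulons["a"], regulons["b"])
        overlap.to_csv(out / "regulon_overlap.tsv", sep="\t", index=False)

        stage = "motif_enrichment"
        motif_results = []
        if cfg.get("pfm") and cfg.get("flanks_fasta"):
            model = nio.read_pfm_jaspar(cfg["pfm"])
            flanks = nio.read_fasta(cfg["flanks_fasta"])
            bg = background_from_sequences(flanks)
            pwm = build_pwm(model, background=bg, pseudocount=params["pseudocount"])
            threshold = score_threshold_from_pvalue(pwm, params["scan_p"])
            carriers = genes_with_motif(pwm, flanks, threshold)
            for name in ("a", "b"):
                universe = universes[name] & set(flanks)
                for reg in regulons[name]:
                    if reg.name not in report.final:
                        continue
                    trimmed = GeneSet(reg.name, reg.description,
                                      [g for g in reg.members if g in universe])
                    if not trimmed.members:
                        continue
                    res = resampling_enrichment(
                        carriers, trimmed, universe,
                        n_samples=params["motif_n_samples"],
                        seed=stage_seed(seed, f"motif:{name}:{reg.name}"),
                    )
                    motif_results.append({"network": name, **_jsonable(res)})

        stage = "survival"
        survival_results = []
        for path in cfg.get("survival_tables", []):
            table = nio.read_survival_table(path)
            fit = cox_fit(table)
            km = km_estimate(table)
            scan = optimal_cutoff_scan(
                table,
                n_permutations=params["cutoff_n_permutations"],
                seed=stage_seed(seed, f"cutoff:{Path(path).name}"),
            )
            survival_results.append(
                {
                    "table": str(path),
                    "cox": _jsonable(fit),
                    "km_final_survival": float(km.survival[-1]) if km.survival.size else 1.0,
                    "cutoff_scan": {
                        "selected_percentile": scan.selected_percentile,
                        "selected_cutoff": scan.selected_cutoff,
                        "selected_p": scan.selected_p,
                        "adjusted_p": scan.adjusted_p,
                        "n_permutations": scan.n_permutations,
                    },
                }
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle = {
        "networks": {
            name: {
                "n_edges": len(net.edges),
                "n_tfs_with_targets": len(net.regulon_map()),
                "params": net.params,
            }
            for name, net in networks.items()
        },
        "signature": {"name": signature_set.name, "n_members": len(signature_set),
                      **(signature_stats or {})},
        "mra": {name: _jsonable(results_to_frame(res)) for name, res in mra_results.items()},
        "proliferation_mra": {
            name: _jsonable(results_to_frame(res)) for name, res in prolif_results.items()
        },
        "consensus_report": _jsonable(report),
        "regulon_overlap": _jsonable(overlap),
        "motif_enrichment": motif_results,
        "survival": survival_results,
        "meta": {
            "seed": seed,
            "params": _jsonable(params),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "inputs": {
                k: hashlib.sha256(Path(v).read_bytes()).hexdigest()
                for k, v in cfg.items()
                if isinstance(v, str) and Path(v).is_file()
            },
        },
    }
    bundle["checksum"] = bundle_checksum(bundle)
    with open(out / "bundle.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(bundle), fh, indent=2, sort_keys=True)
    return bundle
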