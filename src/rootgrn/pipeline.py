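"""End-to-end pipeline: synthetic data -> inference -> thresholding -> signs
-> feedback model -> sensitivity, driven by one YAML/dict config.

Stage order mirrors the analysis: a perturbation expression matrix feeds the
forest inference, the ranked edges are cut by the edge-count rule (optionally
after a precision scan against binding data), an ordered time course signs
the retained edges, and the two-variable feedback model plus its Sobol
analysis run independently of the data stages.  Every stage derives its own
seed deterministically from the global seed, and all artifacts are
byte-stable TSV/JSON, so a config+seed pair is fully reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .containers import (BindingSet, ExpressionMatrix, TimeCourse,
                         read_weighted_edges, write_signed_edges, write_sif,
                         write_weighted_edges, _format_float)
from .errors import InvalidArgument
from .inference import (InferenceConfig, infer_edge_weights, rank_edges,
                        select_threshold, threshold_edges)
from .model import ModelParams, genotype_scenarios, steady_states
from .sensitivity import (SensitivityConfig, default_param_ranges,
                          model_sensitivity, rank_parameters)
from .signs import assign_signs
from .synthetic import (GenotypeSpec, default_genotypes, make_binding_set,
                        make_ground_truth_network, simulate_genotype_expression,
                        simulate_time_course)

log = logging.getLogger("rootgrn")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2 ** 31)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidArgument(f"{path}: config must be a YAML mapping")
    return cfg


def _genotypes_from_config(block: Any) -> list[GenotypeSpec]:
    if block in (None, "default"):
        return default_genotypes()
    out = []
    for item in block:
        out.append(GenotypeSpec(str(item["name"]),
                                {str(k): float(v)
                                 for k, v in (item.get("perturbations") or {}).items()}))
    return out


def _model_params(block: Mapping[str, Any] | None) -> ModelParams:
    block = dict(block or {})
    variant = str(block.pop("variant", "EQN2")).upper()
    return ModelParams(variant=variant,
                       **{k: float(v) for k, v in block.items()})


def run_pipeline(cfg: Mapping[str, Any], out_dir) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict[str, Any] = {
        "version": __version__,
        "global_seed": seed,
        "config": json.loads(json.dumps(cfg, default=str)),
        "seeds": {},
        "stages": {},
        "artifacts": [],
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(out)))

    def done(stage: str, **summary) -> None:
        manifest["stages"][stage] = summary
        log.info("stage %s: %s", stage, summary)

    try:
        expr = timecourse = binding = None
        truth = None
        inputs = cfg.get("inputs") or {}
        syn = cfg.get("synthetic")

        # ---------------- synthetic data ----------------
        if syn is not None:
            s_seed = stage_seed(seed, "synthetic")
            manifest["seeds"]["synthetic"] = s_seed
            truth = make_ground_truth_network(
                n_targets=int(syn.get("n_targets", 36)),
                regulators=syn.get("regulators", ("GTL1", "DF1", "RSL4")),
                edge_density=float(syn.get("edge_density", 0.55)),
                include_feedback=bool(syn.get("include_feedback", True)),
                seed=s_seed)
            expr = simulate_genotype_expression(
                truth, _genotypes_from_config(syn.get("genotypes")),
                n_reps=int(syn.get("n_reps", 3)),
                noise_cv=float(syn.get("noise_cv", 0.2)), seed=s_seed)
            tc_expr = simulate_time_course(
                truth, timepoints=int(syn.get("timepoints", 5)),
                zones=int(syn.get("zones", 2)), seed=s_seed)
            timecourse = TimeCourse.from_expression(tc_expr)
            bind_cfg = syn.get("binding") or {}
            binding = make_binding_set(
                truth, tpr=float(bind_cfg.get("tpr", 1.0)),
                fpr=float(bind_cfg.get("fpr", 0.0)), seed=s_seed)
            truth.write_tsv(out / "network_true.tsv")
            expr.write_tsv(out / "expression.tsv", out / "samples.tsv")
            timecourse.write_tsv(out / "timecourse.tsv")
            binding.write_tsv(out / "binding.tsv")
            for name in ("network_true.tsv", "expression.tsv", "samples.tsv",
                         "timecourse.tsv", "binding.tsv"):
                record(name, out / name)
            done("synthetic", n_nodes=len(truth.nodes),
                 n_true_edges=len(truth.edges), n_samples=len(expr.sample_ids),
                 n_binding_pairs=len(binding))
        else:
            if "expression" in inputs:
                expr = ExpressionMatrix.read_tsv(inputs["expression"],
                                                 inputs.get("samples"))
            if "timecourse" in inputs:
                timecourse = TimeCourse.read_tsv(inputs["timecourse"])
            if "binding" in inputs:
                binding = BindingSet.read_tsv(inputs["binding"])

        # ---------------- inference + thresholding ----------------
        inf_cfg = cfg.get("inference") or {}
        edges_kept = None
        if inf_cfg.get("enabled", True) and expr is not None:
            i_seed = stage_seed(seed, "inference")
            manifest["seeds"]["inference"] = i_seed
            regulators = list(inf_cfg.get("regulators")
                              or (truth.regulators if truth is not None
                                  else ("GTL1", "DF1", "RSL4")))
            edges = infer_edge_weights(expr, InferenceConfig(
                regulators=regulators,
                n_trees=int(inf_cfg.get("n_trees", 10_000)),
                seed=i_seed))
            ranked = rank_edges(edges)
            write_weighted_edges(ranked, out / "edges_ranked.tsv")
            record("edges_ranked.tsv", out / "edges_ranked.tsv")
            n_genes = int(inf_cfg.get("n_genes",
                                      len(expr.gene_ids) - len(regulators)))
            multiplier = float(inf_cfg.get("multiplier", 1.65))
            scan = inf_cfg.get("scan_multipliers")
            summary: dict[str, Any] = {"n_candidate_edges": len(edges)}
            if scan and binding is not None:
                best, table = select_threshold(
                    ranked, binding, n_genes, [float(m) for m in scan],
                    tf_filter=inf_cfg.get("tf_filter", "GTL1"))
                with open(out / "threshold_scan.tsv", "w", encoding="utf-8",
                          newline="\n") as fh:
                    fh.write("multiplier\tn_edges\tprecision\n")
                    for row in table:
                        fh.write(f"{_format_float(row.multiplier)}\t"
                                 f"{row.n_edges}\t"
                                 f"{_format_float(row.precision)}\n")
                record("threshold_scan.tsv", out / "threshold_scan.tsv")
                multiplier = best
                summary["selected_multiplier"] = best
            edges_kept = threshold_edges(ranked, n_genes, multiplier)
            write_weighted_edges(edges_kept, out / "edges_thresholded.tsv")
            write_sif(edges_kept, out / "network.sif")
            record("edges_thresholded.tsv", out / "edges_thresholded.tsv")
            record("network.sif", out / "network.sif")
            summary.update(multiplier=multiplier, n_edges_kept=len(edges_kept),
                           n_genes=n_genes)
            done("inference", **summary)
        elif inf_cfg.get("enabled", True) and "edges" in inputs:
            edges_kept = read_weighted_edges(inputs["edges"])

        # ---------------- sign assignment ----------------
        sign_cfg = cfg.get("signs") or {}
        if sign_cfg.get("enabled", True) and edges_kept is not None \
                and timecourse is not None:
            signed = assign_signs(edges_kept, timecourse,
                                  per_zone=bool(sign_cfg.get("per_zone", False)))
            write_signed_edges(signed, out / "network_signed.tsv")
            record("network_signed.tsv", out / "network_signed.tsv")
            done("signs",
                 n_edges=len(signed),
                 n_activating=sum(1 for e in signed if e.sign > 0),
                 n_repressing=sum(1 for e in signed if e.sign < 0),
                 n_ambiguous=sum(1 for e in signed if e.sign == 0))

        # ---------------- feedback model ----------------
        model_cfg = cfg.get("model") or {}
        params = _model_params(model_cfg.get("params"))
        if model_cfg.get("enabled", True):
            scenarios = genotype_scenarios(
                params, oe_fold=float(model_cfg.get("oe_fold", 15.0)),
                t_end=float(model_cfg.get("t_end", 50.0)),
                n_out=int(model_cfg.get("n_out", 201)))
            with open(out / "scenarios.tsv", "w", encoding="utf-8",
                      newline="\n") as fh:
                fh.write("scenario\tk2\tR_star\tG_star\tratio_R\tratio_G\t"
                         "stability\tresidual\n")
                for sc in scenarios:
                    ss = sc.steady_state
                    fh.write("\t".join([
                        sc.label, _format_float(sc.params.k2),
                        _format_float(ss.R_star), _format_float(ss.G_star),
                        _format_float(sc.ratio_R), _format_float(sc.ratio_G),
                        ss.stability, _format_float(ss.residual)]) + "\n")
            record("scenarios.tsv", out / "scenarios.tsv")
            for sc in scenarios:
                path = out / f"trajectory_{sc.label}.tsv"
                with open(path, "w", encoding="utf-8", newline="\n") as fh:
                    fh.write("t\tR\tG\n")
                    for t, r, g in sc.trajectory:
                        fh.write(f"{_format_float(t)}\t{_format_float(r)}\t"
                                 f"{_format_float(g)}\n")
                record(path.name, path)
            counts = {v: len(steady_states(params.with_(variant=v)))
                      for v in ("EQN1", "EQN2")}
            done("model", steady_state_counts=counts,
                 ratios={sc.label: [sc.ratio_R, sc.ratio_G] for sc in scenarios})

        # ---------------- sensitivity ----------------
        sens_cfg = cfg.get("sensitivity") or {}
        if sens_cfg.get("enabled", True):
            sb_seed = stage_seed(seed, "sensitivity")
            manifest["seeds"]["sensitivity"] = sb_seed
            ranges = sens_cfg.get("ranges")
            if ranges:
                ranges = {str(k): (float(v[0]), float(v[1]))
                          for k, v in ranges.items()}
            else:
                ranges = default_param_ranges(
                    params, rel_width=float(sens_cfg.get("rel_width", 0.5)))
            scfg = SensitivityConfig(
                param_ranges=ranges,
                n_mc=int(sens_cfg.get("n_mc", 1000)),
                n_repeats=int(sens_cfg.get("n_repeats", 10)),
                seed=sb_seed,
                scheme=str(sens_cfg.get("scheme", "sobol")))
            res = model_sensitivity(params, cfg=scfg,
                                    which=str(sens_cfg.get("output", "R_star")))
            ranking = rank_parameters(res)
            with open(out / "sobol.tsv", "w", encoding="utf-8",
                      newline="\n") as fh:
                fh.write("parameter\tS1_mean\tS1_sd\trank\n")
                for name, m, s in res.as_rows():
                    fh.write(f"{name}\t{_format_float(m)}\t{_format_float(s)}\t"
                             f"{ranking.index(name) + 1}\n")
            record("sobol.tsv", out / "sobol.tsv")
            done("sensitivity", ranking=ranking,
                 top2=ranking[:2], n_mc=scfg.n_mc, n_repeats=scfg.n_repeats)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, out)
        raise

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
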