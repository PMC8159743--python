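"""End-to-end analysis pipeline: qc → scan → permute → intervals →
conditioned scans → causal inference → path model, emitting per-stage CSV
files and a single JSON report with a provenance block.

Re-running with the same configuration and inputs is byte-identical: all
randomness flows from the configured seed and the report carries no
timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import causal as causal_mod
from . import pathmodel as path_mod
from . import qc as qc_mod
from . import scan as scan_mod
from .io import read_cross

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_ALLOWED_STAGES = {"qc", "permute", "intervals", "condition", "causal", "path"}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``condition_pairs`` lists (trait, conditioning_trait) scans;
    ``causal_tests`` lists (t1, t2, locus) with ``locus='auto'`` meaning
    the genome-wide peak of t1's scan; ``path_spec`` is a mapping
    outcome → predictor list plus an optional ``residual_covariances``
    list of outcome pairs.
    """

    pheno: str
    geno: str
    map: str
    traits: list[str]
    formula: str = "sex * diet"
    n_permutations: int = 1000
    alphas: list[float] = field(default_factory=lambda: [0.05, 0.01])
    seed: int = 0
    out_dir: str = "dietcross_out"
    stages: dict = field(default_factory=dict)
    condition_pairs: list = field(default_factory=list)
    causal_tests: list = field(default_factory=list)
    path_spec: dict | None = None
    sd_k: float = 3.0
    max_missing: float = 0.1
    lod_drop: float = 1.5

    def __post_init__(self):
        for a in self.alphas:
            if not (0 < a < 1):
                raise ValueError(f"alpha {a} outside (0, 1)")
        unknown = set(self.stages) - _ALLOWED_STAGES
        if unknown:
            raise ValueError(f"unknown stage toggles: {sorted(unknown)}")

    def stage_enabled(self, name: str) -> bool:
        return bool(self.stages.get(name, True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        """Hash of the analysis-relevant configuration (out_dir excluded:
        where results are written does not change what they are)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        pheno, geno, gmap = read_cross(config.pheno, config.geno, config.map)
        log.info("read %d individuals, %d markers, formula %r, seed %d",
                 geno.n_individuals, geno.n_markers, config.formula, config.seed)
        report: dict = {
            "provenance": {
                "config_hash": config.content_hash(),
                "dietcross_version": __version__,
                "seed": config.seed,
                "n_individuals": geno.n_individuals,
                "n_markers": geno.n_markers,
                "formula": config.formula,
            }
        }

        if config.stage_enabled("qc"):
            stage = "qc"
            f2 = pheno[pheno["generation"] == "F2"].copy()
            other = pheno[pheno["generation"] != "F2"]
            f2, qc_rep = qc_mod.remove_outliers_iterative(f2, config.traits, k=config.sd_k)
            pheno = pd.concat([f2, other], ignore_index=True)
            geno, marker_rep = qc_mod.filter_markers(geno, max_missing=config.max_missing)
            qc_rep.outliers.to_csv(out / "qc_outliers.csv", index=False)
            marker_rep.markers.to_csv(out / "qc_markers.csv", index=False)
            report["qc"] = {
                "n_outlier_values": len(qc_rep.outliers),
                "n_markers_removed": len(marker_rep.markers),
                "n_markers_retained": geno.n_markers,
            }

        stage = "scan"
        scans: dict[str, scan_mod.ScanResult] = {}
        for trait in config.traits:
            scans[trait] = scan_mod.genome_scan(pheno, geno, trait, config.formula)
            scans[trait].table.to_csv(out / f"scan_{trait}.csv", index=False)

        thresholds: dict[str, scan_mod.ThresholdSet | None] = {}
        if config.stage_enabled("permute"):
            stage = "permute"
            for i, trait in enumerate(config.traits):
                thresholds[trait] = scan_mod.permutation_thresholds(
                    pheno, geno, trait, config.formula, alphas=tuple(config.alphas),
                    n_perm=config.n_permutations, seed=config.seed + i)
        else:
            thresholds = {t: None for t in config.traits}

        stage = "intervals"
        qtl_rows = []
        for trait in config.traits:
            sc = scans[trait]
            thr = thresholds[trait]
            cut = thr[min(config.alphas)] if thr else None
            sig = thr[max(config.alphas)] if thr else None
            for chrom in gmap.chroms:
                sub = sc.table[sc.table["chrom"] == chrom]
                if sub.empty or sub["lod"].isna().all():
                    continue
                peak = sub.iloc[int(np.nanargmax(sub["lod"].to_numpy()))]
                if thr is not None and peak["lod"] < sig:
                    continue
                row = {
                    "trait": trait, "chrom": chrom, "top_marker": peak["marker"],
                    "top_mb": peak["pos_mb"], "lod": peak["lod"],
                    "effect_het": peak["effect_het"], "effect_fvb": peak["effect_fvb"],
                    "pct_var": scan_mod.variance_explained(
                        pheno, geno, trait, peak["marker"], config.formula),
                    "threshold_5pct": sig if thr else "unavailable",
                    "threshold_1pct": cut if thr else "unavailable",
                    "significance": ("" if thr is None else
                                     "highly_significant" if peak["lod"] >= cut
                                     else "significant"),
                }
                if config.stage_enabled("intervals"):
                    ival = scan_mod.support_interval(sc, chrom, drop=config.lod_drop)
                    row.update(left_marker=ival.left_marker, left_mb=ival.left_mb,
                               right_marker=ival.right_marker, right_mb=ival.right_mb)
                qtl_rows.append(row)
        qtl_table = pd.DataFrame(qtl_rows)
        qtl_table.to_csv(out / "qtl_table.csv", index=False)
        report["qtl_table"] = _jsonable(qtl_table.to_dict(orient="records"))
        report["thresholds"] = {
            t: (_jsonable(thr.thresholds) if thr else "unavailable")
            for t, thr in thresholds.items()}

        if config.stage_enabled("condition") and config.condition_pairs:
            stage = "condition"
            cond_rows = []
            for trait, conditioner in config.condition_pairs:
                _, delta = scan_mod.conditioned_scan(pheno, geno, trait, conditioner,
                                                     config.formula)
                for rec in delta.to_dict(orient="records"):
                    rec.update(trait=trait, conditioned_on=conditioner)
                    cond_rows.append(rec)
            pd.DataFrame(cond_rows).to_csv(out / "conditioned_scans.csv", index=False)
            report["conditioned_scans"] = _jsonable(cond_rows)

        if config.stage_enabled("causal") and config.causal_tests:
            stage = "causal"
            causal_out = []
            for t1, t2, locus in config.causal_tests:
                if locus == "auto":
                    locus = scans[t1].top_marker()["marker"]
                rep = causal_mod.causal_network_inference(pheno, geno, t1, t2, locus)
                causal_out.append(_jsonable({
                    "t1": t1, "t2": t2, "locus": rep.locus,
                    "p_r1": rep.p_r1, "p_r2": rep.p_r2,
                    "holm_reject": list(rep.holm_reject),
                    "classification": rep.classification,
                    "model_scores": rep.model_scores,
                }))
            (out / "causal.json").write_text(json.dumps(causal_out, indent=2, sort_keys=True))
            report["causal"] = causal_out

        if config.stage_enabled("path") and config.path_spec:
            stage = "path"
            spec_dict = dict(config.path_spec)
            covs = spec_dict.pop("residual_covariances", [])
            spec = path_mod.PathModelSpec(
                tuple(path_mod.PathEquation(o, tuple(p)) for o, p in spec_dict.items()),
                tuple(tuple(c) for c in covs))
            pruned_spec, fit = path_mod.prune_paths(spec, pheno, geno)
            fit.paths.to_csv(out / "path_model.csv", index=False)
            report["path_model"] = {
                "paths": _jsonable(fit.paths.to_dict(orient="records")),
                "totals": _jsonable(fit.totals),
                "residual_correlations": _jsonable(
                    {f"{a}~{b}": v for (a, b), v in fit.residual_correlations.items()}),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report
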