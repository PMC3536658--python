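"""End-to-end orchestration: read inputs, run every analysis stage,
write the report bundle and a JSON manifest.

The manifest records input checksums, all seeds, and every test result
so each number in the report is reproducible; timestamps are
deliberately excluded so identical configurations produce identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import divergence as dv
from . import gi
from . import localization as loc
from . import ma
from .stat_tests import TestResult, welch_t

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    gi_edges: str
    pairs: str
    out_dir: str
    alignments: str | None = None
    localizations: str | None = None
    snps: str | None = None
    ancestral_snps: str | None = None
    genes: str | None = None
    alpha: float = 0.05
    sign: str = "all"
    null_pairs: int = 1_000_000
    seed: int = 17
    young_ssd_percentile: float = 0.05
    divergence_variant: str = "asymmetry"
    expected_model: str = "cds-length"

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, TestResult):
        d = {"statistic": obj.statistic, "p_value": obj.p_value,
             "df": obj.df, "estimate": obj.estimate,
             "sidedness": obj.sidedness}
        if obj.extra:
            d.update({k: v for k, v in obj.extra.items()})
        return _jsonable(d)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return None  # frames are written as TSVs, not into the manifest
    return obj


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage on the configured inputs and write the bundle.

    Emits per-class interaction summaries, Theta tables with the
    random-singleton null (overall and per divergence bin), within-pair
    epistasis, kappa tables, the divergence comparison, the
    localization contrast, the MA enrichment analysis, and
    manifest.json.  Any stage failure aborts the run with the stage
    name and removes partial outputs.
    """
    out = Path(config.out_dir)
    started = out.exists()
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "inputs": {},
                      "stages": {}, "results": {}}
    for name in ("gi_edges", "pairs", "alignments", "localizations",
                 "snps", "ancestral_snps", "genes"):
        path = getattr(config, name)
        if path is None:
            continue
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name}: no such file {path}")
        manifest["inputs"][name] = {"path": str(path),
                                    "sha256": _checksum(path)}
    stage = "setup"
    try:
        # --- catalog -------------------------------------------------------
        stage = "catalog"
        t0 = time.monotonic()
        catalog = cat.read_catalog(config.pairs)
        edge_df = gi.read_gi_table(config.gi_edges)
        matrix = gi.GIMatrix.from_edges(
            edge_df, alpha=config.alpha,
            universe=catalog.paired_genes() | catalog.singletons)
        if not catalog.singletons:
            catalog = cat.PairCatalog(
                pairs=catalog.pairs,
                singletons=matrix.universe - catalog.paired_genes())
        manifest["stages"][stage] = {"seconds": time.monotonic() - t0,
                                     "n_pairs": len(catalog.pairs),
                                     "n_edges": len(matrix)}
        logger.info("catalog: %d pairs, %d singletons, %d edges",
                    len(catalog.pairs), len(catalog.singletons), len(matrix))

        # --- divergence ----------------------------------------------------
        divergences: dict = {}
        if config.alignments:
            stage = "divergence"
            t0 = time.monotonic()
            div_df = dv.analyze_fasta(config.alignments)
            div_df.to_csv(out / "divergence.tsv", sep="\t", index=False)
            for row in div_df.itertuples(index=False):
                genes = tuple(sorted(row.pair.split("|")))
                if len(genes) == 2:
                    divergences[genes] = row.d_ab
            manifest["stages"][stage] = {"seconds": time.monotonic() - t0,
                                         "n_triples": len(div_df)}
        if any(p.divergence is not None for p in catalog.pairs):
            divergences.update({p.genes: p.divergence
                                for p in catalog.pairs
                                if p.divergence is not None})
        if divergences:
            catalog = cat.attach_divergence(catalog, divergences)
            ssd = [p.divergence for p in catalog.by_mode("SSD")
                   if p.divergence is not None]
            wgd = [p.divergence for p in catalog.by_mode("WGD")
                   if p.divergence is not None]
            if len(ssd) >= 2 and len(wgd) >= 2:
                manifest["results"]["divergence_contrast"] = {
                    "mean_ssd": float(np.mean(ssd)),
                    "mean_wgd": float(np.mean(wgd)),
                    "welch_t": welch_t(ssd, wgd),
                }
            catalog = cat.filter_young_ssd(
                catalog, percentile=config.young_ssd_percentile)
            manifest["results"]["young_ssd_filter"] = catalog.metadata

        # --- gi statistics ---------------------------------------------------
        stage = "gi_stats"
        t0 = time.monotonic()
        summaries = gi.epistasis_summary(matrix, catalog, config.alpha)
        pd.DataFrame([{k: v for k, v in dataclasses.asdict(s).items()
                       if k != "per_gene_counts"}
                      for s in summaries]).to_csv(
            out / "class_epistasis.tsv", sep="\t", index=False)
        manifest["results"]["class_epistasis"] = [
            {k: v for k, v in dataclasses.asdict(s).items()
             if k != "per_gene_counts"} for s in summaries]
        counts = {s.gene_class: s.per_gene_counts for s in summaries}
        if "SSD" in counts and "WGD" in counts:
            manifest["results"]["gi_count_contrast"] = {
                "welch_t": welch_t(list(counts["SSD"].values()),
                                   list(counts["WGD"].values()))}

        theta_rows = []
        theta_results = gi.pair_thetas(matrix, catalog.pairs, config.alpha,
                                       config.sign)
        mode_of = {p.genes: p.mode for p in catalog.pairs}
        div_of = {p.genes: p.divergence for p in catalog.pairs}
        for r in theta_results:
            key = (r.gene_a, r.gene_b)
            theta_rows.append((r.gene_a, r.gene_b, mode_of[key],
                               div_of[key], r.n_shared, r.gi_a, r.gi_b,
                               r.theta))
        theta_df = pd.DataFrame(theta_rows, columns=[
            "gene_a", "gene_b", "mode", "divergence", "n_shared",
            "gi_a", "gi_b", "theta"])
        theta_df.to_csv(out / "theta_pairs.tsv", sep="\t", index=False)

        null = gi.random_pair_null(
            matrix, catalog.singletons, n_pairs=config.null_pairs,
            seed=config.seed, alpha=config.alpha, sign=config.sign)
        with open(out / "null_distribution.json", "w") as fh:
            json.dump(null.summary(), fh, indent=1)
        theta_tests = {}
        for mode in ("SSD", "WGD"):
            vals = theta_df.loc[(theta_df["mode"] == mode)
                                & theta_df["theta"].notna(), "theta"]
            if len(vals) == 0:
                continue
            p_emp, enriched = gi.empirical_test(float(vals.mean()), null)
            theta_tests[mode] = {"mean_theta": float(vals.mean()),
                                 "n_pairs": int(len(vals)),
                                 "empirical_p": p_emp,
                                 "enriched": enriched}
        manifest["results"]["theta"] = {
            "null": null.summary(), "classes": theta_tests}

        if divergences:
            per_bin = {}
            binnable = [p for p in catalog.pairs if p.divergence is not None]
            for label, members in gi.bin_by_divergence(binnable).items():
                vals = [t.theta for t in gi.pair_thetas(
                    matrix, members, config.alpha, config.sign)
                    if t.theta is not None]
                if not vals:
                    continue
                p_emp, enriched = gi.empirical_test(float(np.mean(vals)),
                                                    null)
                per_bin[label] = {"n": len(vals),
                                  "mean_theta": float(np.mean(vals)),
                                  "empirical_p": p_emp,
                                  "enriched": enriched}
            manifest["results"]["theta_by_divergence_bin"] = per_bin

        manifest["results"]["within_pair"] = gi.within_pair_epistasis(
            matrix, catalog, config.alpha)
        kappa = gi.class_kappa_means(matrix, catalog, config.alpha)
        pd.DataFrame([
            {"gene_class": cls,
             "per_copy_mean": v["per_copy_mean"],
             "per_copy_n": v["per_copy_n"],
             "joint_mean": v.get("joint_mean"),
             "joint_n": v.get("joint_n")}
            for cls, v in kappa.items()]).to_csv(
            out / "kappa_classes.tsv", sep="\t", index=False)
        manifest["results"]["kappa"] = {
            cls: {k: v for k, v in d.items() if not k.endswith("values")}
            for cls, d in kappa.items()}
        if kappa.get("SSD", {}).get("joint_n") and \
           kappa.get("WGD", {}).get("joint_n"):
            manifest["results"]["kappa_contrast"] = {
                "welch_t": welch_t(kappa["WGD"]["joint_values"],
                                   kappa["SSD"]["joint_values"])}
        manifest["results"]["flags"] = {
            "theta_ssd_gt_wgd": bool(
                theta_tests.get("SSD", {}).get("mean_theta", np.nan)
                > theta_tests.get("WGD", {}).get("mean_theta", np.nan)),
            "kappa_wgd_gt_ssd": bool(
                kappa.get("WGD", {}).get("joint_mean", np.nan)
                > kappa.get("SSD", {}).get("joint_mean", np.nan)),
        }
        manifest["stages"][stage] = {"seconds": time.monotonic() - t0}

        # --- localization -----------------------------------------------------
        if config.localizations:
            stage = "localization"
            t0 = time.monotonic()
            table = loc.read_localizations(config.localizations)
            contrast = loc.localization_contrast(catalog, table)
            contrast["per_pair"].to_csv(out / "localization_pairs.tsv",
                                        sep="\t", index=False)
            manifest["results"]["localization"] = {
                k: v for k, v in contrast.items() if k != "per_pair"}
            manifest["stages"][stage] = {"seconds": time.monotonic() - t0}

        # --- mutation accumulation -------------------------------------------
        if config.snps and config.genes:
            stage = "ma"
            t0 = time.monotonic()
            snps = ma.read_snps(config.snps)
            snps = ma.filter_candidates(snps)
            if config.ancestral_snps:
                ancestral = pd.read_csv(config.ancestral_snps, sep="\t",
                                        dtype={"chrom": str})
                snps = ma.subtract_ancestral(snps, ancestral)
            genes = ma.read_gene_annotation(config.genes)
            violations = ma.check_nested_sets(snps)
            regressions = {}
            for line, sub in snps.groupby("line"):
                regressions[str(line)] = {
                    cat_: ma.accumulation_regression(sub, cat_)
                    for cat_ in ("total", "synonymous", "non-synonymous")}
            final = snps[snps["passage"]
                         == snps.groupby("line")["passage"]
                         .transform("max")]
            enrichment = ma.class_enrichment(final, genes,
                                             config.expected_model)
            manifest["results"]["ma"] = {
                "n_snps_final": int(len(final.drop_duplicates(
                    ["line", "chrom", "pos", "alt"]))),
                "nested_violations": len(violations),
                "regressions": regressions,
                "enrichment": enrichment,
            }
            with open(out / "ma_regressions.json", "w") as fh:
                json.dump(_jsonable(regressions), fh, indent=1)
            manifest["stages"][stage] = {"seconds": time.monotonic() - t0}

        with open(out / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:
        logger.error("stage %r failed; removing partial outputs", stage)
        if not started:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for f in out.glob("*"):
                if f.is_file():
                    f.unlink()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
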