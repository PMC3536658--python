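"""Mutation-accumulation (MA) line analysis.

Input SNP tables mirror the output of an upstream short-read mapping
and annotation pipeline: per line and passage, candidate variants with
read depth, mean mapping multiplicity, supporting base-call fraction,
region (exonic/intronic/intergenic), coding effect, and gene.  This
module applies the candidate filters, subtracts ancestral variants,
fits the linear accumulation of SNPs over generations, and tests
whether non-synonymous SNPs are enriched in SSD- versus WGD-duplicated
genes relative to a gene-count or CDS-length expectation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .stat_tests import TestResult, chi_square_gof, fisher_exact_2x2

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["line", "passage", "chrom", "pos", "ref", "alt",
               "depth", "avg_hits", "support", "region", "effect", "gene"]

DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_SUPPORT = 0.85
GENERATIONS_PER_PASSAGE = 22
HITS_TOL = 1e-9

GENE_CLASSES = ("singleton", "SSD", "WGD")


def read_snps(path) -> pd.DataFrame:
    """Read a SNP TSV; validates columns and basic ranges."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_gene_annotation(path) -> pd.DataFrame:
    """Read (gene, class, cds_length) annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    need = {"gene", "class", "cds_length"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(need)}")
    bad = set(df["class"]) - set(GENE_CLASSES)
    if bad:
        raise ValueError(f"unknown gene classes {sorted(bad)}")
    return df


def filter_candidates(candidates: pd.DataFrame,
                      min_depth: int = DEFAULT_MIN_DEPTH,
                      require_unique_mapping: bool = True,
                      min_support: float = DEFAULT_MIN_SUPPORT
                      ) -> pd.DataFrame:
    """Retain candidates with depth >= min_depth, unique mapping
    (mean hits = 1), and supporting-call fraction >= min_support.

    All boundaries are inclusive on the retained side.  Malformed rows
    (non-numeric or out-of-range fields) are rejected with their
    1-based row number.
    """
    df = candidates
    for col, lo, hi in (("depth", 0, None), ("avg_hits", 0, None),
                        ("support", 0.0, 1.0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() | (vals < lo)
                             | ((vals > hi) if hi is not None else False))
        if bad.size:
            raise ValueError(f"malformed {col} in row {bad[0] + 1}")
    keep = (df["depth"] >= min_depth) & (df["support"] >= min_support)
    if require_unique_mapping:
        keep &= (df["avg_hits"] - 1.0).abs() <= HITS_TOL
    out = df[keep].copy()
    logger.info("candidate filter retained %d of %d records",
                len(out), len(df))
    return out


def snp_key(df: pd.DataFrame) -> pd.Index:
    """SNP identity: (chrom, pos, alt)."""
    return pd.MultiIndex.from_frame(df[["chrom", "pos", "alt"]])


def subtract_ancestral(evolved: pd.DataFrame,
                       ancestral: pd.DataFrame) -> pd.DataFrame:
    """Remove variants already present in the ancestor (by chrom/pos/alt)."""
    if len(ancestral) == 0:
        return evolved.copy()
    mask = snp_key(evolved).isin(snp_key(ancestral))
    out = evolved[~mask].copy()
    logger.info("ancestral subtraction: %d -> %d SNPs",
                len(evolved), len(out))
    return out


def check_nested_sets(line_snps: pd.DataFrame) -> list[str]:
    """Report clonal-transfer violations: a SNP present at passage t but
    absent at a later sequenced passage of the same line."""
    problems = []
    for line, grp in line_snps.groupby("line"):
        passages = sorted(grp["passage"].unique())
        prev: set = set()
        for t in passages:
            cur = set(map(tuple,
                          grp.loc[grp["passage"] == t,
                                  ["chrom", "pos", "alt"]].to_numpy()))
            lost = prev - cur
            for key in sorted(lost):
                problems.append(
                    f"line {line}: SNP {key} present before passage {t} "
                    f"but absent at {t}")
            prev = cur
    for msg in problems:
        logger.warning("nested-set violation: %s", msg)
    return problems


def accumulation_regression(line_snps: pd.DataFrame,
                            category: str = "total",
                            generations_per_passage: int =
                            GENERATIONS_PER_PASSAGE) -> dict:
    """OLS fit of cumulative SNP count against generations for one line.

    category: "total", "synonymous" or "non-synonymous".  Counts at each
    sequenced passage are cumulative by construction of the clonal
    transfer design.  Requires >= 3 sequenced passages.
    """
    df = line_snps
    if category != "total":
        df = df[df["effect"] == category]
    passages = sorted(line_snps["passage"].unique())
    if len(passages) < 3:
        raise ValueError("accumulation regression needs >= 3 passages")
    gens = np.array(passages, dtype=float) * generations_per_passage
    counts = np.array([
        len(df[df["passage"] == t].drop_duplicates(["chrom", "pos", "alt"]))
        for t in passages], dtype=float)
    fit = _scipy_stats.linregress(gens, counts)
    return {"category": category,
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue ** 2),
            "generations": gens.tolist(),
            "counts": counts.tolist()}


def _class_shares(genes: pd.DataFrame, model: str) -> pd.Series:
    if model == "gene-count":
        shares = genes.groupby("class").size()
    elif model == "cds-length":
        shares = genes.groupby("class")["cds_length"].sum()
    else:
        raise ValueError(f"unknown expected-model {model!r}")
    shares = shares.reindex(GENE_CLASSES).fillna(0).astype(float)
    if (shares == 0).any():
        zero = shares.index[shares == 0].tolist()
        raise ValueError(f"zero expected share for classes {zero}")
    return shares / shares.sum()


def class_enrichment(snps: pd.DataFrame, genes: pd.DataFrame,
                     expected_model: str = "cds-length") -> dict:
    """Non-synonymous SNP enrichment by gene duplication class.

    Observed: the fraction of annotated non-synonymous SNPs falling in
    genes of each class (at the final sequenced passage of each line,
    i.e. deduplicated variants).  Expected: the class share of total CDS
    length (default) or of gene count.  A chi-square goodness-of-fit
    compares observed to expected counts across the three classes;
    per-line and pooled 2x2 Fisher tests compare the fractions of SSD
    versus WGD genes hit by at least one non-synonymous SNP.
    """
    gene_class = genes.set_index("gene")["class"]
    shares = _class_shares(genes, expected_model)
    nsyn = snps[(snps["effect"] == "non-synonymous")
                & snps["gene"].notna()].copy()
    nsyn = nsyn.drop_duplicates(["line", "chrom", "pos", "alt"])
    nsyn["gene_class"] = nsyn["gene"].map(gene_class)
    unknown = nsyn["gene_class"].isna().sum()
    if unknown:
        logger.warning("%d non-synonymous SNPs in unannotated genes "
                       "ignored", unknown)
        nsyn = nsyn.dropna(subset=["gene_class"])
    observed = (nsyn.groupby("gene_class").size()
                .reindex(GENE_CLASSES).fillna(0).astype(float))
    total = observed.sum()
    if total == 0:
        raise ValueError("no annotated non-synonymous SNPs")
    expected = shares * total
    chi2: TestResult = chi_square_gof(observed.to_numpy(),
                                      expected.to_numpy())
    # genes hit at least once, per class
    class_sizes = genes.groupby("class").size().reindex(GENE_CLASSES).fillna(0)

    def hit_table(sub: pd.DataFrame) -> list[list[int]]:
        hit = sub.groupby("gene_class")["gene"].nunique()
        ssd_hit = int(hit.get("SSD", 0))
        wgd_hit = int(hit.get("WGD", 0))
        return [[ssd_hit, int(class_sizes["SSD"]) - ssd_hit],
                [wgd_hit, int(class_sizes["WGD"]) - wgd_hit]]

    per_line = {}
    for line, sub in nsyn.groupby("line"):
        per_line[str(line)] = fisher_exact_2x2(hit_table(sub))
    pooled = fisher_exact_2x2(hit_table(nsyn))
    return {
        "expected_model": expected_model,
        "observed_counts": observed.to_dict(),
        "expected_counts": expected.to_dict(),
        "observed_fractions": (observed / total).to_dict(),
        "expected_fractions": shares.to_dict(),
        "chi_square": chi2,
        "fisher_per_line": per_line,
        "fisher_pooled": pooled,
    }


def chromosome_counts(snps: pd.DataFrame,
                      chrom_lengths: dict[str, int] | None = None
                      ) -> pd.DataFrame:
    """Per-chromosome SNP counts, optionally length-normalized to the
    longest chromosome."""
    counts = (snps.drop_duplicates(["line", "chrom", "pos", "alt"])
              .groupby("chrom").size().rename("n_snps").reset_index())
    if chrom_lengths:
        longest = max(chrom_lengths.values())
        counts["normalized"] = [
            n * longest / chrom_lengths[c] if c in chrom_lengths else np.nan
            for c, n in counts[["chrom", "n_snps"]].to_numpy()]
    return counts
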