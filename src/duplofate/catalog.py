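"""Duplicate-pair catalog: reciprocal best hits, WGD/SSD classification,
and the young-pair divergence filter.

Paralog pairs are defined as reciprocal best hits (RBH) from an
all-against-all protein similarity search (tabular 12-column hits).
Pairs present in a curated ohnolog list (conserved gene order across the
yeast whole-genome duplication) are labeled WGD; all remaining pairs are
attributed to small-scale duplication (SSD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column names of the 12-column tabular similarity format.
HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_BITSCORE_MIN = 50.0


def canonical(a: str, b: str) -> tuple[str, str]:
    """Order a gene pair lexicographically."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    mode: str = "SSD"          # "WGD" or "SSD"
    divergence: float | None = None

    def __post_init__(self):
        if self.gene_a > self.gene_b:
            raise ValueError("pair must be in canonical (sorted) order")
        if self.mode not in ("WGD", "SSD"):
            raise ValueError(f"unknown duplication mode {self.mode!r}")

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class PairCatalog:
    """Duplicate pairs plus the singleton remainder of the gene universe."""

    pairs: list[DuplicatePair]
    singletons: set[str] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        paired = self.paired_genes()
        if paired & self.singletons:
            raise ValueError("singletons overlap with paired genes")
        seen: dict[str, tuple[str, str]] = {}
        for p in self.pairs:
            for g in p.genes:
                if g in seen:
                    raise ValueError(f"gene {g} appears in more than one pair")
                seen[g] = p.genes

    def paired_genes(self) -> set[str]:
        return {g for p in self.pairs for g in p.genes}

    def by_mode(self, mode: str) -> list[DuplicatePair]:
        return [p for p in self.pairs if p.mode == mode]

    def gene_class(self) -> dict[str, str]:
        """Map every known gene to singleton/SSD/WGD."""
        cls = {g: "singleton" for g in self.singletons}
        for p in self.pairs:
            for g in p.genes:
                cls[g] = p.mode
        return cls

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.gene_a, p.gene_b, p.mode, p.divergence) for p in self.pairs],
            columns=["gene_a", "gene_b", "mode", "divergence"],
        )


def read_hits(path) -> pd.DataFrame:
    """Read 12-column tabular similarity hits (gzip-transparent).

    Malformed rows (wrong column count, non-numeric e-value/bitscore)
    are rejected with their 1-based row number.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 12:
        raise ValueError(
            f"{path}: expected 12 tab-separated columns, found {df.shape[1]}")
    df.columns = HIT_COLUMNS
    for col in ("evalue", "bitscore"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna())
        if bad.size:
            raise ValueError(
                f"{path}: malformed {col} in row {bad[0] + 1}")
        df[col] = vals
    return df


def reciprocal_best_hits(
    hits: pd.DataFrame,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    bitscore_min: float = DEFAULT_BITSCORE_MIN,
) -> list[tuple[str, str]]:
    """Reciprocal best hits among retained similarity hits.

    A hit is retained if evalue <= evalue_max and bitscore >= bitscore_min;
    self-hits are discarded.  The best hit of a query is the retained hit
    with maximal bitscore (ties: minimal e-value, then lexicographically
    smallest subject).  A pair (a, b) is emitted iff each gene is the
    other's best hit.  When a gene would end up in several candidate
    pairs, only its highest-bitscore pair is kept so that each gene
    belongs to at most one pair.
    """
    if len(hits) == 0:
        return []
    df = hits[(hits["query"] != hits["subject"])
              & (hits["evalue"] <= evalue_max)
              & (hits["bitscore"] >= bitscore_min)]
    if len(df) == 0:
        return []
    # collapse duplicate (query, subject) rows to the strongest hit
    df = (df.sort_values(["bitscore", "evalue"], ascending=[False, True])
            .drop_duplicates(["query", "subject"]))
    best: dict[str, tuple[float, float, str]] = {}
    for q, s, ev, bs in df[["query", "subject", "evalue", "bitscore"]].itertuples(index=False):
        key = (-bs, ev, s)
        if q not in best or key < best[q]:
            best[q] = key
    candidates: dict[tuple[str, str], float] = {}
    for q, (neg_bs, _ev, s) in best.items():
        if s in best and best[s][2] == q:
            pair = canonical(q, s)
            score = max(-neg_bs, -best[s][0])
            candidates[pair] = score
    # enforce one pair per gene, strongest pair wins
    result: list[tuple[str, str]] = []
    used: set[str] = set()
    for pair, _score in sorted(candidates.items(),
                               key=lambda kv: (-kv[1], kv[0])):
        if pair[0] in used or pair[1] in used:
            continue
        used.update(pair)
        result.append(pair)
    return sorted(result)


def classify_pairs(
    pairs: list[tuple[str, str]],
    ohnologs: set[tuple[str, str]],
    universe: set[str] | None = None,
) -> PairCatalog:
    """Label pairs WGD (present in the ohnolog list) or SSD (all others).

    The curated ohnolog list is treated as authoritative: ohnolog pairs
    not recovered among the input pairs are injected as WGD pairs (with
    a warning), provided neither gene is already paired.
    """
    pairs = [canonical(*p) for p in pairs]
    ohno = {canonical(*p) for p in ohnologs}
    out = [DuplicatePair(a, b, "WGD" if (a, b) in ohno else "SSD")
           for a, b in pairs]
    paired = {g for p in out for g in p.genes}
    for a, b in sorted(ohno - set(pairs)):
        if a in paired or b in paired:
            logger.warning("ohnolog pair (%s, %s) conflicts with an "
                           "existing pair; skipped", a, b)
            continue
        logger.warning("ohnolog pair (%s, %s) absent from similarity pairs; "
                       "injected as WGD", a, b)
        out.append(DuplicatePair(a, b, "WGD"))
        paired.update((a, b))
    universe = set(universe) if universe is not None else paired
    return PairCatalog(pairs=sorted(out, key=lambda p: p.genes),
                       singletons=universe - paired)


def filter_young_ssd(
    catalog: PairCatalog,
    divergences: dict[tuple[str, str], float] | None = None,
    percentile: float = 0.05,
) -> PairCatalog:
    """Drop SSD pairs younger (less diverged) than nearly all WGD pairs.

    SSD pairs with divergence strictly below the given quantile of the
    WGD divergence distribution (default: 5th percentile, i.e. below the
    divergence of 95% of WGDs) are removed; pairs exactly at the
    threshold are kept.  WGD pairs pass through unchanged.  The
    threshold is recorded in the result metadata.
    """
    def div_of(p: DuplicatePair) -> float:
        if divergences is not None and p.genes in divergences:
            return divergences[p.genes]
        if p.divergence is not None:
            return p.divergence
        raise ValueError(f"SSD pair {p.genes} lacks a divergence value")

    wgd = catalog.by_mode("WGD")
    if not wgd:
        raise ValueError("young-SSD filter undefined without WGD pairs")
    wgd_div = np.array([div_of(p) for p in wgd], dtype=float)
    threshold = float(np.quantile(wgd_div, percentile))
    kept, removed = [], []
    for p in catalog.pairs:
        if p.mode == "SSD" and div_of(p) < threshold:
            removed.append(p)
        else:
            kept.append(p)
    logger.info("young-SSD filter: threshold %.4g removed %d of %d SSD pairs",
                threshold, len(removed), len(catalog.by_mode("SSD")))
    meta = dict(catalog.metadata)
    meta.update(young_ssd_threshold=threshold,
                young_ssd_removed=len(removed))
    return PairCatalog(pairs=kept,
                       singletons=set(catalog.singletons),
                       metadata=meta)


def attach_divergence(
    catalog: PairCatalog, divergences: dict[tuple[str, str], float]
) -> PairCatalog:
    """Return a catalog whose pairs carry divergence values."""
    pairs = [replace(p, divergence=divergences.get(p.genes, p.divergence))
             for p in catalog.pairs]
    return PairCatalog(pairs=pairs, singletons=set(catalog.singletons),
                       metadata=dict(catalog.metadata))


def read_ohnologs(path) -> set[tuple[str, str]]:
    """Read a 2-column TSV of WGD-derived pairs."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 tab-separated columns")
    return {canonical(a, b) for a, b in df.iloc[:, :2].itertuples(index=False)}


def read_catalog(path) -> PairCatalog:
    """Read a pair catalog TSV (gene_a, gene_b, mode[, divergence])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    pairs = []
    for row in df.itertuples(index=False):
        div = getattr(row, "divergence", None)
        div = None if div is None or pd.isna(div) else float(div)
        a, b = canonical(row.gene_a, row.gene_b)
        pairs.append(DuplicatePair(a, b, row.mode, div))
    return PairCatalog(pairs=pairs)


def write_catalog(catalog: PairCatalog, path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)
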