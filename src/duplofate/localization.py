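"""Sub-cellular localization overlap between duplicate copies.

Two copies have a "different" localization when their compartment sets
are not identical — either disjoint or only partially overlapping.  The
WGD/SSD contrast is a pair-level 2x2 table (class x different/same)
tested with Fisher's exact test; copy-level counts (each cell doubled)
are emitted for transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .catalog import PairCatalog
from .stat_tests import TestResult, fisher_exact_2x2

logger = logging.getLogger(__name__)


@dataclass
class LocalizationTable:
    compartments: dict[str, frozenset[str]] = field(default_factory=dict)

    def get(self, gene: str) -> frozenset[str] | None:
        return self.compartments.get(gene)


def _normalize(labels) -> frozenset[str]:
    out = frozenset(" ".join(str(c).split()).casefold()
                    for c in labels if str(c).strip())
    return out


def read_localizations(path) -> LocalizationTable:
    """Read a TSV of (gene, semicolon-separated compartments)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    table = LocalizationTable()
    for gene, comps in df[cols[:2]].itertuples(index=False):
        labels = _normalize(str(comps).split(";"))
        if not labels:
            logger.warning("gene %s has an empty compartment set; skipped",
                           gene)
            continue
        table.compartments[str(gene)] = labels
    return table


def write_localizations(table: LocalizationTable, path) -> None:
    rows = [(g, ";".join(sorted(c)))
            for g, c in sorted(table.compartments.items())]
    pd.DataFrame(rows, columns=["gene", "compartments"]).to_csv(
        path, sep="\t", index=False)


def overlap_class(loc_a, loc_b) -> str:
    """Classify two compartment sets: identical, partial, or disjoint."""
    a, b = _normalize(loc_a), _normalize(loc_b)
    if not a or not b:
        raise ValueError("compartment sets must be non-empty")
    if a == b:
        return "identical"
    if not (a & b):
        return "disjoint"
    return "partial"


def is_different(loc_a, loc_b) -> bool:
    """True when the localization overlap is not complete."""
    return overlap_class(loc_a, loc_b) != "identical"


def localization_contrast(catalog: PairCatalog, table: LocalizationTable
                          ) -> dict:
    """WGD-vs-SSD contrast of localization divergence.

    Only pairs with both copies annotated enter the 2x2 table
    [[SSD different, SSD same], [WGD different, WGD same]]; pairs with
    an unannotated copy are counted as excluded.
    """
    counts = {cls: {"identical": 0, "partial": 0, "disjoint": 0,
                    "excluded": 0}
              for cls in ("SSD", "WGD")}
    per_pair = []
    for p in catalog.pairs:
        loc_a, loc_b = table.get(p.gene_a), table.get(p.gene_b)
        if loc_a is None or loc_b is None:
            counts[p.mode]["excluded"] += 1
            continue
        oc = overlap_class(loc_a, loc_b)
        counts[p.mode][oc] += 1
        per_pair.append((p.gene_a, p.gene_b, p.mode, oc,
                         oc != "identical"))
    summary = {}
    for cls in ("SSD", "WGD"):
        c = counts[cls]
        total = c["identical"] + c["partial"] + c["disjoint"]
        if total == 0:
            raise ValueError(f"no annotated {cls} pairs")
        diff = c["partial"] + c["disjoint"]
        summary[cls] = {**c, "n_pairs": total, "different": diff,
                        "fraction_different": diff / total}
    tab = [[summary["SSD"]["different"],
            summary["SSD"]["n_pairs"] - summary["SSD"]["different"]],
           [summary["WGD"]["different"],
            summary["WGD"]["n_pairs"] - summary["WGD"]["different"]]]
    fisher: TestResult = fisher_exact_2x2(tab)
    copy_level = [[2 * v for v in row] for row in tab]
    return {
        "classes": summary,
        "table_pairs": tab,
        "table_copies": copy_level,
        "fisher": fisher,
        "per_pair": pd.DataFrame(
            per_pair,
            columns=["gene_a", "gene_b", "mode", "overlap", "different"]),
    }
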