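"""Genetic-interaction (epistasis) network statistics.

The substrate is a sparse, signed epistasis network: each measured gene
pair carries an epistasis score epsilon (deviation of the double
mutant's fitness from the multiplicative expectation, in colony-size
units) and a p-value.  Statistics implemented here:

* significant interaction profiles at a p-value threshold, optionally
  restricted by epistasis sign;
* the shared-partner proportion Theta = 2 n_S / (GI_i + GI_j) for a
  duplicate pair, with a resampled null from randomly paired singletons;
* per-class (singleton / SSD / WGD) interaction counts and
  sign-partitioned epistasis means;
* within-pair epistasis rates and strengths;
* divergence binning of duplicate pairs;
* the partner clustering coefficient kappa = 2 l / (n (n - 1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import DuplicatePair, PairCatalog, canonical

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# GI matrix


class GIMatrix:
    """Sparse symmetric epistasis network with per-edge p-values.

    Edges are stored canonically with gene_i < gene_j.  The raw screen
    is directional (query x array) and may contain replicate alleles;
    :meth:`from_edges` collapses replicates of a direction to the
    minimum-p measurement and symmetrizes: an unordered pair is
    significant if either direction is, its epsilon being the
    significant direction's value (the mean if both directions are
    significant at the build-time alpha, the minimum-p direction's
    otherwise).
    """

    def __init__(self, edges: dict[tuple[str, str], tuple[float, float]],
                 universe: set[str] | None = None):
        self.edges: dict[tuple[str, str], tuple[float, float]] = {}
        adj: dict[str, dict[str, tuple[float, float]]] = {}
        for (a, b), (eps, p) in edges.items():
            if a == b:
                continue
            key = canonical(a, b)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"edge {key}: p-value {p} outside [0, 1]")
            if not np.isfinite(eps):
                raise ValueError(f"edge {key}: non-finite epsilon")
            self.edges[key] = (float(eps), float(p))
            adj.setdefault(key[0], {})[key[1]] = self.edges[key]
            adj.setdefault(key[1], {})[key[0]] = self.edges[key]
        self._adj = adj
        self.universe: set[str] = set(universe) if universe else set(adj)
        missing = set(adj) - self.universe
        if missing:
            raise ValueError(f"edges reference genes outside the universe: "
                             f"{sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self.universe

    def neighbors(self, gene: str) -> dict[str, tuple[float, float]]:
        return self._adj.get(gene, {})

    def edge(self, a: str, b: str) -> tuple[float, float] | None:
        return self.edges.get(canonical(a, b))

    @classmethod
    def from_edges(cls, table: pd.DataFrame,
                   alpha: float = DEFAULT_ALPHA,
                   universe: set[str] | None = None) -> "GIMatrix":
        """Build from a directed edge table (query, array, epsilon, pvalue)."""
        need = {"query", "array", "epsilon", "pvalue"}
        if not need.issubset(table.columns):
            raise ValueError(f"edge table must have columns {sorted(need)}")
        df = table.loc[table["query"] != table["array"],
                       ["query", "array", "epsilon", "pvalue"]].copy()
        # replicate screens of the same directed pair: keep minimum p
        df = (df.sort_values("pvalue", kind="stable")
                .drop_duplicates(["query", "array"]))
        df["gene_i"] = np.minimum(df["query"], df["array"])
        df["gene_j"] = np.maximum(df["query"], df["array"])
        df = df.sort_values("pvalue", kind="stable")
        dup_mask = df.duplicated(["gene_i", "gene_j"], keep=False)
        edges: dict[tuple[str, str], tuple[float, float]] = {
            (gi, gj): (float(eps), float(p))
            for gi, gj, eps, p in df.loc[
                ~dup_mask, ["gene_i", "gene_j", "epsilon", "pvalue"]
            ].itertuples(index=False)
        }
        # pairs measured in both directions: significant if either is;
        # epsilon averaged when both directions are significant
        for (gi, gj), grp in df[dup_mask].groupby(["gene_i", "gene_j"],
                                                  sort=False):
            ps = grp["pvalue"].to_numpy()
            es = grp["epsilon"].to_numpy()
            sig = ps < alpha
            if sig.sum() >= 2:
                edges[(gi, gj)] = (float(es[sig].mean()), float(ps.min()))
            else:
                edges[(gi, gj)] = (float(es[0]), float(ps[0]))
        genes = set(table["query"]) | set(table["array"])
        if universe:
            genes |= set(universe)
        return cls(edges, universe=genes)


def read_gi_table(path) -> pd.DataFrame:
    """Read a (query, array, epsilon, pvalue) TSV, gzip-transparent."""
    df = pd.read_csv(path, sep="\t", dtype={"query": str, "array": str})
    return df


# ---------------------------------------------------------------------------
# Profiles and Theta


@dataclass
class GIProfile:
    gene: str
    partners: frozenset[str]
    signed_partners: dict[str, float]

    @property
    def gi_count(self) -> int:
        return len(self.partners)


def significant_profile(matrix: GIMatrix, gene: str,
                        alpha: float = DEFAULT_ALPHA,
                        sign: str = "all") -> GIProfile:
    """Significant interaction partners of a gene (p < alpha, strict).

    sign="pos" keeps only epsilon > 0 partners, "neg" only epsilon < 0.
    """
    if gene not in matrix:
        raise KeyError(f"gene {gene!r} not in the interaction universe")
    if sign not in ("all", "pos", "neg"):
        raise ValueError(f"sign must be all/pos/neg, got {sign!r}")
    signed = {}
    for partner, (eps, p) in matrix.neighbors(gene).items():
        if p >= alpha:
            continue
        if sign == "pos" and eps <= 0:
            continue
        if sign == "neg" and eps >= 0:
            continue
        signed[partner] = eps
    return GIProfile(gene, frozenset(signed), signed)


def all_profiles(matrix: GIMatrix, alpha: float = DEFAULT_ALPHA,
                 sign: str = "all") -> dict[str, frozenset[str]]:
    """Significant partner sets for every gene in the universe."""
    return {g: significant_profile(matrix, g, alpha, sign).partners
            for g in matrix.universe}


@dataclass
class SharedInteractionResult:
    gene_a: str
    gene_b: str
    n_shared: int
    gi_a: int
    gi_b: int
    theta: float | None   # None when both profiles are empty

    @property
    def defined(self) -> bool:
        return self.theta is not None


def theta_of_sets(set_a: frozenset[str], set_b: frozenset[str]) -> float | None:
    total = len(set_a) + len(set_b)
    if total == 0:
        return None
    return 2.0 * len(set_a & set_b) / total


def theta_shared(profile_a: GIProfile, profile_b: GIProfile,
                 exclude_pair_edge: bool = True) -> SharedInteractionResult:
    """Shared-partner proportion Theta between two genes' profiles.

    By default each copy is removed from the other's partner set so
    that a direct interaction between the two genes does not count as a
    shared partner.
    """
    set_a, set_b = profile_a.partners, profile_b.partners
    if exclude_pair_edge:
        set_a = set_a - {profile_b.gene}
        set_b = set_b - {profile_a.gene}
    theta = theta_of_sets(set_a, set_b)
    return SharedInteractionResult(
        profile_a.gene, profile_b.gene,
        n_shared=len(set_a & set_b),
        gi_a=len(set_a), gi_b=len(set_b), theta=theta)


def pair_thetas(matrix: GIMatrix, pairs: list[DuplicatePair],
                alpha: float = DEFAULT_ALPHA, sign: str = "all",
                exclude_pair_edge: bool = True
                ) -> list[SharedInteractionResult]:
    """Theta for every duplicate pair with both members in the universe."""
    out = []
    for p in pairs:
        if p.gene_a not in matrix or p.gene_b not in matrix:
            logger.info("pair %s not fully assayed; skipped", p.genes)
            continue
        out.append(theta_shared(
            significant_profile(matrix, p.gene_a, alpha, sign),
            significant_profile(matrix, p.gene_b, alpha, sign),
            exclude_pair_edge=exclude_pair_edge))
    return out


# ---------------------------------------------------------------------------
# Random-singleton-pair null


@dataclass
class NullDistribution:
    samples: np.ndarray
    n_pairs: int
    seed: int
    quantiles: dict[str, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.samples.mean()) if self.n_pairs else float("nan")

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1)) if self.n_pairs > 1 else float("nan")

    def summary(self) -> dict:
        out = {"n": self.n_pairs, "seed": self.seed}
        if self.n_pairs:
            out.update(mean=self.mean, sd=self.sd, **self.quantiles)
        return out


def random_pair_null(matrix: GIMatrix, singletons: set[str],
                     n_pairs: int = 1_000_000, seed: int = 0,
                     alpha: float = DEFAULT_ALPHA,
                     sign: str = "all") -> NullDistribution:
    """Theta distribution over randomly paired singletons.

    Singletons with empty significant profiles are excluded before
    sampling; each sample is an unordered pair of distinct eligible
    singletons drawn uniformly (with replacement across samples).  As
    for duplicate pairs, each sampled gene is removed from the other's
    partner set before Theta is computed.
    """
    eligible, sets = [], []
    for g in sorted(singletons):
        if g not in matrix:
            continue
        s = significant_profile(matrix, g, alpha, sign).partners
        if s:
            eligible.append(g)
            sets.append(s)
    if n_pairs and len(eligible) < 2:
        raise ValueError("fewer than 2 singletons with non-empty profiles")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_pairs, dtype=float)
    m = len(eligible)
    idx_a = rng.integers(0, m, size=n_pairs) if n_pairs else np.array([], int)
    idx_b = rng.integers(0, m - 1, size=n_pairs) if n_pairs else np.array([], int)
    idx_b = np.where(idx_b >= idx_a, idx_b + 1, idx_b)  # distinct partner
    for k in range(n_pairs):
        ga, gb = eligible[idx_a[k]], eligible[idx_b[k]]
        sa, sb = sets[idx_a[k]], sets[idx_b[k]]
        denom = len(sa) + len(sb) - (gb in sa) - (ga in sb)
        shared = len(sa & sb)
        # denom 0 only when the two genes interact solely with each other
        samples[k] = 2.0 * shared / denom if denom else 0.0
    null = NullDistribution(samples=samples, n_pairs=n_pairs, seed=seed)
    if n_pairs:
        q5, q50, q95 = np.quantile(samples, [0.05, 0.50, 0.95])
        null.quantiles = {"q5": float(q5), "q50": float(q50), "q95": float(q95)}
    return null


def empirical_test(observed_mean: float,
                   null: NullDistribution) -> tuple[float, bool]:
    """One-sided add-one empirical p and upper-tail enrichment flag.

    p = (1 + #{null >= observed}) / (1 + n); the flag is True iff the
    observed mean strictly exceeds the null's 95th percentile.
    """
    if null.n_pairs == 0:
        raise ValueError("empty null distribution")
    ge = int((null.samples >= observed_mean).sum())
    p = (1 + ge) / (1 + null.n_pairs)
    q95 = null.quantiles.get("q95", float(np.quantile(null.samples, 0.95)))
    return p, bool(observed_mean > q95)


# ---------------------------------------------------------------------------
# Class summaries


@dataclass
class EpistasisSummary:
    gene_class: str
    n_genes: int
    mean_gi: float
    mean_eps: float
    mean_eps_pos: float
    mean_eps_neg: float
    n_pos: int
    n_neg: int
    per_gene_counts: dict[str, int] = field(default_factory=dict, repr=False)


def epistasis_summary(matrix: GIMatrix, catalog: PairCatalog,
                      alpha: float = DEFAULT_ALPHA) -> list[EpistasisSummary]:
    """Interaction-count and epistasis-strength summary per gene class.

    Per class: the mean per-gene significant-interaction count, the mean
    epsilon over all significant gene-edge incidences of the class, and
    the sign-restricted means.  Zero-epsilon significant edges count in
    neither sign partition.
    """
    classes = catalog.gene_class()
    out = []
    for cls in ("singleton", "SSD", "WGD"):
        genes = sorted(g for g, c in classes.items()
                       if c == cls and g in matrix)
        if not genes:
            logger.warning("gene class %s empty in the assayed universe", cls)
            continue
        counts, eps_all = {}, []
        for g in genes:
            prof = significant_profile(matrix, g, alpha)
            counts[g] = prof.gi_count
            eps_all.extend(prof.signed_partners.values())
        eps_arr = np.array(eps_all, dtype=float)
        pos, neg = eps_arr[eps_arr > 0], eps_arr[eps_arr < 0]
        out.append(EpistasisSummary(
            gene_class=cls, n_genes=len(genes),
            mean_gi=float(np.mean(list(counts.values()))),
            mean_eps=float(eps_arr.mean()) if eps_arr.size else float("nan"),
            mean_eps_pos=float(pos.mean()) if pos.size else float("nan"),
            mean_eps_neg=float(neg.mean()) if neg.size else float("nan"),
            n_pos=int(pos.size), n_neg=int(neg.size),
            per_gene_counts=counts))
    return out


def within_pair_epistasis(matrix: GIMatrix, catalog: PairCatalog,
                          alpha: float = DEFAULT_ALPHA
                          ) -> dict[str, dict]:
    """Per class: fraction of pairs whose copies interact, and mean epsilon.

    A pair interacts iff its (a, b) edge exists with p < alpha.  Pairs
    with a member absent from the assay are excluded from the
    denominator and counted.
    """
    out = {}
    for cls in ("SSD", "WGD"):
        pairs = catalog.by_mode(cls)
        assayed = interacting = excluded = 0
        strengths = []
        for p in pairs:
            if p.gene_a not in matrix or p.gene_b not in matrix:
                excluded += 1
                continue
            assayed += 1
            e = matrix.edge(p.gene_a, p.gene_b)
            if e is not None and e[1] < alpha:
                interacting += 1
                strengths.append(e[0])
        if excluded:
            logger.info("%s: %d pairs with unassayed member excluded",
                        cls, excluded)
        out[cls] = {
            "n_pairs": assayed,
            "n_interacting": interacting,
            "n_excluded": excluded,
            "fraction": interacting / assayed if assayed else float("nan"),
            "mean_epsilon": (float(np.mean(strengths)) if strengths
                             else float("nan")),
        }
    return out


# ---------------------------------------------------------------------------
# Divergence bins


@dataclass(frozen=True)
class BinSpec:
    """Divergence bins: [0, 0.4], then width-0.2 right-closed bins, and an
    open-ended last bin at >= 1.8 substitutions/site."""

    first_edge: float = 0.4
    width: float = 0.2
    last_edge: float = 1.8

    @property
    def edges(self) -> np.ndarray:
        interior = np.arange(self.first_edge, self.last_edge + 1e-9, self.width)
        return np.concatenate(([0.0], interior))

    def labels(self) -> list[str]:
        e = self.edges
        labels = [f"<={e[1]:g}"]
        labels += [f"({e[i]:g},{e[i+1]:g}]" for i in range(1, len(e) - 1)]
        labels.append(f">={self.last_edge:g}")
        return labels

    def assign(self, divergence: float) -> str:
        if divergence < 0:
            raise ValueError(f"negative divergence {divergence}")
        e = self.edges
        if divergence <= e[1]:
            return self.labels()[0]
        if divergence >= self.last_edge:
            return self.labels()[-1]
        i = int(np.searchsorted(e, divergence, side="left"))
        return self.labels()[i - 1]


def bin_by_divergence(pairs: list[DuplicatePair],
                      spec: BinSpec | None = None
                      ) -> dict[str, list[DuplicatePair]]:
    """Partition duplicate pairs into divergence bins (each in exactly one)."""
    spec = spec or BinSpec()
    out: dict[str, list[DuplicatePair]] = {lab: [] for lab in spec.labels()}
    for p in pairs:
        if p.divergence is None:
            raise ValueError(f"pair {p.genes} lacks a divergence value")
        out[spec.assign(p.divergence)].append(p)
    return out


# ---------------------------------------------------------------------------
# Partner clustering


@dataclass
class ClusteringResult:
    focal: str | tuple[str, str]
    n_partners: int
    n_links: int
    kappa: float | None     # None (undefined) when n_partners < 2

    @property
    def defined(self) -> bool:
        return self.kappa is not None


def kappa_value(n_partners: int, n_links: int) -> float:
    """kappa = 2 l / (n (n - 1)): link density among n partners."""
    if n_partners < 2:
        raise ValueError("kappa undefined for fewer than 2 partners")
    return 2.0 * n_links / (n_partners * (n_partners - 1))


def clustering_kappa(matrix: GIMatrix, partner_set: set[str],
                     alpha: float = DEFAULT_ALPHA,
                     focal: str | tuple[str, str] = "") -> ClusteringResult:
    """Count significant links among a partner set and form kappa."""
    partners = sorted(partner_set)
    n = len(partners)
    if n < 2:
        return ClusteringResult(focal, n, 0, None)
    links = 0
    for i, a in enumerate(partners):
        nbrs = matrix.neighbors(a)
        for b in partners[i + 1:]:
            e = nbrs.get(b)
            if e is not None and e[1] < alpha:
                links += 1
    return ClusteringResult(focal, n, links, kappa_value(n, links))


def gene_kappa(matrix: GIMatrix, gene: str,
               alpha: float = DEFAULT_ALPHA) -> ClusteringResult:
    """kappa over a single gene's significant partner set."""
    prof = significant_profile(matrix, gene, alpha)
    return clustering_kappa(matrix, set(prof.partners), alpha, focal=gene)


def pair_joint_kappa(matrix: GIMatrix, pair: DuplicatePair,
                     alpha: float = DEFAULT_ALPHA) -> ClusteringResult:
    """kappa over the union of both copies' partner sets (copies excluded)."""
    union = set()
    for g in pair.genes:
        union |= significant_profile(matrix, g, alpha).partners
    union -= set(pair.genes)
    return clustering_kappa(matrix, union, alpha, focal=pair.genes)


def class_kappa_means(matrix: GIMatrix, catalog: PairCatalog,
                      alpha: float = DEFAULT_ALPHA) -> dict[str, dict]:
    """Per-copy and joined-pair kappa means per gene class."""
    classes = catalog.gene_class()
    per_copy: dict[str, list[float]] = {"singleton": [], "SSD": [], "WGD": []}
    for g, cls in classes.items():
        if g not in matrix:
            continue
        res = gene_kappa(matrix, g, alpha)
        if res.defined:
            per_copy[cls].append(res.kappa)
    joint: dict[str, list[float]] = {"SSD": [], "WGD": []}
    for p in catalog.pairs:
        if p.gene_a not in matrix or p.gene_b not in matrix:
            continue
        res = pair_joint_kappa(matrix, p, alpha)
        if res.defined:
            joint[p.mode].append(res.kappa)
    out = {}
    for cls, vals in per_copy.items():
        out[cls] = {"per_copy_mean": float(np.mean(vals)) if vals else float("nan"),
                    "per_copy_n": len(vals),
                    "per_copy_values": vals}
    for cls, vals in joint.items():
        out[cls].update(joint_mean=float(np.mean(vals)) if vals else float("nan"),
                        joint_n=len(vals), joint_values=vals)
    return out
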