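"""Synthetic data with controllable ground truth for every pipeline stage.

The generator emulates the study system: a sparse signed epistasis
network over the yeast gene complement containing singletons and
duplicate pairs, duplicate partner sets shaped by the three functional
fates (sub-functionalization, neo-functionalization, redundancy with
buffering), aligned protein triples evolved under the JTT model with an
outgroup, sub-cellular localization tables, and mutation-accumulation
lines fixing SNPs linearly over passages with class-dependent retention
of non-synonymous variants.

Default parameters reproduce the scale and effect sizes of the real
study system where those are known: 4,464 assayed genes, 430 WGD and
248 SSD pairs, a background interaction density matching a mean of
~343 significant interactions per singleton, within-pair interaction
rates of 19.8% (WGD) and 12.9% (SSD), localization-divergence rates of
0.24 (WGD) and 0.33 (SSD), five MA lines sequenced at passages
20-100 with ~22 generations per passage, and SSD non-synonymous
retention 1.25x that of WGD.  Tests and calibration runs pass smaller
explicit configurations.

Every generator is a pure function of its configuration (including the
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import jtt
from .catalog import DuplicatePair, PairCatalog
from .gi import GIMatrix
from .localization import LocalizationTable

__all__ = [
    "SimConfig", "simulate_gi_network", "simulate_sequences",
    "simulate_ma_lines", "simulate_localizations",
]


@dataclass
class SimConfig:
    seed: int = 0

    # --- network scale -----------------------------------------------------
    n_genes: int = 4464
    background_density: float = 0.077       # singleton-singleton edge prob
    n_wgd_pairs: int = 430
    n_ssd_pairs: int = 248
    n_modules: int = 20
    module_enrichment: float = 5.0          # within-module density multiplier

    # --- duplicate partner structure --------------------------------------
    partner_count_mean: float = 350.0       # ancestral partner set size (~K)
    wgd_mode: str = "sub"
    ssd_mode: str = "neo"
    neo_retained_fraction: float = 0.6      # f: ancestral overlap kept by copy B
    sub_asymmetry: float = 0.0              # a: partition imbalance in [0, 1)
    sub_overlap: float = 0.0                # o: residual joint retention
    sub_degree_match: bool = False          # top up copies to singleton degree
    buffering_mask_rate: float = 0.5        # m0: masking prob at divergence 0
    buffering_mask_scale: float = 0.8       # divergence where masking fades out

    # --- epistasis scores and detection ------------------------------------
    alpha: float = 0.05
    detection_power: float = 1.0            # true edges significant w.p. power
    false_positive_rate: float = 0.0        # spurious measured edges (off)
    prob_negative: float = 0.56
    eps_neg_mean: float = 0.07              # magnitudes; sign applied on draw
    eps_neg_sd: float = 0.03
    eps_pos_mean: float = 0.055
    eps_pos_sd: float = 0.025
    class_eps_scale: dict = field(default_factory=lambda: {
        "singleton": 1.09, "SSD": 1.0, "WGD": 0.945})
    within_pair_prob: dict = field(default_factory=lambda: {
        "WGD": 0.198, "SSD": 0.129})
    within_pair_eps_mean: dict = field(default_factory=lambda: {
        "WGD": -0.343, "SSD": -0.222})
    within_pair_eps_sd: float = 0.1

    # --- pair divergences ---------------------------------------------------
    divergence_mean: dict = field(default_factory=lambda: {
        "WGD": 0.267, "SSD": 0.3082})
    divergence_shape: float = 3.0           # gamma shape of divergence draws

    # --- sequence model -----------------------------------------------------
    n_triples: int = 50
    branch_a: float = 0.15
    branch_b: float = 0.15
    branch_c: float = 0.5
    alignment_length: int = 400

    # --- localization model -------------------------------------------------
    n_compartments: int = 15
    loc_probs: dict = field(default_factory=lambda: {
        "WGD": {"identical": 0.760, "partial": 0.160, "disjoint": 0.080},
        "SSD": {"identical": 0.669, "partial": 0.220, "disjoint": 0.111}})

    # --- mutation-accumulation model ---------------------------------------
    n_lines: int = 5
    sequenced_passages: tuple = (20, 30, 50, 70, 90, 100)
    generations_per_passage: int = 22
    mutation_rate_per_passage: float = 1.8
    exonic_fraction: float = 0.72
    intronic_fraction: float = 0.03
    synonymous_fraction: float = 0.28       # of exonic candidates
    nonsyn_base_retention: float = 1.0
    nonsyn_retention: dict = field(default_factory=lambda: {
        "singleton": 0.85, "SSD": 1.0, "WGD": 0.8})
    n_ancestral_snps: int = 30
    artifact_rate_per_passage: float = 0.3  # candidates that fail QC filters
    cds_length_mean: float = 1450.0
    cds_length_sd: float = 700.0

    def validate(self) -> None:
        if 2 * (self.n_wgd_pairs + self.n_ssd_pairs) > self.n_genes:
            raise ValueError("duplicate copies exceed the gene universe")
        for name in ("background_density", "detection_power",
                     "neo_retained_fraction", "sub_overlap",
                     "false_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.sub_asymmetry < 1.0:
            raise ValueError("sub_asymmetry must be in [0, 1)")


# ---------------------------------------------------------------------------
# Genetic-interaction network


def _gene_names(config: SimConfig) -> tuple[list, list, list]:
    """(wgd pair name tuples, ssd pair name tuples, singleton names)."""
    wgd = [(f"W{k:04d}a", f"W{k:04d}b") for k in range(config.n_wgd_pairs)]
    ssd = [(f"S{k:04d}a", f"S{k:04d}b") for k in range(config.n_ssd_pairs)]
    n_single = config.n_genes - 2 * (len(wgd) + len(ssd))
    singles = [f"G{k:05d}" for k in range(n_single)]
    return wgd, ssd, singles


def _draw_epsilon(rng: np.random.Generator, config: SimConfig,
                  size: int, scale: np.ndarray | float = 1.0) -> np.ndarray:
    neg = rng.random(size) < config.prob_negative
    mag_neg = np.abs(rng.normal(config.eps_neg_mean, config.eps_neg_sd, size))
    mag_pos = np.abs(rng.normal(config.eps_pos_mean, config.eps_pos_sd, size))
    eps = np.where(neg, -mag_neg, mag_pos) * scale
    # keep scores away from exactly zero so the sign partition is clean
    eps[eps == 0.0] = 1e-6
    return eps


def _draw_pvalues(rng: np.random.Generator, config: SimConfig,
                  size: int, detected: np.ndarray) -> np.ndarray:
    """Detected edges get p = alpha * Beta(1, 3); missed ones p ~ U(alpha, 1)."""
    p = np.where(detected,
                 config.alpha * rng.beta(1.0, 3.0, size),
                 rng.uniform(config.alpha, 1.0, size))
    return p


def simulate_gi_network(config: SimConfig
                        ) -> tuple[GIMatrix, PairCatalog, dict]:
    """Simulate the epistasis network and its duplicate-pair catalog.

    Background edges are Bernoulli(q) among singletons, enriched within
    functional modules.  Each duplicate pair draws an ancestral partner
    set from one module and transforms it according to its mode:

    * ``sub``: the ancestral set is partitioned between the copies
      (asymmetry ``a``, residual joint retention ``o``), so the copies
      share nothing beyond the configured residual overlap and their
      partner sets stay inside the ancestral module.  With
      ``sub_degree_match`` each copy additionally gains independent
      background partners at a rate calibrated so its expected degree
      matches the singleton mean.
    * ``neo``: copy A keeps the whole ancestral set; copy B keeps a
      fraction ``f`` and gains novel partners from a different module
      until its partner count equals copy A's.
    * ``buffering``: both copies keep the full set but each copy-edge is
      masked (its p-value pushed above alpha) with probability
      m(divergence) = m0 * max(0, 1 - divergence / scale).

    Returns the symmetrized matrix, the catalog (with divergences), and
    a ground-truth dictionary (modes, module memberships, expected
    shared fractions).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    wgd_names, ssd_names, singles = _gene_names(config)
    q = config.background_density
    n_single = len(singles)

    # functional modules over the singleton pool
    n_modules = max(1, min(config.n_modules, max(1, n_single // 10)))
    module_of = rng.integers(0, n_modules, size=n_single)
    modules = [np.flatnonzero(module_of == m) for m in range(n_modules)]

    rows: list[tuple[str, str, float, float]] = []

    # --- background among singletons ---------------------------------------
    if n_single >= 2 and q > 0:
        idx_i, idx_j = np.triu_indices(n_single, k=1)
        prob = np.full(idx_i.shape, q)
        if config.module_enrichment != 1.0 and n_modules > 1:
            same = module_of[idx_i] == module_of[idx_j]
            prob[same] = np.minimum(1.0, q * config.module_enrichment)
        mask = rng.random(idx_i.shape[0]) < prob
        ei, ej = idx_i[mask], idx_j[mask]
        n_e = ei.size
        eps = _draw_epsilon(rng, config, n_e,
                            config.class_eps_scale["singleton"])
        detected = rng.random(n_e) < config.detection_power
        pvals = _draw_pvalues(rng, config, n_e, detected)
        singles_arr = np.array(singles)
        rows.extend(zip(singles_arr[ei], singles_arr[ej], eps, pvals))
        degree = np.zeros(n_single)
        np.add.at(degree, ei, 1)
        np.add.at(degree, ej, 1)
        mean_singleton_degree = float(degree.mean())
    else:
        mean_singleton_degree = 0.0

    # --- duplicate pairs ----------------------------------------------------
    pairs: list[DuplicatePair] = []
    truth: dict = {"pairs": {}, "modules": {g: int(m) for g, m
                                            in zip(singles, module_of)}}
    singles_arr = np.array(singles)

    def partner_edges(gene: str, partners: np.ndarray, cls: str,
                      mask_prob: float = 0.0) -> None:
        n_e = partners.size
        if n_e == 0:
            return
        eps = _draw_epsilon(rng, config, n_e, config.class_eps_scale[cls])
        detected = rng.random(n_e) < config.detection_power
        if mask_prob > 0:
            detected &= rng.random(n_e) >= mask_prob
        pvals = _draw_pvalues(rng, config, n_e, detected)
        rows.extend(zip([gene] * n_e, singles_arr[partners], eps, pvals))

    def ancestral_set(size_mean: float) -> tuple[np.ndarray, int]:
        module = int(rng.integers(0, n_modules))
        pool = modules[module]
        size = min(pool.size, max(1, int(rng.poisson(size_mean))))
        chosen = rng.choice(pool, size=size, replace=False)
        return chosen, module

    all_pairs = ([(a, b, "WGD", config.wgd_mode) for a, b in wgd_names]
                 + [(a, b, "SSD", config.ssd_mode) for a, b in ssd_names])
    for gene_a, gene_b, cls, mode in all_pairs:
        div = rng.gamma(config.divergence_shape,
                        config.divergence_mean[cls] / config.divergence_shape)
        anc, module = ancestral_set(config.partner_count_mean)
        info = {"mode": mode, "class": cls, "module": module,
                "divergence": float(div), "n_ancestral": int(anc.size)}
        if mode == "sub":
            perm = rng.permutation(anc)
            n_both = int(round(config.sub_overlap * anc.size))
            both, rest = perm[:n_both], perm[n_both:]
            n_a = int(round((1 + config.sub_asymmetry) / 2 * rest.size))
            set_a = np.concatenate([both, rest[:n_a]])
            set_b = np.concatenate([both, rest[n_a:]])
            if config.sub_degree_match and n_single > 0:
                def top_up(own: np.ndarray) -> np.ndarray:
                    deficit = mean_singleton_degree - own.size
                    p_bg = max(0.0, deficit / max(1, n_single - own.size))
                    extra_mask = rng.random(n_single) < p_bg
                    extra = np.setdiff1d(np.flatnonzero(extra_mask), own)
                    return np.concatenate([own, extra])
                set_a = top_up(set_a)
                set_b = top_up(set_b)
            info["expected_theta"] = (2 * n_both
                                      / max(1, set_a.size + set_b.size))
        elif mode == "neo":
            set_a = anc
            n_keep = int(round(config.neo_retained_fraction * anc.size))
            kept = rng.choice(anc, size=n_keep, replace=False)
            other_module = int(rng.integers(0, n_modules))
            if n_modules > 1:
                while other_module == module:
                    other_module = int(rng.integers(0, n_modules))
            novel_pool = np.setdiff1d(modules[other_module], anc)
            n_novel = min(novel_pool.size, anc.size - n_keep)
            novel = rng.choice(novel_pool, size=n_novel, replace=False)
            set_b = np.concatenate([kept, novel])
            info["expected_theta"] = (2 * n_keep
                                      / max(1, set_a.size + set_b.size))
        elif mode == "buffering":
            set_a = anc
            set_b = anc.copy()
            info["expected_theta"] = None  # depends on masking realisations
        else:
            raise ValueError(f"unknown duplicate mode {mode!r}")

        mask_prob = 0.0
        if mode == "buffering":
            mask_prob = config.buffering_mask_rate * max(
                0.0, 1.0 - div / config.buffering_mask_scale)
        partner_edges(gene_a, np.unique(set_a), cls, mask_prob)
        partner_edges(gene_b, np.unique(set_b), cls, mask_prob)

        if rng.random() < config.within_pair_prob.get(cls, 0.0):
            eps_w = rng.normal(config.within_pair_eps_mean[cls],
                               config.within_pair_eps_sd)
            rows.append((gene_a, gene_b, eps_w,
                         config.alpha * rng.beta(1.0, 3.0)))
            info["within_pair"] = True
        else:
            info["within_pair"] = False
        truth["pairs"][f"{gene_a}|{gene_b}"] = info
        pairs.append(DuplicatePair(gene_a, gene_b, cls, float(div)))

    # --- optional false positives among unmeasured singleton pairs ---------
    if config.false_positive_rate > 0 and n_single >= 2:
        existing = {(r[0], r[1]) for r in rows}
        n_fp = rng.poisson(config.false_positive_rate
                           * n_single * (n_single - 1) / 2)
        for _ in range(int(n_fp)):
            i, j = rng.choice(n_single, size=2, replace=False)
            a, b = sorted((singles[i], singles[j]))
            if (a, b) in existing:
                continue
            rows.append((a, b, float(_draw_epsilon(rng, config, 1)[0]),
                         float(rng.uniform(0, config.alpha))))

    table = pd.DataFrame(rows, columns=["query", "array", "epsilon", "pvalue"])
    universe = ({g for pair in wgd_names + ssd_names for g in pair}
                | set(singles))
    matrix = GIMatrix.from_edges(table, alpha=config.alpha, universe=universe)
    catalog = PairCatalog(pairs=pairs, singletons=set(singles))
    truth["mean_singleton_degree"] = mean_singleton_degree
    return matrix, catalog, truth


def gi_edge_table(matrix: GIMatrix) -> pd.DataFrame:
    """Export a matrix back to a (query, array, epsilon, pvalue) table."""
    rows = [(a, b, eps, p) for (a, b), (eps, p) in sorted(matrix.edges.items())]
    return pd.DataFrame(rows, columns=["query", "array", "epsilon", "pvalue"])


# ---------------------------------------------------------------------------
# Sequence triples


def simulate_sequences(config: SimConfig) -> tuple[dict, dict]:
    """Simulate aligned (copy a, copy b, outgroup c) protein triples.

    The duplication ancestor is drawn from the JTT equilibrium; copies a
    and b evolve from it along branches of the configured lengths, and
    the outgroup evolves along branch_c, so the true pairwise distances
    are additive: d_ab = t_a + t_b, d_ac = t_a + t_c, d_bc = t_b + t_c.

    Returns (sequences, truth) where sequences maps record id
    '<pair>|<role>' to an amino-acid string.
    """
    rng = np.random.default_rng(config.seed)
    seqs: dict[str, str] = {}
    truth: dict[str, dict] = {}
    for k in range(config.n_triples):
        anc = jtt.sample_equilibrium(config.alignment_length, rng)
        a = jtt.evolve(anc, config.branch_a, rng)
        b = jtt.evolve(anc, config.branch_b, rng)
        c = jtt.evolve(anc, config.branch_c, rng)
        pid = f"pair{k:04d}"
        seqs[f"{pid}|a"] = jtt.decode(a)
        seqs[f"{pid}|b"] = jtt.decode(b)
        seqs[f"{pid}|c"] = jtt.decode(c)
        truth[pid] = {"t_a": config.branch_a, "t_b": config.branch_b,
                      "t_c": config.branch_c,
                      "d_ab": config.branch_a + config.branch_b}
    return seqs, truth


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# Localization


def simulate_localizations(config: SimConfig, catalog: PairCatalog
                           ) -> tuple[LocalizationTable, dict]:
    """Draw compartment sets so each class hits its configured
    identical/partial/disjoint probabilities in expectation."""
    rng = np.random.default_rng(config.seed + 1)
    comp = [f"compartment{k:02d}" for k in range(config.n_compartments)]
    table = LocalizationTable()
    truth: dict[str, str] = {}

    def random_set(k_min=1, k_max=3, exclude=frozenset()):
        avail = [c for c in comp if c not in exclude]
        k = int(rng.integers(k_min, k_max + 1))
        return frozenset(rng.choice(avail, size=min(k, len(avail)),
                                    replace=False))

    for p in catalog.pairs:
        probs = config.loc_probs[p.mode]
        outcome = rng.choice(["identical", "partial", "disjoint"],
                             p=[probs["identical"], probs["partial"],
                                probs["disjoint"]])
        if outcome == "identical":
            s = random_set()
            sa, sb = s, s
        elif outcome == "partial":
            shared = random_set(1, 2)
            sa = shared | random_set(1, 1, exclude=shared)
            sb_extra = random_set(1, 1, exclude=shared | sa)
            sb = shared | sb_extra
        else:
            sa = random_set(1, 2)
            sb = random_set(1, 2, exclude=sa)
        table.compartments[p.gene_a] = sa
        table.compartments[p.gene_b] = sb
        truth[f"{p.gene_a}|{p.gene_b}"] = str(outcome)
    for g in sorted(catalog.singletons):
        table.compartments[g] = random_set()
    return table, truth


# ---------------------------------------------------------------------------
# Mutation-accumulation lines


def simulate_gene_annotation(config: SimConfig,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Gene table (gene, class, cds_length) matching the network naming."""
    wgd_names, ssd_names, singles = _gene_names(config)
    rows = []
    length_factor = {"singleton": 1.0, "SSD": 1.1, "WGD": 1.05}
    for names, cls in ((wgd_names, "WGD"), (ssd_names, "SSD")):
        for a, b in names:
            for g in (a, b):
                rows.append((g, cls))
    rows.extend((g, "singleton") for g in singles)
    df = pd.DataFrame(rows, columns=["gene", "class"])
    mu = np.log(config.cds_length_mean)
    sigma = np.sqrt(np.log(1 + (config.cds_length_sd
                                / config.cds_length_mean) ** 2))
    base = rng.lognormal(mu - sigma ** 2 / 2, sigma, size=len(df))
    df["cds_length"] = np.maximum(
        90, (base * df["class"].map(length_factor)).astype(int))
    # codon-aligned lengths
    df["cds_length"] -= df["cds_length"] % 3
    return df


def simulate_ma_lines(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame,
                                                  pd.DataFrame, dict]:
    """Simulate mutation-accumulation SNP tables.

    Mutations arrive per passage as Poisson(rate) per line and fix
    cumulatively (clonal transfer: sets are nested over passages).
    Exonic candidates land in genes with probability proportional to
    CDS length; non-synonymous candidates are retained with a
    class-specific probability (the functional-constraint knob).
    Retained SNPs receive QC fields that pass the candidate filters; a
    configured rate of artifact candidates fails exactly one filter
    each.  An ancestral variant set is present in every line at every
    passage.

    Returns (candidates, ancestral, genes, truth).
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = simulate_gene_annotation(config, rng)
    gene_arr = genes["gene"].to_numpy()
    class_arr = genes["class"].to_numpy()
    weights = genes["cds_length"].to_numpy().astype(float)
    weights = weights / weights.sum()
    chroms = [f"chr{r}" for r in
              ("I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI"
               .split())]

    def new_site():
        return (str(rng.choice(chroms)), int(rng.integers(1, 1_500_000)))

    ancestral_rows = []
    for _ in range(config.n_ancestral_snps):
        chrom, pos = new_site()
        ancestral_rows.append((chrom, pos, "A", "G"))
    ancestral = pd.DataFrame(ancestral_rows,
                             columns=["chrom", "pos", "ref", "alt"])

    bases = np.array(list("ACGT"))
    candidate_rows = []
    truth = {"per_line": {}}
    max_passage = max(config.sequenced_passages)
    for line_idx in range(config.n_lines):
        line = f"MA{line_idx + 1}"
        fixed: list[dict] = []
        n_true = {"synonymous": 0, "non-synonymous": 0, "other": 0}
        for passage in range(1, max_passage + 1):
            n_new = rng.poisson(config.mutation_rate_per_passage)
            for _ in range(n_new):
                chrom, pos = new_site()
                ref, alt = rng.choice(bases, size=2, replace=False)
                u = rng.random()
                if u < config.exonic_fraction:
                    region = "exonic"
                    g_idx = rng.choice(len(gene_arr), p=weights)
                    gene, cls = gene_arr[g_idx], class_arr[g_idx]
                    if rng.random() < config.synonymous_fraction:
                        effect = "synonymous"
                    else:
                        effect = "non-synonymous"
                        keep_p = (config.nonsyn_base_retention
                                  * config.nonsyn_retention[cls])
                        if rng.random() >= min(1.0, keep_p):
                            continue    # purged by selection, never fixes
                elif u < config.exonic_fraction + config.intronic_fraction:
                    region, effect, gene = "intronic", "other", None
                else:
                    region, effect, gene = "intergenic", "other", None
                fixed.append(dict(chrom=chrom, pos=pos, ref=str(ref),
                                  alt=str(alt), region=region, effect=effect,
                                  gene=gene, fixed_at=passage))
                n_true[effect] += 1
            if passage in config.sequenced_passages:
                n = len(fixed) + len(ancestral)
                qc = {"depth": rng.poisson(15, n) + 5,
                      "avg_hits": np.ones(n),
                      "support": rng.uniform(0.9, 1.0, n)}
                records = fixed + [dict(chrom=r.chrom, pos=r.pos, ref=r.ref,
                                        alt=r.alt, region="intergenic",
                                        effect="other", gene=None,
                                        fixed_at=0)
                                   for r in ancestral.itertuples(index=False)]
                for k, rec in enumerate(records):
                    candidate_rows.append((
                        line, passage, rec["chrom"], rec["pos"], rec["ref"],
                        rec["alt"], int(qc["depth"][k]),
                        float(qc["avg_hits"][k]), float(qc["support"][k]),
                        rec["region"], rec["effect"], rec["gene"]))
                # artifact candidates failing exactly one QC filter
                n_art = rng.poisson(config.artifact_rate_per_passage
                                    * passage)
                for _ in range(n_art):
                    chrom, pos = new_site()
                    ref, alt = rng.choice(bases, size=2, replace=False)
                    failure = rng.choice(["depth", "hits", "support"])
                    depth = int(rng.integers(0, 5)) if failure == "depth" \
                        else int(rng.poisson(15) + 5)
                    hits = float(rng.uniform(1.1, 3.0)) \
                        if failure == "hits" else 1.0
                    support = float(rng.uniform(0.2, 0.849)) \
                        if failure == "support" else float(rng.uniform(0.9, 1))
                    candidate_rows.append((
                        line, passage, chrom, pos, str(ref), str(alt),
                        depth, hits, support, "intergenic", "other", None))
        truth["per_line"][line] = dict(n_fixed=len(fixed), **n_true)
    candidates = pd.DataFrame(candidate_rows, columns=[
        "line", "passage", "chrom", "pos", "ref", "alt", "depth",
        "avg_hits", "support", "region", "effect", "gene"])
    truth["retention"] = dict(config.nonsyn_retention)
    return candidates, ancestral, genes, truth


def small_config(**overrides) -> SimConfig:
    """A desk-scale configuration for quick end-to-end runs and tests."""
    base = SimConfig(
        n_genes=600, background_density=0.05, n_wgd_pairs=40, n_ssd_pairs=40,
        n_modules=8, partner_count_mean=25.0, n_triples=10,
        alignment_length=300, n_lines=3, mutation_rate_per_passage=1.0,
        n_ancestral_snps=10, artifact_rate_per_passage=0.05)
    return replace(base, **overrides)
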