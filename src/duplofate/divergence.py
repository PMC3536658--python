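"""Sequence divergence between duplicate copies.

Distances are maximum-likelihood JTT-corrected amino-acid distances
computed on pre-aligned sequences with pairwise gap deletion.  For each
duplicate pair (a, b) with an outgroup ortholog c, the three pairwise
distances are decomposed by the three-point formula into the branch
lengths from each copy to their inferred common ancestor:

    branch_a = (d_ab + d_ac - d_bc) / 2
    branch_b = (d_ab + d_bc - d_ac) / 2

Negative solutions (possible when estimated distances are not additive)
are clipped to zero with the deficit moved to the sibling branch so the
branch sum always equals d_ab.  Two normalized statistics are emitted:
"asymmetry" |branch_a - branch_b| / (branch_a + branch_b), and "total"
branch_a + branch_b (equal to d_ab when no clipping occurred).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from Bio import SeqIO

from . import jtt

logger = logging.getLogger(__name__)

T_MIN = 1e-6
T_MAX = 10.0
MIN_CONFIDENT_COLUMNS = 30
GAP_CHARS = set("-.*X")


@dataclass
class AlignedPair:
    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"aligned sequences {self.id_a}/{self.id_b} differ in length")


@dataclass
class DistanceTriple:
    d_ab: float
    d_ac: float
    d_bc: float

    def __post_init__(self):
        for name in ("d_ab", "d_ac", "d_bc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class DivergenceRecord:
    pair_id: str
    d_ab: float
    branch_a: float
    branch_b: float
    asymmetry: float | None
    total: float
    flags: list[str]


def _count_matrix(seq_a: str, seq_b: str) -> np.ndarray:
    """20x20 substitution counts over columns ungapped in both sequences."""
    sa, sb = jtt.encode(seq_a), jtt.encode(seq_b)
    keep = (sa >= 0) & (sb >= 0)
    counts = np.zeros((20, 20))
    np.add.at(counts, (sa[keep], sb[keep]), 1.0)
    return counts


def jtt_distance(pair: AlignedPair) -> tuple[float, list[str]]:
    """Maximum-likelihood JTT distance in substitutions per site.

    Maximizes sum_sites log(pi_x P_xy(t)) over t in [1e-6, 10] (Brent,
    tolerance 1e-6).  Estimates at the upper bound are capped and
    flagged "saturated"; alignments with fewer than 30 ungapped columns
    are flagged "low_confidence".
    """
    counts = _count_matrix(pair.seq_a, pair.seq_b)
    n_cols = counts.sum()
    if n_cols == 0:
        raise ValueError(
            f"{pair.id_a}/{pair.id_b}: no ungapped columns in the alignment")
    flags = []
    if n_cols < MIN_CONFIDENT_COLUMNS:
        flags.append("low_confidence")
    log_pi = np.log(jtt.equilibrium_frequencies())

    def neg_loglik(t: float) -> float:
        p = jtt.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(p))
        return -np.where(counts > 0, ll, 0.0).sum()

    res = minimize_scalar(neg_loglik, bounds=(T_MIN, T_MAX),
                          method="bounded",
                          options={"xatol": 1e-6})
    t_hat = float(res.x)
    if t_hat > T_MAX - 1e-3 and neg_loglik(T_MAX) <= res.fun + 1e-9:
        t_hat = T_MAX
        flags.append("saturated")
    return t_hat, flags


def three_point_branches(triple: DistanceTriple
                         ) -> tuple[float, float, list[str]]:
    """Branch lengths from each copy to the inferred ancestor.

    Negative raw branches are clipped to zero, moving the deficit to the
    sibling so branch_a + branch_b = d_ab always; clipping is flagged.
    """
    raw_a = (triple.d_ab + triple.d_ac - triple.d_bc) / 2.0
    raw_b = (triple.d_ab + triple.d_bc - triple.d_ac) / 2.0
    flags = []
    if raw_a < 0:
        raw_a, raw_b = 0.0, triple.d_ab
        flags.append("clipped_a")
    elif raw_b < 0:
        raw_a, raw_b = triple.d_ab, 0.0
        flags.append("clipped_b")
    return raw_a, raw_b, flags


def normalized_divergence(branch_a: float, branch_b: float,
                          variant: str = "asymmetry") -> float | None:
    """Normalized divergence statistic for a decomposed pair.

    "asymmetry": |branch_a - branch_b| / (branch_a + branch_b), the
    imbalance of the two post-duplication branches; undefined (None)
    at zero total divergence.  "total": branch_a + branch_b.
    """
    total = branch_a + branch_b
    if variant == "total":
        return total
    if variant != "asymmetry":
        raise ValueError(f"unknown variant {variant!r}")
    if total <= 0:
        return None
    return abs(branch_a - branch_b) / total


def analyze_triple(pair_id: str, seq_a: str, seq_b: str, seq_c: str,
                   id_a: str = "a", id_b: str = "b", id_c: str = "c"
                   ) -> DivergenceRecord:
    """Full decomposition for one (copy a, copy b, outgroup c) triple.

    The three pairwise distances are estimated independently with
    pairwise gap deletion.
    """
    d_ab, f1 = jtt_distance(AlignedPair(id_a, id_b, seq_a, seq_b))
    d_ac, f2 = jtt_distance(AlignedPair(id_a, id_c, seq_a, seq_c))
    d_bc, f3 = jtt_distance(AlignedPair(id_b, id_c, seq_b, seq_c))
    branch_a, branch_b, f4 = three_point_branches(
        DistanceTriple(d_ab, d_ac, d_bc))
    flags = sorted(set(f1) | set(f2) | set(f3) | set(f4))
    asym = normalized_divergence(branch_a, branch_b, "asymmetry")
    if asym is None:
        flags.append("zero_divergence")
    return DivergenceRecord(
        pair_id=pair_id, d_ab=d_ab,
        branch_a=branch_a, branch_b=branch_b,
        asymmetry=asym,
        total=normalized_divergence(branch_a, branch_b, "total"),
        flags=flags)


def read_triples(path) -> dict[str, dict[str, str]]:
    """Read aligned triples from FASTA; ids are '<pair_id>|<role>' with
    role in {a, b, c}."""
    triples: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"record id {rec.id!r} lacks '|role' suffix")
        pair_id, role = rec.id.rsplit("|", 1)
        if role not in ("a", "b", "c"):
            raise ValueError(f"record {rec.id!r}: role must be a, b or c")
        triples.setdefault(pair_id, {})[role] = str(rec.seq)
    return triples


def analyze_fasta(path) -> pd.DataFrame:
    """DivergenceRecord table for every complete triple in a FASTA file.

    Records missing the outgroup still get d_ab; their branch
    decomposition is undefined and flagged.
    """
    rows = []
    for pair_id, seqs in read_triples(path).items():
        if "a" not in seqs or "b" not in seqs:
            logger.warning("pair %s incomplete (needs roles a and b); "
                           "skipped", pair_id)
            continue
        if "c" in seqs:
            rec = analyze_triple(pair_id, seqs["a"], seqs["b"], seqs["c"])
            rows.append((rec.pair_id, rec.d_ab, rec.branch_a, rec.branch_b,
                         rec.asymmetry, rec.total, ";".join(rec.flags)))
        else:
            d_ab, flags = jtt_distance(
                AlignedPair("a", "b", seqs["a"], seqs["b"]))
            rows.append((pair_id, d_ab, np.nan, np.nan, np.nan, d_ab,
                         ";".join(flags + ["no_outgroup"])))
    return pd.DataFrame(rows, columns=[
        "pair", "d_ab", "branch_a", "branch_b", "asymmetry", "total",
        "flags"])
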