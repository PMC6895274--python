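"""Variant impact scores: coupling number, cost of coupling, CE and CS.

CN (coupling number) ranks residues by how many selected couplings touch
them, percentile-normalized to [0, 1] within the protein — 1 marks the most
coupled residue. CC (cost of coupling) measures how evolutionarily rare the
variant's amino-acid pairings with its coupled partners are, as the mean
entropy change

    dS_ij(alpha->gamma) = -ln((n_ij(gamma, beta) + 1) / n_ij(alpha, beta))

over partners j, where n_ij counts amino-acid pairs in the two aligned
columns, alpha/beta are the wild-type residues at i and j, and gamma is the
altered residue. CE = CN x CC is the combined impact score; CS is the
single-column (conservation-only) analog of the same entropy change.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .coupling import CouplingSet, covariation_matrix, select_couplings
from .msa_io import Alignment, ColumnMask, GAP, MsaError, Variant, apply_column_filters

__all__ = [
    "coupling_number",
    "pair_counts",
    "delta_entropy",
    "cost_of_coupling",
    "ce_score",
    "cs_score",
    "score_variants",
    "ResidueCouplingProfile",
    "PairCountTable",
    "VariantScores",
]


class ScoreError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coupling number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueCouplingProfile:
    """Per-residue coupling counts and their percentile-rank CN values."""

    counts: np.ndarray  # int, length L
    cn: np.ndarray      # float in [0, 1], length L

    def coupling_count(self, position: int) -> int:
        return int(self.counts[position - 1])

    def cn_at(self, position: int) -> float:
        return float(self.cn[position - 1])


def coupling_number(cs: CouplingSet, L: int | None = None) -> ResidueCouplingProfile:
    """Percentile-rank CN per residue from the selected couplings.

    Every residue participates (masked or uncoupled residues count 0), and
    CN = (average rank - 1) / (L - 1) with average ranks for ties, so an
    untied most-coupled residue gets CN 1 and an untied least-coupled
    residue gets CN 0.
    """
    if L is None:
        L = cs.L
    if L < 2:
        raise ScoreError("CN percentile rank needs L >= 2")
    counts = np.zeros(L, dtype=np.int64)
    for i, j in cs.pairs:
        counts[i - 1] += 1
        counts[j - 1] += 1
    ranks = rankdata(counts, method="average")
    cn = (ranks - 1.0) / (L - 1.0)
    return ResidueCouplingProfile(counts=counts, cn=cn)


# ---------------------------------------------------------------------------
# pair counts and entropy differences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairCountTable:
    """Amino-acid pair counts n(alpha, beta) for one coupled column pair.

    Only rows with non-gap residues at both columns contribute, so
    N = sum of all counts = number of contributing rows; the query row
    always contributes, guaranteeing n(wt_i, wt_j) >= 1.
    """

    i: int
    j: int
    counts: dict[tuple[str, str], int]

    @property
    def N(self) -> int:
        return sum(self.counts.values())

    def n(self, a: str, b: str) -> int:
        return self.counts.get((a, b), 0)


def pair_counts(aln: Alignment, i: int, j: int, cs: CouplingSet | None = None) -> PairCountTable:
    """Tally amino-acid pairs observed at query positions (i, j).

    When a :class:`CouplingSet` is given, (i, j) must be a selected pair.
    """
    if cs is not None:
        key = (min(i, j), max(i, j))
        if key not in {(min(a, b), max(a, b)) for a, b in cs.pairs}:
            raise ScoreError(f"({i}, {j}) is not a selected coupling")
    ci, cj = aln.pos_map[i - 1], aln.pos_map[j - 1]
    tally: Counter[tuple[str, str]] = Counter()
    for row in aln.rows:
        a, b = row[ci], row[cj]
        if a != GAP and b != GAP:
            tally[(a, b)] += 1
    return PairCountTable(i=i, j=j, counts=dict(tally))


def delta_entropy(t: PairCountTable, alpha: str, beta: str, gamma: str) -> float:
    """Entropy change of the pair distribution under alpha->gamma at column i.

    -ln((n(gamma, beta) + 1) / n(alpha, beta)): positive (costly) when the
    variant pairing (gamma, beta) is rarer than the wild-type pairing.
    """
    n_ab = t.n(alpha, beta)
    if n_ab == 0:
        raise ScoreError(
            f"n({alpha},{beta}) = 0 at pair ({t.i},{t.j}): "
            "wild type inconsistent with the alignment"
        )
    return -math.log((t.n(gamma, beta) + 1) / n_ab)


def cost_of_coupling(aln: Alignment, cs: CouplingSet, v: Variant) -> float:
    """Mean entropy change over the variant residue's coupled partners.

    beta is the query (wild-type) residue at each partner column j in C_i;
    a residue with no partners has CC 0 by convention.
    """
    wt = aln.query_residue(v.position)
    if wt != v.wt_aa:
        raise ScoreError(
            f"variant {v} wild type {v.wt_aa} does not match query residue {wt}"
        )
    partners = cs.partner_list(v.position)
    if not partners:
        return 0.0
    total = 0.0
    for j in partners:
        t = pair_counts(aln, v.position, j)
        beta = aln.query_residue(j)
        total += delta_entropy(t, v.wt_aa, beta, v.alt_aa)
    return total / len(partners)


def ce_score(cn: float, cc: float) -> float:
    """CE = CN x CC."""
    if not 0.0 <= cn <= 1.0:
        raise ScoreError(f"CN must be in [0, 1]: {cn}")
    return cn * cc


def cs_score(aln: Alignment, v: Variant) -> float:
    """Single-column conservation score: the entropy change of column i alone.

    -ln((n_i(gamma) + 1) / n_i(alpha)) over the non-gap residues of the
    variant's column — high when the column is conserved for the wild type
    and the altered residue is rarely or never observed.
    """
    wt = aln.query_residue(v.position)
    if wt != v.wt_aa:
        raise ScoreError(
            f"variant {v} wild type {v.wt_aa} does not match query residue {wt}"
        )
    col = aln.column(v.position)
    tally = Counter(ch for ch in col if ch != GAP)
    n_alpha = tally.get(v.wt_aa, 0)
    if n_alpha == 0:
        raise ScoreError(f"wild-type residue absent from column {v.position}")
    return -math.log((tally.get(v.alt_aa, 0) + 1) / n_alpha)


# ---------------------------------------------------------------------------
# batch scoring pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantScores:
    """Scores for one variant. CE = CN x CC exactly; flags mark degenerate
    sites (masked column, no coupled partners) or per-variant errors."""

    variant: Variant
    coupling_count: int
    n_partners: int
    CN: float
    CC: float
    CE: float
    CS: float | None = None
    flags: tuple[str, ...] = field(default=())


def score_variants(
    aln: Alignment,
    variants: list[Variant],
    multiplier: float = 2,
    max_gap_frac: float = 0.2,
    min_seq_pairs: int = 10,
    with_cs: bool = False,
) -> list[VariantScores]:
    """Score a batch of variants on one alignment.

    The column mask, covariation matrix, coupling set and CN profile are
    computed once; each variant then gets CN, CC, CE (and CS on request).
    Per-variant failures (e.g. a wild type that contradicts the query) are
    reported via an ``error:`` flag with NaN scores instead of aborting the
    batch. Deterministic: no randomness anywhere in the pipeline.
    """
    mask = apply_column_filters(aln, max_gap_frac=max_gap_frac)
    cov = covariation_matrix(aln, mask, min_seq_pairs=min_seq_pairs)
    cs = select_couplings(cov, L=aln.L, multiplier=multiplier)
    profile = coupling_number(cs, L=aln.L)

    out: list[VariantScores] = []
    for v in variants:
        try:
            if v.position > aln.L:
                raise ScoreError(
                    f"variant position {v.position} beyond query length {aln.L}"
                )
            flags: list[str] = []
            if not mask.is_retained(v.position):
                flags.append("masked_site")
            partners = cs.partner_list(v.position)
            if not partners:
                flags.append("no_partners")
            cn = profile.cn_at(v.position)
            cc = cost_of_coupling(aln, cs, v)
            ce = ce_score(cn, cc)
            s = cs_score(aln, v) if with_cs else None
            out.append(
                VariantScores(
                    variant=v,
                    coupling_count=profile.coupling_count(v.position),
                    n_partners=len(partners),
                    CN=cn, CC=cc, CE=ce, CS=s,
                    flags=tuple(flags),
                )
            )
        except (ScoreError, MsaError) as exc:
            out.append(
                VariantScores(
                    variant=v, coupling_count=0, n_partners=0,
                    CN=float("nan"), CC=float("nan"), CE=float("nan"),
                    CS=None, flags=(f"error:{exc}",),
                )
            )
    return out


def scores_to_rows(results: list[VariantScores], protein_id: str = "") -> list[dict]:
    """Flatten VariantScores into TSV-ready dict rows."""
    rows = []
    for r in results:
        rows.append({
            "protein_id": r.variant.protein_id or protein_id,
            "variant": str(r.variant),
            "position": r.variant.position,
            "wt": r.variant.wt_aa,
            "alt": r.variant.alt_aa,
            "coupling_count": r.coupling_count,
            "n_partners": r.n_partners,
            "CN": r.CN,
            "CC": r.CC,
            "CE": r.CE,
            "CS": "" if r.CS is None else r.CS,
            "flags": ",".join(r.flags),
        })
    return rows
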