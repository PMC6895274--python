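"""Alignment and variant input, query anchoring, and filtering.

Reads query-anchored protein multiple sequence alignments (aligned FASTA,
A2M, Stockholm), maps alignment columns to 1-based query residue positions,
and applies the column and homolog filters used upstream of covariation
analysis: columns with more than ``max_gap_frac`` gaps or with a completely
conserved residue are masked, homologs nearly identical to the query or of
very different length are discarded, and proteins with too few homologs are
flagged as unsuitable for coupling analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner

logger = logging.getLogger("cescore")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
GAP = "-"

#: characters normalized to the canonical gap symbol
_GAP_EQUIVALENT = {"-", "."}

_VARIANT_TOKEN = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MsaError(ValueError):
    """Raised for malformed alignments, variants, or filter parameters."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """A query-anchored protein MSA.

    ``rows`` keep the full original column set (uppercase residues, ``-``
    gaps); ``pos_map[p-1]`` gives the 0-based column index of 1-based query
    position ``p``, skipping columns where the query is gapped, so ``L``
    (the ungapped query length) and all residue coordinates refer to the
    query protein.
    """

    query_id: str
    ids: tuple[str, ...]
    rows: tuple[str, ...]
    pos_map: tuple[int, ...]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def L(self) -> int:
        return len(self.pos_map)

    @property
    def query_index(self) -> int:
        return self.ids.index(self.query_id)

    @property
    def query_row(self) -> str:
        return self.rows[self.query_index]

    def query_residue(self, position: int) -> str:
        """Residue of the query at 1-based position ``position``."""
        if not 1 <= position <= self.L:
            raise MsaError(
                f"position {position} outside query range 1..{self.L}"
            )
        return self.query_row[self.pos_map[position - 1]]

    def column(self, position: int) -> str:
        """The alignment column (over all rows) at a 1-based query position."""
        c = self.pos_map[position - 1]
        return "".join(row[c] for row in self.rows)

    def query_sequence(self) -> str:
        """Ungapped query sequence, reconstructed through ``pos_map``."""
        q = self.query_row
        return "".join(q[c] for c in self.pos_map)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise MsaError("fewer than 2 sequences in alignment")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise MsaError("ragged alignment: rows differ in length")
        if self.ids.count(self.query_id) != 1:
            raise MsaError(f"query id {self.query_id!r} not unique/present")
        if len(self.pos_map) < 1:
            raise MsaError("query has no residues")
        if list(self.pos_map) != sorted(set(self.pos_map)):
            raise MsaError("pos_map must be strictly increasing")


# column status flags
RETAINED = "retained"
MASKED_GAP = "masked_gap"
MASKED_INVARIANT = "masked_invariant"


@dataclass(frozen=True)
class ColumnMask:
    """Per query-position filter status for covariation analysis."""

    status: tuple[str, ...]
    gap_fraction: tuple[float, ...]
    max_gap_frac: float

    def retained_positions(self) -> list[int]:
        """1-based query positions usable for covariation."""
        return [p + 1 for p, s in enumerate(self.status) if s == RETAINED]

    def is_retained(self, position: int) -> bool:
        return self.status[position - 1] == RETAINED


@dataclass(frozen=True)
class Variant:
    """A single amino-acid substitution in 1-based query coordinates."""

    position: int
    wt_aa: str
    alt_aa: str
    protein_id: str = ""

    def __post_init__(self) -> None:
        for aa in (self.wt_aa, self.alt_aa):
            if aa not in AA_SET:
                raise MsaError(f"non-standard residue {aa!r} in variant")
        if self.wt_aa == self.alt_aa:
            raise MsaError(
                f"wild type equals alternate in {self.wt_aa}{self.position}{self.alt_aa}"
            )
        if self.position < 1:
            raise MsaError(f"variant position {self.position} < 1")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.alt_aa}"


@dataclass
class HomologFilterResult:
    """Survivors of homolog filtering plus a sufficiency flag.

    ``sufficient`` is False when fewer than ``min_n`` homologs remain, the
    condition under which a protein is excluded from coupling analysis.
    """

    kept: list[tuple[str, str]]
    removed: list[tuple[str, str]] = field(default_factory=list)
    min_n: int = 10

    @property
    def sufficient(self) -> bool:
        return len(self.kept) >= self.min_n


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_FORMAT_BY_EXT = {
    ".fasta": "fasta", ".fa": "fasta", ".afa": "fasta", ".mfa": "fasta",
    ".a2m": "a2m",
    ".sto": "stockholm", ".stk": "stockholm", ".stockholm": "stockholm",
}


def _detect_format(path: Path) -> str:
    fmt = _FORMAT_BY_EXT.get(path.suffix.lower())
    if fmt is None:
        return "fasta"
    return fmt


def _normalize_row(seq: str, fmt: str) -> str:
    """Normalize one aligned row to uppercase residues and '-' gaps.

    A2M insert states (lowercase, '.') are gap-equivalent: their columns are
    only informative where the query also has an insert, and such columns
    are dropped by query anchoring. Plain FASTA / Stockholm lowercase is
    just case-insensitive residue text.
    """
    out = []
    for ch in seq:
        if ch in _GAP_EQUIVALENT:
            out.append(GAP)
        elif ch.islower():
            out.append(GAP if fmt == "a2m" else ch.upper())
        else:
            out.append(ch)
    row = "".join(out)
    bad = set(row) - AA_SET - {GAP}
    if bad:
        raise MsaError(f"invalid residue character(s) {sorted(bad)} in alignment")
    return row


def read_alignment(
    path: str | Path,
    format: str | None = None,
    query_id: str | None = None,
) -> Alignment:
    """Read an aligned FASTA / A2M / Stockholm file into an :class:`Alignment`.

    The query defaults to the first record. Columns where the query is
    gapped are excluded from ``pos_map`` (the stored rows keep all columns),
    so every downstream coordinate is a 1-based query residue index.
    """
    path = Path(path)
    if not path.exists():
        raise MsaError(f"no such file: {path}")
    fmt = format or _detect_format(path)
    if fmt not in {"fasta", "a2m", "stockholm"}:
        raise MsaError(f"unsupported alignment format {fmt!r}")
    parser_fmt = "fasta" if fmt == "a2m" else fmt
    try:
        records = list(SeqIO.parse(str(path), parser_fmt))
    except Exception as exc:  # Bio raises assorted parse errors
        raise MsaError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not records:
        raise MsaError(f"empty alignment file: {path}")
    if len(records) < 2:
        raise MsaError("fewer than 2 sequences in alignment")
    ids = tuple(r.id for r in records)
    rows = tuple(_normalize_row(str(r.seq), fmt) for r in records)
    qid = query_id if query_id is not None else ids[0]
    return from_rows(ids, rows, qid)


def from_rows(
    ids: Sequence[str], rows: Sequence[str], query_id: str
) -> Alignment:
    """Build a query-anchored Alignment from pre-normalized rows."""
    ids = tuple(ids)
    rows = tuple(rows)
    if query_id not in ids:
        raise MsaError(f"query id {query_id!r} absent from alignment")
    qrow = rows[ids.index(query_id)]
    pos_map = tuple(c for c, ch in enumerate(qrow) if ch != GAP)
    return Alignment(query_id=query_id, ids=ids, rows=rows, pos_map=pos_map)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write the alignment back to aligned FASTA (full column set)."""
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_column_filters(aln: Alignment, max_gap_frac: float = 0.2) -> ColumnMask:
    """Mask query positions unusable for covariation.

    A column is ``masked_gap`` when its gap fraction exceeds
    ``max_gap_frac`` (strict), and ``masked_invariant`` when every non-gap
    residue is identical; remaining columns are ``retained``.
    """
    if not 0 <= max_gap_frac < 1:
        raise MsaError(f"max_gap_frac must be in [0, 1): {max_gap_frac}")
    status: list[str] = []
    gapfrac: list[float] = []
    n = aln.n_rows
    for p in range(1, aln.L + 1):
        col = aln.column(p)
        gf = col.count(GAP) / n
        gapfrac.append(gf)
        if gf > max_gap_frac:
            status.append(MASKED_GAP)
            continue
        residues = {ch for ch in col if ch != GAP}
        status.append(MASKED_INVARIANT if len(residues) <= 1 else RETAINED)
    return ColumnMask(
        status=tuple(status),
        gap_fraction=tuple(gapfrac),
        max_gap_frac=max_gap_frac,
    )


def write_mask_report(aln: Alignment, mask: ColumnMask, path: str | Path) -> None:
    """TSV report: position, column, gap_fraction, status."""
    with open(path, "w") as fh:
        fh.write("position\tcolumn\tgap_fraction\tstatus\n")
        for p in range(1, aln.L + 1):
            fh.write(
                f"{p}\t{aln.pos_map[p - 1]}\t"
                f"{mask.gap_fraction[p - 1]:.4f}\t{mask.status[p - 1]}\n"
            )


def _pairwise_identity(candidate: str, query: str) -> float:
    """Fraction of identical aligned residues under a simple global alignment,
    normalized by the length of the shorter sequence."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(candidate, query)[0]
    a, b = str(alignment[0]), str(alignment[1])
    matches = sum(x == y and x != GAP for x, y in zip(a, b))
    return matches / min(len(candidate), len(query))


def filter_homologs(
    seqs: Iterable[tuple[str, str]] | dict[str, str],
    query: str,
    max_identity: float = 0.90,
    len_lo: float = 0.7,
    len_hi: float = 1.3,
    min_n: int = 10,
) -> HomologFilterResult:
    """Apply homolog quality filters to an unaligned sequence set.

    Retains sequences with identity to the query strictly below
    ``max_identity`` and length within ``[len_lo, len_hi]`` times the query
    length (inclusive). Returns a result whose ``sufficient`` flag is False
    when fewer than ``min_n`` sequences survive — such proteins are excluded
    from coupling analysis rather than silently scored.
    """
    if not query:
        raise MsaError("empty query sequence")
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise MsaError("empty homolog set")
    kept, removed = [], []
    qlen = len(query)
    for sid, seq in items:
        ratio = len(seq) / qlen
        if not len_lo <= ratio <= len_hi:
            removed.append((sid, seq))
            continue
        if _pairwise_identity(seq, query) >= max_identity:
            removed.append((sid, seq))
            continue
        kept.append((sid, seq))
    result = HomologFilterResult(kept=kept, removed=removed, min_n=min_n)
    if not result.sufficient:
        logger.warning(
            "insufficient homologs: %d survivors < %d required; "
            "protein should be excluded from coupling analysis",
            len(kept), min_n,
        )
    return result


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def parse_variant_token(token: str, protein_id: str = "") -> Variant:
    """Parse a token like ``K329E`` into a :class:`Variant`."""
    m = _VARIANT_TOKEN.match(token.strip())
    if not m:
        raise MsaError(f"malformed variant token {token!r}")
    wt, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return Variant(position=pos, wt_aa=wt, alt_aa=alt, protein_id=protein_id)


def parse_variants(path: str | Path) -> list[Variant]:
    """Read variants from a token list (one ``K329E`` per line) or a
    3-column TSV ``position<TAB>wt<TAB>alt`` (header optional).

    Duplicates are preserved in input order.
    """
    path = Path(path)
    if not path.exists():
        raise MsaError(f"no such file: {path}")
    variants: list[Variant] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 3:
                pos_s, wt, alt = fields[0], fields[1], fields[2]
                if lineno == 1 and not pos_s.isdigit():
                    continue  # header row
                try:
                    pos = int(pos_s)
                except ValueError as exc:
                    raise MsaError(
                        f"line {lineno}: non-integer position {pos_s!r}"
                    ) from exc
                variants.append(
                    Variant(position=pos, wt_aa=wt.upper(), alt_aa=alt.upper())
                )
            else:
                variants.append(parse_variant_token(fields[0]))
    if not variants:
        raise MsaError(f"no variants found in {path}")
    return variants
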