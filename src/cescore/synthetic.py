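"""Synthetic coevolving alignments and labeled variant sets.

The MSA generator plants compensatory column pairs — each sequence draws a
joint amino-acid state (e.g. A-K or S-E) with mixing weight ``w``, and two
independent residues otherwise — alongside conserved columns (one dominant
residue at a stated frequency) and background columns drawn uniformly from
a 4-letter per-column sub-alphabet (small alphabets keep pair-count tables
dense at desk-scale N). Gaps are sprinkled per column at ``gap_rate``,
never in the query row; the query is always the first, gap-free row. All
randomness flows from one integer seed through a named generator.

The labeled-variant generator produces a balanced two-class set with one
informative Gaussian score (positive-class mean shifted by ``effect_size``)
and one pure-noise score, for exercising the evaluation stack; its expected
AUC has the closed form Phi(effect_size / (noise_sd * sqrt(2))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa_io import AMINO_ACIDS, Alignment, GAP, from_rows

__all__ = [
    "SyntheticMsaSpec",
    "PlantedPair",
    "ConservedColumn",
    "GroundTruth",
    "generate_coupled_msa",
    "generate_labeled_dataset",
]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedPair:
    """A covarying column pair: 1-based positions and compatible joint states."""

    i: int
    j: int
    states: tuple[tuple[str, str], ...] = (("A", "K"), ("S", "E"))
    w: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise SyntheticError(f"mixing weight w must be in [0, 1]: {self.w}")
        if self.i == self.j:
            raise SyntheticError("planted pair positions must differ")
        if len(self.states) < 2:
            raise SyntheticError("need >= 2 compatible joint states")


@dataclass(frozen=True)
class ConservedColumn:
    position: int
    residue: str = "W"
    frequency: float = 0.95


@dataclass(frozen=True)
class SyntheticMsaSpec:
    """Parameters of one synthetic alignment."""

    L: int = 50
    N: int = 200
    planted_pairs: tuple[PlantedPair, ...] = ()
    conserved_columns: tuple[ConservedColumn, ...] = ()
    gap_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2 or self.N < 2:
            raise SyntheticError("need L >= 2 and N >= 2")
        if not 0.0 <= self.gap_rate <= 0.5:
            raise SyntheticError(f"gap_rate must be in [0, 0.5]: {self.gap_rate}")
        roles: list[int] = []
        for p in self.planted_pairs:
            roles.extend((p.i, p.j))
        for c in self.conserved_columns:
            roles.append(c.position)
        if any(not 1 <= p <= self.L for p in roles):
            raise SyntheticError("column role outside 1..L")
        if len(roles) != len(set(roles)):
            raise SyntheticError("overlapping column roles in spec")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted where, for downstream recovery tests."""

    planted_pairs: tuple[tuple[int, int], ...]
    category: dict[int, str] = field(default_factory=dict)  # position -> role
    states: dict[tuple[int, int], tuple[tuple[str, str], ...]] = field(
        default_factory=dict
    )


def default_spec(
    L: int = 50,
    N: int = 200,
    n_pairs: int = 3,
    w: float = 0.9,
    gap_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticMsaSpec:
    """Convenience spec: ``n_pairs`` planted pairs at fixed spread positions
    plus two conserved columns."""
    state_menu = (
        (("A", "K"), ("S", "E")),
        (("L", "R"), ("F", "D")),
        (("V", "H"), ("T", "N")),
        (("I", "Q"), ("M", "G")),
    )
    pairs = []
    step = max(4, L // max(n_pairs, 1))
    for k in range(n_pairs):
        i = 2 + k * step
        j = i + step // 2
        if j > L - 2:
            raise SyntheticError("too many planted pairs for this L")
        pairs.append(PlantedPair(i=i, j=j, states=state_menu[k % len(state_menu)], w=w))
    conserved = (
        ConservedColumn(position=1, residue="W", frequency=0.95),
        ConservedColumn(position=L, residue="C", frequency=0.95),
    )
    return SyntheticMsaSpec(
        L=L, N=N, planted_pairs=tuple(pairs),
        conserved_columns=conserved, gap_rate=gap_rate, seed=seed,
    )


def generate_coupled_msa(spec: SyntheticMsaSpec) -> tuple[Alignment, GroundTruth]:
    """Generate one alignment plus its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    L, N = spec.L, spec.N
    cols = np.empty((L, N), dtype="<U1")
    category: dict[int, str] = {}

    planted_positions = set()
    for p in spec.planted_pairs:
        planted_positions.update((p.i, p.j))
        category[p.i] = category[p.j] = "planted"
    for c in spec.conserved_columns:
        category[c.position] = "conserved"
    for pos in range(1, L + 1):
        category.setdefault(pos, "background")

    # planted pairs: joint compatible state with prob w, else independent
    # draws from each side's marginal alphabet
    for p in spec.planted_pairs:
        states = p.states
        side_i = sorted({s[0] for s in states})
        side_j = sorted({s[1] for s in states})
        joint = rng.random(N) < p.w
        state_idx = rng.integers(len(states), size=N)
        ci = np.empty(N, dtype="<U1")
        cj = np.empty(N, dtype="<U1")
        for r in range(N):
            if joint[r]:
                ci[r], cj[r] = states[state_idx[r]]
            else:
                ci[r] = side_i[rng.integers(len(side_i))]
                cj[r] = side_j[rng.integers(len(side_j))]
        # query row must carry a compatible state
        if not joint[0]:
            ci[0], cj[0] = states[state_idx[0]]
        cols[p.i - 1], cols[p.j - 1] = ci, cj

    for c in spec.conserved_columns:
        alternates = [x for x in AMINO_ACIDS if x != c.residue][:3]
        dominant = rng.random(N) < c.frequency
        alt_pick = rng.integers(len(alternates), size=N)
        col = np.where(dominant, c.residue, np.array(alternates)[alt_pick])
        col[0] = c.residue
        cols[c.position - 1] = col

    for pos in range(1, L + 1):
        if category[pos] != "background":
            continue
        sub = aa[rng.choice(20, size=4, replace=False)]
        cols[pos - 1] = sub[rng.integers(4, size=N)]

    # gaps per column, never in the query row
    if spec.gap_rate > 0:
        gap_draw = rng.random((L, N)) < spec.gap_rate
        gap_draw[:, 0] = False
        cols[gap_draw] = GAP

    rows = ["".join(cols[:, r]) for r in range(N)]
    ids = ["query"] + [f"seq{r}" for r in range(1, N)]
    aln = from_rows(ids, rows, "query")
    truth = GroundTruth(
        planted_pairs=tuple((p.i, p.j) for p in spec.planted_pairs),
        category=category,
        states={(p.i, p.j): p.states for p in spec.planted_pairs},
    )
    return aln, truth


def generate_labeled_dataset(
    n: int,
    effect_size: float,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced labeled variants with one informative and one noise score.

    Positives' ``informative`` score is Gaussian with mean ``effect_size``
    (negatives: mean 0), both with SD ``noise_sd``; ``noise`` is standard
    Gaussian for both classes. Expected informative-score AUC is
    Phi(effect_size / (noise_sd * sqrt(2))).
    """
    if n < 10:
        raise SyntheticError("need n >= 10")
    if noise_sd <= 0:
        raise SyntheticError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    informative = rng.normal(0.0, noise_sd, size=n) + effect_size * labels
    noise = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame(
        {"label": labels, "informative": informative, "noise": noise}
    )
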