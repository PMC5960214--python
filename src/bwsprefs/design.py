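"""Balanced incomplete block designs (BIBDs) for best-worst scaling.

A BIBD with parameters (v, b, r, k, λ) arranges v outcomes into b blocks
(scenarios) of k outcomes such that every outcome appears in exactly r
blocks and every unordered pair of outcomes co-occurs in exactly λ blocks.
The two counting identities b·k = v·r and λ·(v−1) = r·(k−1) are necessary
for existence.

Designs here are built by cyclic development of a perfect difference set:
a set D of k residues mod v whose pairwise differences hit every nonzero
residue exactly λ times. The translates D, D+1, …, D+(v−1) (mod v) then
form a symmetric BIBD with b = v and r = k. For the 13-outcome study
design, D = {0, 1, 3, 9} mod 13 gives the (13, 13, 4, 4, 1) design: 13
scenarios of 4 outcomes in which every outcome appears 4 times and every
pair is shown together exactly once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .catalogue import OutcomeCatalogue

__all__ = [
    "BlockDesign",
    "DesignCheck",
    "ValidationReport",
    "NoConstructionError",
    "build_bibd",
    "validate_design",
    "design_to_frame",
    "write_design",
    "read_design",
]


class NoConstructionError(ValueError):
    """Raised when no block-design construction is available for (v, k)."""


#: Perfect difference sets, keyed by (v, k). Developed cyclically mod v.
_DIFFERENCE_SETS: dict[tuple[int, int], tuple[int, ...]] = {
    (7, 3): (0, 1, 3),          # Fano plane, lambda = 1
    (11, 5): (1, 3, 4, 5, 9),   # biplane, lambda = 2
    (13, 4): (0, 1, 3, 9),      # projective plane of order 3, lambda = 1
    (21, 5): (3, 6, 7, 12, 14),  # projective plane of order 4, lambda = 1
}


@dataclass(frozen=True)
class BlockDesign:
    """A block design over outcome *indices* 0..v−1.

    Blocks are stored as frozensets: the within-block presentation order is
    not part of the design (it is randomized per respondent at survey or
    simulation time).
    """

    v: int
    b: int
    r: int
    k: int
    lam: int
    blocks: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(frozenset(bl) for bl in self.blocks))
        if len(self.blocks) != self.b:
            raise ValueError(f"expected {self.b} blocks, got {len(self.blocks)}")
        members = set().union(*self.blocks) if self.blocks else set()
        if not members <= set(range(self.v)):
            raise ValueError("block members must be indices in 0..v-1")

    def sorted_blocks(self) -> list[tuple[int, ...]]:
        """Blocks as sorted tuples, in block order."""
        return [tuple(sorted(bl)) for bl in self.blocks]


@dataclass(frozen=True)
class DesignCheck:
    name: str
    passed: bool
    observed: object
    expected: object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flag = "PASS" if self.passed else "FAIL"
        return f"[{flag}] {self.name}: observed={self.observed} expected={self.expected}"


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[DesignCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[DesignCheck]:
        return [c for c in self.checks if not c.passed]


def build_bibd(v: int, k: int) -> BlockDesign:
    """Construct a BIBD for ``v`` outcomes in blocks of ``k`` by cyclic
    development of a catalogued perfect difference set.

    Raises
    ------
    NoConstructionError
        If (v, k) is not in the difference-set catalogue. The message names
        the admissibility conditions: r = λ(v−1)/(k−1) and b = v·r/k must
        be integers, and a perfect difference set must exist and be known
        to the module.
    """
    key = (v, k)
    if key not in _DIFFERENCE_SETS:
        raise NoConstructionError(
            f"no construction available for (v={v}, k={k}): this module builds "
            f"designs by cyclic development of perfect difference sets, which "
            f"requires lambda = k(k-1)/(v-1) to be a positive integer (so that "
            f"r = lambda*(v-1)/(k-1) and b = v*r/k are integers) and a known "
            f"difference set; supported (v, k): {sorted(_DIFFERENCE_SETS)}"
        )
    base = _DIFFERENCE_SETS[key]
    lam, rem = divmod(k * (k - 1), v - 1)
    if rem != 0:  # catalogue entries all satisfy this; guard against typos
        raise NoConstructionError(f"(v={v}, k={k}) fails lambda*(v-1) = k*(k-1)")
    blocks = tuple(frozenset((d + shift) % v for d in base) for shift in range(v))
    return BlockDesign(v=v, b=v, r=k, k=k, lam=lam, blocks=blocks)


def validate_design(design: BlockDesign) -> ValidationReport:
    """Check a block design against the BIBD invariants.

    Failures are reported, not raised, so hand-supplied designs can be
    audited. Checks: block sizes, per-outcome replication, per-pair
    concurrence, and the two counting identities.
    """
    if not design.blocks:
        raise ValueError("design has no blocks")
    checks: list[DesignCheck] = []

    sizes = {i: len(bl) for i, bl in enumerate(design.blocks)}
    bad_sizes = {i: s for i, s in sizes.items() if s != design.k}
    checks.append(DesignCheck("block_sizes", not bad_sizes, bad_sizes or design.k, design.k))

    rep = {t: 0 for t in range(design.v)}
    for bl in design.blocks:
        for t in bl:
            rep[t] += 1
    bad_rep = {t: c for t, c in rep.items() if c != design.r}
    checks.append(DesignCheck("replication", not bad_rep, bad_rep or design.r, design.r))

    conc = {pair: 0 for pair in itertools.combinations(range(design.v), 2)}
    for bl in design.blocks:
        for pair in itertools.combinations(sorted(bl), 2):
            conc[pair] += 1
    bad_conc = {p: c for p, c in conc.items() if c != design.lam}
    checks.append(DesignCheck("pair_concurrence", not bad_conc, bad_conc or design.lam, design.lam))

    checks.append(
        DesignCheck(
            "identity_bk_eq_vr",
            design.b * design.k == design.v * design.r,
            design.b * design.k,
            design.v * design.r,
        )
    )
    checks.append(
        DesignCheck(
            "identity_lambda",
            design.lam * (design.v - 1) == design.r * (design.k - 1),
            design.lam * (design.v - 1),
            design.r * (design.k - 1),
        )
    )
    return ValidationReport(tuple(checks))


def design_to_frame(design: BlockDesign, catalogue: OutcomeCatalogue) -> pd.DataFrame:
    """Long-format design table: one row per (scenario, outcome).

    Scenario ids are 1-based in all user-facing files.
    """
    if design.v != len(catalogue):
        raise ValueError("design size does not match catalogue")
    rows = [
        {"scenario_id": i + 1, "outcome_id": catalogue.outcomes[t]}
        for i, bl in enumerate(design.sorted_blocks())
        for t in bl
    ]
    return pd.DataFrame(rows, columns=["scenario_id", "outcome_id"])


def write_design(design: BlockDesign, catalogue: OutcomeCatalogue, path: str | Path) -> None:
    design_to_frame(design, catalogue).to_csv(path, index=False)


def read_design(path: str | Path, catalogue: OutcomeCatalogue) -> BlockDesign:
    """Read a long-format design CSV back into a :class:`BlockDesign`.

    Design parameters (r, λ) are recomputed from the blocks, so a
    hand-edited file can be audited afterwards with
    :func:`validate_design`.
    """
    frame = pd.read_csv(path)
    if not {"scenario_id", "outcome_id"} <= set(frame.columns):
        raise ValueError("design CSV needs scenario_id and outcome_id columns")
    unknown = set(frame["outcome_id"]) - set(catalogue.outcomes)
    if unknown:
        raise ValueError(f"design CSV has outcomes not in catalogue: {sorted(unknown)}")
    blocks = [
        frozenset(catalogue.index(o) for o in grp["outcome_id"])
        for _, grp in frame.groupby("scenario_id", sort=True)
    ]
    v = len(catalogue)
    b = len(blocks)
    sizes = {len(bl) for bl in blocks}
    k = sizes.pop() if len(sizes) == 1 else max(len(bl) for bl in blocks)
    rep_counts = pd.Series([t for bl in blocks for t in bl]).value_counts()
    r = int(rep_counts.iloc[0])
    pair_counts: dict[tuple[int, int], int] = {}
    for bl in blocks:
        for pair in itertools.combinations(sorted(bl), 2):
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
    lam = max(pair_counts.values()) if pair_counts else 0
    return BlockDesign(v=v, b=b, r=r, k=k, lam=lam, blocks=tuple(blocks))
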