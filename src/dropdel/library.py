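"""Combinatorial library construction and Poisson aliquot sampling.

A split-and-pool encoded library is defined by an ordered list of synthesis
cycles, each offering a set of building blocks.  Diversity is multiplicative:
a 2-cycle design with 3 building blocks per cycle enumerates 9 distinct
members.  Screening consumes a bead *aliquot* whose size is most naturally
expressed in library equivalents (``epsilon``): one equivalent is a number of
beads equal to the library diversity.  Under sampling with replacement from a
large bead pool, the number of replicate beads carrying any given member (its
*k class*) is Poisson distributed with mean ``epsilon``, which makes library
coverage a closed-form quantity (:func:`coverage_at_k`).
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import InvalidDesignError

__all__ = [
    "BuildingBlock",
    "LibraryDesign",
    "Bead",
    "BeadAliquot",
    "diversity",
    "sample_aliquot",
    "coverage_at_k",
    "k_class_histogram",
]

#: Default compound loading per bead, femtomole.  A 10 um synthesis resin
#: particle carries on the order of 100 fmol of a single library member.
DEFAULT_LOADING_FMOL = 100.0


@dataclass(frozen=True)
class BuildingBlock:
    """A single building block: an identifier and an optional monoisotopic mass."""

    id: str
    mass: float | None = None


@dataclass(frozen=True)
class LibraryDesign:
    """A split-and-pool synthesis plan: ordered cycles of building-block sets.

    Parameters
    ----------
    cycles
        One tuple of :class:`BuildingBlock` per synthesis cycle, in synthesis
        order.  Every cycle must be non-empty and identifiers must be unique
        within a cycle.
    tag_scheme_ref
        Optional identifier of the DNA encoding scheme paired with the design.
    name
        Human-readable label, used in file headers.
    """

    cycles: tuple[tuple[BuildingBlock, ...], ...]
    tag_scheme_ref: str | None = None
    name: str = "library"

    def __post_init__(self) -> None:
        if len(self.cycles) == 0:
            raise InvalidDesignError("design must have at least one cycle")
        for c, blocks in enumerate(self.cycles):
            if len(blocks) == 0:
                raise InvalidDesignError(f"cycle {c} has no building blocks")
            ids = [b.id for b in blocks]
            if len(set(ids)) != len(ids):
                raise InvalidDesignError(
                    f"duplicate building-block identifiers in cycle {c}"
                )

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_lists(
        cls,
        cycles: Sequence[Sequence[str | Mapping]],
        tag_scheme_ref: str | None = None,
        name: str = "library",
    ) -> "LibraryDesign":
        """Build a design from plain lists of block ids (or ``{id, mass}`` maps)."""
        parsed = []
        for blocks in cycles:
            row = []
            for b in blocks:
                if isinstance(b, Mapping):
                    row.append(BuildingBlock(str(b["id"]), b.get("mass")))
                else:
                    row.append(BuildingBlock(str(b)))
            parsed.append(tuple(row))
        return cls(tuple(parsed), tag_scheme_ref=tag_scheme_ref, name=name)

    # -- basic accounting ----------------------------------------------------

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def cycle_sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.cycles)

    def diversity(self) -> int:
        """Number of distinct members: the product of per-cycle block counts."""
        n = 1
        for size in self.cycle_sizes:
            n *= size
        return n

    # -- member index <-> building blocks ------------------------------------
    # Members are indexed 0..diversity-1 in mixed radix over the cycles with
    # cycle 1 most significant, so the mapping is bijective and trivially
    # invertible during tag decoding.

    def member_to_blocks(self, member_index: int) -> tuple[int, ...]:
        """Per-cycle building-block indices of a member (cycle 1 first)."""
        if not 0 <= member_index < self.diversity():
            raise IndexError(f"member index {member_index} out of range")
        digits = []
        rem = member_index
        for size in reversed(self.cycle_sizes):
            digits.append(rem % size)
            rem //= size
        return tuple(reversed(digits))

    def blocks_to_member(self, blocks: Sequence[int]) -> int:
        """Inverse of :meth:`member_to_blocks`."""
        if len(blocks) != self.n_cycles:
            raise ValueError("one block index per cycle required")
        idx = 0
        for b, size in zip(blocks, self.cycle_sizes):
            if not 0 <= b < size:
                raise IndexError(f"block index {b} out of range for cycle size {size}")
            idx = idx * size + b
        return idx

    def member_block_ids(self, member_index: int) -> tuple[str, ...]:
        return tuple(
            self.cycles[c][b].id
            for c, b in enumerate(self.member_to_blocks(member_index))
        )

    # -- plain-text round trip -----------------------------------------------

    def to_dict(self) -> dict:
        cycles: list[list] = []
        for blocks in self.cycles:
            if any(b.mass is not None for b in blocks):
                cycles.append([{"id": b.id, "mass": b.mass} for b in blocks])
            else:
                cycles.append([b.id for b in blocks])
        out = {"name": self.name, "cycles": cycles}
        if self.tag_scheme_ref is not None:
            out["tag_scheme"] = self.tag_scheme_ref
        return out

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "LibraryDesign":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(io.StringIO(text))
        if not isinstance(data, Mapping) or "cycles" not in data:
            raise InvalidDesignError("design file must define 'cycles'")
        return cls.from_lists(
            data["cycles"],
            tag_scheme_ref=data.get("tag_scheme"),
            name=data.get("name", "library"),
        )


@dataclass
class Bead:
    """One synthesis bead: many copies of a single member plus its DNA tag."""

    member_index: int
    tag: str | None = None
    loading_fmol: float = DEFAULT_LOADING_FMOL

    def __post_init__(self) -> None:
        if self.loading_fmol <= 0:
            raise ValueError("bead loading must be positive")


@dataclass
class BeadAliquot:
    """A multiset of beads drawn from a design at ``epsilon`` equivalents.

    ``counts`` maps member index to its replicate count (k class); members
    absent from the mapping have k = 0.
    """

    design: LibraryDesign
    epsilon: float
    counts: dict[int, int] = field(default_factory=dict)
    seed: int | None = None

    @property
    def total_beads(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def expected_total(self) -> float:
        """Expected bead count, epsilon times diversity."""
        return self.epsilon * self.design.diversity()

    def count(self, member_index: int) -> int:
        return self.counts.get(member_index, 0)

    def bead_members(self) -> np.ndarray:
        """Member index of every bead in the aliquot (one entry per bead)."""
        if not self.counts:
            return np.empty(0, dtype=np.int64)
        members = np.fromiter(self.counts.keys(), dtype=np.int64, count=len(self.counts))
        reps = np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))
        return np.repeat(members, reps)

    def to_frame(self) -> pd.DataFrame:
        members = sorted(self.counts)
        return pd.DataFrame(
            {"member_index": members, "k": [self.counts[m] for m in members]}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, design: LibraryDesign, epsilon: float = float("nan")
    ) -> "BeadAliquot":
        df = pd.read_csv(path, sep="\t")
        counts = dict(
            zip(df["member_index"].astype(int), df["k"].astype(int))
        )
        return cls(design=design, epsilon=epsilon, counts=counts)


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------


def diversity(design: LibraryDesign) -> int:
    """Distinct members enumerated by a split-and-pool design."""
    return design.diversity()


def sample_aliquot(design: LibraryDesign, epsilon: float, seed: int = 0) -> BeadAliquot:
    """Sample a bead aliquot of ``epsilon`` library equivalents.

    Each member's replicate count is an independent Poisson(``epsilon``) draw,
    the infinite-pool limit of picking beads with replacement.  The expected
    total is ``epsilon * diversity`` (2 equivalents of a 100000-member library
    is 200000 beads in expectation).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    rng = np.random.default_rng(seed)
    n = design.diversity()
    ks = rng.poisson(epsilon, n)
    nonzero = np.nonzero(ks)[0]
    counts = {int(m): int(ks[m]) for m in nonzero}
    return BeadAliquot(design=design, epsilon=float(epsilon), counts=counts, seed=seed)


def coverage_at_k(epsilon, k):
    """Fraction of the library present on at least ``k`` replicate beads.

    The cumulative Poisson survival function
    ``1 - sum_{i<k} exp(-eps) eps^i / i!``; equals 1 at k = 0 for any aliquot.
    Accepts scalars or arrays and broadcasts.
    """
    eps = np.asarray(epsilon, dtype=float)
    kk = np.asarray(k)
    if np.any(eps < 0):
        raise ValueError("epsilon must be nonnegative")
    if np.any(kk < 0):
        raise ValueError("k must be nonnegative")
    out = stats.poisson.sf(kk - 1, eps)
    if np.isscalar(epsilon) and np.isscalar(k):
        return float(out)
    return out


def k_class_histogram(aliquot: BeadAliquot) -> dict[int, int]:
    """Number of members at each replicate count k, including the k = 0 class.

    Totals are conserved: the histogram sums to the design diversity and the
    k-weighted sum equals the aliquot's bead count.
    """
    hist = Counter(aliquot.counts.values())
    hist[0] = aliquot.design.diversity() - len(aliquot.counts)
    return {k: int(hist[k]) for k in sorted(hist)}
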