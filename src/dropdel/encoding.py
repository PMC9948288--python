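"""DNA tag encoding and error-tolerant decoding of library members.

Each bead carries a tag of the form::

    headpiece + opening_primer + codon_cycle1 + ... + codon_cycleC + closing_primer

The headpiece and the two primer binding sites are shared among all members
and carry no information; member identity lives entirely in the per-cycle
codons.  Codebooks are built with a guaranteed minimum pairwise Hamming
distance ``d`` so that nearest-codon decoding corrects up to ``(d - 1) // 2``
substitutions per codon.  Reads are modeled substitution-only, which keeps
the codon region at fixed offsets and decoding exact.

The headpiece and primer defaults below are documented placeholder sequences
for simulation; real platforms use proprietary constructs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CapacityError
from .library import Bead, LibraryDesign

__all__ = [
    "TagScheme",
    "TagRead",
    "DecodeResult",
    "build_scheme",
    "encode",
    "decode",
    "decode_reads",
    "tag_beads",
    "simulate_reads",
    "write_fastq",
    "write_fasta",
    "read_fastq",
    "read_fasta",
]

BASES = "ACGT"

#: Placeholder constant regions (synthetic; no information content).
DEFAULT_HEADPIECE = "GGAGCTTGTGAATTCTGG"
DEFAULT_OPENING_PRIMER = "ACGTCAGGTTCAG"
DEFAULT_CLOSING_PRIMER = "CTGAACCTGTCGA"


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings ('N' mismatches everything)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y or x == "N" for x, y in zip(a, b))


@dataclass(frozen=True)
class TagScheme:
    """Tag layout plus per-cycle codon codebooks with a distance guarantee."""

    headpiece: str
    opening_primer: str
    closing_primer: str
    codon_length: int
    codebooks: tuple[tuple[str, ...], ...]
    min_hamming: int

    def __post_init__(self) -> None:
        for cyc, book in enumerate(self.codebooks):
            for codon in book:
                if len(codon) != self.codon_length:
                    raise ValueError(f"codon {codon!r} in cycle {cyc} has wrong length")
            for a, b in itertools.combinations(book, 2):
                if hamming(a, b) < self.min_hamming:
                    raise ValueError(
                        f"codons {a!r}/{b!r} in cycle {cyc} violate min_hamming"
                    )

    @property
    def n_cycles(self) -> int:
        return len(self.codebooks)

    @property
    def codon_offset(self) -> int:
        """Offset of the first codon within a read."""
        return len(self.headpiece) + len(self.opening_primer)

    @property
    def tag_length(self) -> int:
        return (
            self.codon_offset
            + self.n_cycles * self.codon_length
            + len(self.closing_primer)
        )

    def to_dict(self) -> dict:
        return {
            "headpiece": self.headpiece,
            "opening_primer": self.opening_primer,
            "closing_primer": self.closing_primer,
            "codon_length": self.codon_length,
            "min_hamming": self.min_hamming,
            "codebooks": [list(book) for book in self.codebooks],
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "TagScheme":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text)
        return cls(
            headpiece=data["headpiece"],
            opening_primer=data["opening_primer"],
            closing_primer=data["closing_primer"],
            codon_length=int(data["codon_length"]),
            codebooks=tuple(tuple(book) for book in data["codebooks"]),
            min_hamming=int(data["min_hamming"]),
        )


@dataclass
class TagRead:
    """A sequencing read of one bead's tag."""

    sequence: str
    quality: list[int] | None = None
    id: str = "read"

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("read alphabet is {A, C, G, T, N}")


@dataclass
class DecodeResult:
    read_id: str
    member_index: int | None
    status: str  # ok | ambiguous | unrecognized | too_short

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _int_to_codon(value: int, length: int) -> str:
    return "".join(BASES[(value >> (2 * i)) & 3] for i in range(length))


def build_scheme(
    design: LibraryDesign,
    codon_length: int = 6,
    min_hamming: int = 3,
    seed: int = 0,
    headpiece: str = DEFAULT_HEADPIECE,
    opening_primer: str = DEFAULT_OPENING_PRIMER,
    closing_primer: str = DEFAULT_CLOSING_PRIMER,
) -> TagScheme:
    """Construct per-cycle codebooks by seeded greedy random search.

    Candidate codons are visited in a random (seeded) order and accepted when
    at Hamming distance >= ``min_hamming`` from every codon already accepted
    for that cycle.  Raises :class:`CapacityError` when a cycle's codebook
    cannot reach the required size.
    """
    if min_hamming < 1:
        raise ValueError("min_hamming must be >= 1")
    if min_hamming > codon_length:
        raise CapacityError("min_hamming cannot exceed codon_length")
    rng = np.random.default_rng(seed)
    space = 4**codon_length
    codebooks = []
    for cyc, size in enumerate(design.cycle_sizes):
        if space < size:
            raise CapacityError(
                f"cycle {cyc}: 4^{codon_length} = {space} < {size} building blocks"
            )
        if space <= 4**8:
            candidates: Iterable[int] = rng.permutation(space)
        else:  # sample lazily in huge spaces
            candidates = (int(v) for v in rng.integers(0, space, size=200 * size))
        book: list[str] = []
        for value in candidates:
            codon = _int_to_codon(int(value), codon_length)
            if all(hamming(codon, c) >= min_hamming for c in book):
                book.append(codon)
                if len(book) == size:
                    break
        if len(book) < size:
            raise CapacityError(
                f"cycle {cyc}: cannot build {size} codons of length {codon_length} "
                f"at pairwise distance >= {min_hamming}"
            )
        codebooks.append(tuple(book))
    return TagScheme(
        headpiece=headpiece,
        opening_primer=opening_primer,
        closing_primer=closing_primer,
        codon_length=codon_length,
        codebooks=tuple(codebooks),
        min_hamming=min_hamming,
    )


def encode(member_index: int, scheme: TagScheme, design: LibraryDesign) -> str:
    """Tag sequence of a member: constant regions plus one codon per cycle."""
    blocks = design.member_to_blocks(member_index)  # raises on out-of-range
    codons = [scheme.codebooks[c][b] for c, b in enumerate(blocks)]
    return (
        scheme.headpiece + scheme.opening_primer + "".join(codons) + scheme.closing_primer
    )


def _match_codon(
    codon: str, book: Sequence[str], exact: dict[str, int], max_mismatch: int
) -> tuple[int | None, str]:
    idx = exact.get(codon)
    if idx is not None:
        return idx, "ok"
    dists = [hamming(codon, c) for c in book]
    best = min(dists)
    if best > max_mismatch:
        return None, "unrecognized"
    if dists.count(best) > 1:
        return None, "ambiguous"
    return dists.index(best), "ok"


def decode(
    read: TagRead | str,
    scheme: TagScheme,
    design: LibraryDesign,
    max_mismatch: int = 1,
) -> DecodeResult:
    """Decode a read to a member index by nearest-codon assignment.

    The codon region is located at fixed offsets (substitution-only model).
    Each codon is assigned to its closest codebook entry when the Hamming
    distance is <= ``max_mismatch`` and the minimizer is unique; otherwise the
    read fails with status ``"unrecognized"`` or ``"ambiguous"``.
    """
    if isinstance(read, str):
        read = TagRead(read)
    needed = scheme.codon_offset + scheme.n_cycles * scheme.codon_length
    if len(read.sequence) < needed:
        return DecodeResult(read.id, None, "too_short")
    exact_maps = [
        {c: i for i, c in enumerate(book[: size])}
        for book, size in zip(scheme.codebooks, design.cycle_sizes)
    ]
    blocks = []
    pos = scheme.codon_offset
    for cyc, size in enumerate(design.cycle_sizes):
        codon = read.sequence[pos : pos + scheme.codon_length]
        book = scheme.codebooks[cyc][:size]
        idx, status = _match_codon(codon, book, exact_maps[cyc], max_mismatch)
        if idx is None:
            return DecodeResult(read.id, None, status)
        blocks.append(idx)
        pos += scheme.codon_length
    return DecodeResult(read.id, design.blocks_to_member(blocks), "ok")


def decode_reads(
    reads: Iterable[TagRead | str],
    scheme: TagScheme,
    design: LibraryDesign,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Decode many reads; returns a table (read_id, member_index, status).

    Decoding is per-read and therefore order-independent.
    """
    rows = []
    for i, read in enumerate(reads):
        if isinstance(read, str):
            read = TagRead(read, id=f"read{i}")
        res = decode(read, scheme, design, max_mismatch=max_mismatch)
        rows.append(
            {
                "read_id": res.read_id,
                "member_index": -1 if res.member_index is None else res.member_index,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows, columns=["read_id", "member_index", "status"])


def tag_beads(
    members: Iterable[int], scheme: TagScheme, design: LibraryDesign
) -> list[Bead]:
    """Materialize beads (with encoded tags) for a list of member indices."""
    return [Bead(int(m), tag=encode(int(m), scheme, design)) for m in members]


def simulate_reads(
    beads: Sequence[Bead], per_base_error: float, seed: int = 0
) -> list[SeqRecord]:
    """Simulate one sequencing read per bead with i.i.d. substitution errors.

    Every base is replaced, independently with probability ``per_base_error``,
    by a uniformly random different base.  Phred qualities are constant at
    ``-10 log10(e)`` (capped at 40).
    """
    if not 0 <= per_base_error < 1:
        raise ValueError("per_base_error must be in [0, 1)")
    rng = np.random.default_rng(seed)
    qual = 40 if per_base_error == 0 else min(40, int(round(-10 * np.log10(per_base_error))))
    records = []
    base_idx = {b: i for i, b in enumerate(BASES)}
    for i, bead in enumerate(beads):
        if bead.tag is None:
            raise ValueError("bead has no tag; encode it first (see tag_beads)")
        seq = np.frombuffer(bead.tag.encode(), dtype=np.uint8).copy()
        if per_base_error > 0:
            hit = np.nonzero(rng.random(seq.size) < per_base_error)[0]
            for pos in hit:
                current = base_idx[chr(seq[pos])]
                seq[pos] = ord(BASES[(current + rng.integers(1, 4)) % 4])
        records.append(
            SeqRecord(
                Seq(seq.tobytes().decode()),
                id=f"bead{i}|m{bead.member_index}",
                description="",
                letter_annotations={"phred_quality": [qual] * seq.size},
            )
        )
    return records


# -- sequence file round trips (standard 4-line FASTQ, Phred+33) -------------


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    return SeqIO.write(records, str(path), "fastq")


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> int:
    return SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[TagRead]:
    return [
        TagRead(
            str(rec.seq),
            quality=list(rec.letter_annotations.get("phred_quality", [])) or None,
            id=rec.id,
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def read_fasta(path: str | Path) -> list[TagRead]:
    return [TagRead(str(rec.seq), id=rec.id) for rec in SeqIO.parse(str(path), "fasta")]
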