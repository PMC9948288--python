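"""Hit deconvolution: k-class aggregation, triage, FDR, and block enrichment.

Sorted hit beads are decoded to member indices and aggregated by structure;
a member's *k class among hits* (``k_hit``) is the number of sorted beads
that carry it.  Authentic actives are systematically enriched across
replicate beads, while inactive beads enter the hit collection only through
random coencapsulation or statistical sorting noise, so discarding low-k
rows (triage at ``k_hit >= k_min``) drives the false discovery rate toward
zero.  With simulated ground truth the FDR is computed exactly over distinct
retained structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CorruptTableError
from .library import LibraryDesign, sample_aliquot
from .screen import (
    AssayModel,
    ScreenConfig,
    encapsulate,
    expected_outlier_rate,
    generate_signals,
    rolling_sorter,
)

__all__ = [
    "PCR_BEAD_CAP",
    "TriageResult",
    "aggregate_hits",
    "triage_by_k",
    "productivity_check",
    "building_block_enrichment",
    "enrichment_uniformity_test",
    "screen_fdr_simulation",
]

#: Practical PCR amplification limit on hit-collection size, in beads.
PCR_BEAD_CAP = 30000


def aggregate_hits(
    decoded_members: Iterable[int],
    design: LibraryDesign,
    active_members: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Aggregate decoded sorted beads into a per-structure hit table.

    One row per distinct member with columns ``member_index``, ``k_hit``,
    per-cycle block indices ``bb_cycle1..C``, and (when ground truth is
    supplied) a boolean ``active`` column.  Emits a warning when the hit
    collection exceeds the PCR bead cap.
    """
    members = np.asarray(list(decoded_members), dtype=np.int64)
    n_cycles = design.n_cycles
    if members.size and (members.min() < 0 or members.max() >= design.diversity()):
        raise CorruptTableError("decoded member index outside the design")
    if members.size > PCR_BEAD_CAP:
        warnings.warn(
            f"hit collection of {members.size} beads exceeds the PCR "
            f"constraint (~{PCR_BEAD_CAP} beads)",
            stacklevel=2,
        )
    uniq, k_hit = np.unique(members, return_counts=True)
    rows = {
        "member_index": uniq,
        "k_hit": k_hit.astype(np.int64),
    }
    blocks = np.array(
        [design.member_to_blocks(int(m)) for m in uniq], dtype=np.int64
    ).reshape(len(uniq), n_cycles)
    for c in range(n_cycles):
        rows[f"bb_cycle{c + 1}"] = blocks[:, c]
    table = pd.DataFrame(rows)
    if active_members is not None:
        actives = set(int(m) for m in active_members)
        table["active"] = table["member_index"].isin(actives)
    return table.sort_values(
        ["k_hit", "member_index"], ascending=[False, True], ignore_index=True
    )


@dataclass
class TriageResult:
    """Hit rows surviving the k-class triage, with FDR when truth is known."""

    k_min: int
    retained: pd.DataFrame
    fdr: float  # NaN when truth labels are absent or nothing is retained

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def triage_by_k(table: pd.DataFrame, k_min: int) -> TriageResult:
    """Retain hit structures with ``k_hit >= k_min``; report the FDR.

    The FDR is the fraction of *distinct* retained structures that are
    inactive (per-structure, not per-bead), available only when the table
    carries truth labels; NaN otherwise or when nothing is retained.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    retained = table[table["k_hit"] >= k_min].reset_index(drop=True)
    if "active" in table.columns and len(retained) > 0:
        fdr = float((~retained["active"]).mean())
    else:
        fdr = float("nan")
    return TriageResult(k_min=k_min, retained=retained, fdr=fdr)


def productivity_check(n_droplets: int, n_hits: int, z: float = 4.0) -> bool:
    """True when a screen yielded more hits than sorting noise alone predicts.

    The null expectation is ``n_droplets`` times the one-tailed outlier rate
    at the sort threshold; a screen of 1e6 droplets at z = 4 yielding <= 32
    hit droplets is unproductive.
    """
    if n_droplets < 0 or n_hits < 0:
        raise ValueError("counts must be nonnegative")
    expected = round(n_droplets * expected_outlier_rate(z))
    return n_hits > expected


def building_block_enrichment(
    table: pd.DataFrame, design: LibraryDesign
) -> pd.DataFrame:
    """Per-cycle building-block hit counts, weighted by ``k_hit``.

    Returns a long-format table (cycle, block, block_id, weight) including
    zero-count blocks; within each cycle the weights sum to the table's total
    ``k_hit``.  Conserved blocks across multiple high-k hits surface as
    within-cycle maxima.
    """
    if (table["member_index"] < 0).any() or (
        table["member_index"] >= design.diversity()
    ).any():
        raise CorruptTableError("hit table refers to members outside the design")
    out = []
    for c, blocks in enumerate(design.cycles):
        col = f"bb_cycle{c + 1}"
        weights = table.groupby(col)["k_hit"].sum()
        for b, block in enumerate(blocks):
            out.append(
                {
                    "cycle": c + 1,
                    "block": b,
                    "block_id": block.id,
                    "weight": int(weights.get(b, 0)),
                }
            )
    return pd.DataFrame(out, columns=["cycle", "block", "block_id", "weight"])


def enrichment_uniformity_test(
    enrichment: pd.DataFrame, cycle: int
) -> tuple[float, float]:
    """Chi-square test of one cycle's block weights against uniformity.

    An artifact convention for flagging block conservation: small p-values
    indicate non-uniform usage of a cycle's building blocks among hits.
    Returns (statistic, p-value).
    """
    weights = enrichment.loc[enrichment["cycle"] == cycle, "weight"].to_numpy()
    if weights.size == 0:
        raise ValueError(f"no rows for cycle {cycle}")
    stat, p = sps.chisquare(weights)
    return float(stat), float(p)


def screen_fdr_simulation(
    design: LibraryDesign,
    epsilon: float,
    assay: AssayModel,
    config: ScreenConfig,
    n_droplets: int,
    replicates: int = 20,
    seed: int = 0,
    k_min_values: Sequence[int] = (1, 2, 3),
    scheme=None,
    per_base_error: float = 0.0,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Monte-Carlo FDR-versus-k_min curve over full simulated screens.

    Each replicate runs the whole pipeline — aliquot sampling, droplet
    encapsulation, signal generation, rolling-window sorting, tag sequencing
    and decoding, aggregation, triage — with fresh seeds derived from
    ``seed``.  Returns one row per ``k_min`` with the mean and SD of the FDR
    (over replicates where the retained set is non-empty) and mean retained
    counts.
    """
    from .encoding import TagRead, build_scheme, decode_reads, simulate_reads, tag_beads

    if scheme is None:
        scheme = build_scheme(design, seed=seed)
    ss = np.random.SeedSequence(seed)
    stage_seeds = ss.generate_state(4 * replicates).reshape(replicates, 4) % (2**31)
    fdr = {k: [] for k in k_min_values}
    retained = {k: [] for k in k_min_values}
    for r in range(replicates):
        s_aliquot, s_encap, s_signal, s_reads = (int(v) for v in stage_seeds[r])
        aliquot = sample_aliquot(design, epsilon, seed=s_aliquot)
        stream = encapsulate(aliquot, config, n_droplets, seed=s_encap)
        stream = generate_signals(stream, assay, config, seed=s_signal)
        sort = rolling_sorter(stream, config)
        hit_members = np.concatenate(
            [stream.droplet_beads(i) for i in sort.hit_indices]
        ) if sort.n_hits else np.empty(0, dtype=np.int64)
        beads = tag_beads(hit_members, scheme, design)
        records = simulate_reads(beads, per_base_error, seed=s_reads)
        reads = [TagRead(str(rec.seq), id=rec.id) for rec in records]
        report = decode_reads(reads, scheme, design, max_mismatch=max_mismatch)
        decoded = report.loc[report["status"] == "ok", "member_index"].to_numpy()
        table = aggregate_hits(decoded, design, assay.active_members)
        for k in k_min_values:
            res = triage_by_k(table, k)
            retained[k].append(res.n_retained)
            if not np.isnan(res.fdr):
                fdr[k].append(res.fdr)
    rows = []
    for k in k_min_values:
        vals = np.asarray(fdr[k], dtype=float)
        rows.append(
            {
                "k_min": k,
                "mean_fdr": float(vals.mean()) if vals.size else float("nan"),
                "sd_fdr": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                "n_replicates_with_hits": int(vals.size),
                "mean_retained": float(np.mean(retained[k])),
            }
        )
    return pd.DataFrame(rows)
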