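"""Worked-example fixture bundle: a tiny 9-member screen end to end.

Everything here is synthetic and generated deterministically from a seed, so
the bundle doubles as a reproducibility check: regenerating with the same
seed is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import RunConfig
from .library import LibraryDesign
from .pipeline import run_screen
from .screen import AssayModel, ScreenConfig

__all__ = ["demo_design", "make_fixtures"]


def demo_design() -> LibraryDesign:
    """The canonical worked example: 2 split-and-pool cycles x 3 blocks = 9."""
    return LibraryDesign.from_lists(
        [["amine-1", "amine-2", "amine-3"], ["acid-1", "acid-2", "acid-3"]],
        name="demo9",
    )


def demo_run_config(seed: int = 0) -> RunConfig:
    """A small but complete screen over the 9-member demo design."""
    return RunConfig(
        design=demo_design(),
        epsilon=20.0,  # tiny design, so sample deep to populate k classes
        n_droplets=3000,
        assay=AssayModel(mu_neg=100.0, sigma_neg=8.0, active_members=frozenset({4})),
        screen=ScreenConfig(window=500, bead_occupancy=0.05),
        k_min=2,
        seed=seed,
    )


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict:
    """Write the demo bundle: design, screen outputs, traces, control signals.

    Returns the screen summary dict.  Files:

    - ``screen/``: full output bundle of the demo screen (see ``run_screen``)
    - ``trace.tsv``: two-column time/signal detector trace with 10 droplet peaks
    - ``controls_neg.tsv`` / ``controls_pos.tsv``: labeled control populations
    - ``run_config.yaml``: the demo run configuration
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    cfg = demo_run_config(seed)
    cfg.to_yaml(outdir / "run_config.yaml")
    summary = run_screen(cfg, outdir / "screen")

    # detector trace: 10 rectangular droplet transits over a noisy baseline
    n, width, gap = 2000, 40, 160
    t = np.arange(n) * 1e-4  # 100 us sampling
    y = rng.normal(0.0, 0.02, n)
    heights = 1.0 + rng.random(10)
    for i, h in enumerate(heights):
        start = 100 + i * (width + gap)
        y[start : start + width] += h
    np.savetxt(
        outdir / "trace.tsv",
        np.column_stack([t, y]),
        delimiter="\t",
        header="time_s\tsignal",
        comments="",
        fmt="%.6g",
    )

    # labeled control populations for Z' (separation chosen to be suitable)
    neg = rng.normal(100.0, 3.0, 500)
    pos = rng.normal(40.0, 3.0, 500)
    np.savetxt(outdir / "controls_neg.tsv", neg, fmt="%.6g")
    np.savetxt(outdir / "controls_pos.tsv", pos, fmt="%.6g")
    return summary
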