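"""Run configuration: a plain-text (YAML) description of a whole screen.

Field names spell out their units (``droplet_volume_pl``, ``ic50_mM``) to
prevent unit errors.  Configurations round-trip losslessly through
:meth:`RunConfig.to_yaml` / :meth:`RunConfig.from_yaml`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigError
from .library import LibraryDesign
from .screen import AssayModel, ScreenConfig

__all__ = ["RunConfig"]

_REQUIRED = ("design", "epsilon", "n_droplets", "assay")


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulated screen."""

    design: LibraryDesign
    epsilon: float
    n_droplets: int
    assay: AssayModel
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    per_base_error: float = 0.0
    codon_length: int = 6
    min_hamming: int = 3
    max_mismatch: int = 1
    k_min: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ConfigError("epsilon must be nonnegative")
        if self.n_droplets < 1:
            raise ConfigError("n_droplets must be >= 1")

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        assay: dict = {
            "mu_neg": self.assay.mu_neg,
            "sigma_neg": self.assay.sigma_neg,
            "active_members": sorted(self.assay.active_members),
            "effect": self.assay.effect,
            "hill": self.assay.hill,
        }
        if self.assay.ic50_mM is not None:
            assay["ic50_mM"] = self.assay.ic50_mM
        return {
            "seed": self.seed,
            "epsilon": self.epsilon,
            "n_droplets": self.n_droplets,
            "k_min": self.k_min,
            "design": self.design.to_dict(),
            "screen": {
                "droplet_volume_pl": self.screen.droplet_volume_pl,
                "bead_occupancy": self.screen.bead_occupancy,
                "cell_occupancy": self.screen.cell_occupancy,
                "release_fraction": self.screen.release_fraction,
                "window": self.screen.window,
                "z_threshold": self.screen.z_threshold,
                "hit_direction": self.screen.hit_direction,
                "noise_mode": self.screen.noise_mode,
            },
            "assay": assay,
            "sequencing": {
                "per_base_error": self.per_base_error,
                "codon_length": self.codon_length,
                "min_hamming": self.min_hamming,
                "max_mismatch": self.max_mismatch,
            },
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        for name in _REQUIRED:
            if name not in data:
                raise ConfigError(f"missing required field '{name}'")
        design_data = data["design"]
        if isinstance(design_data, str):
            design = LibraryDesign.from_yaml(design_data)
        else:
            if "cycles" not in design_data:
                raise ConfigError("missing required field 'design.cycles'")
            design = LibraryDesign.from_lists(
                design_data["cycles"],
                tag_scheme_ref=design_data.get("tag_scheme"),
                name=design_data.get("name", "library"),
            )
        assay_data = data["assay"]
        for name in ("mu_neg", "sigma_neg"):
            if name not in assay_data:
                raise ConfigError(f"missing required field 'assay.{name}'")
        seed = int(data.get("seed", 0))
        if "active_members" in assay_data:
            actives = frozenset(int(m) for m in assay_data["active_members"])
        elif "n_actives" in assay_data:
            rng = np.random.default_rng(seed)
            actives = frozenset(
                int(m)
                for m in rng.choice(
                    design.diversity(), size=int(assay_data["n_actives"]), replace=False
                )
            )
        else:
            actives = frozenset()
        try:
            assay = AssayModel(
                mu_neg=float(assay_data["mu_neg"]),
                sigma_neg=float(assay_data["sigma_neg"]),
                active_members=actives,
                effect=float(assay_data.get("effect", 1.0)),
                ic50_mM=assay_data.get("ic50_mM"),
                hill=float(assay_data.get("hill", 1.0)),
            )
            screen = ScreenConfig(**data.get("screen", {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        seqp = data.get("sequencing", {})
        return cls(
            design=design,
            epsilon=float(data["epsilon"]),
            n_droplets=int(data["n_droplets"]),
            assay=assay,
            screen=screen,
            per_base_error=float(seqp.get("per_base_error", 0.0)),
            codon_length=int(seqp.get("codon_length", 6)),
            min_hamming=int(seqp.get("min_hamming", 3)),
            max_mismatch=int(seqp.get("max_mismatch", 1)),
            k_min=int(data.get("k_min", 2)),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(data)
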