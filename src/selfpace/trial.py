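"""Trial logs: synchronized tick, step and event streams with metadata."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .forceplate import ForcePlateSeries


@dataclass
class TrialLog:
    """Synchronized record of one trial.

    ``ticks`` has one row per sample (shared time base ``t``); depending on
    the producer it carries force channels, ground truth (``truth_p``,
    ``truth_v``), estimates (``p_kf``, ``v_kf``, covariance entries) and
    belt speed ``vtm``.  ``steps`` has one row per detected footstep.
    ``meta`` records the seed and parameters of the run.
    """

    ticks: pd.DataFrame
    steps: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def series(self, body_mass=None, body_weight=None) -> ForcePlateSeries:
        """Extract the force-plate record (requires force channels)."""
        if body_mass is None:
            body_mass = self.meta.get("body_mass")
        if body_weight is None:
            body_weight = self.meta.get("body_weight")
        return ForcePlateSeries.from_frame(
            self.ticks, body_mass=body_mass, body_weight=body_weight)

    def save(self, directory, prefix: str = "trial") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.ticks.to_csv(directory / f"{prefix}_ticks.csv", index=False)
        self.steps.to_csv(directory / f"{prefix}_steps.csv", index=False)
        with open(directory / f"{prefix}_meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)

    @classmethod
    def load(cls, directory, prefix: str = "trial") -> "TrialLog":
        directory = Path(directory)
        ticks = pd.read_csv(directory / f"{prefix}_ticks.csv")
        steps = pd.read_csv(directory / f"{prefix}_steps.csv")
        meta_path = directory / f"{prefix}_meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(ticks=ticks, steps=steps, meta=meta)
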