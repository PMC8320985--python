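"""Full two-stage pipeline: EO population search, then random-search growth.

A single master seed deterministically derives independent streams for the
two stages, so the pipeline is reproducible end to end and each stage can be
re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CodeSet, ConstraintProfile
from .eo import EOParams, eo_search
from .rs import RSParams, rs_augment

__all__ = ["EORSResult", "eors_search"]


@dataclass
class EORSResult:
    profile: ConstraintProfile
    eo_set: CodeSet
    final_set: CodeSet
    seed: int | None
    eo_params: EOParams
    rs_params: RSParams
    trajectory: list = field(default_factory=list)

    def summary(self) -> dict:
        """JSON-serialisable run summary."""
        return {
            "profile": {
                "n": self.profile.n,
                "d": self.profile.d,
                "w": self.profile.w,
                "nrl": self.profile.nrl,
            },
            "seed": self.seed,
            "eo": {
                "pop_size": self.eo_params.pop_size,
                "t_max": self.eo_params.t_max,
                "size": len(self.eo_set),
            },
            "rs": {
                "budget": self.rs_params.budget,
                "batch": self.rs_params.batch,
                "size": len(self.final_set),
            },
            "coding_rate": self.final_set.coding_rate() if len(self.final_set) else None,
        }


def eors_search(
    profile: ConstraintProfile,
    eo_params: EOParams | None = None,
    rs_params: RSParams | None = None,
    seed: int | None = None,
    collect_trajectory: bool = False,
) -> EORSResult:
    """Run EO then random-search augmentation under one master seed."""
    eo_params = eo_params or EOParams()
    rs_params = rs_params or RSParams()
    ss_eo, ss_rs = np.random.SeedSequence(seed).spawn(2)
    trajectory: list = []
    eo_set = eo_search(
        profile,
        eo_params,
        rng=np.random.default_rng(ss_eo),
        trajectory=trajectory if collect_trajectory else None,
    )
    final = rs_augment(eo_set, profile, rs_params, rng=np.random.default_rng(ss_rs))
    return EORSResult(
        profile=profile,
        eo_set=eo_set,
        final_set=final.canonical_sorted(),
        seed=seed,
        eo_params=eo_params,
        rs_params=rs_params,
        trajectory=trajectory,
    )
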