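"""Versioned model checkpoints.

A checkpoint bundles everything needed to sample: the denoiser parameters
and architecture, the noise-schedule parameters, the element alphabet and
feature scalings, the empirical size distribution p(N), and the property
normaliser of a conditional model.  Serialised as JSON so checkpoints are
portable, diffable text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .denoiser import GCPDenoiser
from .molecules import CHARGE_SCALE, ONEHOT_SCALE
from .sampling import SizeDistribution
from .schedule import NoiseSchedule, build_noise_schedule

__all__ = ["Checkpoint", "save_checkpoint", "load_checkpoint"]

SCHEMA_VERSION = 1


@dataclass
class Checkpoint:
    model: GCPDenoiser
    schedule: NoiseSchedule
    alphabet: tuple[str, ...]
    size_dist: SizeDistribution
    onehot_scale: float = ONEHOT_SCALE
    charge_scale: float = CHARGE_SCALE

    @property
    def is_conditional(self) -> bool:
        return self.model.config.condition_dim > 0


def save_checkpoint(path, model: GCPDenoiser, schedule: NoiseSchedule,
                    alphabet, size_dist: SizeDistribution,
                    onehot_scale: float = ONEHOT_SCALE,
                    charge_scale: float = CHARGE_SCALE) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "model": model.to_dict(),
        "schedule": {"T": schedule.T, "kind": schedule.kind,
                     "precision": schedule.precision},
        "alphabet": list(alphabet),
        "size_dist": {"support": size_dist.support.tolist(),
                      "probs": size_dist.probs.tolist()},
        "scalings": {"onehot": onehot_scale, "charge": charge_scale},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> Checkpoint:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"checkpoint schema version {version!r} unsupported "
            f"(expected {SCHEMA_VERSION})"
        )
    model = GCPDenoiser.from_dict(payload["model"])
    schedule = build_noise_schedule(**payload["schedule"])
    if model.T != schedule.T:
        raise ValueError("checkpoint inconsistent: model T != schedule T")
    size_dist = SizeDistribution(
        support=np.array(payload["size_dist"]["support"]),
        probs=np.array(payload["size_dist"]["probs"]),
    )
    return Checkpoint(
        model=model,
        schedule=schedule,
        alphabet=tuple(payload["alphabet"]),
        size_dist=size_dist,
        onehot_scale=payload["scalings"]["onehot"],
        charge_scale=payload["scalings"]["charge"],
    )
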