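"""Plan-vs-log comparison: SPM-to-isocenter projection and spot deviations.

The spot position monitor (SPM) sits upstream of the isocenter, so logged
coordinates must be magnified onto the isocenter plane before they are
comparable with the plan::

    x_iso = x_spm * f_x        y_iso = y_spm * f_y

with dimensionless projection factors (defaults f_x = 1.696, f_y = 1.391 for
the modelled beamline).  Deviations are signed delivered-minus-planned, so a
positive mean reads as the delivered spots sitting on the positive side of
the planned position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SynchronizationError, ValidationError
from .log_io import DeliverySession
from .plan_io import IonPlan

#: columns of a deviation table, one row per matched spot per session
DEVIATION_COLUMNS = [
    "room",
    "date",
    "layer_index",
    "spot_index",
    "energy",
    "planned_x",
    "planned_y",
    "planned_mu",
    "dx",
    "dy",
    "d",
    "d2",
    "dmu",
]


@dataclass(frozen=True)
class ProjectionFactors:
    """SPM-plane to isocenter-plane magnification factors (dimensionless)."""

    f_x: float = 1.696
    f_y: float = 1.391

    def __post_init__(self):
        if not (self.f_x > 0 and self.f_y > 0):
            raise ValidationError("projection factors must be > 0")


def project_to_iso(x_spm, y_spm, f: ProjectionFactors = ProjectionFactors()):
    """Project SPM-plane coordinates (mm) onto the isocenter plane.

    Accepts scalars or arrays; returns ``(x_iso, y_iso)``.
    """
    return np.multiply(x_spm, f.f_x), np.multiply(y_spm, f.f_y)


@dataclass
class MatchedSpots:
    """Plan and log spots paired positionally, as aligned flat arrays."""

    room: str
    date: object
    layer_index: np.ndarray
    spot_index: np.ndarray
    energy: np.ndarray  # nominal energy from the *plan*
    planned_x: np.ndarray
    planned_y: np.ndarray
    planned_mu: np.ndarray
    x_spm: np.ndarray
    y_spm: np.ndarray
    mu_delivered: np.ndarray

    def __len__(self) -> int:
        return len(self.layer_index)


def match_spots(plan: IonPlan, session: DeliverySession) -> MatchedSpots:
    """Pair plan and log spots by (layer, delivery order within layer).

    Matching is strictly positional: demand data records every planned spot,
    so any count mismatch is a data-integrity failure and raises
    :class:`SynchronizationError` naming the offending layer.  The nominal
    energy label is taken from the plan.
    """
    if session.n_layers != len(plan.layers):
        raise SynchronizationError(
            f"layer count mismatch: plan has {len(plan.layers)}, "
            f"log has {session.n_layers}"
        )
    arrays = plan.spot_arrays()
    # logs are written layer-block by layer-block, but be robust to any
    # stored order: delivery order within a layer is the record order
    order = np.argsort(session.layer_index, kind="stable")
    log_layers = session.layer_index[order]
    counts_log = np.bincount(log_layers, minlength=len(plan.layers))
    for li, layer in enumerate(plan.layers):
        if counts_log[li] != layer.n_spots:
            raise SynchronizationError(
                f"layer {li}: plan has {layer.n_spots} spots, "
                f"log has {int(counts_log[li])}"
            )
    return MatchedSpots(
        room=session.room,
        date=session.date,
        layer_index=arrays["layer_index"],
        spot_index=arrays["spot_index"],
        energy=arrays["energy"],
        planned_x=arrays["x"],
        planned_y=arrays["y"],
        planned_mu=arrays["mu"],
        x_spm=session.x_spm[order],
        y_spm=session.y_spm[order],
        mu_delivered=session.mu[order],
    )


def compute_deviations(
    pairs: MatchedSpots | Iterable[MatchedSpots],
    f: ProjectionFactors = ProjectionFactors(),
) -> pd.DataFrame:
    """Spot-wise deviation table (delivered - planned) for one or more sessions.

    Columns per :data:`DEVIATION_COLUMNS`; ``d`` is the Euclidean distance and
    ``d2`` its square (``d2 = dx**2 + dy**2`` holds exactly row-wise).
    """
    if isinstance(pairs, MatchedSpots):
        pairs = [pairs]
    frames = []
    for m in pairs:
        x_iso, y_iso = project_to_iso(m.x_spm, m.y_spm, f)
        dx = x_iso - m.planned_x
        dy = y_iso - m.planned_y
        d2 = dx * dx + dy * dy
        frames.append(
            pd.DataFrame(
                {
                    "room": m.room,
                    "date": m.date,
                    "layer_index": m.layer_index,
                    "spot_index": m.spot_index,
                    "energy": m.energy,
                    "planned_x": m.planned_x,
                    "planned_y": m.planned_y,
                    "planned_mu": m.planned_mu,
                    "dx": dx,
                    "dy": dy,
                    "d": np.sqrt(d2),
                    "d2": d2,
                    "dmu": m.mu_delivered - m.planned_mu,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=DEVIATION_COLUMNS)
    return pd.concat(frames, ignore_index=True)
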