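"""Grasp-level metrics: finger index, lift-delta, static equilibrium.

The finger index summarizes which finger a participant uses to oppose
the thumb over the 10 repetitions of a condition:

    finger index = (N_index - N_middle) / (N_index + N_middle)

so +1 means the index finger always opposed, -1 always the middle
finger, 0 equal use.  The equilibrium check verifies the four conditions
of a stationary prismatic soft-contact hold with the opposing fingers
reduced to a single virtual finger: opposed normals, tangential sum
carrying the gravity load, slip margins, zero net moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import G_M_S2, ForceSnapshot


def finger_index(n_index: int, n_middle: int) -> float:
    """(N_index - N_middle) / (N_index + N_middle), in [-1, 1]."""
    if n_index < 0 or n_middle < 0:
        raise ValueError("finger counts must be nonnegative")
    total = n_index + n_middle
    if total == 0:
        raise ValueError("finger index undefined for zero counts")
    return (n_index - n_middle) / total


def lift_delta(delay_force_ms: float, delay_distance_ms: float) -> float:
    """Force-algorithm delay minus distance-algorithm delay (ms)."""
    return delay_force_ms - delay_distance_ms


def finger_index_table(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Per participant x size x weight cell: finger counts and index.

    ``per_trial`` needs columns giver, size, weight_g, opposing_finger.
    """
    def _cell(g: pd.DataFrame) -> pd.Series:
        n_idx = int((g["opposing_finger"] == "index").sum())
        n_mid = int((g["opposing_finger"] == "middle").sum())
        return pd.Series(
            {
                "n_index": n_idx,
                "n_middle": n_mid,
                "finger_index": finger_index(n_idx, n_mid),
            }
        )

    out = (
        per_trial.groupby(["giver", "size", "weight_g"])
        .apply(_cell, include_groups=False)
        .reset_index()
    )
    out[["n_index", "n_middle"]] = out[["n_index", "n_middle"]].astype(int)
    return out


@dataclass(frozen=True)
class EquilibriumReport:
    """Residuals of the four stationary-hold conditions."""

    residual_normal_n: float      # |thumb normal + VF normal|
    residual_tangential_n: float  # |sum tangential - m g|
    residual_moment_nmm: float    # |net moment about the grasp center|
    slip_margin_ok: bool          # normals >= tangential / mu, both digits

    def ok(self, tol_n: float = 1e-9, tol_nmm: float = 1e-6) -> bool:
        return (
            self.residual_normal_n <= tol_n
            and self.residual_tangential_n <= tol_n
            and self.residual_moment_nmm <= tol_nmm
            and self.slip_margin_ok
        )


def check_equilibrium(
    snapshot: ForceSnapshot,
    mass_g: float | None = None,
    slip_coefficient: float = 0.8,
) -> EquilibriumReport:
    """Residuals of the prismatic-hold equilibrium conditions.

    Reports, never raises: (1) thumb normal vs. virtual-finger normal,
    (2) tangential sum vs. gravity load, (3) slip margins, (4) net
    moment about the grasp-surface center (N mm).
    """
    if mass_g is None:
        mass_g = snapshot.mass_g
    load = mass_g / 1000.0 * G_M_S2

    res_normal = float(np.linalg.norm(snapshot.thumb_normal + snapshot.vf_normal))
    t_sum = snapshot.thumb_tangential + snapshot.vf_tangential
    res_tangential = float(abs(t_sum[2] - load) + np.linalg.norm(t_sum[:2]))

    moment = np.cross(
        snapshot.thumb_point, snapshot.thumb_normal + snapshot.thumb_tangential
    ) + np.cross(snapshot.vf_point, snapshot.vf_normal + snapshot.vf_tangential)
    res_moment = float(np.linalg.norm(moment))

    slip_ok = bool(
        np.linalg.norm(snapshot.thumb_normal) * slip_coefficient
        >= np.linalg.norm(snapshot.thumb_tangential) - 1e-12
        and np.linalg.norm(snapshot.vf_normal) * slip_coefficient
        >= np.linalg.norm(snapshot.vf_tangential) - 1e-12
    )
    return EquilibriumReport(res_normal, res_tangential, res_moment, slip_ok)
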