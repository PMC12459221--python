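"""Methyl chemical-shift perturbation between two sample states.

Combined two-nucleus quadrature form with the 13C axis scaled to the 1H
shift range:

    CSP = sqrt(ΔδH² + (α·ΔδC)²),   α = 0.133 by default.

The module ranks perturbations; a significance cutoff is a configurable
report parameter, not a built-in claim.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .peaklist_io import PeakTable

__all__ = ["csp", "csp_profile", "DEFAULT_C_SCALE"]

DEFAULT_C_SCALE = 0.133


def csp(delta_H_ppm, delta_C_ppm, c_scale: float = DEFAULT_C_SCALE):
    """Combined 1H/13C chemical-shift perturbation in ppm (vectorized)."""
    dh = np.asarray(delta_H_ppm, dtype=float)
    dc = np.asarray(delta_C_ppm, dtype=float)
    if not np.all(np.isfinite(dh)) or not np.all(np.isfinite(dc)):
        raise ValueError("shift differences must be finite")
    out = np.hypot(dh, c_scale * dc)
    return float(out) if out.ndim == 0 else out


def csp_profile(
    state_a: PeakTable,
    state_b: PeakTable,
    c_scale: float = DEFAULT_C_SCALE,
    cutoff_ppm: float | None = None,
) -> pd.DataFrame:
    """Per-peak CSP between two states, ranked by magnitude.

    Only keys present in both tables are compared; unmatched keys are listed
    in the ``unmatched_in`` column (value "a" or "b") with NaN CSP.  If
    ``cutoff_ppm`` is given, an ``above_cutoff`` column is added.  Symmetric
    in its two table arguments.
    """
    key = ["residue_index", "methyl_id"]
    for name, t in (("a", state_a), ("b", state_b)):
        if t.df["shift_H_ppm"].isna().any() or t.df["shift_C_ppm"].isna().any():
            raise ValueError(f"table {name} lacks chemical shifts for some peaks")
    merged = state_a.df.merge(state_b.df, on=key, how="outer",
                              suffixes=("_a", "_b"), indicator="merge_side")
    rows = []
    for r in merged.itertuples(index=False):
        if r.merge_side != "both":
            rows.append(
                {
                    "residue_index": int(r.residue_index),
                    "methyl_id": r.methyl_id,
                    "delta_H_ppm": np.nan,
                    "delta_C_ppm": np.nan,
                    "csp_ppm": np.nan,
                    "unmatched_in": "a" if r.merge_side == "left_only" else "b",
                }
            )
            continue
        dh = abs(r.shift_H_ppm_a - r.shift_H_ppm_b)
        dc = abs(r.shift_C_ppm_a - r.shift_C_ppm_b)
        rows.append(
            {
                "residue_index": int(r.residue_index),
                "methyl_id": r.methyl_id,
                "delta_H_ppm": dh,
                "delta_C_ppm": dc,
                "csp_ppm": csp(dh, dc, c_scale),
                "unmatched_in": "",
            }
        )
    df = pd.DataFrame(rows)
    if df["csp_ppm"].isna().all():
        raise ValueError("tables share no (residue, methyl) keys")
    df = df.sort_values(["csp_ppm"], ascending=False, na_position="last").reset_index(
        drop=True
    )
    if cutoff_ppm is not None:
        df["above_cutoff"] = df["csp_ppm"] >= cutoff_ppm
    return df
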