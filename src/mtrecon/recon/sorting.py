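"""Protofilament-number sorting by multi-reference alignment.

Each segment is matched against the projection galleries of the 13-, 14-
and 15-PF references; filaments are assigned the PF number winning the
majority vote of their segments' best-scoring references (ties are left
unassigned — a filament is a single MT, so the per-filament vote pools
evidence across its segments).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mtrecon.density import DensityMap
from mtrecon.recon.matching import projection_match

__all__ = ["sort_pf_number"]


def sort_pf_number(
    stack: np.ndarray,
    filament_ids,
    references: dict[int, DensityMap],
    angular_step_deg: float = 4.0,
    shift_range_A: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sort filaments into PF-number classes by reference alignment.

    Returns ``(per_filament, per_segment)`` tables. ``per_filament`` has
    columns (filament_id, pf_assignment, n_segments, vote_fraction) with
    pf_assignment <NA> on vote ties; ``per_segment`` records each
    segment's best reference and score.
    """
    if len(references) < 2:
        raise ValueError("need at least two references")
    stack = np.asarray(stack)
    filament_ids = np.asarray(filament_ids)
    if len(filament_ids) != stack.shape[0]:
        raise ValueError("one filament_id per segment required")

    scores = {}
    for n_pf, ref in sorted(references.items()):
        tab = projection_match(stack, ref, angular_step_deg, shift_range_A)
        scores[n_pf] = tab["cc"].to_numpy()
    pf_keys = sorted(scores)
    score_mat = np.stack([scores[k] for k in pf_keys], axis=1)
    winner = np.array([pf_keys[i] for i in np.argmax(score_mat, axis=1)])

    per_segment = pd.DataFrame(
        {
            "segment_id": np.arange(stack.shape[0]),
            "filament_id": filament_ids,
            "pf_winner": winner,
            **{f"cc_{k}": scores[k] for k in pf_keys},
        }
    )
    rows = []
    for fid in np.unique(filament_ids):
        sel = winner[filament_ids == fid]
        if sel.size == 0:
            raise ValueError(f"filament {fid} has zero segments")
        vals, counts = np.unique(sel, return_counts=True)
        top = counts.max()
        tied = vals[counts == top]
        assignment = int(tied[0]) if len(tied) == 1 else pd.NA
        rows.append(
            {
                "filament_id": fid,
                "pf_assignment": assignment,
                "n_segments": int(sel.size),
                "vote_fraction": float(top / sel.size),
            }
        )
    return pd.DataFrame(rows), per_segment
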