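"""Detection scoring against simulated ground truth.

Used by the test-suite and validation scripts to quantify how well the
grain detector recovers the particles a synthetic scan was built from.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import volumetrics
from .detect import unflagged

_UNMATCHABLE = 1e12


def match_detections(
    truth: pd.DataFrame, table: pd.DataFrame, max_dist: float
) -> pd.DataFrame:
    """One-to-one match of unflagged detections to ground-truth particles.

    Minimum-total-distance assignment (Hungarian algorithm); pairs farther
    apart than ``max_dist`` (nm) are not matched.  Returns one row per
    matched pair with truth and measured h, r, and the measured molecular
    volume alongside the true one.
    """
    det = unflagged(table)
    if truth.empty or det.empty:
        return pd.DataFrame(
            columns=["truth_index", "det_index", "dist_nm",
                     "h_true", "r_true", "v_true", "h_meas", "r_meas", "v_meas"]
        )
    tx = truth[["x_nm", "y_nm"]].to_numpy()
    dx = det[["x_nm", "y_nm"]].to_numpy()
    dist = np.hypot(tx[:, None, 0] - dx[None, :, 0], tx[:, None, 1] - dx[None, :, 1])
    cost = np.where(dist <= max_dist, dist, _UNMATCHABLE)
    rows_t, rows_d = linear_sum_assignment(cost)
    keep = cost[rows_t, rows_d] < _UNMATCHABLE
    rows_t, rows_d = rows_t[keep], rows_d[keep]
    v_meas = volumetrics.particle_volume(
        det["h_nm"].to_numpy()[rows_d], det["r_nm"].to_numpy()[rows_d]
    )
    return pd.DataFrame(
        {
            "truth_index": truth.index.to_numpy()[rows_t],
            "det_index": det.index.to_numpy()[rows_d],
            "dist_nm": dist[rows_t, rows_d],
            "h_true": truth["h_nm"].to_numpy()[rows_t],
            "r_true": truth["r_nm"].to_numpy()[rows_t],
            "v_true": truth["volume_nm3"].to_numpy()[rows_t],
            "h_meas": det["h_nm"].to_numpy()[rows_d],
            "r_meas": det["r_nm"].to_numpy()[rows_d],
            "v_meas": np.atleast_1d(v_meas),
        }
    )


def detection_metrics(
    truth: pd.DataFrame, table: pd.DataFrame, max_dist: float
) -> dict:
    """Recall, spurious rate and volume accuracy of a detection run.

    * ``recall`` — matched unflagged detections / ground-truth particles;
    * ``spurious_rate`` — unmatched unflagged detections / ground-truth
      particles (false grains per true particle);
    * ``median_volume_rel_error`` — median |v_meas - v_true| / v_true over
      matched pairs.
    """
    matches = match_detections(truth, table, max_dist)
    n_truth = len(truth)
    n_det = len(unflagged(table))
    n_match = len(matches)
    rel_err = (
        np.abs(matches["v_meas"] - matches["v_true"]) / matches["v_true"]
        if n_match
        else np.array([np.nan])
    )
    return {
        "n_truth": n_truth,
        "n_detected_unflagged": n_det,
        "n_matched": n_match,
        "recall": n_match / n_truth if n_truth else float("nan"),
        "spurious_rate": (n_det - n_match) / n_truth if n_truth else float("nan"),
        "median_volume_rel_error": float(np.median(rel_err)),
    }
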