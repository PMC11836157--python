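"""Travel-time predictions from the fitted gain curve (second MVT test).

Given the gain-curve parameters estimated from the (residence time, gain)
scatter, each record's MVT-optimal travel time is the zero-crossing of the
tangent at its observed residence time, ``t = T - g(T)/g'(T)`` — negative
under the signed convention and independent of the asymptote ``A`` (which
cancels in ``g/g'``). Observed travel times are the negated survey reports;
residuals are vertical in the travel-time direction (the prediction
target), and a paired t-test compares observed with predicted times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import TTestResult, paired_t_test
from .model import predict_travel_time
from .odr import FitResult

__all__ = ["TravelEvaluation", "evaluate_travel_predictions"]


@dataclass
class TravelEvaluation:
    """Per-record travel-time predictions, residuals and summary statistics.

    ``s2_resid = sum(r^2) / (n - 2)`` inherits two degrees of freedom from
    the fitted gain-curve parameters; ``se_resid`` is its square root.
    """

    t_pred: np.ndarray        # signed predicted travel time, all < 0
    t_obs: np.ndarray         # signed observed travel time (negated report)
    residuals: np.ndarray     # t_obs - t_pred
    s2_resid: float
    se_resid: float
    n: int
    paired_test: TTestResult
    absolute: bool = False

    def to_json(self, path) -> None:
        payload = {
            "s2_resid": self.s2_resid,
            "se_resid": self.se_resid,
            "n": self.n,
            "absolute": self.absolute,
            "paired_test": self.paired_test.as_dict(),
            "t_pred": self.t_pred.tolist(),
            "t_obs": self.t_obs.tolist(),
            "residuals": self.residuals.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def evaluate_travel_predictions(
    fit: FitResult, records: pd.DataFrame, absolute: bool = False
) -> TravelEvaluation:
    """Predict and score signed travel times for every record.

    ``records`` must carry positive ``patch_time_min`` and
    ``travel_time_min`` columns (the survey stores travel time as a
    positive report; it is negated here at the model boundary). With
    ``absolute=True`` the paired comparison and residuals use absolute
    travel times instead of signed ones.
    """
    T = np.asarray(records["patch_time_min"], dtype=float)
    t_report = np.asarray(records["travel_time_min"], dtype=float)
    if np.any(~(T > 0)):
        raise ValueError(
            "non-positive or missing patch residence times: run preprocessing first"
        )
    if np.any(~(t_report > 0)):
        raise ValueError(
            "non-positive or missing travel-time reports: run preprocessing first"
        )

    t_pred = np.asarray(predict_travel_time(fit.curve, T), dtype=float)
    t_obs = -t_report
    if absolute:
        t_pred_c, t_obs_c = -t_pred, -t_obs
    else:
        t_pred_c, t_obs_c = t_pred, t_obs
    residuals = t_obs_c - t_pred_c
    n = residuals.size
    if n <= 2:
        raise ValueError("need more than 2 records for residual statistics")
    s2 = float(np.sum(residuals**2) / (n - 2))
    return TravelEvaluation(
        t_pred=t_pred_c,
        t_obs=t_obs_c,
        residuals=residuals,
        s2_resid=s2,
        se_resid=float(np.sqrt(s2)),
        n=n,
        paired_test=paired_t_test(t_obs_c, t_pred_c),
        absolute=absolute,
    )
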