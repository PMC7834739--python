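"""Scaled-logit transforms for salmon marine-survival proportions.

Marine survival p (proportion of a hatchery cohort surviving to Age 2 for
Chinook; total marine survival for Coho) is bounded in (0, 1), so model
fitting happens on the logit scale, alpha = log(p / (1 - p)), after centring
and scaling.  The stored (centre, scale) constants make the back-transform
exact:  beta = alpha * scale + centre;  S = exp(beta) / (exp(beta) + 1).

The logit is inversely related to the instantaneous mortality rate
k = -ln(S): higher alpha means higher survival and lower k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.special import logit as _sp_logit


def logit(p):
    """log(p / (1 - p)); defined only on the open interval (0, 1)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError("logit requires 0 < p < 1")
    out = _sp_logit(arr)
    return float(out) if out.ndim == 0 else out


def inv_logit(alpha):
    """exp(a) / (exp(a) + 1), the inverse of the logit."""
    out = expit(np.asarray(alpha, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass
class ScaledLogit:
    """Standardized logit survival with its back-transform constants."""

    values: pd.Series  # standardized alpha, indexed by ocean-entry year
    centre: float  # mean of the logit series
    scale: float  # SD (n-1 denominator) of the logit series

    def back_transform(self, alpha) -> np.ndarray:
        """Map model-scale values back to survival proportions."""
        beta = np.asarray(alpha, dtype=float) * self.scale + self.centre
        return inv_logit(beta)


def centre_scale(survival: pd.Series, status: pd.Series | None = None) -> ScaledLogit:
    """Centre and scale logit survivals; preliminary years are excluded from
    the centring statistics but still transformed with them.

    Parameters
    ----------
    survival : Series of proportions in (0, 1), indexed by ocean-entry year.
    status : optional Series of {"final", "preliminary"} flags.
    """
    alpha = pd.Series(logit(survival.to_numpy()), index=survival.index, dtype=float)
    use = alpha if status is None else alpha[status.to_numpy() == "final"]
    if len(use) < 2:
        raise ValueError("need at least two final-status values")
    centre = float(use.mean())
    scale = float(use.std(ddof=1))
    if scale == 0:
        raise ValueError("zero variance in logit survivals")
    return ScaledLogit(values=(alpha - centre) / scale, centre=centre, scale=scale)


def transform_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-stock scaled-logit transform of a (stock, year, survival, status) table.

    Returns a tidy frame with columns stock, ocean_entry_year, alpha
    (standardized logit), centre and scale.
    """
    out = []
    for stock, grp in table.groupby("stock"):
        grp = grp.set_index("ocean_entry_year").sort_index()
        sl = centre_scale(grp["survival"], grp.get("status"))
        frame = sl.values.rename("alpha").reset_index()
        frame["stock"] = stock
        frame["centre"] = sl.centre
        frame["scale"] = sl.scale
        out.append(frame)
    return pd.concat(out, ignore_index=True)
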