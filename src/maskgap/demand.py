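"""Demand side: expected counts and raw relative risks.

The demand benchmark for village i is E_i = r * Pop_i, where
r = sum(Y_i) / sum(Pop_i) is the overall service rate of the study area and
Pop_i the adult (15+) population. E_i enters the count models as an offset;
the raw relative risk rho_i = Y_i / E_i says whether a village is over-
(rho > 1) or under- (rho < 1) supplied relative to its population share.
By construction sum(E) = sum(Y), so the E-weighted mean raw RR is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DemandResult:
    r: float  # overall service rate, customers per adult per day
    E: np.ndarray  # expected counts r * Pop_i
    rho_raw: np.ndarray  # Y_i / E_i (0 where E_i = 0, flagged)
    zero_E: np.ndarray  # boolean mask of villages with E_i = 0


def expected_counts(villages: pd.DataFrame) -> DemandResult:
    """Overall service rate, expected counts and raw RR per village.

    Villages with zero population get E_i = 0 and are flagged: their raw RR
    is undefined and they are excluded from model likelihoods downstream
    (the log offset does not exist). The rate r is computed on the total
    population, preserving sum(E) = sum(Y) over the full frame.
    """
    Y = villages["Y"].to_numpy(dtype=float)
    pop = villages["pop"].to_numpy(dtype=float)
    if np.any(pop < 0) or np.any(Y < 0):
        raise ValueError("populations and counts must be non-negative")
    total_pop = pop.sum()
    if total_pop <= 0:
        raise ValueError("total population is zero; service rate undefined")
    r = float(Y.sum() / total_pop)
    E = r * pop
    zero_E = E == 0
    rho_raw = np.zeros_like(E)
    np.divide(Y, E, out=rho_raw, where=~zero_E)
    return DemandResult(r=r, E=E, rho_raw=rho_raw, zero_E=zero_E)


def attach_expected(villages: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the frame with E and rho_raw columns added."""
    res = expected_counts(villages)
    out = villages.copy()
    out["E"] = res.E
    out["rho_raw"] = res.rho_raw
    return out


def classify_raw(rho_raw) -> np.ndarray:
    """Label each raw RR as 'over' (>1), 'under' (<1) or 'par' (=1)."""
    rho = np.asarray(rho_raw, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("raw RR must be finite")
    labels = np.where(rho > 1, "over", np.where(rho < 1, "under", "par"))
    return labels
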