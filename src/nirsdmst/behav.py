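"""Signal-detection and response-time summaries of same/different behavior.

A "different" response on a different trial is a hit; a "different"
response on a same trial is a false alarm. Sensitivity d' = z(H) - z(F) and
criterion c = -(z(H) + z(F))/2 are computed after the log-linear
correction, which adds 0.5 to every contingency cell unconditionally
(rates become (hits + 0.5)/(n + 1)), keeping both z-scores finite even for
perfect or empty cells. Missed (timed-out) responses are excluded from
both the SDT tabulation and the RT means; RT means use correct trials only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "tabulate_sdt",
    "dprime_criterion",
    "sdt_table",
    "rt_summary",
]


def _cell_factors(responses: pd.DataFrame, by_factors=None) -> list[str]:
    if by_factors is not None:
        return list(by_factors)
    cand = [c for c in ("task", "material", "memory_load")
            if c in responses.columns and responses[c].astype(str).str.len().gt(0).any()]
    return cand


def tabulate_sdt(responses: pd.DataFrame, by_factors=None) -> pd.DataFrame:
    """Hit / false-alarm counts per participant and condition cell.

    Missed responses are excluded. Returns one row per cell with columns
    hits, false_alarms, n_signal (different trials), n_noise (same trials).
    Raises if any cell has no usable trials.
    """
    factors = _cell_factors(responses, by_factors)
    ok = responses[responses.response != "missed"].copy()
    keys = ["participant", *factors]
    rows = []
    for key, cell in ok.groupby(keys, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        diff = cell[cell.trial_type == "different"]
        same = cell[cell.trial_type == "same"]
        rows.append(dict(zip(keys, key)) | dict(
            hits=int((diff.response == "different").sum()),
            false_alarms=int((same.response == "different").sum()),
            n_signal=len(diff), n_noise=len(same)))
    out = pd.DataFrame(rows)
    empty = out[(out.n_signal == 0) | (out.n_noise == 0)]
    if not empty.empty:
        cell = empty.iloc[0]
        raise ValueError(
            f"empty SDT cell for {dict(cell[keys])}: both trial types required")
    return out


def dprime_criterion(hits: int, false_alarms: int, n_signal: int,
                     n_noise: int) -> tuple[float, float]:
    """Sensitivity and criterion with the unconditional log-linear correction.

    H = (hits + 0.5) / (n_signal + 1), F = (fa + 0.5) / (n_noise + 1);
    d' = z(H) - z(F), c = -(z(H) + z(F)) / 2. The corrected rates are
    strictly inside (0, 1), so both statistics are always finite.
    """
    if n_signal < 1 or n_noise < 1:
        raise ValueError("each trial type needs at least one trial")
    if not (0 <= hits <= n_signal and 0 <= false_alarms <= n_noise):
        raise ValueError("counts exceed trial totals")
    H = (hits + 0.5) / (n_signal + 1.0)
    F = (false_alarms + 0.5) / (n_noise + 1.0)
    zH, zF = norm.ppf(H), norm.ppf(F)
    return float(zH - zF), float(-(zH + zF) / 2.0)


def sdt_table(responses: pd.DataFrame, by_factors=None) -> pd.DataFrame:
    """Per-cell SDT summary: counts plus d' and criterion."""
    counts = tabulate_sdt(responses, by_factors)
    d, c = zip(*(dprime_criterion(r.hits, r.false_alarms, r.n_signal, r.n_noise)
                 for r in counts.itertuples(index=False)))
    out = counts.copy()
    out["d_prime"] = d
    out["criterion_c"] = c
    return out


def rt_summary(responses: pd.DataFrame, by_factors=None) -> pd.DataFrame:
    """Mean response time of correct, non-missed trials per cell.

    Correct means responding "different" on a different trial or "same" on
    a same trial. Cells without any correct trial yield NaN with a warning.
    ``by_factors`` defaults to the detected condition factors plus
    trial_type.
    """
    factors = _cell_factors(responses, by_factors)
    if by_factors is None and "trial_type" not in factors:
        factors = factors + ["trial_type"]
    ok = responses[(responses.response != "missed")
                   & (responses.response == responses.trial_type.map(
                       {"different": "different", "same": "same"}))]
    keys = ["participant", *factors]
    grouped = ok.groupby(keys, observed=True).rt_ms.mean().rename("mean_rt_ms")
    # reindex over all cells present in the input so empty cells surface
    all_cells = responses.groupby(keys, observed=True).size().index
    out = grouped.reindex(all_cells).reset_index()
    if out.mean_rt_ms.isna().any():
        warnings.warn("cells without correct trials: RT reported as NaN",
                      stacklevel=2)
    return out
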