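"""FIR deconvolution GLM with block and short-channel nuisance regressors.

Each participant's concatenated recording is fitted, per channel and
chromophore, with an ordinary-least-squares GLM whose design contains:

* 36 one-second boxcar (finite impulse response) regressors per condition,
  anchored on S1 onset (Experiment 1, window starting -5 s) or delay onset
  (Experiment 2, window starting -9 s) — silent trials get no regressor and
  act as the implicit baseline;
* one boxcar regressor per recording block, absorbing per-block offsets
  (no global intercept);
* the preprocessed short-channel series (8 channels x 2 chromophores = 16
  regressors), orthonormalized, as regressors of no interest.

The FIR window convention is recorded in the design metadata: 36 one-second
bins starting at the stated window start, so the supported range is
[start, start + 36) seconds around the anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CHROMOPHORES, HbSeries

__all__ = [
    "FIRWindow",
    "DesignMatrix",
    "BetaSeries",
    "build_fir_design",
    "orthogonalize_nuisance",
    "fit_ols",
    "fit_participant",
    "extract_roi_betas",
    "EXP_WINDOWS",
]

#: Per-experiment FIR anchor and window start (seconds relative to anchor).
EXP_WINDOWS = {"exp1": ("s1", -5.0), "exp2": ("delay", -9.0)}


@dataclass(frozen=True)
class FIRWindow:
    """FIR bin grid: ``n_bins`` bins of ``bin_width_s`` from ``start_s``."""

    start_s: float = -5.0
    n_bins: int = 36
    bin_width_s: float = 1.0

    def bin_start(self, k: int) -> float:
        return self.start_s + k * self.bin_width_s

    @property
    def support(self) -> tuple[float, float]:
        return (self.start_s, self.start_s + self.n_bins * self.bin_width_s)


@dataclass
class DesignMatrix:
    """Labeled design matrix.

    ``columns`` holds one ``(kind, name, bin)`` tuple per column with kinds
    ``"fir"`` (name = condition, bin = 0..35), ``"block"`` and ``"nuisance"``.
    """

    values: np.ndarray
    columns: list
    anchor: str
    window: FIRWindow
    fs: float

    def fir_column_indices(self, condition: str) -> np.ndarray:
        return np.array([i for i, (kind, name, _) in enumerate(self.columns)
                         if kind == "fir" and name == condition])

    @property
    def n_fir_columns(self) -> int:
        return sum(1 for kind, _, _ in self.columns if kind == "fir")


def _anchor_phase(anchor: str) -> str:
    if anchor == "s1":
        return "S1"
    if anchor == "delay":
        return "delay"
    raise ValueError(f"unknown anchor {anchor!r}")


def build_fir_design(events: pd.DataFrame, conditions: list[str], anchor: str,
                     window: FIRWindow, fs: float, n_samples: int,
                     nuisance: np.ndarray | None = None) -> DesignMatrix:
    """Assemble the FIR + block (+ nuisance) design matrix.

    For each stimulation trial of condition ``c`` anchored at time ``a``,
    samples with time in ``[a + start + k, a + start + k + 1)`` get 1 in
    column ``fir(c, k)``. Overlapping support within a condition is summed
    (and warned about). Block columns are 1 over each block's span.
    ``nuisance`` is an already-orthonormalized ``(n_samples, m)`` block.
    """
    phase = _anchor_phase(anchor)
    stim = events[events.phase == phase]
    cols: list = []
    mats: list[np.ndarray] = []

    fir = np.zeros((n_samples, len(conditions) * window.n_bins))
    overlap = False
    for _, row in stim.iterrows():
        if row.condition not in conditions:
            continue
        c = conditions.index(row.condition)
        a = float(row.onset)
        for k in range(window.n_bins):
            lo = a + window.bin_start(k)
            hi = lo + window.bin_width_s
            i0 = max(0, int(np.ceil(lo * fs - 1e-9)))
            i1 = min(n_samples, int(np.ceil(hi * fs - 1e-9)))
            if i1 > i0:
                col = c * window.n_bins + k
                if np.any(fir[i0:i1, col] > 0):
                    overlap = True
                fir[i0:i1, col] += 1.0
    if overlap:
        warnings.warn("overlapping FIR support within a condition; "
                      "contributions were summed", stacklevel=2)
    for c, cond in enumerate(conditions):
        for k in range(window.n_bins):
            cols.append(("fir", cond, k))
    mats.append(fir)

    blocks = events[["block", "block_onset", "block_duration"]].drop_duplicates()
    blk = np.zeros((n_samples, len(blocks)))
    for j, row in enumerate(blocks.itertuples(index=False)):
        i0 = max(0, int(np.ceil(row.block_onset * fs - 1e-9)))
        i1 = min(n_samples, int(np.ceil(
            (row.block_onset + row.block_duration) * fs - 1e-9)))
        blk[i0:i1, j] = 1.0
        cols.append(("block", row.block, None))
    mats.append(blk)

    if nuisance is not None:
        if nuisance.shape[0] != n_samples:
            raise ValueError("nuisance length does not match design length")
        mats.append(nuisance)
        for j in range(nuisance.shape[1]):
            cols.append(("nuisance", f"n{j}", None))

    return DesignMatrix(values=np.hstack(mats), columns=cols, anchor=anchor,
                        window=window, fs=fs)


def orthogonalize_nuisance(short_series: np.ndarray,
                           tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the short-channel series (same column span).

    ``short_series`` is ``(n_samples, k)``. Zero or linearly dependent
    series are dropped with a warning; the output Gram matrix is the
    identity. Because OLS projections are invariant to invertible
    recombinations of a regressor block, FIR betas are unchanged by this
    step; it only conditions the solve.
    """
    s = np.asarray(short_series, dtype=float)
    if s.ndim != 2:
        raise ValueError("expected a 2-D (n_samples, k) array")
    norms = np.linalg.norm(s, axis=0)
    keep = norms > tol * max(1.0, norms.max(initial=0.0))
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} all-zero nuisance series",
                      stacklevel=2)
    s = s[:, keep]
    if s.shape[1] == 0:
        return np.zeros((short_series.shape[0], 0))
    u, sv, _ = np.linalg.svd(s, full_matrices=False)
    rank = int(np.sum(sv > tol * sv[0]))
    if rank < s.shape[1]:
        warnings.warn(f"rank-deficient nuisance block reduced to {rank} columns",
                      stacklevel=2)
    return u[:, :rank]


@dataclass
class BetaSeries:
    """OLS estimates for one participant.

    ``beta`` has shape ``(n_targets, n_columns)`` where targets are the
    fitted (channel, chromophore) series in ``targets`` order.
    """

    beta: np.ndarray
    design: DesignMatrix
    targets: list  # list of (channel_name, chromophore)
    residual_var: np.ndarray

    def fir(self, channel_name: str, chromophore: str,
            condition: str) -> np.ndarray:
        i = self.targets.index((channel_name, chromophore))
        return self.beta[i, self.design.fir_column_indices(condition)]


def fit_ols(Y: np.ndarray, design: DesignMatrix,
            targets: list | None = None) -> BetaSeries:
    """Ordinary least squares, all target series jointly.

    ``Y`` is ``(n_samples, n_targets)``. A rank-deficient design falls back
    to the pseudo-inverse with a warning. NaNs in ``Y`` raise, naming the
    offending target.
    """
    X = design.values
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y length does not match design length")
    bad = np.any(~np.isfinite(Y), axis=0)
    if np.any(bad):
        idx = int(np.argmax(bad))
        name = targets[idx] if targets else idx
        raise ValueError(f"non-finite values in target {name!r}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"design matrix rank {rank} < {X.shape[1]} columns; using "
            "pseudo-inverse", stacklevel=2)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(X.shape[0] - rank, 1)
    res_var = (resid**2).sum(axis=0) / dof
    return BetaSeries(beta=beta.T, design=design,
                      targets=targets or list(range(Y.shape[1])),
                      residual_var=res_var)


def fit_participant(hb: HbSeries, events: pd.DataFrame, experiment: str,
                    window: FIRWindow | None = None,
                    use_short_regressors: bool = True,
                    anchor: str | None = None) -> pd.DataFrame:
    """Fit the FIR GLM for one participant's recording.

    Long channels are the fitted targets; short channels supply the
    orthonormalized nuisance block. Returns a long-format table with
    columns (channel, roi, chromophore, condition, bin, bin_start_s, beta).
    """
    default_anchor, default_start = EXP_WINDOWS[experiment]
    anchor = anchor or default_anchor
    window = window or FIRWindow(start_s=default_start)
    mont = hb.montage
    n = hb.conc.shape[-1]
    conditions = sorted(
        events.loc[(events.phase == "S1") & (events.condition != ""),
                   "condition"].unique())

    nuis = None
    if use_short_regressors and mont.short_indices.size:
        short = hb.conc[mont.short_indices]  # (n_short, 2, T)
        nuis = orthogonalize_nuisance(
            short.reshape(-1, n).T)
    design = build_fir_design(events, conditions, anchor, window, hb.fs, n,
                              nuisance=nuis)

    long_idx = mont.long_indices
    targets = [(mont.channels[i].name, chrom)
               for i in long_idx for chrom in CHROMOPHORES]
    Y = np.stack([hb.conc[i, ci]
                  for i in long_idx for ci in range(2)], axis=1)
    fit = fit_ols(Y, design, targets=targets)

    rows = []
    roi_of = {c.name: c.roi for c in mont.channels}
    for (ch_name, chrom) in targets:
        for cond in conditions:
            betas = fit.fir(ch_name, chrom, cond)
            for k in range(window.n_bins):
                rows.append(dict(channel=ch_name, roi=roi_of[ch_name],
                                 chromophore=chrom, condition=cond, bin=k,
                                 bin_start_s=window.bin_start(k),
                                 beta=betas[k]))
    return pd.DataFrame(rows)


def extract_roi_betas(beta_table: pd.DataFrame,
                      roi_map: dict[str, list[str]]) -> pd.DataFrame:
    """Unweighted mean of channel betas over each ROI's member channels.

    ``beta_table`` is the output of :func:`fit_participant` (optionally with
    a ``participant`` column). Raises if an ROI's channel is absent.
    """
    frames = []
    group_cols = [c for c in ("participant", "chromophore", "condition",
                              "bin", "bin_start_s") if c in beta_table.columns]
    for roi, members in roi_map.items():
        present = set(beta_table.channel.unique())
        missing = [m for m in members if m not in present]
        if missing:
            raise ValueError(
                f"ROI {roi!r} channels missing from beta table: {missing} "
                f"(membership: {members})")
        sub = beta_table[beta_table.channel.isin(members)]
        agg = sub.groupby(group_cols, as_index=False).beta.mean()
        agg.insert(0, "roi", roi)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)
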