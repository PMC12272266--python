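"""Forward simulation of two-wavelength fNIRS recordings with known ground truth.

The participant data this pipeline targets cannot be redistributed, so this
module generates recordings whose statistical structure matches what the
analysis assumes: long channels carry a trial-locked hemodynamic response
(a stimulus boxcar convolved with a double-gamma HRF peaking ~5 s) plus
systemic physiology shared with the short channels; short channels carry
systemic physiology and noise only; motion artifacts (transient spikes and
step baseline shifts) can be injected in the optical-density domain; and
behavioral responses follow a signal-detection model with per-condition
sensitivity and bias.

The trial-locked response is injected as a *staircase*: the smooth
boxcar-HRF convolution is sampled at the centers of the 1-second FIR bins
and held constant within each bin. The injected signal therefore lies
exactly in the span of the FIR design matrix, which makes the ground-truth
FIR coefficients identifiable to machine precision on noiseless data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import ExperimentPlan
from .preprocess import (CHROMOPHORES, DEFAULT_FS, Channel, HbSeries, Montage,
                         OpticalConstants, RawRecording)

__all__ = [
    "ForwardConfig",
    "GroundTruth",
    "BehavioralTruth",
    "default_montage",
    "double_gamma_hrf",
    "fir_ground_truth",
    "simulate_hb",
    "hb_to_raw_intensity",
    "inject_motion",
    "plan_trials",
    "behavioral_simulator",
    "ROI_SIZES",
]

#: Channels per region of interest among the 18 analyzed long channels.
ROI_SIZES = {"lIFG": 3, "rIFG": 3, "ldlPFC": 4, "rdlPFC": 4, "SFG": 4}


def default_montage() -> Montage:
    """Synthetic frontal montage: 22 long channels (2.9-4.1 cm) + 8 short (0.8 cm).

    The geometry is a schematic frontal arc, not an anatomical optode
    layout: positions exist so that source-detector distances and
    short-channel flags are well defined and survive SNIRF round trips.
    18 long channels are assigned to the five ROIs (3+3+4+4+4); the
    remaining 4 long channels are recorded but unassigned, mirroring a
    montage in which some channels are excluded from analysis.
    """
    rois = (["lIFG"] * 3 + ["ldlPFC"] * 4 + ["SFG"] * 4 + ["rdlPFC"] * 4 +
            ["rIFG"] * 3 + [None] * 4)
    channels = []
    rng_dist = np.linspace(2.9, 4.1, 22)  # deterministic spread of separations
    for i in range(22):
        theta = math.pi * (i + 1) / 23.0
        x, y = 10.0 * math.cos(theta), 10.0 * math.sin(theta)
        d = float(rng_dist[i])
        channels.append(Channel(
            name=f"L{i + 1:02d}", source=i + 1, detector=i + 1,
            distance_cm=d, is_short=False, roi=rois[i],
            source_pos=(x, y, 0.0), detector_pos=(x + d, y, 0.0)))
    for j in range(8):
        x, y = 2.5 * j, -5.0
        channels.append(Channel(
            name=f"S{j + 1:02d}", source=23 + j, detector=23 + j,
            distance_cm=0.8, is_short=True, roi=None,
            source_pos=(x, y, 0.0), detector_pos=(x + 0.8, y, 0.0)))
    return Montage(tuple(channels))


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------

def double_gamma_hrf(t, peak_shape: float = 6.0, undershoot_shape: float = 16.0,
                     scale: float = 1.0, undershoot_ratio: float = 1.0 / 6.0):
    """Canonical double-gamma HRF, peak-normalized to 1.

    ``h(t) = g(t; a1, b) - c * g(t; a2, b)`` with gamma densities ``g``;
    with the defaults the main lobe peaks at ``(a1 - 1) * b = 5`` seconds
    and ``h(0) = 0``.
    """
    if peak_shape <= 0 or undershoot_shape <= 0 or scale <= 0:
        raise ValueError("gamma shape/scale parameters must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("HRF is defined for t >= 0")

    def gamma_pdf(x, a, b):
        with np.errstate(divide="ignore"):
            logp = ((a - 1) * np.log(np.where(x > 0, x, 1.0)) - x / b
                    - math.lgamma(a) - a * math.log(b))
        return np.where(x > 0, np.exp(logp), 0.0)

    h = (gamma_pdf(t, peak_shape, scale)
         - undershoot_ratio * gamma_pdf(t, undershoot_shape, scale))
    # normalize by the analytic peak of the same kernel on a fine grid
    tt = np.arange(0.0, 40.0, 0.005)
    hh = (gamma_pdf(tt, peak_shape, scale)
          - undershoot_ratio * gamma_pdf(tt, undershoot_shape, scale))
    return h / hh.max()


@dataclass
class ForwardConfig:
    """Generative parameters of the simulator.

    ``effects`` maps ``(roi, condition)`` to the peak HbO concentration
    change in uM; HbR is generated as ``-hbr_ratio`` times the HbO response.
    Systemic amplitudes are in uM on the HbO scale; cardiac (~1.2 Hz) and
    respiratory (~0.25 Hz) components fall outside the 0.01-0.2 Hz analysis
    band, while the Mayer-wave component (~0.1 Hz) falls inside it and is
    what short-channel regression must remove. All systemic components are
    shared across channels up to per-channel gains, which is the premise of
    short-channel regression.
    """

    effects: dict = field(default_factory=dict)
    hbr_ratio: float = 0.3
    hrf_peak_shape: float = 6.0
    hrf_undershoot_shape: float = 16.0
    hrf_scale: float = 1.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    cardiac_hz: float = 1.2
    cardiac_amp: float = 0.0
    resp_hz: float = 0.25
    resp_amp: float = 0.0
    mayer_hz: float = 0.1
    mayer_amp: float = 0.0
    drift_hz: float = 0.008
    drift_amp: float = 0.0
    noise_sd: float = 0.0
    spike_rate_per_min: float = 0.0
    spike_amp: float = 0.0
    shift_rate_per_min: float = 0.0
    shift_amp: float = 0.0
    intensity_noise_sd: float = 0.0
    fs: float = DEFAULT_FS
    anchor: str = "s1"  # "s1" | "delay"
    window_start_s: float = -5.0
    n_bins: int = 36
    bin_width_s: float = 1.0

    def __post_init__(self) -> None:
        nyq = self.fs / 2.0
        for f in (self.cardiac_hz, self.resp_hz, self.mayer_hz, self.drift_hz):
            if not (0 < f < nyq):
                raise ValueError(f"systemic frequency {f} Hz outside (0, {nyq})")
        for a in (self.cardiac_amp, self.resp_amp, self.mayer_amp,
                  self.drift_amp, self.noise_sd):
            if a < 0:
                raise ValueError("amplitudes must be >= 0")

    def hrf(self, t):
        return double_gamma_hrf(t, self.hrf_peak_shape, self.hrf_undershoot_shape,
                                self.hrf_scale, self.hrf_undershoot_ratio)


@dataclass
class GroundTruth:
    """Closed-form expected FIR coefficients and the artifact log.

    ``profiles[condition]`` is the unit-peak staircase profile over the FIR
    bins; the expected beta for a channel is ``profile * effect(roi,
    condition)`` for HbO and ``-hbr_ratio`` times that for HbR.
    """

    profiles: dict
    config: ForwardConfig
    montage: Montage
    artifact_log: list = field(default_factory=list)

    def fir(self, channel_name: str, chromophore: str, condition: str) -> np.ndarray:
        ch = next(c for c in self.montage.channels if c.name == channel_name)
        eff = 0.0 if ch.roi is None else self.config.effects.get(
            (ch.roi, condition), 0.0)
        sign = 1.0 if chromophore == "hbo" else -self.config.hbr_ratio
        return self.profiles[condition] * eff * sign

    def roi_fir(self, roi: str, chromophore: str, condition: str) -> np.ndarray:
        eff = self.config.effects.get((roi, condition), 0.0)
        sign = 1.0 if chromophore == "hbo" else -self.config.hbr_ratio
        return self.profiles[condition] * eff * sign


def fir_ground_truth(boxcar_duration_s: float, anchor_offset_s: float,
                     config: ForwardConfig) -> np.ndarray:
    """Unit-peak FIR profile of one condition.

    Convolves a boxcar of the given duration (starting ``anchor_offset_s``
    seconds relative to the FIR anchor) with the HRF on a 10 ms grid,
    normalizes the peak to 1, and samples at the FIR bin centers.
    """
    dt = 0.01
    tmax = config.window_start_s + config.n_bins * config.bin_width_s + 1.0
    t = np.arange(0.0, tmax - min(0.0, anchor_offset_s) + 35.0, dt)
    hrf = config.hrf(t)
    box = ((t >= 0) & (t < boxcar_duration_s)).astype(float)
    conv = np.convolve(box, hrf)[:t.size] * dt
    peak = conv.max()
    if peak <= 0:
        return np.zeros(config.n_bins)
    conv /= peak
    centers = (config.window_start_s
               + (np.arange(config.n_bins) + 0.5) * config.bin_width_s
               - anchor_offset_s)
    return np.interp(centers, t, conv, left=0.0, right=0.0)


# ---------------------------------------------------------------------------
# Hemoglobin-level simulation
# ---------------------------------------------------------------------------

def _anchor_column(anchor: str) -> str:
    if anchor == "s1":
        return "S1"
    if anchor == "delay":
        return "delay"
    raise ValueError(f"unknown anchor {anchor!r}")


def simulate_hb(events: pd.DataFrame, montage: Montage, config: ForwardConfig,
                rng: np.random.Generator):
    """Simulate HbO/HbR series for all channels of one participant.

    ``events`` is a session events table (see ``design.session_events``).
    Long channels receive, per stimulation trial, the condition's staircase
    FIR profile scaled by the ROI effect; silent trials contribute nothing
    (implicit baseline). Systemic components and white noise are added to
    long and short channels alike; short channels carry no neural term.

    Returns ``(hb, ground_truth)`` where ``hb`` is an :class:`HbSeries`
    over the full montage.
    """
    stim = events[events.phase == _anchor_column(config.anchor)]
    conditions = sorted(stim.condition.unique())
    for cond in conditions:
        found = any((roi, cond) in config.effects for roi in ROI_SIZES)
        if config.effects and not found:
            raise ValueError(f"condition {cond!r} missing from effects map")

    total_s = float((events.block_onset + events.block_duration).max())
    n = int(round(total_s * config.fs))
    t = np.arange(n) / config.fs

    # per-condition unit profiles (staircase heights at bin centers)
    s1_rows = events[events.phase == "S1"]
    profiles = {}
    for cond in conditions:
        row = s1_rows[s1_rows.condition == cond].iloc[0]
        seq_s = float(row.duration)
        trial_s = 2 * seq_s + 6.0  # S1 + delay + S2
        offset = 0.0 if config.anchor == "s1" else -seq_s
        profiles[cond] = fir_ground_truth(trial_s, offset, config)

    # neural staircase, built once per condition then scaled per channel
    cond_signal = {c: np.zeros(n) for c in conditions}
    for _, row in stim.iterrows():
        prof = profiles[row.condition]
        anchor_t = float(row.onset)
        for k in range(config.n_bins):
            lo = anchor_t + config.window_start_s + k * config.bin_width_s
            hi = lo + config.bin_width_s
            i0 = max(0, int(np.ceil(lo * config.fs - 1e-9)))
            i1 = min(n, int(np.ceil(hi * config.fs - 1e-9)))
            if i1 > i0:
                cond_signal[row.condition][i0:i1] += prof[k]

    # systemic latents, shared across channels up to gains
    latents = []
    for freq, amp in ((config.cardiac_hz, config.cardiac_amp),
                      (config.resp_hz, config.resp_amp),
                      (config.mayer_hz, config.mayer_amp),
                      (config.drift_hz, config.drift_amp)):
        phase = rng.uniform(0, 2 * np.pi)
        latents.append(amp * np.sin(2 * np.pi * freq * t + phase))
    latents = np.array(latents)

    n_ch = montage.n_channels
    conc = np.zeros((n_ch, 2, n))
    for i, ch in enumerate(montage.channels):
        gains = rng.uniform(0.5, 1.5, size=latents.shape[0])
        systemic = gains @ latents
        for ci, chrom in enumerate(CHROMOPHORES):
            sys_scale = 1.0 if chrom == "hbo" else config.hbr_ratio
            sig = sys_scale * systemic + rng.normal(0, config.noise_sd, n) \
                if config.noise_sd > 0 else sys_scale * systemic
            if not ch.is_short and ch.roi is not None:
                neural_sign = 1.0 if chrom == "hbo" else -config.hbr_ratio
                for cond in conditions:
                    eff = config.effects.get((ch.roi, cond), 0.0)
                    if eff:
                        sig = sig + neural_sign * eff * cond_signal[cond]
            conc[i, ci] = sig

    hb = HbSeries(conc=conc, fs=config.fs, montage=montage)
    return hb, GroundTruth(profiles=profiles, config=config, montage=montage)


# ---------------------------------------------------------------------------
# Optics: hemoglobin -> raw intensity
# ---------------------------------------------------------------------------

def inject_motion(series: np.ndarray, fs: float, rng: np.random.Generator,
                  spike_rate_per_min: float = 0.0, spike_amp: float = 0.0,
                  shift_rate_per_min: float = 0.0, shift_amp: float = 0.0):
    """Add transient spikes and step baseline shifts at Poisson times.

    ``series`` is ``(n_series, n_times)``; spikes decay exponentially with a
    0.25 s time constant (support well under 1 s), shifts are persistent
    steps. Returns ``(corrupted, log)`` where the log records each event as
    ``(time_s, kind, series_index, magnitude)``.
    """
    if spike_rate_per_min < 0 or shift_rate_per_min < 0:
        raise ValueError("artifact rates must be >= 0")
    series = np.asarray(series, dtype=float)
    out = series.copy()
    n_series, n = out.shape
    dur_min = n / fs / 60.0
    log = []
    t = np.arange(n) / fs
    for idx in range(n_series):
        for _ in range(rng.poisson(spike_rate_per_min * dur_min)):
            t0 = rng.uniform(0, n / fs)
            amp = spike_amp * rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.2)
            mask = t >= t0
            out[idx, mask] += amp * np.exp(-(t[mask] - t0) / 0.25)
            log.append((t0, "spike", idx, amp))
        for _ in range(rng.poisson(shift_rate_per_min * dur_min)):
            t0 = rng.uniform(0, n / fs)
            amp = shift_amp * rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.2)
            out[idx, t >= t0] += amp
            log.append((t0, "shift", idx, amp))
    return out, log


def hb_to_raw_intensity(hb: HbSeries, constants: OpticalConstants | None = None,
                        rng: np.random.Generator | None = None,
                        config: ForwardConfig | None = None):
    """Forward modified Beer-Lambert law: concentrations -> raw intensities.

    ``dOD_lambda = (eps_HbO dHbO + eps_HbR dHbR) * d * DPF_lambda`` with
    concentrations in mM, then ``I = baseline * exp(-dOD)``, optionally with
    multiplicative log-normal measurement noise and motion artifacts
    injected into the optical density. Returns ``(RawRecording, artifact_log)``.
    """
    constants = constants or OpticalConstants()
    eps = constants.extinction_matrix
    dpf = np.asarray(constants.dpf)
    n_ch, _, n = hb.conc.shape
    od = np.empty((n_ch, 2, n))
    for i, ch in enumerate(hb.montage.channels):
        conc_mM = hb.conc[i] / 1000.0  # (chromophore, time)
        od[i] = (eps @ conc_mM) * (ch.distance_cm * dpf)[:, None]

    log = []
    if config is not None and (config.spike_rate_per_min > 0
                               or config.shift_rate_per_min > 0):
        if rng is None:
            raise ValueError("motion injection requires an rng")
        flat, log = inject_motion(
            od.reshape(-1, n), hb.fs, rng,
            spike_rate_per_min=config.spike_rate_per_min,
            spike_amp=config.spike_amp,
            shift_rate_per_min=config.shift_rate_per_min,
            shift_amp=config.shift_amp)
        od = flat.reshape(od.shape)

    intensity = constants.baseline_intensity * np.exp(-od)
    if config is not None and config.intensity_noise_sd > 0:
        if rng is None:
            raise ValueError("intensity noise requires an rng")
        intensity = intensity * np.exp(
            rng.normal(0, config.intensity_noise_sd, intensity.shape))
    raw = RawRecording(intensity=intensity, fs=hb.fs, montage=hb.montage)
    return raw, log


# ---------------------------------------------------------------------------
# Behavioral simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehavioralTruth:
    """Generative per-cell behavioral parameters."""

    d_prime: float
    criterion: float
    rt_median_ms: float = 1000.0
    rt_sigma: float = 0.3


def plan_trials(plan: ExperimentPlan) -> pd.DataFrame:
    """Flatten an experiment plan into one row per stimulation trial."""
    rows = []
    for p in range(plan.n_participants):
        for blk in plan.participant_blocks(p):
            for e in blk.stimulation_entries:
                pr = e.pair
                rows.append(dict(participant=p, block=blk.block_id,
                                 task=pr.task, material=pr.material,
                                 memory_load=pr.memory_load or "",
                                 trial_type=pr.trial_type))
    return pd.DataFrame(rows)


def _cell_key(row) -> tuple:
    if row.memory_load:
        return (row.memory_load, row.material)
    return (row.task, row.material)


def behavioral_simulator(trials: pd.DataFrame, truth: dict,
                         rng: np.random.Generator,
                         response_window_ms: float = 3000.0) -> pd.DataFrame:
    """Simulate same/different responses under an equal-variance SDT model.

    For a cell with sensitivity d' and criterion c, a different-trial is
    answered "different" with probability ``Phi(d'/2 - c)`` and a same-trial
    with probability ``Phi(-d'/2 - c)``. Response times are log-normal;
    draws beyond the response window are marked ``"missed"``.
    """
    out = trials.copy()
    responses, rts = [], []
    for row in out.itertuples(index=False):
        cell = truth[_cell_key(row)]
        if not np.isfinite(cell.d_prime):
            raise ValueError("d' must be finite")
        p_diff = norm.cdf((cell.d_prime / 2.0 if row.trial_type == "different"
                           else -cell.d_prime / 2.0) - cell.criterion)
        resp = "different" if rng.uniform() < p_diff else "same"
        rt = float(np.exp(rng.normal(np.log(cell.rt_median_ms), cell.rt_sigma)))
        if rt > response_window_ms:
            resp, rt = "missed", np.nan
        responses.append(resp)
        rts.append(rt)
    out["response"] = responses
    out["rt_ms"] = rts
    return out
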