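"""Protocol-faithful synthetic EEG with controllable class effects.

Each simulated run reproduces the shoe-viewing trial structure: 2 s
fixation, 8 s product display, 1 s rest (11 s total), with event markers
at the stage boundaries and a like/dislike response marker placed
uniformly at random inside the display window.

The signal model per channel is

    x(t) = g_subj * [ background_{1/f}(t) + sum_b A_b * m_b(t) * sin(2*pi*f_b*t + phi) ]
           + sensor noise,

where ``background`` is white noise spectrally shaped to 1/f^exponent,
each band b contributes a sinusoid at its center frequency f_b with
random phase, and ``m_b(t)`` is 1 outside the stimulus window and a
class-dependent gain inside it. Effects are declared per band and per
region (or channel list): on like trials the oscillator amplitude is
multiplied by ``like_gain`` and split left/right by ``asym_delta``
(left channels scaled by 1 - delta, right by 1 + delta); dislike
trials get ``dislike_gain`` with no asymmetry. Amplitude-modulated
sinusoids (rather than band-filtered noise) keep injected band powers
analytically predictable: a sinusoid of amplitude A carries power
A^2 / 2.

Both the background and the oscillators are synthesized from
independent grains joined by short power-preserving crossfades, with
fresh noise realizations and oscillator phases per grain and grain
boundaries aligned to the sub-segment grid of the default analysis.
Sub-segments of one run are then statistically exchangeable with
sub-segments of any other run of the same condition. A single run-wide
realization would instead stamp all sub-segments of a run with a
common random fingerprint (low-frequency amplitude, oscillator phase),
which a pooled segment-level cross-validation can exploit to recover
run identity — and with it the label — even when no class effect
exists.

The per-subject amplitude scale g_subj is drawn once per subject from a
lognormal distribution and multiplies everything physiological
(background and oscillators) but not the additive sensor noise.

With an empty effect list the signal is statistically identical for
like and dislike runs, which is the null condition used to calibrate
the statistical and classification stages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .recording import EventMarker, Montage, RawRecording, default_montage

FIXATION_SEC = 2.0
STIMULUS_SEC = 8.0
REST_SEC = 1.0
RUN_SEC = FIXATION_SEC + STIMULUS_SEC + REST_SEC

#: Band-center frequencies (Hz) of the oscillators, midpoints of the
#: standard delta/theta/alpha/beta definitions.
BAND_CENTERS = {"delta": 2.25, "theta": 6.0, "alpha": 10.5, "beta": 21.5}

_DIGITS = re.compile(r"(\d+)$")


def channel_side(label: str) -> str:
    """``left``/``right``/``midline`` from a 10-20 label (odd=left, even=right)."""
    m = _DIGITS.search(label)
    if m is None:
        return "midline"
    return "left" if int(m.group(1)) % 2 == 1 else "right"


@dataclass(frozen=True)
class EffectSpec:
    """A class-dependent band-power effect placed on a region or channel set."""

    band: str
    region_or_channels: str | tuple[str, ...]
    like_gain: float = 1.0
    dislike_gain: float = 1.0
    asym_delta: float = 0.0

    def __post_init__(self):
        if self.like_gain <= 0 or self.dislike_gain <= 0:
            raise ParameterError("effect gains must be positive")
        if not abs(self.asym_delta) < 1:
            raise ParameterError("|asym_delta| must be < 1")

    def channels(self, montage: Montage) -> tuple[str, ...]:
        if isinstance(self.region_or_channels, str):
            return montage.region_channels(self.region_or_channels)
        return tuple(self.region_or_channels)


def default_effects() -> tuple[EffectSpec, ...]:
    """Calibrated default class effects.

    Like trials raise band power in every band with the alpha effect
    strongest and anchored occipitally (plus a rightward alpha
    asymmetry over occipital and frontal channels); delta/theta/beta
    carry weaker increases over frontal, temporal, parietal and
    occipital sites. The central region is left effect-free as a
    negative control. This layout reproduces the qualitative preference
    signature the pipeline is built to detect: the strongest
    like-vs-dislike power contrast in occipital alpha, above-chance but
    weaker single-band decoding everywhere else, and fusion across
    bands or regions at least matching the best subset.
    """
    return (
        EffectSpec(band="alpha", region_or_channels="occipital",
                   like_gain=2.6, dislike_gain=1.0, asym_delta=0.25),
        EffectSpec(band="alpha", region_or_channels="frontal",
                   like_gain=1.8, dislike_gain=1.0, asym_delta=0.25),
        EffectSpec(band="beta", region_or_channels="occipital", like_gain=1.6),
        EffectSpec(band="beta", region_or_channels="parietal", like_gain=1.45),
        EffectSpec(band="theta", region_or_channels=("T7", "T8"), like_gain=1.55),
        EffectSpec(band="theta", region_or_channels="frontal", like_gain=1.4),
        EffectSpec(band="delta", region_or_channels=("T7", "T8"), like_gain=1.5),
        EffectSpec(band="delta", region_or_channels="frontal", like_gain=1.4),
    )


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults reproduce the study design: 15 subjects x 25 runs at
    500 Hz, balanced like probability, and the calibrated default
    effects. ``band_amps`` are oscillator amplitudes in microvolts;
    ``background_sd`` and ``noise_sd`` are standard deviations in
    microvolts of the 1/f background and the white sensor noise.
    """

    n_subjects: int = 15
    n_runs_per_subject: int = 25
    fs: float = 500.0
    like_prob: float = 0.5
    background_exponent: float = 1.0
    background_sd: float = 10.0
    band_amps: dict[str, float] = field(
        default_factory=lambda: {"delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 4.0})
    subject_gain_sd: float = 0.02
    effects: tuple[EffectSpec, ...] = field(default_factory=default_effects)
    noise_sd: float = 2.0
    artifact_rate: float = 0.0
    seed: int = 0
    balanced_labels: bool = False
    montage: Montage = field(default_factory=default_montage)

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_runs_per_subject < 1:
            raise ParameterError("need at least one subject and one run")
        if not 0 < self.like_prob < 1:
            raise ParameterError("like_prob must be in (0, 1)")
        if self.fs < 128:
            raise ParameterError("fs must be >= 128 Hz")
        for name in self.band_amps:
            if name not in BAND_CENTERS:
                raise ParameterError(f"unknown band {name!r} in band_amps")
        self.effects = tuple(
            e if isinstance(e, EffectSpec) else EffectSpec(**e) for e in self.effects
        )


#: Seconds of sample-grid time per analysis sub-segment after the default
#: preprocessing (8-s window, downsampled to 256 Hz, split into 6 equal
#: segments of 341 samples): the synthesis grain grid aligns with it.
SEGMENT_SEC = 341.0 / 256.0

#: Total crossfade width (s) joining adjacent grains; kept to a few
#: milliseconds so the random mass shared by neighbouring analysis
#: segments is negligible.
GRAIN_XFADE_SEC = 0.008


def grain_boundaries(fs: float) -> np.ndarray:
    """Grain-boundary sample indices for one run.

    Grains inside the stimulus window are aligned with the sub-segment
    grid of the default analysis (six segments of ``SEGMENT_SEC``), so
    each analysis segment maps onto exactly one independent grain;
    fixation and rest are covered by their own grains. Random mass
    shared between adjacent segments is then limited to the short
    crossfade at the joins — without alignment, a grain straddling a
    segment boundary hands both neighbours the same realization, which
    a pooled segment-level cross-validation can exploit as a run
    fingerprint.
    """
    n = int(round(RUN_SEC * fs))
    bounds = [0.0, 1.0, FIXATION_SEC]
    bounds += [FIXATION_SEC + k * SEGMENT_SEC for k in range(1, 7)]
    bounds += [RUN_SEC]
    idx = np.unique(np.clip(np.round(np.array(bounds) * fs).astype(int), 0, n))
    return idx


def _grain_envelopes(bounds: np.ndarray, n: int, xfade: int):
    """Per-grain (start, stop, envelope) with sine/cosine crossfades
    whose squared sum is 1 across each join."""
    half = xfade // 2
    grains = []
    for g in range(len(bounds) - 1):
        lo = max(bounds[g] - half, 0)
        hi = min(bounds[g + 1] + half, n)
        env = np.ones(hi - lo)
        if bounds[g] > 0:  # fade in across [bound-half, bound+half)
            ramp = np.sin(np.pi * (np.arange(2 * half) + 0.5) / (4 * half))
            env[:2 * half] = ramp[: hi - lo]
        if bounds[g + 1] < n:  # fade out
            ramp = np.cos(np.pi * (np.arange(2 * half) + 0.5) / (4 * half))
            env[-2 * half:] = ramp[-(hi - lo):]
        grains.append((lo, hi, env))
    return grains


def _shaped_noise(rng: np.random.Generator, n_ch: int, length: int, fs: float,
                  exponent: float) -> np.ndarray:
    white = rng.standard_normal((n_ch, length))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(length, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * scale, n=length, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _shaped_background(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                       exponent: float, grains) -> np.ndarray:
    """1/f^exponent background: an independent FFT-shaped realization
    per grain (unit sd), joined by power-preserving crossfades. Grain
    independence keeps disjoint analysis segments statistically
    exchangeable; a single run-wide realization would stamp all
    sub-segments of a run with the same low-frequency amplitude."""
    out = np.zeros((n_ch, n))
    for lo, hi, env in grains:
        out[:, lo:hi] += env * _shaped_noise(rng, n_ch, hi - lo, fs, exponent)
    return out


def _grain_oscillator(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                      fc: float, grains) -> np.ndarray:
    """Unit-amplitude oscillator at ``fc`` Hz whose phase is redrawn
    per grain and per channel; expected instantaneous power stays 1/2
    (crossfaded neighbours have independent phases and squared
    envelopes summing to 1)."""
    out = np.zeros((n_ch, n))
    for lo, hi, env in grains:
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        tt = np.arange(lo, hi) / fs
        out[:, lo:hi] += env * np.sin(
            2 * np.pi * fc * tt[None, :] + phases[:, None])
    return out


def generate_run(cfg: SimConfig, subject_id: str, run_id: str, label: int,
                 rng: np.random.Generator,
                 subject_gain: float = 1.0) -> RawRecording:
    """Simulate one 11-s run.

    ``label`` is 1 (like) or 0 (dislike); it selects the effect gains
    inside the stimulus window and the response-marker code. With an
    empty effect list the label influences markers only.
    """
    montage = cfg.montage
    n_ch = montage.n_channels
    n = int(round(RUN_SEC * cfg.fs))
    xfade = max(2, int(round(GRAIN_XFADE_SEC * cfg.fs)))
    grains = _grain_envelopes(grain_boundaries(cfg.fs), n, xfade)

    stim_start = int(round(FIXATION_SEC * cfg.fs))
    stim_stop = int(round((FIXATION_SEC + STIMULUS_SEC) * cfg.fs))

    signal = cfg.background_sd * _shaped_background(
        rng, n_ch, n, cfg.fs, cfg.background_exponent, grains)

    stim_mask = np.zeros(n)
    stim_mask[stim_start:stim_stop] = 1.0

    for band, amp in cfg.band_amps.items():
        fc = BAND_CENTERS[band]
        wave = _grain_oscillator(rng, n_ch, n, cfg.fs, fc, grains)
        # per-channel stimulus-window gain for this band
        gain = np.ones(n_ch)
        for eff in cfg.effects:
            if eff.band != band:
                continue
            g = eff.like_gain if label == 1 else eff.dislike_gain
            for ch in eff.channels(montage):
                idx = montage.index(ch)
                g_ch = g
                if label == 1 and eff.asym_delta != 0.0:
                    side = channel_side(ch)
                    if side == "left":
                        g_ch *= 1.0 - eff.asym_delta
                    elif side == "right":
                        g_ch *= 1.0 + eff.asym_delta
                gain[idx] *= g_ch
        envelope = 1.0 + (gain[:, None] - 1.0) * stim_mask[None, :]
        signal += amp * envelope * wave

    signal *= subject_gain
    signal += cfg.noise_sd * rng.standard_normal((n_ch, n))

    response_code = "response_like" if label == 1 else "response_dislike"
    resp_onset = int(rng.integers(stim_start + 1, stim_stop))
    markers = [
        EventMarker(0, "fixation"),
        EventMarker(stim_start, "stimulus_on"),
        EventMarker(resp_onset, response_code),
        EventMarker(stim_stop, "rest"),
    ]

    rec = RawRecording(data=signal, fs=cfg.fs, montage=montage, markers=markers,
                       subject_id=subject_id, run_id=run_id)

    if cfg.artifact_rate > 0:
        n_blinks = rng.poisson(cfg.artifact_rate * RUN_SEC / 60.0)
        for _ in range(n_blinks):
            onset = rng.uniform(0, RUN_SEC - 0.4)
            amp = rng.lognormal(np.log(80.0), 0.3)
            rec = inject_blink(rec, onset, amp)
    return rec


def _run_rng(seed: int, subj_idx: int, run_idx: int) -> np.random.Generator:
    """Deterministic per-run substream, reproducible in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subj_idx, run_idx)))


def generate_dataset(cfg: SimConfig) -> tuple[list[RawRecording], pd.DataFrame]:
    """Simulate the full dataset: one recording per (subject, run).

    Returns the recordings plus a truth table with columns
    ``subject_id, run_id, label, subject_gain``. Labels are drawn
    i.i.d. Bernoulli(like_prob) per run; the subject amplitude scale is
    drawn once per subject. Fully reproducible from ``cfg.seed``, and
    each run is reproducible in isolation from its (subject, run)
    index.
    """
    root = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2 ** 20,)))
    gains = np.exp(root.normal(0.0, cfg.subject_gain_sd, size=cfg.n_subjects))
    if cfg.balanced_labels:
        # near-exact class balance per subject (shuffled), for
        # calibration runs where class-prior fluctuations of the
        # Bernoulli draw would masquerade as decoding bias
        m = cfg.n_runs_per_subject
        labels = np.empty((cfg.n_subjects, m), dtype=int)
        for si in range(cfg.n_subjects):
            n_like = m // 2 + (si % 2 if m % 2 else 0)
            lab = np.array([1] * n_like + [0] * (m - n_like))
            labels[si] = root.permutation(lab)
    else:
        labels = (root.random((cfg.n_subjects, cfg.n_runs_per_subject))
                  < cfg.like_prob).astype(int)

    recordings: list[RawRecording] = []
    rows = []
    for si in range(cfg.n_subjects):
        subject_id = f"sub{si + 1:02d}"
        for ri in range(cfg.n_runs_per_subject):
            run_id = f"run{ri + 1:02d}"
            rng = _run_rng(cfg.seed, si, ri)
            rec = generate_run(cfg, subject_id, run_id, int(labels[si, ri]),
                               rng, subject_gain=float(gains[si]))
            recordings.append(rec)
            rows.append({"subject_id": subject_id, "run_id": run_id,
                         "label": int(labels[si, ri]),
                         "subject_gain": float(gains[si])})
    return recordings, pd.DataFrame(rows)


#: Anterior-to-posterior spatial weighting of the eye-blink artifact.
_BLINK_WEIGHTS = (("FP", 1.0), ("TP", 0.2), ("F", 0.55), ("T", 0.3),
                  ("C", 0.3), ("P", 0.1), ("O", 0.03))


def _blink_weight(label: str) -> float:
    for prefix, w in _BLINK_WEIGHTS:
        if label.upper().startswith(prefix):
            return w
    return 0.1


def inject_blink(rec: RawRecording, onset: float, amplitude: float,
                 width: float = 0.4) -> RawRecording:
    """Return a copy of ``rec`` with an eye-blink transient added.

    The blink is a positive half-cosine bump of ``width`` seconds
    peaking at ``onset + width/2``, maximal on the prefrontal channels
    and decaying toward posterior sites. Superposition is linear, so
    multiple blinks add.
    """
    if not 0 <= onset < rec.duration:
        raise ParameterError(f"blink onset {onset} s outside recording "
                             f"(0-{rec.duration} s)")
    out = rec.copy()
    start = int(round(onset * rec.fs))
    stop = min(start + int(round(width * rec.fs)), rec.n_samples)
    tt = (np.arange(stop - start)) / rec.fs
    bump = 0.5 * (1 - np.cos(2 * np.pi * tt / width))
    weights = np.array([_blink_weight(c) for c in rec.montage.channel_names])
    out.data[:, start:stop] += amplitude * weights[:, None] * bump[None, :]
    return out
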