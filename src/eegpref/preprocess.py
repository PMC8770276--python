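"""The offline preprocessing chain.

Stage order is fixed: re-reference -> bandpass -> epoch extraction ->
downsample -> segmentation. Individual stages can be skipped via
:func:`run_preprocessing` but never reordered, because the stages are
not commutative (filtering after epoching, for instance, would leak
edge transients into every epoch).

Filtering is zero-phase (forward-backward Butterworth). The design
order refers to the one-pass filter; the effective order after the
backward pass is doubled. Zero-phase filtering is the standard choice
for offline feature extraction since phase distortion would shift
oscillatory energy between the sub-segments that later become
classification samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import MarkerError, ParameterError
from .recording import EpochSet, Montage, RawRecording

from fractions import Fraction


@dataclass
class SegmentSet:
    """Equal-length sub-windows of epochs, the unit of classification.

    ``meta`` holds (subject_id, run_id, segment_index) per segment;
    labels are inherited from the parent epoch.
    """

    segments: np.ndarray
    fs: float
    labels: np.ndarray
    meta: list[tuple[str, str, int]]
    montage: Montage

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.segments.ndim != 3:
            raise ParameterError("segments must be segments x channels x samples")
        if len(self.labels) != self.segments.shape[0]:
            raise ParameterError("labels length must equal segment count")
        if len(self.meta) != self.segments.shape[0]:
            raise ParameterError("meta length must equal segment count")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


def rereference(rec: RawRecording, refs: tuple[str, ...] = ("TP9", "TP10")) -> RawRecording:
    """Re-express every channel relative to the mean of the reference
    channels (default: the bilateral mastoids TP9/TP10), sample-wise.
    Reference channels stay in the output (they become the negated
    common mode)."""
    for r in refs:
        if r not in rec.montage.channel_names:
            raise ParameterError(f"reference channel {r!r} not in montage")
    idx = [rec.montage.index(r) for r in refs]
    out = rec.copy()
    out.data = out.data - out.data[idx].mean(axis=0, keepdims=True)
    return out


def bandpass(rec: RawRecording, lo: float = 0.5, hi: float = 40.0,
             order: int = 4) -> RawRecording:
    """Zero-phase Butterworth bandpass, applied per channel.

    ``order`` is the one-pass design order (default 4); the
    forward-backward application squares the magnitude response.
    """
    nyq = rec.fs / 2.0
    if not 0 < lo < hi:
        raise ParameterError("need 0 < lo < hi")
    if hi >= nyq:
        raise ParameterError(f"high edge {hi} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=-1)
    return out


def extract_epochs(recs: list[RawRecording],
                   window: tuple[float, float] = (0.0, 8.0)) -> EpochSet:
    """Cut one stimulus-locked epoch per run.

    The window is in seconds relative to the ``stimulus_on`` marker,
    half-open. Each recording must contain exactly one ``stimulus_on``
    and exactly one response marker; the response code supplies the
    label (like=1, dislike=0).
    """
    if not recs:
        raise ParameterError("no recordings given")
    epochs, labels, meta = [], [], []
    for rec in recs:
        run = f"{rec.subject_id}/{rec.run_id}"
        stim = rec.markers_by_code("stimulus_on")
        if len(stim) != 1:
            raise MarkerError(f"run {run}: expected exactly one stimulus_on marker, "
                              f"found {len(stim)}")
        resp = rec.markers_by_code("response_like") + rec.markers_by_code("response_dislike")
        if len(resp) != 1:
            raise MarkerError(f"run {run}: expected exactly one response marker, "
                              f"found {len(resp)}")
        start = stim[0].onset + int(round(window[0] * rec.fs))
        stop = stim[0].onset + int(round(window[1] * rec.fs))
        if start < 0 or stop > rec.n_samples:
            raise MarkerError(f"run {run}: epoch window [{start}, {stop}) outside recording")
        epochs.append(rec.data[:, start:stop])
        labels.append(1 if resp[0].code == "response_like" else 0)
        meta.append((rec.subject_id, rec.run_id))
    return EpochSet(epochs=np.stack(epochs), fs=recs[0].fs,
                    labels=np.array(labels), meta=meta, montage=recs[0].montage)


def downsample(x: EpochSet | RawRecording, target_fs: float = 256.0):
    """Anti-aliased rational-ratio resampling (polyphase FIR).

    Returns the same container type at ``target_fs``. Band powers below
    40 Hz are preserved to within a few percent (the FIR passband).
    """
    if target_fs >= x.fs:
        raise ParameterError(f"target_fs {target_fs} must be below fs {x.fs}")
    frac = Fraction(target_fs / x.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if isinstance(x, RawRecording):
        out = x.copy()
        out.data = sps.resample_poly(out.data, up, down, axis=-1, padtype="line")
        out.fs = target_fs
        scale = target_fs / x.fs
        out.markers = [type(m)(int(round(m.onset * scale)), m.code) for m in x.markers]
        return out
    if isinstance(x, EpochSet):
        data = sps.resample_poly(x.epochs, up, down, axis=-1, padtype="line")
        return EpochSet(epochs=data, fs=target_fs, labels=x.labels.copy(),
                        meta=list(x.meta), montage=x.montage)
    raise ParameterError(f"cannot downsample object of type {type(x).__name__}")


def segment_epochs(epochs: EpochSet, n_segments: int = 6) -> SegmentSet:
    """Split each epoch into ``n_segments`` equal, contiguous,
    non-overlapping pieces (floor division; trailing remainder samples
    are discarded). Labels and provenance propagate to every piece."""
    if n_segments < 1:
        raise ParameterError("n_segments must be >= 1")
    n_samp = epochs.epochs.shape[2]
    seg_len = n_samp // n_segments
    if seg_len < 1:
        raise ParameterError(f"epoch length {n_samp} shorter than {n_segments} segments")
    used = seg_len * n_segments
    n_ep, n_ch = epochs.epochs.shape[:2]
    segs = (epochs.epochs[:, :, :used]
            .reshape(n_ep, n_ch, n_segments, seg_len)
            .transpose(0, 2, 1, 3)
            .reshape(n_ep * n_segments, n_ch, seg_len))
    labels = np.repeat(epochs.labels, n_segments)
    meta = [(s, r, k) for (s, r) in epochs.meta for k in range(n_segments)]
    return SegmentSet(segments=segs, fs=epochs.fs, labels=labels, meta=meta,
                      montage=epochs.montage)


def run_preprocessing(recs: list[RawRecording], *,
                      refs: tuple[str, ...] | None = ("TP9", "TP10"),
                      band: tuple[float, float] | None = (0.5, 40.0),
                      filter_order: int = 4,
                      window: tuple[float, float] = (0.0, 8.0),
                      target_fs: float | None = 256.0,
                      n_segments: int = 6,
                      clean_fn=None) -> SegmentSet:
    """Run the full chain in its fixed order, skipping stages whose
    parameter is ``None``.

    ``clean_fn``, if given, is applied to each recording between
    filtering and epoching — a hook for external artifact correction
    (e.g. an ICA-based EOG cleaner); the package itself does not
    implement artifact removal.
    """
    homogeneous = recs and all(
        r.fs == recs[0].fs and r.data.shape == recs[0].data.shape
        and r.montage is recs[0].montage for r in recs)
    if homogeneous:
        # batched fast path: identical filters, applied across all runs at once
        X = np.stack([r.data for r in recs])
        if refs is not None:
            for ref in refs:
                if ref not in recs[0].montage.channel_names:
                    raise ParameterError(f"reference channel {ref!r} not in montage")
            idx = [recs[0].montage.index(r) for r in refs]
            X = X - X[:, idx, :].mean(axis=1, keepdims=True)
        if band is not None:
            nyq = recs[0].fs / 2.0
            if not 0 < band[0] < band[1] < nyq:
                raise ParameterError("need 0 < lo < hi < Nyquist")
            sos = sps.butter(filter_order, band, btype="bandpass",
                             fs=recs[0].fs, output="sos")
            X = sps.sosfiltfilt(sos, X, axis=-1)
        staged = []
        for i, rec in enumerate(recs):
            r = rec.copy()
            r.data = X[i]
            if clean_fn is not None:
                r = clean_fn(r)
            staged.append(r)
    else:
        staged = []
        for rec in recs:
            r = rec
            if refs is not None:
                r = rereference(r, refs)
            if band is not None:
                r = bandpass(r, band[0], band[1], order=filter_order)
            if clean_fn is not None:
                r = clean_fn(r)
            staged.append(r)
    epochs = extract_epochs(staged, window=window)
    if target_fs is not None:
        epochs = downsample(epochs, target_fs)
    return segment_epochs(epochs, n_segments)
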