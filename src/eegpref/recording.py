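"""Core data model: montage, event markers, raw recordings, and epochs.

All voltages are in microvolts, all sample indices are 0-based, and all
time windows are half-open ``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MarkerError, ParameterError

#: Legal event-marker codes, in within-run protocol order.
MARKER_CODES = ("fixation", "stimulus_on", "response_like", "response_dislike", "rest")

#: Protocol position of each code (the two response codes share a slot).
_CODE_ORDER = {
    "fixation": 0,
    "stimulus_on": 1,
    "response_like": 2,
    "response_dislike": 2,
    "rest": 3,
}

DEFAULT_CHANNELS = (
    "FP1", "FPz", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)


@dataclass(frozen=True)
class Montage:
    """Electrode layout: ordered channel labels, homologous left/right
    pairs, and scalp-region membership.

    Midline electrodes (``z`` suffix) have no mirror and belong to no
    left/right pair; each label belongs to at most one region.
    """

    channel_names: tuple[str, ...]
    ground: str = "FPz"
    online_reference: str = "Fz"
    lr_pairs: tuple[tuple[str, str], ...] = ()
    regions: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        names = set(self.channel_names)
        if len(names) != len(self.channel_names):
            raise ParameterError("duplicate channel labels in montage")
        for left, right in self.lr_pairs:
            if left not in names or right not in names:
                raise ParameterError(f"lr_pair ({left},{right}) not in channel_names")
        seen: dict[str, str] = {}
        for region, labels in self.regions.items():
            for lab in labels:
                if lab not in names:
                    raise ParameterError(f"region {region!r} label {lab!r} not in channel_names")
                if lab in seen:
                    raise ParameterError(f"label {lab!r} in two regions: {seen[lab]!r}, {region!r}")
                seen[lab] = region

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, label: str) -> int:
        """Row index of a channel label."""
        try:
            return self.channel_names.index(label)
        except ValueError:
            raise ParameterError(f"channel {label!r} not in montage") from None

    def region_channels(self, region: str) -> tuple[str, ...]:
        if region not in self.regions:
            raise ParameterError(f"unknown region {region!r}")
        return self.regions[region]


def default_montage() -> Montage:
    """The 22-channel 10-20 montage used throughout the package.

    FPz is the amplifier ground and Fz the online reference; TP9/TP10 (the
    bilateral mastoids) are retained as channels so recordings can be
    re-referenced to them offline. Nine homologous left/right pairs are
    defined; the four midline electrodes have no pair.
    """
    return Montage(
        channel_names=DEFAULT_CHANNELS,
        ground="FPz",
        online_reference="Fz",
        lr_pairs=(
            ("FP1", "FP2"), ("F7", "F8"), ("F3", "F4"), ("T7", "T8"),
            ("C3", "C4"), ("TP9", "TP10"), ("P7", "P8"), ("P3", "P4"),
            ("O1", "O2"),
        ),
        regions={
            "frontal": ("FP1", "FPz", "FP2", "F7", "F3", "Fz", "F4", "F8"),
            "temporal": ("T7", "T8", "TP9", "TP10"),
            "central": ("C3", "Cz", "C4"),
            "parietal": ("P7", "P3", "Pz", "P4", "P8"),
            "occipital": ("O1", "O2"),
        },
    )


@dataclass(frozen=True)
class EventMarker:
    """One event on a recording: 0-based sample index plus a protocol code."""

    onset: int
    code: str

    def __post_init__(self):
        if self.code not in MARKER_CODES:
            raise ParameterError(f"unknown marker code {self.code!r}")
        if self.onset < 0:
            raise ParameterError("marker onset must be >= 0")


@dataclass
class RawRecording:
    """A continuous multichannel recording for one run.

    ``data`` is channels x samples in microvolts, rows ordered as
    ``montage.channel_names``.
    """

    data: np.ndarray
    fs: float
    montage: Montage
    markers: list[EventMarker] = field(default_factory=list)
    subject_id: str = ""
    run_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ParameterError("data must be a channels x samples matrix")
        if self.data.shape[0] != self.montage.n_channels:
            raise ParameterError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not self.fs > 0:
            raise ParameterError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("data contains non-finite values")
        self._check_markers()

    def _check_markers(self):
        n = self.data.shape[1]
        prev = -1
        for m in self.markers:
            if m.onset >= n:
                raise MarkerError(f"marker {m.code!r} onset {m.onset} beyond recording length {n}")
            order = _CODE_ORDER[m.code]
            if order < prev:
                raise MarkerError(f"marker {m.code!r} out of protocol order")
            prev = order

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    def markers_by_code(self, code: str) -> list[EventMarker]:
        return [m for m in self.markers if m.code == code]

    def copy(self) -> "RawRecording":
        return RawRecording(
            data=self.data.copy(), fs=self.fs, montage=self.montage,
            markers=list(self.markers), subject_id=self.subject_id, run_id=self.run_id,
        )


@dataclass
class EpochSet:
    """Stimulus-locked windows with like/dislike labels.

    ``epochs`` is epochs x channels x samples (microvolts); ``labels`` is
    1 for like, 0 for dislike; ``meta`` carries (subject_id, run_id) per
    epoch.
    """

    epochs: np.ndarray
    fs: float
    labels: np.ndarray
    meta: list[tuple[str, str]]
    montage: Montage

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise ParameterError("epochs must be epochs x channels x samples")
        if len(self.labels) != self.epochs.shape[0]:
            raise ParameterError("labels length must equal epoch count")
        if len(self.meta) != self.epochs.shape[0]:
            raise ParameterError("meta length must equal epoch count")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ParameterError("labels must be binary (like=1, dislike=0)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]
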