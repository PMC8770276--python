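"""Reading and writing recordings.

Three formats are supported:

* ``fixture`` — the package's own single-file container (a NumPy ``.npz``
  archive holding the float64 data matrix, sampling rate, channel names,
  and the marker table). Round-trips are bit-exact, which CSV cannot
  guarantee for floats.
* ``brainvision`` — the BrainVision ``.vhdr``/``.vmrk``/``.eeg`` triplet,
  read through MNE.
* ``edf`` — European Data Format, read through MNE.

Vendor marker strings vary between acquisition setups, so external
formats take a user-supplied ``code_map`` from vendor annotation strings
to the internal code set (fixation / stimulus_on / response_like /
response_dislike / rest). Annotations absent from the map are ignored.
Voltages are converted to microvolts on load.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError, MontageMismatchError
from .recording import EventMarker, Montage, RawRecording, default_montage

FORMATS = ("fixture", "brainvision", "edf")


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording to the internal fixture container.

    The file is a ``.npz`` archive; ``read_recording(path, "fixture")``
    reproduces data, fs, and markers bit-exactly.
    """
    path = Path(path)
    onsets = np.array([m.onset for m in rec.markers], dtype=np.int64)
    codes = np.array([m.code for m in rec.markers], dtype="U20")
    try:
        with open(path, "wb") as fh:
            np.savez(
                fh,
                data=rec.data,
                fs=np.float64(rec.fs),
                channel_names=np.array(rec.montage.channel_names, dtype="U16"),
                marker_onsets=onsets,
                marker_codes=codes,
                subject_id=np.str_(rec.subject_id),
                run_id=np.str_(rec.run_id),
            )
    except OSError as exc:
        raise FormatError(f"cannot write fixture to {path}: {exc}") from exc


def _check_channels(labels: list[str], montage: Montage) -> None:
    expected = list(montage.channel_names)
    if labels != expected:
        missing = [c for c in expected if c not in labels]
        extra = [c for c in labels if c not in expected]
        offenders = missing + extra
        raise MontageMismatchError(
            f"channel labels do not match montage ({len(labels)} vs "
            f"{len(expected)} channels); offenders: {offenders}",
            offenders=offenders,
        )


def _read_fixture(path: Path, montage: Montage) -> RawRecording:
    try:
        with np.load(path) as npz:
            data = npz["data"]
            fs = float(npz["fs"])
            labels = [str(c) for c in npz["channel_names"]]
            onsets = npz["marker_onsets"]
            codes = npz["marker_codes"]
            subject_id = str(npz["subject_id"])
            run_id = str(npz["run_id"])
    except (OSError, KeyError, ValueError) as exc:
        raise FormatError(f"cannot read fixture {path}: {exc}") from exc
    _check_channels(labels, montage)
    markers = [EventMarker(int(o), str(c)) for o, c in zip(onsets, codes)]
    return RawRecording(data=data, fs=fs, montage=montage, markers=markers,
                        subject_id=subject_id, run_id=run_id)


def _read_mne(path: Path, fmt: str, montage: Montage,
              code_map: dict[str, str] | None) -> RawRecording:
    import mne

    try:
        if fmt == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises many types for malformed files
        raise FormatError(f"cannot parse {fmt} file {path}: {exc}") from exc

    _check_channels(list(raw.ch_names), montage)
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    fs = float(raw.info["sfreq"])
    markers: list[EventMarker] = []
    code_map = code_map or {}
    for ann in raw.annotations:
        code = code_map.get(ann["description"])
        if code is None:
            continue
        markers.append(EventMarker(int(round(ann["onset"] * fs)), code))
    markers.sort(key=lambda m: m.onset)
    return RawRecording(data=data_uv, fs=fs, montage=montage, markers=markers,
                        subject_id="", run_id=path.stem)


def read_recording(path: str | Path, format: str = "fixture",
                   montage: Montage | None = None,
                   code_map: dict[str, str] | None = None) -> RawRecording:
    """Read a recording from disk.

    Parameters
    ----------
    path
        File to read (``.vhdr`` for BrainVision).
    format
        One of ``fixture``, ``brainvision``, ``edf``.
    montage
        Expected montage; channel labels must match exactly (order
        included). Defaults to :func:`default_montage`.
    code_map
        Vendor annotation string -> internal marker code, required to
        recover markers from external formats. Ignored for fixtures.
    """
    path = Path(path)
    montage = montage or default_montage()
    if format == "fixture":
        return _read_fixture(path, montage)
    if format in ("brainvision", "edf"):
        return _read_mne(path, format, montage, code_map)
    raise FormatError(f"unknown format {format!r}; expected one of {FORMATS}")
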