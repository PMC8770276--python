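"""Synthetic minimal BrainVision and EDF writers, used only to build
on-the-fly test inputs for the external-format readers. These are
deliberately tiny stand-ins constructed for tests, not general-purpose
exporters."""

from pathlib import Path

import numpy as np


def write_brainvision(path_stem: Path, data_uv: np.ndarray, fs: float,
                      channel_names, markers=()):
    """Write a minimal BrainVision .vhdr/.vmrk/.eeg triplet.

    ``data_uv`` is channels x samples in microvolts; ``markers`` is a
    sequence of (type, description, onset_sample_1based).
    """
    stem = Path(path_stem)
    n_ch = data_uv.shape[0]
    vhdr = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem.name}.eeg",
        f"MarkerFile={stem.name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:.0f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, name in enumerate(channel_names):
        vhdr.append(f"Ch{i + 1}={name},,1,µV")
    stem.with_suffix(".vhdr").write_text("\n".join(vhdr) + "\n", encoding="utf-8")

    vmrk = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem.name}.eeg",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20200101000000000000",
    ]
    for k, (mtype, desc, onset) in enumerate(markers, start=2):
        vmrk.append(f"Mk{k}={mtype},{desc},{onset},1,0")
    stem.with_suffix(".vmrk").write_text("\n".join(vmrk) + "\n", encoding="utf-8")

    data_uv.astype("<f4").T.tofile(stem.with_suffix(".eeg"))
    return stem.with_suffix(".vhdr")


def write_edf(path: Path, data_uv: np.ndarray, fs: float, channel_names):
    """Write a minimal single-record EDF file (int16, physical
    microvolts)."""
    path = Path(path)
    n_ch, n_samp = data_uv.shape
    assert float(fs).is_integer() and n_samp % int(fs) == 0
    n_records = n_samp // int(fs)
    spr = int(fs)  # samples per record per signal

    phys_min, phys_max = -3000.0, 3000.0
    dig_min, dig_max = -32768, 32767

    def pad(s, n):
        s = str(s)[:n]
        return s + " " * (n - len(s))

    header = pad("0", 8) + pad("X X X X", 80) + pad("Startdate 01-JAN-2020", 80)
    header += pad("01.01.20", 8) + pad("00.00.00", 8)
    header += pad(256 * (1 + n_ch), 8) + pad("", 44)
    header += pad(n_records, 8) + pad("1", 8) + pad(n_ch, 4)
    for name in channel_names:
        header += pad(name, 16)
    header += pad("", 80) * n_ch
    header += pad("uV", 8) * n_ch
    header += "".join(pad(f"{phys_min:.0f}", 8) for _ in range(n_ch))
    header += "".join(pad(f"{phys_max:.0f}", 8) for _ in range(n_ch))
    header += "".join(pad(dig_min, 8) for _ in range(n_ch))
    header += "".join(pad(dig_max, 8) for _ in range(n_ch))
    header += pad("", 80) * n_ch
    header += "".join(pad(spr, 8) for _ in range(n_ch))
    header += pad("", 32) * n_ch

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip((data_uv - phys_min) * scale + dig_min, dig_min, dig_max)
    digital = np.round(digital).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        for rec in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch, rec * spr:(rec + 1) * spr].tobytes())
    return path
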