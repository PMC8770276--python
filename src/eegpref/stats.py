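"""Per-channel, per-band two-sample t-tests on band power.

This produces the values behind a p-value scalp topography: for every
(channel, band) cell, the like and dislike segments' relative band
powers are contrasted with a two-sample t-test. The Welch
(unequal-variance) variant is the default; pooled-variance is
available. No multiplicity correction is applied by default — the maps
are exploratory, thresholded at raw p <= 0.05 — but Benjamini-Hochberg
FDR-adjusted p-values can be requested.

The unit of analysis is the segment, pooled across subjects. Segments
from one subject are not independent, so the pooled test is
anti-conservative; ``per_subject=True`` first averages each subject's
segments per class and tests subject means instead.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ClassBalanceError, ParameterError
from .features import FeatureTable


def band_power_ttest(features: FeatureTable, equal_var: bool = False,
                     fdr: bool = False, per_subject: bool = False) -> pd.DataFrame:
    """Two-sided two-sample t-test per (channel, band).

    ``features`` must be a psd-family table (columns ``psd:CH:band``).
    Returns a DataFrame with columns channel, band, t, p, n_like,
    n_dislike (plus p_fdr when requested). The t statistic is signed
    like - dislike.
    """
    cells = [n for n in features.feature_names if n.startswith("psd:")]
    if not cells:
        raise ParameterError("band_power_ttest needs psd-family features")
    like_mask = features.labels == 1
    if like_mask.all() or not like_mask.any():
        raise ClassBalanceError("both classes are required for a t-test")

    values = features.values[:, [features.feature_names.index(n) for n in cells]]
    labels = features.labels
    if per_subject:
        subjects = np.array([m[0] for m in features.meta])
        rows_v, rows_l = [], []
        for s in np.unique(subjects):
            for cls in (0, 1):
                sel = (subjects == s) & (labels == cls)
                if sel.any():
                    rows_v.append(values[sel].mean(axis=0))
                    rows_l.append(cls)
        values = np.vstack(rows_v)
        labels = np.array(rows_l)
        if len(set(labels)) < 2:
            raise ClassBalanceError("both classes required after per-subject averaging")

    like = values[labels == 1]
    dislike = values[labels == 0]
    if len(like) < 2 or len(dislike) < 2:
        raise ClassBalanceError("need >= 2 samples per class")
    t, p = sstats.ttest_ind(like, dislike, axis=0, equal_var=equal_var)

    out = pd.DataFrame({
        "channel": [n.split(":")[1] for n in cells],
        "band": [n.split(":")[2] for n in cells],
        "t": t,
        "p": p,
        "n_like": len(like),
        "n_dislike": len(dislike),
    })
    if fdr:
        from statsmodels.stats.multitest import multipletests
        out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def export_topography(ttest_map: pd.DataFrame, path: str | Path) -> None:
    """Write the t-test map as CSV (channel, band, t, p, n_like, n_dislike)."""
    cols = ["channel", "band", "t", "p", "n_like", "n_dislike"]
    extra = [c for c in ttest_map.columns if c not in cols]
    ttest_map[cols + extra].to_csv(path, index=False)


def read_topography(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
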