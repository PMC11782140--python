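"""Scalar feature extraction from preprocessed epochs.

One subject-condition yields, per the configured bands: relative band
power per channel, the theta/beta ratio per channel, and PLV/wPLI per
channel pair. Feature names follow the grammar
``<metric>_<band>_<item>_<condition>`` (the theta/beta ratio uses the
band token ``thetabeta``), so every column is parseable back into its
components.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .connectivity import plv_matrix, wpli_matrix
from .io import (
    CANONICAL_BANDS,
    BandDefinition,
    EpochedRecording,
    FeatureTable,
    format_feature_name,
    get_band,
)
from .spectral import band_powers, psd_welch_mirrored, theta_beta_ratio

DEFAULT_CONNECTIVITY_BANDS = ("delta", "theta", "alpha", "beta")


def extract_condition_features(
    ep: EpochedRecording,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    connectivity_bands: Sequence[str] = DEFAULT_CONNECTIVITY_BANDS,
    include_relpower: bool = True,
    include_tbr: bool = True,
    include_plv: bool = True,
    include_wpli: bool = True,
) -> dict[str, float]:
    """All scalar features of one preprocessed subject-condition."""
    cond = ep.condition
    out: dict[str, float] = {}
    if include_relpower or include_tbr:
        ps = psd_welch_mirrored(ep)
        bp = band_powers(ps, bands)
        if include_relpower:
            for band in bands:
                for ch in ep.layout.names:
                    out[format_feature_name("relpower", band.name, ch, cond)] = float(
                        bp.relative.loc[ch, band.name]
                    )
        if include_tbr:
            tbr = theta_beta_ratio(bp)
            for ch in ep.layout.names:
                out[format_feature_name("tbr", "thetabeta", ch, cond)] = float(tbr[ch])
    for band_name in connectivity_bands:
        band = get_band(band_name, bands)
        if include_plv:
            mat = plv_matrix(ep, band)
            for _, row in mat.to_long().iterrows():
                out[
                    format_feature_name("plv", band.name, (row.ch1, row.ch2), cond)
                ] = float(row.value)
        if include_wpli:
            mat = wpli_matrix(ep, band)
            for _, row in mat.to_long().iterrows():
                out[
                    format_feature_name("wpli", band.name, (row.ch1, row.ch2), cond)
                ] = float(row.value)
    return out


def build_feature_tables(
    epoched: Iterable[EpochedRecording],
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    connectivity_bands: Sequence[str] = DEFAULT_CONNECTIVITY_BANDS,
    **kwargs,
) -> dict[str, FeatureTable]:
    """Per-condition feature tables from preprocessed recordings."""
    rows: dict[str, dict[str, dict[str, float]]] = {}
    for ep in epoched:
        feats = extract_condition_features(
            ep, bands=bands, connectivity_bands=connectivity_bands, **kwargs
        )
        rows.setdefault(ep.condition, {})[ep.subject_id] = feats
    return {
        cond: FeatureTable(pd.DataFrame.from_dict(recs, orient="index"))
        for cond, recs in rows.items()
    }
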