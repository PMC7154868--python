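"""Two-channel array (RIP-chip) enrichment.

Per probe: replicate-wise F635/F532 ratios, the median of those ratios,
normalization by the summed median F532 of the rRNA probes, and the
wt / control differential. Works identically for ~1 kb tiling probes and
50-nt oligo probes; probe length is metadata only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBE_KEYS = ["probe_id", "start", "end", "feature", "is_rrna"]


class NormalizationError(ValueError):
    pass


def replicate_ratios(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add a ``ratio`` = F635 / F532 column; drop replicates with F532 <= 0."""
    df = measurements.copy()
    bad = ~(df["F532"] > 0)
    if bad.any():
        dropped = df.loc[bad, ["probe_id", "replicate"]].itertuples(index=False)
        logger.warning(
            "replicate_ratios: dropping %d probe-replicates with F532 <= 0: %s",
            int(bad.sum()),
            list(dropped),
        )
        df = df.loc[~bad]
    df["ratio"] = df["F635"] / df["F532"]
    return df


def median_of_ratios(ratio_table: pd.DataFrame) -> pd.DataFrame:
    """Per-probe median over replicate ratios (even count: mean of central pair)."""
    if ratio_table.empty:
        raise ValueError("no surviving probe-replicates")
    grouped = ratio_table.groupby(PROBE_KEYS, as_index=False, sort=False)
    out = grouped.agg(median_ratio=("ratio", "median"))
    return out


def rrna_normalization_factor(measurements: pd.DataFrame) -> float:
    """Sum over rRNA probes of the median (over replicates) F532 signal."""
    rrna = measurements[measurements["is_rrna"].astype(bool)]
    if rrna.empty:
        raise NormalizationError("no rRNA probes available for normalization")
    per_probe = rrna.groupby("probe_id")["F532"].median()
    factor = float(per_probe.sum())
    if not factor > 0:
        raise NormalizationError("rRNA normalization factor is not positive")
    return factor


def probe_enrichment(measurements: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios per probe plus rRNA-normalized values for one array."""
    ratios = replicate_ratios(measurements)
    medians = median_of_ratios(ratios)
    factor = rrna_normalization_factor(measurements)
    medians["normalized"] = medians["median_ratio"] / factor
    return medians


def normalize_and_compare(wt: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Per-probe differential = normalized(wt) / normalized(control).

    Probes missing from the control get NaN differential and a warning.
    Output is sorted by genome position; ``top_probe`` in ``.attrs`` names
    the non-rRNA probe with the maximal differential.
    """
    wt_enr = probe_enrichment(wt)
    ctl_enr = probe_enrichment(control)[PROBE_KEYS + ["normalized"]].rename(
        columns={"normalized": "control_normalized"}
    )
    merged = wt_enr.merge(ctl_enr, on=PROBE_KEYS, how="left")
    missing = merged["control_normalized"].isna()
    if missing.any():
        logger.warning(
            "normalize_and_compare: %d probes missing from control; differential undefined",
            int(missing.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["differential"] = merged["normalized"] / merged["control_normalized"]
    merged.loc[~(merged["control_normalized"] > 0), "differential"] = np.nan
    merged = merged.sort_values(["start", "end", "probe_id"]).reset_index(drop=True)
    non_rrna = merged[~merged["is_rrna"].astype(bool)].dropna(subset=["differential"])
    if not non_rrna.empty:
        merged.attrs["top_probe"] = str(non_rrna.loc[non_rrna["differential"].idxmax(), "probe_id"])
    return merged


def export_track(
    enrichments: pd.DataFrame,
    path,
    column: str = "normalized",
    seq_id: str = "genome",
    allow_overlap: bool = False,
) -> None:
    """Write a 4-column bedGraph of per-probe values."""
    df = enrichments.sort_values(["start", "end"])
    if not allow_overlap:
        overlapping = (df["start"].values[1:] < df["end"].values[:-1]).any()
        if overlapping:
            raise ValueError("overlapping probes; pass allow_overlap=True to export anyway")
    rows = df[["start", "end", column]].copy()
    rows.insert(0, "chrom", seq_id)
    rows.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
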