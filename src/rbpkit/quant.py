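"""Quantitative binding metrics from paired signal measurements.

Covers dot-blot pellet/supernatant pairs (fold enrichment, fraction bound,
control-adjusted specificity calls) and stroma/membrane western pairs
(partition fraction). Signals are volume-corrected: equal loaded fractions
are the validated default, but unequal loads are supported because
membrane-IP blots routinely load different pellet and supernatant shares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_RATIO = 2.0


@dataclass
class PairedSignal:
    target: str
    signal_a: float  # pellet or stroma
    signal_b: float  # supernatant or membrane
    genotype: str = "wt"
    volume_fraction_a: float = 1.0
    volume_fraction_b: float = 1.0

    def __post_init__(self) -> None:
        if self.signal_a < 0 or self.signal_b < 0:
            raise ValueError(f"{self.target}: signals must be >= 0")
        if not (0 < self.volume_fraction_a <= 1 and 0 < self.volume_fraction_b <= 1):
            raise ValueError(f"{self.target}: volume fractions must lie in (0, 1]")
        if self.signal_a == 0 and self.signal_b == 0:
            raise ValueError(f"{self.target}: at least one signal must be positive")

    @property
    def corrected_a(self) -> float:
        return self.signal_a / self.volume_fraction_a

    @property
    def corrected_b(self) -> float:
        return self.signal_b / self.volume_fraction_b


def fold_enrichment(p: PairedSignal) -> float:
    """Volume-corrected a/b ratio; infinite (with a warning) when b is 0."""
    if p.corrected_b == 0:
        logger.warning("fold_enrichment: %s has zero denominator signal; reporting inf", p.target)
        return math.inf
    return p.corrected_a / p.corrected_b


def fraction_bound(p: PairedSignal) -> float:
    """a / (a + b) after volume correction; equals fold / (1 + fold)."""
    total = p.corrected_a + p.corrected_b
    return p.corrected_a / total


def partition_fraction(p: PairedSignal) -> float:
    """Share of signal in compartment a (e.g. stroma of stroma+membrane)."""
    return fraction_bound(p)


def control_adjusted_call(
    wt: PairedSignal, control: PairedSignal | None, min_ratio: float = DEFAULT_MIN_RATIO
) -> dict:
    """Specificity call: enriched in wt and over the control by >= min_ratio."""
    fold_wt = fold_enrichment(wt)
    if control is None:
        logger.warning("control_adjusted_call: %s has no control; abstaining", wt.target)
        return {"target": wt.target, "fold_wt": fold_wt, "fold_control": math.nan, "is_specific": None}
    if control.target != wt.target:
        raise ValueError(f"target mismatch: {wt.target!r} vs {control.target!r}")
    fold_control = fold_enrichment(control)
    if fold_control == 0:
        is_specific = fold_wt >= min_ratio
    else:
        is_specific = fold_wt >= min_ratio and fold_wt / fold_control >= min_ratio
    return {
        "target": wt.target,
        "fold_wt": fold_wt,
        "fold_control": fold_control,
        "is_specific": bool(is_specific),
    }


# ---------------------------------------------------------------------------
# Table-level processing
# ---------------------------------------------------------------------------

def pairs_from_table(df: pd.DataFrame) -> dict[tuple[str, str], PairedSignal]:
    """Build PairedSignals from a long table.

    Expected columns: target, genotype, fraction_label (P/S or
    stroma/membrane), signal, and optionally volume_fraction (default 1).
    """
    df = df.copy()
    if "volume_fraction" not in df:
        df["volume_fraction"] = 1.0
    label_a = {"P", "pellet", "stroma"}
    pairs: dict[tuple[str, str], PairedSignal] = {}
    for (target, genotype), group in df.groupby(["target", "genotype"], sort=False):
        a = group[group["fraction_label"].isin(label_a)]
        b = group[~group["fraction_label"].isin(label_a)]
        if len(a) != 1 or len(b) != 1:
            raise ValueError(f"{target}/{genotype}: need exactly one row per fraction")
        pairs[(str(target), str(genotype))] = PairedSignal(
            target=str(target),
            genotype=str(genotype),
            signal_a=float(a["signal"].iloc[0]),
            signal_b=float(b["signal"].iloc[0]),
            volume_fraction_a=float(a["volume_fraction"].iloc[0]),
            volume_fraction_b=float(b["volume_fraction"].iloc[0]),
        )
    return pairs


def blot_metrics(df: pd.DataFrame, min_ratio: float = DEFAULT_MIN_RATIO) -> pd.DataFrame:
    """Per-target fold enrichment, fraction bound and specificity call."""
    pairs = pairs_from_table(df)
    targets = sorted({t for t, _ in pairs})
    rows = []
    for target in targets:
        wt = pairs.get((target, "wt"))
        control = pairs.get((target, "control"))
        if wt is None:
            logger.warning("blot_metrics: no wt rows for %s; skipping", target)
            continue
        call = control_adjusted_call(wt, control, min_ratio=min_ratio)
        rows.append(
            {
                "target": target,
                "fold_enrichment": call["fold_wt"],
                "fraction_bound": fraction_bound(wt),
                "fold_control": call["fold_control"],
                "is_specific": call["is_specific"],
            }
        )
    return pd.DataFrame(rows)
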