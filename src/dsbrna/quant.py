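"""Closed-form quantifications: resection %ssDNA, ΔΔCT, percent-input
qPCR enrichment, laser-stripe normalisation and repair-reporter
efficiency.

The resection assay measures 5'->3' end resection at a break: genomic
DNA is restriction-digested in vitro, which cleaves double-stranded DNA
but spares resected single-stranded DNA, so qPCR across the digestion
site amplifies only the resected fraction. With ΔCT the difference in
mean cycles between the digested sample and its undigested counterpart,

    %ssDNA = 100 / (2^(ΔCT - 1) + 0.5)

ΔCT = 0 corresponds to 100 % ssDNA and the value decreases
monotonically as ΔCT grows. The -1 and 0.5 constants come from the
assay's geometry (only one strand of a resected duplex protects the
amplicon) and are implemented verbatim.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

ROLES = ("digested", "undigested", "IP", "input", "target", "reference")


@dataclass(frozen=True)
class QpcrSample:
    """Replicate CT values for one target/condition with a role tag."""

    target: str
    condition: str
    role: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role {self.role!r} not in {ROLES}")
        if not self.ct_values:
            raise ValueError("need at least one CT replicate")
        if any(not math.isfinite(c) or c <= 0 for c in self.ct_values):
            raise ValueError("CT values must be finite and > 0")

    @property
    def ct_mean(self) -> float:
        return sum(self.ct_values) / len(self.ct_values)


class SuperUnityResectionWarning(UserWarning):
    """ΔCT < 0: the digested sample amplified earlier than the
    undigested one, implying a nominal ssDNA fraction above 100 %."""


def percent_ssdna(ct_digested_mean: float, ct_undigested_mean: float) -> float:
    """Resected single-stranded DNA fraction from digest-protection qPCR.

    Returns ``100 / (2**(dCT - 1) + 0.5)`` with
    ``dCT = ct_digested_mean - ct_undigested_mean``. Emits a warning
    when ΔCT < 0 (value exceeds 100 %).
    """
    if not (math.isfinite(ct_digested_mean)
            and math.isfinite(ct_undigested_mean)):
        raise ValueError("CT means must be finite")
    dct = ct_digested_mean - ct_undigested_mean
    if dct < 0:
        warnings.warn(
            f"ΔCT = {dct:.3f} < 0 implies > 100 % ssDNA",
            SuperUnityResectionWarning, stacklevel=2,
        )
    return 100.0 / (2.0 ** (dct - 1.0) + 0.5)


def delta_ct_for_fraction(f: float) -> float:
    """Invert :func:`percent_ssdna`: the ΔCT that yields fraction ``f`` %."""
    if not 0 < f <= 100:
        raise ValueError("f must be in (0, 100]")
    return 1.0 + math.log2(100.0 / f - 0.5)


def relative_abundance_ddct(
    samples: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    control_condition: str,
) -> dict[str, float]:
    """2^-ΔΔCT relative quantification against a reference RNA.

    ``samples`` maps condition -> (target CTs, reference CTs). Per
    condition, ΔCT = mean(target) - mean(reference); ΔΔCT subtracts the
    control condition's ΔCT; the fold change is ``2**-ΔΔCT``. The
    control condition is exactly 1 by construction.
    """
    if control_condition not in samples:
        raise ValueError(f"control condition {control_condition!r} missing")
    dct: dict[str, float] = {}
    for cond, (target, reference) in samples.items():
        if not len(reference):
            raise ValueError(f"condition {cond!r}: missing reference CTs")
        if not len(target):
            raise ValueError(f"condition {cond!r}: missing target CTs")
        dct[cond] = (sum(target) / len(target)
                     - sum(reference) / len(reference))
    out = {cond: 2.0 ** -(d - dct[control_condition])
           for cond, d in dct.items()}
    out[control_condition] = 1.0
    return out


def qpcr_enrichment(ct_ip: float, ct_input: float,
                    input_fraction: float) -> float:
    """Percent-of-input IP enrichment.

    The input CT is first adjusted for the fraction of material it
    represents (``ct_input - log2(input_fraction)``), then
    ``100 * 2**(ct_input_adj - ct_ip)``.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    ct_input_adj = ct_input - math.log2(input_fraction)
    return 100.0 * 2.0 ** (ct_input_adj - ct_ip)


def chip_relative(target_percent_input: float,
                  h3_percent_input: float) -> float:
    """ChIP efficiency relative to a histone H3 ChIP run in parallel."""
    if h3_percent_input == 0:
        raise ValueError("H3 percent-input must be nonzero")
    return target_percent_input / h3_percent_input


def stripe_normalization(damage: Sequence[float],
                         background: Sequence[float]) -> list[float]:
    """Laser-stripe intensity normalisation.

    Each damage-stripe intensity is divided by the intensity of a
    second, undamaged stripe in the same nucleus, and the series is
    scaled so the first time point is exactly 1.
    """
    if len(damage) != len(background) or not damage:
        raise ValueError("series must be non-empty and of equal length")
    if any(b <= 0 for b in background):
        raise ValueError("background intensities must be positive")
    ratio = [d / b for d, b in zip(damage, background)]
    first = ratio[0]
    if first == 0:
        raise ValueError("first time point ratio is zero")
    out = [r / first for r in ratio]
    out[0] = 1.0
    return out


def reporter_efficiency(
    counts: Mapping[str, tuple[int, int]],
    control_condition: str,
) -> dict[str, float]:
    """GFP repair-reporter efficiency normalised to the control siRNA.

    ``counts`` maps condition -> (gfp_positive, total). Efficiency is
    the GFP-positive proportion divided by the control condition's
    proportion; the control is exactly 1.
    """
    if control_condition not in counts:
        raise ValueError(f"control condition {control_condition!r} missing")
    props: dict[str, float] = {}
    for cond, (pos, total) in counts.items():
        if total < 1:
            raise ValueError(f"condition {cond!r}: total must be >= 1")
        if not 0 <= pos <= total:
            raise ValueError(
                f"condition {cond!r}: gfp_positive must be in [0, total]"
            )
        props[cond] = pos / total
    control = props[control_condition]
    if control == 0:
        raise ValueError("control proportion is zero")
    out = {cond: p / control for cond, p in props.items()}
    out[control_condition] = 1.0
    return out


PLATE_COLUMNS = ["sample", "target", "role", "condition", "ct"]


def read_plate_csv(path: str | Path) -> list[QpcrSample]:
    """Read a qPCR plate CSV (columns sample, target, role, condition, ct)
    and aggregate replicate wells into :class:`QpcrSample` objects."""
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns {sorted(missing)}")
    out = []
    for (target, condition, role), grp in df.groupby(
            ["target", "condition", "role"], sort=False):
        out.append(QpcrSample(target=str(target), condition=str(condition),
                              role=str(role),
                              ct_values=tuple(grp["ct"].astype(float))))
    return out
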