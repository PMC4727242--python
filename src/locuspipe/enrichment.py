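"""MeDIP and ChIP-qPCR enrichment normalization.

MeDIP percent methylation interpolates the immunoprecipitation recovery of a
region linearly between the recoveries of an unmethylated (0%) and a fully
methylated (100%) spike-in control, cancelling day-to-day IP efficiency.
ChIP signal is expressed as percent of (dilution-adjusted) input and, for
histone marks, normalized to the amount pulled down with an anti-H3
antibody so that nucleosome density drops out.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from . import qpcr

__all__ = [
    "EnrichmentMeasurement",
    "SpikeInControls",
    "medip_percent_methylation",
    "medip_table_percent_methylation",
    "chip_percent_input",
    "normalize_to_h3",
    "region_methylation_correlation",
]

#: recovery may exceed the methylated control by this much before a warning
CLIP_TOLERANCE = 1e-9


@dataclass(frozen=True)
class EnrichmentMeasurement:
    region: str
    sample: str
    ip_pg: float
    input_pg: float
    assay_kind: str = "medip"  # medip | chip
    antibody: str = "5mC"

    def __post_init__(self) -> None:
        if self.input_pg <= 0:
            raise ValueError("input quantity must be positive")
        if self.ip_pg < 0:
            raise ValueError("IP quantity cannot be negative")
        if self.assay_kind not in ("medip", "chip"):
            raise ValueError(f"unknown assay kind {self.assay_kind!r}")

    @property
    def recovery(self) -> float:
        return self.ip_pg / self.input_pg


@dataclass(frozen=True)
class SpikeInControls:
    """IP recoveries of the fully methylated / unmethylated spike-ins."""

    meth_recovery: float
    unmeth_recovery: float

    def __post_init__(self) -> None:
        if not 0 <= self.unmeth_recovery < self.meth_recovery <= 1:
            raise ValueError(
                "need 0 <= unmeth_recovery < meth_recovery <= 1, got "
                f"({self.meth_recovery}, {self.unmeth_recovery})")


def medip_percent_methylation(
    m: EnrichmentMeasurement, ctl: SpikeInControls
) -> float:
    """Methylated fraction of a region from its MeDIP recovery.

    Linear two-point interpolation between the spike-in recoveries:
    (recovery - unmeth) / (meth - unmeth), clipped to [0, 1].  Recoveries
    outside the control range are clipped with a warning.
    """
    if m.assay_kind != "medip":
        raise ValueError("measurement is not a MeDIP assay")
    r = m.recovery
    frac = (r - ctl.unmeth_recovery) / (ctl.meth_recovery - ctl.unmeth_recovery)
    if frac > 1 + CLIP_TOLERANCE or frac < -CLIP_TOLERANCE:
        warnings.warn(
            f"region {m.region!r}: recovery {r:.4g} outside the spike-in "
            "range; fraction clipped", stacklevel=2)
    return min(1.0, max(0.0, frac))


def chip_percent_input(
    ip_ct: float, input_ct: float, input_dilution: float = 0.01
) -> float:
    """ChIP signal as percent of input from a Ct pair.

    The input aliquot is a fraction `input_dilution` of the chromatin used
    for the IP, so its Ct is first corrected by log2(1/dilution):
    %input = 100 * 2^((input_ct - log2(1/dilution)) - ip_ct).
    Missing Cts propagate as NaN.
    """
    if not 0 < input_dilution <= 1:
        raise ValueError("input dilution must be in (0, 1]")
    if any(c is None or math.isnan(c) for c in (ip_ct, input_ct)):
        return float("nan")
    adjusted = input_ct - math.log2(1.0 / input_dilution)
    return 100.0 * 2.0 ** (adjusted - ip_ct)


def normalize_to_h3(target_percent_input: float, h3_percent_input: float) -> float:
    """Histone-mark signal relative to total H3 at the same region."""
    if math.isnan(h3_percent_input) or h3_percent_input == 0:
        return float("nan")
    return target_percent_input / h3_percent_input


def medip_table_percent_methylation(medip: pd.DataFrame) -> pd.DataFrame:
    """Percent methylation per region from a MeDIP plate table.

    Expects columns region, sample, replicate, ip_pg, input_pg, with
    spike-in control rows named 'meth_ctrl' and 'unmeth_ctrl'.  Replicate
    recoveries are averaged per region before interpolation.  Returns a
    DataFrame (region, sample, recovery, percent_methylation) with both the
    raw IP/input recovery and the spike-in-interpolated value.
    """
    recov = (medip.assign(recovery=medip["ip_pg"] / medip["input_pg"])
             .groupby(["region", "sample"], sort=False)["recovery"]
             .mean().reset_index())
    ctl_rows = recov[recov["region"].isin(["meth_ctrl", "unmeth_ctrl"])]
    if set(ctl_rows["region"]) != {"meth_ctrl", "unmeth_ctrl"}:
        raise ValueError("MeDIP table must contain meth_ctrl and unmeth_ctrl rows")
    ctl = SpikeInControls(
        meth_recovery=float(
            ctl_rows.loc[ctl_rows["region"] == "meth_ctrl", "recovery"].mean()),
        unmeth_recovery=float(
            ctl_rows.loc[ctl_rows["region"] == "unmeth_ctrl", "recovery"].mean()),
    )
    rows = []
    for r in recov.itertuples():
        if r.region in ("meth_ctrl", "unmeth_ctrl"):
            continue
        m = EnrichmentMeasurement(region=r.region, sample=r.sample,
                                  ip_pg=r.recovery, input_pg=1.0)
        rows.append((r.region, r.sample, r.recovery,
                     100.0 * medip_percent_methylation(m, ctl)))
    return pd.DataFrame(rows, columns=[
        "region", "sample", "recovery", "percent_methylation"])


def region_methylation_correlation(methylation: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho between regions across samples.

    `methylation` is regions x samples with >= 5 samples.  Constant regions
    give NaN entries (undefined rank correlation), flagged by value.
    The diagonal is 1 by convention.
    """
    if methylation.shape[1] < 5:
        raise ValueError("needs >= 5 samples")
    regions = list(methylation.index)
    out = pd.DataFrame(1.0, index=regions, columns=regions)
    for i, ra in enumerate(regions):
        for rb in regions[i + 1:]:
            res = qpcr.spearman(methylation.loc[ra], methylation.loc[rb])
            out.loc[ra, rb] = out.loc[rb, ra] = res.rho
    return out
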