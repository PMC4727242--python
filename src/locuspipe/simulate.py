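"""Synthetic-data generators for every pipeline input.

The generators emulate the measurement model of the assays the toolkit
analyses, so every stage can be exercised and calibrated without external
data:

* qPCR plates — Ct drawn from the standard-curve line of each primer pair
  (per-assay efficiency and intercept) plus Gaussian cycle noise, censored
  at a maximum cycle number, together with a matching 10-fold BAC dilution
  series measured on the same plate.
* expression cohorts — genes at ordered genomic positions with optional
  co-expression blocks (shared latent factor) and a copy-number block that
  adds a log-ratio shift to amplified/deleted samples and writes matching
  SEG segments.
* 3C junction tables — power-law distance decay from an anchor fragment,
  optional promoter-promoter loops, multiplicative per-primer bias, and an
  equimolar digested/ligated BAC control that cancels that bias.
* MeDIP / ChIP tables — immunoprecipitation recovery interpolated between
  fully-methylated and unmethylated spike-in controls, and occupancy
  relative to histone H3.

All generators take an explicit seed and use a private Generator stream;
the same seed reproduces byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .threec import FragmentMap

__all__ = [
    "ENTITIES",
    "DEFAULT_ASSAY_MAP",
    "LocusPreset",
    "QpcrNoiseModel",
    "CohortSpec",
    "ThreeCScenario",
    "PRESETS",
    "make_locus_plates",
    "make_cohort",
    "make_3c_tables",
    "make_enrichment_tables",
    "make_methylation_cohort",
]

#: the five transcript entities quantified along the locus
ENTITIES = ("pri_PTPN6", "PTPN6_dpA", "intermediate", "pri_miR", "pri_miR_EST")

#: default primer-assay -> entity map; pri-PTPN6 is probed by two assays
DEFAULT_ASSAY_MAP: dict[str, str] = {
    "pri_PTPN6_1": "pri_PTPN6",
    "pri_PTPN6_2": "pri_PTPN6",
    "PTPN6_dpA": "PTPN6_dpA",
    "set1_intermediate": "intermediate",
    "pri_miR": "pri_miR",
    "pri_miR_EST": "pri_miR_EST",
}


@dataclass(frozen=True)
class LocusPreset:
    """Ground-truth transcript quantities (pg per reaction) for one condition.

    The absolute scale is arbitrary; only the ratios between entities and
    between presets are meaningful (bypass fraction, read-through yield,
    stress folds, EST excess).
    """

    name: str
    true_pg: Mapping[str, float]
    loading_control_pg: float = 10.0

    def __post_init__(self) -> None:
        if set(self.true_pg) != set(ENTITIES):
            raise ValueError(
                f"preset {self.name!r} must define exactly the entities {ENTITIES}"
            )
        if any(v <= 0 for v in self.true_pg.values()) or self.loading_control_pg <= 0:
            raise ValueError("all preset quantities must be positive")


#: Condition presets.  Absolute picogram values are arbitrary constants; the
#: ratios encode the locus biology: untreated SKOV3 has complete polyA-site
#: bypass and complete read-through (all ratios 1); H2O2 stress induces
#: pri-PTPN6 fivefold but the intermediate only 2.8-fold, i.e. only 56% of
#: primary transcripts still bypass the polyA signal; IGROV-1 expresses the
#: whole chain at a high level with complete bypass, and its stable EST
#: isoform is 2.4-fold above stressed SKOV3.
PRESETS: dict[str, LocusPreset] = {
    "SKOV3_NT": LocusPreset("SKOV3_NT", {
        "pri_PTPN6": 0.05, "PTPN6_dpA": 0.05, "intermediate": 0.05,
        "pri_miR": 0.05, "pri_miR_EST": 0.625,
    }),
    "SKOV3_H2O2": LocusPreset("SKOV3_H2O2", {
        "pri_PTPN6": 0.25, "PTPN6_dpA": 0.14, "intermediate": 0.14,
        "pri_miR": 0.14, "pri_miR_EST": 1.75,
    }),
    "IGROV1": LocusPreset("IGROV1", {
        "pri_PTPN6": 0.35, "PTPN6_dpA": 0.35, "intermediate": 0.35,
        "pri_miR": 0.35, "pri_miR_EST": 4.2,
    }),
}

#: default per-assay standard-curve parameters: efficiencies deliberately
#: not all 1.0 so that BAC-curve calibration is actually exercised
_DEFAULT_EFFICIENCY: dict[str, float] = {
    "pri_PTPN6_1": 0.97, "pri_PTPN6_2": 0.93, "PTPN6_dpA": 0.99,
    "set1_intermediate": 0.95, "pri_miR": 0.91, "pri_miR_EST": 0.98,
    "GAPDH": 1.00,
}
_DEFAULT_INTERCEPT: dict[str, float] = {
    "pri_PTPN6_1": 32.5, "pri_PTPN6_2": 33.0, "PTPN6_dpA": 31.8,
    "set1_intermediate": 32.2, "pri_miR": 33.1, "pri_miR_EST": 30.9,
    "GAPDH": 28.0,
}

#: 6-point 10-fold BAC dilution series, pg
DILUTION_SERIES_PG = (1000.0, 100.0, 10.0, 1.0, 0.1, 0.01)


@dataclass(frozen=True)
class QpcrNoiseModel:
    """Per-assay qPCR response and noise.

    ct_sd is the per-well Gaussian cycle noise (0 = deterministic);
    max_cycles censors undetected wells; per_assay_efficiency holds
    fractional efficiencies in (0, 1]; per_assay_intercept the Ct at 1 pg.
    """

    ct_sd: float = 0.0
    max_cycles: float = 40.0
    per_assay_efficiency: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFICIENCY))
    per_assay_intercept: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_INTERCEPT))

    def __post_init__(self) -> None:
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be >= 0")
        for assay, e in self.per_assay_efficiency.items():
            if not 0 < e <= 1:
                raise ValueError(f"efficiency for {assay!r} must be in (0, 1]")

    def slope(self, assay: str) -> float:
        e = self.per_assay_efficiency[assay]
        return -1.0 / math.log10(1.0 + e)

    def ct_for(self, assay: str, quantity_pg: float) -> float:
        """Noise-free Ct for a quantity under this assay's response line."""
        if quantity_pg <= 0:
            raise ValueError("template quantity must be positive")
        if assay not in self.per_assay_efficiency:
            raise KeyError(f"assay {assay!r} not in noise model")
        return self.per_assay_intercept[assay] + self.slope(assay) * math.log10(
            quantity_pg)


def _render_wells(
    noise: QpcrNoiseModel,
    rng: np.random.Generator,
    assay: str,
    quantity_pg: float,
    n_wells: int,
) -> list[float]:
    """Ct values for replicate wells; censored wells become NaN."""
    base = noise.ct_for(assay, quantity_pg)
    cts = base + rng.normal(0.0, noise.ct_sd, size=n_wells)
    return [float(c) if c <= noise.max_cycles else float("nan") for c in cts]


def make_locus_plates(
    preset: LocusPreset,
    noise: QpcrNoiseModel | None = None,
    seed: int = 0,
    n_technical: int = 3,
    n_biological: int = 1,
    assay_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a locus qPCR plate and its same-plate BAC dilution series.

    Returns (plate, dilutions): the plate has columns
    assay, sample, replicate, ct (NaN = undetermined well) and includes a
    GAPDH loading-control assay; the dilution table has columns
    assay, quantity_pg, ct covering a 6-point 10-fold series per assay.
    """
    noise = noise or QpcrNoiseModel()
    assay_map = dict(assay_map or DEFAULT_ASSAY_MAP)
    for assay in assay_map:
        if assay not in noise.per_assay_efficiency:
            raise KeyError(f"assay {assay!r} has no response in the noise model")
    rng = np.random.default_rng(seed)
    assays = list(assay_map) + ["GAPDH"]

    plate_rows = []
    for b in range(n_biological):
        sample = f"{preset.name}_rep{b + 1}"
        for assay in assays:
            entity = assay_map.get(assay)
            q = (preset.true_pg[entity] if entity is not None
                 else preset.loading_control_pg)
            for r, ct in enumerate(
                    _render_wells(noise, rng, assay, q, n_technical), start=1):
                plate_rows.append((assay, sample, r, ct))
    plate = pd.DataFrame(plate_rows, columns=["assay", "sample", "replicate", "ct"])

    dil_rows = []
    for assay in assays:
        for q in DILUTION_SERIES_PG:
            ct = _render_wells(noise, rng, assay, q, 1)[0]
            dil_rows.append((assay, q, ct))
    dilutions = pd.DataFrame(dil_rows, columns=["assay", "quantity_pg", "ct"])
    return plate, dilutions


# ---------------------------------------------------------------------------
# expression cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Blueprint for a synthetic expression cohort.

    coexpression_blocks: [(start, stop, rho)] gene-index ranges (half-open)
    sharing a latent factor giving pairwise correlation ~= rho.
    cnv_block: (start, stop, frac_amplified, frac_deleted, magnitude) — the
    named fraction of samples carries a copy-number segment of log-ratio
    +/-magnitude over the block, added to expression on the log scale.
    """

    n_samples: int = 200
    n_genes: int = 1000
    chrom: str = "chr12"
    gene_spacing: int = 10_000
    coexpression_blocks: Sequence[tuple[int, int, float]] = ()
    cnv_block: tuple[int, int, float, float, float] | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("cohort needs >= 2 samples and >= 1 gene")
        for lo, hi, rho in self.coexpression_blocks:
            if not (0 <= lo < hi <= self.n_genes):
                raise ValueError(f"block range [{lo}, {hi}) outside genome")
            if not -1 <= rho <= 1:
                raise ValueError("block correlation must be in [-1, 1]")
        if self.cnv_block is not None:
            lo, hi, fa, fd, mag = self.cnv_block
            if not (0 <= lo < hi <= self.n_genes):
                raise ValueError(f"cnv block range [{lo}, {hi}) outside genome")
            if fa < 0 or fd < 0 or fa + fd > 1:
                raise ValueError("amplified + deleted fractions must be in [0, 1]")
            if mag <= 0:
                raise ValueError("cnv magnitude must be positive")


def make_cohort(spec: CohortSpec) -> dict[str, object]:
    """Generate an expression matrix, gene positions, SEG file and truth labels.

    Returns a dict with:
      expression — DataFrame genes x samples (log2-scale units),
      positions  — BED-like DataFrame (chrom, start, end, gene),
      segments   — SEG-like DataFrame (sample, chrom, start, end, seg_mean),
      labels     — Series sample -> {amplified, deleted, unchanged} truth.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    samples = [f"s{j:04d}" for j in range(spec.n_samples)]
    starts = np.arange(spec.n_genes) * spec.gene_spacing
    positions = pd.DataFrame({
        "chrom": spec.chrom, "start": starts, "end": starts + 1000, "gene": genes,
    })

    x = rng.normal(0.0, 1.0, size=(spec.n_genes, spec.n_samples))
    for lo, hi, rho in spec.coexpression_blocks:
        factor = rng.normal(0.0, 1.0, size=spec.n_samples)
        a = math.sqrt(abs(rho))
        sign = 1.0 if rho >= 0 else -1.0
        x[lo:hi] = sign * a * factor + math.sqrt(1 - abs(rho)) * x[lo:hi]
    x *= spec.noise_sd

    labels = pd.Series("unchanged", index=samples, name="label")
    seg_rows: list[tuple] = []
    chrom_end = int(starts[-1] + 1000) if spec.n_genes else 1000
    if spec.cnv_block is not None:
        lo, hi, fa, fd, mag = spec.cnv_block
        n_amp = int(round(fa * spec.n_samples))
        n_del = int(round(fd * spec.n_samples))
        order = rng.permutation(spec.n_samples)
        amp_idx = order[:n_amp]
        del_idx = order[n_amp:n_amp + n_del]
        labels.iloc[amp_idx] = "amplified"
        labels.iloc[del_idx] = "deleted"
        block_start, block_end = int(starts[lo]), int(starts[hi - 1] + 1000)
        x[lo:hi, amp_idx] += mag
        x[lo:hi, del_idx] -= mag
        for j, sample in enumerate(samples):
            sm = mag if j in amp_idx else (-mag if j in del_idx else 0.0)
            if sm != 0.0:
                if block_start > 0:
                    seg_rows.append((sample, spec.chrom, 0, block_start, 0.0))
                seg_rows.append((sample, spec.chrom, block_start, block_end, sm))
                if block_end < chrom_end:
                    seg_rows.append((sample, spec.chrom, block_end, chrom_end, 0.0))
            else:
                seg_rows.append((sample, spec.chrom, 0, chrom_end, 0.0))
    else:
        for sample in samples:
            seg_rows.append((sample, spec.chrom, 0, chrom_end, 0.0))

    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "seg_mean"])
    expression = pd.DataFrame(x, index=genes, columns=samples)
    return {"expression": expression, "positions": positions,
            "segments": segments, "labels": labels}


# ---------------------------------------------------------------------------
# 3C


@dataclass(frozen=True)
class ThreeCScenario:
    """Ground truth for a 3C-qPCR experiment on a digested locus.

    Junction abundance for fragment f at genomic distance d from the anchor
    midpoint is primer_bias(f) * (d / d0)^-background_alpha, multiplied by
    the loop fold where a (anchor, partner, fold) loop applies.  The BAC
    control carries primer_bias only (all junctions equimolar).
    """

    fragment_map: FragmentMap
    anchor: str
    background_alpha: float = 1.0
    loops: Sequence[tuple[str, str, float]] = ()
    primer_bias: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    base_pg: float = 50.0
    bac_pg: float = 20.0

    def __post_init__(self) -> None:
        ids = {f.id for f in self.fragment_map.fragments}
        if self.anchor not in ids:
            raise ValueError(f"anchor {self.anchor!r} not in fragment map")
        if self.background_alpha <= 0:
            raise ValueError("decay exponent must be positive")
        for a, p, fold in self.loops:
            if a not in ids or p not in ids:
                raise ValueError(f"loop ({a!r}, {p!r}) references unknown fragments")
            if fold <= 1:
                raise ValueError("loop enrichment fold must be > 1")
        for f in self.primer_bias:
            if f not in ids:
                raise ValueError(f"primer bias for unknown fragment {f!r}")


def _junction_assay(anchor: str, fragment: str) -> str:
    return f"jx_{anchor}_{fragment}"


def true_junction_quantities(scenario: ThreeCScenario) -> dict[str, float]:
    """Noise-free sample junction quantities (pg) per non-anchor fragment."""
    fmap = scenario.fragment_map
    anchor_mid = fmap.midpoint(scenario.anchor)
    d0 = min(abs(f.midpoint - anchor_mid)
             for f in fmap.fragments if f.id != scenario.anchor)
    out: dict[str, float] = {}
    for frag in fmap.fragments:
        if frag.id == scenario.anchor:
            continue          # self-ligation excluded
        d = max(abs(frag.midpoint - anchor_mid), 1)
        q = scenario.base_pg * (d / d0) ** (-scenario.background_alpha)
        for a, p, fold in scenario.loops:
            if a == scenario.anchor and p == frag.id:
                q *= fold
        q *= scenario.primer_bias.get(frag.id, 1.0)
        out[frag.id] = q
    return out


def make_3c_tables(
    scenario: ThreeCScenario,
    noise: QpcrNoiseModel | None = None,
    n_technical: int = 3,
    sample: str = "sample",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate 3C junction plates: sample, BAC control, and BAC dilutions.

    Junction assays share one efficiency/intercept unless the noise model
    overrides them per assay.  Returns (sample_plate, bac_plate, dilutions);
    the plates have columns anchor, fragment, sample, replicate, ct, the
    dilution table assay ('jx_<anchor>_<fragment>'), quantity_pg, ct.
    """
    noise = noise or QpcrNoiseModel()
    rng = np.random.default_rng(scenario.seed)
    truths = true_junction_quantities(scenario)

    def assay_params(fragment: str) -> tuple[float, float]:
        assay = _junction_assay(scenario.anchor, fragment)
        e = noise.per_assay_efficiency.get(assay, 0.95)
        ic = noise.per_assay_intercept.get(assay, 30.0)
        return e, ic

    def wells(fragment: str, q: float, n: int) -> list[float]:
        e, ic = assay_params(fragment)
        base = ic - math.log10(q) / math.log10(1.0 + e)
        cts = base + rng.normal(0.0, noise.ct_sd, size=n)
        return [float(c) if c <= noise.max_cycles else float("nan") for c in cts]

    sample_rows, bac_rows, dil_rows = [], [], []
    for frag_id, q in truths.items():
        for r, ct in enumerate(wells(frag_id, q, n_technical), start=1):
            sample_rows.append((scenario.anchor, frag_id, sample, r, ct))
        q_bac = scenario.bac_pg * scenario.primer_bias.get(frag_id, 1.0)
        for r, ct in enumerate(wells(frag_id, q_bac, n_technical), start=1):
            bac_rows.append((scenario.anchor, frag_id, "BAC", r, ct))
        for qd in DILUTION_SERIES_PG:
            ct = wells(frag_id, qd, 1)[0]
            dil_rows.append((_junction_assay(scenario.anchor, frag_id), qd, ct))

    cols = ["anchor", "fragment", "sample", "replicate", "ct"]
    return (pd.DataFrame(sample_rows, columns=cols),
            pd.DataFrame(bac_rows, columns=cols),
            pd.DataFrame(dil_rows, columns=["assay", "quantity_pg", "ct"]))


# ---------------------------------------------------------------------------
# MeDIP / ChIP


def make_enrichment_tables(
    regions: Sequence[str],
    truth_methylation: Mapping[str, float],
    meth_recovery: float = 0.2,
    unmeth_recovery: float = 0.005,
    truth_occupancy: Mapping[str, float] | None = None,
    ct_sd: float = 0.0,
    n_replicates: int = 3,
    input_pg: float = 100.0,
    input_dilution: float = 0.01,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate MeDIP and ChIP qPCR tables with spike-in controls.

    MeDIP recovery for a region with methylated fraction m is
    unmeth_recovery + m * (meth_recovery - unmeth_recovery); spike-in rows
    ('meth_ctrl', 'unmeth_ctrl') carry the pure control recoveries.  ChIP
    %input is proportional to the truth occupancy (H3 reference = 1).
    Cycle noise of sd `ct_sd` multiplies recovered quantities by 2^N(0, sd).
    """
    if not 0 <= unmeth_recovery < meth_recovery <= 1:
        raise ValueError("need 0 <= unmeth_recovery < meth_recovery <= 1")
    for r in regions:
        m = truth_methylation[r]
        if not 0 <= m <= 1:
            raise ValueError(f"methylated fraction for {r!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    occupancy = dict(truth_occupancy or {})

    def noisy(x: float) -> float:
        return x * 2.0 ** rng.normal(0.0, ct_sd)

    medip_rows = []
    for r in regions:
        recov = unmeth_recovery + truth_methylation[r] * (
            meth_recovery - unmeth_recovery)
        for rep in range(1, n_replicates + 1):
            medip_rows.append(
                (r, "sample", "5mC", rep, noisy(recov * input_pg), input_pg))
    for name, recov in (("meth_ctrl", meth_recovery),
                        ("unmeth_ctrl", unmeth_recovery)):
        for rep in range(1, n_replicates + 1):
            medip_rows.append(
                (name, "sample", "5mC", rep, noisy(recov * input_pg), input_pg))
    medip = pd.DataFrame(medip_rows, columns=[
        "region", "sample", "antibody", "replicate", "ip_pg", "input_pg"])

    chip_rows = []
    # ChIP rendered as Ct pairs measured on an `input_dilution` input aliquot;
    # the anti-H3 pulldown recovers `h3_frac` of input chromatin and the mark
    # antibody h3_frac * occupancy, so the H3-normalised ratio is the occupancy.
    h3_frac = 0.1
    full_input_ct = 25.0  # Ct of the undiluted input, arbitrary reference
    for r in regions:
        for antibody, frac in (("H3", h3_frac),
                               ("mark", h3_frac * occupancy.get(r, 0.0))):
            if frac <= 0:
                continue
            for rep in range(1, n_replicates + 1):
                ip_ct = full_input_ct - math.log2(frac) + rng.normal(0.0, ct_sd)
                diluted_input_ct = (full_input_ct
                                    + math.log2(1.0 / input_dilution)
                                    + rng.normal(0.0, ct_sd))
                chip_rows.append(
                    (r, "sample", antibody, rep, ip_ct, diluted_input_ct))
    chip = pd.DataFrame(chip_rows, columns=[
        "region", "sample", "antibody", "replicate", "ip_ct", "input_ct"])
    return {"medip": medip, "chip": chip}


def make_methylation_cohort(
    regions: Sequence[str],
    n_samples: int,
    shared_groups: Sequence[Sequence[str]] = (),
    shared_sd: float = 0.3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample methylated fractions (regions x samples) with co-methylated
    promoter groups driven by a shared latent factor.

    Fractions are logistic transforms of a latent Gaussian, so values stay in
    (0, 1) while group members remain rank-correlated across samples.
    """
    rng = np.random.default_rng(seed)
    samples = [f"s{j:03d}" for j in range(n_samples)]
    latent = {r: rng.normal(0.0, noise_sd, size=n_samples) for r in regions}
    for group in shared_groups:
        factor = rng.normal(0.0, shared_sd, size=n_samples)
        for r in group:
            latent[r] = latent[r] + factor
    frac = {r: 1.0 / (1.0 + np.exp(-latent[r])) for r in regions}
    return pd.DataFrame(frac, index=samples).T
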