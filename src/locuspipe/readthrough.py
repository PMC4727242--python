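"""Absolute quantification of the transcript chain across the locus.

Five RNA entities are measured along the upstream gene and the downstream
intergenic miRNA cluster: the upstream primary transcript (pri_PTPN6,
averaged over its two primer assays), the assay spanning the polyadenylation
signal (PTPN6_dpA), the intermediate read-through transcript between the
polyA site and the miRNA promoter, the intronic miRNA primary transcript
(pri_miR), and its stabilised exonic EST isoform (pri_miR_EST).

Each assay is calibrated against the 6-point BAC dilution series measured on
the same plate, so quantities from different primer pairs are comparable in
absolute picograms and their ratios are meaningful:

* bypass fraction   = intermediate / pri_PTPN6   (polyA-signal read-through)
* read-through yield = pri_miR / intermediate    (chain completion)
* EST ratio         = pri_miR_EST / pri_miR      (isoform stabilisation)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import qpcr

__all__ = [
    "ENTITIES",
    "LocusQuantities",
    "ReadthroughSummary",
    "quantify_locus",
    "bypass_fraction",
    "readthrough_yield",
    "est_ratio",
    "stress_fold_changes",
    "compare_cell_lines",
    "summarize",
]

ENTITIES = ("pri_PTPN6", "PTPN6_dpA", "intermediate", "pri_miR", "pri_miR_EST")


@dataclass(frozen=True)
class LocusQuantities:
    """Replicate-averaged absolute quantities (pg) per transcript entity.

    Missing entities (e.g. all wells censored) are kept in the map as NaN
    with a reason in `missing`, never dropped.
    """

    condition: str
    pg: Mapping[str, float]
    se: Mapping[str, float] = field(default_factory=dict)
    n_reps: int = 0
    missing: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.pg) - set(ENTITIES)
        if unknown:
            raise ValueError(f"unknown entities {sorted(unknown)}")
        for e, v in self.pg.items():
            if not math.isnan(v) and v < 0:
                raise ValueError(f"negative quantity for {e}")

    def get(self, entity: str) -> float:
        if entity not in ENTITIES:
            raise KeyError(f"unknown entity {entity!r}")
        return float(self.pg.get(entity, float("nan")))


@dataclass(frozen=True)
class ReadthroughSummary:
    condition: str
    bypass_fraction: float
    readthrough_yield: float
    est_ratio: float
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    uncertainty: Mapping[str, float] = field(default_factory=dict)


def quantify_locus(
    plates: pd.DataFrame,
    dilutions: pd.DataFrame,
    assay_map: Mapping[str, str],
    condition: str | None = None,
) -> LocusQuantities:
    """Absolute entity quantities from a locus plate and its dilution series.

    Per assay: fit the standard curve from the same-plate BAC dilutions,
    mean-aggregate technical-replicate Cts per sample, invert to picograms,
    then average over samples.  Where two assays probe one entity (the two
    upstream-gene primer pairs) their estimates are averaged.  Assays absent
    from `assay_map` (loading controls) are ignored.  An entity whose wells
    are all censored is flagged missing, the rest are still computed.
    """
    agg = qpcr.aggregate_replicates(plates[plates["assay"].isin(assay_map)])
    if condition is None:
        samples = sorted(agg["sample"].unique())
        condition = samples[0].rsplit("_rep", 1)[0] if samples else "unknown"

    per_entity_pg: dict[str, list[float]] = {e: [] for e in ENTITIES}
    per_entity_logvar: dict[str, list[float]] = {e: [] for e in ENTITIES}
    n_reps = 0
    for assay, entity in assay_map.items():
        if entity not in ENTITIES:
            raise ValueError(f"assay {assay!r} maps to unknown entity {entity!r}")
        dil = dilutions[dilutions["assay"] == assay]
        if dil.empty:
            raise ValueError(f"no same-plate dilution series for assay {assay!r}")
        curve = qpcr.fit_standard_curve(list(zip(dil["quantity_pg"], dil["ct"])))
        rows = agg[agg["assay"] == assay]
        for _, row in rows.iterrows():
            if row["n_wells"] == 0 or math.isnan(row["ct"]):
                continue
            q = curve.invert(row["ct"])
            per_entity_pg[entity].append(q)
            # delta-method variance of log10(q) from replicate Ct scatter
            se_ct = row["ct_sd"] / math.sqrt(row["n_wells"]) if row["n_wells"] else 0.0
            per_entity_logvar[entity].append((se_ct / abs(curve.slope)) ** 2)
            n_reps = max(n_reps, int(row["n_wells"]))

    pg: dict[str, float] = {}
    se: dict[str, float] = {}
    missing: dict[str, str] = {}
    for entity in ENTITIES:
        vals = per_entity_pg[entity]
        if not vals:
            pg[entity] = float("nan")
            missing[entity] = qpcr.REASON_CENSORED
            continue
        mean = sum(vals) / len(vals)
        pg[entity] = mean
        # pooled log-scale variance back to pg units
        var_log10 = sum(per_entity_logvar[entity]) / len(vals) ** 2
        se[entity] = mean * math.log(10) * math.sqrt(var_log10)
    return LocusQuantities(condition=condition, pg=pg, se=se,
                           n_reps=n_reps, missing=missing)


def _ratio(num: float, den: float) -> float:
    """num/den with NaN propagation; zero denominator is undefined (NaN)."""
    if math.isnan(num) or math.isnan(den) or den == 0:
        return float("nan")
    return num / den


def bypass_fraction(q: LocusQuantities) -> float:
    """Fraction of upstream primary transcripts reading past the polyA signal:
    intermediate / pri_PTPN6.  1 means every primary transcript bypasses."""
    return _ratio(q.get("intermediate"), q.get("pri_PTPN6"))


def readthrough_yield(q: LocusQuantities) -> float:
    """Fraction of intermediate transcripts reaching the miRNA unit:
    pri_miR / intermediate."""
    return _ratio(q.get("pri_miR"), q.get("intermediate"))


def est_ratio(q: LocusQuantities) -> float:
    """Excess of the stabilised exonic isoform over the intronic primary
    transcript: pri_miR_EST / pri_miR."""
    return _ratio(q.get("pri_miR_EST"), q.get("pri_miR"))


def stress_fold_changes(
    basal: LocusQuantities, stressed: LocusQuantities
) -> dict[str, dict[str, float]]:
    """Per-entity stressed/basal quantity ratios, with log2 folds."""
    out: dict[str, dict[str, float]] = {}
    for entity in ENTITIES:
        fold = _ratio(stressed.get(entity), basal.get(entity))
        out[entity] = {
            "fold": fold,
            "log2_fold": math.log2(fold) if fold > 0 else float("nan"),
        }
    return out


def compare_cell_lines(
    a: LocusQuantities, b: LocusQuantities, entity: str
) -> float:
    """Quantity ratio a/b for one entity across two conditions/cell lines."""
    qa, qb = a.get(entity), b.get(entity)
    if math.isnan(qa) or math.isnan(qb):
        raise ValueError(f"entity {entity!r} missing in one of the conditions")
    return _ratio(qa, qb)


def summarize(
    q: LocusQuantities, basal: LocusQuantities | None = None
) -> ReadthroughSummary:
    """Derived read-through ratios for one condition (folds vs `basal` if given).

    Ratio uncertainty: delta method on the log scale — the standard error of
    a ratio r = x/y is r * sqrt((se_x/x)^2 + (se_y/y)^2).
    """
    def ratio_se(num: str, den: str, r: float) -> float:
        x, y = q.get(num), q.get(den)
        if math.isnan(r) or x <= 0 or y <= 0:
            return float("nan")
        sx = q.se.get(num, 0.0)
        sy = q.se.get(den, 0.0)
        return r * math.sqrt((sx / x) ** 2 + (sy / y) ** 2)

    bf = bypass_fraction(q)
    ry = readthrough_yield(q)
    er = est_ratio(q)
    folds = {}
    if basal is not None:
        folds = {e: v["fold"] for e, v in stress_fold_changes(basal, q).items()}
    return ReadthroughSummary(
        condition=q.condition,
        bypass_fraction=bf,
        readthrough_yield=ry,
        est_ratio=er,
        fold_changes=folds,
        uncertainty={
            "bypass_fraction": ratio_se("intermediate", "pri_PTPN6", bf),
            "readthrough_yield": ratio_se("pri_miR", "intermediate", ry),
            "est_ratio": ratio_se("pri_miR_EST", "pri_miR", er),
        },
    )
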