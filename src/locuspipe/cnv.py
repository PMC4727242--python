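"""Copy-number subgrouping over a locus window and within-subgroup correlation.

Samples are classified amplified / deleted / unchanged from segmented
copy-number profiles (SEG-like: sample, chrom, start, end, seg_mean) over a
genomic window: any overlapping segment whose log-ratio mean exceeds the
threshold (default +/-0.3) makes the call.  Gene-pair Spearman correlations
are then recomputed within the unchanged subgroup to test whether a
correlation survives once copy-number-driven samples are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from . import qpcr

__all__ = [
    "SegmentProfile",
    "LocusWindow",
    "SampleLabel",
    "DEFAULT_THRESHOLD",
    "classify_sample",
    "classify_cohort",
    "subgroup_correlations",
]

DEFAULT_THRESHOLD = 0.3
#: default window width around the locus of interest, bp
DEFAULT_WINDOW_BP = 150_000


@dataclass(frozen=True)
class SegmentProfile:
    """Segmented copy-number profile for one sample (0-based half-open)."""

    sample: str
    segments: tuple[tuple[str, int, int, float], ...]  # (chrom, start, end, mean)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.segments:
            if end <= start:
                raise ValueError(f"segment [{start}, {end}) has non-positive length")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping segments on {chrom}")

    @classmethod
    def from_frame(cls, seg: pd.DataFrame, sample: str) -> "SegmentProfile":
        rows = seg[seg["sample"] == sample]
        return cls(sample=sample, segments=tuple(
            (r.chrom, int(r.start), int(r.end), float(r.seg_mean))
            for r in rows.itertuples()))


@dataclass(frozen=True)
class LocusWindow:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Any base-pair overlap counts."""
        return chrom == self.chrom and start < self.end and end > self.start


@dataclass(frozen=True)
class SampleLabel:
    sample: str
    label: str  # amplified | deleted | unchanged
    max_seg: float
    min_seg: float
    coverage_warning: bool = False


def classify_sample(
    profile: SegmentProfile,
    window: LocusWindow,
    threshold: float = DEFAULT_THRESHOLD,
) -> SampleLabel:
    """Label one sample from its segment means over the window.

    amplified if any overlapping segment mean > +threshold, else deleted if
    any < -threshold, else unchanged.  Amplified takes precedence when both
    thresholds are crossed (the altered samples are pooled downstream, so
    the precedence never affects the unchanged-vs-altered contrast).  No
    overlapping segment at all gives unchanged with a coverage warning.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    means = [m for chrom, s, e, m in profile.segments
             if window.overlaps(chrom, s, e)]
    if not means:
        warnings.warn(f"sample {profile.sample!r} has no segment overlapping "
                      f"the window; labelled unchanged", stacklevel=2)
        return SampleLabel(profile.sample, "unchanged",
                           float("nan"), float("nan"), coverage_warning=True)
    mx, mn = max(means), min(means)
    if mx > threshold:
        label = "amplified"
    elif mn < -threshold:
        label = "deleted"
    else:
        label = "unchanged"
    return SampleLabel(profile.sample, label, mx, mn)


def classify_cohort(
    segments: pd.DataFrame,
    window: LocusWindow,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Classify every sample in a SEG-like table.

    Returns a DataFrame (sample, label, max_seg, min_seg, coverage_warning);
    each sample receives exactly one label.
    """
    rows = []
    for sample in pd.unique(segments["sample"]):
        lab = classify_sample(SegmentProfile.from_frame(segments, sample),
                              window, threshold)
        rows.append((lab.sample, lab.label, lab.max_seg, lab.min_seg,
                     lab.coverage_warning))
    return pd.DataFrame(rows, columns=[
        "sample", "label", "max_seg", "min_seg", "coverage_warning"])


MIN_SUBGROUP_N = 5


def subgroup_correlations(
    expression: pd.DataFrame,
    labels: pd.DataFrame | pd.Series,
    gene_pairs: Iterable[tuple[str, str]],
    subgroups: Sequence[str] = ("all", "altered", "unchanged"),
) -> pd.DataFrame:
    """Spearman rho per gene pair within copy-number subgroups.

    `expression` is genes x samples; `labels` maps sample -> label (a frame
    from classify_cohort or a Series).  Subgroups: 'all' (every sample),
    'altered' (amplified union deleted), 'unchanged', or a single label.
    Subgroups below 5 samples are still reported, flagged low_n.
    Returns columns subgroup, gene_a, gene_b, rho, p, n, low_n.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels.set_index("sample")["label"]
    labels = labels.reindex(expression.columns)

    def members(name: str) -> list[str]:
        if name == "all":
            return list(expression.columns)
        if name == "altered":
            return list(labels.index[labels.isin(["amplified", "deleted"])])
        return list(labels.index[labels == name])

    rows = []
    for name in subgroups:
        cols = members(name)
        low_n = len(cols) < MIN_SUBGROUP_N
        for ga, gb in gene_pairs:
            if ga not in expression.index or gb not in expression.index:
                raise KeyError(f"gene pair ({ga!r}, {gb!r}) not in the matrix")
            if len(cols) >= 3:
                res = qpcr.spearman(expression.loc[ga, cols],
                                    expression.loc[gb, cols])
                rho, p = res.rho, res.pvalue
            else:
                rho, p = float("nan"), float("nan")
            rows.append((name, ga, gb, rho, p, len(cols), low_n))
    return pd.DataFrame(rows, columns=[
        "subgroup", "gene_a", "gene_b", "rho", "p", "n", "low_n"])
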