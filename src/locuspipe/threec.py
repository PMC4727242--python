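"""Chromosome conformation capture (3C-qPCR) quantification.

In-silico restriction digestion of the locus, restriction-efficiency QC,
BAC-control primer normalization, relative interaction frequency over the
closest 3' fragment from the anchor, and loop-peak calling.

The normalization logic mirrors the standard 3C-qPCR design: every junction
assay is calibrated on a dilution series of a digested-and-religated BAC
template covering the locus, in which all junctions are equimolar.  Dividing
the sample junction quantity by the BAC junction quantity therefore cancels
per-primer-pair efficiency bias exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import qpcr

__all__ = [
    "Fragment",
    "FragmentMap",
    "InteractionProfile",
    "digest_sequence",
    "restriction_efficiency",
    "normalize_junctions",
    "relative_profile",
    "detect_interaction_peaks",
]

NCOI_SITE = "CCATGG"   # NcoI recognition motif, its own reverse complement
NCOI_CUT_OFFSET = 1    # C^CATGG


@dataclass(frozen=True)
class Fragment:
    id: str
    start: int
    end: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentMap:
    """Ordered restriction fragments tiling a linear locus (0-based half-open)."""

    fragments: tuple[Fragment, ...]
    enzyme_site: str = NCOI_SITE
    cut_offset: int = NCOI_CUT_OFFSET

    def __post_init__(self) -> None:
        prev_end = None
        prev_mid = None
        for f in self.fragments:
            if f.end <= f.start:
                raise ValueError(f"fragment {f.id} has non-positive length")
            if prev_end is not None and f.start != prev_end:
                raise ValueError("fragments must tile without gaps or overlap")
            if prev_mid is not None and f.midpoint <= prev_mid:
                raise ValueError("fragment midpoints must be strictly increasing")
            prev_end, prev_mid = f.end, f.midpoint

    def __len__(self) -> int:
        return len(self.fragments)

    def ids(self) -> list[str]:
        return [f.id for f in self.fragments]

    def index_of(self, fragment_id: str) -> int:
        for i, f in enumerate(self.fragments):
            if f.id == fragment_id:
                return i
        raise KeyError(f"fragment {fragment_id!r} not in map")

    def midpoint(self, fragment_id: str) -> int:
        return self.fragments[self.index_of(fragment_id)].midpoint


@dataclass(frozen=True)
class InteractionProfile:
    """Per-fragment 3C interaction frequencies around one anchor.

    table columns: fragment, midpoint, distance (bp from anchor midpoint),
    normalized (sample/BAC), relative (over the closest 3' fragment).
    """

    anchor: str
    reference: str
    table: pd.DataFrame = field(repr=False)


def _read_sequence(source) -> str:
    """Accept a plain string, a Bio.SeqRecord, or a FASTA path."""
    if isinstance(source, (str, Path)) and str(source):
        try:
            is_file = Path(str(source)).is_file()
        except OSError:  # raw sequence longer than a file name can be
            is_file = False
        if is_file:
            from Bio import SeqIO
            record = next(SeqIO.parse(str(source), "fasta"))
            return str(record.seq)
    if hasattr(source, "seq"):
        return str(source.seq)
    return str(source)


def digest_sequence(sequence, site: str = NCOI_SITE,
                    cut_offset: int = NCOI_CUT_OFFSET) -> FragmentMap:
    """In-silico restriction digestion of a linear sequence.

    Scans the forward strand for exact matches of `site` (strict A/C/G/T:
    ambiguous bases never match) and cuts at match start + `cut_offset`.
    NcoI's CCATGG is palindromic, so one strand suffices.  Fragments are the
    0-based half-open intervals between successive cuts; a sequence without
    the motif yields a single fragment spanning it entirely.
    """
    seq = _read_sequence(sequence).upper()
    if not seq:
        raise ValueError("empty sequence")
    if len(site) < 4:
        raise ValueError("restriction motif must be at least 4 bases")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut offset outside the motif")
    site = site.upper()
    cuts = []
    i = seq.find(site)
    while i != -1:
        cuts.append(i + cut_offset)
        i = seq.find(site, i + 1)
    bounds = [0] + cuts + [len(seq)]
    frags = tuple(
        Fragment(id=f"f{k + 1:03d}", start=bounds[k], end=bounds[k + 1])
        for k in range(len(bounds) - 1)
    )
    return FragmentMap(fragments=frags, enzyme_site=site, cut_offset=cut_offset)


def restriction_efficiency(
    across_site_pg: Mapping[str, float],
    reference_pg: float,
) -> dict[str, float]:
    """Fraction cut at each restriction site from non-ligated controls.

    An amplicon spanning an uncut site survives digestion, so
    efficiency = 1 - across_site / reference, clipped to [0, 1].
    """
    if reference_pg <= 0:
        raise ValueError("reference quantity must be positive")
    out = {}
    for site, q in across_site_pg.items():
        if q < 0:
            raise ValueError(f"negative quantity for site {site!r}")
        if q > reference_pg:
            warnings.warn(
                f"across-site amplicon exceeds reference at {site!r}; "
                "efficiency clipped to 0", stacklevel=2)
        out[site] = float(np.clip(1.0 - q / reference_pg, 0.0, 1.0))
    return out


def normalize_junctions(
    sample_plate: pd.DataFrame,
    bac_plate: pd.DataFrame,
    bac_dilutions: pd.DataFrame,
) -> pd.DataFrame:
    """Quantify junctions and cancel primer bias with the BAC control.

    Both plates need columns anchor, fragment, sample, replicate, ct and the
    dilution table assay ('jx_<anchor>_<fragment>'), quantity_pg, ct.  Each
    junction assay is calibrated with its own standard curve from the BAC
    dilutions, Ct replicates are mean-aggregated before inversion, and
    normalized = q_sample / q_bac.  Fragments whose BAC quantity is zero or
    unmeasurable come back NaN (flagged via the q_bac column), not dropped.
    """
    anchors = set(sample_plate["anchor"]) | set(bac_plate["anchor"])
    if len(anchors) != 1:
        raise ValueError(f"expected a single anchor per plate, got {sorted(anchors)}")
    anchor = anchors.pop()
    missing = set(sample_plate["fragment"]) ^ set(bac_plate["fragment"])
    if missing:
        raise ValueError(f"fragments not shared by sample and BAC plates: {missing}")

    sample_ct = qpcr.aggregate_replicates(sample_plate, by=("fragment",))
    bac_ct = qpcr.aggregate_replicates(bac_plate, by=("fragment",))
    rows = []
    for frag in sample_ct["fragment"]:
        assay = f"jx_{anchor}_{frag}"
        dil = bac_dilutions[bac_dilutions["assay"] == assay]
        if dil.empty:
            raise ValueError(f"no dilution series for junction assay {assay!r}")
        curve = qpcr.fit_standard_curve(
            list(zip(dil["quantity_pg"], dil["ct"])))
        q_s = curve.invert(float(sample_ct.loc[sample_ct["fragment"] == frag, "ct"].iloc[0]))
        q_b = curve.invert(float(bac_ct.loc[bac_ct["fragment"] == frag, "ct"].iloc[0]))
        norm = q_s / q_b if q_b and not math.isnan(q_b) and q_b > 0 else float("nan")
        rows.append((frag, q_s, q_b, norm))
    return pd.DataFrame(rows, columns=["fragment", "q_sample", "q_bac", "normalized"])


def relative_profile(
    normalized: pd.DataFrame | Mapping[str, float],
    fragment_map: FragmentMap,
    anchor: str,
) -> InteractionProfile:
    """Relative interaction frequency over the closest 3' fragment from the anchor.

    The reference is the first measured fragment 3' of the anchor (higher
    coordinate); its relative frequency is 1 by construction.  Distances are
    measured between fragment midpoints.
    """
    if isinstance(normalized, pd.DataFrame):
        freq = dict(zip(normalized["fragment"], normalized["normalized"]))
    else:
        freq = dict(normalized)
    anchor_idx = fragment_map.index_of(anchor)
    anchor_mid = fragment_map.fragments[anchor_idx].midpoint
    reference = None
    for frag in fragment_map.fragments[anchor_idx + 1:]:
        if frag.id in freq and not math.isnan(freq[frag.id]):
            reference = frag.id
            break
    if reference is None:
        raise ValueError(
            f"anchor {anchor!r} has no measured fragment on its 3' side")
    ref_freq = freq[reference]
    if ref_freq <= 0:
        raise ValueError("reference fragment has non-positive frequency")
    rows = []
    for frag in fragment_map.fragments:
        if frag.id == anchor or frag.id not in freq:
            continue
        rows.append((
            frag.id, frag.midpoint, frag.midpoint - anchor_mid,
            freq[frag.id], freq[frag.id] / ref_freq,
        ))
    table = pd.DataFrame(
        rows, columns=["fragment", "midpoint", "distance", "normalized", "relative"])
    return InteractionProfile(anchor=anchor, reference=reference, table=table)


def detect_interaction_peaks(
    profile: InteractionProfile,
    min_fold: float = 2.0,
    flank: int = 2,
) -> list[list[str]]:
    """Call looping fragments against their local background.

    A fragment is called when its relative frequency is at least `min_fold`
    times the median of its `flank` fragments on each side (itself excluded;
    truncated at profile edges).  The anchor's immediate neighbours are not
    candidates: the 3' one is the normalization reference (pinned to 1 by
    construction) and both are dominated by random-collision background at
    near-zero genomic distance, as is usual in 3C viewpoint analyses.
    Contiguous calls merge into one region; the return value is a list of
    regions, each a list of fragment ids.
    """
    t = profile.table.reset_index(drop=True)
    if len(t) < 2 * flank + 1:
        raise ValueError(f"need at least {2 * flank + 1} measured fragments")
    rel = t["relative"].to_numpy()
    # fragments adjacent to the anchor: smallest |distance| on each side
    dist = t["distance"].to_numpy()
    excluded = {profile.reference}
    for side in (dist > 0, dist < 0):
        if side.any():
            nearest = np.abs(np.where(side, dist, np.iinfo(np.int64).max)).argmin()
            excluded.add(t.loc[nearest, "fragment"])
    called = np.zeros(len(t), dtype=bool)
    for i in range(len(t)):
        if t.loc[i, "fragment"] in excluded:
            continue
        lo, hi = max(0, i - flank), min(len(t), i + flank + 1)
        neighbours = np.concatenate([rel[lo:i], rel[i + 1:hi]])
        neighbours = neighbours[~np.isnan(neighbours)]
        if neighbours.size == 0 or math.isnan(rel[i]):
            continue
        called[i] = rel[i] >= min_fold * float(np.median(neighbours))
    regions: list[list[str]] = []
    current: list[str] = []
    for i, c in enumerate(called):
        if c:
            current.append(t.loc[i, "fragment"])
        elif current:
            regions.append(current)
            current = []
    if current:
        regions.append(current)
    return regions
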