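"""Classification of the genome into the four H3K27me3 fate categories:

    i_maintained        autosomal signal present before and after the mutation
    ii_lost             autosomal signal present before, absent after
    iii_never           signal absent (or never present)
    iv_chrX_maintained  X-chromosome signal retained

plus per-chromosome and per-domain occupancy summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, ValidationError
from .track_io import BinnedTrack, _require_same_grid

CAT_I = "i_maintained"
CAT_II = "ii_lost"
CAT_III = "iii_never"
CAT_IV = "iv_chrX_maintained"
CATEGORIES = (CAT_I, CAT_II, CAT_III, CAT_IV)


def _runs(mask: np.ndarray):
    """Yield (start, end, value) runs of a 1-D array, end exclusive."""
    if mask.size == 0:
        return
    boundaries = np.flatnonzero(np.diff(mask) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [mask.size]])
    for s, e in zip(starts, ends):
        yield int(s), int(e), mask[s]


def presence_mask(
    values: np.ndarray, tau: float, min_bins: int = 1, max_gap_bins: int = 0
) -> np.ndarray:
    """Threshold a bin vector at tau, bridge internal gaps of at most
    max_gap_bins, then drop present runs shorter than min_bins."""
    if not np.isfinite(tau):
        raise ValidationError(f"threshold tau must be finite, got {tau}")
    if min_bins < 1 or max_gap_bins < 0:
        raise ValidationError("min_bins must be >= 1 and max_gap_bins >= 0")
    present = values > tau
    if max_gap_bins > 0:
        bridged = present.copy()
        for s, e, val in _runs(present):
            # only internal gaps (flanked by present runs) are bridged
            if not val and s > 0 and e < present.size and (e - s) <= max_gap_bins:
                bridged[s:e] = True
        present = bridged
    if min_bins > 1:
        filtered = present.copy()
        for s, e, val in _runs(present):
            if val and (e - s) < min_bins:
                filtered[s:e] = False
        present = filtered
    return present


@dataclass(frozen=True)
class DomainAnnotation:
    """Non-overlapping category intervals covering every bin of the genome."""

    intervals: tuple[tuple[str, int, int, str], ...]  # (chrom, start, end, category)
    bin_size: int
    labels: dict[str, np.ndarray]  # per-chromosome per-bin category index into CATEGORIES

    def category_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(CATEGORIES, 0)
        for lab in self.labels.values():
            for idx, cat in enumerate(CATEGORIES):
                counts[cat] += int(np.sum(lab == idx))
        return counts

    @property
    def total_bins(self) -> int:
        return sum(v.size for v in self.labels.values())

    def mask(self, chrom: str, category: str) -> np.ndarray:
        return self.labels[chrom] == CATEGORIES.index(category)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["chrom", "start", "end", "category"])

    def write_bed(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def call_domains(
    wt: BinnedTrack,
    mut: BinnedTrack,
    tau: float = 0.0,
    min_domain_bins: int = 5,
    max_gap_bins: int = 2,
) -> DomainAnnotation:
    """Assign every bin a fate category from wild-type and mutant presence.

    A bin is "present" in a condition when its (input-normalized) value exceeds
    tau, after bridging short gaps and discarding short runs. Autosomes:
    present in both -> i, wild type only -> ii, otherwise -> iii. X: present
    in both -> iv, otherwise -> iii.
    """
    _require_same_grid(wt, mut, "wild-type and mutant tracks")
    labels: dict[str, np.ndarray] = {}
    intervals: list[tuple[str, int, int, str]] = []
    for chrom_obj in wt.assembly:
        chrom = chrom_obj.name
        w = presence_mask(wt.values[chrom], tau, min_domain_bins, max_gap_bins)
        m = presence_mask(mut.values[chrom], tau, min_domain_bins, max_gap_bins)
        lab = np.full(w.size, CATEGORIES.index(CAT_III), dtype=np.int8)
        if chrom_obj.is_x:
            lab[w & m] = CATEGORIES.index(CAT_IV)
        else:
            lab[w & m] = CATEGORIES.index(CAT_I)
            lab[w & ~m] = CATEGORIES.index(CAT_II)
        labels[chrom] = lab
        length = wt.assembly.length(chrom)
        for s, e, val in _runs(lab):
            start = s * wt.bin_size
            end = min(e * wt.bin_size, length)
            intervals.append((chrom, start, end, CATEGORIES[int(val)]))
    return DomainAnnotation(tuple(intervals), wt.bin_size, labels)


def chromosome_summary(track: BinnedTrack) -> pd.DataFrame:
    """Per-chromosome occupancy stats (the per-chromosome boxplot numbers)."""
    rows = []
    for chrom_obj in track.assembly:
        v = track.values[chrom_obj.name]
        q1, med, q3 = np.percentile(v, [25, 50, 75]) if v.size else (np.nan,) * 3
        rows.append(
            {
                "chrom": chrom_obj.name,
                "chrom_class": chrom_obj.chrom_class,
                "n_bins": int(v.size),
                "mean": float(np.mean(v)) if v.size else np.nan,
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
            }
        )
    return pd.DataFrame(rows)


def domain_summary(tracks: dict[str, BinnedTrack], domains: DomainAnnotation) -> pd.DataFrame:
    """Mean/median occupancy per (category, track); every bin counted once.

    Categories with no bins are kept in the output with n_bins 0 and NaN stats
    so downstream consumers see them flagged rather than silently dropped.
    """
    if not tracks:
        raise ValidationError("domain_summary needs at least one track")
    rows = []
    for name, track in tracks.items():
        if set(track.values) != set(domains.labels) or any(
            track.values[c].size != domains.labels[c].size for c in domains.labels
        ):
            raise DimensionError(f"track {name!r} does not share the domain grid")
        for cat in CATEGORIES:
            pooled = np.concatenate(
                [track.values[c][domains.mask(c, cat)] for c in track.values]
            )
            rows.append(
                {
                    "category": cat,
                    "track": name,
                    "n_bins": int(pooled.size),
                    "mean": float(np.mean(pooled)) if pooled.size else np.nan,
                    "median": float(np.median(pooled)) if pooled.size else np.nan,
                    "empty": pooled.size == 0,
                }
            )
    return pd.DataFrame(rows)
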