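"""Binned signal tracks: bedGraph I/O, binning, scaling, input normalization,
smoothing, replicate merging and re-binning.

All coordinates are 0-based half-open (bedGraph convention). A chromosome of
length L at bin size b has ceil(L / b) bins; the trailing partial bin is a
real bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DimensionError,
    NormalizationError,
    ParseError,
    ValidationError,
)
from .genome import GenomeAssembly

# normalization states, in legal transition order raw -> scaled -> {delta|logratio} -> smoothed
STATE_RAW = "raw"
STATE_SCALED = "scaled"
STATE_DELTA = "delta"
STATE_LOGRATIO = "logratio"
STATE_SMOOTHED = "smoothed"
STATES = (STATE_RAW, STATE_SCALED, STATE_DELTA, STATE_LOGRATIO, STATE_SMOOTHED)
_NORMALIZED_STATES = (STATE_DELTA, STATE_LOGRATIO)


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width bin values with a normalization-state tag."""

    assembly: GenomeAssembly
    bin_size: int
    values: dict[str, np.ndarray]
    state: str = STATE_RAW
    read_total: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValidationError(f"bin_size must be positive, got {self.bin_size}")
        if self.state not in STATES:
            raise ValidationError(f"unknown track state {self.state!r}")
        if set(self.values) != set(self.assembly.names):
            raise DimensionError(
                f"track chromosomes {sorted(self.values)} do not match "
                f"assembly {sorted(self.assembly.names)}"
            )
        vals = {}
        for chrom in self.assembly.names:
            v = np.asarray(self.values[chrom], dtype=float)
            expected = self.assembly.n_bins(chrom, self.bin_size)
            if v.ndim != 1 or v.size != expected:
                raise DimensionError(
                    f"{chrom}: expected {expected} bins at {self.bin_size} bp, got shape {v.shape}"
                )
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"{chrom}: non-finite values in track")
            if self.state in (STATE_RAW, STATE_SCALED) and np.any(v < 0):
                raise ValidationError(f"{chrom}: negative values in a {self.state} track")
            vals[chrom] = v
        self.values = vals

    def n_bins(self, chrom: str) -> int:
        return self.assembly.n_bins(chrom, self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(v.size for v in self.values.values())

    def flatten(self, chroms=None) -> np.ndarray:
        names = self.assembly.names if chroms is None else tuple(chroms)
        return np.concatenate([self.values[c] for c in names])

    def like(self, values: dict[str, np.ndarray], state: str | None = None, **kw) -> "BinnedTrack":
        return BinnedTrack(
            assembly=self.assembly,
            bin_size=self.bin_size,
            values={c: np.asarray(v, dtype=float) for c, v in values.items()},
            state=self.state if state is None else state,
            read_total=kw.pop("read_total", self.read_total),
            metadata=kw.pop("metadata", dict(self.metadata)),
        )

    def copy(self) -> "BinnedTrack":
        return replace(self, values={c: v.copy() for c, v in self.values.items()},
                       metadata=dict(self.metadata))

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.assembly.names == other.assembly.names
            and self.bin_size == other.bin_size
            and all(self.assembly.length(c) == other.assembly.length(c) for c in self.assembly.names)
        )


def _require_same_grid(a: BinnedTrack, b: BinnedTrack, what: str = "tracks"):
    if not a.same_grid(b):
        raise DimensionError(f"{what} do not share assembly and bin size")


@dataclass(frozen=True)
class ReadPlacements:
    """Aligned-fragment intervals per chromosome, 0-based half-open."""

    intervals: dict[str, list[tuple[int, int]]]

    def validate(self, assembly: GenomeAssembly):
        for chrom, ivs in self.intervals.items():
            if chrom not in assembly:
                raise ValidationError(f"placements on unknown chromosome {chrom!r}")
            length = assembly.length(chrom)
            for start, end in ivs:
                if not (0 <= start < end <= length):
                    raise ValidationError(
                        f"{chrom}:[{start},{end}) out of bounds for length {length}"
                    )

    @property
    def n_fragments(self) -> int:
        return sum(len(v) for v in self.intervals.values())


def bin_coverage(
    placements: ReadPlacements,
    assembly: GenomeAssembly,
    bin_size: int,
    statistic: str = "max",
) -> BinnedTrack:
    """Bin fragment placements into a raw track.

    ``statistic='max'``: each bin value is the maximum per-base fragment depth
    within the bin — the only well-defined reading of "maximum amount of reads
    in each bin" for fragments spanning bin edges. ``statistic='count'``
    (number of fragments overlapping the bin) is offered as the alternative.
    """
    if statistic not in ("max", "count"):
        raise ValidationError(f"unknown binning statistic {statistic!r}")
    placements.validate(assembly)
    values: dict[str, np.ndarray] = {}
    for chrom in assembly.names:
        length = assembly.length(chrom)
        nbins = assembly.n_bins(chrom, bin_size)
        ivs = placements.intervals.get(chrom, [])
        if statistic == "max":
            diff = np.zeros(length + 1)
            for start, end in ivs:
                diff[start] += 1
                diff[end] -= 1
            depth = np.cumsum(diff[:-1])
            edges = np.arange(0, length, bin_size)
            values[chrom] = np.maximum.reduceat(depth, edges) if length else np.zeros(0)
        else:
            out = np.zeros(nbins)
            for start, end in ivs:
                b0 = start // bin_size
                b1 = (end - 1) // bin_size
                out[b0 : b1 + 1] += 1
            values[chrom] = out
    total = float(placements.n_fragments)
    return BinnedTrack(assembly, bin_size, values, state=STATE_RAW, read_total=total)


def scale_to_total(
    track: BinnedTrack, target_total: float, read_total: float | None = None
) -> BinnedTrack:
    """Rescale a raw track so libraries are comparable at a common read total."""
    if track.state != STATE_RAW:
        raise ValidationError(f"scale_to_total expects a raw track, got {track.state!r}")
    total = track.read_total if read_total is None else read_total
    if total is None:
        raise NormalizationError("track read total unknown; pass read_total")
    if total <= 0:
        raise NormalizationError(f"cannot scale a track with read total {total}")
    factor = target_total / total
    scaled = {c: v * factor for c, v in track.values.items()}
    return track.like(scaled, state=STATE_SCALED, read_total=float(target_total))


def normalize_input(
    ip: BinnedTrack, input_track: BinnedTrack, method: str = "logratio", pseudocount: float = 1.0
) -> BinnedTrack:
    """Correct IP signal by chromatin input.

    delta:    ip - input  (avoids low-read-count biases)
    logratio: log2((ip + pseudocount) / (input + pseudocount))
    """
    _require_same_grid(ip, input_track, "IP and input")
    if ip.state != STATE_SCALED or input_track.state != STATE_SCALED:
        raise ValidationError("normalize_input expects equal-total scaled tracks")
    if method == "delta":
        out = {c: ip.values[c] - input_track.values[c] for c in ip.values}
        state = STATE_DELTA
    elif method == "logratio":
        if pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        out = {}
        for c in ip.values:
            num = ip.values[c] + pseudocount
            den = input_track.values[c] + pseudocount
            if np.any(num <= 0) or np.any(den <= 0):
                raise NormalizationError(
                    f"{c}: non-positive values under pseudocount {pseudocount}; logratio undefined"
                )
            out[c] = np.log2(num / den)
        state = STATE_LOGRATIO
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    return ip.like(out, state=state)


def merge_replicates(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Combine replicate raw tracks by summing per-bin values and read totals.

    This matches merging at the aligned-read level exactly for count
    statistics and is a documented approximation for max-depth bins.
    """
    if not tracks:
        raise ValidationError("merge_replicates needs at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        _require_same_grid(first, t, "replicates")
        if t.state != STATE_RAW:
            raise ValidationError("merge_replicates expects raw tracks")
    if first.state != STATE_RAW:
        raise ValidationError("merge_replicates expects raw tracks")
    values = {
        c: np.sum([t.values[c] for t in tracks], axis=0) for c in first.values
    }
    totals = [t.read_total for t in tracks]
    total = float(sum(totals)) if all(t is not None for t in totals) else None
    return first.like(values, state=STATE_RAW, read_total=total)


def smooth(track: BinnedTrack, window_bins: int = 5) -> BinnedTrack:
    """Centered running mean; the window shrinks at chromosome ends and never
    crosses a chromosome boundary."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValidationError(f"window must be a positive odd integer, got {window_bins}")
    if track.state not in _NORMALIZED_STATES:
        raise ValidationError(
            f"smooth expects an input-normalized track (delta/logratio), got {track.state!r}"
        )
    half = window_bins // 2
    kernel = np.ones(window_bins)
    out = {}
    for c, v in track.values.items():
        if v.size == 0:
            out[c] = v.copy()
            continue
        # full convolution sliced to center: exact windowed sums for any
        # window/vector length combination
        sums = np.convolve(v, kernel, mode="full")[half : half + v.size]
        counts = np.convolve(np.ones_like(v), kernel, mode="full")[half : half + v.size]
        out[c] = sums / counts
    return track.like(out, state=STATE_SMOOTHED, metadata={**track.metadata, "smoothed_from": track.state, "window_bins": window_bins})


def rebin(track: BinnedTrack, new_bin_size: int) -> BinnedTrack:
    """Coarsen to a multiple of the current bin size; coarse bin value = mean of
    the fine bins present in it (the partial last group averages its members)."""
    if new_bin_size == track.bin_size:
        return track.copy()
    if new_bin_size <= 0 or new_bin_size % track.bin_size != 0:
        raise ValidationError(
            f"new bin size {new_bin_size} is not a multiple of {track.bin_size}"
        )
    factor = new_bin_size // track.bin_size
    out = {}
    for c, v in track.values.items():
        n_coarse = track.assembly.n_bins(c, new_bin_size)
        padded = np.full(n_coarse * factor, np.nan)
        padded[: v.size] = v
        out[c] = np.nanmean(padded.reshape(n_coarse, factor), axis=1)
    return BinnedTrack(track.assembly, new_bin_size, out, state=track.state,
                       read_total=track.read_total, metadata=dict(track.metadata))


# ---------------------------------------------------------------------------
# bedGraph I/O


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a 4-column bedGraph, merging equal-value runs and omitting zeros.

    A `#state=` comment preserves the normalization-state tag for round-trips.
    Values are formatted with shortest round-trip float repr, so
    read(write(t)) == t exactly.
    """
    with open(path, "w") as fh:
        fh.write(f"#state={track.state}\n")
        for chrom in track.assembly.names:
            v = track.values[chrom]
            length = track.assembly.length(chrom)
            i = 0
            while i < v.size:
                j = i
                while j + 1 < v.size and v[j + 1] == v[i]:
                    j += 1
                if v[i] != 0.0:
                    start = i * track.bin_size
                    end = min((j + 1) * track.bin_size, length)
                    fh.write(f"{chrom}\t{start}\t{end}\t{float(v[i])!r}\n")
                i = j + 1


def read_bedgraph(path, assembly: GenomeAssembly, bin_size: int,
                  state: str | None = None) -> BinnedTrack:
    """Read a grid-aligned bedGraph; unmentioned bins are 0.

    Records must start on a bin boundary and end on one (or at the chromosome
    end). Overlapping records, unknown chromosomes and malformed lines raise
    :class:`ParseError` with the offending line number.
    """
    values = {c: np.zeros(assembly.n_bins(c, bin_size)) for c in assembly.names}
    filled = {c: np.zeros(assembly.n_bins(c, bin_size), dtype=bool) for c in assembly.names}
    file_state = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#state="):
                    file_state = line[len("#state="):].strip()
                continue
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 4:
                raise ParseError(f"expected 4 columns, got {len(fields)}", path, lineno)
            chrom, s_start, s_end, s_val = fields
            if chrom not in assembly:
                raise ParseError(f"unknown chromosome {chrom!r}", path, lineno)
            try:
                start, end, val = int(s_start), int(s_end), float(s_val)
            except ValueError as exc:
                raise ParseError(f"malformed record: {exc}", path, lineno) from None
            length = assembly.length(chrom)
            if not (0 <= start < end <= length):
                raise ParseError(
                    f"interval [{start},{end}) out of bounds for {chrom} (length {length})",
                    path, lineno,
                )
            if start % bin_size != 0 or (end % bin_size != 0 and end != length):
                raise ParseError(
                    f"interval [{start},{end}) not aligned to the {bin_size} bp grid",
                    path, lineno,
                )
            b0 = start // bin_size
            b1 = math.ceil(end / bin_size)
            if filled[chrom][b0:b1].any():
                raise ParseError(f"overlapping records over {chrom}:[{start},{end})", path, lineno)
            values[chrom][b0:b1] = val
            filled[chrom][b0:b1] = True
    final_state = state if state is not None else (file_state or STATE_RAW)
    return BinnedTrack(assembly, bin_size, values, state=final_state)


# ---------------------------------------------------------------------------
# whole-genome coverage uniformity


@dataclass(frozen=True)
class UniformityReport:
    log2_ratio: BinnedTrack
    sd: float
    mad: float
    outlier_fraction: float
    threshold: float

    @property
    def n_bins(self) -> int:
        return self.log2_ratio.total_bins


def coverage_uniformity(
    sample: BinnedTrack,
    reference: BinnedTrack,
    pseudocount: float = 1.0,
    threshold: float = 1.0,
) -> UniformityReport:
    """Per-bin log2(sample/reference) with dispersion stats, for judging whether
    a genome is evenly covered relative to a reference library."""
    _require_same_grid(sample, reference, "sample and reference")
    ratios = {}
    for c in sample.values:
        num = sample.values[c] + pseudocount
        den = reference.values[c] + pseudocount
        if np.any(num <= 0) or np.any(den <= 0):
            raise NormalizationError(f"{c}: non-positive values; increase pseudocount")
        ratios[c] = np.log2(num / den)
    lr = BinnedTrack(sample.assembly, sample.bin_size, ratios, state=STATE_LOGRATIO)
    flat = lr.flatten()
    sd = float(np.std(flat))
    mad = float(np.median(np.abs(flat - np.median(flat))))
    frac = float(np.mean(np.abs(flat) > threshold))
    return UniformityReport(lr, sd, mad, frac, threshold)
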