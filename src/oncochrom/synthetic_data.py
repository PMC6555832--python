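"""Seeded generation of all pipeline inputs: a worm-like multi-chromosome
assembly, blocky wild-type H3K27me3 domains with a uniformly high X, H3.3- or
H3-like-pattern oncohistone tracks placed away from pre-existing H3K27me3,
mutant H3K27me3 produced by a planted dependency model, gene tables with
expression changes anti-correlated with the H3K27me3 change, and DAPI
intensities linear in DNA content.

One global integer seed feeds a named substream per generator, so adding a
generator never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import expression, ploidy
from .dependency_model import N_COEFFS, REFERENCE_MODEL, DependencyModel, evaluate
from .errors import ConfigurationError, DimensionError, OncochromError, PlacementError
from .genome import AUTOSOME, X, Chromosome, GenomeAssembly
from .track_io import STATE_LOGRATIO, BinnedTrack, write_bedgraph

MODE_H33 = "H3.3"
MODE_H3LIKE = "H3-like"

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV"]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent, deterministic generator per (seed, name)."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ChromosomeSpec:
    n_autosomes: int = 5
    autosome_length: int = 1_700_000
    x_length: int = 1_500_000


@dataclass(frozen=True)
class DomainSpec:
    """Wild-type H3K27me3 structure: alternating geometric-length blocks on
    autosomes, a constant high baseline on X."""

    mean_length_bp: int = 50_000
    autosome_fraction: float = 0.4
    level: float = 1.5
    background: float = 0.0
    x_baseline: float = 2.0


@dataclass(frozen=True)
class OncohistoneSpec:
    mode: str = MODE_H33
    fraction: float = 0.35  # target fraction of genome bins covered
    mean_length_bp: int = 20_000
    level: float = 1.5
    spread_factor: float = 2.0  # H3-like domain widening
    x_depletion_factor: float = 0.1  # H3.3 X retention relative to autosomes
    weight_floor: float = 0.5  # fraction of the wt signal range added to all weights


@dataclass(frozen=True)
class GeneSpec:
    n_genes: int = 1000
    gene_length: int = 2_000
    expression_log_mean: float = 3.0
    expression_log_sd: float = 1.5
    n_de: int = 100
    de_q23_fraction: float = 0.7  # DE genes drawn from expression quintiles II+III
    anticorrelation_strength: float = 1.0
    effect_scale: float = 1.5  # extra |log2FC| per unit |delta K27me3|
    germline_fraction: float = 0.05


@dataclass(frozen=True)
class DapiSpec:
    slope: float = 10.0  # intensity per n
    offset: float = 100.0  # background intensity
    cv: float = 0.05
    n_per_population: int = 50
    endomitotic_content: float = 64.0


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    bin_size: int = 1_000
    chromosomes: ChromosomeSpec = field(default_factory=ChromosomeSpec)
    domains: DomainSpec = field(default_factory=DomainSpec)
    oncohistone: OncohistoneSpec = field(default_factory=OncohistoneSpec)
    noise_sd: float = 0.1
    dependency_coefficients: tuple[float, ...] = REFERENCE_MODEL.coefficients
    genes: GeneSpec = field(default_factory=GeneSpec)
    dapi: DapiSpec = field(default_factory=DapiSpec)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ConfigurationError("bin_size must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for name, frac in [
            ("domains.autosome_fraction", self.domains.autosome_fraction),
            ("oncohistone.fraction", self.oncohistone.fraction),
            ("genes.de_q23_fraction", self.genes.de_q23_fraction),
            ("genes.anticorrelation_strength", self.genes.anticorrelation_strength),
            ("genes.germline_fraction", self.genes.germline_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {frac}")
        if self.oncohistone.mode not in (MODE_H33, MODE_H3LIKE):
            raise ConfigurationError(
                f"oncohistone mode must be {MODE_H33!r} or {MODE_H3LIKE!r}, "
                f"got {self.oncohistone.mode!r}"
            )
        if self.oncohistone.spread_factor < 1.0:
            raise ConfigurationError("spread_factor must be >= 1")
        if self.dapi.cv < 0:
            raise ConfigurationError("dapi.cv must be >= 0")
        if len(self.dependency_coefficients) != N_COEFFS:
            raise ConfigurationError(f"need {N_COEFFS} dependency coefficients")

    @property
    def dependency_model(self) -> DependencyModel:
        return DependencyModel(tuple(self.dependency_coefficients))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dependency_coefficients"] = list(d["dependency_coefficients"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key, sub in [("chromosomes", ChromosomeSpec), ("domains", DomainSpec),
                         ("oncohistone", OncohistoneSpec), ("genes", GeneSpec),
                         ("dapi", DapiSpec)]:
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "dependency_coefficients" in d:
            d["dependency_coefficients"] = tuple(d["dependency_coefficients"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# generators


def make_assembly(config: SyntheticConfig) -> GenomeAssembly:
    spec = config.chromosomes
    if spec.n_autosomes < 1:
        raise ConfigurationError("need at least one autosome")
    for what, length in [("autosome", spec.autosome_length), ("X", spec.x_length)]:
        if length < 10 * config.bin_size:
            raise ConfigurationError(
                f"{what} length {length} is shorter than 10 bins of {config.bin_size} bp"
            )
    chroms = []
    for i in range(spec.n_autosomes):
        name = f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chrA{i + 1}"
        chroms.append(Chromosome(name, spec.autosome_length, AUTOSOME))
    chroms.append(Chromosome("chrX", spec.x_length, X))
    return GenomeAssembly(tuple(chroms))


def _geometric_runs(rng: np.random.Generator, n_bins: int, mean_high: float,
                    mean_low: float, p_start_high: float):
    """Alternating (is_high, length) runs filling n_bins."""
    runs = []
    high = bool(rng.random() < p_start_high)
    pos = 0
    while pos < n_bins:
        mean = mean_high if high else mean_low
        length = int(rng.geometric(min(1.0, 1.0 / max(mean, 1.0))))
        length = min(length, n_bins - pos)
        runs.append((high, pos, pos + length))
        pos += length
        high = not high
    return runs


def simulate_wt_k27me3(assembly: GenomeAssembly, config: SyntheticConfig) -> BinnedTrack:
    """Wild-type H3K27me3: geometric-length high/background blocks covering the
    configured fraction of each autosome, and a constant high X baseline; plus
    seeded Gaussian noise. Planted block boundaries and the noiseless signal
    are kept in ``track.metadata``."""
    rng = _substream(config.seed, "wt_k27me3")
    spec = config.domains
    mean_high = max(1.0, spec.mean_length_bp / config.bin_size)
    f = spec.autosome_fraction
    noiseless: dict[str, np.ndarray] = {}
    planted: list[tuple[str, int, int]] = []
    for chrom_obj in assembly:
        chrom = chrom_obj.name
        n = assembly.n_bins(chrom, config.bin_size)
        if chrom_obj.is_x:
            noiseless[chrom] = np.full(n, spec.x_baseline)
            continue
        v = np.full(n, spec.background)
        if f >= 1.0:
            v[:] = spec.level
            planted.append((chrom, 0, n))
        elif f > 0.0:
            mean_low = max(1.0, mean_high * (1.0 - f) / f)
            for high, s, e in _geometric_runs(rng, n, mean_high, mean_low, f):
                if high:
                    v[s:e] = spec.level
                    planted.append((chrom, s, e))
        noiseless[chrom] = v
    values = {
        c: v + (rng.normal(0.0, config.noise_sd, v.size) if config.noise_sd else 0.0)
        for c, v in noiseless.items()
    }
    return BinnedTrack(
        assembly, config.bin_size, values, state=STATE_LOGRATIO,
        metadata={"planted_domains": planted, "noiseless": noiseless},
    )


def simulate_oncohistone(
    assembly: GenomeAssembly,
    wt: BinnedTrack,
    mode: str,
    config: SyntheticConfig,
) -> BinnedTrack:
    """Oncohistone occupancy placed preferentially where wild-type H3K27me3 is
    low (anti-correlated placement).

    Domain centers are sampled with probability proportional to
    (max - wt) plus a configurable floor; the floor lets the uniformly high X
    still receive domains, which the H3-like mode keeps while the H3.3 mode
    scales X down by the depletion factor. H3-like widens every domain by the
    spread factor around the same centers; at spread factor 1 the two modes
    share an identical footprint apart from X retention.
    """
    if mode not in (MODE_H33, MODE_H3LIKE):
        raise ConfigurationError(f"unknown oncohistone mode {mode!r}")
    if wt.assembly.names != assembly.names or wt.bin_size != config.bin_size:
        raise DimensionError("wild-type track does not match the assembly/bin size")
    rng = _substream(config.seed, "oncohistone")
    spec = config.oncohistone
    base = wt.metadata.get("noiseless", wt.values)
    chroms = assembly.names
    flat = np.concatenate([base[c] for c in chroms])
    sizes = [base[c].size for c in chroms]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    vmax, vmin = float(flat.max()), float(flat.min())
    span = vmax - vmin
    weights = (vmax - flat) + spec.weight_floor * (span if span > 0 else 1.0)
    weights = weights / weights.sum()

    mean_len = max(1.0, spec.mean_length_bp / config.bin_size)
    total_bins = int(flat.size)
    n_domains = max(1, round(spec.fraction * total_bins / mean_len)) if spec.fraction > 0 else 0
    centers = rng.choice(total_bins, size=n_domains, p=weights) if n_domains else np.array([], int)
    lengths = rng.geometric(1.0 / mean_len, size=n_domains) if n_domains else np.array([], int)
    if mode == MODE_H3LIKE:
        lengths = np.maximum(1, np.round(lengths * spec.spread_factor).astype(int))

    noiseless = {c: np.zeros(base[c].size) for c in chroms}
    intervals: list[tuple[str, int, int]] = []
    for center, length in zip(centers, lengths):
        ci = int(np.searchsorted(offsets, center, side="right")) - 1
        chrom = chroms[ci]
        local = int(center - offsets[ci])
        s = max(0, local - int(length) // 2)
        e = min(sizes[ci], s + int(length))
        if e > s:
            noiseless[chrom][s:e] = spec.level
            intervals.append((chrom, s, e))
    if mode == MODE_H33:
        noiseless[assembly.x_name()] = noiseless[assembly.x_name()] * spec.x_depletion_factor
    values = {
        c: v + (rng.normal(0.0, config.noise_sd, v.size) if config.noise_sd else 0.0)
        for c, v in noiseless.items()
    }
    return BinnedTrack(
        assembly, config.bin_size, values, state=STATE_LOGRATIO,
        metadata={"mode": mode, "planted_intervals": intervals, "noiseless": noiseless},
    )


def simulate_mut_k27me3(
    wt: BinnedTrack,
    onco: BinnedTrack,
    model: DependencyModel,
    noise_sd: float,
    seed: int = 0,
) -> BinnedTrack:
    """Mutant H3K27me3 as the dependency-function image of (wt, onco) plus
    seeded Gaussian noise."""
    if not wt.same_grid(onco):
        raise DimensionError("wt and oncohistone tracks do not share a grid")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = _substream(seed, "mut_k27me3")
    values = {}
    noiseless = {}
    for c in wt.values:
        z = np.asarray(evaluate(model, wt.values[c], onco.values[c]))
        noiseless[c] = z
        values[c] = z + (rng.normal(0.0, noise_sd, z.size) if noise_sd else 0.0)
    return BinnedTrack(
        wt.assembly, wt.bin_size, values, state=STATE_LOGRATIO,
        metadata={"noiseless": noiseless},
    )


def simulate_gene_table(
    assembly: GenomeAssembly,
    config: SyntheticConfig,
    wt: BinnedTrack,
    mut: BinnedTrack,
) -> pd.DataFrame:
    """Non-overlapping single-strand genes with log-normal wild-type
    expression; a configured subset is differentially expressed with sign
    opposite to its gene-body H3K27me3 change and magnitude growing with it,
    drawn preferentially from expression quintiles II and III."""
    rng = _substream(config.seed, "genes")
    spec = config.genes
    if spec.n_genes < 1:
        raise ConfigurationError("genes.n_genes must be >= 1")
    if spec.n_de > spec.n_genes:
        raise ConfigurationError("genes.n_de cannot exceed n_genes")

    total = assembly.total_length
    counts = {c.name: max(1, round(spec.n_genes * c.length / total)) for c in assembly}
    # trim/extend to hit n_genes exactly, largest chromosomes first
    drift = sum(counts.values()) - spec.n_genes
    for name in sorted(counts, key=counts.get, reverse=True):
        while drift > 0 and counts[name] > 1:
            counts[name] -= 1
            drift -= 1
        while drift < 0:
            counts[name] += 1
            drift += 1
    rows = []
    gid = 0
    for chrom_obj in assembly:
        chrom, length = chrom_obj.name, chrom_obj.length
        n_c = counts[chrom]
        slot = length // n_c
        if slot <= spec.gene_length:
            raise PlacementError(
                f"{chrom}: {n_c} genes of {spec.gene_length} bp do not fit in {length} bp"
            )
        for i in range(n_c):
            jitter = int(rng.integers(0, slot - spec.gene_length))
            start = i * slot + jitter
            rows.append(
                {"gene_id": f"g{gid:05d}", "chrom": chrom, "start": start,
                 "end": start + spec.gene_length, "strand": "+"}
            )
            gid += 1
    table = pd.DataFrame(rows)
    table["wt_expression"] = rng.lognormal(
        spec.expression_log_mean, spec.expression_log_sd, len(table)
    )
    table = expression.assign_quintiles(table)
    delta = expression.delta_k27me3(wt, mut, table)
    table["delta_k27me3_planted"] = table["gene_id"].map(delta)

    # DE gene selection, weighted toward quintiles II+III
    de_ids: list[str] = []
    if spec.n_de > 0:
        q23 = table.loc[table["quintile"].isin(["II", "III"]), "gene_id"].to_numpy()
        rest = table.loc[~table["quintile"].isin(["II", "III"]), "gene_id"].to_numpy()
        n23 = min(round(spec.de_q23_fraction * spec.n_de), q23.size)
        n_rest = min(spec.n_de - n23, rest.size)
        de_ids = list(rng.choice(q23, size=n23, replace=False)) + list(
            rng.choice(rest, size=n_rest, replace=False)
        )
    is_de = table["gene_id"].isin(de_ids).to_numpy()

    lfc = rng.normal(0.0, 0.3, len(table))
    fdr = rng.uniform(0.05, 1.0, len(table))
    d = table["delta_k27me3_planted"].to_numpy()
    for idx in np.flatnonzero(is_de):
        anti = -np.sign(d[idx]) if d[idx] != 0 else rng.choice([-1.0, 1.0])
        sign = anti if rng.random() < spec.anticorrelation_strength else -anti
        magnitude = 1.05 + spec.effect_scale * abs(d[idx]) + rng.exponential(0.2)
        lfc[idx] = sign * magnitude
        fdr[idx] = rng.uniform(1e-8, 0.049)
    table["log2_fc"] = lfc
    table["fdr"] = fdr
    table["mut_expression"] = table["wt_expression"] * np.exp2(table["log2_fc"])
    table = expression.de_filter(table)

    germline = np.zeros(len(table), dtype=bool)
    n_germ = round(spec.germline_fraction * len(table))
    non_de = np.flatnonzero(~is_de)
    if n_germ > 0 and non_de.size > 0:
        chosen = rng.choice(non_de, size=min(n_germ, non_de.size), replace=False)
        germline[chosen] = True
    table["germline_specific"] = germline
    return table


def simulate_dapi(config: SyntheticConfig) -> pd.DataFrame:
    """DAPI integrated intensities linear in DNA content for the three nucleus
    populations (4n oocytes, 32n intestine, configurable endomitotic)."""
    rng = _substream(config.seed, "dapi")
    spec = config.dapi
    if spec.cv < 0:
        raise ConfigurationError("dapi.cv must be >= 0")
    populations = [
        (ploidy.OOCYTE, 4.0),
        (ploidy.INTESTINE, 32.0),
        (ploidy.ENDOMITOTIC, spec.endomitotic_content),
    ]
    rows = []
    for pop, content in populations:
        mean = spec.slope * content + spec.offset
        sd = spec.cv * mean
        intensities = rng.normal(mean, sd, spec.n_per_population) if sd else np.full(
            spec.n_per_population, mean
        )
        for i, inten in enumerate(intensities):
            rows.append({"nucleus_id": f"{pop}_{i:03d}", "population": pop,
                         "intensity": float(inten)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset assembly and fixtures on disk


@dataclass(frozen=True)
class SyntheticDataset:
    config: SyntheticConfig
    assembly: GenomeAssembly
    wt_k27me3: BinnedTrack
    oncohistone: BinnedTrack
    mut_k27me3: BinnedTrack
    genes: pd.DataFrame
    dapi: pd.DataFrame

    @property
    def model(self) -> DependencyModel:
        return self.config.dependency_model


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run every generator under the configured seed."""
    assembly = make_assembly(config)
    wt = simulate_wt_k27me3(assembly, config)
    onco = simulate_oncohistone(assembly, wt, config.oncohistone.mode, config)
    mut = simulate_mut_k27me3(
        wt, onco, config.dependency_model, config.noise_sd, seed=config.seed
    )
    genes = simulate_gene_table(assembly, config, wt, mut)
    dapi = simulate_dapi(config)
    return SyntheticDataset(config, assembly, wt, onco, mut, genes, dapi)


FIXTURE_FILES = {
    "wt_k27me3": "wt_k27me3.bedgraph",
    "oncohistone": "oncohistone.bedgraph",
    "mut_k27me3": "mut_k27me3.bedgraph",
    "genes": "genes.tsv",
    "dapi": "dapi.tsv",
    "assembly": "assembly.tsv",
}


def write_fixture_set(config: SyntheticConfig, out_dir) -> dict:
    """Write bedGraph tracks, TSV tables and a JSON manifest; deterministic
    byte-for-byte for a fixed config."""
    from pathlib import Path

    out = Path(out_dir)
    ds = generate_dataset(config)
    try:
        out.mkdir(parents=True, exist_ok=True)
        write_bedgraph(ds.wt_k27me3, out / FIXTURE_FILES["wt_k27me3"])
        write_bedgraph(ds.oncohistone, out / FIXTURE_FILES["oncohistone"])
        write_bedgraph(ds.mut_k27me3, out / FIXTURE_FILES["mut_k27me3"])
        ds.genes.to_csv(out / FIXTURE_FILES["genes"], sep="\t", index=False)
        ds.dapi.to_csv(out / FIXTURE_FILES["dapi"], sep="\t", index=False)
        asm = pd.DataFrame(
            [{"chrom": c.name, "length": c.length, "chrom_class": c.chrom_class}
             for c in ds.assembly]
        )
        asm.to_csv(out / FIXTURE_FILES["assembly"], sep="\t", index=False)
        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "bin_size": config.bin_size,
            "files": dict(FIXTURE_FILES),
            "config": config.to_dict(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OncochromIOError(out, exc) from exc
    return manifest


class OncochromIOError(OncochromError):
    def __init__(self, path, cause):
        super().__init__(f"failed writing fixture set under {path}: {cause}")


def read_assembly_tsv(path) -> GenomeAssembly:
    df = pd.read_csv(path, sep="\t")
    return GenomeAssembly(
        tuple(Chromosome(r.chrom, int(r.length), r.chrom_class)
              for r in df.itertuples(index=False))
    )
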