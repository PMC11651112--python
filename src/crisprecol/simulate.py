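"""Synthetic communities, annotations, repeats, and reads with planted truth.

Every analysis stage in this package can be exercised without external
downloads by generating data whose ground truth is known:

* :func:`gen_community` — a genus x sample count table with per-sample
  cell counts and a strain-level CRISPR annotation table.  Genus mean
  abundances are log-normal (heavy-tailed, as in 16S surveys); sample
  counts are multinomial around jittered genus means; CRISPR carriage
  is planted at the *strain* level with a genus carriage probability
  that declines with log mean abundance at a chosen slope (the density
  effect), so the incidence module is exercised end to end.
* :func:`gen_reads` — background reads with a direct repeat inserted
  into a known fraction of reads (the planted CRISPR load), on a
  random strand at a random offset.
* :func:`gen_diversity_gradient` — samples spanning low to high
  evenness via a Dirichlet concentration sweep, with per-sample CRISPR
  incidence coupled linearly to Shannon diversity (the diversity
  effect).
* :func:`gen_mag_records` — MAG abundance records with a log-scale
  shift between the CRISPR-free and CRISPR-carrying groups.

All generators are deterministic for a given seed and return a truth
manifest sufficient to score downstream estimates without
re-simulation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .density import CountTable, MagRecord
from .diversity import shannon
from .incidence import StrainAnnotation
from .repeat_load import reverse_complement

__all__ = [
    "CommunityModel",
    "ReadSimSpec",
    "CommunityDataset",
    "ReadsDataset",
    "GradientDataset",
    "gen_community",
    "gen_reads",
    "gen_diversity_gradient",
    "gen_mag_records",
    "gen_repeat_pool",
    "gen_planted_regression",
    "write_fastq",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class CommunityModel:
    """Parameters of the synthetic community generator.

    Abundance: genus mean log-abundances are N(abundance_mu,
    abundance_sigma^2); each sample jitters every genus mean by an
    independent N(0, sample_sigma^2) log-perturbation before a
    multinomial draw of ``depth`` reads, so between-sample composition
    varies as strongly as it does between ocean stations.

    Carriage: the genus carriage probability is
    logistic(alpha - beta * z + eps) where z is the standardized log
    mean abundance, beta (``density_effect``) is the planted slope of
    declining CRISPR carriage with abundance, and eps ~ N(0,
    noise_sd^2).  Each strain of the genus carries an evidence-level-4
    array independently with that probability.

    Diversity: ``diversity_effect`` (gamma) is the planted slope of
    expected per-sample incidence on Shannon H, used by
    :func:`gen_diversity_gradient` together with ``base_incidence``,
    ``incidence_noise_sd`` and the Dirichlet ``concentration_range``.
    """

    n_samples: int = 135
    n_genera: int = 500
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    sample_sigma: float = 2.0
    depth: int = 10_000
    strains_per_genus: tuple[int, int] = (1, 10)
    max_species_per_genus: int = 3
    carriage_intercept: float = 0.0
    density_effect: float = 2.0
    diversity_effect: float = 0.1
    noise_sd: float = 0.5
    cell_count_mean: float = 5e5
    cell_count_sigma: float = 0.5
    base_incidence: float = 0.1
    incidence_noise_sd: float = 0.05
    concentration_range: tuple[float, float] = (0.1, 30.0)

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genera < 2:
            raise ValueError("need n_samples >= 1 and n_genera >= 2")
        if self.abundance_sigma <= 0 or self.sample_sigma < 0:
            raise ValueError("abundance_sigma must be > 0 and sample_sigma >= 0")
        lo, hi = self.strains_per_genus
        if lo < 1 or hi < lo:
            raise ValueError("strains_per_genus must be a range with 1 <= lo <= hi")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.concentration_range[0] <= 0:
            raise ValueError("Dirichlet concentrations must be positive")


@dataclass
class CommunityDataset:
    table: CountTable
    strains: list[StrainAnnotation]
    truth: dict


def gen_community(model: CommunityModel, seed: int = 0) -> CommunityDataset:
    """Generate a count table, cell counts, and a strain annotation table."""
    rng = np.random.default_rng(seed)
    m = model
    genera = [f"g{i:04d}" for i in range(m.n_genera)]

    log_mean = rng.normal(m.abundance_mu, m.abundance_sigma, m.n_genera)
    z = (log_mean - log_mean.mean()) / log_mean.std()
    p_carry = expit(
        m.carriage_intercept - m.density_effect * z + rng.normal(0, m.noise_sd, m.n_genera)
    )

    counts = np.empty((m.n_genera, m.n_samples), dtype=np.int64)
    for s in range(m.n_samples):
        w = np.exp(log_mean + rng.normal(0, m.sample_sigma, m.n_genera))
        counts[:, s] = rng.multinomial(m.depth, w / w.sum())
    samples = [f"S{j:03d}" for j in range(m.n_samples)]
    frame = pd.DataFrame(counts, index=pd.Index(genera, name="genus"), columns=samples)
    # a sample with no reads at all cannot occur at realistic depth, but guard anyway
    frame = frame.loc[:, frame.sum(axis=0) > 0]
    cell_counts = pd.Series(
        m.cell_count_mean * rng.lognormal(0.0, m.cell_count_sigma, len(frame.columns)),
        index=frame.columns,
    )

    strains: list[StrainAnnotation] = []
    for i, g in enumerate(genera):
        n_strains = int(rng.integers(m.strains_per_genus[0], m.strains_per_genus[1] + 1))
        n_species = int(rng.integers(1, m.max_species_per_genus + 1))
        species_of = rng.integers(0, n_species, n_strains)
        carrier = rng.random(n_strains) < p_carry[i]
        for k in range(n_strains):
            level = 4 if carrier[k] else int(rng.choice([0, 1, 2, 3], p=[0.7, 0.1, 0.1, 0.1]))
            strains.append(
                StrainAnnotation(
                    strain_id=f"{g}_s{species_of[k]}_t{k}",
                    species=f"{g}_s{species_of[k]}",
                    genus=g,
                    evidence_level=level,
                )
            )

    truth = {
        "seed": int(seed),
        "model": asdict(m),
        "genera": genera,
        "log_mean_abundance": log_mean.tolist(),
        "carriage_prob": p_carry.tolist(),
    }
    return CommunityDataset(
        table=CountTable(counts=frame, cell_counts=cell_counts),
        strains=strains,
        truth=truth,
    )


@dataclass
class ReadSimSpec:
    """Parameters of the read simulator.

    ``planted_load`` is the per-read probability of carrying one
    inserted direct repeat (random pool member, random strand, random
    offset); the remaining sequence is i.i.d. background with GC
    content ``background_gc``.  Repeat lengths default to 24-48 bp to
    match real direct repeats.
    """

    n_samples: int = 1
    n_reads: int = 50_000
    read_length: int = 100
    planted_load: float = 0.02
    repeat_pool: tuple[str, ...] | None = None
    n_pool_repeats: int = 20
    repeat_length_range: tuple[int, int] = (24, 48)
    background_gc: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_load <= 1.0:
            raise ValueError("planted_load must be in [0, 1]")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must be in (0, 1)")
        max_rep = (
            max(len(r) for r in self.repeat_pool)
            if self.repeat_pool
            else self.repeat_length_range[1]
        )
        if self.read_length <= max_rep:
            raise ValueError(
                f"read_length {self.read_length} must exceed the longest repeat ({max_rep})"
            )


@dataclass
class ReadsDataset:
    reads: dict[str, list[str]]
    repeat_pool: tuple[str, ...]
    truth: dict


def gen_repeat_pool(
    n: int = 20,
    length_range: tuple[int, int] = (24, 48),
    rng: np.random.Generator | int | None = None,
) -> tuple[str, ...]:
    """Random direct-repeat sequences with lengths in the given range."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pool = []
    for _ in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        pool.append("".join(_BASES[rng.integers(0, 4, length)]))
    return tuple(pool)


def _background_matrix(
    rng: np.random.Generator, n: int, length: int, gc: float
) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=(n, length), p=p)


def gen_reads(spec: ReadSimSpec, seed: int = 0) -> ReadsDataset:
    """Simulate FASTQ-ready reads with a planted CRISPR load per sample.

    The truth manifest records, per sample, the planted load and the
    indices of reads carrying an insertion, plus the repeat pool.
    """
    rng = np.random.default_rng(seed)
    pool = spec.repeat_pool or gen_repeat_pool(
        spec.n_pool_repeats, spec.repeat_length_range, rng
    )
    for r in pool:
        if len(r) >= spec.read_length:
            raise ValueError("repeat longer than read length")
    reads: dict[str, list[str]] = {}
    truth_samples: dict[str, dict] = {}
    for s in range(spec.n_samples):
        sample_id = f"S{s:03d}"
        mat = _background_matrix(rng, spec.n_reads, spec.read_length, spec.background_gc)
        base = _BASES[mat]
        carrier = np.flatnonzero(rng.random(spec.n_reads) < spec.planted_load)
        seqs = ["".join(row) for row in base]
        for idx in carrier:
            rep = pool[int(rng.integers(0, len(pool)))]
            if rng.random() < 0.5:
                rep = reverse_complement(rep)
            off = int(rng.integers(0, spec.read_length - len(rep) + 1))
            seqs[idx] = seqs[idx][:off] + rep + seqs[idx][off + len(rep):]
        reads[sample_id] = seqs
        truth_samples[sample_id] = {
            "planted_load": spec.planted_load,
            "n_reads": spec.n_reads,
            "inserted_read_indices": carrier.tolist(),
        }
    truth = {"seed": int(seed), "spec": asdict(spec), "samples": truth_samples}
    truth["spec"]["repeat_pool"] = list(pool)
    return ReadsDataset(reads=reads, repeat_pool=tuple(pool), truth=truth)


@dataclass
class GradientDataset:
    table: CountTable
    sample_incidence: pd.Series
    truth: dict


def gen_diversity_gradient(model: CommunityModel, seed: int = 0) -> GradientDataset:
    """Samples spanning an evenness gradient with incidence coupled to H.

    Sample evenness is controlled by a log-spaced sweep of the
    symmetric Dirichlet concentration; per-sample incidence is
    clip(base + gamma * H + noise, 0, 1) where H is the realized
    Shannon index of the sample's counts and gamma is
    ``model.diversity_effect``.
    """
    if not np.isfinite(model.diversity_effect):
        raise ValueError("diversity_effect must be finite")
    rng = np.random.default_rng(seed)
    m = model
    conc = np.geomspace(m.concentration_range[0], m.concentration_range[1], m.n_samples)
    genera = [f"g{i:04d}" for i in range(m.n_genera)]
    samples = [f"S{j:03d}" for j in range(m.n_samples)]
    counts = np.empty((m.n_genera, m.n_samples), dtype=np.int64)
    h = np.empty(m.n_samples)
    for j in range(m.n_samples):
        p = rng.dirichlet(np.full(m.n_genera, conc[j]))
        counts[:, j] = rng.multinomial(m.depth, p)
        h[j] = shannon(counts[:, j])
    noise = rng.normal(0.0, m.incidence_noise_sd, m.n_samples)
    incidence = np.clip(m.base_incidence + m.diversity_effect * h + noise, 0.0, 1.0)
    frame = pd.DataFrame(counts, index=pd.Index(genera, name="genus"), columns=samples)
    truth = {
        "seed": int(seed),
        "model": asdict(m),
        "concentration": conc.tolist(),
        "shannon": h.tolist(),
        "sample_incidence": incidence.tolist(),
    }
    return GradientDataset(
        table=CountTable(counts=frame),
        sample_incidence=pd.Series(incidence, index=samples),
        truth=truth,
    )


def gen_mag_records(
    n_with: int = 200,
    n_without: int = 200,
    log_shift: float = 0.5,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[list[MagRecord], dict]:
    """Log-normal MAG abundances with the CRISPR-free group shifted up.

    ``log_shift`` is the planted difference in mean log relative
    abundance (without minus with); positive values reproduce the
    observed pattern that CRISPR-free genomes are more abundant.
    """
    rng = np.random.default_rng(seed)
    records: list[MagRecord] = []
    for k, (n, has, mu) in enumerate(
        [(n_with, True, 0.0), (n_without, False, log_shift)]
    ):
        abund = rng.lognormal(mu - 8.0, sigma, n)  # centered near 1e-3 relative abundance
        for i, a in enumerate(abund):
            records.append(
                MagRecord(
                    mag_id=f"MAG{'w' if has else 'o'}{i:04d}",
                    sample_id="S000",
                    relative_abundance=float(a),
                    has_crispr=has,
                )
            )
    truth = {
        "seed": int(seed),
        "log_shift": log_shift,
        "sigma": sigma,
        "n_with": n_with,
        "n_without": n_without,
    }
    return records, truth


def gen_planted_regression(
    r_squared: float, n: int = 2000, seed: int = 0, slope: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) points with a planted population R^2.

    x ~ N(0, 1) and y = slope * x + eps with the noise variance chosen
    so that the population coefficient of determination equals
    ``r_squared`` exactly: var(eps) = slope^2 * (1 - R^2) / R^2.
    """
    if not 0.0 < r_squared < 1.0:
        raise ValueError("r_squared must be in (0, 1)")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    noise_sd = abs(slope) * np.sqrt((1.0 - r_squared) / r_squared)
    y = slope * x + rng.normal(0.0, noise_sd, n)
    return x, y


def write_fastq(reads: Sequence[str], path, sample_id: str = "S000") -> None:
    """Write reads as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{sample_id}_r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
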