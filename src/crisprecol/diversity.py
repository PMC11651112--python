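"""Diversity vs CRISPR incidence: Shannon index, rarefaction, Bray-Curtis pairing.

Alpha diversity is Shannon's index H = -sum_i p_i ln p_i over genus
relative frequencies (natural log, so H is in nats), computed after
rarefying each sample to a common depth (default 2,000 reads) by
multivariate-hypergeometric subsampling.  Per-sample CRISPR incidence
is the abundance-weighted mean of genus-level incidences, and its
association with H is summarized by ordinary least squares.

Beta diversity enters through a pairing design that controls for alpha
diversity: all pairs of samples whose Shannon indices differ by at most
5% (relative) are formed, and the absolute difference in CRISPR
incidence within a pair is regressed on the pair's Bray-Curtis
dissimilarity 1 - 2*C_ij / (S_i + S_j), where C_ij sums the lesser
counts of genera shared by both samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .density import CountTable
from .incidence import IncidenceMap

__all__ = [
    "DiversityResult",
    "SamplePair",
    "RegressionResult",
    "rarefy",
    "rarefy_table",
    "shannon",
    "sample_incidence",
    "similar_pairs",
    "bray_curtis",
    "complete_pairs",
    "incidence_diversity_regression",
    "beta_incidence_correlation",
    "format_p",
]

logger = logging.getLogger(__name__)

#: p-values below this are reported as exactly 0 in printed output.
P_UNDERFLOW = 1e-300


@dataclass(frozen=True)
class DiversityResult:
    """Shannon diversity of one sample at a given rarefaction depth."""

    sample_id: str
    shannon: float
    depth_used: int

    def __post_init__(self) -> None:
        if self.shannon < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative Shannon index")


@dataclass
class SamplePair:
    """A pair of alpha-diversity-matched samples."""

    sample_i: str
    sample_j: str
    h_i: float
    h_j: float
    bray_curtis: float | None = None
    incidence_diff: float | None = None

    def __post_init__(self) -> None:
        if self.bray_curtis is not None and not 0.0 <= self.bray_curtis <= 1.0 + 1e-12:
            raise ValueError("bray_curtis outside [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    """OLS summary: slope, intercept, r^2, two-sided p for slope, n."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")
        if self.n < 3:
            raise ValueError(f"regression needs n >= 3, got {self.n}")


def _as_series(counts) -> pd.Series:
    if isinstance(counts, pd.Series):
        return counts
    if isinstance(counts, Mapping):
        return pd.Series(counts)
    return pd.Series(np.asarray(counts))


def rarefy(counts, depth: int = 2000, seed=None) -> pd.Series:
    """Subsample a count vector to exactly ``depth`` reads without replacement.

    Draws from the multivariate hypergeometric distribution, so the
    output sums to ``depth`` and never exceeds the input in any genus.
    A vector already summing to ``depth`` is returned unchanged.

    ``seed`` may be an int, a :class:`numpy.random.Generator`, or None.

    Raises
    ------
    ValueError
        If the vector sums to less than ``depth`` (such samples are to
        be excluded from analysis).
    """
    s = _as_series(counts)
    values = s.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError("rarefy requires integer counts")
    ints = np.round(values).astype(np.int64)
    if (ints < 0).any():
        raise ValueError("rarefy requires non-negative counts")
    total = int(ints.sum())
    if total < depth:
        raise ValueError(
            f"sample has {total} reads, fewer than rarefaction depth {depth}"
        )
    if total == depth:
        return pd.Series(ints, index=s.index)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(ints, depth)
    return pd.Series(drawn, index=s.index)


def rarefy_table(
    table: CountTable, depth: int = 2000, seed: int = 0
) -> tuple[CountTable, list[str]]:
    """Rarefy every sample of a table; drop (and log) under-depth samples.

    Each sample gets an independent random stream spawned from ``seed``,
    so results are reproducible and independent of which samples are
    excluded.
    """
    streams = np.random.SeedSequence(seed).spawn(len(table.samples))
    kept: dict[str, pd.Series] = {}
    excluded: list[str] = []
    for s, ss in zip(table.samples, streams):
        try:
            kept[s] = rarefy(table.counts[s], depth=depth, seed=np.random.default_rng(ss))
        except ValueError as e:
            logger.info("excluding sample %r from rarefaction: %s", s, e)
            excluded.append(s)
    if not kept:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    out = pd.DataFrame(kept).reindex(index=table.counts.index)
    cc = table.cell_counts
    if cc is not None:
        cc = cc[cc.index.isin(out.columns)]
    return CountTable(counts=out, cell_counts=cc), excluded


def shannon(counts) -> float:
    """Shannon's index H = -sum_i p_i ln p_i in nats.

    Zero-count genera contribute nothing; an all-zero vector is an
    error.  H is scale-invariant in the counts.
    """
    values = _as_series(counts).to_numpy(float)
    if (values < 0).any():
        raise ValueError("negative counts")
    total = values.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero count vector")
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


def sample_incidence(
    counts, incidence: IncidenceMap, weighted: bool = True
) -> float:
    """Per-sample CRISPR incidence aggregated over annotated genera.

    By default the abundance-weighted mean sum(c_g * I_g) / sum(c_g)
    over genera with positive count and a known incidence; with
    ``weighted=False`` the unweighted mean over those genera.
    """
    if incidence.level != "genus":
        raise ValueError("sample_incidence expects a genus-level IncidenceMap")
    s = _as_series(counts)
    usable = s[(s > 0) & s.index.isin(incidence.values)]
    if usable.empty:
        raise ValueError("no genus with positive count and known incidence")
    inc = np.array([incidence[g] for g in usable.index])
    if not weighted:
        return float(inc.mean())
    w = usable.to_numpy(float)
    return float((w * inc).sum() / w.sum())


def similar_pairs(
    results: Sequence[DiversityResult], tolerance: float = 0.05
) -> list[SamplePair]:
    """All unordered sample pairs with relative Shannon difference <= tolerance.

    The criterion is |H_i - H_j| / max(H_i, H_j) <= tolerance.  The
    degenerate case H_i = H_j = 0 has relative difference 0/0 and is
    *paired* (the absolute difference is zero).  Self-pairs are
    excluded.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if len(results) < 2:
        raise ValueError("similar_pairs requires at least two samples")
    pairs: list[SamplePair] = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            a, b = results[i], results[j]
            top = max(a.shannon, b.shannon)
            if top == 0.0 or abs(a.shannon - b.shannon) / top <= tolerance:
                pairs.append(
                    SamplePair(a.sample_id, b.sample_id, a.shannon, b.shannon)
                )
    return pairs


def bray_curtis(counts_i, counts_j) -> float:
    """Bray-Curtis dissimilarity 1 - 2*C_ij / (S_i + S_j).

    C_ij is the sum over genera of the lesser of the two counts; S_i
    and S_j are the sample totals.  Symmetric, zero for identical
    samples, one for disjoint genus sets.
    """
    a = _as_series(counts_i)
    b = _as_series(counts_j)
    a, b = a.align(b, fill_value=0.0)
    av = a.to_numpy(float)
    bv = b.to_numpy(float)
    s_i, s_j = av.sum(), bv.sum()
    if s_i <= 0 or s_j <= 0:
        raise ValueError("Bray-Curtis undefined for an empty sample")
    c = np.minimum(av, bv).sum()
    return float(1.0 - 2.0 * c / (s_i + s_j))


def complete_pairs(
    pairs: Sequence[SamplePair],
    table: CountTable,
    incidences: Mapping[str, float],
) -> list[SamplePair]:
    """Fill Bray-Curtis and |incidence difference| into pair stubs.

    ``incidences`` maps sample_id -> per-sample CRISPR incidence (see
    :func:`sample_incidence`); ``table`` supplies the count columns the
    dissimilarity is computed on (normally the rarefied counts used for
    Shannon, for comparability).
    """
    out = []
    for p in pairs:
        bc = bray_curtis(table.counts[p.sample_i], table.counts[p.sample_j])
        diff = abs(incidences[p.sample_i] - incidences[p.sample_j])
        out.append(replace(p, bray_curtis=bc, incidence_diff=diff))
    return out


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if len(x) < 3:
        raise ValueError(f"regression needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("regression undefined: zero variance in a variable")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )


def incidence_diversity_regression(
    samples: Sequence[tuple[float, float]]
) -> RegressionResult:
    """OLS of per-sample CRISPR incidence on Shannon diversity.

    ``samples`` is a sequence of (shannon, incidence) points; r^2 is
    the squared Pearson correlation and the p-value is the two-sided
    test of slope != 0.
    """
    arr = np.asarray(samples, float)
    return _ols(arr[:, 0], arr[:, 1])


def beta_incidence_correlation(pairs: Sequence[SamplePair]) -> RegressionResult:
    """OLS of within-pair |incidence difference| on Bray-Curtis dissimilarity.

    Pairs share samples and are therefore not independent; the reported
    p-value ignores this dependence and should be read as descriptive.
    """
    usable = [p for p in pairs if p.bray_curtis is not None and p.incidence_diff is not None]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 completed pairs, got {len(usable)}")
    x = np.array([p.bray_curtis for p in usable])
    y = np.array([p.incidence_diff for p in usable])
    return _ols(x, y)


def format_p(p: float) -> float:
    """Collapse p-values below the reporting underflow (1e-300) to 0."""
    return 0.0 if p < P_UNDERFLOW else p
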