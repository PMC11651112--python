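"""Abundance vs CRISPR incidence: split-half, binned medians, MAG contrast.

Three complementary tests of whether CRISPR carriage associates with
taxon density in a community:

* a per-sample *split-half* comparison — genera sorted by within-sample
  abundance are divided into a less-abundant and a more-abundant half,
  and the abundance-weighted mean CRISPR incidence of the halves is
  compared;
* a pooled *binned-median curve* — (abundance, incidence) observations
  from all samples are sorted by abundance and summarized as the median
  incidence in consecutive bins (default 500 observations per bin),
  optionally after removing genera present in more than 75% of samples;
* a *MAG contrast* — relative abundances of metagenome-assembled
  genomes with and without a high-confidence CRISPR array are compared
  with a two-sided Mann-Whitney rank-sum test.

Absolute abundances are obtained as relative abundance times the
per-sample cell count (e.g. from flow cytometry); the split-half
statistic is invariant to this rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .incidence import IncidenceMap

__all__ = [
    "CountTable",
    "SplitHalfResult",
    "BinnedCurve",
    "MagRecord",
    "read_count_table",
    "read_cell_counts",
    "absolute_abundance",
    "split_half_statistic",
    "split_half_all",
    "abundance_incidence_observations",
    "binned_median_curve",
    "prevalence_filter",
    "mag_density_comparison",
    "read_mag_table",
]


@dataclass
class CountTable:
    """Genus x sample count matrix with optional per-sample cell counts.

    ``counts`` is indexed by genus with one column per sample; entries
    are non-negative and every sample column sums to a positive total.
    ``cell_counts`` (cells per unit volume) must be positive where
    present.
    """

    counts: pd.DataFrame
    cell_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            bad = self.counts.lt(0).any()
            raise ValueError(
                f"negative counts in sample(s) {list(bad[bad].index)[:3]}"
            )
        colsums = self.counts.sum(axis=0)
        if (colsums <= 0).any():
            empty = list(colsums[colsums <= 0].index)[:3]
            raise ValueError(f"sample column(s) with zero total counts: {empty}")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate genus labels in count table")
        if self.cell_counts is not None and (self.cell_counts <= 0).any():
            bad = list(self.cell_counts[self.cell_counts <= 0].index)[:3]
            raise ValueError(f"non-positive cell count(s) for sample(s) {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genera(self) -> list[str]:
        return list(self.counts.index)

    def relative(self) -> pd.DataFrame:
        """Column-normalized relative abundances."""
        return self.counts / self.counts.sum(axis=0)


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (rows = genera, first column ``genus``)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "genus":
        raise ValueError(f"{path}: first column must be 'genus', got {df.columns[0]!r}")
    df = df.set_index("genus")
    values = df.apply(pd.to_numeric, errors="raise")
    neg = values.lt(0)
    if neg.any().any():
        genus = values.index[neg.any(axis=1)][0]
        sample = values.columns[neg.loc[genus]][0]
        raise ValueError(f"{path}: negative count at genus {genus!r}, sample {sample!r}")
    return CountTable(counts=values)


def read_cell_counts(path: str | Path) -> pd.Series:
    """Read per-sample cell counts from TSV ``sample_id<TAB>cell_count``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "cell_count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, cell_count")
    return pd.Series(df["cell_count"].astype(float).values, index=df["sample_id"])


def absolute_abundance(table: CountTable) -> CountTable:
    """Convert counts to absolute abundance: relative abundance x cell count."""
    if table.cell_counts is None:
        raise ValueError("absolute_abundance requires per-sample cell counts")
    missing = [s for s in table.samples if s not in table.cell_counts.index]
    if missing:
        raise ValueError(f"missing cell count(s) for sample(s) {missing[:5]}")
    rel = table.relative()
    absolute = rel * table.cell_counts.reindex(table.samples)
    return CountTable(counts=absolute, cell_counts=table.cell_counts)


@dataclass(frozen=True)
class SplitHalfResult:
    """Weighted incidence of the rare vs common half of one sample."""

    sample_id: str
    low_half_incidence: float
    high_half_incidence: float
    n_genera_used: int

    def __post_init__(self) -> None:
        for v in (self.low_half_incidence, self.high_half_incidence):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"sample {self.sample_id!r}: incidence outside [0, 1]")
        if self.n_genera_used < 2:
            raise ValueError(f"sample {self.sample_id!r}: fewer than 2 genera used")


def split_half_statistic(
    sample_column: pd.Series,
    incidence: IncidenceMap,
    sample_id: str | None = None,
) -> SplitHalfResult:
    """Abundance-weighted incidence of the rare half vs the common half.

    Genera are restricted to those with positive abundance in the
    sample and a known genus-level incidence, then sorted ascending by
    abundance (ties broken by taxon label).  The first ceil(n/2) genera
    form the low (rare) half, the rest the high half; each half's
    incidence is the abundance-weighted mean sum(a_g * I_g) / sum(a_g).

    The statistic is invariant to rescaling all abundances by a
    positive constant, so relative and absolute abundance give the
    same result.
    """
    if incidence.level != "genus":
        raise ValueError("split_half_statistic expects a genus-level IncidenceMap")
    sid = sample_id if sample_id is not None else str(sample_column.name)
    usable = sample_column[(sample_column > 0) & sample_column.index.isin(incidence.values)]
    if len(usable) < 2:
        raise ValueError(
            f"sample {sid!r}: need >=2 genera with positive abundance and "
            f"known incidence, got {len(usable)}"
        )
    order = usable.reset_index()
    order.columns = ["genus", "abundance"]
    order = order.sort_values(["abundance", "genus"], kind="stable")
    n = len(order)
    n_low = math.ceil(n / 2)
    halves = []
    for block in (order.iloc[:n_low], order.iloc[n_low:]):
        w = block["abundance"].to_numpy(float)
        i = np.array([incidence[g] for g in block["genus"]])
        halves.append(float((w * i).sum() / w.sum()))
    return SplitHalfResult(
        sample_id=sid,
        low_half_incidence=halves[0],
        high_half_incidence=halves[1],
        n_genera_used=n,
    )


def split_half_all(table: CountTable, incidence: IncidenceMap) -> pd.DataFrame:
    """Split-half statistic for every sample of a table.

    Samples with fewer than two usable genera are skipped.
    """
    rows = []
    for s in table.samples:
        try:
            r = split_half_statistic(table.counts[s], incidence, sample_id=s)
        except ValueError:
            continue
        rows.append(
            {
                "sample_id": r.sample_id,
                "low_half_incidence": r.low_half_incidence,
                "high_half_incidence": r.high_half_incidence,
                "n_genera_used": r.n_genera_used,
            }
        )
    return pd.DataFrame(rows, columns=[
        "sample_id", "low_half_incidence", "high_half_incidence", "n_genera_used"
    ])


def abundance_incidence_observations(
    table: CountTable, incidence: IncidenceMap
) -> list[tuple[float, float]]:
    """Pool (abundance, incidence) observations over all samples.

    One observation per (genus, sample) pair with positive abundance
    and a known genus incidence.
    """
    if incidence.level != "genus":
        raise ValueError("expects a genus-level IncidenceMap")
    obs: list[tuple[float, float]] = []
    annotated = [g for g in table.genera if g in incidence.values]
    sub = table.counts.loc[annotated]
    for s in table.samples:
        col = sub[s]
        for g, a in col[col > 0].items():
            obs.append((float(a), incidence[g]))
    return obs


@dataclass
class BinnedCurve:
    """Median incidence in consecutive abundance bins.

    ``bins`` has columns ``median_abundance, median_incidence,
    n_observations`` with median_abundance non-decreasing.
    """

    bins: pd.DataFrame

    def __post_init__(self) -> None:
        med = self.bins["median_abundance"].to_numpy()
        if (np.diff(med) < 0).any():
            raise ValueError("bin median abundances must be non-decreasing")


def binned_median_curve(
    observations: Sequence[tuple[float, float]], bin_size: int = 500
) -> BinnedCurve:
    """Smooth pooled observations into per-bin medians.

    Observations are sorted ascending by abundance (ties by incidence,
    then input order) and grouped into consecutive bins of ``bin_size``;
    a trailing incomplete bin is dropped.
    """
    if bin_size < 2:
        raise ValueError(f"bin_size must be >= 2, got {bin_size}")
    if len(observations) < bin_size:
        raise ValueError(
            f"need at least bin_size={bin_size} observations, got {len(observations)}"
        )
    df = pd.DataFrame(observations, columns=["abundance", "incidence"])
    df = df.sort_values(["abundance", "incidence"], kind="stable").reset_index(drop=True)
    n_bins = len(df) // bin_size
    rows = []
    for b in range(n_bins):
        chunk = df.iloc[b * bin_size : (b + 1) * bin_size]
        rows.append(
            {
                "median_abundance": float(chunk["abundance"].median()),
                "median_incidence": float(chunk["incidence"].median()),
                "n_observations": bin_size,
            }
        )
    return BinnedCurve(bins=pd.DataFrame(rows))


def prevalence_filter(table: CountTable, max_prevalence: float = 0.75) -> CountTable:
    """Drop genera present (count > 0) in more than ``max_prevalence`` of samples.

    The boundary is inclusive: a genus present in exactly
    ``max_prevalence`` of samples is retained.  Idempotent.
    """
    prev = (table.counts > 0).mean(axis=1)
    keep = prev.index[prev <= max_prevalence]
    return CountTable(counts=table.counts.loc[keep], cell_counts=table.cell_counts)


@dataclass(frozen=True)
class MagRecord:
    """Relative abundance of one MAG in one sample, with CRISPR presence."""

    mag_id: str
    sample_id: str
    relative_abundance: float
    has_crispr: bool

    def __post_init__(self) -> None:
        if self.relative_abundance < 0:
            raise ValueError(f"MAG {self.mag_id!r}: negative relative abundance")


def mag_density_comparison(records: Iterable[MagRecord]) -> dict:
    """Two-sided Mann-Whitney comparison of MAG abundance by CRISPR status.

    Returns ``n_with, n_without, statistic, p_value, direction`` where
    direction is the sign of (median without) - (median with): positive
    means CRISPR-free MAGs are the more abundant group.
    """
    with_c = [r.relative_abundance for r in records if r.has_crispr]
    without = [r.relative_abundance for r in records if not r.has_crispr]
    if not with_c or not without:
        raise ValueError("both CRISPR-positive and CRISPR-negative MAGs are required")
    res = stats.mannwhitneyu(without, with_c, alternative="two-sided")
    diff = float(np.median(without) - np.median(with_c))
    return {
        "n_with": len(with_c),
        "n_without": len(without),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "direction": int(np.sign(diff)),
    }


def read_mag_table(path: str | Path) -> list[MagRecord]:
    """Read TSV ``mag_id, sample_id, relative_abundance, has_crispr``."""
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str, "sample_id": str})
    required = {"mag_id", "sample_id", "relative_abundance", "has_crispr"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    flags = df["has_crispr"]
    if flags.dtype == object:
        flags = flags.astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        if flags.isna().any():
            raise ValueError(f"{path}: unparseable has_crispr value")
    return [
        MagRecord(row.mag_id, row.sample_id, float(row.relative_abundance), bool(flag))
        for row, flag in zip(df.itertuples(index=False), flags)
    ]
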