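"""Landscape statistics: prophage density, genome-size binning, kernel
density estimates, unimodality testing, trend regression, and group
comparisons.

Per-genome summaries are plain DataFrames with one row per assembly and the
columns: accession, genome_bp (host bp, prophage-excluded), prophage_bp,
n_prophages, density, is_lysogen, is_mag, isolation_year, country, phylum,
species.  Density is always prophage_bp / genome_bp — prophage DNA per base
of host DNA, with the prophage regions excluded from the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dip import DipResult, dip_statistic, dip_test  # noqa: F401  (re-exported)
from .genomes import parse_gtdb_lineage

logger = logging.getLogger(__name__)

__all__ = [
    "BinSpec",
    "KdeResult",
    "TrendResult",
    "MagComparison",
    "prophage_density",
    "build_summaries",
    "summaries_from_truth",
    "bin_by_genome_size",
    "dip_statistic",
    "dip_test",
    "kde",
    "trend_regression",
    "mag_isolate_comparison",
    "verified_fraction_analysis",
]

SUMMARY_COLUMNS = (
    "accession", "genome_bp", "prophage_bp", "n_prophages", "density",
    "is_lysogen", "is_mag", "isolation_year", "country", "phylum", "species",
)


def prophage_density(prophage_bp: float, host_bp: float) -> float:
    """Prophage DNA per base pair of host DNA (host excludes prophages)."""
    if host_bp <= 0:
        raise ValueError(f"host_bp must be positive, got {host_bp}")
    if prophage_bp < 0:
        raise ValueError(f"prophage_bp must be >= 0, got {prophage_bp}")
    return prophage_bp / host_bp


def _merge_metadata(df: pd.DataFrame, metadata: pd.DataFrame | None) -> pd.DataFrame:
    df = df.copy()
    if metadata is not None:
        meta = metadata.rename(columns={"assembly_accession": "accession"})
        df = df.merge(meta, on="accession", how="left", suffixes=("", "_meta"))
    for col, default in (
        ("is_mag", False), ("isolation_year", np.nan), ("country", ""),
        ("gtdb_lineage", ""),
    ):
        if col not in df.columns:
            df[col] = default
    if "isolation_year" not in df.columns or df["isolation_year"].isna().all():
        if "isolation_date" in df.columns:
            from .genomes import parse_isolation_date

            df["isolation_year"] = [parse_isolation_date(v) for v in df["isolation_date"]]
    ranks = df["gtdb_lineage"].map(parse_gtdb_lineage)
    df["phylum"] = [r["phylum"] for r in ranks]
    df["species"] = [r["species"] for r in ranks]
    df["is_mag"] = df["is_mag"].fillna(False).astype(bool)
    return df


def summaries_from_truth(truth, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-genome summaries from a synthetic cohort's ground truth."""
    g = truth.genomes.copy()
    g["density"] = g["prophage_bp"] / g["genome_bp"]
    g["is_lysogen"] = g["n_prophages"] >= 1
    df = _merge_metadata(g, metadata)
    return df[[c for c in SUMMARY_COLUMNS if c in df.columns]]


def build_summaries(
    regions: pd.DataFrame,
    genome_bp: dict[str, int] | pd.Series,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-genome summaries from detector output.

    ``regions`` holds one row per region with columns accession, start, end,
    status; only kept regions contribute prophage bp.  ``genome_bp`` maps
    accession to the total bp of contigs retained for detection (prophage
    included; it is subtracted here so density uses host DNA only).
    """
    gb = pd.Series(genome_bp, name="total_bp")
    kept = regions[regions["status"] == "kept"] if len(regions) else regions
    agg = (
        kept.assign(length=lambda d: d["end"] - d["start"])
        .groupby("accession")["length"]
        .agg(["sum", "count"])
        if len(kept)
        else pd.DataFrame(columns=["sum", "count"])
    )
    df = pd.DataFrame({"accession": gb.index, "total_bp": gb.to_numpy()})
    df = df.merge(
        agg.rename(columns={"sum": "prophage_bp", "count": "n_prophages"}),
        left_on="accession", right_index=True, how="left",
    ).fillna({"prophage_bp": 0, "n_prophages": 0})
    df["prophage_bp"] = df["prophage_bp"].astype(int)
    df["n_prophages"] = df["n_prophages"].astype(int)
    df["genome_bp"] = df["total_bp"] - df["prophage_bp"]
    df["density"] = df["prophage_bp"] / df["genome_bp"]
    df["is_lysogen"] = df["n_prophages"] >= 1
    df = _merge_metadata(df, metadata)
    return df[[c for c in SUMMARY_COLUMNS if c in df.columns]]


@dataclass(frozen=True)
class BinSpec:
    """Left-closed, right-open genome-size bins.

    When the range is not a whole multiple of the step (as with the default
    0 .. 1.2e7 in steps of 1.4e6), the final bin is truncated at the
    maximum; values at or above the maximum are excluded.
    """

    minimum: float = 0.0
    maximum: float = 1.2e7
    step: float = 1.4e6

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.maximum <= self.minimum:
            raise ValueError("maximum must exceed minimum")

    @property
    def edges(self) -> np.ndarray:
        edges = np.arange(self.minimum, self.maximum, self.step)
        return np.append(edges, self.maximum)


def bin_by_genome_size(
    summaries: pd.DataFrame,
    bins: BinSpec | None = None,
    lysogens_only: bool = True,
) -> pd.DataFrame:
    """Mean prophage density and concentration per genome-size bin.

    Genomes at or above the bin maximum are excluded (and counted in the
    log).  With ``lysogens_only`` (the default) only genomes carrying at
    least one prophage contribute, matching analyses reported over
    lysogenic genomes.
    """
    if len(summaries) == 0:
        raise ValueError("summaries must be non-empty")
    bins = bins or BinSpec()
    df = summaries
    if lysogens_only:
        df = df[df["is_lysogen"]]
    over = int((df["genome_bp"] >= bins.maximum).sum())
    if over:
        logger.info("%d genomes >= %g bp excluded from binning", over, bins.maximum)
    df = df[(df["genome_bp"] >= bins.minimum) & (df["genome_bp"] < bins.maximum)]
    edges = bins.edges
    idx = np.digitize(df["genome_bp"].to_numpy(float), edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = df[idx == b]
        rows.append(
            dict(
                bin_left=edges[b],
                bin_right=edges[b + 1],
                n=len(sel),
                mean_density=sel["density"].mean() if len(sel) else np.nan,
                mean_concentration=sel["n_prophages"].mean() if len(sel) else np.nan,
                mean_concentration_per_mbp=(
                    (sel["n_prophages"] / (sel["genome_bp"] / 1e6)).mean()
                    if len(sel)
                    else np.nan
                ),
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KdeResult:
    grid: np.ndarray
    density: np.ndarray
    mode: float  # argmax of the estimate
    bandwidth: float

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def kde(sample, bw_method="scott", grid_points: int = 2048) -> KdeResult:
    """Gaussian kernel density estimate with its mode.

    The evaluation grid pads the sample range by six bandwidths so the
    estimate integrates to 1 (within 1e-3).  Zero-variance samples are
    rejected — use a histogram for those.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("kde requires n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample; use a histogram instead")
    k = sps.gaussian_kde(x, bw_method=bw_method)
    h = float(k.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 6 * h, x.max() + 6 * h, grid_points)
    dens = k(grid)
    return KdeResult(grid=grid, density=dens, mode=float(grid[np.argmax(dens)]), bandwidth=h)


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def trend_regression(x, y) -> TrendResult:
    """Ordinary least squares with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("trend regression requires >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


@dataclass(frozen=True)
class MagComparison:
    mean_mag: float
    mean_isolate: float
    median_mag: float
    median_isolate: float
    p_value: float
    n_mag: int
    n_isolate: int


def mag_isolate_comparison(summaries: pd.DataFrame) -> MagComparison:
    """Compare prophage density between MAGs and isolates (Mann-Whitney U)."""
    mag = summaries[summaries["is_mag"]]["density"].to_numpy(float)
    iso = summaries[~summaries["is_mag"]]["density"].to_numpy(float)
    if len(mag) == 0 or len(iso) == 0:
        raise ValueError("both MAG and isolate groups must be non-empty")
    p = float(sps.mannwhitneyu(mag, iso, alternative="two-sided").pvalue)
    return MagComparison(
        mean_mag=float(mag.mean()),
        mean_isolate=float(iso.mean()),
        median_mag=float(np.median(mag)),
        median_isolate=float(np.median(iso)),
        p_value=p,
        n_mag=len(mag),
        n_isolate=len(iso),
    )


def verified_fraction_analysis(
    regions: pd.DataFrame,
    phylum_first_described: dict[str, float] | pd.Series | None = None,
) -> tuple[pd.DataFrame, TrendResult, TrendResult | None]:
    """Per-phylum verified fraction of proposed prophage DNA.

    ``regions`` needs columns phylum, start, end, verified_bp_fraction
    (kept and discarded regions both count as proposed DNA).  Returns the
    per-phylum table, the regression of verified fraction on proposed bp,
    and — when a first-described year table is supplied — the regression of
    verified fraction on that year.
    """
    df = regions.copy()
    df["proposed_bp"] = df["end"] - df["start"]
    df["verified_bp"] = df["proposed_bp"] * df["verified_bp_fraction"]
    per = (
        df.groupby("phylum")[["proposed_bp", "verified_bp"]]
        .sum()
        .reset_index()
    )
    per["fraction"] = np.where(
        per["proposed_bp"] > 0, per["verified_bp"] / per["proposed_bp"], 0.0
    )
    reg_bp = (
        trend_regression(per["proposed_bp"], per["fraction"])
        if per["proposed_bp"].nunique() >= 3
        else None
    )
    reg_year = None
    if phylum_first_described is not None:
        years = pd.Series(phylum_first_described)
        per["first_described"] = per["phylum"].map(years)
        sub = per.dropna(subset=["first_described"])
        reg_year = trend_regression(sub["first_described"], sub["fraction"])
    return per, reg_bp, reg_year
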