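"""Cis-instrument selection and qualification.

A drug-target MR analysis restricts candidate instruments to the window around
the gene encoding the target (here: *TNFRSF1A* on chromosome 12, GRCh37, with
a small flank), keeps variants strongly associated with the exposure, prunes
them to approximate LD independence by greedy clumping, and screens instrument
strength with the single-variant F statistic (beta/se)², conventionally
requiring F > 10 to rule out weak-instrument bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import LdError
from .gwas_io import LdMatrix, VariantAssociation

__all__ = [
    "GeneRegion",
    "InstrumentRecord",
    "TNFRSF1A_REGION",
    "select_cis",
    "f_statistic",
    "with_f_statistics",
    "ld_clump",
    "filter_instruments",
]


@dataclass(frozen=True)
class GeneRegion:
    """A gene window: 1-based inclusive [start, end] plus a flank on each side."""

    chrom: str
    start: int
    end: int
    flank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def window_start(self) -> int:
        return self.start - self.flank

    @property
    def window_end(self) -> int:
        return self.end + self.flank


#: TNFRSF1A (encodes TNF receptor 1), GRCh37, with the conventional 1 kb flank.
TNFRSF1A_REGION = GeneRegion(chrom="12", start=6_437_923, end=6_451_280, flank=1_000)


@dataclass(frozen=True)
class InstrumentRecord:
    """An exposure association qualified by its instrument-strength F statistic."""

    association: VariantAssociation
    f_stat: float

    def __post_init__(self) -> None:
        if self.f_stat < 0:
            raise ValueError("f_stat must be >= 0")


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def select_cis(table: pd.DataFrame, region: GeneRegion) -> pd.DataFrame:
    """Retain records on ``region.chrom`` with pos in the flanked window (inclusive)."""
    chrom = _norm_chrom(region.chrom)
    mask = (
        table["chrom"].map(_norm_chrom).eq(chrom)
        & (table["pos"] >= region.window_start)
        & (table["pos"] <= region.window_end)
    )
    return table.loc[mask].copy()


def f_statistic(association: VariantAssociation) -> InstrumentRecord:
    """Single-variant instrument strength F = (beta/se)²; symmetric in beta's sign."""
    return InstrumentRecord(association, (association.beta / association.se) ** 2)


def with_f_statistics(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``table`` with an ``f_stat`` column."""
    out = table.copy()
    out["f_stat"] = (out["beta"] / out["se"]) ** 2
    return out


def _clump_order(table: pd.DataFrame) -> pd.DataFrame:
    # ties on p broken by smaller position, then lexicographic rsid, for determinism
    return table.sort_values(["pval", "pos", "rsid"], kind="mergesort")


def ld_clump(table: pd.DataFrame, ld: LdMatrix, r2_threshold: float) -> pd.DataFrame:
    """Greedy LD clumping.

    Candidates are ranked by ascending p-value; the best remaining variant is
    kept and every remaining candidate with r² >= ``r2_threshold`` against it
    is removed, until the pool is empty. Returns kept rows in kept order, so
    every retained pair satisfies r² < ``r2_threshold``.
    """
    if r2_threshold <= 0:
        raise ValueError("r2_threshold must be > 0")
    missing = [r for r in table["rsid"] if r not in set(ld.labels)]
    if missing:
        raise LdError(f"variant(s) absent from the LD matrix: {', '.join(missing)}")
    ordered = _clump_order(table)
    remaining = list(ordered["rsid"])
    kept: list[str] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        i = ld.index(best)
        remaining = [
            r for r in remaining if ld.r[i, ld.index(r)] ** 2 < r2_threshold
        ]
    by_rsid = ordered.set_index("rsid", drop=False)
    return by_rsid.loc[kept].reset_index(drop=True)


def filter_instruments(
    table: pd.DataFrame,
    ld: LdMatrix,
    p_threshold: float = 5e-5,
    r2_threshold: float = 0.001,
    f_threshold: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the full instrument filter: p < p_threshold, LD clump, F > f_threshold.

    All inequalities are strict. Returns the surviving table (with an
    ``f_stat`` column, in clump-kept order) together with a per-stage count
    log ``(stage, n_in, n_out)``. An empty final set triggers a warning, not
    an error — the caller decides whether that aborts the analysis.
    """
    stages = []
    sig = table.loc[table["pval"] < p_threshold]
    stages.append(("p_filter", len(table), len(sig)))
    clumped = ld_clump(sig, ld, r2_threshold) if len(sig) else sig.copy()
    stages.append(("ld_clump", len(sig), len(clumped)))
    scored = with_f_statistics(clumped)
    strong = scored.loc[scored["f_stat"] > f_threshold].reset_index(drop=True)
    stages.append(("f_filter", len(clumped), len(strong)))
    if strong.empty:
        warnings.warn("no instruments survive selection", stacklevel=2)
    log = pd.DataFrame(stages, columns=["stage", "n_in", "n_out"])
    return strong, log
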