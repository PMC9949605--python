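"""End-to-end analysis orchestration: load → harmonize → select → estimate → report.

A single :class:`AnalysisConfig` (built in code or loaded from YAML) drives
the whole drug-target cis-MR analysis. The published study layout maps onto
two configs sharing the same input files: a primary one forcing the single
instrument rs1800693 through the Wald ratio, and a secondary one forcing the
correlated trio rs767455/rs4149570/rs4149577 through the correlated-IVW and
PCA-IVW estimators. Purely statistical selection (p-threshold, LD clumping,
F screening) is used when no explicit instrument list is given.

:func:`make_fixture` writes the published per-variant association tables
(the per-variant CRP and periodontitis associations of the four TNFRSF1A
variants) as a ready-to-run input set, with placeholder positions/alleles and
a placeholder LD matrix, since neither is printed in the source tables.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PipelineError
from .estimators import (
    CausalEstimate,
    invert_direction,
    ivw_correlated,
    ivw_pca,
    wald_ratio,
)
from .gwas_io import HarmonizedSet, LdMatrix, harmonize, read_sumstats, write_sumstats
from .instruments import (
    TNFRSF1A_REGION,
    GeneRegion,
    filter_instruments,
    select_cis,
    with_f_statistics,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_pipeline",
    "make_fixture",
    "published_study_fixture",
]

_KNOWN_METHODS = ("wald", "ivw_correlated", "ivw_pca")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a pipeline run needs, mirroring the YAML layout."""

    exposure_path: str
    outcome_path: str
    ld_path: str
    region: GeneRegion = TNFRSF1A_REGION
    p_threshold: float = 5e-5
    clump_r2: float = 0.001
    f_min: float = 10.0
    instrument_list: Optional[tuple[str, ...]] = None
    methods: tuple[str, ...] = ("wald", "ivw_correlated", "ivw_pca")
    pca_variance_threshold: float = 0.99
    palindromic_eaf_limit: float = 0.42
    invert_direction: bool = False
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ConfigError("at least one method must be requested")
        unknown = [m for m in self.methods if m not in _KNOWN_METHODS]
        if unknown:
            raise ConfigError(
                f"unknown method(s): {', '.join(unknown)}; valid: {', '.join(_KNOWN_METHODS)}"
            )
        if not 0 < self.p_threshold <= 1:
            raise ConfigError("p_threshold must lie in (0, 1]")
        if not 0 < self.clump_r2 <= 1:
            raise ConfigError("clump_r2 must lie in (0, 1]")
        if self.f_min < 0:
            raise ConfigError("f_min must be >= 0")
        if not 0 < self.pca_variance_threshold <= 1:
            raise ConfigError("pca_variance_threshold must lie in (0, 1]")
        if not 0 < self.palindromic_eaf_limit <= 0.5:
            raise ConfigError("palindromic_eaf_limit must lie in (0, 0.5]")
        if self.instrument_list is not None:
            object.__setattr__(self, "instrument_list", tuple(self.instrument_list))
            if not self.instrument_list:
                raise ConfigError("instrument_list, if given, must be non-empty")
        object.__setattr__(self, "methods", tuple(self.methods))

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        region = d.pop("region", None)
        kwargs = {}
        if region is not None:
            try:
                kwargs["region"] = GeneRegion(
                    chrom=str(region["chrom"]),
                    start=int(region["start"]),
                    end=int(region["end"]),
                    flank=int(region.get("flank_bp", region.get("flank", 1000))),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"invalid region spec: {exc}") from exc
        select = d.pop("select", {})
        for yaml_key, attr in (
            ("p_threshold", "p_threshold"),
            ("clump_r2", "clump_r2"),
            ("f_min", "f_min"),
            ("instrument_list", "instrument_list"),
        ):
            if yaml_key in select:
                kwargs[attr] = select[yaml_key]
        for key in ("exposure_path", "outcome_path", "ld_path"):
            if key in d:
                kwargs[key] = str(d.pop(key))
        allowed = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - allowed
        if extra:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(extra))}")
        kwargs.update(d)
        if "methods" in kwargs:
            kwargs["methods"] = tuple(kwargs["methods"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(loaded)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region"] = dataclasses.asdict(self.region)
        d["methods"] = list(self.methods)
        if self.instrument_list is not None:
            d["instrument_list"] = list(self.instrument_list)
        return d


@dataclass
class AnalysisReport:
    """Pipeline output: estimates plus the per-variant and per-stage audit trail."""

    estimates: list[CausalEstimate]
    instrument_table: pd.DataFrame
    selection_log: pd.DataFrame
    harmonization_log: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def estimates_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": e.method,
                "n_snps": e.n_snps,
                "n_components": e.n_components if e.n_components is not None else "",
                "beta_hat": e.beta_hat,
                "se_hat": e.se_hat,
                "or": e.or_point,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(
            rows,
            columns=["method", "n_snps", "n_components", "beta_hat", "se_hat",
                     "or", "ci_low", "ci_high", "pval"],
        )


def _write_report(report: AnalysisReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.estimates_frame().to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    report.instrument_table.to_csv(out_dir / "instruments.tsv", sep="\t", index=False)
    report.selection_log.to_csv(out_dir / "selection_log.tsv", sep="\t", index=False)
    report.harmonization_log.to_csv(out_dir / "harmonization_log.tsv", sep="\t", index=False)
    with open(out_dir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(report.provenance, fh, sort_keys=False)


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full analysis described by ``config``.

    Reads and harmonizes the two studies, restricts to the cis window, selects
    instruments (statistically, or by the explicit ``instrument_list``), runs
    each requested estimator (the Wald ratio only when exactly one instrument
    survives; the multi-instrument estimators for any count), and writes the
    report files into ``config.output_dir`` when set. Deterministic given
    fixed inputs; only the provenance timestamp varies between runs.
    """
    exposure = read_sumstats(config.exposure_path)
    outcome = read_sumstats(config.outcome_path)
    ld = LdMatrix.from_tsv(config.ld_path)

    h = harmonize(exposure, outcome, ld, config.palindromic_eaf_limit)
    stages = [("shared", len(exposure), len(h.log)), ("harmonized", len(h.log), len(h))]

    exp_h = exposure[exposure["rsid"].isin(set(h.rsids))]
    cis = select_cis(exp_h, config.region)
    stages.append(("cis_window", len(h), len(cis)))
    if cis.empty:
        selection_log = pd.DataFrame(stages, columns=["stage", "n_in", "n_out"])
        raise PipelineError(
            "no instruments survive selection (cis window is empty)\n"
            + selection_log.to_string(index=False)
        )

    if config.instrument_list is not None:
        wanted = list(config.instrument_list)
        available = set(cis["rsid"])
        missing = [r for r in wanted if r not in available]
        if missing:
            raise PipelineError(
                "instrument_list variant(s) not available after harmonization/cis "
                f"restriction: {', '.join(missing)}"
            )
        selected = with_f_statistics(
            cis.set_index("rsid", drop=False).loc[wanted].reset_index(drop=True)
        )
        stages.append(("instrument_list", len(cis), len(selected)))
    else:
        selected, filter_log = filter_instruments(
            cis, ld, config.p_threshold, config.clump_r2, config.f_min
        )
        stages.extend(filter_log.itertuples(index=False, name=None))
    selection_log = pd.DataFrame(stages, columns=["stage", "n_in", "n_out"])
    if selected.empty:
        raise PipelineError(
            "no instruments survive selection\n" + selection_log.to_string(index=False)
        )

    h_sel = h.subset(list(selected["rsid"]))
    out_by_rsid = outcome.set_index("rsid")
    instrument_table = pd.DataFrame(
        {
            "rsid": h_sel.rsids,
            "chrom": list(selected["chrom"]),
            "pos": list(selected["pos"]),
            "ea": list(selected["ea"]),
            "nea": list(selected["nea"]),
            "eaf": list(selected["eaf"]),
            "bx": h_sel.bx,
            "sx": h_sel.sx,
            "by": h_sel.by,
            "sy": h_sel.sy,
            "f_stat": list(selected["f_stat"]),
        }
    )

    estimates: list[CausalEstimate] = []
    notes: list[str] = []
    for method in config.methods:
        if method == "wald":
            if len(h_sel) == 1:
                est = wald_ratio(h_sel)
            else:
                notes.append(f"wald skipped: {len(h_sel)} instruments survive")
                continue
        elif method == "ivw_correlated":
            est = ivw_correlated(h_sel)
        else:
            est = ivw_pca(h_sel, config.pca_variance_threshold)
        if config.invert_direction:
            est = invert_direction(est)
        estimates.append(est)
    if not estimates:
        raise PipelineError("no requested method is applicable; " + "; ".join(notes))

    report = AnalysisReport(
        estimates=estimates,
        instrument_table=instrument_table,
        selection_log=selection_log,
        harmonization_log=h.log,
        provenance={
            "config": config.to_dict(),
            "software": f"cismr {__version__}",
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "notes": notes,
            "direction": "per SD decrement of exposure" if config.invert_direction
            else "per SD increment of exposure",
        },
    )
    if config.output_dir:
        _write_report(report, Path(config.output_dir))
    return report


# ---------------------------------------------------------------------------
# Published-table fixture

# Per-variant associations of the four TNFRSF1A variants as published:
# exposure = CRP (N=575,531), outcome = periodontitis (17,353 cases /
# 28,210 controls). Positions and alleles are synthetic placeholders inside
# the gene window (the source tables do not print them); the LD matrix is a
# placeholder too: rs1800693 uncorrelated with the trio, and a uniform signed
# r = +0.84 within the trio, approximating the reported pairwise r² ≈ 0.7.
_PUBLISHED = pd.DataFrame(
    {
        "rsid": ["rs1800693", "rs767455", "rs4149570", "rs4149577"],
        "pos": [6_439_000, 6_441_500, 6_444_000, 6_446_500],
        "ea": ["G", "C", "T", "A"],
        "nea": ["A", "T", "G", "C"],
        "eaf": [0.574, 0.571, 0.374, 0.528],
        "bx": [0.022, 0.020, 0.015, 0.018],
        "sx": [0.002, 0.002, 0.002, 0.002],
        "px": [9.56e-27, 2.39e-22, 5.23e-13, 9.60e-19],
        "by": [0.010, 0.013, 0.004, 0.006],
        "sy": [0.016, 0.016, 0.016, 0.015],
        "py": [0.530, 0.405, 0.799, 0.685],
    }
)
_N_EXPOSURE = 575_531
_N_OUTCOME = 17_353 + 28_210
_TRIO_R = 0.84


def published_study_fixture() -> tuple[pd.DataFrame, pd.DataFrame, LdMatrix]:
    """The published four-variant study as in-memory tables plus placeholder LD."""
    t = _PUBLISHED
    base = {
        "rsid": t["rsid"], "chrom": "12", "pos": t["pos"].astype(np.int64),
        "ea": t["ea"], "nea": t["nea"], "eaf": t["eaf"],
    }
    exposure = pd.DataFrame(
        {**base, "beta": t["bx"], "se": t["sx"], "pval": t["px"], "n": np.int64(_N_EXPOSURE)}
    )
    outcome = pd.DataFrame(
        {**base, "beta": t["by"], "se": t["sy"], "pval": t["py"], "n": np.int64(_N_OUTCOME)}
    )
    r = np.eye(4)
    r[1:, 1:] = _TRIO_R
    np.fill_diagonal(r, 1.0)
    ld = LdMatrix(list(t["rsid"]), r)
    return exposure, outcome, ld


def make_fixture(output_dir: str | Path) -> dict[str, Path]:
    """Write the published-table fixture (exposure.tsv, outcome.tsv, ld.tsv)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    exposure, outcome, ld = published_study_fixture()
    paths = {
        "exposure": write_sumstats(exposure, out / "exposure.tsv"),
        "outcome": write_sumstats(outcome, out / "outcome.tsv"),
        "ld": ld.to_tsv(out / "ld.tsv"),
    }
    return paths
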