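"""Read, write and harmonize GWAS summary statistics and LD matrices.

Summary-statistics tables travel as :class:`pandas.DataFrame` objects with the
canonical columns ``rsid chrom pos ea nea eaf beta se pval n`` and are stored
on disk as tab-separated text with exactly that header. ``ea`` is the effect
allele: the exposure ``beta`` is in trait units per copy of ``ea``, the outcome
``beta`` in log-odds per copy. LD is a signed correlation matrix ``r`` (the
square of which is the familiar r²) over labelled variants.

Harmonization aligns the outcome table to the exposure's effect alleles —
flipping swapped records, resolving strand complements, and applying a
frequency rule to palindromic (A/T, C/G) variants — and returns a
:class:`HarmonizedSet` carrying the aligned effect vectors together with the
matching LD submatrix and a per-variant action log.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import HarmonizationError, LdError, SumstatsError

SUMSTAT_COLUMNS = ("rsid", "chrom", "pos", "ea", "nea", "eaf", "beta", "se", "pval", "n")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(COMPLEMENT)

#: Eigenvalue tolerance below which an LD matrix is declared non-PSD.
PSD_TOL = 1e-8


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association with one trait.

    ``beta`` is the effect per copy of the effect allele ``ea``; ``eaf`` is the
    effect-allele frequency; ``n`` the GWAS sample size.
    """

    rsid: str
    chrom: str
    pos: int
    ea: str
    nea: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        problems = _record_problems(
            self.ea, self.nea, self.eaf, self.se, self.pval, self.pos, self.n
        )
        if problems:
            raise SumstatsError(f"{self.rsid}: " + "; ".join(problems))


def _record_problems(ea, nea, eaf, se, pval, pos, n) -> list[str]:
    out = []
    if ea not in _VALID_ALLELES or nea not in _VALID_ALLELES:
        out.append(f"alleles must be single A/C/G/T bases (got ea={ea!r}, nea={nea!r})")
    elif ea == nea:
        out.append("effect and non-effect allele must differ (ea != nea)")
    if not se > 0:
        out.append(f"se must be > 0 (got {se!r})")
    if not 0 < eaf < 1:
        out.append(f"eaf must lie in (0, 1) (got {eaf!r})")
    if not 0 < pval <= 1:
        out.append(f"pval must lie in (0, 1] (got {pval!r})")
    if pos < 1:
        out.append(f"pos must be >= 1 (got {pos!r})")
    if n < 1:
        out.append(f"n must be >= 1 (got {n!r})")
    return out


def _coerce_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["rsid"] = df["rsid"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["ea"] = df["ea"].astype(str).str.upper()
    df["nea"] = df["nea"].astype(str).str.upper()
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = df[col].astype(float)
    return df[list(SUMSTAT_COLUMNS)]


def validate_sumstats(df: pd.DataFrame, source: str = "<table>") -> None:
    """Raise :class:`SumstatsError` if any row violates the record invariants."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsError(f"{source}: missing mandatory column(s): {', '.join(missing)}")
    errors = []
    for i, row in enumerate(df.itertuples(index=False)):
        problems = _record_problems(row.ea, row.nea, row.eaf, row.se, row.pval, row.pos, row.n)
        if problems:
            errors.append(f"row {i + 1} ({row.rsid}): " + "; ".join(problems))
    if errors:
        raise SumstatsError(f"{source}: invalid rows:\n" + "\n".join(errors))
    if df["rsid"].duplicated().any():
        dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
        raise SumstatsError(f"{source}: duplicated rsid(s): {', '.join(dups)}")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated summary-statistics table.

    Column names are matched case-insensitively against the canonical header.
    Any row violating a record invariant (se <= 0, eaf outside (0,1), ...) is
    rejected with its file line number.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    rename = {c: c.lower() for c in raw.columns}
    raw = raw.rename(columns=rename)
    missing = [c for c in SUMSTAT_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    raw = raw[list(SUMSTAT_COLUMNS)]
    if raw.empty:
        empty = {c: pd.Series(dtype=t) for c, t in zip(
            SUMSTAT_COLUMNS,
            (str, str, np.int64, str, str, float, float, float, float, np.int64),
        )}
        return pd.DataFrame(empty)[list(SUMSTAT_COLUMNS)]

    errors: list[str] = []
    parsed = raw.copy()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        converted = pd.to_numeric(parsed[col], errors="coerce")
        bad = converted.isna() & parsed[col].notna() | parsed[col].isna()
        for idx in parsed.index[bad]:
            # header is line 1, first data row line 2
            errors.append(f"line {idx + 2}: column '{col}' is not numeric: {parsed.at[idx, col]!r}")
        parsed[col] = converted
    if errors:
        raise SumstatsError(f"{path}: unparseable values:\n" + "\n".join(errors))

    df = _coerce_sumstats(parsed)
    for i, row in enumerate(df.itertuples(index=False)):
        problems = _record_problems(row.ea, row.nea, row.eaf, row.se, row.pval, row.pos, row.n)
        if problems:
            errors.append(f"line {i + 2} ({row.rsid}): " + "; ".join(problems))
    if errors:
        raise SumstatsError(f"{path}: invalid rows:\n" + "\n".join(errors))
    if df["rsid"].duplicated().any():
        dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
        raise SumstatsError(f"{path}: duplicated rsid(s): {', '.join(dups)}")
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table in the canonical TSV dialect (lossless round-trip)."""
    validate_sumstats(df, source=str(path))
    path = Path(path)
    df = _coerce_sumstats(df)
    df.to_csv(path, sep="\t", index=False)
    return path


def records(df: pd.DataFrame) -> list[VariantAssociation]:
    """Materialize table rows as :class:`VariantAssociation` records."""
    return [VariantAssociation(**{c: row[c] for c in SUMSTAT_COLUMNS}) for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# LD matrices


@dataclass
class LdMatrix:
    """Signed pairwise correlation ``r`` among labelled variants.

    Symmetric, unit diagonal, entries in [-1, 1], positive semidefinite within
    ``PSD_TOL`` on the smallest eigenvalue. Note the matrix stores signed r,
    not r²; clumping squares it, GLS weighting needs the sign.
    """

    labels: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.labels)
        if self.r.shape != (m, m):
            raise LdError(f"LD matrix shape {self.r.shape} does not match {m} labels")
        if len(set(self.labels)) != m:
            raise LdError("duplicate labels in LD matrix")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise LdError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise LdError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise LdError("LD entries must lie in [-1, 1]")
        if m and np.linalg.eigvalsh(self.r).min() < -PSD_TOL:
            raise LdError(
                f"LD matrix is not positive semidefinite "
                f"(smallest eigenvalue {np.linalg.eigvalsh(self.r).min():.3e})"
            )

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def identity(cls, labels: Sequence[str]) -> "LdMatrix":
        return cls(list(labels), np.eye(len(labels)))

    def index(self, rsid: str) -> int:
        try:
            return self.labels.index(rsid)
        except ValueError:
            raise LdError(f"variant {rsid!r} is absent from the LD matrix") from None

    def submatrix(self, labels: Sequence[str]) -> "LdMatrix":
        """Restrict and reorder to ``labels`` (each must be present)."""
        idx = [self.index(l) for l in labels]
        return LdMatrix(list(labels), self.r[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = pd.DataFrame(self.r, index=self.labels, columns=self.labels)
        frame.to_csv(path, sep="\t", index_label="rsid")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, assume_positive_ld: bool = False) -> "LdMatrix":
        """Read an LD matrix (header row + first column carry rsids).

        ``assume_positive_ld`` treats the input as r² and takes the positive
        square root — only defensible when true signs are unknown; a warning
        is emitted because GLS estimates depend on them.
        """
        frame = pd.read_csv(path, sep="\t", index_col=0)
        r = frame.to_numpy(dtype=float)
        if list(frame.index.astype(str)) != [str(c) for c in frame.columns]:
            raise LdError(f"{path}: row and column labels disagree")
        if assume_positive_ld:
            import warnings

            warnings.warn(
                "interpreting LD input as r-squared and assuming all-positive r; "
                "signed LD is required for exact GLS estimates",
                stacklevel=2,
            )
            r = np.sqrt(np.clip(r, 0.0, 1.0))
        return cls([str(c) for c in frame.columns], r)


# ---------------------------------------------------------------------------
# Harmonization


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome effect vectors plus their LD submatrix.

    Vectors follow the order of ``rsids``, which matches ``ld.labels``. ``log``
    records one action per shared variant: kept / flipped / dropped + reason.
    """

    rsids: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    ld: LdMatrix
    log: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.rsids = [str(r) for r in self.rsids]
        for name in ("bx", "sx", "by", "sy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.rsids)
        if not all(getattr(self, v).shape == (k,) for v in ("bx", "sx", "by", "sy")):
            raise HarmonizationError("harmonized vectors must all have one entry per rsid")
        if self.ld.labels != self.rsids:
            raise HarmonizationError("LD labels must match rsids in order")

    def __len__(self) -> int:
        return len(self.rsids)

    def subset(self, rsids: Sequence[str]) -> "HarmonizedSet":
        """Restrict to ``rsids`` in the given order."""
        pos = {r: i for i, r in enumerate(self.rsids)}
        missing = [r for r in rsids if r not in pos]
        if missing:
            raise HarmonizationError(f"rsid(s) not in harmonized set: {', '.join(missing)}")
        idx = np.array([pos[r] for r in rsids], dtype=int)
        return HarmonizedSet(
            list(rsids),
            self.bx[idx],
            self.sx[idx],
            self.by[idx],
            self.sy[idx],
            self.ld.submatrix(list(rsids)),
            self.log[self.log["rsid"].isin(set(rsids))].reset_index(drop=True),
        )


def _is_palindromic(ea: str, nea: str) -> bool:
    return COMPLEMENT[ea] == nea


def _classify(ea1, nea1, eaf1, ea2, nea2, eaf2, limit):
    """Decide the harmonization action for one shared variant.

    Returns (action, reason, flip) with action in {kept, flipped, dropped};
    flip means the outcome beta must be negated (and its eaf complemented).
    """
    if _is_palindromic(ea1, nea1):
        if {ea2, nea2} != {ea1, nea1}:
            return "dropped", "incompatible alleles", False
        maf1, maf2 = min(eaf1, 1 - eaf1), min(eaf2, 1 - eaf2)
        if maf1 < limit and maf2 < limit:
            flip = (eaf1 < 0.5) != (eaf2 < 0.5)
            action = "flipped" if flip else "kept"
            return action, "palindromic, aligned by frequency", flip
        return "dropped", "palindromic, frequency uninformative", False
    if ea2 == ea1 and nea2 == nea1:
        return "kept", "alleles match", False
    if ea2 == nea1 and nea2 == ea1:
        return "flipped", "effect allele swapped", True
    cea2, cnea2 = COMPLEMENT[ea2], COMPLEMENT[nea2]
    if cea2 == ea1 and cnea2 == nea1:
        return "kept", "strand complement", False
    if cea2 == nea1 and cnea2 == ea1:
        return "flipped", "strand complement, effect allele swapped", True
    return "dropped", "incompatible alleles", False


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LdMatrix,
    palindromic_eaf_limit: float = 0.42,
    ld_aligned_to: str = "exposure",
) -> HarmonizedSet:
    """Align outcome records to the exposure's effect alleles.

    The exposure orientation is the reference: where the outcome's ea/nea are
    swapped (directly or through a strand complement) the outcome beta is
    negated and its eaf complemented. Palindromic variants are aligned by
    allele frequency when both minor-allele frequencies are below
    ``palindromic_eaf_limit`` and dropped otherwise. Variants absent from the
    LD matrix, or with irreconcilable alleles, are dropped with a reason.

    ``ld_aligned_to`` declares which study's allele coding the LD matrix
    follows. With ``"exposure"`` (default, the usual reference-panel
    convention) the submatrix is used as-is; with ``"outcome"`` the rows and
    columns of flipped variants have their signed r negated so the matrix ends
    up in the exposure orientation.
    """
    if ld_aligned_to not in ("exposure", "outcome"):
        raise HarmonizationError("ld_aligned_to must be 'exposure' or 'outcome'")
    if not 0 < palindromic_eaf_limit <= 0.5:
        raise HarmonizationError("palindromic_eaf_limit must lie in (0, 0.5]")
    validate_sumstats(exposure, "exposure")
    validate_sumstats(outcome, "outcome")
    if exposure.empty or outcome.empty:
        raise HarmonizationError("exposure and outcome tables must both be non-empty")

    out_by_rsid = {row.rsid: row for row in outcome.itertuples(index=False)}
    shared = [row for row in exposure.itertuples(index=False) if row.rsid in out_by_rsid]
    if not shared:
        raise HarmonizationError("no shared rsids between exposure and outcome")

    kept_rsids: list[str] = []
    bx, sx, by, sy = [], [], [], []
    flipped: set[str] = set()
    log_rows = []
    ld_labels = set(ld.labels)
    for exp in shared:
        out = out_by_rsid[exp.rsid]
        if exp.rsid not in ld_labels:
            log_rows.append((exp.rsid, "dropped", "absent from LD matrix"))
            continue
        action, reason, flip = _classify(
            exp.ea, exp.nea, exp.eaf, out.ea, out.nea, out.eaf, palindromic_eaf_limit
        )
        log_rows.append((exp.rsid, action, reason))
        if action == "dropped":
            continue
        kept_rsids.append(exp.rsid)
        bx.append(exp.beta)
        sx.append(exp.se)
        by.append(-out.beta if flip else out.beta)
        sy.append(out.se)
        if flip:
            flipped.add(exp.rsid)

    log = pd.DataFrame(log_rows, columns=["rsid", "action", "reason"])
    if not kept_rsids:
        raise HarmonizationError("no harmonizable instruments")

    sub = ld.submatrix(kept_rsids)
    r = sub.r
    if ld_aligned_to == "outcome" and flipped:
        sign = np.array([-1.0 if rs in flipped else 1.0 for rs in kept_rsids])
        r = r * np.outer(sign, sign)
    return HarmonizedSet(kept_rsids, bx, sx, by, sy, LdMatrix(kept_rsids, r), log)
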