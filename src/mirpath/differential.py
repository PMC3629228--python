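"""Differential miRNA expression from paired qPCR profiles.

A profile pairs a stem-enriched cell fraction ("test") with its non-stem
counterpart ("reference") for one cell line.  Expression is measured as a
normalized threshold cycle ΔCt, where lower ΔCt means higher expression.
Relative quantification follows the comparative-Ct convention:

    ΔΔCt     = ΔCt(test) − ΔCt(reference)
    fold     = 2^(−ΔΔCt)
    Δx       = log2(fold) = −ΔΔCt

so a positive ``delta_x`` means the miRNA is up-regulated in the
stem-enriched fraction.  Missing readouts (no amplification) are carried
as NaN and never silently imputed at this stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PairedProfile",
    "QCReport",
    "DifferentialTable",
    "DemirCall",
    "qc_concordance",
    "compute_differential",
    "call_demirs",
    "signature_chance_probability",
    "delta_ct_from_controls",
    "read_profiles_tsv",
    "write_profiles_tsv",
    "demir_table_frame",
    "write_demir_table",
    "write_qc_reports",
]


@dataclass
class PairedProfile:
    """ΔCt readouts for one cell line, test (stem-enriched) vs reference.

    Missing readouts are encoded as NaN in ``dct_test`` / ``dct_reference``;
    the boolean masks are derived properties.
    """

    cell_line_id: str
    mirna_ids: list[str]
    dct_test: np.ndarray
    dct_reference: np.ndarray

    def __post_init__(self) -> None:
        self.mirna_ids = list(self.mirna_ids)
        self.dct_test = np.asarray(self.dct_test, dtype=float)
        self.dct_reference = np.asarray(self.dct_reference, dtype=float)
        n = len(self.mirna_ids)
        if self.dct_test.shape != (n,) or self.dct_reference.shape != (n,):
            raise ValueError(
                f"profile {self.cell_line_id!r}: both fractions must index the "
                f"same {n} miRNAs"
            )
        for name, arr in (("test", self.dct_test), ("reference", self.dct_reference)):
            if np.isinf(arr).any():
                raise ValueError(
                    f"profile {self.cell_line_id!r}: non-finite ΔCt in {name} "
                    "fraction (use NaN for missing readouts)"
                )

    @property
    def missing_test(self) -> np.ndarray:
        return np.isnan(self.dct_test)

    @property
    def missing_reference(self) -> np.ndarray:
        return np.isnan(self.dct_reference)


@dataclass
class QCReport:
    """Concordance check between the two fractions of one profile."""

    cell_line_id: str
    r: float
    n_pairs: int
    min_r: float
    passed: bool


def qc_concordance(profile: PairedProfile, min_r: float = 0.75) -> QCReport:
    """Pearson concordance of test vs reference ΔCt over complete pairs.

    The two fractions assay the same miRNA panel, so their ΔCt vectors are
    expected to be strongly correlated; a low correlation flags a failed
    assay.  Failure is reported, not raised — the remedy (re-assaying) is
    outside the software.

    Parameters
    ----------
    profile : PairedProfile
    min_r : float
        Pass threshold; the profile passes iff ``r > min_r`` (default 0.75).

    Raises
    ------
    ValueError
        If fewer than 3 miRNAs have readouts in both fractions.
    """
    ok = ~profile.missing_test & ~profile.missing_reference
    n = int(ok.sum())
    if n < 3:
        raise ValueError(
            f"profile {profile.cell_line_id!r}: only {n} complete ΔCt pairs; "
            "need at least 3 for a concordance check"
        )
    x = profile.dct_test[ok]
    y = profile.dct_reference[ok]
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        logger.warning(
            "profile %r: constant ΔCt vector, concordance undefined",
            profile.cell_line_id,
        )
        r = float("nan")
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    passed = bool(r > min_r)
    if not passed:
        logger.warning(
            "QC fail for %r: r=%.3f <= %.3f (a replication would be called)",
            profile.cell_line_id, r, min_r,
        )
    return QCReport(profile.cell_line_id, r, n, min_r, passed)


@dataclass
class DifferentialTable:
    """log2 differential expression (Δx = −ΔΔCt), miRNAs × cell lines.

    ``delta_x`` holds NaN wherever either fraction lacked a readout; the
    ``missing`` mask is the NaN pattern.
    """

    mirna_ids: list[str]
    cell_line_ids: list[str]
    delta_x: np.ndarray

    def __post_init__(self) -> None:
        self.mirna_ids = list(self.mirna_ids)
        self.cell_line_ids = list(self.cell_line_ids)
        self.delta_x = np.asarray(self.delta_x, dtype=float)
        if self.delta_x.shape != (len(self.mirna_ids), len(self.cell_line_ids)):
            raise ValueError("delta_x shape does not match the id lists")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.delta_x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.delta_x, index=self.mirna_ids, columns=self.cell_line_ids
        )

    def restrict(self, mirna_ids: list[str]) -> "DifferentialTable":
        """Row subset in the given order (ids must exist)."""
        pos = {m: i for i, m in enumerate(self.mirna_ids)}
        idx = [pos[m] for m in mirna_ids]
        return DifferentialTable(
            list(mirna_ids), self.cell_line_ids, self.delta_x[idx, :]
        )


def compute_differential(profiles: list[PairedProfile]) -> DifferentialTable:
    """Assemble the Δx matrix from paired profiles.

    The miRNA universe is the union across profiles, ordered by first
    appearance; a miRNA absent from a profile is missing in that column.
    ``delta_x[i, j] = −(ΔCt_test − ΔCt_reference)``, NaN where either
    fraction is missing.
    """
    if not profiles:
        raise ValueError("no profiles given")
    mirna_ids: list[str] = []
    seen: set[str] = set()
    for p in profiles:
        for m in p.mirna_ids:
            if m not in seen:
                seen.add(m)
                mirna_ids.append(m)
    cell_line_ids = [p.cell_line_id for p in profiles]
    if len(set(cell_line_ids)) != len(cell_line_ids):
        raise ValueError("duplicate cell line ids among profiles")
    dx = np.full((len(mirna_ids), len(profiles)), np.nan)
    pos = {m: i for i, m in enumerate(mirna_ids)}
    for j, p in enumerate(profiles):
        rows = [pos[m] for m in p.mirna_ids]
        dx[rows, j] = -(p.dct_test - p.dct_reference)
    return DifferentialTable(mirna_ids, cell_line_ids, dx)


@dataclass
class DemirCall:
    """Per-miRNA differential-expression call across cell lines.

    ``direction_per_line`` holds +1 (up), −1 (down) or 0 (below threshold)
    per cell line, and NaN where the readout is missing.  ``direction``
    summarizes the DE lines by majority sign ('up', 'down', 'mixed', or
    'none' when no line is DE).
    """

    mirna_id: str
    n_de_lines: int
    n_missing_lines: int
    direction_per_line: np.ndarray
    is_demir: bool
    is_signature: bool
    direction: str = field(default="none")


def call_demirs(
    table: DifferentialTable,
    fold_threshold: float = 2.0,
    min_de_lines: int = 1,
    signature_min_lines: int = 4,
    max_missing_lines: int = 2,
) -> list[DemirCall]:
    """Call differentially expressed miRNAs and the consistency signature.

    A cell line counts as DE for a miRNA iff its Δx is observed and
    ``|Δx| ≥ log2(fold_threshold)``.  A miRNA is a DEmiR iff it is DE in at
    least ``min_de_lines`` lines and missing in at most
    ``max_missing_lines`` lines (miRNAs with no readout count as
    non-differentially expressed, never as DE).  A DEmiR belongs to the
    cross-line signature iff it is DE in at least ``signature_min_lines``
    lines (default 4 of 6, tolerating line-specific faults).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    n_lines = len(table.cell_line_ids)
    if min_de_lines > n_lines or signature_min_lines > n_lines:
        raise ValueError(
            f"required DE line count exceeds the {n_lines} available cell lines"
        )
    log_thr = math.log2(fold_threshold)
    calls: list[DemirCall] = []
    for i, mirna in enumerate(table.mirna_ids):
        dx = table.delta_x[i, :]
        missing = np.isnan(dx)
        de = ~missing & (np.abs(dx) >= log_thr)
        dirs = np.where(missing, np.nan, np.sign(dx) * de)
        n_de = int(de.sum())
        n_miss = int(missing.sum())
        is_demir = (n_de >= min_de_lines) and (n_miss <= max_missing_lines)
        is_signature = is_demir and (n_de >= signature_min_lines)
        n_up = int(np.nansum(dirs == 1))
        n_down = int(np.nansum(dirs == -1))
        if n_de == 0:
            direction = "none"
        elif n_up > n_down:
            direction = "up"
        elif n_down > n_up:
            direction = "down"
        else:
            direction = "mixed"
        calls.append(
            DemirCall(mirna, n_de, n_miss, dirs, is_demir, is_signature, direction)
        )
    return calls


def signature_chance_probability(
    n_lines: int, min_de_lines: int, per_line_prob: float
) -> float:
    """Chance of a null miRNA reaching the signature by exact binomial tail.

    Returns P(X ≥ min_de_lines) for X ~ Binomial(n_lines, per_line_prob),
    summed exactly.  With 6 lines, a 4-line requirement and a 20% per-line
    DE rate the tail is ≈0.017, i.e. about 1 in 58 signature members would
    be expected by chance alone.
    """
    if not 0.0 < per_line_prob < 1.0:
        raise ValueError("per_line_prob must lie strictly between 0 and 1")
    if min_de_lines < 0 or min_de_lines > n_lines:
        raise ValueError("min_de_lines must lie in [0, n_lines]")
    p = per_line_prob
    return float(
        sum(
            math.comb(n_lines, i) * p**i * (1 - p) ** (n_lines - i)
            for i in range(min_de_lines, n_lines + 1)
        )
    )


def delta_ct_from_controls(
    ct: pd.Series, control_ids: list[str]
) -> pd.Series:
    """Optional ΔCt normalization: Ct minus the mean of control assays.

    For cards carrying normalization-control assays, ΔCt for each miRNA is
    its raw Ct minus the mean Ct of the named controls (controls with
    missing readouts are ignored; all-missing controls raise).
    """
    ctrl = ct.reindex(control_ids).dropna()
    if ctrl.empty:
        raise ValueError("no control assay has a readout")
    return ct.drop(index=[c for c in control_ids if c in ct.index]) - ctrl.mean()


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_profiles_tsv(path) -> list[PairedProfile]:
    """Read long-format profiles: cell_line, fraction, mirna_id, delta_ct.

    ``fraction`` is 'test' or 'reference'; an empty cell or 'NA' in
    ``delta_ct`` (or an absent row) means no readout.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str, "mirna_id": str},
                     na_values=["NA", ""])
    required = {"cell_line", "fraction", "mirna_id", "delta_ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"profile TSV must have columns {sorted(required)}")
    bad = set(df["fraction"]) - {"test", "reference"}
    if bad:
        raise ValueError(f"unknown fraction labels: {sorted(bad)}")
    profiles = []
    for cl, grp in df.groupby("cell_line", sort=False):
        wide = grp.pivot_table(
            index="mirna_id", columns="fraction", values="delta_ct",
            aggfunc="first", dropna=False,
        )
        mirnas = [m for m in grp["mirna_id"].unique()]
        wide = wide.reindex(mirnas)
        for col in ("test", "reference"):
            if col not in wide:
                wide[col] = np.nan
        profiles.append(
            PairedProfile(
                str(cl), mirnas,
                wide["test"].to_numpy(float),
                wide["reference"].to_numpy(float),
            )
        )
    return profiles


def write_profiles_tsv(profiles: list[PairedProfile], path) -> None:
    rows = []
    for p in profiles:
        for frac, arr in (("test", p.dct_test), ("reference", p.dct_reference)):
            for m, v in zip(p.mirna_ids, arr):
                rows.append(
                    (p.cell_line_id, frac, m, "" if np.isnan(v) else f"{v:.6f}")
                )
    out = pd.DataFrame(rows, columns=["cell_line", "fraction", "mirna_id", "delta_ct"])
    out.to_csv(path, sep="\t", index=False)


def demir_table_frame(
    table: DifferentialTable, calls: list[DemirCall]
) -> pd.DataFrame:
    """DEmiR report: per-line Δx plus call summary columns."""
    df = table.to_frame().copy()
    df.columns = [f"delta_x_{c}" for c in table.cell_line_ids]
    df["n_de_lines"] = [c.n_de_lines for c in calls]
    df["n_missing_lines"] = [c.n_missing_lines for c in calls]
    df["is_demir"] = [c.is_demir for c in calls]
    df["is_signature"] = [c.is_signature for c in calls]
    df["direction"] = [c.direction for c in calls]
    df.index.name = "mirna_id"
    return df


def write_demir_table(table: DifferentialTable, calls: list[DemirCall], path) -> None:
    demir_table_frame(table, calls).to_csv(path, sep="\t", float_format="%.6f")


def write_qc_reports(reports: list[QCReport], path) -> None:
    pd.DataFrame(
        [
            {
                "cell_line": r.cell_line_id,
                "r": round(r.r, 6),
                "n_pairs": r.n_pairs,
                "min_r": r.min_r,
                "passed": r.passed,
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)
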