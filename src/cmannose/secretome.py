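"""Differential secretome statistics in the Perseus style.

The screen compares conditioned-medium proteomes of wild-type cells against
C-mannosyltransferase knockouts.  The quantification matrix is a MaxQuant
proteinGroups table (label-free quantification, zeros meaning "not
quantified").  The analysis chain is: remove decoy/contaminant rows, keep
extracellular proteins (GO-CC slim), require >= 2 peptides plus a
replicate-detection rule, log2-transform, impute missing values from a
left-shifted per-column normal (width 0.3 x SD, down-shift 1.8 x SD — the
standard treatment for missing-not-at-random dropout of low-abundance
proteins), then run per-protein two-sided equal-variance t-tests of each
knockout group (both clones pooled, n = 6) against wild type (n = 3) at a
raw p <= 0.05 threshold, with no multiple-testing correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: GO-CC slim terms defining the extracellular compartment filter.
EXTRACELLULAR_TERMS = frozenset(
    {"extracellular matrix", "extracellular region", "extracellular space"}
)


@dataclass(frozen=True)
class Design:
    """Sample layout: WT replicates and per-knockout clone replicates."""

    wt: tuple[str, ...]
    ko: Mapping[str, Mapping[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        if len(self.wt) < 2:
            raise ValueError("design needs at least 2 WT replicates")
        if not self.ko:
            raise ValueError("design needs at least one KO group")

    @property
    def all_samples(self) -> tuple[str, ...]:
        cols = list(self.wt)
        for clones in self.ko.values():
            for reps in clones.values():
                cols.extend(reps)
        return tuple(cols)

    def ko_samples(self, ko: str) -> tuple[str, ...]:
        cols: list[str] = []
        for reps in self.ko[ko].values():
            cols.extend(reps)
        return tuple(cols)

    def cell_lines(self) -> dict[str, tuple[str, ...]]:
        """Columns per cell line: WT plus each individual clone."""
        lines = {"WT": self.wt}
        for ko, clones in self.ko.items():
            for clone, reps in clones.items():
                lines[f"{ko}_{clone}"] = tuple(reps)
        return lines


def default_design() -> Design:
    """WT n=3 against two knockouts, each with two clones of n=3 (n=6 per KO)."""
    return Design(
        wt=("WT_1", "WT_2", "WT_3"),
        ko={
            "DPY19L1": {
                "C1": ("DPY19L1C1_1", "DPY19L1C1_2", "DPY19L1C1_3"),
                "C2": ("DPY19L1C2_1", "DPY19L1C2_2", "DPY19L1C2_3"),
            },
            "DPY19L3": {
                "C1": ("DPY19L3C1_1", "DPY19L3C1_2", "DPY19L3C1_3"),
                "C2": ("DPY19L3C2_1", "DPY19L3C2_2", "DPY19L3C2_3"),
            },
        },
    )


@dataclass
class LfqMatrix:
    """A protein-group quantification matrix with its sample design.

    ``intensities``: linear-scale LFQ values, NaN for missing, indexed by
    group id.  ``meta``: per-group members (accession tuple), peptide count
    and decoy flags, sharing the index.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame
    design: Design

    def __post_init__(self) -> None:
        missing = [c for c in self.design.all_samples if c not in self.intensities]
        if missing:
            raise ValueError(f"intensity matrix lacks design samples: {missing}")
        if not self.intensities.index.equals(self.meta.index):
            raise ValueError("intensities and meta must share an index")
        vals = self.intensities[list(self.design.all_samples)].to_numpy(float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("non-missing LFQ intensities must be positive")

    def __len__(self) -> int:
        return len(self.intensities)

    @property
    def group_ids(self) -> pd.Index:
        return self.intensities.index

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (non-missing LFQ)."""
        return self.intensities[list(self.design.all_samples)].notna()

    def subset(self, ids: Sequence[str]) -> "LfqMatrix":
        return LfqMatrix(
            self.intensities.loc[list(ids)].copy(),
            self.meta.loc[list(ids)].copy(),
            self.design,
        )


@dataclass(frozen=True)
class FilterReport:
    """Row counts after each sequential filter stage (non-increasing)."""

    initial: int
    after_decoy_removal: int
    after_extracellular: int
    after_identification: int
    final: int
    detected_in_all_lines: int
    unannotated: int = 0

    def __post_init__(self) -> None:
        seq = (
            self.initial,
            self.after_decoy_removal,
            self.after_extracellular,
            self.after_identification,
            self.final,
        )
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"filter counts must be non-increasing: {seq}")

    def as_dict(self) -> dict[str, int]:
        return {
            "initial": self.initial,
            "after_decoy_removal": self.after_decoy_removal,
            "after_extracellular": self.after_extracellular,
            "after_identification": self.after_identification,
            "final": self.final,
            "detected_in_all_lines": self.detected_in_all_lines,
            "unannotated": self.unannotated,
        }


@dataclass(frozen=True)
class ImputeConfig:
    """Left-shifted normal imputation parameters (Perseus-style).

    ``width`` is the SD of the imputation distribution as a fraction of the
    observed column SD; ``downshift`` shifts its mean down by that many
    column SDs.  Applied separately per sample column.
    """

    width: float = 0.3
    downshift: float = 1.8
    per_column: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("imputation width must be positive")


@dataclass
class DifferentialResult:
    """Per-protein fold changes and t-test results for one KO-vs-WT contrast.

    ``table`` columns: log2_fc (mean KO − mean WT), t, p, significant.
    """

    table: pd.DataFrame
    group_a: tuple[str, ...]  # WT columns
    group_b: tuple[str, ...]  # KO columns
    alpha: float = 0.05

    @property
    def significant_ids(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def _group_detected(det: pd.DataFrame, design: Design) -> pd.Series:
    """Replicate-detection rule: >=2 WT replicates, or >=1 replicate in each
    clone of the same KO."""
    ok = det[list(design.wt)].sum(axis=1) >= 2
    for ko, clones in design.ko.items():
        both = pd.Series(True, index=det.index)
        for reps in clones.values():
            both &= det[list(reps)].sum(axis=1) >= 1
        ok |= both
    return ok


def filter_secretome(
    matrix: LfqMatrix,
    go_annotation: Mapping[str, Iterable[str]],
    min_peptides: int = 2,
    extracellular_terms: frozenset[str] = EXTRACELLULAR_TERMS,
) -> tuple[LfqMatrix, FilterReport]:
    """Apply the screen's sequential filters and report stagewise counts.

    Stages: (1) drop contaminant / reverse / only-identified-by-site rows;
    (2) keep groups with any member annotated with an extracellular GO-CC
    slim term (accessions without annotation count as not extracellular and
    are tallied in the report); (3) keep groups identified by at least
    ``min_peptides`` peptides AND passing the replicate-detection rule.
    """
    meta = matrix.meta
    initial = len(matrix)

    decoy = (
        meta["contaminant"].astype(bool)
        | meta["reverse"].astype(bool)
        | meta["only_by_site"].astype(bool)
    )
    keep1 = meta.index[~decoy]

    ann = {acc: frozenset(terms) for acc, terms in go_annotation.items()}
    unannotated = 0
    extracellular: list[str] = []
    for gid in keep1:
        members = meta.loc[gid, "members"]
        member_terms = []
        for acc in members:
            if acc in ann:
                member_terms.append(ann[acc])
            else:
                unannotated += 1
        if any(terms & extracellular_terms for terms in member_terms):
            extracellular.append(gid)

    sub = matrix.subset(extracellular)
    det = sub.detected()
    ok = (sub.meta["peptides"] >= min_peptides) & _group_detected(det, matrix.design)
    keep3 = list(sub.group_ids[ok])

    out = matrix.subset(keep3)
    det3 = out.detected()
    lines = matrix.design.cell_lines()
    in_all = pd.Series(True, index=det3.index)
    for cols in lines.values():
        in_all &= det3[list(cols)].sum(axis=1) >= 1

    report = FilterReport(
        initial=initial,
        after_decoy_removal=len(keep1),
        after_extracellular=len(extracellular),
        after_identification=len(keep3),
        final=len(keep3),
        detected_in_all_lines=int(in_all.sum()),
        unannotated=unannotated,
    )
    return out, report


def log2_and_impute(
    matrix: LfqMatrix | pd.DataFrame,
    cfg: ImputeConfig = ImputeConfig(),
) -> pd.DataFrame:
    """Log2-transform and fill missing values from a left-shifted normal.

    Each missing cell of column ``c`` is drawn from
    Normal(mean_c − downshift·sd_c, (width·sd_c)²), with mean and SD taken
    over the observed (log2) values of that column.  Seeded and reproducible;
    a column with fewer than two observed values raises, naming the column.
    """
    if isinstance(matrix, LfqMatrix):
        df = matrix.intensities[list(matrix.design.all_samples)]
    else:
        df = matrix
    log2 = np.log2(df.where(df > 0))
    rng = np.random.default_rng(cfg.seed)
    out = log2.copy()
    for col in out.columns:
        observed = out[col].dropna()
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValueError(
                f"column {col!r} has {len(observed)} observed values; "
                "cannot estimate an imputation distribution"
            )
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - cfg.downshift * sd, cfg.width * sd, size=n_missing)
        out.loc[out[col].isna(), col] = draws
    return out


def differential_test(
    matrix: pd.DataFrame,
    wt_labels: Sequence[str],
    ko_labels: Sequence[str],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> DifferentialResult:
    """Row-wise two-sided t-test of KO against WT on complete log2 values.

    Equal-variance (Student) by default; fold change is mean(KO) − mean(WT)
    in log2.  Rows with zero variance on both sides and equal means get
    p = 1 by convention; zero variance with unequal means yields the
    smallest positive float (p is never exactly 0).
    """
    if len(wt_labels) < 2 or len(ko_labels) < 2:
        raise ValueError("need at least 2 samples per side")
    a = matrix[list(wt_labels)].to_numpy(float)
    b = matrix[list(ko_labels)].to_numpy(float)
    fc = b.mean(axis=1) - a.mean(axis=1)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    t = np.atleast_1d(np.asarray(t, dtype=float)).copy()
    p = np.atleast_1d(np.asarray(p, dtype=float)).copy()
    bad = ~np.isfinite(p)
    if bad.any():
        equal = np.isclose(fc, 0.0)
        p[bad & equal], t[bad & equal] = 1.0, 0.0
        unequal = bad & ~equal
        p[unequal] = np.finfo(float).tiny
        t[unequal] = np.sign(fc[unequal]) * np.inf
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "log2_fc": fc,
            "t": t,
            "p": p,
            "significant": p <= alpha,
        },
        index=matrix.index,
    )
    return DifferentialResult(table, tuple(wt_labels), tuple(ko_labels), alpha)


def per_clone_fold_changes(
    matrix: pd.DataFrame,
    wt_labels: Sequence[str],
    clone_sets: Mapping[str, Mapping[str, Sequence[str]]],
) -> pd.DataFrame:
    """Fold change of every KO sample against the mean WT level, per protein.

    Returns one column per KO sample (log2 sample − mean WT) plus a
    ``<KO>_mean`` column: the mean of the per-sample fold changes of that KO.
    """
    wt_mean = matrix[list(wt_labels)].mean(axis=1)
    out = pd.DataFrame(index=matrix.index)
    for ko, clones in clone_sets.items():
        sample_cols = []
        for reps in clones.values():
            for s in reps:
                out[s] = matrix[s] - wt_mean
                sample_cols.append(s)
        out[f"{ko}_mean"] = out[sample_cols].mean(axis=1)
    return out
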