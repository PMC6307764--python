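"""Expression matrices, differential expression and within-group correlation.

The pipeline works on a single log2-scale expression matrix holding genes,
transcription factors and mature miRNAs as rows and case/control samples as
columns.  This module loads and validates that matrix, collapses duplicate
probes, computes per-feature differential expression (a self-contained
empirical-Bayes moderated t, or Welch's t), applies the SDE
(significantly-differentially-expressed) filter, and computes Spearman rank
correlations with significance separately within the case and control groups
— the ingredients consumed by the loop-scoring stage.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

log = logging.getLogger(__name__)

GROUPS = ("case", "control")
CLASSES = ("gene", "TF", "miRNA")

#: Minimum samples per group for correlation scoring; the differential
#: co-expression statistic divides by n - 3.
MIN_GROUP_N = 4


class StudyError(ValueError):
    """Raised for malformed expression input (contract violations)."""


@dataclass
class ExpressionStudy:
    """Matched case/control expression matrix with per-feature classes.

    Parameters
    ----------
    features : list of str
        Feature identifiers (gene symbols, TF symbols, mature miRNA names);
        unique after preprocessing.
    samples : list of str
        Sample identifiers, one per matrix column.
    values : ndarray of shape (n_features, n_samples)
        Log2-scale expression intensities.
    labels : list of str
        Per-sample group tag, each ``"case"`` or ``"control"``.
    feature_class : dict
        Maps every feature to ``"gene"``, ``"TF"`` or ``"miRNA"``.
    """

    features: list[str]
    samples: list[str]
    values: np.ndarray
    labels: list[str]
    feature_class: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise StudyError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if len(set(self.features)) != len(self.features):
            dupes = [f for f, c in _count(self.features).items() if c > 1]
            raise StudyError(f"duplicate feature IDs after preprocessing: {dupes[:5]}")
        if len(self.labels) != len(self.samples):
            raise StudyError("one label per sample required")
        bad = sorted(set(self.labels) - set(GROUPS))
        if bad:
            raise StudyError(f"unknown group labels {bad}; expected {GROUPS}")
        missing = [f for f in self.features if f not in self.feature_class]
        if missing:
            raise StudyError(f"features without a class: {missing[:5]}")
        badc = sorted({c for c in self.feature_class.values()} - set(CLASSES))
        if badc:
            raise StudyError(f"unknown feature classes {badc}; expected {CLASSES}")
        self._index = {f: i for i, f in enumerate(self.features)}
        lab = np.asarray(self.labels)
        self._case_cols = np.flatnonzero(lab == "case")
        self._ctrl_cols = np.flatnonzero(lab == "control")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_case(self) -> int:
        return len(self._case_cols)

    @property
    def n_control(self) -> int:
        return len(self._ctrl_cols)

    def group_columns(self, group: str) -> np.ndarray:
        if group == "case":
            return self._case_cols
        if group == "control":
            return self._ctrl_cols
        raise StudyError(f"unknown group {group!r}")

    def group_matrix(self, group: str) -> np.ndarray:
        return self.values[:, self.group_columns(group)]

    def row(self, feature: str) -> np.ndarray:
        try:
            return self.values[self._index[feature]]
        except KeyError:
            raise StudyError(f"feature {feature!r} not in study") from None

    def index_of(self, feature: str) -> int:
        return self._index[feature]

    def __contains__(self, feature: str) -> bool:
        return feature in self._index

    def of_class(self, cls: str) -> list[str]:
        return [f for f in self.features if self.feature_class[f] == cls]


@dataclass
class DiffExpResult:
    """Differential expression of one feature (case vs control)."""

    feature: str
    p: float
    log2fc: float
    t: float
    method: str
    is_sde: bool = False
    flagged: bool = False  # zero variance in both groups

    @property
    def fold_change(self) -> float:
        """Linear fold change, 2**log2fc (log2-scale input assumed)."""
        return float(2.0 ** self.log2fc)


@dataclass
class CorrResult:
    """Spearman correlation of one feature pair within one sample group."""

    r: float
    p: float
    n: int
    flagged: bool = False  # constant vector; r/p are placeholders


def _count(xs: Iterable[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for x in xs:
        out[x] = out.get(x, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a feature->class TSV with columns ``feature_id`` and ``class``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("feature_id", "class"):
        if col not in df.columns:
            raise StudyError(f"class map {path} lacks column {col!r}")
    out: dict[str, str] = {}
    for fid, cls in zip(df["feature_id"], df["class"]):
        if fid in out and out[fid] != cls:
            raise StudyError(f"feature {fid!r} assigned conflicting classes")
        out[fid] = cls
    return out


def load_study(
    expr_path: str | Path,
    labels_path: str | Path,
    class_map: Mapping[str, str] | str | Path,
) -> ExpressionStudy:
    """Load an expression TSV plus labels, collapsing duplicate feature rows.

    Duplicate rows for the same feature (multiple probes per gene) are
    collapsed by arithmetic mean.  Features absent from ``class_map`` are
    dropped with a logged count.  Every matrix sample must appear in the
    labels file; any non-numeric cell is a hard error naming its row and
    column.
    """
    if not isinstance(class_map, Mapping):
        class_map = read_class_map(class_map)

    raw = pd.read_csv(expr_path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise StudyError(f"{expr_path}: expected feature column plus >=1 sample")
    feat_col = raw.columns[0]
    samples = list(raw.columns[1:])
    numeric = raw[samples].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw[samples].notna()
    orig_na = raw[samples].isna()
    if bad.any().any() or orig_na.any().any():
        mask = (bad | orig_na).to_numpy()
        i, j = np.argwhere(mask)[0]
        raise StudyError(
            f"{expr_path}: non-numeric cell at feature "
            f"{raw[feat_col].iloc[i]!r}, sample {samples[j]!r}"
        )
    numeric.index = raw[feat_col].astype(str)

    # collapse duplicate probes by arithmetic mean, preserving first-seen order
    if numeric.index.has_duplicates:
        n_before = len(numeric)
        order = list(dict.fromkeys(numeric.index))
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
        log.info("collapsed %d duplicate rows by mean", n_before - len(numeric))

    keep = [f for f in numeric.index if f in class_map]
    dropped = len(numeric) - len(keep)
    if dropped:
        log.info("dropped %d features absent from the class map", dropped)
    numeric = numeric.loc[keep]

    lab_df = pd.read_csv(labels_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in lab_df.columns:
            raise StudyError(f"labels file {labels_path} lacks column {col!r}")
    lab_map = dict(zip(lab_df["sample_id"], lab_df["group"]))
    missing = [s for s in samples if s not in lab_map]
    if missing:
        raise StudyError(f"labels file missing sample {missing[0]!r}")

    return ExpressionStudy(
        features=list(numeric.index),
        samples=samples,
        values=numeric.to_numpy(dtype=float),
        labels=[lab_map[s] for s in samples],
        feature_class={f: class_map[f] for f in numeric.index},
    )


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-12, maxit: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by safeguarded Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    x = 0.5 + 1.0 / y
    for _ in range(maxit):
        f = float(special.polygamma(1, x)) - y
        if abs(f) < tol * y:
            break
        step = f / float(special.polygamma(2, x))
        x = max(x - step, 1e-8)
    return x


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (df0, s0^2) by moment matching on log variances.

    Models per-feature sample variances as scaled-F draws around a common
    prior variance; matches the mean and spread of log(s^2) using digamma /
    trigamma moments.  Returns ``df0 = inf`` when the observed spread is no
    larger than pure chi-square noise (complete shrinkage).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    e = np.log(s2[ok]) - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    target = evar - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        return math.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(target)
    s02 = float(np.exp(emean + special.digamma(half_d0) - math.log(half_d0)))
    return 2.0 * half_d0, s02


def differential_expression(
    study: ExpressionStudy,
    method: str = "moderated_t",
    p_threshold: float = 0.01,
    fc_threshold: float = 1.2,
) -> list[DiffExpResult]:
    """Per-feature two-sided differential expression, case minus control.

    ``moderated_t`` shrinks per-feature pooled variances toward a common
    prior estimated by moment matching across all features and tests with
    the augmented degrees of freedom; ``welch_t`` is the unequal-variance
    two-sample t test.  ``log2fc`` is the difference of group means on the
    log2 scale.  Features constant in both groups are flagged with p = 1.
    """
    if method not in ("moderated_t", "welch_t"):
        raise ValueError(f"unknown method {method!r}")
    case = study.group_matrix("case")
    ctrl = study.group_matrix("control")
    n1, n0 = case.shape[1], ctrl.shape[1]
    if n1 == 0 or n0 == 0:
        raise StudyError("both groups must be non-empty")
    m1 = case.mean(axis=1)
    m0 = ctrl.mean(axis=1)
    log2fc = m1 - m0
    v1 = case.var(axis=1, ddof=1) if n1 > 1 else np.zeros(len(m1))
    v0 = ctrl.var(axis=1, ddof=1) if n0 > 1 else np.zeros(len(m0))
    flat = (v1 <= 0) & (v0 <= 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "welch_t":
            se2 = v1 / n1 + v0 / n0
            tstat = log2fc / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / max(n1 - 1, 1) + (v0 / n0) ** 2 / max(n0 - 1, 1))
            pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        else:
            df_res = n1 + n0 - 2
            if df_res < 1:
                raise StudyError("moderated_t needs n_case + n_control >= 3")
            s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df_res
            df0, s02 = _squeeze_variances(s2, df_res)
            if math.isinf(df0):
                s2_post = np.full_like(s2, s02)
                df_tot = np.inf
            else:
                s2_post = (df0 * s02 + df_res * s2) / (df0 + df_res)
                df_tot = df_res + df0
            tstat = log2fc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
            if math.isinf(df_tot):
                pvals = 2.0 * stats.norm.sf(np.abs(tstat))
            else:
                pvals = 2.0 * stats.t.sf(np.abs(tstat), df_tot)

    pvals = np.where(flat, 1.0, np.nan_to_num(pvals, nan=1.0))
    tstat = np.where(flat, 0.0, np.nan_to_num(tstat, nan=0.0))
    if flat.any():
        log.info("%d features constant in both groups flagged with p=1", int(flat.sum()))

    out = []
    for i, f in enumerate(study.features):
        p = float(min(max(pvals[i], 0.0), 1.0))
        fc = 2.0 ** log2fc[i]
        out.append(
            DiffExpResult(
                feature=f,
                p=p,
                log2fc=float(log2fc[i]),
                t=float(tstat[i]),
                method=method,
                is_sde=bool(p < p_threshold and max(fc, 1.0 / fc) > fc_threshold),
                flagged=bool(flat[i]),
            )
        )
    return out


def sde_filter(
    results: Sequence[DiffExpResult],
    p_threshold: float = 0.01,
    fc_threshold: float = 1.2,
) -> set[str]:
    """Features passing p < p_threshold and two-sided fold change > fc_threshold.

    The fold-change rule uses max(FC, 1/FC) so down-regulation passes
    symmetrically.
    """
    if p_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = set()
    for r in results:
        fc = r.fold_change
        if r.p < p_threshold and max(fc, 1.0 / fc) > fc_threshold:
            out.add(r.feature)
    return out


# ---------------------------------------------------------------------------
# Within-group Spearman correlation
# ---------------------------------------------------------------------------

def _spearman_p_from_r(r: float, n: int) -> float:
    """Two-sided p for Spearman r via the t approximation with n-2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p by full enumeration (n <= 8 only)."""
    n = len(x)
    if n > 8:
        raise ValueError("exact Spearman p supported for n <= 8 only")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r_obs = _rank_corr(rx, ry)
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (pc @ rxc) / denom
    rs = np.nan_to_num(rs, nan=0.0)
    return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    if denom == 0:
        return 0.0
    return float((rxc @ ryc) / denom)


def spearman_group(
    study: ExpressionStudy,
    feature_a: str,
    feature_b: str,
    group: str,
    exact: bool = False,
) -> CorrResult:
    """Spearman correlation of two features within one sample group.

    Uses midranks for ties; the two-sided p comes from the t approximation
    ``t = r * sqrt((n-2)/(1-r^2))`` (p = 0 when |r| = 1), or from exact
    permutation enumeration when ``exact`` is set (n <= 8).  A constant
    vector yields r = 0, p = 1, flagged, so a flat probe cannot abort a
    genome-wide run.
    """
    cols = study.group_columns(group)
    n = len(cols)
    if n < MIN_GROUP_N:
        raise StudyError(f"group {group!r} has {n} samples; need >= {MIN_GROUP_N}")
    x = study.row(feature_a)[cols]
    y = study.row(feature_b)[cols]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.debug("constant vector for %s/%s in %s", feature_a, feature_b, group)
        return CorrResult(r=0.0, p=1.0, n=n, flagged=True)
    r = _rank_corr(stats.rankdata(x), stats.rankdata(y))
    p = _exact_spearman_p(x, y) if exact else _spearman_p_from_r(r, n)
    return CorrResult(r=r, p=p, n=n)
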